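# Methods

This note documents the models and algorithms behind `tethermorph`: what
the synthetic-data generator simulates and deliberately does not, how each
measurement stage works, which constants were calibrated and how, and what
the test suite's passing does and does not establish about real scans.

## Synthetic topographs

### Molecule model

Molecules are modelled as surface-adsorbed, effectively planar polymers: a
discrete two-dimensional worm-like chain whose successive turning angles
are i.i.d. Gaussian with variance `step / Lp`, giving the planar tangent
correlation `exp(-s / 2Lp)` for persistence length `Lp`. The closed form
`<R²> = 2λL − 2λ²(1 − e^{−L/λ})` with `λ = 2Lp` is implemented alongside
the sampler and pinned by a Monte-Carlo test. The chain has no excluded
volume; self-crossing molecules occur at realistic rates and are rejected
downstream as untraceable, as a human would reject overlapping molecules.

Structural features decorate the backbone:

* **Splays.** Each terminus is independently splayed with probability
  `splay_prob_per_end` (default 0.6164, the value for which the both-ends
  fraction is 0.38 and the at-least-one fraction 0.85 under independence).
  A splayed end replaces the terminal sub-path of arc length equal to the
  mean of its two arm lengths (arms ~ N(20, 5) nm, clipped to [8, L/3])
  with two gently curved arms diverging at ±28° ± jitter, so that the
  length an annotator measures — averaging paired arms — matches the drawn
  contour.
* **Bubble.** With probability `bubble_prob` a central sub-path is replaced
  by two circular-arc strands sharing its endpoints, bulging to opposite
  sides. Strand lengths are drawn with a common Gaussian component and a
  small asymmetry; the chord is solved numerically so the strands are
  `bubble_lateral_offset_nm` (default 8 nm) apart at mid-span, clamped to
  the geometric limits for very asymmetric pairs. The bubble centre sits at
  backbone fraction 0.48 (the hinge region). Draws whose bubble cannot fit
  in the available stalk of a short molecule are regenerated bubble-free.
* **Globules and label.** Spherical caps: GFP (radius 3.5 nm, apex 2.5 nm)
  at the N tip(s), the smaller GRIP domain (3.0 nm, 2.0 nm) at the C
  tip(s), and optionally an antibody blob (5.0 nm, 4.0 nm) offset 4 nm
  laterally from the backbone at the label position. The N/C height
  contrast is what the orientation step reads.

Ground truth per molecule records the drawn features and
`true_contour_length_nm`, defined as the arc length an ideal tracer would
report (remaining duplex + averaged arms + averaged strands); by
construction this stays within one or two nanometres of the drawn contour
length.

### Rendering

Placed geometries (uniform random anchor and orientation; placements
overlapping an existing molecule's bounding box by more than 60% are
re-drawn a bounded number of times; border contact is recorded, never
prevented) are rasterized as flat-top ridges of height 1.5 nm and ~1 nm
half-width, with globules as spherical caps, combined by maximum. Heights
were chosen so all features fit the ~2.5 nm Z range of real scans while
remaining separable: ridge 1.5 < GRIP 2.0 < GFP 2.5 < antibody 4.0 nm.

Tip convolution is grayscale dilation with a spherical tip of radius
`tip_radius_nm` (default 3 nm, the middle of the 2–5 nm range of sharp
probes): the image is the maximum over the footprint of surface height
plus the (negative) tip profile, which preserves the apex height of
isolated convex features and broadens them laterally. A brute-force
neighbourhood-max oracle pins the implementation exactly. Scan nuisances
follow: a random-orientation plane gradient (0.004 nm/px), per-scan-line
offsets (SD 0.3 nm), and i.i.d. Gaussian height noise (SD 0.15 nm).

Determinism: one root seed spawns one child stream per molecule and per
field, so the population's ground truth does not depend on batching.

### Presets (the study conditions)

| preset | contour (nm) | Lp (nm) | splay/end | bubble p | strands (nm) |
|---|---|---|---|---|---|
| `wt` | 145 ± 15 | 50 | 0.6164 | 0.5 | 27 ± 7 |
| `dhinge` | 134 ± 12 | 150 | 0.6164 | 0.2 | 17 ± 2.5 |
| `noDTT` | 145 ± 15 | 10⁴ | 0.08 | 0.04 | — |
| `wt-ha` | as `wt` + antibody at fraction 0.48 | | | | |
| `fragment:1-889` | 91.2 ± 9 | 50 | 0.6164 | 0.5 | ≤27 |

The hinge-deletion preset is 105 residues shorter and stiffer, with rarer,
smaller and more uniform bubbles; the non-reducing (`noDTT`) preset is
rod-like. Fragment contour means other than the N-terminal half (whose
mean is taken from its measured value) are set at ~70% of the predicted
coiled-coil length, the same compaction the full-length molecule shows.
Density defaults to 6 molecules per 1.2 µm field — a moderate coverage
chosen so that overlaps and border contacts occur but do not dominate; no
measured surface density was available to match.

### What the generator does not emulate

No 3D mechanics or electrostatics of mica adsorption, no cantilever
dynamics, feedback artifacts, thermal drift or scar lines; noise is white,
whereas real scans have correlated line noise; molecules are rendered with
uniform ridge height, whereas real duplexes show height variation along
the contour. Tests passing on this generator therefore validate the
measurement chain's geometry and statistics, not its robustness to every
instrumental artifact of a physical AFM.

## Measurement chain

### Flattening

Row medians are subtracted, then column medians (in that order; the median
of an even-length line is the mean of the two central values). Because
molecules are sparse, line medians estimate the local background robustly;
a separable row+column offset field flattens to exactly zero and the
output's column medians are exactly zero. No polynomial fit, scar removal
or filtering is performed. Note that median flattening is deliberately
single-pass per axis: unlike mean subtraction it is not exactly idempotent
on arbitrary inputs, and iterating it is neither needed nor implemented.

### Detection and selection

Foreground is a hysteresis threshold: pixels above `median + 2·(1.4826·MAD)`
that connect to a pixel above `median + 3·(1.4826·MAD)` (absolute floors
0.25 / 0.75 nm keep noise-free images from thresholding at background).
Hysteresis keeps the sub-nanometre gap inside a bubble open — a single
blur-based threshold closes small bubbles — while isolated noise
essentially never reaches the high threshold. Components are 8-connected
(thin diagonal curves fragment under 4-connectivity); those under 30 px
are dropped as specks. Selection then rejects border-touching objects,
aggregates (area above 2.5× the median molecule-scale area, or more than
one ground-truth molecule when truth is supplied), and objects whose
skeleton later fails to parse. Every detected object lands in exactly one
of the metrics or rejection tables. The retained fraction of
molecule-scale objects is logged and flagged when outside the 40–70% range
typical of manual curation.

### Tracing

The object mask is skeletonized (medial axis) and condensed to a graph
whose nodes are endpoints and junction *clusters* (8-connected skeletons
produce small clumps of mutually adjacent junction pixels; each clump is
one node, and intra-clump adjacencies are discarded so they cannot
masquerade as cycles). Edge lengths use the chain-code rule (1 px axial,
√2 px diagonal), are floored by the straight-line distance between node
coordinates, and deliberately exclude the shared cluster pixels — counting
them into every incident edge inflates lengths by several nanometres per
junction. Terminal spurs under 6 nm (below the tip-broadened duplex width,
so genuine splay arms, ≥8 nm by construction, are never pruned) are
removed iteratively. Skeletons with more than 2 independent cycles or more
than 6 endpoints are untraceable.

The anatomy parser then reduces the graph to
`(N splay?) – stalk – (bubble?) – stalk – (C splay?)`:

* the unique cycle, if any, must be a pair of parallel edges — its two
  paths are the bubble strands (cycles under 8 nm total are pixel-scale
  artifacts and are dissolved into the stalk); self-loops (self-crossing
  molecules) and multi-junction cycles are untraceable;
* short, tall leaf edges (mean height ≥ ~3 nm, i.e. about twice the ridge)
  are antibody-blob spurs and are removed; short low spurs at interior
  junctions are forgiven up to 12 nm; anything longer is an unexplained
  branch and the molecule is rejected;
* remaining junctions must carry exactly two leaf arms (a three-leaf
  "star" is a single-splay molecule whose stalk is the longest branch);
  the two molecule ends are the splay junctions and/or plain termini;
* N/C orientation: the end whose terminal region (arm tips or terminus,
  7×7 px window) is taller is N (GFP > GRIP). If the two ends differ by
  less than 0.25 nm the molecule is kept but flagged
  orientation-ambiguous, and orientation-dependent metrics are withheld.

### Bubble strand lengths: lens reconstruction

The skeleton fuses the two strands slightly inside the true bubble
vertices, so raw cycle strands are short and the flanking stalks long by
the same amount. Strand lengths are therefore reconstructed under the
generative lens model (two circular arcs over a common chord) from
observables that survive pixelation: an anchor chord and each strand's
sagitta (mean offset of the path near mid-chord from the junction line).
Two anchors are computed — the junction-to-junction chord, and the extent
of the enclosed background hole along that direction — and each is
extended by the vertex offset `t` solving `separation(t) = δ` under the
model. The instrument constants δ were calibrated once on synthetic
targets independent of the molecule presets: Y-junctions (two straight
ridges meeting a stalk, opening angles 10–45°) give a junction merge
separation of ≈1.1 px, and lens targets (strand lengths 15–27 nm,
orientations 0–70°, sub-pixel phases) give a hole pinch-out separation of
≈2.05 px — the latter agreeing with the geometric prediction of one
background pixel plus the rendered ridge width. Because either landmark
can be displaced *outward* at oblique orientations (a chain-code effect),
the smaller of the two reconstructions is reported; on the calibration
targets this estimator is accurate to a few tenths of a nanometre in the
orientation average, with ~2 nm per-molecule scatter. The reclaimed vertex
length is moved from the stalks into the strands, so the total length is
conserved.

### Metrics and statistics

Definitions are in the README. Implementation notes: the normalized
splay-to-splay distance substitutes the backbone terminus for a missing
splay junction (otherwise nearly half of a wild-type population would be
discarded) and traverses the bubble at the averaged strand length;
relative positions measure from the N end, averaging paired arms; the
antibody position projects blob pixels onto the traced backbone.
Group comparisons use Welch's unequal-variance two-tailed t test (the
safer default when only "unpaired, two-tailed t test" is specified); two
degenerate zero-variance groups with equal means report p = 1. Binomial
confidence intervals are Wilson, 95%. Histograms default to 10 nm bins for
lengths and 0.05 for fractions. No multiple-testing correction is applied:
comparisons are single pairwise tests per quantity.

The ends-independence check `1 − (1 − √f_both)²` is a consistency test of
the independence model, not a measurement, and is labelled as such where
reported.

## Study sizes and evaluation conditions

Validation studies in the test suite use 200 molecules per group (150 for
the antibody-labelled population); the reproduction script uses 600 (300)
to keep the binomial error on reported fractions near two percentage
points. Both run at the native 512 px scan resolution — large
enough that binomial intervals on fractions are ±7% and length means are
determined to ~1 nm, while the whole suite stays fast. Recovery of
resolution-limited quantities (bubble frequency and size, conformation
classes, label position) is evaluated on the ideal render (no tip, no
noise, no slant), which isolates the measurement chain's fidelity;
total-length recovery is additionally checked under the realistic scan
(3 nm tip, noise, slant), and the wild-type vs hinge-deletion contrasts
are required to hold under the realistic scan. Under a 3 nm tip, small
bubbles genuinely blur shut — frequency recovery there reflects physical
resolution loss, not algorithmic error, which is why the package reports
both conditions rather than hiding the difference.

## Known limitations

* Bubble reconstruction assumes the lens (circular-arc) shape; strongly
  non-circular or twisted bubbles would be measured with the raw skeleton
  bias (a few nm short).
* Self-crossing molecules are rejected rather than disentangled, which
  slightly enriches retained populations in shorter/straighter molecules.
* Orientation calls rely on the GFP/GRIP height contrast; constructs
  without differential end caps are mostly orientation-ambiguous and
  contribute no position metrics.
* The X1/X2 (and X7/X8) assignment within an end pair is by descending
  length, not by chain identity, which is unknowable from topography.
* Chain-code path length overestimates oblique smooth curves by up to
  ~5–8%; the circle check in the suite bounds this for the canonical
  diameter-60 px case at <5%.
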