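# tethermorph

Single-molecule morphometry of long coiled-coil tethers imaged by atomic
force microscopy (AFM), together with a synthetic-topograph generator that
makes every stage of the measurement chain testable without raw scan data.

## The problem

Golgins are dimeric coiled-coil proteins, anchored to the Golgi by their
C-termini, that capture transport vesicles. AFM height imaging of single
purified molecules (1.2 µm × 1.2 µm scans at 512 × 512 px, heights within a
~2.5 nm Z range) shows that a trans-Golgi tether such as GCC185 is far from
the rigid rod cartoons suggest: its termini are frequently *splayed* into
two visible arms, and about half of the molecules carry a central
*bubble* — a local unwinding of the coiled coil visible as a small loop.
Quantifying those features requires tracing each molecule's contour and
decomposing it into at most eight segments, indexed from the N terminus:

```
X1, X2   N-terminal splay arms          (0 if the N end is not splayed)
X3       duplex stalk, N side
X4, X5   the two bubble strands         (0 if no bubble)
X6       duplex stalk, C side           (0 if no bubble: whole stalk in X3)
X7, X8   C-terminal splay arms          (0 if the C end is not splayed)
```

with the per-molecule statistics

- bubble size = (X4 + X5) / 2,
- total length = (X1+X2)/2 + X3 + (X4+X5)/2 + X6 + (X7+X8)/2,
- normalized splay-to-splay distance = Euclidean distance between the two
  splay junctions divided by the traced path length between them (≈ 1 for
  rigid, extended molecules; small for bent ones),
- relative positions of the bubble or an antibody label along the molecule
  measured from the GFP-tagged N terminus,
- an 8-way conformational class from (N-splay, C-splay, bubble),

and population-level comparisons: splay fractions with binomial confidence
intervals, bubble frequency and size per construct, Welch two-sample tests
between constructs, and measured-vs-predicted length shortfalls using the
canonical coiled-coil rise of 0.1485 nm per residue.

The package implements that chain end to end: scan flattening by row- and
column-wise median subtraction, molecule detection and selection (border /
aggregate / traceability filters), skeleton-graph tracing with feature
identification, segment measurement, and the population statistics — plus
a seeded generator of synthetic topographs (worm-like-chain backbones,
splay arms, lens-shaped bubbles, terminal globules, antibody labels, tip
convolution, scan slant and noise) whose per-molecule ground truth lets
every stage be validated quantitatively.

## Worked example

Simulate 30 wild-type-like molecules, analyze them, and report:

```sh
tethermorph simulate --preset wt --seed 42 -n 30 --out demo/sim
tethermorph analyze demo/sim --out demo/ana
tethermorph report demo/ana/metrics.csv --labels wt --out demo/rep
```

The analyze step prints `analyzed 5 file(s): 28 molecules retained, 3
objects rejected` (one molecule touched the field border, one speck was
below the minimum area, one molecule could not be traced to the canonical
anatomy), and the report contains, among other entries:

```
n                        = 28
total_length_mean_nm     = 146.6      # generator preset mean: 145 nm
total_length_sd_nm       = 17.1
bubble_frequency         = 0.43       # preset probability: 0.5
bubble_size_mean_nm      = 19.9
norm_splay_distance_mean = 0.82
splay_at_least_one       = 0.68  (95% CI 0.49-0.82)
splay_both_ends          = 0.46
```

At n = 28 the fractions carry wide binomial error bars; the full test suite
runs the same recovery at 200 molecules per group, where the measured means
and fractions land within a few percent of the generator's parameters.
Per-molecule rows (X1..X8, metrics, conformation class) are in
`demo/ana/metrics.csv`; every rejected object appears exactly once in
`demo/ana/rejections.csv` with its reason.

The library surface mirrors the CLI: `tethermorph.generate_population`,
`flatten`, `detect_objects`, `select_molecules`, `skeletonize_molecule`,
`identify_features`, `measure_segments`, and the statistics in
`tethermorph.metrics` / `tethermorph.report`.

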