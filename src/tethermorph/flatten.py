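"""Scan flattening: removal of sample slant by median subtraction.

AFM raster scans of a nominally flat substrate carry two nuisance signals:
an overall plane tilt of the sample and independent DC offsets of each scan
line.  Because molecules are sparse, the median of every scan line is a
robust estimate of its local background, so both signals are removed by
subtracting, from every row, its median, and then, from every column of the
result, its median.  Nothing else is done — no polynomial fit, no scar
removal, no frequency-domain filtering.

The row pass runs first, then the column pass.  The median of an
even-length line is the mean of its two central values (the conventional
definition).  Consequences that the test suite pins down:

* every column median of the output is exactly 0;
* a pure row-offset + column-offset field flattens to exactly 0;
* adding a constant to the input leaves the output unchanged.

(Median subtraction is deliberately single-pass per axis; unlike mean
subtraction it is not exactly idempotent on arbitrary inputs.)
"""

from __future__ import annotations

import numpy as np

from .topograph import Topograph


def flatten(topo: Topograph) -> Topograph:
    """Remove sample slant by row- then column-wise median subtraction.

    Parameters
    ----------
    topo
        A ``raw`` topograph.  Non-finite heights are a data error.

    Returns
    -------
    Topograph
        A new topograph with ``provenance="flattened"``; pixel size and
        metadata are carried over unchanged.
    """
    if topo.provenance != "raw":
        raise ValueError(f"flatten expects a raw topograph, got provenance={topo.provenance!r}")
    topo.require_finite()
    h = topo.heights.astype(float)
    h = h - np.median(h, axis=1, keepdims=True)
    h = h - np.median(h, axis=0, keepdims=True)
    return Topograph(h, topo.pixel_size_nm, provenance="flattened",
                     metadata=dict(topo.metadata))
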