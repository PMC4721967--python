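"""Topographic height maps and their on-disk formats.

A topograph is a rectangular grid of surface heights in nanometres with a
physical pixel size.  Raw scans carry an overall sample slant and per-line
offsets that must be removed (see :mod:`tethermorph.flatten`) before any
morphometric measurement; the ``provenance`` field tracks that state.

Supported file dialects: single-channel 32-bit float TIFF (heights in nm,
no compression) and whitespace-delimited ASCII grids.  Both round-trip the
stored float32 values exactly.  A sidecar JSON carries pixel size and
free-form metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile


class DataError(ValueError):
    """Raised for ill-formed image data (non-finite heights, bad shapes)."""


@dataclass
class Topograph:
    heights: np.ndarray          # 2D, nm
    pixel_size_nm: float
    provenance: str = "raw"      # "raw" | "flattened"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise DataError(f"heights must be 2D, got shape {self.heights.shape}")
        if not (self.pixel_size_nm > 0 and np.isfinite(self.pixel_size_nm)):
            raise DataError(f"pixel_size_nm must be finite and positive, got {self.pixel_size_nm}")
        if self.provenance not in ("raw", "flattened"):
            raise DataError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def require_finite(self) -> None:
        """Raise :class:`DataError` naming offending indices if any height is non-finite."""
        bad = ~np.isfinite(self.heights)
        if bad.any():
            idx = np.argwhere(bad)[:10]
            raise DataError(
                f"{bad.sum()} non-finite heights, first at (row, col) = "
                + ", ".join(str((int(r), int(c))) for r, c in idx)
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_topograph(topo: Topograph, path: str | Path, fmt: str | None = None) -> Path:
    """Write a topograph to TIFF (``.tif``/``.tiff``) or ASCII grid (anything else).

    A sidecar ``<name>.json`` stores pixel size, provenance and metadata.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii"
    if fmt == "tiff":
        tifffile.imwrite(path, topo.heights.astype(np.float32), compression=None)
    else:
        # 9 significant digits round-trip float32 exactly
        np.savetxt(path, topo.heights.astype(np.float32), fmt="%.9e")
    sidecar = {
        "pixel_size_nm": topo.pixel_size_nm,
        "provenance": topo.provenance,
        "metadata": topo.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def read_topograph(path: str | Path, pixel_size_nm: float | None = None) -> Topograph:
    """Read a TIFF or ASCII grid topograph; pixel size from sidecar JSON unless given."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = np.asarray(tifffile.imread(path), dtype=float)
    else:
        # files are written at float32 precision; parsing at that precision
        # makes the round trip exact
        heights = np.loadtxt(path, dtype=np.float32)
    provenance, metadata = "raw", {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if pixel_size_nm is None:
            pixel_size_nm = meta.get("pixel_size_nm")
        provenance = meta.get("provenance", "raw")
        metadata = meta.get("metadata", {})
    if pixel_size_nm is None:
        raise DataError(f"no pixel size: {sidecar} missing and none supplied")
    return Topograph(heights, float(pixel_size_nm), provenance, metadata)
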