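"""Run configuration: one reproducible bundle for a whole pipeline run.

A run is fully reconstructible from its config snapshot: the scan spec, the
population spec (or preset name), every analysis threshold, the seed and
the output directory are echoed verbatim into ``config_snapshot.json`` in
the output directory, together with a content hash that all other outputs
can reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .detect import SelectionCriteria, ThresholdPolicy
from .pipeline import AnalysisParams
from .synthetic import MoleculePopulationSpec, ScanSpec, get_preset


@dataclass
class RunConfig:
    scan: ScanSpec = field(default_factory=ScanSpec)
    population: MoleculePopulationSpec = field(default_factory=MoleculePopulationSpec)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    preset: str | None = None
    seed: int = 0
    out_dir: str = "tethermorph_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def snapshot_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write_snapshot(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        d = self.to_dict()
        d["config_hash"] = self.snapshot_hash()
        p = out_dir / "config_snapshot.json"
        p.write_text(json.dumps(d, indent=1, default=str))
        return p


def _update_dataclass(obj, data: dict):
    names = {f.name for f in dataclasses.fields(obj)}
    kwargs = {}
    for k, v in data.items():
        if k not in names:
            raise KeyError(f"unknown config key {k!r} for {type(obj).__name__}")
        cur = getattr(obj, k)
        if dataclasses.is_dataclass(cur) and isinstance(v, dict):
            kwargs[k] = _update_dataclass(cur, v)
        else:
            kwargs[k] = v
    return dataclasses.replace(obj, **kwargs)


def load_config(path: str | Path | None = None, preset: str | None = None,
                seed: int | None = None, out_dir: str | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional JSON file plus CLI overrides.

    The file uses sections mirroring the dataclass fields: ``scan``,
    ``population``, ``analysis``, plus top-level ``preset``, ``seed`` and
    ``out_dir``.  A preset (from the file or the CLI) seeds the population
    section before explicit population keys are applied on top.
    """
    data: dict = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
    cfg = RunConfig()
    preset = preset or data.get("preset")
    if preset:
        cfg = dataclasses.replace(cfg, population=get_preset(preset), preset=preset)
    for section in ("scan", "population", "analysis"):
        if section in data:
            cfg = dataclasses.replace(
                cfg, **{section: _update_dataclass(getattr(cfg, section), data[section])})
    if overrides:
        for section, vals in overrides.items():
            cfg = dataclasses.replace(
                cfg, **{section: _update_dataclass(getattr(cfg, section), vals)})
    if "seed" in data:
        cfg = dataclasses.replace(cfg, seed=int(data["seed"]))
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    cfg = dataclasses.replace(cfg, population=dataclasses.replace(
        cfg.population, seed=cfg.seed))
    if out_dir is not None or "out_dir" in data:
        cfg = dataclasses.replace(cfg, out_dir=out_dir or data["out_dir"])
    return cfg
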