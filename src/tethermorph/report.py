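"""Population reports: group summaries, contrasts, and plots.

Turns per-molecule metrics tables into the quantities a morphometry study
reports: conformation-class abundances, splay fractions with confidence
intervals, bubble frequency and size, normalized splay-to-splay distance
comparisons between groups, measured-vs-predicted length shortfalls, and
ECDF / histogram plot data.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .conformations import ALL_CLASSES
from .metrics import (PredictionParams, compare_groups, ecdf_overlay,
                      independent_ends_check, percent_shortfall,
                      predicted_length, splay_fraction_stats, summarize)


def summarize_group(metrics: pd.DataFrame, label: str = "") -> dict:
    """Headline statistics of one analyzed population."""
    if len(metrics) == 0:
        return {"group": label, "n": 0}
    classes = metrics["conformation_class"].tolist()
    any_spl, both_spl = splay_fraction_stats(classes)
    bubbled = metrics[metrics["bubble_size_nm"] > 0]
    nsd = metrics["norm_splay_distance"].dropna()
    out = {
        "group": label,
        "n": int(len(metrics)),
        "total_length_mean_nm": float(metrics["total_length_nm"].mean()),
        "total_length_sd_nm": float(metrics["total_length_nm"].std(ddof=1))
        if len(metrics) > 1 else 0.0,
        "splay_at_least_one": asdict(any_spl),
        "splay_both_ends": asdict(both_spl),
        "splay_predicted_at_least_one_if_independent":
            independent_ends_check(both_spl.fraction),
        "bubble_frequency": float(len(bubbled) / len(metrics)),
        "bubble_size_mean_nm": float(bubbled["bubble_size_nm"].mean())
        if len(bubbled) else 0.0,
        "bubble_size_sd_nm": float(bubbled["bubble_size_nm"].std(ddof=1))
        if len(bubbled) > 1 else 0.0,
        "norm_splay_distance_mean": float(nsd.mean()) if len(nsd) else None,
        "class_abundance": {c: int((metrics["conformation_class"] == c).sum())
                            for c in ALL_CLASSES},
    }
    return out


def compare_report(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                   label_a: str = "a", label_b: str = "b") -> dict:
    """Pairwise group contrasts: bubble frequency/size and bending metric.

    Welch unpaired two-tailed tests are reported for bubble size and
    normalized splay-to-splay distance.
    """
    sa, sb = summarize_group(metrics_a, label_a), summarize_group(metrics_b, label_b)
    out = {"groups": (label_a, label_b),
           "bubble_frequency": (sa["bubble_frequency"], sb["bubble_frequency"]),
           "bubble_size_mean_nm": (sa["bubble_size_mean_nm"], sb["bubble_size_mean_nm"]),
           "norm_splay_distance_mean": (sa["norm_splay_distance_mean"],
                                        sb["norm_splay_distance_mean"])}
    ba = metrics_a.loc[metrics_a["bubble_size_nm"] > 0, "bubble_size_nm"]
    bb = metrics_b.loc[metrics_b["bubble_size_nm"] > 0, "bubble_size_nm"]
    if len(ba) >= 2 and len(bb) >= 2:
        out["bubble_size_test"] = asdict(compare_groups(ba, bb))
    na = metrics_a["norm_splay_distance"].dropna()
    nb = metrics_b["norm_splay_distance"].dropna()
    if len(na) >= 2 and len(nb) >= 2:
        out["norm_splay_distance_test"] = asdict(compare_groups(na, nb))
    return out


def shortfall_table(measured_means_nm: dict[str, float],
                    params: PredictionParams | None = None) -> pd.DataFrame:
    """Measured vs predicted lengths and percent shortfall per construct.

    ``measured_means_nm`` maps construct names (keys of the residue-count
    table, e.g. "full", "1-889") to measured mean lengths in nm.
    """
    params = params or PredictionParams()
    rows = []
    for name, measured in measured_means_nm.items():
        res = params.residue_counts[name]
        pred = predicted_length(res, params)
        rows.append({"construct": name, "residues": res,
                     "predicted_nm": pred, "measured_mean_nm": measured,
                     "shortfall_pct": percent_shortfall(measured, pred)})
    return pd.DataFrame(rows)


def length_histogram_data(metrics: pd.DataFrame, bin_width_nm: float = 10.0):
    return summarize(metrics["total_length_nm"].to_numpy(), bin_width=bin_width_nm)


def position_ecdf_data(groups: dict[str, pd.Series]):
    return ecdf_overlay({k: v.dropna().to_numpy() for k, v in groups.items()})


def plot_report(summaries: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Render histogram and ECDF figures; returns written file names."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, df in summaries.items():
        s = length_histogram_data(df)
        centers = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
        ax.step(centers, s.counts, where="mid", label=f"{label} (n={s.n})")
    ax.set_xlabel("total length (nm)")
    ax.set_ylabel("molecules")
    ax.legend(frameon=False)
    fig.tight_layout()
    p = out_dir / "length_histograms.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))

    fig, ax = plt.subplots(figsize=(5, 3.5))
    curves = position_ecdf_data(
        {label: df["rel_center"] for label, df in summaries.items()})
    for label, (v, f) in curves.items():
        if len(v):
            ax.step(v, f, where="post", label=label)
    ax.set_xlabel("relative position of feature center")
    ax.set_ylabel("cumulative fraction")
    ax.set_xlim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    p = out_dir / "position_ecdf.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))
    return written
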