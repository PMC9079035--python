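"""Dot plots of per-nucleus intensities and per-embryo cycle ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_intensity_dots", "plot_ratio_dots"]


def _strip(ax, groups: list[tuple[str, np.ndarray]], rng: np.random.Generator):
    for i, (label, vals) in enumerate(groups):
        x = i + rng.uniform(-0.12, 0.12, size=len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        if len(vals):
            m, s = float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            ax.errorbar([i + 0.25], [m], yerr=[s], fmt="_", color="k", capsize=3)
            ax.annotate(f"n={len(vals)}", (i, ax.get_ylim()[0]), ha="center",
                        xytext=(0, -2), textcoords="offset points", fontsize=7)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([g[0] for g in groups])


def plot_intensity_dots(
    measurements: pd.DataFrame,
    value_col: str = "corrected_intensity",
    out_path: str | None = None,
    seed: int = 0,
):
    """Per-nucleus normalized intensity per nuclear cycle, one dot per
    nucleus, with mean ± s.d. per cycle."""
    inc = measurements[~measurements.get("excluded", False).astype(bool)] \
        if "excluded" in measurements.columns else measurements
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(4, 3))
    groups = [
        (f"NC{int(c)}", grp[value_col].dropna().to_numpy())
        for c, grp in inc.groupby("cycle")
    ]
    _strip(ax, groups, rng)
    ax.set_ylabel("centromeric intensity per nucleus (a.u.)")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path)
        plt.close(fig)
    return fig


def plot_ratio_dots(
    per_embryo_ratios: pd.DataFrame, out_path: str | None = None, seed: int = 0
):
    """Per-embryo cycle-to-cycle intensity ratios, one dot per embryo,
    with the cross-embryo mean ± s.d. per ratio."""
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(4, 3))
    groups = [
        (name, grp["value"].to_numpy())
        for name, grp in per_embryo_ratios.groupby("ratio_name", sort=False)
    ]
    _strip(ax, groups, rng)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("ratio of cycle mean intensities")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path)
        plt.close(fig)
    return fig
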