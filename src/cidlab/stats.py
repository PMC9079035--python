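"""Normalization, cycle-ratio statistics and mitotic scoring.

The unit of replication for cycle-to-cycle comparisons is the embryo: per
embryo, corrected per-nucleus intensities are averaged within each nuclear
cycle, ratios between cycle means are formed (NC12/NC11, NC13/NC12,
NC13/NC11, ...), and the mean ± sample s.d. of those per-embryo ratios is
reported across embryos.  A fully replenishing loading process predicts all
ratios equal to one; a complete loading block predicts 0.5 per elapsed
cycle (0.25 across two).  For display, intensities within an embryo are
conventionally normalized so that the NC12 mean equals 100.

Also here: per-centromere loading curves (pre-anaphase nuclei hold sister
centromere pairs, so their values are halved), catastrophic-anaphase
fractions per mitosis, and the two-sample t test used for treatment
comparisons (Welch by default).  Standard deviations are sample (n−1)
throughout.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import PHASES, PRE_ANAPHASE_PHASES

__all__ = [
    "normalize_to_reference_cycle",
    "cycle_summaries",
    "cycle_ratios",
    "pooled_cycle_ratios",
    "per_centromere_intensity",
    "catastrophe_fraction",
    "two_sample_test",
    "DEFAULT_RATIO_PAIRS",
]

#: (numerator cycle, denominator cycle) pairs reported by default
DEFAULT_RATIO_PAIRS = ((12, 11), (13, 12), (13, 11))


def _included(measurements: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in measurements.columns:
        return measurements[~measurements["excluded"].astype(bool)]
    return measurements


def normalize_to_reference_cycle(
    measurements: pd.DataFrame,
    reference_cycle: int = 12,
    scale: float = 100.0,
    value_col: str = "corrected_intensity",
) -> pd.DataFrame:
    """Scale each embryo so its reference-cycle mean equals ``scale``.

    Returns a copy with ``value_col`` rescaled per embryo by
    ``scale / mean(reference-cycle values)``.  Idempotent and invariant to
    any prior multiplicative scaling of an embryo's values.
    """
    out = measurements.copy()
    for embryo, grp in measurements.groupby("embryo_id"):
        inc = _included(grp)
        ref = inc.loc[inc["cycle"] == reference_cycle, value_col]
        if ref.empty or not np.isfinite(ref.mean()) :
            raise ValueError(
                f"embryo {embryo!r} has no usable measurements in reference "
                f"cycle NC{reference_cycle}"
            )
        factor = scale / ref.mean()
        out.loc[out["embryo_id"] == embryo, value_col] = (
            measurements.loc[measurements["embryo_id"] == embryo, value_col] * factor
        )
    return out


def cycle_summaries(
    measurements: pd.DataFrame, value_col: str = "corrected_intensity"
) -> pd.DataFrame:
    """Per-embryo, per-cycle n, mean and sample s.d. of included nuclei."""
    inc = _included(measurements)
    rows = []
    for (embryo, cycle), grp in inc.groupby(["embryo_id", "cycle"]):
        vals = grp[value_col].dropna()
        if vals.empty:
            continue
        rows.append(
            {
                "embryo_id": embryo,
                "cycle": int(cycle),
                "n_nuclei": int(len(vals)),
                "mean_corrected_intensity": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cycle_ratios(
    summaries: pd.DataFrame,
    pairs: tuple[tuple[int, int], ...] = DEFAULT_RATIO_PAIRS,
) -> dict[str, pd.DataFrame]:
    """Per-embryo ratios of cycle means, aggregated across embryos.

    ``summaries`` is the output of :func:`cycle_summaries`.  Returns
    ``{"per_embryo": ..., "aggregate": ...}``; embryos missing a cycle of a
    pair are skipped for that pair with a warning.  The aggregate carries
    mean, sample s.d. (n−1) and the embryo count per ratio name.
    """
    per_rows = []
    means = summaries.set_index(["embryo_id", "cycle"])["mean_corrected_intensity"]
    for embryo in summaries["embryo_id"].unique():
        for num, den in pairs:
            name = f"NC{num}/NC{den}"
            try:
                v_num = means[(embryo, num)]
                v_den = means[(embryo, den)]
            except KeyError:
                warnings.warn(
                    f"embryo {embryo!r}: cycle NC{num} or NC{den} absent; "
                    f"skipped for {name}",
                    stacklevel=2,
                )
                continue
            per_rows.append(
                {"embryo_id": embryo, "ratio_name": name, "value": v_num / v_den}
            )
    per_embryo = pd.DataFrame(per_rows, columns=["embryo_id", "ratio_name", "value"])
    agg_rows = []
    for name, grp in per_embryo.groupby("ratio_name", sort=False):
        vals = grp["value"]
        agg_rows.append(
            {
                "ratio_name": name,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_embryos": int(len(vals)),
            }
        )
    aggregate = pd.DataFrame(agg_rows, columns=["ratio_name", "mean", "sd", "n_embryos"])
    return {"per_embryo": per_embryo, "aggregate": aggregate}


def pooled_cycle_ratios(
    measurements: pd.DataFrame,
    pairs: tuple[tuple[int, int], ...] = DEFAULT_RATIO_PAIRS,
    value_col: str = "corrected_intensity",
) -> pd.DataFrame:
    """Cycle ratios with nuclei pooled across embryos.

    Alternative aggregation for comparisons of fixed-embryo populations,
    where all nuclei of a condition are pooled before averaging.  The
    per-embryo aggregation of :func:`cycle_ratios` remains the default for
    time-lapse ratio statistics.
    """
    inc = _included(measurements)
    means = inc.groupby("cycle")[value_col].mean()
    counts = inc.groupby("cycle")[value_col].count()
    rows = []
    for num, den in pairs:
        if num not in means.index or den not in means.index:
            warnings.warn(f"cycle NC{num} or NC{den} absent; skipped", stacklevel=2)
            continue
        rows.append(
            {
                "ratio_name": f"NC{num}/NC{den}",
                "value": float(means[num] / means[den]),
                "n_nuclei_num": int(counts[num]),
                "n_nuclei_den": int(counts[den]),
            }
        )
    return pd.DataFrame(rows, columns=["ratio_name", "value", "n_nuclei_num", "n_nuclei_den"])


def per_centromere_intensity(
    measurements: pd.DataFrame,
    phase_col: str = "phase",
    value_col: str = "corrected_intensity",
) -> pd.DataFrame:
    """Convert per-nucleus values to per-centromere estimates.

    Before anaphase each nucleus holds sister-centromere pairs, so
    per-nucleus values are divided by two; during anaphase and telophase
    each (daughter) nucleus holds single centromeres and values pass
    through unchanged.  Suitable for mitotic loading curves, which show an
    approximate doubling of the per-centromere signal across the
    anaphase–telophase loading window when loading is fully replenishing.
    """
    phases = set(measurements[phase_col])
    unknown = phases - set(PHASES)
    if unknown:
        raise ValueError(f"unknown phase labels: {sorted(unknown)}")
    out = measurements.copy()
    pre = out[phase_col].isin(PRE_ANAPHASE_PHASES)
    out["per_centromere_intensity"] = np.where(
        pre, out[value_col] / 2.0, out[value_col]
    )
    return out


def catastrophe_fraction(
    track: pd.DataFrame, group_cols: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Fraction of nuclei undergoing a catastrophic anaphase, per mitosis.

    A nucleus "enters" mitosis ``M(c)`` if it has a metaphase row at cycle
    ``c``; it is catastrophic if its fate label at that cycle says so.  The
    fraction is computed in exact rational arithmetic before conversion to
    float.  Mitoses without entering nuclei are reported with a missing
    fraction.  ``group_cols`` (e.g. ``("treatment",)``) adds extra grouping
    columns taken from the track table.
    """
    meta = track[track["phase"] == "metaphase"]
    keys = [*group_cols, "cycle"]
    rows = []
    for key, grp in meta.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        nuclei = grp.drop_duplicates("nucleus_id")
        n_total = len(nuclei)
        n_cat = int((nuclei["fate"] == "catastrophic").sum())
        frac = float(Fraction(n_cat, n_total)) if n_total else np.nan
        rows.append(
            {
                **dict(zip(keys, key)),
                "mitosis": f"M{key[-1]}",
                "n_entering": n_total,
                "n_catastrophic": n_cat,
                "fraction": frac,
            }
        )
    return pd.DataFrame(rows)


def two_sample_test(
    group_a, group_b, variant: str = "welch"
) -> tuple[float, float]:
    """Two-sided two-sample t test; Welch (unequal variances) by default.

    ``variant='student'`` pools variances.  Returns (t statistic, p value).
    Identical groups give t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    with warnings.catch_warnings():
        # identical zero-variance groups trip scipy's precision warning;
        # that case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) and np.allclose(a, b):  # zero-variance identical groups
        t, p = 0.0, 1.0
    return t, p
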