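"""RT-qPCR relative quantification against a reference transcript.

Implements the ΔCt workflow used to estimate absolute transcript numbers in
single embryos: technical replicates are averaged on the Ct scale, the level
of a target relative to a reference gene is ``efficiency**-(Ct_target -
Ct_reference)``, and absolute copies per embryo follow by multiplying with
the assumed copy number of the reference (Act5C, taken to be present at
15 million transcripts per embryo).  Treatment effects are expressed as
percent of the matched control.  Quality control covers genomic-DNA
contamination (−RT wells), reagent contamination (no-template wells) and
targets near the detection limit of standard SYBR assays.

"Not detected" (undetermined Ct) is propagated as a distinct state — never
as a level of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QpcrPlate",
    "QpcrResult",
    "relative_level",
    "copies_per_embryo",
    "percent_of_control",
    "percent_of_control_per_replicate",
    "replicate_relative_levels",
    "qc_contamination",
    "analyze_plate",
    "DEFAULT_REFERENCE_GENE",
    "DEFAULT_REFERENCE_COPIES",
]

DEFAULT_REFERENCE_GENE = "Act5C"
#: assumed absolute abundance of the reference transcript per embryo
DEFAULT_REFERENCE_COPIES = 15_000_000

PLATE_COLUMNS = ["well", "target", "sample", "replicate", "ct", "is_minus_rt", "is_ntc"]


@dataclass
class QpcrPlate:
    """Well table of one qPCR run.

    ``wells`` columns: well, target, sample, replicate, ct (NaN =
    undetermined), is_minus_rt, is_ntc.  +RT wells need at least one
    technical replicate per (target, sample); three is typical.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        ct = self.wells["ct"]
        if (ct.dropna() <= 0).any():
            raise ValueError("Ct values must be > 0 (or NaN for undetermined)")

    @property
    def plus_rt(self) -> pd.DataFrame:
        w = self.wells
        return w[~w["is_minus_rt"] & ~w["is_ntc"]]

    def mean_ct(self, target: str, sample: str) -> float:
        """Arithmetic mean Ct over +RT technical replicates; NaN if none
        amplified."""
        sel = self.plus_rt.query("target == @target and sample == @sample")
        if sel.empty:
            raise KeyError(f"no +RT wells for target={target!r} sample={sample!r}")
        return float(sel["ct"].mean())  # NaN-skipping; all-NaN -> NaN

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.wells.to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "QpcrPlate":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class QpcrResult:
    """Derived quantities for one (target, sample)."""

    target: str
    sample: str
    mean_ct: float
    relative_level: float  # NaN when not detected
    copies_per_embryo: float
    qc_flags: frozenset = field(default_factory=frozenset)

    @property
    def detected(self) -> bool:
        return not math.isnan(self.relative_level)


def relative_level(
    ct_target: float, ct_reference: float, efficiency: float = 2.0
) -> float:
    """Level of a target relative to the reference: efficiency**(-ΔCt).

    ΔCt = ct_target - ct_reference; one extra cycle at efficiency 2 means a
    two-fold lower level.  An undetermined Ct (NaN) yields NaN ("not
    detected").
    """
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1 fold per cycle")
    if math.isnan(ct_target) or math.isnan(ct_reference):
        return math.nan
    return float(efficiency ** -(ct_target - ct_reference))


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or math.isnan(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def copies_per_embryo(
    relative_level: float,
    reference_copies: float = DEFAULT_REFERENCE_COPIES,
    sig_figs: int | None = 2,
) -> float:
    """Absolute transcript copies per embryo implied by a relative level.

    The product ``relative_level * reference_copies``; the estimate inherits
    the uncertainty of the assumed reference abundance, hence the default
    rounding to two significant figures.  ``sig_figs=None`` disables
    rounding.
    """
    if relative_level < 0:
        raise ValueError("relative_level must be >= 0")
    copies = relative_level * reference_copies
    if sig_figs is not None:
        copies = _round_sig(copies, sig_figs)
    return float(copies)


def percent_of_control(treated: QpcrResult, control: QpcrResult) -> float:
    """Treated level as a percentage of the matched control level.

    Invariant to the Ct anchor of the run because both levels share the same
    reference gene.  Undefined (NaN) when the control was not detected.
    """
    if treated.target != control.target:
        raise ValueError(
            f"targets differ: {treated.target!r} vs {control.target!r}"
        )
    if not control.detected or control.relative_level == 0:
        return math.nan
    if not treated.detected:
        return math.nan
    return 100.0 * treated.relative_level / control.relative_level


def replicate_relative_levels(
    plate: QpcrPlate,
    target: str,
    sample: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = 2.0,
) -> np.ndarray:
    """Relative level per technical replicate (ΔCt pairing by replicate index).

    Replicates lacking a matching reference-gene replicate are dropped;
    undetermined wells yield NaN entries.
    """
    plus = plate.plus_rt
    tgt = plus.query("target == @target and sample == @sample").set_index("replicate")
    ref = plus.query("target == @reference_gene and sample == @sample").set_index(
        "replicate"
    )
    shared = tgt.index.intersection(ref.index)
    if shared.empty:
        raise KeyError(
            f"no replicate-matched wells for {target!r} vs {reference_gene!r}"
        )
    return np.array(
        [
            relative_level(float(tgt.loc[r, "ct"]), float(ref.loc[r, "ct"]), efficiency)
            for r in shared
        ]
    )


def percent_of_control_per_replicate(
    treated: QpcrPlate,
    control: QpcrPlate,
    target: str,
    treated_sample: str,
    control_sample: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = 2.0,
) -> float:
    """Percent-of-control computed per replicate pair, then averaged.

    The default :func:`percent_of_control` works from replicate-averaged
    Cts; this variant forms the ratio per replicate index first.  The two
    agree exactly at zero Ct noise and differ only at second order
    otherwise.
    """
    rel_t = replicate_relative_levels(treated, target, treated_sample,
                                      reference_gene, efficiency)
    rel_c = replicate_relative_levels(control, target, control_sample,
                                      reference_gene, efficiency)
    n = min(len(rel_t), len(rel_c))
    vals = 100.0 * rel_t[:n] / rel_c[:n]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return math.nan
    return float(vals.mean())


def qc_contamination(
    plate: QpcrPlate,
    minus_rt_margin: float = 3.0,
    ct_ceiling: float = 33.0,
) -> pd.DataFrame:
    """Contamination and detection-limit QC per (target, sample).

    Flags raised (never exceptions):

    - ``genomic_dna``: a −RT well amplified within ``minus_rt_margin``
      cycles of the +RT mean Ct, so the product may derive from genomic DNA
      rather than cDNA.
    - ``reagent_contamination``: any no-template control amplified.
    - ``near_detection_limit``: mean +RT Ct above ``ct_ceiling`` — levels
      this low are at the limit of reliable SYBR detection and call for
      cautious interpretation.
    """
    w = plate.wells
    rows = []
    for (target, sample), grp in w.groupby(["target", "sample"], sort=False):
        plus = grp[~grp["is_minus_rt"] & ~grp["is_ntc"]]["ct"]
        minus = grp[grp["is_minus_rt"]]["ct"]
        ntc = grp[grp["is_ntc"]]["ct"]
        mean_ct = float(plus.mean()) if len(plus) else math.nan
        flags = set()
        if len(minus.dropna()) and not math.isnan(mean_ct):
            if (minus.dropna() <= mean_ct + minus_rt_margin).any():
                flags.add("genomic_dna")
        if len(ntc.dropna()):
            flags.add("reagent_contamination")
        if not math.isnan(mean_ct) and mean_ct > ct_ceiling:
            flags.add("near_detection_limit")
        rows.append(
            {
                "target": target,
                "sample": sample,
                "mean_ct": mean_ct,
                "flags": frozenset(flags),
            }
        )
    return pd.DataFrame(rows)


def analyze_plate(
    plate: QpcrPlate,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    reference_copies: float = DEFAULT_REFERENCE_COPIES,
    efficiency: float = 2.0,
    sig_figs: int | None = 2,
    minus_rt_margin: float = 3.0,
    ct_ceiling: float = 33.0,
) -> list[QpcrResult]:
    """Replicate-averaged ΔCt analysis of a whole plate.

    For every (target, sample) with +RT wells: mean Ct, level relative to
    the reference gene in the same sample, absolute copies per embryo, and
    QC flags.  The reference gene itself is reported too (relative level 1).
    """
    qc = qc_contamination(plate, minus_rt_margin, ct_ceiling)
    qc_map = {(r.target, r.sample): r.flags for r in qc.itertuples()}
    results: list[QpcrResult] = []
    plus = plate.plus_rt
    for sample in plus["sample"].unique():
        sub = plus[plus["sample"] == sample]
        if reference_gene not in set(sub["target"]):
            raise ValueError(
                f"reference gene {reference_gene!r} absent from sample {sample!r}"
            )
        ct_ref = plate.mean_ct(reference_gene, sample)
        for target in sub["target"].unique():
            ct_t = plate.mean_ct(target, sample)
            rel = relative_level(ct_t, ct_ref, efficiency)
            copies = (
                copies_per_embryo(rel, reference_copies, sig_figs)
                if not math.isnan(rel)
                else math.nan
            )
            flags = set(qc_map.get((target, sample), frozenset()))
            if math.isnan(rel):
                flags.add("not_detected")
            results.append(
                QpcrResult(
                    target=target,
                    sample=sample,
                    mean_ct=ct_t,
                    relative_level=rel,
                    copies_per_embryo=copies,
                    qc_flags=frozenset(flags),
                )
            )
    return results


def results_to_frame(results: list[QpcrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": [r.target for r in results],
            "sample": [r.sample for r in results],
            "mean_ct": [r.mean_ct for r in results],
            "relative_level": [r.relative_level for r in results],
            "copies_per_embryo": [r.copies_per_embryo for r in results],
            "qc_flags": [";".join(sorted(r.qc_flags)) for r in results],
        }
    )
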