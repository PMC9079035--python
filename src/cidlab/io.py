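"""Run configuration, provenance records and the pipeline driver.

A run configuration is a TOML or JSON file with up to four blocks —
``simulation``, ``quantification``, ``stats``, ``qpcr`` — plus a global
``seed``.  Every block is validated against its module's parameter schema
(unknown keys are rejected with a message naming them) before any
computation runs.

The single global seed fans out deterministically to per-embryo child seeds
through ``numpy.random.SeedSequence(seed).spawn(...)``, so a pipeline run
and a module-level rerun with the same configuration agree.  Every run
writes a machine-readable provenance record (config, seed, package
versions, config hash) sufficient to reproduce its outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import ModelParams, fit_loading_efficiency, predict_relative_intensity
from .quantify import QuantifyConfig, measure_embryo
from .stats import (
    DEFAULT_RATIO_PAIRS,
    catastrophe_fraction,
    cycle_ratios,
    cycle_summaries,
    normalize_to_reference_cycle,
)
from .synthetic import EmbryoSimConfig, PhaseDurations, generate_timelapse

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_run_config",
    "child_seeds",
    "provenance_record",
    "run_simulation",
    "run_pipeline",
]

logger = logging.getLogger("cidlab")

_BLOCKS = ("simulation", "quantification", "stats", "qpcr")


class ConfigError(ValueError):
    """Invalid run configuration."""


def _dataclass_from_block(cls, block: dict, context: str):
    """Build a dataclass from a config block, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(
            f"unknown keys in [{context}]: {sorted(unknown)}; "
            f"allowed: {sorted(names)}"
        )
    kwargs = dict(block)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{context}] block: {exc}") from exc


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int = 0
    n_embryos: int = 4
    simulation: EmbryoSimConfig = dataclasses.field(default_factory=EmbryoSimConfig)
    quantification: QuantifyConfig = dataclasses.field(default_factory=QuantifyConfig)
    reference_cycle: int = 12
    ratio_pairs: tuple[tuple[int, int], ...] = DEFAULT_RATIO_PAIRS
    raw: dict = dataclasses.field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Read and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = tomllib.loads(text)
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a table/object")
    unknown = set(raw) - {*_BLOCKS, "seed", "n_embryos"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    return parse_run_config(raw)


def parse_run_config(raw: dict) -> RunConfig:
    seed = int(raw.get("seed", 0))
    n_embryos = int(raw.get("n_embryos", 4))
    if n_embryos < 0:
        raise ConfigError("n_embryos must be >= 0")

    sim_block = dict(raw.get("simulation", {}))
    model_block = sim_block.pop("model", None)
    phase_block = sim_block.pop("phase_durations", None)
    if "field_size_px" in sim_block:
        sim_block["field_size_px"] = tuple(sim_block["field_size_px"])
    sim = _dataclass_from_block(EmbryoSimConfig, sim_block, "simulation")
    if model_block is not None:
        sim = replace(
            sim, model=_dataclass_from_block(ModelParams, model_block, "simulation.model")
        )
    if phase_block is not None:
        sim = replace(
            sim,
            phase_durations=_dataclass_from_block(
                PhaseDurations, phase_block, "simulation.phase_durations"
            ),
        )

    quant_block = dict(raw.get("quantification", {}))
    if "dog_sigmas" in quant_block:
        quant_block["dog_sigmas"] = tuple(quant_block["dog_sigmas"])
    quant = _dataclass_from_block(QuantifyConfig, quant_block, "quantification")

    stats_block = dict(raw.get("stats", {}))
    allowed = {"reference_cycle", "ratio_pairs"}
    unknown = set(stats_block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [stats]: {sorted(unknown)}")
    pairs = tuple(
        tuple(int(v) for v in p) for p in stats_block.get("ratio_pairs", DEFAULT_RATIO_PAIRS)
    )
    return RunConfig(
        seed=seed,
        n_embryos=n_embryos,
        simulation=sim,
        quantification=quant,
        reference_cycle=int(stats_block.get("reference_cycle", 12)),
        ratio_pairs=pairs,
        raw=raw,
    )


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-embryo seeds spawned from the global seed."""
    return [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(seed).spawn(n)
    ]


def provenance_record(config: RunConfig) -> dict:
    return {
        "tool": "cidlab",
        "version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.raw,
    }


# ---------------------------------------------------------------------------


def run_simulation(config: RunConfig, outdir: str | Path) -> list[Path]:
    """Simulate ``n_embryos`` embryos and write stacks + tables to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, config.n_embryos)
    written: list[Path] = []
    for i, s in enumerate(seeds):
        eid = f"embryo_{i:03d}"
        sim = replace(config.simulation, seed=s)
        stack, gt, track = generate_timelapse(sim, embryo_id=eid)
        tif = stack.save(outdir / f"{eid}.tif")
        track_path = outdir / f"{eid}_track.csv"
        track.to_csv(track_path, index=False)
        gt_path = outdir / f"{eid}_ground_truth.csv"
        gt.nuclei.to_csv(gt_path, index=False)
        foci_path = outdir / f"{eid}_foci.csv"
        gt.foci.to_csv(foci_path, index=False)
        written += [tif, track_path, gt_path, foci_path]
        logger.info("simulated %s: %d frames, seed %d", eid, stack.n_frames, s)
    prov = outdir / "provenance.json"
    prov.write_text(json.dumps(provenance_record(config), indent=2))
    written.append(prov)
    return written


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """simulate → quantify → normalize → cycle ratios → model fit.

    Writes ``measurements.csv``, ``summaries.csv``, ``ratios.csv``,
    ``report.json``, ``report.md`` and ``provenance.json`` under ``outdir``
    and returns the report dictionary.
    """
    if config.n_embryos == 0:
        raise ValueError("empty embryo set: n_embryos must be >= 1 for the pipeline")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, config.n_embryos)

    frames, tracks = [], []
    for i, s in enumerate(seeds):
        eid = f"embryo_{i:03d}"
        sim = replace(config.simulation, seed=s)
        stack, gt, track = generate_timelapse(sim, embryo_id=eid)
        m = measure_embryo(stack, track, config.quantification)
        n_excl = int(m["excluded"].sum())
        logger.info(
            "%s: %d nuclei measured, %d excluded (%s)",
            eid,
            len(m),
            n_excl,
            ", ".join(sorted(set(m.loc[m["excluded"], "exclusion_reason"]))) or "-",
        )
        frames.append(m)
        tracks.append(track)
    measurements = pd.concat(frames, ignore_index=True)
    track_all = pd.concat(tracks, ignore_index=True)

    normalized = normalize_to_reference_cycle(
        measurements, reference_cycle=config.reference_cycle
    )
    summaries = cycle_summaries(measurements)
    ratios = cycle_ratios(summaries, pairs=config.ratio_pairs)

    consecutive = ratios["per_embryo"][
        ratios["per_embryo"]["ratio_name"].isin(
            [f"NC{n}/NC{d}" for n, d in config.ratio_pairs if n - d == 1]
        )
    ]["value"]
    fit = fit_loading_efficiency(consecutive, seed=config.seed)
    catas = catastrophe_fraction(track_all)

    e = config.simulation.model.loading_efficiency
    report = {
        "n_embryos": config.n_embryos,
        "n_nuclei_measured": int((~measurements["excluded"]).sum()),
        "n_nuclei_excluded": int(measurements["excluded"].sum()),
        "exclusion_reasons": measurements.loc[
            measurements["excluded"], "exclusion_reason"
        ]
        .value_counts()
        .to_dict(),
        "ratio_aggregate": ratios["aggregate"].to_dict(orient="records"),
        "loading_efficiency": {
            "estimate": fit.loading_efficiency,
            "conf_int": list(fit.conf_int),
            "conf_level": fit.conf_level,
            "n_ratio_observations": fit.n_obs,
        },
        "catastrophe_fractions": catas.to_dict(orient="records"),
        "analytic_predictions": {
            "generating_efficiency": e,
            "per_cycle_ratio": predict_relative_intensity(e, 1),
            "no_loading_per_cycle_ratio": predict_relative_intensity(0.0, 1),
            "no_loading_two_cycle_ratio": predict_relative_intensity(0.0, 2),
        },
    }

    measurements.to_csv(outdir / "measurements.csv", index=False)
    normalized.to_csv(outdir / "measurements_normalized.csv", index=False)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    ratios["per_embryo"].to_csv(outdir / "ratios_per_embryo.csv", index=False)
    ratios["aggregate"].to_csv(outdir / "ratios_aggregate.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "report.md").write_text(_report_markdown(report, fit.summary()))
    (outdir / "provenance.json").write_text(
        json.dumps(provenance_record(config), indent=2)
    )
    return report


def _report_markdown(report: dict, fit_summary: str) -> str:
    lines = [
        "# Centromeric intensity pipeline report",
        "",
        f"- embryos: {report['n_embryos']}",
        f"- nuclei measured: {report['n_nuclei_measured']} "
        f"(excluded: {report['n_nuclei_excluded']} {report['exclusion_reasons']})",
        "",
        "## Cycle-to-cycle intensity ratios (mean ± s.d. across embryos)",
        "",
    ]
    for row in report["ratio_aggregate"]:
        lines.append(
            f"- {row['ratio_name']}: {row['mean']:.3f} ± {row['sd']:.3f} "
            f"(n = {row['n_embryos']})"
        )
    lines += ["", "## Loading-efficiency fit", "", "```", fit_summary, "```", ""]
    lines += [
        "## Catastrophic anaphases",
        "",
    ]
    for row in report["catastrophe_fractions"]:
        frac = row["fraction"]
        lines.append(
            f"- {row['mitosis']}: {row['n_catastrophic']}/{row['n_entering']} "
            f"({100 * frac:.1f}%)"
        )
    preds = report["analytic_predictions"]
    lines += [
        "",
        "## Analytic reference points",
        "",
        f"- generating loading efficiency: {preds['generating_efficiency']}",
        f"- predicted per-cycle ratio at that efficiency: "
        f"{preds['per_cycle_ratio']:.4f}",
        f"- no-loading predictions: {preds['no_loading_per_cycle_ratio']:.2f} per "
        f"cycle, {preds['no_loading_two_cycle_ratio']:.2f} across two cycles",
        "",
    ]
    return "\n".join(lines)
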