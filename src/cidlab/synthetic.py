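"""Synthetic syncytial-blastoderm data with known ground truth.

Everything the analysis pipeline consumes can be generated here: two-channel
(centromere + chromatin) 3D time-lapse stacks of a syncytial Drosophila
embryo surface, single-timepoint "fixed embryo" fields, nucleus track tables
with mitotic-phase and fate labels, and qPCR plates whose Ct values encode
known transcript copy numbers.

The simulated embryo follows the blastoderm choreography the quantification
assumes: nuclei double at every mitosis (NC11 onward), each nucleus carries a
cluster of centromeric foci whose total intensity follows the
dilution–replenishment model, foci congress into a compact cluster during
prometaphase/metaphase, split into two half-intensity sister groups at
anaphase, and new-CID loading ramps intensities back up during the
anaphase→telophase window.  Occasional nuclei undergo a catastrophic
anaphase (failed chromosome separation); they keep a normal centromeric
signal up to the failure and leave no daughters.  Photon (Poisson) noise and
Gaussian camera read noise are applied on top of diffuse background.

Mitotic choreography is stylized — the quantifier only needs correct
photometry at the prometaphase/metaphase quantification frames and during
the anaphase–telophase loading window.  All randomness flows from a single
seeded generator; identical seeds give byte-identical stacks and tables.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ImageStack
from .model import ModelParams, simulate_trajectory
from .qpcr import DEFAULT_REFERENCE_COPIES, DEFAULT_REFERENCE_GENE, QpcrPlate

__all__ = [
    "EmbryoSimConfig",
    "PhaseDurations",
    "GroundTruth",
    "generate_timelapse",
    "generate_fixed_field",
    "generate_qpcr_plate",
    "PHASES",
    "PRE_ANAPHASE_PHASES",
    "TRACK_COLUMNS",
]

PHASES = (
    "interphase",
    "prophase",
    "prometaphase",
    "metaphase",
    "anaphase",
    "telophase",
)
PRE_ANAPHASE_PHASES = ("interphase", "prophase", "prometaphase", "metaphase")

TRACK_COLUMNS = [
    "embryo_id",
    "nucleus_id",
    "frame",
    "time_s",
    "cycle",
    "phase",
    "fate",
    "centroid_y",
    "centroid_x",
]


@dataclass(frozen=True)
class PhaseDurations:
    """Frames spent in each mitotic phase of one nuclear cycle.

    At the default 60 s cadence one frame is one minute; blastoderm cycles
    last on the order of ten minutes, most of it S phase/interphase.
    """

    interphase: int = 3
    prophase: int = 1
    prometaphase: int = 2
    metaphase: int = 1
    anaphase: int = 1
    telophase: int = 1

    def __post_init__(self) -> None:
        for p in PHASES:
            if getattr(self, p) < 1:
                raise ValueError(f"phase {p} needs at least one frame")

    @property
    def frames_per_cycle(self) -> int:
        return sum(getattr(self, p) for p in PHASES)

    @property
    def first_anaphase_offset(self) -> int:
        return self.interphase + self.prophase + self.prometaphase + self.metaphase

    @property
    def exit_window(self) -> int:
        """Frames of the anaphase→telophase loading window."""
        return self.anaphase + self.telophase

    def phase_at(self, offset: int) -> str:
        acc = 0
        for p in PHASES:
            acc += getattr(self, p)
            if offset < acc:
                return p
        raise ValueError(f"offset {offset} outside cycle of {acc} frames")


@dataclass(frozen=True)
class EmbryoSimConfig:
    """Configuration of one simulated embryo.

    The centromeric photometry is driven by ``model``: a nucleus in its
    birth cycle carries the intensity produced by the dilution–replenishment
    recursion, split between daughters at anaphase and replenished during
    the anaphase→telophase loading window.
    """

    field_size_px: tuple[int, int] = (144, 144)
    n_z: int = 12
    pixel_size_um: float = 0.13
    z_spacing_um: float = 0.5
    frame_interval_s: float = 60.0
    start_cycle: int = 11
    n_cycles: int = 3
    nuclei_at_start: int = 8
    foci_per_nucleus: int = 8
    model: ModelParams = field(
        default_factory=lambda: ModelParams(
            initial_intensity=90000.0,
            loading_efficiency=1.0,
            n_cycles=3,
            partition_cv=0.02,
            loading_cv=0.05,
        )
    )
    phase_durations: PhaseDurations = field(default_factory=PhaseDurations)
    psf_sigma_px: float = 1.2
    psf_sigma_z_planes: float = 0.7
    nuclear_radius_px: float = 6.0
    background_level: float = 20.0
    chromatin_level: float = 150.0
    camera_gain: float = 1.0
    read_noise_sd: float = 2.0
    offset: float = 100.0
    shot_noise: bool = True
    catastrophe_rate_per_mitosis: float = 0.01
    z_drift: bool = False
    z_drift_planes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.nuclei_at_start < 1:
            raise ValueError("need at least one cycle and one starting nucleus")
        if self.foci_per_nucleus < 1:
            raise ValueError("foci_per_nucleus must be >= 1")
        if min(self.psf_sigma_px, self.psf_sigma_z_planes) <= 0:
            raise ValueError("PSF widths must be > 0")
        for name in ("background_level", "chromatin_level", "read_noise_sd", "offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.catastrophe_rate_per_mitosis <= 1:
            raise ValueError("catastrophe_rate_per_mitosis must be in [0, 1]")
        if self.n_z < 3:
            raise ValueError("n_z must be >= 3")

    @property
    def n_frames(self) -> int:
        return self.phase_durations.frames_per_cycle * self.n_cycles

    def nuclei_at_cycle(self, cycle: int) -> int:
        """Expected count at ``cycle`` with doubling each mitosis (no
        catastrophes)."""
        if cycle < self.start_cycle:
            raise ValueError(f"cycle {cycle} precedes start_cycle {self.start_cycle}")
        return self.nuclei_at_start * 2 ** (cycle - self.start_cycle)

    def validate_capacity(self) -> None:
        """Raise if nuclei cannot fit the field at any simulated cycle."""
        h, w = self.field_size_px
        margin = self.nuclear_radius_px + 5
        for j in range(self.n_cycles + 1):
            cyc = self.start_cycle + j
            n = self.nuclei_at_start * 2**j
            rows, cols = _grid_shape(n, h, w)
            pitch = min((h - 2 * margin) / rows, (w - 2 * margin) / cols)
            if pitch < 2.2 * self.nuclear_radius_px:
                raise ValueError(
                    f"field {h}x{w} cannot fit {n} nuclei of radius "
                    f"{self.nuclear_radius_px} px at cycle NC{cyc}"
                )


@dataclass
class GroundTruth:
    """True per-nucleus intensities and per-focus positions, per frame.

    ``nuclei`` has the track-table columns plus ``true_intensity`` (total
    centromeric flux of the nucleus in the frame, a.u.); ``foci`` lists
    every rendered focus (frame, nucleus_id, focus_id, y, x, z_plane,
    amplitude).
    """

    nuclei: pd.DataFrame
    foci: pd.DataFrame

    def track_table(self) -> pd.DataFrame:
        return self.nuclei[TRACK_COLUMNS].copy()


# ---------------------------------------------------------------------------
# geometry helpers


def _grid_shape(n: int, h: int, w: int) -> tuple[int, int]:
    rows = max(1, int(round(np.sqrt(n * h / w))))
    cols = int(np.ceil(n / rows))
    while rows * cols < n:
        cols += 1
    return rows, cols


def _grid_positions(
    n: int, h: int, w: int, margin: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """n jittered lattice positions (y, x) inside the field margins."""
    rows, cols = _grid_shape(n, h, w)
    ys = np.linspace(margin, h - margin, rows)
    xs = np.linspace(margin, w - margin, cols)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])[:n]
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return np.clip(pts, margin, [h - margin, w - margin])


def _sorted_assignment(parents: np.ndarray, slots: np.ndarray) -> np.ndarray:
    """Map daughter origins to grid slots preserving rough spatial order."""
    order_p = np.lexsort((parents[:, 1], parents[:, 0]))
    order_s = np.lexsort((slots[:, 1], slots[:, 0]))
    out = np.empty_like(slots)
    out[order_p] = slots[order_s]
    return out


# ---------------------------------------------------------------------------
# nucleus bookkeeping


@dataclass
class _Nucleus:
    nid: int
    cycle: int
    intensity: float  # post-loading level held through its interphase..metaphase
    pos: np.ndarray  # (y, x) at interphase
    z_plane: int
    focus_offsets: np.ndarray  # (n_foci, 2) relative positions at interphase
    focus_weights: np.ndarray  # fractions summing to 1
    fate: str = "normal"
    # set at its mitosis:
    ana_positions: dict | None = None


def _make_focus_layout(
    n_foci: int, radius: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    r = radius * 0.55 * np.sqrt(rng.uniform(0.05, 1.0, n_foci))
    th = rng.uniform(0, 2 * np.pi, n_foci)
    offsets = np.column_stack([r * np.sin(th), r * np.cos(th)])
    weights = rng.uniform(0.8, 1.2, n_foci)
    weights /= weights.sum()
    return offsets, weights


def _phase_scale(phase: str) -> float:
    """Congression factor applied to focus offsets."""
    return {"prometaphase": 0.45, "metaphase": 0.4, "anaphase": 0.4, "telophase": 0.45}.get(
        phase, 1.0
    )


# ---------------------------------------------------------------------------
# rendering


def _render_focus(
    vol: np.ndarray,
    y: float,
    x: float,
    z_plane: int,
    amplitude: float,
    sigma: float,
    sigma_z: float,
) -> None:
    """Add one centromeric focus to a (Z, Y, X) photon-rate volume.

    The lateral profile is a 2D Gaussian integrating to ``amplitude``; the
    axial profile peaks at 1 in the focus plane, so the flux recovered by a
    maximum-intensity projection equals ``amplitude`` (up to tail
    truncation at 4 sigma).
    """
    n_z, h, w = vol.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    patch = (
        amplitude
        / (2 * np.pi * sigma**2)
        * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    )
    rz = int(np.ceil(4 * sigma_z))
    for dz in range(-rz, rz + 1):
        z = z_plane + dz
        if 0 <= z < n_z:
            vol[z, y0:y1, x0:x1] += patch * np.exp(-(dz**2) / (2 * sigma_z**2))


def _render_disc(
    vol: np.ndarray,
    y: float,
    x: float,
    z_plane: int,
    radius: float,
    level: float,
    sigma_z: float,
) -> None:
    """Add a chromatin disc (soft-edged) around a nucleus centroid."""
    n_z, h, w = vol.shape
    r = int(np.ceil(radius + 2))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    dist = np.sqrt(yy**2 + xx**2)
    patch = level / (1.0 + np.exp((dist - radius) / 0.7))
    for dz in range(-3, 4):
        z = z_plane + dz
        if 0 <= z < n_z:
            vol[z, y0:y1, x0:x1] += patch * np.exp(-(dz**2) / (2 * sigma_z**2))


def _apply_camera(
    rate: np.ndarray, config: EmbryoSimConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.shot_noise:
        out = rng.poisson(rate).astype(np.float32)
    else:
        out = rate.astype(np.float32, copy=True)
    if config.camera_gain != 1.0:
        out *= config.camera_gain
    out += config.offset
    if config.read_noise_sd > 0:
        out += rng.normal(0.0, config.read_noise_sd, size=out.shape).astype(np.float32)
    out += 0.5  # floor(x + 0.5) == round-to-nearest for non-negative x
    np.clip(out, 0, 65535, out=out)
    return out.astype(np.uint16)


# ---------------------------------------------------------------------------
# time-lapse generation


def generate_timelapse(
    config: EmbryoSimConfig, embryo_id: str = "sim"
) -> tuple[ImageStack, GroundTruth, pd.DataFrame]:
    """Simulate one embryo through ``config.n_cycles`` nuclear cycles.

    Returns the image stack, the ground truth (per-nucleus intensities and
    focus positions per frame) and the track table (one row per nucleus per
    frame with cycle/phase/fate labels and centroids).  Deterministic given
    ``config.seed``.
    """
    config.validate_capacity()
    rng = np.random.default_rng(config.seed)
    pd_ = config.phase_durations
    h, w = config.field_size_px
    margin = config.nuclear_radius_px + 5
    e = config.model.loading_efficiency
    fpc = pd_.frames_per_cycle
    n_frames = config.n_cycles * fpc

    z_mid = config.n_z // 2
    drift_per_frame = (
        config.z_drift_planes / max(1, n_frames - 1) if config.z_drift else 0.0
    )

    # founder nuclei
    next_id = 0
    positions = _grid_positions(config.nuclei_at_start, h, w, margin, 2.0, rng)
    nuclei: list[_Nucleus] = []
    for i in range(config.nuclei_at_start):
        offs, wts = _make_focus_layout(
            config.foci_per_nucleus, config.nuclear_radius_px, rng
        )
        nuclei.append(
            _Nucleus(
                nid=next_id,
                cycle=config.start_cycle,
                intensity=config.model.initial_intensity,
                pos=positions[i],
                z_plane=int(np.clip(z_mid + rng.integers(-1, 2), 1, config.n_z - 2)),
                focus_offsets=offs,
                focus_weights=wts,
            )
        )
        next_id += 1

    nuc_rows: list[dict] = []
    foci_rows: list[dict] = []
    foci_by_frame: list[list] = [[] for _ in range(n_frames)]
    disc_by_frame: list[list] = [[] for _ in range(n_frames)]
    stack = np.empty((n_frames, config.n_z, 2, h, w), dtype=np.uint16)

    def emit(frame: int, nuc: _Nucleus, cycle: int, phase: str, pos, intensity: float):
        zp = int(np.clip(nuc.z_plane + round(drift_per_frame * frame), 0, config.n_z - 1))
        nuc_rows.append(
            {
                "embryo_id": embryo_id,
                "nucleus_id": nuc.nid,
                "frame": frame,
                "time_s": frame * config.frame_interval_s,
                "cycle": cycle,
                "phase": phase,
                "fate": nuc.fate,
                "centroid_y": float(pos[0]),
                "centroid_x": float(pos[1]),
                "true_intensity": float(intensity),
            }
        )
        scale = _phase_scale(phase)
        disc_radius = config.nuclear_radius_px * (
            0.75 if phase not in ("interphase", "prophase") else 1.0
        )
        disc_by_frame[frame].append((float(pos[0]), float(pos[1]), disc_radius))
        for fi, (off, wt) in enumerate(zip(nuc.focus_offsets, nuc.focus_weights)):
            fy = float(pos[0] + scale * off[0])
            fx = float(pos[1] + scale * off[1])
            amp = float(intensity * wt)
            foci_rows.append(
                {
                    "frame": frame,
                    "nucleus_id": nuc.nid,
                    "focus_id": fi,
                    "y": fy,
                    "x": fx,
                    "z_plane": zp,
                    "amplitude": amp,
                }
            )
            foci_by_frame[frame].append((fy, fx, zp, amp))

    for j in range(config.n_cycles):
        cycle = config.start_cycle + j
        base = j * fpc
        ana0 = pd_.first_anaphase_offset
        win = pd_.exit_window

        # decide fates at this mitosis
        for nuc in nuclei:
            nuc.fate = (
                "catastrophic"
                if rng.random() < config.catastrophe_rate_per_mitosis
                else "normal"
            )

        # mother frames: interphase .. metaphase
        for off in range(ana0):
            phase = pd_.phase_at(off)
            for nuc in nuclei:
                emit(base + off, nuc, cycle, phase, nuc.pos, nuc.intensity)

        # mitosis exit: daughters (or the failing mother) during ana/telo
        daughters: list[_Nucleus] = []
        for nuc in nuclei:
            if nuc.fate == "catastrophic":
                # chromosome separation fails: no daughters, signal persists
                for k in range(win):
                    off = ana0 + k
                    emit(base + off, nuc, cycle, pd_.phase_at(off), nuc.pos, nuc.intensity)
                continue
            r = float(
                _truncnorm_scalar(rng, 0.5, config.model.partition_cv, 0.0, 1.0)
            )
            axis = rng.uniform(0, 2 * np.pi)
            unit = np.array([np.sin(axis), np.cos(axis)])
            halves = []
            for frac, sign in ((r, +1.0), (1.0 - r, -1.0)):
                offs, wts = _make_focus_layout(
                    config.foci_per_nucleus, config.nuclear_radius_px, rng
                )
                load_mult = float(
                    _truncnorm_scalar(rng, 1.0, config.model.loading_cv, 0.0, 2.0)
                )
                start = frac * nuc.intensity
                inc = e * (0.5 * nuc.intensity) * load_mult
                d = _Nucleus(
                    nid=next_id,
                    cycle=cycle + 1,
                    intensity=start + inc,
                    pos=nuc.pos.copy(),
                    z_plane=nuc.z_plane,
                    focus_offsets=offs,
                    focus_weights=wts,
                )
                next_id += 1
                for k in range(win):
                    off = ana0 + k
                    ramp = k / (win - 1) if win > 1 else 1.0
                    sep = 2.0 + 0.8 * config.nuclear_radius_px * (k + 1) / win
                    pos = np.clip(
                        nuc.pos + sign * sep * unit, margin, [h - margin, w - margin]
                    )
                    emit(base + off, d, cycle, pd_.phase_at(off), pos, start + ramp * inc)
                halves.append(d)
            daughters.extend(halves)

        # relocate daughters onto the next-cycle lattice
        if daughters:
            slots = _grid_positions(len(daughters), h, w, margin, 2.0, rng)
            origins = np.array([d.pos for d in daughters])
            assigned = _sorted_assignment(origins, slots)
            for d, p in zip(daughters, assigned):
                d.pos = p
                d.z_plane = int(
                    np.clip(z_mid + rng.integers(-1, 2), 1, config.n_z - 2)
                )
        nuclei = daughters
        if not nuclei:
            break

    gt_nuclei = pd.DataFrame(nuc_rows)
    gt_foci = pd.DataFrame(foci_rows)

    # render frames
    cid = np.empty((config.n_z, h, w), dtype=np.float64)
    chrom = np.empty((config.n_z, h, w), dtype=np.float64)
    for t in range(n_frames):
        cid.fill(config.background_level)
        chrom.fill(2.0)
        for fy, fx, zp, amp in foci_by_frame[t]:
            _render_focus(
                cid, fy, fx, zp, amp, config.psf_sigma_px, config.psf_sigma_z_planes
            )
        disc_zp = int(np.clip(z_mid + round(drift_per_frame * t), 0, config.n_z - 1))
        for cy, cx, radius in disc_by_frame[t]:
            _render_disc(chrom, cy, cx, disc_zp, radius, config.chromatin_level, 1.5)
        stack[t, :, 0] = _apply_camera(cid, config, rng)
        stack[t, :, 1] = _apply_camera(chrom, config, rng)

    image = ImageStack(
        pixels=stack,
        pixel_size_um=config.pixel_size_um,
        z_spacing_um=config.z_spacing_um,
        frame_interval_s=config.frame_interval_s,
    )
    gt = GroundTruth(nuclei=gt_nuclei, foci=gt_foci)
    return image, gt, gt.track_table()


def _truncnorm_scalar(
    rng: np.random.Generator, mean: float, cv: float, lo: float, hi: float
) -> float:
    if cv == 0:
        return mean
    sd = cv * mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# ---------------------------------------------------------------------------
# fixed embryos


def generate_fixed_field(
    config: EmbryoSimConfig,
    target_cycle: int,
    cycles_elapsed: int | None = None,
    count_cv: float = 0.05,
    embryo_id: str = "fixed",
) -> tuple[ImageStack, GroundTruth]:
    """One interphase frame of an embryo aged to ``target_cycle``.

    The nucleus count is drawn near ``nuclei_at_start * 2**(target_cycle -
    start_cycle)``; per-nucleus intensities come from simulating the
    dilution–replenishment recursion over ``cycles_elapsed`` cycles (default:
    cycles since ``start_cycle``), so a zero-loading model aged seven cycles
    sits at 1/2**7 of a fully replenishing one.
    """
    if target_cycle < config.start_cycle:
        raise ValueError("target_cycle must be >= start_cycle")
    rng = np.random.default_rng(config.seed)
    n_expect = config.nuclei_at_cycle(target_cycle)
    n = max(1, int(round(n_expect * _truncnorm_scalar(rng, 1.0, count_cv, 0.0, 2.0))))
    if cycles_elapsed is None:
        cycles_elapsed = target_cycle - config.start_cycle

    h, w = config.field_size_px
    margin = config.nuclear_radius_px + 5
    rows, cols = _grid_shape(n, h, w)
    pitch = min((h - 2 * margin) / rows, (w - 2 * margin) / cols)
    if pitch < 2.2 * config.nuclear_radius_px:
        raise ValueError(
            f"field cannot fit {n} nuclei of radius {config.nuclear_radius_px} px "
            f"at cycle NC{target_cycle}"
        )
    positions = _grid_positions(n, h, w, margin, 2.0, rng)

    params = replace(config.model, n_cycles=max(1, cycles_elapsed))
    sims = simulate_trajectory(params, n_replicates=n, rng=rng)
    intensities = (
        sims.samples[:, cycles_elapsed]
        if cycles_elapsed > 0
        else np.full(n, config.model.initial_intensity)
    )

    z_mid = config.n_z // 2
    nuc_rows, foci_rows = [], []
    cid = np.full((config.n_z, h, w), config.background_level, dtype=np.float64)
    chrom = np.full((config.n_z, h, w), 2.0, dtype=np.float64)
    for i in range(n):
        offs, wts = _make_focus_layout(
            config.foci_per_nucleus, config.nuclear_radius_px, rng
        )
        zp = int(np.clip(z_mid + rng.integers(-1, 2), 1, config.n_z - 2))
        y, x = positions[i]
        nuc_rows.append(
            {
                "embryo_id": embryo_id,
                "nucleus_id": i,
                "frame": 0,
                "time_s": 0.0,
                "cycle": target_cycle,
                "phase": "interphase",
                "fate": "normal",
                "centroid_y": float(y),
                "centroid_x": float(x),
                "true_intensity": float(intensities[i]),
            }
        )
        for fi, (off, wt) in enumerate(zip(offs, wts)):
            amp = float(intensities[i] * wt)
            foci_rows.append(
                {
                    "frame": 0,
                    "nucleus_id": i,
                    "focus_id": fi,
                    "y": float(y + off[0]),
                    "x": float(x + off[1]),
                    "z_plane": zp,
                    "amplitude": amp,
                }
            )
            _render_focus(
                cid, y + off[0], x + off[1], zp, amp,
                config.psf_sigma_px, config.psf_sigma_z_planes,
            )
        _render_disc(chrom, y, x, z_mid, config.nuclear_radius_px,
                     config.chromatin_level, 1.5)

    stack = np.empty((1, config.n_z, 2, h, w), dtype=np.uint16)
    stack[0, :, 0] = _apply_camera(cid, config, rng)
    stack[0, :, 1] = _apply_camera(chrom, config, rng)
    image = ImageStack(
        pixels=stack,
        pixel_size_um=config.pixel_size_um,
        z_spacing_um=config.z_spacing_um,
        frame_interval_s=config.frame_interval_s,
    )
    return image, GroundTruth(nuclei=pd.DataFrame(nuc_rows), foci=pd.DataFrame(foci_rows))


# ---------------------------------------------------------------------------
# qPCR plates


def generate_qpcr_plate(
    true_copies: Mapping[str, float],
    reference_copies: float = DEFAULT_REFERENCE_COPIES,
    ct_noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int | None = None,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    reference_anchor_ct: float = 15.0,
    sample: str = "NC14",
    minus_rt_ct: Mapping[str, float] | None = None,
    include_controls: bool = True,
) -> QpcrPlate:
    """qPCR plate whose Cts encode known absolute transcript numbers.

    Each target's expected Ct is ``reference_anchor_ct - log2(copies /
    reference_copies)`` (perfect doubling per cycle), plus Gaussian noise of
    s.d. ``ct_noise_sd`` per well.  −RT and no-template wells are included
    undetermined unless ``minus_rt_ct`` plants genomic-DNA contamination for
    a target.  The analysis round-trip recovers the planted copy numbers.
    """
    for tgt, c in true_copies.items():
        if c <= 0:
            raise ValueError(f"copies for {tgt!r} must be > 0")
    if reference_gene in true_copies:
        raise ValueError("reference gene is added automatically; do not plant it")
    rng = np.random.default_rng(seed)
    targets = {reference_gene: reference_copies, **dict(true_copies)}
    rows = []
    wi = 0

    def well_name(i: int) -> str:
        return f"{string.ascii_uppercase[i // 12]}{i % 12 + 1}"

    for tgt, copies in targets.items():
        expect = reference_anchor_ct - np.log2(copies / reference_copies)
        for rep in range(n_replicates):
            ct = expect + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            rows.append(
                {
                    "well": well_name(wi),
                    "target": tgt,
                    "sample": sample,
                    "replicate": rep,
                    "ct": float(ct),
                    "is_minus_rt": False,
                    "is_ntc": False,
                }
            )
            wi += 1
        if include_controls:
            mrt = (minus_rt_ct or {}).get(tgt, np.nan)
            rows.append(
                {
                    "well": well_name(wi),
                    "target": tgt,
                    "sample": sample,
                    "replicate": 0,
                    "ct": float(mrt) if not np.isnan(mrt) else np.nan,
                    "is_minus_rt": True,
                    "is_ntc": False,
                }
            )
            wi += 1
            rows.append(
                {
                    "well": well_name(wi),
                    "target": tgt,
                    "sample": sample,
                    "replicate": 0,
                    "ct": np.nan,
                    "is_minus_rt": False,
                    "is_ntc": True,
                }
            )
            wi += 1
    return QpcrPlate(pd.DataFrame(rows))
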