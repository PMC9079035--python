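"""Photometry chain: z selection, projection, ROIs, background correction."""

import numpy as np
import pandas as pd
import pytest

from cidlab.containers import ImageStack
from cidlab.quantify import (
    QuantifyConfig,
    RoiPair,
    build_nucleus_roi,
    corrected_intensity,
    max_project,
    measure_embryo,
    select_quantification_frames,
    select_z_range,
)
from cidlab.synthetic import generate_timelapse

from conftest import noise_free_config, small_config


def _stack_from_cid(cid: np.ndarray) -> ImageStack:
    """Wrap a (T, Z, Y, X) centromere-channel array into a two-channel stack."""
    pixels = np.zeros((*cid.shape[:2], 2, *cid.shape[2:]), dtype=np.uint16)
    pixels[:, :, 0] = cid
    return ImageStack(pixels, 0.13, 0.5, 60.0)


class TestSelectZRange:
    def test_signal_planes_4_to_11_of_19(self):
        cid = np.zeros((2, 19, 32, 32), dtype=np.uint16)
        cid[:, 4:12] = 50
        _, sel = select_z_range(_stack_from_cid(cid), n_planes=8)
        assert (sel.start, sel.stop) == (4, 12)
        assert not sel.drifted

    def test_uniform_stack_lowest_window(self):
        cid = np.full((1, 12, 16, 16), 7, dtype=np.uint16)
        reduced, sel = select_z_range(_stack_from_cid(cid), n_planes=8)
        assert sel.start == 0
        assert reduced.n_z == 8

    def test_too_few_planes_errors(self):
        cid = np.zeros((1, 5, 8, 8), dtype=np.uint16)
        with pytest.raises(ValueError):
            select_z_range(_stack_from_cid(cid), n_planes=8)

    def test_drifting_embryo_flagged(self):
        config = small_config(seed=8, n_z=18, z_drift=True, z_drift_planes=8)
        stack, _, _ = generate_timelapse(config)
        _, sel = select_z_range(stack, n_planes=8)
        assert sel.drifted

    def test_stable_embryo_not_flagged(self, small_embryo):
        _, stack, _, _ = small_embryo
        _, sel = select_z_range(stack, n_planes=8)
        assert not sel.drifted


class TestMaxProject:
    def test_single_plane_identity(self):
        plane = np.arange(12, dtype=np.uint16).reshape(1, 3, 4)
        assert (max_project(plane) == plane[0]).all()

    def test_disjoint_foci_union(self):
        a = np.zeros((2, 4, 4), dtype=np.uint16)
        a[0, 1, 1] = 9
        a[1, 2, 3] = 7
        proj = max_project(a)
        assert proj[1, 1] == 9 and proj[2, 3] == 7

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 1000, size=(6, 9, 11)).astype(np.uint16)
        proj = max_project(arr)
        for y in range(9):
            for x in range(11):
                assert proj[y, x] == max(arr[z, y, x] for z in range(6))

    def test_imagestack_axes(self, small_embryo):
        _, stack, _, _ = small_embryo
        proj = max_project(stack)
        assert proj.shape == (stack.n_frames, 2, *stack.shape_yx)


class TestSelectQuantificationFrames:
    @staticmethod
    def _track(rows):
        return pd.DataFrame(rows, columns=["cycle", "frame", "phase"])

    def test_first_anaphase_minus_two(self):
        track = self._track([(12, 30, "metaphase"), (12, 31, "anaphase"), (12, 32, "anaphase")])
        assert select_quantification_frames(track) == {12: 29}

    def test_two_mitoses(self):
        track = self._track(
            [(11, 10, "anaphase"), (11, 11, "anaphase"), (12, 25, "anaphase")]
        )
        assert select_quantification_frames(track) == {11: 8, 12: 23}

    def test_early_anaphase_skipped_with_warning(self):
        track = self._track([(11, 1, "anaphase"), (12, 20, "anaphase")])
        with pytest.warns(UserWarning, match="frame 1"):
            frames = select_quantification_frames(track)
        assert frames == {12: 18}

    def test_no_anaphase_errors(self):
        with pytest.raises(ValueError):
            select_quantification_frames(self._track([(11, 3, "metaphase")]))

    def test_selected_frames_are_prometa_or_metaphase(self, small_embryo):
        _, _, gt, track = small_embryo
        for cycle, frame in select_quantification_frames(track).items():
            phases = set(
                gt.nuclei.query("frame == @frame and cycle == @cycle")["phase"]
            )
            assert phases <= {"prometaphase", "metaphase"}


def _brute_force_dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Set-based 8-connected dilation oracle."""
    pts = {(y, x) for y, x in zip(*np.nonzero(mask))}
    h, w = mask.shape
    for _ in range(iterations):
        new = set(pts)
        for y, x in pts:
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w:
                        new.add((ny, nx))
        pts = new
    out = np.zeros_like(mask)
    for y, x in pts:
        out[y, x] = True
    return out


class TestBuildNucleusRoi:
    def test_shell_is_three_pixel_dilation_minus_inner(self):
        img = np.zeros((25, 25))
        img[12, 12] = 500.0
        roi = build_nucleus_roi(img, (12.0, 12.0), footprint_radius_px=6.0)
        assert roi is not None
        expected_shell = _brute_force_dilate(roi.inner, 3) & ~roi.inner
        assert (roi.shell == expected_shell).all()
        assert roi.inner[12, 12]

    def test_border_roi_clipped_and_flagged(self):
        img = np.zeros((25, 25))
        img[1, 1] = 500.0
        roi = build_nucleus_roi(img, (1.0, 1.0), footprint_radius_px=4.0)
        assert roi is not None
        assert roi.touches_border

    def test_no_dots_returns_none(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 1, size=(25, 25))
        roi = build_nucleus_roi(img, (12.0, 12.0), threshold_k=50.0)
        assert roi is None

    def test_inner_covers_all_planted_foci(self, small_embryo):
        config, stack, gt, track = small_embryo
        reduced, _ = select_z_range(stack, 8)
        frames = select_quantification_frames(track)
        cycle, frame = sorted(frames.items())[0]
        proj = max_project(reduced)[frame, 0].astype(np.float64)
        nuc = gt.nuclei.query("frame == @frame").iloc[0]
        roi = build_nucleus_roi(
            proj,
            (nuc.centroid_y, nuc.centroid_x),
            footprint_radius_px=config.nuclear_radius_px * 1.5,
        )
        assert roi is not None
        foci = gt.foci.query("frame == @frame and nucleus_id == @nuc.nucleus_id")
        for row in foci.itertuples():
            assert roi.inner[int(round(row.y)), int(round(row.x))]

    def test_disjointness_enforced(self):
        inner = np.zeros((5, 5), dtype=bool)
        inner[2, 2] = True
        with pytest.raises(ValueError):
            RoiPair(inner=inner, shell=inner.copy())


class TestCorrectedIntensity:
    @staticmethod
    def _roi(shape, cy, cx, r_in, dilate=3):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        inner = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_in**2
        outer = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r_in + dilate) ** 2
        return RoiPair(inner=inner, shell=outer & ~inner)

    def test_constant_image_gives_zero(self):
        img = np.full((20, 20), 37.0)
        roi = self._roi((20, 20), 10, 10, 4)
        m = corrected_intensity(img, roi)
        assert m.corrected_intensity == pytest.approx(0.0, abs=1e-9)

    def test_single_bright_pixel(self):
        img = np.zeros((20, 20))
        img[10, 10] = 100.0
        roi = self._roi((20, 20), 10, 10, 3)
        m = corrected_intensity(img, roi)
        assert m.corrected_intensity == pytest.approx(100.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            img = rng.integers(0, 4096, size=(64, 64)).astype(np.float64)
            cy, cx = rng.integers(10, 54, size=2)
            roi = self._roi((64, 64), cy, cx, rng.integers(3, 8))
            m = corrected_intensity(img, roi)
            raw = sum(
                img[y, x] for y in range(64) for x in range(64) if roi.inner[y, x]
            )
            shell_vals = [
                img[y, x] for y in range(64) for x in range(64) if roi.shell[y, x]
            ]
            expected = raw - np.mean(shell_vals) * roi.n_inner_px
            assert m.corrected_intensity == pytest.approx(expected, rel=1e-12)

    def test_offset_invariance_and_gain_equivariance(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1000, size=(40, 40))
        roi = self._roi((40, 40), 20, 20, 5)
        base = corrected_intensity(img, roi).corrected_intensity
        for b, c in [(50.0, 1.0), (0.0, 3.0), (123.4, 0.25)]:
            v = corrected_intensity(c * img + b, roi).corrected_intensity
            assert v == pytest.approx(c * base, rel=1e-9)

    def test_empty_shell_errors(self):
        inner = np.ones((4, 4), dtype=bool)
        roi = RoiPair(inner=inner, shell=np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="nucleus 7"):
            corrected_intensity(np.ones((4, 4)), roi, nucleus_id=7)

    def test_identity_holds_in_output(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 500, size=(30, 30))
        roi = self._roi((30, 30), 15, 15, 4)
        m = corrected_intensity(img, roi)
        assert m.corrected_intensity == pytest.approx(
            m.raw_integrated - m.background_mean_per_px * m.n_inner_px, rel=1e-12
        )


class TestMeasureEmbryo:
    def test_noise_free_recovery_within_2_percent(self):
        config = noise_free_config(e=1.0, seed=21)
        stack, gt, track = generate_timelapse(config)
        m = measure_embryo(stack, track)
        frames = select_quantification_frames(track)
        for cycle, frame in frames.items():
            truth = gt.nuclei.query("frame == @frame").set_index("nucleus_id")[
                "true_intensity"
            ]
            got = m.query("cycle == @cycle and not excluded").set_index("nucleus_id")[
                "corrected_intensity"
            ]
            assert len(got) > 0
            rel = (got / truth.loc[got.index]).to_numpy()
            assert np.abs(rel - 1).max() < 0.02

    def test_all_catastrophic_rows_excluded(self):
        config = small_config(seed=13, catastrophe_rate_per_mitosis=1.0)
        stack, _, track = generate_timelapse(config)
        m = measure_embryo(stack, track)
        assert len(m) > 0
        assert m["excluded"].all()
        assert set(m["exclusion_reason"]) == {"catastrophic"}

    def test_drifting_embryo_rows_excluded(self):
        config = small_config(seed=8, n_z=18, z_drift=True, z_drift_planes=8)
        stack, _, track = generate_timelapse(config)
        m = measure_embryo(stack, track)
        assert m["excluded"].all()
        assert set(m["exclusion_reason"]) == {"z_drift_embryo"}

    def test_default_noise_relative_error_95th_percentile(self, default_embryo):
        _, stack, gt, track = default_embryo
        m = measure_embryo(stack, track)
        frames = select_quantification_frames(track)
        errs = []
        for cycle, frame in frames.items():
            truth = gt.nuclei.query("frame == @frame").set_index("nucleus_id")[
                "true_intensity"
            ]
            got = m.query("cycle == @cycle and not excluded").set_index("nucleus_id")[
                "corrected_intensity"
            ]
            errs.extend(np.abs(got / truth.loc[got.index] - 1).tolist())
        assert np.quantile(errs, 0.95) <= 0.10

    def test_photometric_linearity(self):
        from dataclasses import replace

        base = small_config(seed=17)
        bright = replace(
            base, model=replace(base.model, initial_intensity=2 * base.model.initial_intensity)
        )
        m1 = measure_embryo(*_sim_and_track(base))
        m2 = measure_embryo(*_sim_and_track(bright))
        v1 = m1.query("not excluded").groupby("cycle")["corrected_intensity"].mean()
        v2 = m2.query("not excluded").groupby("cycle")["corrected_intensity"].mean()
        assert ((v2 / v1) == pytest.approx(2.0, rel=0.02)).all() or np.allclose(
            v2 / v1, 2.0, rtol=0.02
        )


def _sim_and_track(config):
    stack, _, track = generate_timelapse(config)
    return stack, track


def test_z_integration_mode_preserves_cycle_ratio():
    # 3D (z-sum) photometry recovers the same halving as the projection mode
    config = noise_free_config(e=0.0, seed=23)
    stack, _, track = generate_timelapse(config)
    m = measure_embryo(stack, track, QuantifyConfig(integrate_z=True))
    means = m.query("not excluded").groupby("cycle")["corrected_intensity"].mean()
    assert means.loc[12] / means.loc[11] == pytest.approx(0.5, abs=0.02)
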