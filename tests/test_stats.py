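"""Normalization, cycle ratios, loading curves, catastrophe scoring, t test."""

import numpy as np
import pandas as pd
import pytest

from cidlab.quantify import measure_embryo
from cidlab.stats import (
    catastrophe_fraction,
    cycle_ratios,
    cycle_summaries,
    normalize_to_reference_cycle,
    per_centromere_intensity,
    two_sample_test,
)
from cidlab.synthetic import generate_timelapse

from conftest import small_config


def _meas(rows):
    return pd.DataFrame(rows, columns=["embryo_id", "cycle", "corrected_intensity"])


class TestNormalize:
    def test_all_equal_becomes_100(self):
        m = _meas([("a", 11, 7.0), ("a", 12, 7.0), ("a", 13, 7.0)])
        out = normalize_to_reference_cycle(m)
        assert (out["corrected_intensity"] == 100.0).all()

    def test_reference_mean_exact(self):
        m = _meas([("a", 12, 50.0), ("a", 12, 150.0), ("a", 13, 100.0)])
        out = normalize_to_reference_cycle(m)
        ref = out.query("cycle == 12")["corrected_intensity"]
        assert ref.mean() == pytest.approx(100.0, rel=1e-12)
        assert out.query("cycle == 13")["corrected_intensity"].iloc[0] == pytest.approx(100.0)

    def test_random_measurements_reference_mean_100(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"e{i}", c, float(v))
            for i in range(5)
            for c in (11, 12, 13)
            for v in rng.uniform(10, 1000, size=8)
        ]
        out = normalize_to_reference_cycle(_meas(rows))
        for _, grp in out.groupby("embryo_id"):
            assert grp.query("cycle == 12")["corrected_intensity"].mean() == pytest.approx(
                100.0, rel=1e-9
            )

    def test_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        m = _meas([("a", c, float(v)) for c in (11, 12) for v in rng.uniform(1, 50, 6)])
        once = normalize_to_reference_cycle(m)
        twice = normalize_to_reference_cycle(once)
        pd.testing.assert_frame_equal(once, twice)
        scaled = m.copy()
        scaled["corrected_intensity"] *= 13.7
        pd.testing.assert_series_equal(
            normalize_to_reference_cycle(scaled)["corrected_intensity"],
            once["corrected_intensity"],
        )

    def test_missing_reference_cycle_names_embryo(self):
        m = _meas([("bad_embryo", 11, 5.0)])
        with pytest.raises(ValueError, match="bad_embryo"):
            normalize_to_reference_cycle(m)


class TestCycleRatios:
    def test_equal_means_ratio_one(self):
        summ = cycle_summaries(_meas([("a", 11, 100.0), ("a", 12, 100.0)]))
        res = cycle_ratios(summ, pairs=((12, 11),))
        assert res["per_embryo"]["value"].iloc[0] == pytest.approx(1.0)

    def test_halving_pattern(self):
        # complete loading block: successive halving gives 0.5 and 0.25
        summ = cycle_summaries(
            _meas([("a", 11, 100.0), ("a", 12, 50.0), ("a", 13, 25.0)])
        )
        res = cycle_ratios(summ)["per_embryo"].set_index("ratio_name")["value"]
        assert res["NC12/NC11"] == pytest.approx(0.5)
        assert res["NC13/NC12"] == pytest.approx(0.5)
        assert res["NC13/NC11"] == pytest.approx(0.25)

    def test_multiplicativity_identity(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"e{i}", c, float(v))
            for i in range(10)
            for c in (11, 12, 13)
            for v in rng.uniform(5, 500, size=4)
        ]
        res = cycle_ratios(cycle_summaries(_meas(rows)))["per_embryo"]
        wide = res.pivot(index="embryo_id", columns="ratio_name", values="value")
        lhs = wide["NC13/NC11"]
        rhs = wide["NC13/NC12"] * wide["NC12/NC11"]
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_missing_cycle_skipped_with_warning(self):
        summ = cycle_summaries(_meas([("a", 11, 10.0), ("b", 11, 10.0), ("b", 12, 20.0)]))
        with pytest.warns(UserWarning, match="'a'"):
            res = cycle_ratios(summ, pairs=((12, 11),))
        assert set(res["per_embryo"]["embryo_id"]) == {"b"}

    def test_aggregate_uses_sample_sd(self):
        rows = [("a", 11, 10.0), ("a", 12, 10.0), ("b", 11, 10.0), ("b", 12, 20.0)]
        res = cycle_ratios(cycle_summaries(_meas(rows)), pairs=((12, 11),))
        agg = res["aggregate"].iloc[0]
        vals = np.array([1.0, 2.0])
        assert agg["mean"] == pytest.approx(vals.mean())
        assert agg["sd"] == pytest.approx(vals.std(ddof=1))
        assert agg["n_embryos"] == 2


class TestPerCentromere:
    def _df(self, phase, value):
        return pd.DataFrame(
            {"phase": [phase], "corrected_intensity": [value]}
        )

    def test_metaphase_halved(self):
        out = per_centromere_intensity(self._df("metaphase", 200.0))
        assert out["per_centromere_intensity"].iloc[0] == 100.0

    def test_telophase_unchanged(self):
        out = per_centromere_intensity(self._df("telophase", 100.0))
        assert out["per_centromere_intensity"].iloc[0] == 100.0

    def test_unknown_phase_errors(self):
        with pytest.raises(ValueError, match="cytokinesis"):
            per_centromere_intensity(self._df("cytokinesis", 1.0))

    def test_loading_doubles_per_centromere_signal(self):
        # full replenishment: late-telophase per-centromere level is about
        # twice the early-anaphase level
        config = small_config(e=1.0, seed=19)
        _, gt, _ = generate_timelapse(config)
        df = gt.nuclei.rename(columns={"true_intensity": "corrected_intensity"})
        out = per_centromere_intensity(df)
        exit_rows = out[out["phase"].isin(["anaphase", "telophase"])]
        by_frame = exit_rows.groupby("frame")["per_centromere_intensity"].mean()
        first_ana = by_frame.index.min()
        last_telo = by_frame.index.max()
        assert by_frame[last_telo] / by_frame[first_ana] == pytest.approx(2.0, rel=0.05)


class TestCatastropheFraction:
    def _track(self, n_total, n_cat, cycle=12):
        rows = []
        for i in range(n_total):
            fate = "catastrophic" if i < n_cat else "normal"
            rows.append(("e1", i, 0, cycle, "metaphase", fate))
        return pd.DataFrame(
            rows,
            columns=["embryo_id", "nucleus_id", "frame", "cycle", "phase", "fate"],
        )

    def test_two_of_hundred(self):
        out = catastrophe_fraction(self._track(100, 2))
        assert out["fraction"].iloc[0] == 0.02
        assert out["mitosis"].iloc[0] == "M12"

    def test_zero_catastrophes(self):
        out = catastrophe_fraction(self._track(50, 0))
        assert out["fraction"].iloc[0] == 0.0

    def test_generator_rate_within_binomial_ci(self):
        rate = 0.05
        tracks = []
        for s in range(6):
            config = small_config(
                seed=60 + s, catastrophe_rate_per_mitosis=rate, n_cycles=3,
                field_size_px=(176, 176),
            )
            _, _, track = generate_timelapse(config, embryo_id=f"e{s}")
            tracks.append(track)
        out = catastrophe_fraction(pd.concat(tracks))
        n = out["n_entering"].sum()
        k = out["n_catastrophic"].sum()
        p_hat = k / n
        half = 1.96 * np.sqrt(rate * (1 - rate) / n)
        assert abs(p_hat - rate) < half + 1e-12


class TestTwoSampleTest:
    def test_identical_groups(self):
        t, p = two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_zero_variance_identical(self):
        t, p = two_sample_test([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_small_groups_error(self):
        with pytest.raises(ValueError):
            two_sample_test([1.0], [1.0, 2.0])

    def test_separated_groups_vs_permutation_oracle(self):
        rng = np.random.default_rng(4)
        a = 0.0 + rng.normal(0, 1e-3, 4)
        b = 1.0 + rng.normal(0, 1e-3, 4)
        t, p = two_sample_test(a, b)
        assert p < 1e-4
        # permutation oracle: observed |t| is the most extreme attainable
        from itertools import combinations

        pooled = np.concatenate([a, b])
        count_ge = 0
        total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(idx)] = True
            tt, _ = two_sample_test(pooled[mask], pooled[~mask])
            total += 1
            if abs(tt) >= abs(t) - 1e-12:
                count_ge += 1
        assert count_ge == 2  # only the observed split and its mirror
        assert count_ge / total == pytest.approx(2 / 70)


class TestEndToEnd:
    @pytest.mark.parametrize("e, expected", [(0.0, 0.5), (1.0, 1.0)])
    def test_generator_to_ratio_recovers_prediction(self, e, expected):
        frames = []
        for s in range(3):
            config = small_config(e=e, seed=80 + s)
            stack, _, track = generate_timelapse(config, embryo_id=f"e{s}")
            frames.append(measure_embryo(stack, track))
        summ = cycle_summaries(pd.concat(frames, ignore_index=True))
        res = cycle_ratios(summ, pairs=((12, 11),))
        assert res["aggregate"]["mean"].iloc[0] == pytest.approx(expected, abs=0.05)


class TestPooledRatios:
    def test_pooled_matches_hand_computation(self):
        rows = [
            ("a", 11, 100.0), ("a", 11, 200.0), ("b", 11, 300.0),
            ("a", 12, 50.0), ("b", 12, 100.0), ("b", 12, 150.0),
        ]
        from cidlab.stats import pooled_cycle_ratios

        out = pooled_cycle_ratios(_meas(rows), pairs=((12, 11),))
        # pooled means: NC11 = 200, NC12 = 100
        assert out["value"].iloc[0] == pytest.approx(0.5)
        assert out["n_nuclei_num"].iloc[0] == 3
        assert out["n_nuclei_den"].iloc[0] == 3
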