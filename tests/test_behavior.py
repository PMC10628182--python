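import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from driftring import GenerativeModelSpec, SessionConfig, generate_dataset
from driftring.behavior import (
    DIAGONAL,
    bias_and_precision,
    bias_precision_along_diagonal,
    binomial_chance_test,
    cochrans_q_test,
    friedman_test,
    hodges_ajne_test,
    normalized_response_frequency,
    performance_by_condition,
    serial_dependence_curve,
    session_cell_performance,
    variance_partitioning,
    _half_circle_min,
)
from driftring.fokker_planck import DriftField
from driftring.wheel import ColorWheelSpec, index_to_angle


class TestPerformanceMatrix:
    def test_all_exact_gives_ones(self, six_attractor_table):
        t = six_attractor_table.copy()
        t["response_idx"] = t["target_idx"]
        perf = performance_by_condition(t)
        for mat in perf["matrices"].values():
            assert np.allclose(mat.to_numpy(float), 1.0)

    def test_uniform_responses_at_chance(self):
        rng = np.random.default_rng(0)
        t = generate_dataset(SessionConfig(n_trials=45_000, seed=1), GenerativeModelSpec())
        t["response_idx"] = rng.integers(1, 65, len(t))
        perf = performance_by_condition(t)
        full = perf["matrices"]["full"].to_numpy(float)
        n_cell = perf["counts"].to_numpy(float)
        se = np.sqrt((7 / 64) * (1 - 7 / 64) / n_cell)
        assert np.all(np.abs(full - 7 / 64) < 4 * se)

    def test_accuracy_nesting(self, six_attractor_table):
        perf = performance_by_condition(six_attractor_table)
        exact = perf["matrices"]["exact"].to_numpy(float)
        inner = perf["matrices"]["inner"].to_numpy(float)
        full = perf["matrices"]["full"].to_numpy(float)
        assert np.all(exact <= inner + 1e-12) and np.all(inner <= full + 1e-12)

    def test_empty_cell_flagged_missing(self):
        w = np.zeros(9)
        w[0] = 1.0
        t = generate_dataset(
            SessionConfig(n_trials=200, trial_type_weights=w, seed=2), GenerativeModelSpec(p_swap=0)
        )
        perf = performance_by_condition(t)
        assert np.isnan(perf["matrices"]["full"].loc["load2_retro", "long"])


class TestBiasPrecision:
    def test_identical_errors_bias_and_cap(self):
        out = bias_and_precision(np.full(100, 0.2))
        assert out["bias"] == pytest.approx(0.2)
        assert out["degenerate"]
        assert out["precision"] > 100  # reported at the documented cap

    def test_uniform_errors_precision_near_zero(self):
        rng = np.random.default_rng(3)
        out = bias_and_precision(rng.uniform(-np.pi, np.pi, 1000))
        assert abs(out["precision"]) < 0.05

    def test_von_mises_inverse_sd_matches_bessel_closed_form(self):
        from driftring.behavior import circular_sd

        rng = np.random.default_rng(4)
        kappa = 2.0
        errors = rng.vonmises(0, kappa, 200_000)
        rbar = special.i1e(kappa) / special.i0e(kappa)
        expected_inv_sd = 1 / np.sqrt(-2 * np.log(rbar))  # ~1.18
        assert 1 / circular_sd(errors) == pytest.approx(expected_inv_sd, rel=0.01)

    def test_demand_diagonal_monotone(self):
        # rising sigma*t along the diagonal: bias non-decreasing, precision non-increasing
        cfg = SessionConfig(n_trials=18_000, seed=5)
        tab = generate_dataset(cfg, GenerativeModelSpec())
        res = bias_precision_along_diagonal(tab)
        assert list(res["condition"]) == [c for c, _ in DIAGONAL]
        assert np.all(np.diff(res["bias"]) >= -0.01)
        assert np.all(np.diff(res["precision"]) <= 0.05)


class TestNormalizedResponseFrequency:
    def test_identity_responses_give_unit_ratio(self, six_attractor_table):
        t = six_attractor_table.copy()
        t["response_idx"] = t["target_idx"]
        out = normalized_response_frequency(t)
        assert np.allclose(out["ratio"], 1.0)

    def test_mass_conservation(self, six_attractor_table):
        out = normalized_response_frequency(six_attractor_table)
        assert (out["ratio"] * out["target_count"]).sum() == pytest.approx(len(six_attractor_table))

    def test_all_responses_one_color(self, six_attractor_table):
        t = six_attractor_table.copy()
        t["response_idx"] = 1
        out = normalized_response_frequency(t)
        assert out.loc[0, "ratio"] == pytest.approx(len(t) / out.loc[0, "target_count"])
        assert np.all(out["ratio"].iloc[1:] == 0)

    def test_missing_target_color_rejected(self, six_attractor_table):
        t = six_attractor_table[six_attractor_table["target_idx"] != 5]
        with pytest.raises(ValueError, match="5"):
            normalized_response_frequency(t)

    def test_peaks_at_generating_attractors(self):
        # responses cluster at the six attractor colors (1, ~11.7, ...)
        tab = generate_dataset(SessionConfig(n_trials=30_000, seed=6), GenerativeModelSpec())
        ratio = normalized_response_frequency(tab)["ratio"].to_numpy()
        attractor_angles = np.arange(6) * np.pi / 3
        attractor_cols = np.round(attractor_angles / (2 * np.pi / 64)).astype(int)  # 0-based
        for c in attractor_cols:
            window = ratio[[(c - 1) % 64, c, (c + 1) % 64]]
            neighborhood = ratio[[(c + k) % 64 for k in range(-5, 6)]]
            assert window.max() == pytest.approx(neighborhood.max())


class TestHodgesAjne:
    def test_exact_formula_half_circle(self):
        rng = np.random.default_rng(7)
        angles = rng.uniform(0.2, np.pi - 0.2, 10)
        res = hodges_ajne_test(angles)
        assert res["m"] == 0
        assert res["p"] == pytest.approx(10 / 2**9)

    def test_antipodal_pairs_maximally_uniform(self):
        base = np.linspace(0, np.pi, 8, endpoint=False)
        angles = np.concatenate([base, base + np.pi])
        res = hodges_ajne_test(angles)
        assert res["p"] > 0.5

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        n = 20
        angles = np.concatenate([rng.vonmises(0, 2, 14), rng.uniform(0, 2 * np.pi, 6)])
        res = hodges_ajne_test(angles)
        m_obs = _half_circle_min(angles)
        null = np.array(
            [_half_circle_min(rng.uniform(0, 2 * np.pi, n)) for _ in range(20_000)]
        )
        p_mc = np.mean(null <= m_obs)
        se = np.sqrt(p_mc * (1 - p_mc) / 20_000)
        if res["method"] == "exact":
            assert abs(res["p"] - p_mc) < max(4 * se, 0.01)

    def test_clustered_data_highly_significant(self):
        rng = np.random.default_rng(9)
        angles = rng.vonmises(1.0, 3.0, 2000)
        assert hodges_ajne_test(angles)["p"] < 1e-4


class TestCochransQ:
    def test_identical_columns(self):
        x = np.tile([[1], [0], [1], [1]], (1, 3))
        res = cochrans_q_test(x)
        assert res["Q"] == 0 and res["p"] == pytest.approx(1.0)

    def test_worked_example_equals_three(self):
        res = cochrans_q_test([[1, 0], [1, 0], [1, 0], [1, 1], [0, 0]])
        assert res["Q"] == pytest.approx(3.0)
        # McNemar equivalence for k = 2: (b - c)^2 / (b + c) with b=3, c=0
        assert res["Q"] == pytest.approx((3 - 0) ** 2 / (3 + 0))

    def test_strong_difference_significant(self):
        rng = np.random.default_rng(10)
        x = np.column_stack([rng.random(100) < 0.9, rng.random(100) < 0.1]).astype(int)
        assert cochrans_q_test(x)["p"] < 0.001

    def test_degenerate_constant_rows(self):
        res = cochrans_q_test(np.ones((5, 3)))
        assert res["degenerate"] and res["Q"] == 0.0


class TestBinomialChanceTest:
    def test_k_zero_is_one(self):
        assert binomial_chance_test(0, 50, 0.11) == pytest.approx(1.0)

    def test_all_successes_closed_form(self):
        assert binomial_chance_test(50, 50, 0.11) == pytest.approx(0.11**50)

    def test_matches_enumeration_oracle(self):
        n, p0 = 10, 0.11
        for k in range(n + 1):
            brute = sum(
                special.comb(n, j, exact=True) * p0**j * (1 - p0) ** (n - j)
                for j in range(k, n + 1)
            )
            assert binomial_chance_test(k, n, p0) == pytest.approx(brute, rel=1e-10)


class TestVariancePartitioning:
    @staticmethod
    def _cells(load_effect, delay_effect, noise, n_sessions, rng):
        rows = []
        for s in range(n_sessions):
            for i, lc in enumerate(["load1", "load2_sim", "load2_retro"]):
                for j, dc in enumerate(["simultaneous", "short", "long"]):
                    rows.append(
                        {
                            "session_id": f"s{s}",
                            "load_condition": lc,
                            "delay_class": dc,
                            "performance": 0.5 + load_effect * i + delay_effect * j + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_pure_load_effect(self):
        rng = np.random.default_rng(11)
        res = variance_partitioning(self._cells(0.1, 0.0, 0.01, 12, rng)).set_index("factor")
        assert res.loc["load", "omega_sq_partial"] > 0.5
        assert abs(res.loc["delay", "omega_sq_partial"]) < 0.1

    def test_null_unbiased(self):
        rng = np.random.default_rng(12)
        omegas = []
        for _ in range(200):
            res = variance_partitioning(self._cells(0, 0, 0.05, 6, rng))
            omegas.append(res["omega_sq_partial"].to_numpy())
        assert np.all(np.abs(np.mean(omegas, axis=0)) < 0.01)

    def test_effect_ordering_recovered(self):
        rng = np.random.default_rng(13)
        res = variance_partitioning(self._cells(0.02, 0.08, 0.02, 20, rng)).set_index("factor")
        assert res.loc["delay", "omega_sq_partial"] > res.loc["load", "omega_sq_partial"]

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(14)
        cells = self._cells(0, 0, 0.05, 4, rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            variance_partitioning(cells)

    def test_session_cell_performance_shape(self, six_attractor_table):
        cells = session_cell_performance(six_attractor_table)
        assert set(cells.columns) == {"session_id", "load_condition", "delay_class", "performance"}


class TestFriedman:
    def test_identical_conditions(self):
        res = friedman_test(np.ones((10, 3)))
        assert res["chi2"] == 0 and res["p"] == 1.0 and res["kendalls_w"] == 0

    def test_perfect_concordance_w_is_one(self):
        x = np.tile([1.0, 2.0, 3.0], (20, 1)) + np.arange(20)[:, None]
        res = friedman_test(x)
        assert res["kendalls_w"] == pytest.approx(1.0)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(20, 3))
        res = friedman_test(x)
        chi2, p = stats.friedmanchisquare(*x.T)
        assert res["chi2"] == pytest.approx(chi2)
        assert res["p"] == pytest.approx(p)

    def test_monotone_shift_significant_vs_permutation(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(20, 3)) + np.array([0.0, 0.8, 1.6])
        res = friedman_test(x)
        assert res["p"] < 0.01
        # permutation oracle: shuffle within blocks
        null = []
        for _ in range(500):
            xp = np.apply_along_axis(rng.permutation, 1, x)
            null.append(friedman_test(xp)["chi2"])
        assert np.mean(np.array(null) >= res["chi2"]) < 0.02


class TestSerialDependence:
    @staticmethod
    def _dataset(gain, n, seed):
        cfg = SessionConfig(n_trials=n, seed=seed, serial_bias_gain=gain)
        model = GenerativeModelSpec(
            drift=DriftField(np.zeros(12)),
            beta_encode={1: 0, 2: 0}, beta_memory={1: 0, 2: 0},
            sigma_encode={1: 0.15, 2: 0.15}, sigma_memory={1: 0.15, 2: 0.15},
            p_swap=0.0, p_guess={1: 0, 2: 0},
        )
        return generate_dataset(cfg, model)

    def test_no_injection_no_peak(self):
        curve = serial_dependence_curve(self._dataset(0.0, 10_000, 17))
        assert abs(curve.peak_magnitude_rad) < 0.02

    def test_recovers_injected_attraction(self):
        curve = serial_dependence_curve(self._dataset(0.1, 10_000, 18))
        assert curve.peak_magnitude_rad == pytest.approx(0.1, abs=0.02)
        assert curve.peak_location_deg == pytest.approx(90, abs=10)

    def test_shuffling_previous_targets_destroys_peak(self):
        tab = self._dataset(0.1, 10_000, 19)
        rng = np.random.default_rng(20)
        shuffled = tab.copy()
        shuffled["prev_target_idx"] = rng.permutation(shuffled["prev_target_idx"].to_numpy())
        curve = serial_dependence_curve(shuffled)
        assert abs(curve.peak_magnitude_rad) < 0.02

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="previous target"):
            serial_dependence_curve(self._dataset(0.0, 200, 21), min_trials=1000)
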