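import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from beadtask.stats import (
    adjust_correlated_p,
    draws_to_decision,
    exclusion_filter,
    jtc_split,
    kolmogorov_sf,
    ks_test,
    mann_whitney_u,
    outlier_sensitivity,
    partial_spearman,
    spearman,
)


class TestExclusionFilter:
    def test_equal_error_rates_nobody_excluded(self):
        df = pd.DataFrame({"subject_id": list("abcd"), "error_rate": [0.1] * 4})
        kept, excl = exclusion_filter(df)
        assert len(kept) == 4 and len(excl) == 0

    def test_planted_outliers_excluded(self):
        rng = np.random.default_rng(0)
        rates = np.concatenate([rng.uniform(0.0, 0.15, 94), [0.6, 0.65, 0.7, 0.75]])
        df = pd.DataFrame({"subject_id": range(98), "error_rate": rates})
        kept, excl = exclusion_filter(df)
        assert set(excl["subject_id"]) == {94, 95, 96, 97}
        assert len(kept) == 94

    def test_single_subject_kept(self):
        df = pd.DataFrame({"subject_id": ["a"], "error_rate": [0.9]})
        kept, excl = exclusion_filter(df)
        assert len(kept) == 1 and len(excl) == 0


class TestDrawsToDecision:
    def test_unit_and_mean(self):
        rows = []
        for rnd, n in enumerate([2, 3, 4], start=1):
            for d in range(1, n + 1):
                rows.append({"subject_id": "s", "round": rnd, "draw": d,
                             "committed": d == n})
        assert draws_to_decision(pd.DataFrame(rows)).loc["s"] == pytest.approx(3.0)

    def test_missing_commit_raises(self):
        df = pd.DataFrame([{"subject_id": "s", "round": 1, "draw": 1, "committed": False}])
        with pytest.raises(ValueError):
            draws_to_decision(df)

    def test_higher_threshold_more_draws(self, task_config):
        from beadtask.models import ModelParams
        from beadtask.synthetic import simulate_subject

        p = ModelParams(0.25, 0.6, 3.4)
        lo = simulate_subject(p, 0.30, 0.05, task_config, np.random.default_rng(5), "lo")
        hi = simulate_subject(p, 0.45, 0.05, task_config, np.random.default_rng(5), "hi")
        both = pd.concat([lo, hi])
        dtd = draws_to_decision(both)
        assert dtd["hi"] > dtd["lo"]


class TestJtcSplit:
    def test_quartile_brute_force(self):
        df = pd.DataFrame({"mean_draws_to_decision": np.arange(1.0, 9.0)})
        labels = jtc_split(df, rule="quartile")
        assert labels.tolist() == [True, True] + [False] * 6

    def test_fixed_rule(self):
        df = pd.DataFrame({"mean_draws_to_decision": [1.5, 2.0, 2.1]})
        assert jtc_split(df, rule="fixed").tolist() == [True, True, False]

    def test_all_ties_included(self):
        df = pd.DataFrame({"mean_draws_to_decision": [3.0] * 6})
        assert jtc_split(df, rule="quartile").all()


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(b, a)
        assert p1 == pytest.approx(p2)

    def test_null_p_distribution(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            ps.append(mann_whitney_u(rng.normal(size=40), rng.normal(size=40))[1])
        assert 0.3 <= np.median(ps) <= 0.7


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_simulation_calibration(self):
        rng = np.random.default_rng(8)
        target = -0.25
        rho_lat = 2 * np.sin(np.pi * target / 6)
        rhos = []
        for _ in range(500):
            z = rng.standard_normal((94, 2))
            x = z[:, 0]
            y = rho_lat * z[:, 0] + np.sqrt(1 - rho_lat**2) * z[:, 1]
            rhos.append(spearman(x, y)[0])
        assert np.mean(rhos) == pytest.approx(target, abs=0.03)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3)
        assert rho2 == pytest.approx(rho)
        assert p2 == pytest.approx(p)

    def test_type_one_error_calibration(self):
        """Nominal 5% level holds at n=94 under the null."""
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            if spearman(rng.normal(size=94), rng.normal(size=94))[1] < 0.05:
                hits += 1
        assert 0.03 <= hits / n_rep <= 0.07


class TestPartialSpearman:
    def test_independent_covariate_matches_plain(self):
        rng = np.random.default_rng(11)
        n = 500
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        rho, _ = spearman(x, y)
        prho, _ = partial_spearman(x, y, z)
        assert prho == pytest.approx(rho, abs=0.02)

    def test_collinear_covariate_errors(self):
        x = np.arange(10.0)
        y = np.arange(10.0)[::-1]
        with pytest.raises(ValueError):
            partial_spearman(x, y, y)

    def test_null_centred_at_zero(self):
        rng = np.random.default_rng(12)
        vals = [partial_spearman(*rng.normal(size=(3, 40)))[0] for _ in range(300)]
        assert abs(np.mean(vals)) < 0.03

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        n = 60
        z = rng.normal(size=n)
        x = 0.4 * z + rng.normal(size=n)
        y = -0.3 * z + 0.2 * x + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        rho, p = partial_spearman(x, y, z)
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-10)


class TestKsTest:
    @pytest.mark.parametrize("z,expected", [(1.374, 0.046), (1.941, 0.001), (1.051, 0.219)])
    def test_printed_z_to_p_pairs(self, z, expected):
        assert round(kolmogorov_sf(z), 3) == expected

    def test_series_oracle(self):
        """Q(Z) agrees with a 100-term alternating series to 1e-10."""
        for z in [0.3, 0.7, 1.051, 1.374, 1.941, 2.5]:
            k = np.arange(1, 101)
            series = 2 * np.sum((-1.0) ** (k - 1) * np.exp(-2 * k**2 * z**2))
            assert kolmogorov_sf(z) == pytest.approx(series, abs=1e-10)

    def test_null_uniformity(self):
        rng = np.random.default_rng(14)
        ps = [ks_test(rng.uniform(size=1000), "uniform", (0, 1))[2] for _ in range(200)]
        assert 0.3 <= np.median(ps) <= 0.7

    def test_normal_reference_uses_sample_moments(self):
        rng = np.random.default_rng(15)
        x = rng.normal(10, 3, 500)
        d, z, p = ks_test(x, "normal")
        assert p > 0.05
        assert z == pytest.approx(np.sqrt(500) * d)


class TestAdjustCorrelatedP:
    @pytest.mark.parametrize(
        "p_raw,expected",
        [(0.042, 0.051), (0.089, 0.108), (0.022, 0.027), (0.056, 0.068)],
    )
    def test_printed_adjustments(self, p_raw, expected):
        assert round(adjust_correlated_p(p_raw, m=2, rbar=0.70), 3) == expected

    def test_limits(self):
        assert adjust_correlated_p(0.04, m=2, rbar=1.0) == pytest.approx(0.04)
        sidak = 1 - (1 - 0.04) ** 2
        assert adjust_correlated_p(0.04, m=2, rbar=0.0) == pytest.approx(sidak)

    @given(p=st.floats(0.0, 1.0), rbar=st.floats(0.0, 0.999))
    def test_never_decreases_p(self, p, rbar):
        assert adjust_correlated_p(p, m=2, rbar=rbar) >= p - 1e-12

    def test_monotone_in_p(self):
        ps = np.linspace(0, 1, 50)
        adj = adjust_correlated_p(ps, m=3, rbar=0.5)
        assert np.all(np.diff(adj) >= 0)


class TestOutlierSensitivity:
    def test_no_outliers_identical_analyses(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(3, 4, 50)
        y = rng.normal(size=50)
        out = outlier_sensitivity(x, y)
        assert out["n_outliers"] == 0
        assert out["primary"] == out["excluded_rerun"]

    def test_planted_low_outliers_flagged(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.normal(3.44, 0.2, 90), [1.0, 1.1, 1.2, 0.9]])
        y = rng.normal(size=94)
        out = outlier_sensitivity(x, y)
        assert out["n_outliers"] == 4
        assert set(out["outlier_index"]) == {90, 91, 92, 93}
        assert out["excluded_rerun"]["n"] == 90
        assert out["excluded_rerun"]["rho"] != out["primary"]["rho"]
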