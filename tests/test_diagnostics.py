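import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson

import bdlm
from bdlm.diagnostics import (
    breusch_pagan,
    durbin_watson,
    gelman_rubin,
    shapiro_wilk,
    validate_model,
)
from bdlm.dlm import DLMSpec, kalman_filter


def _oracle_psrf(chains):
    """Plain split-free PSRF: sqrt(((n-1)/n * W + B/n * (1+1/m)) / W)."""
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    return np.sqrt(((n - 1) / n * W + (1 + 1 / m) * B / n) / W)


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self, rng):
        chain = rng.standard_normal(500)
        array = np.stack([chain] * 4)[:, :, None]
        table = gelman_rubin(array, split=True)
        assert table["Rhat"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert table["Upper CI"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack(
            [rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)]
        )[:, :, None]
        table = gelman_rubin(chains, split=False)
        rhat = table["Rhat"].iloc[0]
        oracle = _oracle_psrf(chains[:, :, 0])
        assert rhat > 1.1
        # the df-adjusted estimate is bounded by sqrt(3) x the plain PSRF
        assert 0.95 * oracle <= rhat <= np.sqrt(3.0) * oracle

    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 1000, 1))
        table = gelman_rubin(chains)
        assert 0.999 <= table["Rhat"].iloc[0] <= 1.01

    def test_split_detects_within_chain_drift(self, rng):
        # chains agree marginally but each drifts: split variant must flag it
        drift = np.linspace(-3, 3, 1000)
        chains = np.stack([drift + rng.normal(0, 0.3, 1000) for _ in range(4)])
        plain = gelman_rubin(chains[:, :, None], split=False)["Rhat"].iloc[0]
        split = gelman_rubin(chains[:, :, None], split=True)["Rhat"].iloc[0]
        assert split > 1.5 > plain

    def test_single_chain_errors(self, rng):
        with pytest.raises(ValueError, match="n_chains >= 2"):
            gelman_rubin(rng.standard_normal((1, 100, 1)))

    def test_table_columns(self, rng):
        table = gelman_rubin(rng.standard_normal((2, 100, 3)))
        assert list(table.columns) == ["Parameter", "Rhat", "Upper CI"]
        assert len(table) == 3

    def test_accepts_posterior_draws(self, rng):
        draws = bdlm.PosteriorDraws(
            labels=("a", "b"),
            draws=rng.standard_normal((2, 200, 2)),
            level_mean=np.zeros(3),
            seeds=(0, 1),
        )
        table = gelman_rubin(draws)
        assert list(table["Parameter"]) == ["a", "b"]


class TestDurbinWatson:
    def test_constant_residuals_give_zero(self):
        dw, _ = durbin_watson(np.ones(50))
        assert dw == 0.0

    def test_alternating_residuals(self):
        e = np.resize([1.0, -1.0], 100)
        dw, p = durbin_watson(e)
        assert dw == pytest.approx(99 * 4 / 100, abs=1e-12)  # = 3.96
        assert p < 1e-6

    def test_white_noise_near_two(self, rng):
        dw, p = durbin_watson(rng.standard_normal(10000))
        assert abs(dw - 2.0) < 0.05
        assert p > 0.05

    def test_matches_statsmodels_statistic(self, rng):
        e = rng.standard_normal(200)
        dw, _ = durbin_watson(e)
        assert dw == pytest.approx(sm_durbin_watson(e), abs=1e-12)

    def test_bounds_and_reversal_symmetry(self, rng):
        for _ in range(20):
            e = rng.standard_normal(rng.integers(3, 50))
            dw, _ = durbin_watson(e)
            assert 0.0 <= dw <= 4.0
            assert dw == pytest.approx(durbin_watson(e[::-1])[0], abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            durbin_watson(np.zeros(10))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            durbin_watson(np.array([1.0, 2.0]))


class TestBreuschPagan:
    def test_constant_squared_residuals_give_zero(self, rng):
        Z = rng.standard_normal((50, 2))
        e = np.ones(50)
        bp, p, _ = breusch_pagan(e, Z)
        assert bp == 0.0
        assert p == 1.0

    def test_matches_statsmodels(self, rng):
        n = 300
        Z = rng.standard_normal((n, 3))
        e = rng.standard_normal(n) * (1 + 0.5 * np.abs(Z[:, 0]))
        bp, p, df = breusch_pagan(e, Z)
        lm, lm_p, _, _ = het_breuschpagan(e, sm.add_constant(Z))
        assert bp == pytest.approx(lm, abs=1e-8)
        assert p == pytest.approx(lm_p, abs=1e-10)
        assert df == 3

    def test_type_one_error_calibrated(self, rng):
        n, reps = 150, 400
        Z = rng.standard_normal((n, 3))
        rejections = 0
        for _ in range(reps):
            e = rng.standard_normal(n)
            _, p, _ = breusch_pagan(e, Z)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.035

    def test_power_against_heteroscedasticity(self, rng):
        n = 500
        Z = rng.standard_normal((n, 2))
        e = rng.standard_normal(n) * np.exp(0.6 * Z[:, 0])
        _, p, _ = breusch_pagan(e, Z)
        assert p < 0.01

    def test_rank_deficient_design_warns(self, rng):
        Z = rng.standard_normal((100, 2))
        Z = np.column_stack([Z, Z[:, 0]])  # duplicated column
        with pytest.warns(UserWarning, match="rank deficient"):
            _, _, df = breusch_pagan(rng.standard_normal(100), Z)
        assert df == 2

    def test_classical_form_differs(self, rng):
        n = 200
        Z = rng.standard_normal((n, 2))
        e = rng.standard_normal(n)
        bp_stud, _, _ = breusch_pagan(e, Z, studentized=True)
        bp_lm, _, _ = breusch_pagan(e, Z, studentized=False)
        assert bp_stud != pytest.approx(bp_lm)

    def test_mismatched_lengths_error(self, rng):
        with pytest.raises(ValueError, match="row count"):
            breusch_pagan(np.ones(10), rng.standard_normal((11, 2)))


class TestShapiroWilk:
    def test_matches_scipy_on_normal_sample(self, rng):
        x = rng.standard_normal(100)
        W, p = shapiro_wilk(x)
        ref = stats.shapiro(x)
        assert W == pytest.approx(ref.statistic, abs=1e-5)
        assert p == pytest.approx(ref.pvalue, abs=1e-4)

    @pytest.mark.parametrize("n", [3, 5, 8, 11, 12, 50, 500, 4999])
    def test_matches_scipy_across_sizes(self, n, rng):
        x = rng.standard_normal(n)
        W, p = shapiro_wilk(x)
        ref = stats.shapiro(x)
        assert W == pytest.approx(ref.statistic, abs=1e-4)
        assert p == pytest.approx(ref.pvalue, abs=2e-3)

    def test_normal_probability_points_near_one(self):
        x = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        W, _ = shapiro_wilk(x)
        assert W > 0.99

    def test_rejects_skewed_sample(self, rng):
        x = rng.exponential(size=500)
        W, p = shapiro_wilk(x)
        assert W < 0.95
        assert p < 0.05

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(80)
        W1, p1 = shapiro_wilk(x)
        W2, p2 = shapiro_wilk(5.0 - 3.0 * x)
        assert W1 == pytest.approx(W2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_bounds(self, rng):
        for _ in range(20):
            W, _ = shapiro_wilk(rng.exponential(size=rng.integers(5, 100)))
            assert 0.0 < W <= 1.0

    def test_out_of_range_n_errors(self, rng):
        with pytest.raises(ValueError, match="3 <= n <= 5000"):
            shapiro_wilk(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="3 <= n <= 5000"):
            shapiro_wilk(rng.standard_normal(5001))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            shapiro_wilk(np.ones(10))


def _simulated_fit(rng, T=150, het=False, trend=False):
    """Kalman fit with known variances on self-generated local-level data."""
    X = np.column_stack([np.ones(T), rng.standard_normal(T)])
    level = np.cumsum(rng.normal(0, 0.3, T))
    noise = rng.normal(0, 1.0, T)
    if het:
        noise *= np.exp(0.8 * X[:, 1])
    y = level + 0.5 * X[:, 1] + noise
    if trend:
        y = y + np.linspace(0, 25, T)
    spec = DLMSpec(
        p=2, obs_variance=1.0,
        state_cov=np.diag([0.09, 0.0]),
        m0=np.zeros(2), c0=np.diag([3.0, 1.0]),
        first_step_evolves=False,
    )
    moments = kalman_filter((X, y), spec)
    return moments, X


class TestValidateModel:
    def test_report_has_three_rows_with_stats_and_pvalues(self, rng):
        moments, X = _simulated_fit(rng)
        report = validate_model(moments, X)
        assert len(report.tests) == 3
        assert set(report.tests.columns) >= {"Test", "statistic", "p_value", "passed"}
        assert report.tests["statistic"].between(0, 40).all()

    def test_well_specified_fit_mostly_passes_bp(self, rng):
        passes = 0
        reps = 20
        for _ in range(reps):
            moments, X = _simulated_fit(rng)
            report = validate_model(moments, X)
            passes += report.passed["Studentized Breusch-Pagan heteroscedasticity"]
        assert passes >= reps * 0.8

    def test_heteroscedastic_noise_flagged(self, rng):
        flags = 0
        for _ in range(10):
            moments, X = _simulated_fit(rng, het=True)
            report = validate_model(moments, X)
            flags += not report.passed[
                "Studentized Breusch-Pagan heteroscedasticity"
            ]
        assert flags >= 7

    def test_trending_residuals_raise_dw_flag(self, rng):
        # a deterministic ramp the level cannot fully absorb leaves
        # autocorrelated one-step residuals
        moments, X = _simulated_fit(rng, trend=True)
        report = validate_model(moments, X)
        assert not report.passed["Durbin-Watson autocorrelation"]

    def test_to_csv_and_str(self, rng, tmp_path):
        moments, X = _simulated_fit(rng)
        report = validate_model(moments, X)
        path = report.to_csv(tmp_path / "diag.csv")
        assert path.exists()
        text = str(report)
        assert "Durbin-Watson" in text and "Shapiro-Wilk" in text
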