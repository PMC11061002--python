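"""Tests of the rank-correlation, heteroskedasticity and quantile analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from harvestgame.game import GameConfig, play_game, threshold_policy
from harvestgame.stats import (
    breusch_pagan,
    mean_replenishment_control,
    partial_spearman,
    pinball_loss,
    profile_to_frame,
    quantile_profile,
    quantile_regression,
    spearman,
)


class TestSpearman:
    def test_perfect_reversal(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        r = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.rho == pytest.approx(0.8)
        assert r.df == 2

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, size=80).astype(float)
        y = x + rng.integers(0, 3, size=80)
        ours = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestPartialSpearman:
    def test_identical_variables_stay_correlated(self, rng):
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        r = partial_spearman(x, x.copy(), z)
        assert r.rho == pytest.approx(1.0, abs=1e-9)
        assert r.df == 197

    def test_shared_covariate_explains_the_association(self, rng):
        z = rng.normal(size=4000)
        x = z + rng.normal(size=4000)
        y = z + rng.normal(size=4000)
        plain = spearman(x, y)
        partial = partial_spearman(x, y, z)
        assert plain.rho > 0.3
        assert abs(partial.rho) < 0.05

    def test_independent_covariate_changes_nothing_much(self, rng):
        x = rng.normal(size=1000)
        y = x + rng.normal(size=1000)
        z = rng.normal(size=1000)
        plain = spearman(x, y)
        partial = partial_spearman(x, y, z)
        assert partial.rho == pytest.approx(plain.rho, abs=0.05)

    def test_constant_covariate_falls_back_with_warning(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        with pytest.warns(UserWarning, match="constant covariate"):
            r = partial_spearman(x, y, np.ones(50))
        assert r.rho == pytest.approx(spearman(x, y).rho)
        assert not r.partial_flag


class TestBreuschPagan:
    def test_constructed_homoskedastic_data_scores_zero(self):
        # residuals (+c, -c, -c, +c) are orthogonal to x and the constant,
        # so squared residuals are literally constant
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 2 * x + np.array([1.0, -1.0, -1.0, 1.0])
        assert breusch_pagan(y, x).statistic == pytest.approx(0.0, abs=1e-12)

    def test_six_point_fixture_matches_independent_recomputation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.3, 1.1, 1.8, 3.5, 3.6, 5.9])
        ours = breusch_pagan(y, x)
        import statsmodels.api as sm
        import statsmodels.stats.diagnostic as smd

        design = sm.add_constant(x)
        resid = sm.OLS(y, design).fit().resid
        lm, lm_p, _, _ = smd.het_breuschpagan(resid, design)
        assert ours.statistic == pytest.approx(lm, rel=1e-10)
        assert ours.p_value == pytest.approx(lm_p, rel=1e-9)

    def test_power_against_variance_proportional_to_x(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.5, 3.0, size=2000)
            y = x + rng.normal(size=2000) * x
            if breusch_pagan(y, x).p_value < 0.05:
                rejections += 1
        assert rejections == 20

    def test_rank_deficient_design_rejected(self, rng):
        x = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank"):
            breusch_pagan(rng.normal(size=30), x)


class TestQuantileRegression:
    def test_intercept_only_median_is_the_sample_median(self):
        fit = quantile_regression(
            np.array([1.0, 2.0, 9.0]), np.empty((3, 0)), 0.5, n_boot=0
        )
        assert fit.intercept == pytest.approx(2.0)

    def test_exact_linear_data_recovered_at_any_quantile(self, rng):
        x = rng.normal(size=40)
        y = 2.0 * x
        for tau in (0.1, 0.5, 0.9):
            fit = quantile_regression(y, x, tau, n_boot=0)
            assert fit.intercept == pytest.approx(0.0, abs=1e-9)
            assert fit.coef[0] == pytest.approx(2.0, abs=1e-9)

    def test_eight_point_fixture_matches_grid_search_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([1.0, 2.5, 1.8, 4.9, 4.1, 6.5, 5.9, 8.2])
        tau = 0.25
        fit = quantile_regression(y, x, tau, n_boot=0)

        # coarse-to-fine brute-force minimization of the pinball loss
        a_lo, a_hi, b_lo, b_hi = -5.0, 5.0, -2.0, 4.0
        best = None
        for _ in range(6):
            aa = np.linspace(a_lo, a_hi, 41)
            bb = np.linspace(b_lo, b_hi, 41)
            losses = np.array(
                [[pinball_loss(y, a + b * x, tau) for b in bb] for a in aa]
            )
            i, j = np.unravel_index(losses.argmin(), losses.shape)
            best = (aa[i], bb[j])
            da, db = aa[1] - aa[0], bb[1] - bb[0]
            a_lo, a_hi = aa[i] - 2 * da, aa[i] + 2 * da
            b_lo, b_hi = bb[j] - 2 * db, bb[j] + 2 * db
        assert fit.intercept == pytest.approx(best[0], abs=1e-3)
        assert fit.coef[0] == pytest.approx(best[1], abs=1e-3)
        assert pinball_loss(y, fit.predict(x), tau) <= pinball_loss(
            y, best[0] + best[1] * x, tau
        ) + 1e-9

    def test_balance_condition_on_random_fits(self, rng):
        for tau in (0.05, 0.3, 0.5, 0.7, 0.95):
            x = rng.normal(size=101)
            y = x + rng.standard_t(4, size=101)
            fit = quantile_regression(y, x, tau, n_boot=0)
            resid = y - fit.predict(x)
            assert np.sum(resid < -1e-9) / 101 <= tau
            assert tau <= np.sum(resid <= 1e-9) / 101

    def test_invalid_tau_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="tau"):
            quantile_regression(x, x, 1.5, n_boot=0)

    def test_matches_reference_implementations(self, rng):
        """Dual-route check on a handful of random datasets; the full
        50-dataset sweep runs in the acceptance suite."""
        from sklearn.linear_model import QuantileRegressor
        from statsmodels.regression.quantile_regression import QuantReg

        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=80)
            y = 1.5 * x + r.standard_t(5, size=80)
            for tau in (0.25, 0.5, 0.75):
                fit = quantile_regression(y, x, tau, n_boot=0)
                sk = QuantileRegressor(quantile=tau, alpha=0.0).fit(x[:, None], y)
                assert fit.intercept == pytest.approx(sk.intercept_, abs=1e-8)
                assert fit.coef[0] == pytest.approx(sk.coef_[0], abs=1e-8)
                sm_fit = QuantReg(
                    y, np.column_stack([np.ones(80), x])
                ).fit(q=tau, p_tol=1e-10)
                # IRLS converges less tightly than the exact LP
                assert fit.coef[0] == pytest.approx(sm_fit.params[1], abs=1e-4)


class TestQuantileProfile:
    def test_grid_has_19_points(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        fits = quantile_profile(y, x, n_boot=0)
        assert len(fits) == 19
        assert fits[0].tau == pytest.approx(0.05)
        assert fits[-1].tau == pytest.approx(0.95)

    def test_uniform_slope_recovered_within_median_ci(self, rng):
        beta = 3.0
        x = rng.normal(size=300)
        y = beta * x + rng.normal(size=300)
        fits = quantile_profile(y, x, n_boot=200, seed=5, normalize=False)
        median_fit = fits[9]
        assert median_fit.tau == pytest.approx(0.5)
        assert median_fit.ci_low[0] <= beta <= median_fit.ci_high[0]

    def test_null_slope_cis_mostly_cover_zero(self):
        """With y independent of x, the 95% bootstrap bands should cover
        zero for the overwhelming majority of quantiles across repeated
        simulations."""
        covered = total = 0
        for sim in range(6):
            r = np.random.default_rng(40 + sim)
            x = r.normal(size=120)
            y = r.normal(size=120)
            fits = quantile_profile(y, x, n_boot=150, seed=sim, normalize=True)
            for f in fits:
                total += 1
                covered += f.ci_low[0] <= 0.0 <= f.ci_high[0]
        assert covered / total >= 0.90

    def test_profile_frame_is_tidy(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        fits = quantile_profile(y, x, n_boot=0)
        frame = profile_to_frame(fits, predictor_names=["audit"])
        assert list(frame["predictor"].unique()) == ["audit"]
        assert len(frame) == 19


class TestReplenishmentControl:
    @staticmethod
    def _toy_cohort(n=40, seed=0):
        rng = np.random.default_rng(seed)
        config = GameConfig()
        trajectories = [
            play_game(threshold_policy(rng.integers(20, 55)), config, rng)
            for _ in range(n)
        ]
        outcomes = pd.DataFrame(
            {
                "rounds_lasted": [t.rounds_lasted for t in trajectories],
                "total_rewards": [t.total_rewards for t in trajectories],
            }
        )
        return trajectories, outcomes

    def test_window_one_equals_the_first_drawn_fraction(self):
        trajectories, outcomes = self._toy_cohort()
        outcomes["rounds_lasted"] = np.arange(len(outcomes))  # force variation
        table = mean_replenishment_control(trajectories, outcomes, windows=(1,))
        firsts = np.array([t.replenish_fractions[0] for t in trajectories])
        row = table[table["outcome"] == "rounds_lasted"].iloc[0]
        expected = spearman(firsts, outcomes["rounds_lasted"]).rho
        assert row["rho"] == pytest.approx(expected)

    def test_noiseless_replenishment_is_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        config = GameConfig(replenish_sd=0.0)
        trajectories = [
            play_game(threshold_policy(t), config, rng) for t in (30, 40, 50)
        ]
        outcomes = pd.DataFrame(
            {"rounds_lasted": [1, 2, 3], "total_rewards": [10.0, 20.0, 30.0]}
        )
        table = mean_replenishment_control(trajectories, outcomes)
        assert table["degenerate"].all()
        assert table["rho"].isna().all()

    def test_mismatched_lengths_rejected(self):
        trajectories, outcomes = self._toy_cohort(n=5)
        with pytest.raises(ValueError):
            mean_replenishment_control(trajectories, outcomes.iloc[:3])
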