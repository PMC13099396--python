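"""Design-engine tests: weighted moments, weight harmonization, and the
Taylor-linearized survey-weighted least squares core, checked against
independent sandwich and jackknife oracles."""

import numpy as np
import pandas as pd
import pytest

from pexwas.design import (DesignError, RankError, WeightComponent,
                           fit_survey_wls, harmonize_weights,
                           weighted_moments)
from .conftest import simple_design_frame


# ---------------------------------------------------------------------------
# independent oracles


def sandwich_oracle(y, X, w, strata, psu):
    """Brute-force stratified sandwich SEs computed from first principles."""
    Xv = np.asarray(X, float)
    A = Xv.T @ (w[:, None] * Xv)
    beta = np.linalg.solve(A, Xv.T @ (w * y))
    u = (w * (y - Xv @ beta))[:, None] * Xv
    G = np.zeros((Xv.shape[1], Xv.shape[1]))
    for h in np.unique(strata):
        rows = np.where(strata == h)[0]
        zs = np.array([u[rows[psu[rows] == c]].sum(axis=0)
                       for c in np.unique(psu[rows])])
        nh = len(zs)
        d = zs - zs.mean(axis=0)
        G += nh / (nh - 1) * d.T @ d
    Ainv = np.linalg.inv(A)
    return beta, np.sqrt(np.diag(Ainv @ G @ Ainv))


def jackknife_oracle(y, X, w, strata, psu):
    """Stratified delete-one-PSU jackknife (JKn) standard errors."""
    Xv = np.asarray(X, float)

    def _fit(wts):
        A = Xv.T @ (wts[:, None] * Xv)
        return np.linalg.solve(A, Xv.T @ (wts * y))

    full = _fit(w)
    var = np.zeros(Xv.shape[1])
    for h in np.unique(strata):
        in_h = strata == h
        psus = np.unique(psu[in_h])
        nh = len(psus)
        for c in psus:
            wts = w.copy()
            drop = in_h & (psu == c)
            wts[drop] = 0.0
            keep = in_h & ~drop
            wts[keep] *= nh / (nh - 1)
            # guard: dropping a PSU must not empty the design
            rep = _fit(np.where(wts > 0, wts, 1e-12))
            var += (nh - 1) / nh * (rep - full) ** 2
    return full, np.sqrt(var)


# ---------------------------------------------------------------------------


class TestWeightedMoments:
    def test_unit_weights(self):
        mean, sd = weighted_moments([1, 2, 3], [1, 1, 1])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_duplicate_point_equivalence(self):
        m1, _ = weighted_moments([1.0, 5.0], [2.0, 1.0])
        m2, _ = weighted_moments([1.0, 1.0, 5.0], [1.0, 1.0, 1.0])
        assert m1 == pytest.approx(m2)

    def test_hand_computed_sd(self):
        # var = sum w (x - 2)^2 / (sum w - 1) = 16/3
        _, sd = weighted_moments([0, 0, 4, 4], np.ones(4))
        assert sd == pytest.approx(np.sqrt(16 / 3), abs=1e-10)
        assert sd == pytest.approx(2.3094, abs=1e-4)

    def test_small_weight_sum_rejected(self):
        with pytest.raises(DesignError):
            weighted_moments([1.0, 2.0], [0.4, 0.4])


class TestHarmonizeWeights:
    def test_smallest_subsample_chosen(self):
        idx = pd.RangeIndex(5)
        exam = WeightComponent("exam", pd.Series(10.0, index=idx), 9000)
        diet = WeightComponent("diet", pd.Series(20.0, index=idx), 4000)
        out = harmonize_weights([exam, diet])
        assert (out == 20.0).all()

    def test_divided_by_waves_combined(self):
        comp = WeightComponent("full", pd.Series([50_000.0]), 10_000)
        assert harmonize_weights([comp], n_waves_combined=5).iloc[0] == 10_000.0

    def test_single_wave_unchanged(self):
        comp = WeightComponent("full", pd.Series([123.0]), 10)
        assert harmonize_weights([comp]).iloc[0] == 123.0

    def test_errors(self):
        with pytest.raises(DesignError):
            harmonize_weights([])
        bad = WeightComponent("x", pd.Series([1.0, -2.0]), 2)
        with pytest.raises(DesignError):
            harmonize_weights([bad])


class TestFitSurveyWLS:
    def test_perfect_fit(self):
        y, X, w, strata, psu = simple_design_frame(noise=0.0)
        fit = fit_survey_wls(y, X, w, strata, psu)
        assert fit.params["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.bse.max() == pytest.approx(0.0, abs=1e-8)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_matches_sandwich_oracle_each_row_own_psu(self):
        # single stratum, 20 rows, each row its own PSU, equal weights
        rng = np.random.default_rng(4)
        n = 20
        x = rng.standard_normal(n)
        y = 0.5 + 0.3 * x + rng.standard_normal(n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        w = np.ones(n)
        strata = np.zeros(n, dtype=int)
        psu = np.arange(n)
        fit = fit_survey_wls(y, X, w, strata, psu)
        beta0, se0 = sandwich_oracle(y, X, w, strata, psu)
        np.testing.assert_allclose(fit.params.to_numpy(), beta0, atol=1e-10)
        np.testing.assert_allclose(fit.bse.to_numpy(), se0, atol=1e-10)

    def test_matches_sandwich_oracle_stratified(self):
        y, X, w, strata, psu = simple_design_frame(seed=5)
        fit = fit_survey_wls(y, X, w, strata, psu)
        beta0, se0 = sandwich_oracle(y, X, w, strata.astype(int),
                                     np.asarray(psu))
        np.testing.assert_allclose(fit.params.to_numpy(), beta0, rtol=1e-12)
        np.testing.assert_allclose(fit.bse.to_numpy(), se0, rtol=1e-10)

    def test_jackknife_agreement_30_psus(self):
        # 15 strata x 2 PSUs; linearized and JKn SEs are both
        # design-consistent and should agree within 15%
        y, X, w, strata, psu = simple_design_frame(n=600, n_strata=15, seed=6)
        fit = fit_survey_wls(y, X, w, strata, psu)
        _, se_jk = jackknife_oracle(y, X, w, strata.astype(int),
                                    np.asarray(psu))
        assert fit.bse.to_numpy() == pytest.approx(se_jk, rel=0.15)

    def test_weight_scale_invariance(self):
        y, X, w, strata, psu = simple_design_frame(seed=7)
        f1 = fit_survey_wls(y, X, w, strata, psu)
        f2 = fit_survey_wls(y, X, 7.3 * w, strata, psu)
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-12)
        np.testing.assert_allclose(f1.bse, f2.bse, rtol=1e-10)
        assert f1.rsquared == pytest.approx(f2.rsquared, rel=1e-12)

    def test_ols_equivalence_constant_weights(self):
        y, X, w, strata, psu = simple_design_frame(seed=8)
        fit = fit_survey_wls(y, X, np.ones_like(w), strata, psu)
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), ols, rtol=1e-10)

    def test_nesting_never_decreases_r2(self):
        rng = np.random.default_rng(123)
        y, X, w, strata, psu = simple_design_frame(seed=9)
        X2 = X.copy()
        X2["z"] = rng.standard_normal(len(y))
        f1 = fit_survey_wls(y, X, w, strata, psu)
        f2 = fit_survey_wls(y, X2, w, strata, psu)
        assert f2.rsquared >= f1.rsquared - 1e-12

    def test_design_df_rule(self):
        y, X, w, strata, psu = simple_design_frame(n_strata=10)
        fit = fit_survey_wls(y, X, w, strata, psu)
        assert fit.df_design == 20 - 10

    def test_rank_deficiency_names_column(self):
        y, X, w, strata, psu = simple_design_frame()
        X = X.copy()
        X["x_copy"] = X["x"]
        with pytest.raises(RankError, match="x_copy"):
            fit_survey_wls(y, X, w, strata, psu)

    def test_lonely_psu_policy(self):
        y, X, w, strata, psu = simple_design_frame(n=200, n_strata=10)
        strata = strata.copy()
        psu = np.asarray(psu).copy()
        psu[strata == 0] = 1  # stratum 0 collapses to a single PSU
        fit = fit_survey_wls(y, X, w, strata, psu, lonely="adjust")
        assert fit.lonely_strata == 1
        with pytest.raises(DesignError):
            fit_survey_wls(y, X, w, strata, psu, lonely="error")

    def test_nonpositive_weights_rejected(self):
        y, X, w, strata, psu = simple_design_frame()
        w = w.copy()
        w[0] = 0.0
        with pytest.raises(DesignError):
            fit_survey_wls(y, X, w, strata, psu)
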