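"""Generator tests: determinism, design structure, censoring, and the
closed-form truth table checked against simulation."""

import numpy as np
import pandas as pd
import pytest

from pexwas.synthetic import (ConfigError, ExposureSpec, PhenotypeSpec,
                              SimConfig, generate_population, truth_table)


def _tiny_cfg(**kw):
    base = dict(
        n_waves=2, strata_per_wave=10, n_per_psu=50,
        exposures=[ExposureSpec("e1"), ExposureSpec("e2", block="b"),
                   ExposureSpec("e3", block="b")],
        phenotypes=[PhenotypeSpec("p1", demo_coefs={"age": 0.3})],
        block_rho={"b": 0.5},
        effects={("p1", "e1"): 0.4},
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGeneration:
    def test_deterministic_given_seed(self):
        d1 = generate_population(_tiny_cfg())
        d2 = generate_population(_tiny_cfg())
        for w in d1.waves:
            for comp in d1.tables[w]:
                pd.testing.assert_frame_equal(d1.tables[w][comp],
                                              d2.tables[w][comp])

    def test_seed_changes_data(self):
        d1 = generate_population(_tiny_cfg())
        d2 = generate_population(_tiny_cfg(seed=6))
        assert not d1.tables[1]["phenotypes"].equals(d2.tables[1]["phenotypes"])

    def test_weight_totals_match_pseudo_population(self):
        cfg = _tiny_cfg(target_population=250_000.0)
        data = generate_population(cfg)
        for w in data.waves:
            tot = data.tables[w]["demographics"]["wt_full"].sum()
            assert tot == pytest.approx(250_000.0, rel=1e-9)

    def test_design_structure(self):
        cfg = _tiny_cfg()
        demo = generate_population(cfg).tables[1]["demographics"]
        assert demo["stratum"].nunique() == cfg.strata_per_wave
        sizes = demo.groupby(["stratum", "psu"]).size()
        assert (sizes == cfg.n_per_psu).all()
        assert len(sizes) == cfg.strata_per_wave * cfg.psus_per_stratum

    def test_llod_censoring_fraction(self):
        cfg = _tiny_cfg(
            exposures=[ExposureSpec("e1", llod_quantile=0.10)],
            strata_per_wave=25, n_per_psu=100, effects={},
        )
        data = generate_population(cfg)
        tab = data.tables[1]["exposures_core"]
        frac = tab["e1_llod_flag"].mean()
        # binomial MC error at n=5,000
        assert frac == pytest.approx(0.10, abs=3 * np.sqrt(0.1 * 0.9 / 5000))
        llod = data.catalog["e1"].llod[1]
        assert (tab.loc[tab["e1_llod_flag"] == 1.0, "e1"] == llod).all()

    def test_subsample_membership_and_weights(self):
        cfg = _tiny_cfg(
            exposures=[ExposureSpec("e1", panel="lab")],
            panels={"lab": 0.4}, effects={},
        )
        data = generate_population(cfg)
        tab = data.tables[1]["exposures_lab"]
        demo = data.tables[1]["demographics"]
        member = tab["e1"].notna()
        assert member.mean() == pytest.approx(0.4, abs=0.06)
        np.testing.assert_allclose(
            tab.loc[member, "wt_lab"],
            demo.loc[member, "wt_full"] / 0.4, rtol=1e-12,
        )
        assert tab.loc[~member, "wt_lab"].isna().all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            _tiny_cfg(psus_per_stratum=1)
        with pytest.raises(ConfigError):
            _tiny_cfg(panels={"lab": 1.5},
                      exposures=[ExposureSpec("e1", panel="lab")])
        with pytest.raises(ConfigError):
            # demographic loadings + block correlation exceed unit variance
            _tiny_cfg(exposures=[ExposureSpec("e1", block="b",
                                              demo_loadings={"age": 0.8})])
        with pytest.raises(ConfigError):
            _tiny_cfg(effects={("p1", "e1"): np.inf})


class TestTruthTable:
    def test_null_effect_zero_truth(self):
        tt = truth_table(_tiny_cfg(effects={}))
        assert tt.beta_univariate[("p1", "e1")] == pytest.approx(0.0, abs=1e-14)
        assert tt.incremental_r2["p1"] == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_r2_single_exposure(self):
        # beta=0.5, sigma=1, demo var = 0.3^2:
        # R2_expo = 0.25 / (0.25 + 1 + 0.09)
        cfg = _tiny_cfg(
            exposures=[ExposureSpec("e1")],
            effects={("p1", "e1"): 0.5},
        )
        tt = truth_table(cfg)
        assert tt.incremental_r2["p1"] == pytest.approx(0.25 / 1.34, abs=1e-12)
        sd = np.sqrt(1.34)
        assert tt.beta_univariate[("p1", "e1")] == pytest.approx(0.5 / sd)

    def test_r2_verified_by_large_n_simulation(self):
        cfg = _tiny_cfg(
            exposures=[ExposureSpec("e1")],
            effects={("p1", "e1"): 0.5},
            strata_per_wave=25, n_per_psu=200, n_waves=1,
        )
        data = generate_population(cfg)
        demo = data.tables[1]["demographics"]
        expo = data.tables[1]["exposures_core"]["e1"]
        pheno = data.tables[1]["phenotypes"]["p1"]
        z = np.log10(expo)
        z = (z - z.mean()) / z.std()
        # empirical incremental R^2 of exposure over the age driver
        import numpy.linalg as la

        age = (demo["age"] - demo["age"].mean()).to_numpy()
        X0 = np.column_stack([np.ones(len(age)), age])
        X1 = np.column_stack([X0, z])
        y = pheno.to_numpy()
        r0 = y - X0 @ la.lstsq(X0, y, rcond=None)[0]
        r1 = y - X1 @ la.lstsq(X1, y, rcond=None)[0]
        tss = ((y - y.mean()) ** 2).sum()
        inc = (r0 @ r0 - r1 @ r1) / tss
        assert inc == pytest.approx(truth_table(cfg).incremental_r2["p1"],
                                    abs=0.02)

    def test_uncorrelated_blocks_zero_correlation(self):
        tt = truth_table(_tiny_cfg())
        assert tt.exposure_corr.loc["e1", "e2"] == 0.0
        assert tt.exposure_corr.loc["e2", "e3"] == pytest.approx(0.5)

    def test_confounded_exposure_univariate_vs_adjusted(self):
        cfg = _tiny_cfg(
            exposures=[ExposureSpec("e1", demo_loadings={"age": 0.6})],
            phenotypes=[PhenotypeSpec("p1", demo_coefs={"age": 0.5})],
            effects={("p1", "e1"): -0.2},
        )
        tt = truth_table(cfg)
        # positive age confounding overwhelms the negative direct effect
        assert tt.beta_univariate[("p1", "e1")] > 0
        assert tt.beta_adjusted[("p1", "e1")] < 0


class TestEstimationCalibration:
    def test_planted_beta_ci_coverage(self):
        """95% CIs from the design engine cover a planted standardized
        effect of 0.2 in at least 90 of 100 replicates."""
        from pexwas.exwas import run_pair_pooled

        covered = 0
        for rep in range(100):
            cfg = SimConfig(
                n_waves=2, strata_per_wave=13, n_per_psu=100,
                exposures=[ExposureSpec("e")],
                phenotypes=[PhenotypeSpec("p")],
                effects={("p", "e"): 0.2},
                seed=20_000 + rep,
            )
            truth = truth_table(cfg).beta_adjusted[("p", "e")]
            data = generate_population(cfg)
            rec = run_pair_pooled(data, ("p", "e"), scenario=2)[0]
            if abs(rec.beta - truth) <= 1.96 * rec.se:
                covered += 1
        assert covered >= 90
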