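"""ExWAS engine tests: scenarios, pair fits, pooled mode, variance
decomposition and age interactions, validated against generator truth."""

import numpy as np
import pandas as pd
import pytest

from pexwas.exwas import (SCENARIOS, incremental_r2, interaction_delta_r2,
                          run_exwas, run_pair_pooled, run_pair_wave,
                          scenario_covariates)
from pexwas.synthetic import (ExposureSpec, PhenotypeSpec, SimConfig,
                              generate_population, truth_table)


class TestScenarios:
    def test_nine_scenarios_exact_sets(self):
        assert scenario_covariates(2) == []
        assert scenario_covariates(7) == ["income", "education", "wave"]
        assert scenario_covariates(1) == ["age", "age2", "sex", "income",
                                          "ethnicity", "education", "wave"]
        assert len(SCENARIOS) == 9

    def test_wave_dropped_in_single_wave_fits(self):
        assert "wave" not in scenario_covariates(1, pooled=False)
        assert scenario_covariates(2, pooled=False) == []

    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            scenario_covariates(10)
        with pytest.raises(ValueError):
            scenario_covariates(0)


class TestPairFits:
    def test_estimate_within_3se_of_truth(self, effect_cfg, effect_data):
        truth = truth_table(effect_cfg).beta_adjusted[("pheno", "expo")]
        rec = run_pair_pooled(effect_data, ("pheno", "expo"), scenario=1)[0]
        assert abs(rec.beta - truth) < 3 * rec.se
        assert rec.p < 1e-6

    def test_scenario2_equals_simple_slope(self, effect_data):
        """The unadjusted scenario must reproduce the plain survey-weighted
        regression slope of the standardized variables."""
        from pexwas.design import fit_survey_wls
        from pexwas.exwas import _prepare_pair_frame

        rec = run_pair_pooled(effect_data, ("pheno", "expo"), scenario=2)[0]
        frame, expo_cols, _ = _prepare_pair_frame(
            effect_data, "pheno", "expo", 2)
        X = pd.DataFrame({"intercept": 1.0, "expo": frame["expo"]},
                         index=frame.index)
        strata = (frame["wave"].astype(str) + ":"
                  + frame["stratum"].astype(str)).to_numpy()
        manual = fit_survey_wls(frame["_y"].to_numpy(), X,
                                frame["weight"].to_numpy(), strata,
                                frame["psu"].to_numpy())
        assert rec.beta == pytest.approx(manual.params["expo"], rel=1e-12)

    def test_r2_decomposition_nesting(self, demo_data):
        for scen in (1, 5, 7):
            rec = run_pair_pooled(demo_data, ("pheno_bmi", "bio1"),
                                  scenario=scen)[0]
            assert rec.rsq_full >= rec.rsq_base
            assert rec.rsq_diff == pytest.approx(
                rec.rsq_full - rec.rsq_base, abs=1e-12)

    def test_wave_fit_skips_small_samples(self, demo_data):
        recs = run_pair_wave(demo_data, ("pheno_bmi", "bio1"), 1, wave=1,
                             min_n=10**6)
        assert recs[0].status == "skipped-n"
        assert np.isnan(recs[0].beta)

    def test_duplicated_wave_same_beta(self):
        """Pooling two identical waves reproduces the single-wave slope."""
        import copy

        cfg = SimConfig(n_waves=1, strata_per_wave=10, n_per_psu=60,
                        exposures=[ExposureSpec("e")],
                        phenotypes=[PhenotypeSpec("p")],
                        effects={("p", "e"): 0.3}, seed=3)
        data = generate_population(cfg)
        single = run_pair_pooled(data, ("p", "e"), scenario=2)[0]
        dup = copy.copy(data)
        t2 = {c: t.set_axis(t.index + 5_000_000) for c, t in
              data.tables[1].items()}
        dup.tables = {1: data.tables[1], 2: t2}
        pooled = run_pair_pooled(dup, ("p", "e"), scenario=2)[0]
        assert pooled.beta == pytest.approx(single.beta, rel=1e-10)
        assert pooled.n == 2 * single.n

    def test_confounded_pair_sign_switch(self):
        """When exposure and phenotype share a demographic driver pushing
        the marginal association positive against a negative direct effect,
        the unadjusted and adjusted scenarios disagree in sign."""
        cfg = SimConfig(
            n_waves=2, strata_per_wave=20, n_per_psu=100,
            exposures=[ExposureSpec("e", demo_loadings={"age": 0.6})],
            phenotypes=[PhenotypeSpec("p", demo_coefs={"age": 0.5})],
            effects={("p", "e"): -0.2}, seed=17,
        )
        data = generate_population(cfg)
        unadj = run_pair_pooled(data, ("p", "e"), scenario=2)[0]
        adj = run_pair_pooled(data, ("p", "e"), scenario=4)[0]
        assert unadj.beta > 0 > adj.beta

    def test_incremental_r2_requires_same_sample(self, demo_data):
        from pexwas.exwas import _fit_records, _prepare_pair_frame

        frame, cols, _ = _prepare_pair_frame(demo_data, "pheno_bmi", "bio1", 2)
        _, full = _fit_records(frame, cols, "pheno_bmi", "bio1", 2, None, True)
        _, other = _fit_records(frame.iloc[:-50], cols, "pheno_bmi", "bio1",
                                2, None, True)
        with pytest.raises(ValueError):
            incremental_r2(full, other)


class TestInteraction:
    def test_null_interaction_near_zero(self, effect_data):
        d = interaction_delta_r2(effect_data, ("pheno", "expo"), scenario=5)
        assert d < 1e-3

    def test_planted_interaction_recovered(self):
        """An exposure-by-age interaction planted to contribute ~5% of
        phenotype variance is recovered by the delta-R^2 machinery."""
        rng = np.random.default_rng(8)
        cfg = SimConfig(n_waves=1, strata_per_wave=25, n_per_psu=200,
                        exposures=[ExposureSpec("e")],
                        phenotypes=[PhenotypeSpec("p")], seed=21)
        data = generate_population(cfg)
        demo = data.tables[1]["demographics"]
        z = np.log10(data.tables[1]["exposures_core"]["e"])
        z = (z - z.mean()) / z.std()
        s_age = (demo["age"] - 45.0) / 15.0
        beta_int = np.sqrt(0.05 / (1 - 0.05))  # interaction R^2 ~ 5%
        y = beta_int * z * s_age + rng.standard_normal(len(z))
        data.tables[1]["phenotypes"]["p"] = y.to_numpy()
        d = interaction_delta_r2(data, ("p", "e"), scenario=2)
        assert d == pytest.approx(0.05, abs=0.01)

    def test_categorical_exposure_rejected(self, demo_data):
        with pytest.raises(ValueError):
            interaction_delta_r2(demo_data, ("pheno_bmi", "smoke_status"))


class TestBatchRunner:
    def test_atlas_records_complete(self, demo_data):
        pairs = [("pheno_bmi", "bio1"), ("pheno_bmi", "diet1"),
                 ("pheno_null", "bio3")]
        wave, meta = run_exwas(demo_data, pairs, scenarios=(1, 2))
        assert set(meta["model_number"]) == {1, 2}
        assert len(meta) == 6
        # every meta row's k equals its number of wave rows
        for row in meta.itertuples():
            nw = len(wave[(wave["phenotype"] == row.pvarname)
                          & (wave["exposure"] == row.evarname)
                          & (wave["scenario"] == row.model_number)
                          & (wave["term"] == row.term)])
            assert row.k_uwls == nw

    def test_pooled_and_uwls_consistent_when_homogeneous(self, effect_data):
        _, meta = run_exwas(effect_data, [("pheno", "expo")], scenarios=(2,))
        row = meta.iloc[0]
        # both cross-wave estimates target the same homogeneous effect
        assert row.estimate_uwls == pytest.approx(
            row.estimate_pooled, abs=3 * row.se_pooled)
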