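import numpy as np
import pandas as pd
import pytest

from pexwas.synthetic import (DemographicsSpec, ExposureSpec, PhenotypeSpec,
                              SimConfig, demo_config, generate_population)


@pytest.fixture(scope="session")
def demo_cfg():
    return demo_config(seed=7)


@pytest.fixture(scope="session")
def demo_data(demo_cfg):
    return generate_population(demo_cfg)


@pytest.fixture(scope="session")
def effect_cfg():
    """One planted effect (standardized beta 0.2 on the latent scale) at
    n ~ 5,000 per wave, no censoring, no confounding."""
    return SimConfig(
        n_waves=2, strata_per_wave=25, n_per_psu=100,
        exposures=[ExposureSpec("expo")],
        phenotypes=[PhenotypeSpec("pheno")],
        effects={("pheno", "expo"): 0.2},
        seed=11,
    )


@pytest.fixture(scope="session")
def effect_data(effect_cfg):
    return generate_population(effect_cfg)


def simple_design_frame(n=200, seed=0, n_strata=10, beta=(1.0, 2.0),
                        noise=1.0):
    """A small survey frame with known linear structure for design tests."""
    rng = np.random.default_rng(seed)
    strata = np.repeat(np.arange(n_strata), n // n_strata)
    psu = np.tile(np.repeat([1, 2], n // n_strata // 2), n_strata)
    x = rng.standard_normal(n)
    w = rng.uniform(0.5, 2.0, n)
    y = beta[0] + beta[1] * x + noise * rng.standard_normal(n)
    X = pd.DataFrame({"intercept": np.ones(n), "x": x})
    return y, X, w, strata, psu
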