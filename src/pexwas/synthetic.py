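"""Multi-wave synthetic survey generator with known ground truth.

Emulates the structure of a stratified multistage health survey: per-wave
strata each containing (by default) two PSUs, unequal inverse-inclusion
weights ratio-adjusted to a pseudo-population total, subsample panels with
their own weights, log-normal exposure biomarkers with below-LLOD censoring,
and quantitative phenotypes generated from the linear model

    P = sum_d g_d * s_d  +  sum_e beta_e * z_e  +  (PSU effect)  +  sigma * eps

where ``s_d`` are standardized demographic drivers, ``z_e`` standardized
latent (log-scale) exposures with block correlation, and ``eps`` standard
normal. Because every variable is a linear combination of an orthonormal
factor basis, all population moments — and hence the true standardized
effects, incremental R-squared and exposure correlations — follow exactly
from the loading matrix; :func:`truth_table` returns them in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog, VariableRecord
from .data import MultiWaveData

__all__ = [
    "ConfigError",
    "demo_config",
    "read_simulated",
    "DemographicsSpec",
    "ExposureSpec",
    "PhenotypeSpec",
    "SimConfig",
    "TruthTable",
    "generate_population",
    "truth_table",
]

_DEMO_DRIVERS = ("age", "sex", "ethnicity", "education", "income")
# income-to-poverty ratio: 2.5 + 1.25 * z with z ~ N(0,1) truncated to [-2, 2]
_INC_TRUNC = 2.0


class ConfigError(ValueError):
    pass


@dataclass
class DemographicsSpec:
    age_mean: float = 45.0
    age_sd: float = 15.0
    sex_p: float = 0.5
    ethnicity_probs: tuple = (0.40, 0.25, 0.15, 0.12, 0.08)
    education_probs: tuple = (0.25, 0.45, 0.30)


@dataclass
class ExposureSpec:
    """One simulated exposure.

    ``family`` is ``lognormal`` (continuous biomarker), ``categorical`` or
    ``ordinal`` (both derived by slicing the latent score at quantiles).
    ``demo_loadings`` map demographic driver name -> loading of the latent
    exposure on that standardized driver (the confounding mechanism).
    """

    name: str
    family: str = "lognormal"
    panel: str | None = None
    block: str | None = None
    llod_quantile: float = 0.0
    log_mean: float = 0.0
    log_sd: float = 0.5
    n_levels: int = 3
    demo_loadings: dict = field(default_factory=dict)


@dataclass
class PhenotypeSpec:
    name: str
    demo_coefs: dict = field(default_factory=dict)
    resid_sd: float = 1.0
    psu_sd: float = 0.0
    wave_shifts: dict = field(default_factory=dict)


@dataclass
class SimConfig:
    n_waves: int = 2
    strata_per_wave: int = 15
    psus_per_stratum: int = 2
    n_per_psu: int = 100
    target_population: float = 1_000_000.0
    weight_dispersion: float = 0.25
    demographics: DemographicsSpec = field(default_factory=DemographicsSpec)
    exposures: list = field(default_factory=list)
    phenotypes: list = field(default_factory=list)
    block_rho: dict = field(default_factory=dict)
    panels: dict = field(default_factory=dict)      # panel -> subsample fraction
    effects: dict = field(default_factory=dict)     # (pheno, expo) -> beta (or wave->beta)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.psus_per_stratum < 2:
            raise ConfigError("psus_per_stratum must be >= 2")
        if not self.weight_dispersion >= 0:
            raise ConfigError("weight_dispersion must be non-negative")
        for panel, frac in self.panels.items():
            if not (0 < frac <= 1):
                raise ConfigError(f"subsample fraction for panel {panel!r} not in (0, 1]")
        for rho in self.block_rho.values():
            if not (0 <= rho < 1):
                raise ConfigError("block correlation must be in [0, 1)")
        for e in self.exposures:
            rho = self.block_rho.get(e.block, 0.0) if e.block else 0.0
            ssq = sum(v * v for v in e.demo_loadings.values())
            if ssq + rho > 1.0 + 1e-12:
                raise ConfigError(
                    f"exposure {e.name!r}: demographic loadings plus block "
                    "correlation exceed unit variance (non-PSD latent correlation)"
                )
            if e.llod_quantile < 0 or e.llod_quantile >= 1:
                raise ConfigError(f"exposure {e.name!r}: LLOD quantile not in [0, 1)")
            if e.panel is not None and e.panel not in self.panels:
                raise ConfigError(f"exposure {e.name!r}: unknown panel {e.panel!r}")
        for (ph, ex), beta in self.effects.items():
            vals = beta.values() if isinstance(beta, dict) else [beta]
            if not all(np.isfinite(v) for v in vals):
                raise ConfigError(f"effect for ({ph}, {ex}) must be finite")

    @property
    def n_per_wave(self) -> int:
        return self.strata_per_wave * self.psus_per_stratum * self.n_per_psu


# ---------------------------------------------------------------------------
# factor bookkeeping


def _factor_names(config: SimConfig) -> list[str]:
    blocks = sorted({e.block for e in config.exposures if e.block})
    return (
        [f"demo:{d}" for d in _DEMO_DRIVERS]
        + [f"block:{b}" for b in blocks]
        + [f"idio:{e.name}" for e in config.exposures]
    )


def _exposure_loadings(config: SimConfig) -> pd.DataFrame:
    """Loading of each latent exposure score on the orthonormal factors."""
    factors = _factor_names(config)
    L = pd.DataFrame(0.0, index=[e.name for e in config.exposures], columns=factors)
    for e in config.exposures:
        ssq = 0.0
        for d, a in e.demo_loadings.items():
            if d not in _DEMO_DRIVERS:
                raise ConfigError(f"unknown demographic driver {d!r}")
            L.loc[e.name, f"demo:{d}"] = a
            ssq += a * a
        rho = config.block_rho.get(e.block, 0.0) if e.block else 0.0
        if e.block:
            L.loc[e.name, f"block:{e.block}"] = np.sqrt(rho)
        L.loc[e.name, f"idio:{e.name}"] = np.sqrt(max(1.0 - ssq - rho, 0.0))
    return L


def _phenotype_effect(config: SimConfig, pheno: str, expo: str, wave=None) -> float:
    beta = config.effects.get((pheno, expo), 0.0)
    if isinstance(beta, dict):
        if wave is None:
            return float(np.mean(list(beta.values())))
        return float(beta.get(wave, 0.0))
    return float(beta)


def _phenotype_loadings(config: SimConfig, wave=None) -> pd.DataFrame:
    """Loading of each phenotype on the factors (excludes noise/PSU terms)."""
    Le = _exposure_loadings(config)
    factors = list(Le.columns)
    P = pd.DataFrame(0.0, index=[p.name for p in config.phenotypes], columns=factors)
    for p in config.phenotypes:
        row = np.zeros(len(factors))
        for d, g in p.demo_coefs.items():
            row[factors.index(f"demo:{d}")] += g
        for e in config.exposures:
            beta = _phenotype_effect(config, p.name, e.name, wave)
            if beta != 0.0:
                row += beta * Le.loc[e.name].to_numpy()
        P.loc[p.name] = row
    return P


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class TruthTable:
    """Closed-form population truth implied by a :class:`SimConfig`."""

    beta_univariate: dict      # (pheno, expo) -> standardized univariate slope
    beta_adjusted: dict        # (pheno, expo) -> standardized demographic-adjusted slope
    phenotype_sd: dict
    incremental_r2: dict       # pheno -> exposure-block R^2 over demographics
    exposure_corr: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(phenotype=ph, exposure=ex,
                 beta_univariate=bu, beta_adjusted=self.beta_adjusted[(ph, ex)])
            for (ph, ex), bu in self.beta_univariate.items()
        ]
        return pd.DataFrame(rows)


def truth_table(config: SimConfig) -> TruthTable:
    Le = _exposure_loadings(config)
    Lp = _phenotype_loadings(config)
    factors = list(Le.columns)
    demo_cols = [f for f in factors if f.startswith("demo:")]
    other_cols = [f for f in factors if not f.startswith("demo:")]

    expo_corr = Le @ Le.T

    beta_uni, beta_adj, pheno_sd, inc_r2 = {}, {}, {}, {}
    for p in config.phenotypes:
        lp = Lp.loc[p.name]
        var_extra = p.resid_sd**2 + p.psu_sd**2
        var_p = float(lp @ lp) + var_extra
        sd_p = float(np.sqrt(var_p))
        pheno_sd[p.name] = sd_p
        # demographic-only linear predictor explains the demo loadings exactly
        var_demo = float(lp[demo_cols] @ lp[demo_cols])
        # the full model (demographics + effect exposures) spans every factor
        # appearing in P, leaving only residual and PSU variance unexplained
        inc_r2[p.name] = (var_p - var_extra - var_demo) / var_p
        for e in config.exposures:
            le = Le.loc[e.name]
            cov = float(lp @ le)
            beta_uni[(p.name, e.name)] = cov / sd_p
            cov_perp = float(lp[other_cols] @ le[other_cols])
            var_perp = float(le[other_cols] @ le[other_cols])
            beta_adj[(p.name, e.name)] = (
                cov_perp / var_perp / sd_p if var_perp > 0 else np.nan
            )
    return TruthTable(beta_uni, beta_adj, pheno_sd, inc_r2, expo_corr)


# ---------------------------------------------------------------------------
# generation


def _draw_demographics(config: SimConfig, n: int, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    d = config.demographics
    z_age = rng.standard_normal(n)
    age = d.age_mean + d.age_sd * z_age

    sex = (rng.random(n) < d.sex_p).astype(int)
    s_sex = (sex - d.sex_p) / np.sqrt(d.sex_p * (1 - d.sex_p))

    eth_p = np.asarray(d.ethnicity_probs, dtype=float)
    eth = rng.choice(len(eth_p), size=n, p=eth_p / eth_p.sum())
    mu = (eth_p * np.arange(len(eth_p))).sum() / eth_p.sum()
    sd = np.sqrt((eth_p * np.arange(len(eth_p)) ** 2).sum() / eth_p.sum() - mu**2)
    s_eth = (eth - mu) / sd

    edu_p = np.asarray(d.education_probs, dtype=float)
    edu = rng.choice(len(edu_p), size=n, p=edu_p / edu_p.sum())
    mu_e = (edu_p * np.arange(len(edu_p))).sum() / edu_p.sum()
    sd_e = np.sqrt((edu_p * np.arange(len(edu_p)) ** 2).sum() / edu_p.sum() - mu_e**2)
    s_edu = (edu - mu_e) / sd_e

    z_inc = stats.truncnorm.rvs(-_INC_TRUNC, _INC_TRUNC, size=n,
                                random_state=rng)
    trunc_sd = float(stats.truncnorm.std(-_INC_TRUNC, _INC_TRUNC))
    income = 2.5 + 1.25 * z_inc
    s_inc = z_inc / trunc_sd

    obs = pd.DataFrame(
        dict(age=age, sex=sex, ethnicity=eth.astype(str),
             education=edu.astype(str), income=income)
    )
    drivers = pd.DataFrame(
        {"demo:age": z_age, "demo:sex": s_sex, "demo:ethnicity": s_eth,
         "demo:education": s_edu, "demo:income": s_inc}
    )
    return obs, drivers


def _make_weights(config: SimConfig, strata: np.ndarray, rng) -> np.ndarray:
    """Base weight x lognormal noise, ratio-adjusted so each stratum sums to
    its share of the pseudo-population."""
    n = len(strata)
    target_per_stratum = config.target_population / config.strata_per_wave
    w = np.empty(n)
    disp = config.weight_dispersion
    noise = rng.lognormal(mean=-0.5 * disp**2, sigma=disp, size=n) if disp > 0 else np.ones(n)
    for h in np.unique(strata):
        m = strata == h
        base = target_per_stratum / m.sum()
        wh = base * noise[m]
        w[m] = wh * (target_per_stratum / wh.sum())
    return w


def _build_sim_catalog(config: SimConfig) -> Catalog:
    records = []
    for e in config.exposures:
        vartype = {"lognormal": "continuous", "categorical": "categorical",
                   "ordinal": "ordinal"}[e.family]
        llod = {}
        if e.family == "lognormal" and e.llod_quantile > 0:
            lv = 10 ** (e.log_mean + e.log_sd * stats.norm.ppf(e.llod_quantile))
            llod = {w: float(lv) for w in range(1, config.n_waves + 1)}
        records.append(
            VariableRecord(name=e.name, role="exposure", vartype=vartype,
                           category=e.block or "exposure", panel=e.panel,
                           llod=llod,
                           comment_flag_column=f"{e.name}_llod_flag" if llod else None)
        )
    for p in config.phenotypes:
        records.append(
            VariableRecord(name=p.name, role="phenotype", vartype="continuous")
        )
    return Catalog(records)


def generate_population(config: SimConfig) -> MultiWaveData:
    """Generate the multi-wave dataset described by ``config``.

    Deterministic given ``config.seed``. Returns a :class:`MultiWaveData`
    whose component tables mirror a public-use survey release: demographics
    (with stratum, PSU and full-sample weight), one exposure table per
    subsample panel (with subsample weights and below-LLOD flags, censored
    values reported at the LLOD), and a phenotype table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    Le = _exposure_loadings(config)
    factors = list(Le.columns)
    blocks = [f for f in factors if f.startswith("block:")]

    tables = {}
    for wave in range(1, config.n_waves + 1):
        n = config.n_per_wave
        strata = np.repeat(np.arange(1, config.strata_per_wave + 1),
                           config.psus_per_stratum * config.n_per_psu)
        psu = np.tile(np.repeat(np.arange(1, config.psus_per_stratum + 1),
                                config.n_per_psu), config.strata_per_wave)
        pid = pd.Index(wave * 10_000_000 + np.arange(n), name="pid")

        obs, drivers = _draw_demographics(config, n, rng)
        fac = drivers.copy()
        for b in blocks:
            fac[b] = rng.standard_normal(n)
        for e in config.exposures:
            fac[f"idio:{e.name}"] = rng.standard_normal(n)
        F = fac[factors].to_numpy()

        Z = F @ Le.to_numpy().T  # latent standardized exposure scores
        weights = _make_weights(config, strata, rng)

        demo = obs.copy()
        demo.index = pid
        demo.insert(0, "stratum", strata)
        demo.insert(1, "psu", psu)
        demo.insert(2, "wt_full", weights)

        # exposure panels
        panel_names = sorted({e.panel for e in config.exposures if e.panel})
        membership = {
            pn: rng.random(n) < config.panels[pn] for pn in panel_names
        }
        expo_tables: dict[str, pd.DataFrame] = {}
        for j, e in enumerate(config.exposures):
            z = Z[:, j]
            if e.family == "lognormal":
                vals = 10.0 ** (e.log_mean + e.log_sd * z)
                flags = np.zeros(n, dtype=bool)
                if e.llod_quantile > 0:
                    llod = 10 ** (e.log_mean + e.log_sd
                                  * stats.norm.ppf(e.llod_quantile))
                    flags = vals < llod
                    vals = np.where(flags, llod, vals)
                cols = {e.name: vals}
                if e.llod_quantile > 0:
                    # stored as 0/1 floats so CSV round-trips and panel
                    # non-membership can be marked NaN
                    cols[f"{e.name}_llod_flag"] = flags.astype(float)
            elif e.family == "categorical":
                qs = np.linspace(0, 1, e.n_levels + 1)[1:-1]
                cuts = stats.norm.ppf(qs)
                codes = np.searchsorted(cuts, z)
                cols = {e.name: np.array([f"L{i}" for i in codes], dtype=object)}
            elif e.family == "ordinal":
                qs = np.linspace(0, 1, e.n_levels + 1)[1:-1]
                cuts = stats.norm.ppf(qs)
                cols = {e.name: (np.searchsorted(cuts, z) + 1).astype(float)}
            else:
                raise ConfigError(f"unknown exposure family {e.family!r}")
            comp = f"exposures_{e.panel}" if e.panel else "exposures_core"
            tab = expo_tables.setdefault(comp, pd.DataFrame(index=pid))
            for cname, cvals in cols.items():
                tab[cname] = cvals
            if e.panel:
                mem = membership[e.panel]
                for cname in cols:
                    tab.loc[~mem, cname] = np.nan
                wcol = f"wt_{e.panel}"
                if wcol not in tab.columns:
                    wt = np.where(mem, weights / config.panels[e.panel], np.nan)
                    tab[wcol] = wt

        # phenotypes
        Lp = _phenotype_loadings(config, wave)
        pheno = pd.DataFrame(index=pid)
        cluster_codes = (strata - 1) * config.psus_per_stratum + (psu - 1)
        n_clusters = config.strata_per_wave * config.psus_per_stratum
        for p in config.phenotypes:
            base = F @ Lp.loc[p.name].to_numpy()
            if p.psu_sd > 0:
                effects = rng.normal(0.0, p.psu_sd, size=n_clusters)
                base = base + effects[cluster_codes]
            vals = base + p.resid_sd * rng.standard_normal(n)
            vals += p.wave_shifts.get(wave, 0.0)
            pheno[p.name] = vals

        tables[wave] = {"demographics": demo, "phenotypes": pheno, **expo_tables}

    return MultiWaveData(
        tables=tables,
        catalog=_build_sim_catalog(config),
        panel_fractions=dict(config.panels),
    )


# ---------------------------------------------------------------------------
# convenience configurations


def demo_config(seed: int = 0, n_waves: int = 2, strata_per_wave: int = 15,
                n_per_psu: int = 100) -> SimConfig:
    """A small study-shaped configuration for demonstrations and the CLI.

    Two exposure panels (a biomarker panel on a 50% subsample and a dietary
    panel on the full sample), two correlated biomarker blocks, mild
    below-LLOD censoring, one confounded exposure, and a handful of
    phenotypes with planted effects spanning null to moderate.
    """
    exposures = [
        ExposureSpec("bio1", panel="lab", block="metals", llod_quantile=0.05),
        ExposureSpec("bio2", panel="lab", block="metals", llod_quantile=0.05),
        ExposureSpec("bio3", panel="lab", block="organics"),
        ExposureSpec("bio4", panel="lab", block="organics",
                     demo_loadings={"age": 0.4}),
        ExposureSpec("diet1"),
        ExposureSpec("diet2"),
        ExposureSpec("smoke_status", family="categorical", n_levels=3),
        ExposureSpec("activity", family="ordinal", n_levels=3),
    ]
    phenotypes = [
        PhenotypeSpec("pheno_bmi", demo_coefs={"age": 0.3, "sex": -0.1},
                      resid_sd=1.0, psu_sd=0.1),
        PhenotypeSpec("pheno_lipid", demo_coefs={"age": 0.2}, resid_sd=1.0),
        PhenotypeSpec("pheno_null", resid_sd=1.0),
    ]
    effects = {
        ("pheno_bmi", "bio1"): 0.2,
        ("pheno_bmi", "diet1"): -0.1,
        ("pheno_lipid", "bio3"): 0.15,
        ("pheno_lipid", "diet2"): 0.1,
    }
    return SimConfig(
        n_waves=n_waves, strata_per_wave=strata_per_wave, n_per_psu=n_per_psu,
        exposures=exposures, phenotypes=phenotypes,
        block_rho={"metals": 0.4, "organics": 0.3},
        panels={"lab": 0.5}, effects=effects, seed=seed,
    )


def read_simulated(indir) -> MultiWaveData:
    """Load a dataset written by :meth:`MultiWaveData.write_csv`."""
    return MultiWaveData.read_csv(indir)
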