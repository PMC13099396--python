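"""Exposome-wide association engine.

Fits every eligible (phenotype, exposure) pair under each of nine adjustment
scenarios, per survey wave and pooled across waves, using the design engine
for survey-weighted estimation. Each fit standardizes the phenotype,
transforms the exposure (log10 + standardize for continuous biomarkers,
indicators against the largest category for categoricals, rank codes for
ordinals), and reports the association coefficient with linearized SE and p
together with the variance decomposition: R-squared of the full model, of
the covariates-only model on the same sample, and their difference — the
variance attributable to the exposure beyond demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data import MultiWaveData
from .design import fit_survey_wls, weighted_moments, DesignError, RankError
from .transforms import scale_phenotype, transform_exposure

__all__ = [
    "SCENARIOS",
    "WaveAssociation",
    "scenario_covariates",
    "run_pair_wave",
    "run_pair_pooled",
    "incremental_r2",
    "interaction_delta_r2",
    "run_exwas",
]

# the nine adjustment scenarios; "wave" enters pooled fits only
SCENARIOS = {
    1: ["age", "age2", "sex", "income", "ethnicity", "education", "wave"],
    2: [],
    3: ["sex", "wave"],
    4: ["age", "age2", "wave"],
    5: ["sex", "age", "age2", "wave"],
    6: ["ethnicity", "wave"],
    7: ["income", "education", "wave"],
    8: ["age", "age2", "sex", "ethnicity", "wave"],
    9: ["age", "age2", "sex", "income", "education", "wave"],
}

_CATEGORICAL_TOKENS = {"ethnicity", "education", "wave"}
_TOKEN_RAW = {"age": "age", "age2": "age", "sex": "sex", "income": "income",
              "ethnicity": "ethnicity", "education": "education"}


def scenario_covariates(scenario: int, pooled: bool = True) -> list[str]:
    """Covariate tokens for one adjustment scenario (1..9)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be in 1..9, got {scenario}")
    tokens = list(SCENARIOS[scenario])
    if not pooled:
        tokens = [t for t in tokens if t != "wave"]
    return tokens


def raw_covariate_columns(scenario: int) -> tuple:
    """Raw data columns a scenario needs (for complete-case assembly)."""
    return tuple(dict.fromkeys(
        _TOKEN_RAW[t] for t in scenario_covariates(scenario, pooled=False)
    ))


@dataclass
class WaveAssociation:
    """One fitted association: a pair x scenario in one wave (or pooled)."""

    phenotype: str
    exposure: str
    scenario: int
    wave: object            # wave id, or None for the pooled fit
    term: str               # model-matrix column tested (level for categoricals)
    beta: float
    se: float
    statistic: float
    p: float
    n: int
    rsq_full: float
    rsq_base: float
    rsq_diff: float
    df_design: int
    status: str = "ok"


def _categorical_dummies(s: pd.Series, w: np.ndarray, name: str) -> pd.DataFrame:
    s = s.astype(str)
    totals = pd.Series(w, index=s.index).groupby(s).sum()
    ref = totals.sort_index().sort_values(ascending=False, kind="stable").index[0]
    levels = [lv for lv in sorted(totals.index) if lv != ref]
    return pd.DataFrame(
        {f"{name}[{lv}]": (s == lv).astype(float) for lv in levels}, index=s.index
    )


def build_covariate_matrix(frame: pd.DataFrame, tokens: list[str],
                           weights) -> pd.DataFrame:
    """Model matrix (with intercept) for a list of covariate tokens.

    Age is centered at its survey-weighted mean before squaring, so the
    quadratic term is well conditioned and fits are shift-invariant.
    """
    w = np.asarray(weights, dtype=float)
    X = pd.DataFrame(index=frame.index)
    X["intercept"] = 1.0
    age_c = None
    if "age" in tokens or "age2" in tokens:
        mean_age, _ = weighted_moments(frame["age"].to_numpy(), w)
        age_c = frame["age"] - mean_age
    for t in tokens:
        if t == "age":
            X["age"] = age_c
        elif t == "age2":
            X["age2"] = age_c**2
        elif t in ("sex", "income"):
            X[t] = frame[t].astype(float)
        elif t in _CATEGORICAL_TOKENS:
            dums = _categorical_dummies(frame[t], w, t)
            for c in dums.columns:
                X[c] = dums[c]
        else:
            raise ValueError(f"unknown covariate token {t!r}")
    return X


def incremental_r2(fit_full, fit_base) -> float:
    """R-squared attributable to the exposure: full minus covariates-only.

    Both fits must be on the identical estimation sample; non-negative by
    nesting (tiny negative rounding is clipped at zero).
    """
    if fit_full.nobs != fit_base.nobs:
        raise ValueError("fits are not on the same estimation sample")
    if (fit_full.sample_index is not None and fit_base.sample_index is not None
            and not fit_full.sample_index.equals(fit_base.sample_index)):
        raise ValueError("fits are not on the same estimation sample")
    diff = fit_full.rsquared - fit_base.rsquared
    if diff < -1e-8:
        raise ValueError("full-model R^2 below base-model R^2: samples differ?")
    return max(diff, 0.0)


def _prepare_pair_frame(data: MultiWaveData, phenotype: str, exposure: str,
                        scenario: int, waves=None,
                        phenotype_method: str = "standardize"):
    """Assemble + transform the pooled estimation frame for one pair.

    The zero-offset, standardization moments and reference category are
    computed on the pooled sample so the transform is identical across waves.
    """
    raw_cov = raw_covariate_columns(scenario)
    frame = data.assemble_pair(phenotype, exposure, covariates=raw_cov,
                               waves=waves)
    if frame.empty:
        return None
    w = frame["weight"].to_numpy()
    vartype = data.catalog[exposure].vartype
    y, _ = scale_phenotype(frame[phenotype], w, method=phenotype_method)
    e_t, emeta = transform_exposure(frame[exposure], vartype, w, name=exposure)
    frame = frame.copy()
    frame["_y"] = y
    e_t = e_t.to_frame() if isinstance(e_t, pd.Series) else e_t
    expo_cols = list(e_t.columns)
    for c in expo_cols:
        frame[c] = e_t[c]
    return frame, expo_cols, emeta


def _fit_records(frame, expo_cols, phenotype, exposure, scenario, wave,
                 pooled: bool, extra_terms: pd.DataFrame | None = None):
    tokens = scenario_covariates(scenario, pooled=pooled and
                                 frame["wave"].nunique() > 1)
    w = frame["weight"].to_numpy()
    Xcov = build_covariate_matrix(frame, tokens, w)
    Xfull = Xcov.copy()
    for c in expo_cols:
        Xfull[c] = frame[c]
    if extra_terms is not None:
        for c in extra_terms.columns:
            Xfull[c] = extra_terms[c]
    # per-wave release files reuse stratum/PSU labels; waves are independent
    # samplings, so pooled fits treat (wave, stratum) as the stratum
    strata = (frame["wave"].astype(str) + ":" + frame["stratum"].astype(str)).to_numpy()
    psu = frame["psu"].to_numpy()
    y = frame["_y"].to_numpy()
    full = fit_survey_wls(y, Xfull, w, strata, psu, scenario=scenario)
    base = fit_survey_wls(y, Xcov, w, strata, psu, scenario=scenario)
    diff = incremental_r2(full, base)
    records = []
    for c in expo_cols:
        records.append(WaveAssociation(
            phenotype=phenotype, exposure=exposure, scenario=scenario,
            wave=wave, term=c,
            beta=float(full.params[c]), se=float(full.bse[c]),
            statistic=float(full.tvalues[c]), p=float(full.pvalues[c]),
            n=full.nobs, rsq_full=full.rsquared, rsq_base=base.rsquared,
            rsq_diff=diff, df_design=full.df_design,
        ))
    return records, full


def run_pair_pooled(data: MultiWaveData, pair, scenario: int = 1,
                    waves=None, phenotype_method: str = "standardize"
                    ) -> list[WaveAssociation]:
    """Pooled-across-waves fit for one pair (wave indicator as covariate)."""
    phenotype, exposure = pair
    prep = _prepare_pair_frame(data, phenotype, exposure, scenario, waves,
                               phenotype_method)
    if prep is None:
        return []
    frame, expo_cols, _ = prep
    recs, _ = _fit_records(frame, expo_cols, phenotype, exposure, scenario,
                           wave=None, pooled=True)
    return recs


def run_pair_wave(data: MultiWaveData, pair, scenario: int, wave,
                  phenotype_method: str = "standardize",
                  min_n: int = 50) -> list[WaveAssociation]:
    """Single-wave fit (transform moments still pooled across all waves)."""
    phenotype, exposure = pair
    prep = _prepare_pair_frame(data, phenotype, exposure, scenario,
                               phenotype_method=phenotype_method)
    if prep is None:
        return []
    frame, expo_cols, _ = prep
    sub = frame[frame["wave"] == wave]
    if len(sub) < min_n:
        return [WaveAssociation(
            phenotype=phenotype, exposure=exposure, scenario=scenario,
            wave=wave, term=c, beta=np.nan, se=np.nan, statistic=np.nan,
            p=np.nan, n=len(sub), rsq_full=np.nan, rsq_base=np.nan,
            rsq_diff=np.nan, df_design=0, status="skipped-n",
        ) for c in expo_cols]
    recs, _ = _fit_records(sub, expo_cols, phenotype, exposure, scenario,
                           wave=wave, pooled=False)
    return recs


def interaction_delta_r2(data: MultiWaveData, pair, scenario: int = 1,
                         waves=None) -> float:
    """Gain in R-squared from an exposure-by-age interaction term.

    Compares scenario covariates + exposure + exposure x centered-age with
    scenario covariates + exposure, on the identical pooled sample.
    Continuous exposures only.
    """
    phenotype, exposure = pair
    if data.catalog[exposure].vartype != "continuous":
        raise ValueError("age interaction requires a continuous exposure")
    raw_cov = tuple(dict.fromkeys(raw_covariate_columns(scenario) + ("age",)))
    frame = data.assemble_pair(phenotype, exposure, covariates=raw_cov,
                               waves=waves)
    if frame.empty:
        raise ValueError("no data for pair")
    w = frame["weight"].to_numpy()
    y, _ = scale_phenotype(frame[phenotype], w)
    e_t, _ = transform_exposure(frame[exposure], "continuous", w, name=exposure)
    frame = frame.copy()
    frame["_y"] = y
    frame[exposure] = e_t
    mean_age, _ = weighted_moments(frame["age"].to_numpy(), w)
    inter = pd.DataFrame(
        {f"{exposure}:age": e_t * (frame["age"] - mean_age)}, index=frame.index
    )
    _, fit_main = _fit_records(frame, [exposure], phenotype, exposure,
                               scenario, wave=None, pooled=True)
    _, fit_int = _fit_records(frame, [exposure], phenotype, exposure,
                              scenario, wave=None, pooled=True,
                              extra_terms=inter)
    return max(fit_int.rsquared - fit_main.rsquared, 0.0)


def run_exwas(data: MultiWaveData, manifest, scenarios=(1,),
              phenotype_method: str = "standardize", min_wave_n: int = 50,
              progress: bool = False):
    """Batch-run the atlas: per-wave fits, pooled fits, and cross-wave meta.

    Returns ``(wave_records, meta_records)`` as DataFrames. ``meta_records``
    carries, per pair x scenario x term, the pooled-regression estimate and
    the unrestricted-WLS meta-analytic columns, replication counts, and the
    exposure R-squared decomposition of the pooled fit. Multiplicity
    adjustment is applied afterwards over each scenario family (see
    :func:`pexwas.meta.annotate_significance`).
    """
    from .meta import uwls_meta, replication_counts

    wave_rows, meta_rows = [], []
    pairs = manifest.pairs() if hasattr(manifest, "pairs") else list(manifest)
    for pnum, (pheno, expo) in enumerate(pairs):
        if progress and pnum % 50 == 0:
            print(f"[exwas] pair {pnum + 1}/{len(pairs)}")
        for scen in scenarios:
            prep = _prepare_pair_frame(data, pheno, expo, scen,
                                       phenotype_method=phenotype_method)
            if prep is None:
                continue
            frame, expo_cols, _ = prep
            try:
                pooled_recs, _ = _fit_records(frame, expo_cols, pheno, expo,
                                              scen, wave=None, pooled=True)
            except (DesignError, RankError):
                continue
            waves = sorted(frame["wave"].unique())
            per_wave: dict[str, list[WaveAssociation]] = {c: [] for c in expo_cols}
            for wv in waves:
                sub = frame[frame["wave"] == wv]
                if len(sub) < min_wave_n:
                    continue
                try:
                    recs, _ = _fit_records(sub, expo_cols, pheno, expo, scen,
                                           wave=wv, pooled=False)
                except (DesignError, RankError):
                    continue
                for r in recs:
                    per_wave[r.term].append(r)
                    wave_rows.append(asdict(r))
            for prec in pooled_recs:
                term_waves = per_wave[prec.term]
                row = dict(
                    pvarname=pheno, evarname=expo, model_number=scen,
                    term=prec.term,
                    estimate_pooled=prec.beta, se_pooled=prec.se,
                    p_pooled=prec.p, total_n=prec.n,
                    rsq_full=prec.rsq_full, rsq_base=prec.rsq_base,
                    rsq_adjusted_base_diff=prec.rsq_diff,
                )
                if len(term_waves) >= 2:
                    b = np.array([r.beta for r in term_waves])
                    se = np.array([r.se for r in term_waves])
                    ok = se > 0
                    if ok.sum() >= 2:
                        m = uwls_meta(b[ok], se[ok])
                        conc, sconc, repl = replication_counts(
                            [r.p for r in term_waves],
                            [np.sign(r.beta) for r in term_waves],
                            np.sign(m.estimate),
                        )
                        row.update(
                            estimate_uwls=m.estimate, std_error_uwls=m.se,
                            statistic_uwls=m.statistic, p_value_uwls=m.p,
                            q_uwls=m.Q, h_squared_uwls=m.H2,
                            i_squared_uwls=m.I2, k_uwls=m.k,
                            model_concordance=conc,
                            model_concordance_1_2=sconc,
                            replicated=repl,
                        )
                meta_rows.append(row)
    return pd.DataFrame(wave_rows), pd.DataFrame(meta_rows)
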