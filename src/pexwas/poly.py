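"""Poly-exposomic models: joint variance explained by multiple exposures.

For one phenotype, the workflow (i) takes the FDR-significant exposures from
the association atlas and keeps up to the top 20 ranked by their univariate
incremental R-squared, (ii) completes missing exposure values by chained
equations with predictive mean matching (PMM) into m = 10 imputed datasets,
and (iii) fits, on each completed dataset, a demographics-only model and a
demographics-plus-exposures model, reporting the incremental R-squared
averaged over imputations. Coefficient tables are pooled by Rubin's rules.

The baseline demographic set for this workflow is age, sex, ethnicity and
education.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import fit_survey_wls
from .exwas import build_covariate_matrix

__all__ = [
    "PolyModelSpec",
    "select_top_exposures",
    "mice_pmm",
    "poly_r2",
    "pool_coefficients",
]

POLY_DEMOGRAPHICS = ("age", "age2", "sex", "ethnicity", "education")


@dataclass
class PolyModelSpec:
    phenotype: str
    exposures: list = field(default_factory=list)
    k_max: int = 20
    m: int = 10
    n_iter: int = 10
    donors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.k_max < 1 or self.m < 1 or self.donors < 1:
            raise ValueError("k_max, m and donors must all be >= 1")


def select_top_exposures(atlas: pd.DataFrame, phenotype: str,
                         k_max: int = 20, alpha: float = 0.05,
                         p_col: str = "pval_BY",
                         r2_col: str = "rsq_adjusted_base_diff") -> list[str]:
    """FDR-significant exposures ranked by univariate R^2 contribution.

    Sorted by incremental R-squared descending (name as deterministic
    tie-break), truncated at ``k_max``. Empty list if nothing is significant.
    """
    sub = atlas[(atlas["pvarname"] == phenotype) & (atlas[p_col] < alpha)]
    sub = sub.sort_values([r2_col, "evarname"], ascending=[False, True],
                          kind="stable")
    seen: list[str] = []
    for e in sub["evarname"]:
        if e not in seen:
            seen.append(e)
        if len(seen) == k_max:
            break
    return seen


def _pmm_impute_column(X: np.ndarray, y: np.ndarray, miss: np.ndarray,
                       donors: int, rng) -> np.ndarray:
    """One PMM draw for one column given completed predictors X."""
    obs = ~miss
    Xo = np.column_stack([np.ones(obs.sum()), X[obs]])
    Xm = np.column_stack([np.ones(miss.sum()), X[miss]])
    yo = y[obs]
    XtX = Xo.T @ Xo
    XtX += np.eye(XtX.shape[0]) * 1e-8 * np.trace(XtX) / XtX.shape[0]
    beta = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ beta
    dof = max(obs.sum() - Xo.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    # draw sigma*^2 from its scaled inverse-chi-squared posterior, then
    # beta* ~ N(beta_hat, sigma*^2 (X'X)^-1)
    sigma2_star = sigma2 * dof / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    pred_obs = Xo @ beta          # observed scored with beta_hat
    pred_mis = Xm @ beta_star     # missing scored with the perturbed draw
    out = y.copy()
    d = min(donors, len(yo))
    for row, pm in zip(np.where(miss)[0], pred_mis):
        nearest = np.argpartition(np.abs(pred_obs - pm), d - 1)[:d]
        out[row] = yo[rng.choice(nearest)]
    return out


def mice_pmm(data: pd.DataFrame, columns=None, m: int = 10, n_iter: int = 10,
             donors: int = 5, seed: int = 0) -> list[pd.DataFrame]:
    """Chained-equation imputation with predictive mean matching.

    Only the listed ``columns`` (default: every column with missing values)
    are imputed; all other columns must be complete and serve as predictors.
    Each imputed value is an observed value copied from one of the ``donors``
    cases with the nearest model prediction, so imputations stay within the
    observed support. Reproducible under ``seed``.
    """
    df = data.copy()
    if columns is None:
        columns = [c for c in df.columns if df[c].isna().any()]
    for c in columns:
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
        if (~df[c].isna()).sum() < donors:
            raise ValueError(f"column {c!r} has fewer observed values than donors")
    others = [c for c in df.columns if c not in columns]
    if df[others].isna().any().any():
        raise ValueError("predictor columns must be complete")
    if not columns:
        return [df.copy() for _ in range(m)]

    rng = np.random.default_rng(seed)
    mat = df.astype(float).to_numpy()
    colpos = {c: df.columns.get_loc(c) for c in df.columns}
    miss_masks = {c: df[c].isna().to_numpy() for c in columns}

    completed = []
    for _ in range(m):
        work = mat.copy()
        for c in columns:  # initialize with observed means
            j = colpos[c]
            mk = miss_masks[c]
            work[mk, j] = np.nanmean(mat[:, j])
        for _ in range(n_iter):
            for c in columns:
                j = colpos[c]
                mk = miss_masks[c]
                if not mk.any():
                    continue
                pred_cols = [colpos[o] for o in df.columns if o != c]
                work[:, j] = _pmm_impute_column(
                    work[:, pred_cols], work[:, j], mk, donors, rng
                )
        completed.append(pd.DataFrame(work, index=df.index, columns=df.columns))
    return completed


def poly_r2(completed: list[pd.DataFrame], phenotype: str, exposures: list,
            demographics=POLY_DEMOGRAPHICS, weighted: bool = True
            ) -> tuple[float, pd.DataFrame]:
    """Incremental R^2 of the exposure block over demographics.

    Each completed dataset must carry ``stratum``, ``psu`` and ``weight``
    columns besides the phenotype, exposures and demographic covariates.
    Returns the incremental R-squared averaged over imputations and the
    Rubin-pooled coefficient table for the exposure terms.
    """
    if not completed:
        raise ValueError("need at least one completed dataset")
    diffs, coef_fits = [], []
    for df in completed:
        w = df["weight"].to_numpy() if weighted else np.ones(len(df))
        tokens = [t for t in demographics]
        Xbase = build_covariate_matrix(df, tokens, w)
        Xfull = Xbase.copy()
        for e in exposures:
            Xfull[e] = df[e].astype(float)
        y = df[phenotype].to_numpy(dtype=float)
        strata, psu = df["stratum"].to_numpy(), df["psu"].to_numpy()
        full = fit_survey_wls(y, Xfull, w, strata, psu)
        base = fit_survey_wls(y, Xbase, w, strata, psu)
        diffs.append(max(full.rsquared - base.rsquared, 0.0))
        coef_fits.append(full)
    coefs = pool_coefficients(coef_fits, terms=list(exposures))
    return float(np.mean(diffs)), coefs


def pool_coefficients(fits, terms=None) -> pd.DataFrame:
    """Rubin's rules across imputation fits: estimate, SE, t, p per term."""
    m = len(fits)
    params = pd.concat([f.params for f in fits], axis=1)
    variances = pd.concat([f.bse**2 for f in fits], axis=1)
    if terms is not None:
        params, variances = params.loc[terms], variances.loc[terms]
    qbar = params.mean(axis=1)
    ubar = variances.mean(axis=1)
    bvar = params.var(axis=1, ddof=1) if m > 1 else 0.0 * qbar
    total = ubar + (1 + 1 / m) * bvar
    se = np.sqrt(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = qbar / se
        # Rubin small-sample df; infinite when between-imputation var is 0
        r = (1 + 1 / m) * bvar / ubar
        df = np.where(r > 0, (m - 1) * (1 + 1 / r) ** 2, np.inf)
    from scipy import stats as _st
    p = 2 * _st.t.sf(np.abs(t), np.clip(df, 1, None))
    return pd.DataFrame(
        {"estimate": qbar, "se": se, "statistic": t, "df": df, "p": p}
    )
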