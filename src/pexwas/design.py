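"""Design-based estimation for complex multistage surveys.

Implements the estimation core used by every association fit: analysis-weight
harmonization across survey components, survey-weighted moments, and weighted
least squares with Taylor-linearized ("sandwich") variance that accounts for
stratification and clustering by primary sampling unit (PSU).

The variance estimator aggregates weighted score residuals to PSU totals
``z_hc = sum_{i in (h,c)} w_i x_i (y_i - x_i' beta)`` and measures their
between-PSU variation within each stratum:

    G = sum_h [n_h / (n_h - 1)] sum_c (z_hc - zbar_h)(z_hc - zbar_h)'
    V(beta) = (X'WX)^{-1} G (X'WX)^{-1}

Inference uses a t reference with design degrees of freedom
``#PSUs - #strata``, the conventional rule for public-use designs with two
masked variance units per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignError",
    "RankError",
    "WeightComponent",
    "FitResult",
    "harmonize_weights",
    "weighted_moments",
    "fit_survey_wls",
]


class DesignError(ValueError):
    """Invalid survey design (weights, strata/PSU structure, or df)."""


class RankError(ValueError):
    """Model matrix is rank deficient; names the aliased columns."""


@dataclass
class WeightComponent:
    """One merged survey component contributing a candidate weight column.

    ``n_subsample`` defaults to the number of participants carrying a
    positive weight, i.e. the size of the subsample the component was
    measured on.
    """

    name: str
    weights: pd.Series
    n_subsample: int | None = None

    def effective_n(self) -> int:
        if self.n_subsample is not None:
            return int(self.n_subsample)
        return int(self.weights.notna().sum())


def harmonize_weights(
    components: list[WeightComponent], n_waves_combined: int = 1
) -> pd.Series:
    """Choose the analysis weight across merged survey components.

    The weight of the component measured on the smallest subsample is used
    (that component constrains the estimation sample), then divided by the
    number of survey waves combined so that pooled estimates still refer to
    a single-wave pseudo-population.
    """
    usable = [c for c in components if c.weights is not None and c.effective_n() > 0]
    if not usable:
        raise DesignError("no component provides a usable weight column")
    smallest = min(usable, key=lambda c: (c.effective_n(), c.name))
    w = smallest.weights.astype(float)
    if (w.dropna() <= 0).any():
        raise DesignError(
            f"non-positive weights in component {smallest.name!r}"
        )
    if n_waves_combined < 1:
        raise DesignError("n_waves_combined must be >= 1")
    return w / float(n_waves_combined)


def weighted_moments(x, w) -> tuple[float, float]:
    """Survey-weighted mean and standard deviation.

    mean = sum(w x) / sum(w);  var = sum(w (x - mean)^2) / (sum(w) - 1)
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError("x and w must have matching length")
    if np.any(w <= 0):
        raise DesignError("weights must be positive")
    sw = w.sum()
    if sw <= 1:
        raise DesignError("sum of weights must exceed 1 for the variance denominator")
    mean = float((w * x).sum() / sw)
    var = float((w * (x - mean) ** 2).sum() / (sw - 1.0))
    return mean, float(np.sqrt(var))


@dataclass
class FitResult:
    """A fitted survey-weighted linear model."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_design: int
    rsquared: float
    nobs: int
    vcov: pd.DataFrame = field(repr=False)
    scenario: int | None = None
    lonely_strata: int = 0
    sample_index: pd.Index | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.df_design <= 0:
            raise DesignError(
                f"design degrees of freedom must be positive, got {self.df_design}"
            )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # small diagonal entries of R expose (near-)aliased columns
    _, r = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    if scale == 0.0:
        raise RankError(f"model matrix is all zero: {names}")
    bad = diag < scale * 1e-10
    if bad.any():
        aliased = [names[j] for j in np.where(bad)[0]]
        raise RankError(f"model matrix is rank deficient; aliased columns: {aliased}")


def fit_survey_wls(
    y,
    X: pd.DataFrame,
    weights,
    strata,
    psu,
    lonely: str = "adjust",
    scenario: int | None = None,
) -> FitResult:
    """Survey-weighted least squares with linearized variance.

    Parameters
    ----------
    y, X, weights
        Response, model matrix (include an intercept column explicitly),
        and positive analysis weights, row-aligned.
    strata, psu
        Stratum and PSU identifiers per row. PSU labels are interpreted
        within stratum, so reused PSU codes across strata are safe.
    lonely
        Policy for strata with a single PSU: ``"adjust"`` scores the lonely
        PSU against the grand mean of all PSU totals (certainty-like
        handling); ``"error"`` raises.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    names = [str(c) for c in X.columns]
    yv = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(~np.isfinite(yv)) or np.any(~np.isfinite(Xv)):
        raise ValueError("y and X must be finite (complete cases only)")
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise DesignError("weights must be positive and finite")

    _check_rank(np.sqrt(w)[:, None] * Xv, names)

    A = Xv.T @ (w[:, None] * Xv)
    b = Xv.T @ (w * yv)
    beta = np.linalg.solve(A, b)
    resid = yv - Xv @ beta

    # PSU totals of weighted score residuals
    strata = np.asarray(strata)
    psu = np.asarray(psu)
    score = (w * resid)[:, None] * Xv
    cluster = pd.MultiIndex.from_arrays([strata, psu])
    totals = pd.DataFrame(score, index=cluster).groupby(level=[0, 1]).sum()

    n_psu = len(totals)
    strat_labels = totals.index.get_level_values(0)
    n_strata = strat_labels.nunique()
    df_design = n_psu - n_strata
    if df_design <= 0:
        raise DesignError(
            f"non-positive design df: {n_psu} PSUs in {n_strata} strata"
        )

    p = Xv.shape[1]
    G = np.zeros((p, p))
    grand_mean = totals.to_numpy().mean(axis=0)
    lonely_strata = 0
    for _, zh in totals.groupby(level=0):
        Z = zh.to_numpy()
        nh = Z.shape[0]
        if nh == 1:
            if lonely == "error":
                raise DesignError("stratum with a single PSU (lonely PSU)")
            lonely_strata += 1
            d = Z[0] - grand_mean
            G += np.outer(d, d)
        else:
            D = Z - Z.mean(axis=0)
            G += (nh / (nh - 1.0)) * (D.T @ D)

    Ainv = np.linalg.inv(A)
    V = Ainv @ G @ Ainv
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_design)

    # weighted R^2 about the weighted mean (models carry an intercept)
    sw = w.sum()
    ybar = (w * yv).sum() / sw
    tss = (w * (yv - ybar) ** 2).sum()
    rss = (w * resid**2).sum()
    rsq = 1.0 - rss / tss if tss > 0 else np.nan

    idx = pd.Index(names)
    return FitResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        df_design=int(df_design),
        rsquared=float(rsq),
        nobs=int(len(yv)),
        vcov=pd.DataFrame(V, index=idx, columns=idx),
        scenario=scenario,
        lonely_strata=lonely_strata,
        sample_index=X.index if isinstance(X, pd.DataFrame) else None,
    )
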