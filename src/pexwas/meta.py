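"""Cross-wave meta-analysis, multiplicity control, and power.

Cross-wave pooling uses unrestricted weighted least squares (UWLS): the
fixed-effect inverse-variance point estimate whose standard error is scaled
by sqrt(H^2) = sqrt(Q/(k-1)) with no floor at 1, so under-dispersed sets of
wave estimates yield standard errors below the fixed-effect one. Cochran's
Q, H^2 and I^2 quantify between-wave heterogeneity.

Multiplicity control offers the Bonferroni family-wise error rate and the
Benjamini-Yekutieli FDR (valid under arbitrary dependence; step-up with the
harmonic-sum factor c(m) = sum_{i<=m} 1/i). The exposome inflation factor
lambda compares the median squared test statistic against the null median
of chi-squared(1), exactly as genomic control does for GWAS.

The power module inverts the noncentral-F power function of a single-df
exposure test (noncentrality n R^2 / (1 - R^2)) to the minimum detectable
R^2 at a given sample size, significance level and power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "UwlsResult",
    "uwls_meta",
    "replication_counts",
    "adjust_pvalues",
    "annotate_significance",
    "bonferroni_threshold",
    "inflation_factor",
    "power_for_r2",
    "min_detectable_r2",
]

CHI2_1_MEDIAN = float(stats.chi2.median(1))


@dataclass
class UwlsResult:
    estimate: float
    se: float          # UWLS standard error: se_FE * sqrt(H^2), unfloored
    se_fixed: float
    statistic: float
    p: float
    Q: float
    H2: float
    I2: float          # percent
    k: int
    zero_dispersion: bool = False


def uwls_meta(estimates, std_errors, reference: str = "t") -> UwlsResult:
    """Unrestricted weighted least squares meta-analysis over k waves.

    ``reference="t"`` (default) refers the statistic to a t distribution on
    k-1 df; ``"normal"`` uses the standard normal. If Q = 0 the UWLS
    standard error is exactly 0 and the result is flagged
    ``zero_dispersion`` rather than floored.
    """
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(std_errors, dtype=float)
    k = len(b)
    if k < 2:
        raise ValueError("meta-analysis requires k >= 2 wave estimates")
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("standard errors must be positive and finite")
    v = 1.0 / se**2
    bbar = float((v * b).sum() / v.sum())
    se_fe = float(v.sum() ** -0.5)
    Q = float((v * (b - bbar) ** 2).sum())
    H2 = Q / (k - 1)
    I2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
    se_uwls = se_fe * np.sqrt(H2)
    if se_uwls > 0:
        t = bbar / se_uwls
        if reference == "t":
            p = 2.0 * stats.t.sf(abs(t), k - 1)
        elif reference == "normal":
            p = 2.0 * stats.norm.sf(abs(t))
        else:
            raise ValueError(f"unknown reference {reference!r}")
        zero = False
    else:
        t = np.inf if bbar != 0 else 0.0
        p = 0.0 if bbar != 0 else 1.0
        zero = True
    return UwlsResult(bbar, float(se_uwls), se_fe, float(t), float(p),
                      Q, float(H2), float(I2), k, zero)


def replication_counts(p_values, signs, pooled_sign,
                       alpha: float = 0.05) -> tuple[int, int, bool]:
    """Per-wave replication accounting for one association.

    Returns ``(concordance, sign_concordance, replicated)``: the number of
    waves nominally significant at ``alpha``, the number of those whose sign
    matches the pooled estimate, and whether the association replicated
    (nominally significant in at least two waves).
    """
    p = np.asarray(p_values, dtype=float)
    s = np.asarray(signs, dtype=float)
    if p.shape != s.shape:
        raise ValueError("p-values and signs must align")
    sig = p < alpha
    conc = int(sig.sum())
    sconc = int((sig & (s == pooled_sign)).sum())
    return conc, sconc, conc >= 2


def adjust_pvalues(p, method: str = "benjamini_yekutieli") -> np.ndarray:
    """Adjusted p-values: ``bonferroni`` or ``benjamini_yekutieli``.

    BY is the step-up procedure with the harmonic factor c(m): adjusted
    p_(i) = min over j >= i of min(1, c(m) * m / j * p_(j)).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(m * p, 1.0)
    if method in ("benjamini_yekutieli", "by"):
        cm = (1.0 / np.arange(1, m + 1)).sum()
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        raw = cm * m / np.arange(1, m + 1) * ranked
        adj = np.minimum.accumulate(raw[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty(m)
        out[order] = adj
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def annotate_significance(atlas: pd.DataFrame, p_col: str = "p_value_uwls",
                          family_col: str = "model_number",
                          alpha: float = 0.05, suffix: str = "") -> pd.DataFrame:
    """Add multiplicity columns to an association table.

    Adjusts within each scenario family (one family of tests per adjustment
    scenario): ``pvalue_bonferroni``, ``pval_BY`` and the nested tier label
    ``sig_levels`` in {``bonferroni``, ``fdr``, ``none``}. ``suffix`` lets a
    second p-value column (e.g. the pooled-regression p) be annotated
    alongside the meta-analytic one.
    """
    out = atlas.copy()
    bonf_col, by_col, tier_col = (f"pvalue_bonferroni{suffix}",
                                  f"pval_BY{suffix}", f"sig_levels{suffix}")
    out[bonf_col] = np.nan
    out[by_col] = np.nan
    out[tier_col] = "none"
    for _, idx in out.groupby(family_col).groups.items():
        p = out.loc[idx, p_col].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if not ok.any():
            continue
        bonf = np.full(len(p), np.nan)
        by = np.full(len(p), np.nan)
        bonf[ok] = adjust_pvalues(p[ok], "bonferroni")
        by[ok] = adjust_pvalues(p[ok], "benjamini_yekutieli")
        out.loc[idx, bonf_col] = bonf
        out.loc[idx, by_col] = by
        tier = np.where(bonf < alpha, "bonferroni",
                        np.where(by < alpha, "fdr", "none"))
        out.loc[idx, tier_col] = tier
    return out


def inflation_factor(z=None, p=None) -> float:
    """Exposome inflation factor: median(z^2) / median(chi-squared_1).

    Accepts either test statistics ``z`` or two-sided p-values ``p``
    (converted to |z| via the normal quantile). Requires at least 10 tests.
    """
    if z is None and p is None:
        raise ValueError("provide z statistics or p-values")
    if z is None:
        p = np.asarray(p, dtype=float)
        p = p[np.isfinite(p)]
        z = stats.norm.isf(p / 2.0)
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 10:
        raise ValueError("inflation factor needs at least 10 tests")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def power_for_r2(r2: float, n: int, alpha: float) -> float:
    """Power of the single-df exposure F test at true R^2 and sample size n."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    lam = n * r2 / (1.0 - r2)
    fcrit = stats.f.isf(alpha, 1, n - 2)
    return float(stats.ncf.sf(fcrit, 1, n - 2, lam))


def min_detectable_r2(n: int, alpha: float = 1e-6, power: float = 0.80) -> float:
    """Smallest R^2 detectable by a single-df exposure test.

    Inverts the noncentral-F power function with noncentrality
    n R^2 / (1 - R^2); strictly decreasing in n.
    """
    if n <= 2:
        raise ValueError("n must exceed 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("requested power not above the significance level")
    f = lambda r2: power_for_r2(r2, n, alpha) - power
    lo, hi = 1e-10, 1.0 - 1e-10
    if f(hi) < 0:
        raise ValueError("infeasible: even R^2 near 1 cannot reach the power")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))
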