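"""Deterministic variable transforms applied before model fitting.

Phenotypes are standardized to survey-weighted mean 0 / s.d. 1 (or mapped to
rank-based inverse-normal scores). Continuous exposures are log10-transformed
— with a uniform offset equal to the smallest nonzero observed value whenever
zeros are present — then survey-weighted standardized, so a one-unit change
in the transformed exposure is one weighted s.d. on the log scale.
Categorical exposures expand to indicators against the largest (weighted)
category; ordinal exposures pass through as numeric rank codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import weighted_moments

__all__ = [
    "TransformError",
    "TransformMeta",
    "scale_phenotype",
    "inverse_normal",
    "transform_exposure",
]


class TransformError(ValueError):
    pass


@dataclass
class TransformMeta:
    """Record of the transform actually applied, for exact reproduction."""

    kind: str
    zero_offset: float | None = None
    center: float | None = None
    scale: float | None = None
    reference: str | None = None
    levels: list[str] | None = None


def _standardize(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean, sd = weighted_moments(x, w)
    if sd <= 0 or not np.isfinite(sd):
        raise TransformError("cannot standardize a constant column")
    return (x - mean) / sd, mean, sd


def inverse_normal(y) -> np.ndarray:
    """Blom rank-based inverse normal scores, ties mid-ranked."""
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(y, method="average")
    n = len(y)
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 1.0 / 4.0))


def scale_phenotype(y, weights, method: str = "standardize"):
    """Scale a quantitative phenotype.

    ``standardize``: survey-weighted mean 0 and s.d. 1. ``inverse-normal``:
    Blom scores (weights ignored for ranking, as is conventional).
    Returns ``(y', TransformMeta)``.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y[np.isfinite(y)])) < 2:
        raise TransformError("phenotype has fewer than 2 distinct values")
    if method == "standardize":
        w = np.asarray(weights, dtype=float)
        out, mean, sd = _standardize(y, w)
        return out, TransformMeta("standardize", center=mean, scale=sd)
    if method in ("inverse-normal", "inverse_normal"):
        return inverse_normal(y), TransformMeta("inverse-normal")
    raise TransformError(f"unknown phenotype scaling method {method!r}")


def transform_exposure(
    e,
    vartype: str,
    weights,
    zero_offset: float | None = None,
    reference: str | None = None,
    name: str = "exposure",
):
    """Transform one exposure column for fitting.

    Parameters
    ----------
    e
        Raw exposure values (after any limit-of-detection substitution).
    vartype
        ``continuous`` | ``categorical`` | ``ordinal``.
    zero_offset
        Offset ``c`` for the log10 transform of continuous exposures. When
        ``None`` it is computed from ``e`` as the smallest nonzero value;
        pass the pooled-sample value to keep the transform identical across
        waves. The offset is added to every value, and only applied when
        zeros are present.
    reference
        Reference level for categorical exposures; defaults to the largest
        weighted category (ties broken lexicographically).

    Returns
    -------
    (transformed, meta)
        ``transformed`` is a Series (continuous/ordinal) or DataFrame of
        indicator columns (categorical); ``meta`` is a :class:`TransformMeta`.
    """
    w = np.asarray(weights, dtype=float)
    if vartype == "continuous":
        x = np.asarray(e, dtype=float)
        if np.any(x < 0):
            raise TransformError(f"{name}: negative values, log10 undefined")
        has_zero = bool(np.any(x == 0))
        if zero_offset is None:
            nonzero = x[x > 0]
            if nonzero.size == 0:
                raise TransformError(f"{name}: all values zero")
            zero_offset = float(nonzero.min())
        c = float(zero_offset) if has_zero else 0.0
        if has_zero and c <= 0:
            raise TransformError(f"{name}: zero offset must be positive")
        logged = np.log10(x + c)
        out, mean, sd = _standardize(logged, w)
        idx = e.index if isinstance(e, pd.Series) else None
        return (
            pd.Series(out, index=idx, name=name),
            TransformMeta("log10-standardize", zero_offset=c if has_zero else None,
                          center=mean, scale=sd),
        )

    if vartype == "categorical":
        s = pd.Series(e).astype(str)
        totals = pd.Series(w, index=s.index).groupby(s).sum()
        if len(totals) < 2:
            raise TransformError(f"{name}: categorical exposure has a single level")
        if reference is None:
            # largest weighted category; lexicographic tie-break
            reference = totals.sort_index().sort_values(
                ascending=False, kind="stable"
            ).index[0]
        elif reference not in totals.index:
            raise TransformError(f"{name}: reference level {reference!r} not observed")
        levels = [lv for lv in sorted(totals.index) if lv != reference]
        cols = {f"{name}[{lv}]": (s == lv).astype(float) for lv in levels}
        return (
            pd.DataFrame(cols, index=s.index),
            TransformMeta("indicator", reference=str(reference),
                          levels=[str(reference)] + levels),
        )

    if vartype == "ordinal":
        idx = e.index if isinstance(e, pd.Series) else None
        return (
            pd.Series(np.asarray(e, dtype=float), index=idx, name=name),
            TransformMeta("ordinal"),
        )

    raise TransformError(f"unknown exposure vartype {vartype!r}")
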