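"""Exposure-correlation globes and shared associational architecture.

The exposure-exposure "globe" is an undirected graph whose nodes are
exposures and whose edges carry the demographic-adjusted partial correlation
between the transformed exposures, drawn only when |r| exceeds a threshold
(0.25 by default). Partial correlations residualize both exposures on age,
age-squared, income-to-poverty ratio, education and ethnicity via
survey-weighted least squares and correlate the weighted residuals.

Shared associational architecture compares two exposures (or two
phenotypes) by the Pearson correlation of their association-coefficient
vectors across the opposite axis of the atlas.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignError
from .exwas import build_covariate_matrix
from .transforms import transform_exposure

__all__ = [
    "GLOBE_COVARIATES",
    "partial_correlation",
    "exposure_correlations",
    "build_globe",
    "shared_architecture",
    "ArchitectureSimilarity",
]

GLOBE_COVARIATES = ("age", "age2", "income", "education", "ethnicity")


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    mx, my = (w * x).sum() / sw, (w * y).sum() / sw
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def partial_correlation(frame: pd.DataFrame, e1: str, e2: str,
                        covariates=GLOBE_COVARIATES, weighted: bool = True,
                        min_n: int = 30) -> tuple[float, float, int]:
    """Survey-weighted partial correlation between two transformed exposures.

    ``frame`` must carry both exposure columns (already transformed), the
    covariate columns, and a ``weight`` column. Returns ``(r, p, n)`` with a
    t-based p on n - #covariates - 2 df; ``r`` is NaN (flagged undefined)
    when a residual is constant.
    """
    cols = [e1, e2, *{c for t in covariates for c in ([ "age" ] if t in ("age", "age2") else [t])}]
    sub = frame.dropna(subset=[c for c in dict.fromkeys(cols)])
    n = len(sub)
    if n < min_n:
        raise DesignError(f"pairwise-complete n = {n} below minimum {min_n}")
    w = sub["weight"].to_numpy() if weighted else np.ones(n)
    X = build_covariate_matrix(sub, list(covariates), w)
    Xv = X.to_numpy(dtype=float)
    WX = w[:, None] * Xv
    XtWX = Xv.T @ WX
    def _resid(col):
        yv = sub[col].to_numpy(dtype=float)
        beta = np.linalg.solve(XtWX, Xv.T @ (w * yv))
        return yv - Xv @ beta
    r = _weighted_corr(_resid(e1), _resid(e2), w)
    if not np.isfinite(r):
        return np.nan, np.nan, n
    df = n - len(covariates) - 2
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p), n


def exposure_correlations(data, exposures=None, covariates=GLOBE_COVARIATES,
                          weighted: bool = True, min_n: int = 30
                          ) -> pd.DataFrame:
    """All pairwise partial correlations among continuous exposures.

    Assembles each exposure pair on its pairwise-complete sample (using the
    first exposure's panel weight harmonization) and returns records with
    columns ``e1, e2, r, p, n``.
    """
    cat = data.catalog
    if exposures is None:
        exposures = [e for e in cat.exposures if cat[e].vartype == "continuous"]
    raw_cov = tuple(dict.fromkeys(
        "age" if t in ("age", "age2") else t for t in covariates
    ))
    rows = []
    for i, a in enumerate(exposures):
        for b in exposures[i + 1:]:
            frame = data.assemble_exposures(a, b, covariates=raw_cov)
            if frame.empty or len(frame) < min_n:
                continue
            w = frame["weight"].to_numpy()
            fa, _ = transform_exposure(frame[a], "continuous", w, name=a)
            fb, _ = transform_exposure(frame[b], "continuous", w, name=b)
            frame = frame.copy()
            frame[a], frame[b] = fa, fb
            r, p, n = partial_correlation(frame, a, b, covariates=covariates,
                                          weighted=weighted, min_n=min_n)
            rows.append(dict(e1=a, e2=b, r=r, p=p, n=n))
    return pd.DataFrame(rows, columns=["e1", "e2", "r", "p", "n"])


def build_globe(correlations: pd.DataFrame, threshold: float = 0.25,
                keep_isolates: bool = False, categories: dict | None = None
                ) -> nx.Graph:
    """Exposure globe: edges where |partial r| exceeds the threshold.

    Nodes carry a ``category`` attribute when a mapping is supplied;
    isolated nodes are dropped unless ``keep_isolates``. Node and edge
    insertion order is deterministic (sorted).
    """
    g = nx.Graph(threshold=threshold)
    recs = correlations.sort_values(["e1", "e2"], kind="stable")
    if keep_isolates:
        for node in sorted(set(recs["e1"]) | set(recs["e2"])):
            g.add_node(node)
    for rec in recs.itertuples(index=False):
        if rec.e1 == rec.e2:
            continue
        if np.isfinite(rec.r) and abs(rec.r) > threshold:
            g.add_edge(rec.e1, rec.e2, r=float(rec.r),
                       p=float(rec.p), n=int(rec.n))
    if categories:
        for node in g.nodes:
            g.nodes[node]["category"] = categories.get(node, "")
    return g


def export_globe(graph: nx.Graph, path_graphml=None, path_edgelist=None) -> None:
    if path_graphml is not None:
        nx.write_graphml(graph, path_graphml)
    if path_edgelist is not None:
        rows = [dict(e1=u, e2=v, **d) for u, v, d in graph.edges(data=True)]
        pd.DataFrame(rows).to_csv(path_edgelist, index=False)


@dataclass
class ArchitectureSimilarity:
    a: str
    b: str
    r: float
    n_shared: int
    defined: bool


def shared_architecture(atlas: pd.DataFrame, a: str, b: str,
                        axis: str = "exposure",
                        beta_col: str = "estimate_uwls"
                        ) -> ArchitectureSimilarity:
    """Correlation of two entities' association vectors across the atlas.

    For ``axis="exposure"`` the vectors are the coefficients of exposures
    ``a`` and ``b`` across all shared phenotypes (and vice versa for
    ``axis="phenotype"``). Pairwise-complete; flagged undefined below 3
    shared cells.
    """
    if axis == "exposure":
        key, other = "evarname", "pvarname"
    elif axis == "phenotype":
        key, other = "pvarname", "evarname"
    else:
        raise ValueError("axis must be 'exposure' or 'phenotype'")
    va = atlas[atlas[key] == a].set_index(other)[beta_col]
    vb = atlas[atlas[key] == b].set_index(other)[beta_col]
    joined = pd.concat([va, vb], axis=1, keys=["a", "b"], join="inner").dropna()
    n = len(joined)
    if n < 3:
        return ArchitectureSimilarity(a, b, np.nan, n, False)
    r = float(np.corrcoef(joined["a"], joined["b"])[0, 1])
    return ArchitectureSimilarity(a, b, r, n, True)
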