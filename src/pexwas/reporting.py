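"""Descriptive summaries over the association atlas.

All summaries consume the atlas records alone: tier counts per category,
replication tables stratified by the number of contributing waves,
R-squared distributions, the effect of adjustment (per-scenario coefficient
differences with sign-flip accounting among top-tier findings), and
measurement concordance between duplicate measurements of one exposure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "replication_rate",
    "replication_table",
    "tier_counts",
    "r2_distribution",
    "adjustment_difference",
    "measurement_concordance",
]


def replication_rate(replicated_flags) -> float:
    """Percent of associations replicated (nominal p < 0.05 in >= 2 waves)."""
    flags = np.asarray(replicated_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no associations")
    return 100.0 * flags.sum() / flags.size


def replication_table(atlas: pd.DataFrame) -> pd.DataFrame:
    """Counts of associations by k and by number of nominally significant
    waves; rows at each k sum to the number of pairs assessed in k waves."""
    sub = atlas.dropna(subset=["k_uwls", "model_concordance"])
    out = (
        sub.groupby([sub["k_uwls"].astype(int),
                     sub["model_concordance"].astype(int)])
        .size().rename("n_pairs").reset_index()
    )
    out.columns = ["k", "n_significant_waves", "n_pairs"]
    return out


def tier_counts(atlas: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Nested counts per significance tier (bonferroni subset of fdr)."""
    df = atlas.copy()
    group = [by] if by else []
    rows = []
    for keys, sub in (df.groupby(group) if group else [((), df)]):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n_bonf = int((sub["sig_levels"] == "bonferroni").sum())
        n_fdr = n_bonf + int((sub["sig_levels"] == "fdr").sum())
        rows.append(dict(zip(group, keys)) | dict(
            n_total=len(sub), n_fdr=n_fdr, n_bonferroni=n_bonf))
    return pd.DataFrame(rows)


def r2_distribution(atlas: pd.DataFrame, col: str = "rsq_adjusted_base_diff",
                    by: str | None = None) -> pd.DataFrame:
    """Median, IQR and 5th-95th percentiles of exposure R-squared."""
    group = [by] if by else []
    rows = []
    df = atlas.dropna(subset=[col])
    for keys, sub in (df.groupby(group) if group else [((), df)]):
        keys = keys if isinstance(keys, tuple) else (keys,)
        q = np.percentile(sub[col], [5, 25, 50, 75, 95])
        rows.append(dict(zip(group, keys)) | dict(
            n=len(sub), p5=q[0], q1=q[1], median=q[2], q3=q[3], p95=q[4]))
    return pd.DataFrame(rows)


def adjustment_difference(atlas: pd.DataFrame, scenario_a: int,
                          scenario_b: int, beta_col: str = "estimate_uwls",
                          flag_tier: str = "bonferroni"):
    """Per-pair coefficient difference between two adjustment scenarios.

    Returns ``(table, mean, sd)`` where the table holds, per shared pair,
    beta_a - beta_b and a sign-flip flag. Sign flips are flagged only among
    pairs in the requested significance tier of scenario ``a``.
    """
    cols = ["pvarname", "evarname", "term", beta_col]
    a = atlas[atlas["model_number"] == scenario_a][cols + ["sig_levels"]]
    b = atlas[atlas["model_number"] == scenario_b][cols]
    merged = a.merge(b, on=["pvarname", "evarname", "term"],
                     suffixes=("_a", "_b")).dropna(
        subset=[f"{beta_col}_a", f"{beta_col}_b"])
    if merged.empty:
        raise ValueError("no shared pairs between the two scenarios")
    merged["difference"] = merged[f"{beta_col}_a"] - merged[f"{beta_col}_b"]
    in_tier = merged["sig_levels"] == flag_tier
    if flag_tier == "fdr":
        in_tier = merged["sig_levels"].isin(["fdr", "bonferroni"])
    merged["sign_flip"] = in_tier & (
        np.sign(merged[f"{beta_col}_a"]) * np.sign(merged[f"{beta_col}_b"]) < 0
    )
    return merged, float(merged["difference"].mean()), float(merged["difference"].std(ddof=1))


def measurement_concordance(atlas: pd.DataFrame, exposure_a: str,
                            exposure_b: str, scenario: int | None = None,
                            beta_col: str = "estimate_uwls"):
    """Correlation of association vectors for two measurements of one
    exposure construct (e.g. day-1 vs day-2 recall, blood vs urine).

    Returns ``(r, n_shared)``; r is NaN (undefined) below 3 shared
    phenotypes.
    """
    df = atlas if scenario is None else atlas[atlas["model_number"] == scenario]
    va = df[df["evarname"] == exposure_a].set_index("pvarname")[beta_col]
    vb = df[df["evarname"] == exposure_b].set_index("pvarname")[beta_col]
    joined = pd.concat([va, vb], axis=1, keys=["a", "b"], join="inner").dropna()
    if len(joined) < 3:
        return np.nan, len(joined)
    return float(np.corrcoef(joined["a"], joined["b"])[0, 1]), len(joined)
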