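"""Association-atlas persistence and querying.

The atlas is a relational store (SQLite) holding the pooled association
records, the per-wave fits behind them, exposure correlations, poly-model
summaries, the variable catalog, and run metadata (seed, configuration
hash, software version) sufficient to re-execute a run. Records are keyed
on (pvarname, evarname, model_number, term) and upserted idempotently.

CSV export renames the internal sanitized columns to the published
dotted-name schema (``estimate.uwls``, ``i.squared.uwls``, ...).
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AtlasError", "AtlasStore", "CSV_COLUMN_MAP"]

CSV_COLUMN_MAP = {
    "estimate_uwls": "estimate.uwls",
    "std_error_uwls": "std.error.uwls",
    "p_value_uwls": "p.value.uwls",
    "statistic_uwls": "statistic.uwls",
    "q_uwls": "Q.uwls",
    "h_squared_uwls": "h.squared.uwls",
    "i_squared_uwls": "i.squared.uwls",
    "k_uwls": "k.uwls",
}

_KEY = ["pvarname", "evarname", "model_number", "term"]


class AtlasError(ValueError):
    pass


def _validate_associations(df: pd.DataFrame) -> None:
    for col in ("pvarname", "evarname", "model_number"):
        if col not in df.columns:
            raise AtlasError(f"associations table missing column {col!r}")
    if "i_squared_uwls" in df.columns:
        i2 = df["i_squared_uwls"].to_numpy(dtype=float)
        bad = np.where(np.isfinite(i2) & ((i2 < 0) | (i2 > 100)))[0]
        if bad.size:
            raise AtlasError(f"I^2 outside [0, 100] at row index {bad[0]}")
    for col in ("p_value_uwls", "p_pooled", "pval_BY", "pvalue_bonferroni"):
        if col in df.columns:
            p = df[col].to_numpy(dtype=float)
            bad = np.where(np.isfinite(p) & ((p < 0) | (p > 1)))[0]
            if bad.size:
                raise AtlasError(f"{col} outside [0, 1] at row index {bad[0]}")
    if {"model_concordance", "model_concordance_1_2", "k_uwls"} <= set(df.columns):
        c = df["model_concordance"].to_numpy(dtype=float)
        s = df["model_concordance_1_2"].to_numpy(dtype=float)
        k = df["k_uwls"].to_numpy(dtype=float)
        ok = np.isfinite(c) & np.isfinite(s) & np.isfinite(k)
        bad = np.where(ok & ~((0 <= s) & (s <= c) & (c <= k)))[0]
        if bad.size:
            raise AtlasError(
                f"concordance counts violate 0 <= sign <= total <= k at row {bad[0]}"
            )


class AtlasStore:
    """SQLite-backed atlas with idempotent keyed upserts."""

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # ------------------------------------------------------------------
    def write_associations(self, records: pd.DataFrame) -> None:
        df = records.copy()
        if "term" not in df.columns:
            df["term"] = df["evarname"]
        _validate_associations(df)
        df = df.drop_duplicates(subset=_KEY, keep="last")
        cur = self.conn
        existing = self._table_df("associations")
        if existing is not None:
            merged = pd.concat([existing, df], ignore_index=True)
            merged = merged.drop_duplicates(subset=_KEY, keep="last")
        else:
            merged = df
        merged.to_sql("associations", cur, if_exists="replace", index=False)
        cur.commit()

    def write_table(self, name: str, df: pd.DataFrame) -> None:
        df.to_sql(name, self.conn, if_exists="replace", index=False)
        self.conn.commit()

    def write_metadata(self, **meta) -> None:
        rows = pd.DataFrame(
            [{"key": k, "value": json.dumps(v)} for k, v in sorted(meta.items())]
        )
        rows.to_sql("run_metadata", self.conn, if_exists="replace", index=False)
        self.conn.commit()

    def read_metadata(self) -> dict:
        df = self._table_df("run_metadata")
        if df is None:
            return {}
        return {k: json.loads(v) for k, v in zip(df["key"], df["value"])}

    # ------------------------------------------------------------------
    def _table_df(self, name: str) -> pd.DataFrame | None:
        try:
            return pd.read_sql_query(f"SELECT * FROM {name}", self.conn)
        except (pd.errors.DatabaseError, sqlite3.OperationalError):
            return None

    def associations(self) -> pd.DataFrame:
        df = self._table_df("associations")
        return df if df is not None else pd.DataFrame()

    def query(self, phenotype=None, exposure=None, scenario=None,
              tier=None) -> pd.DataFrame:
        """Filter associations; stable sort by meta-analytic p-value."""
        df = self.associations()
        if df.empty:
            return df
        known = {"phenotype": "pvarname", "exposure": "evarname",
                 "scenario": "model_number", "tier": "sig_levels"}
        for arg, col in known.items():
            val = {"phenotype": phenotype, "exposure": exposure,
                   "scenario": scenario, "tier": tier}[arg]
            if val is None:
                continue
            if col not in df.columns:
                raise AtlasError(f"unknown column {col!r} in associations table")
            if arg == "tier" and val == "fdr":
                df = df[df[col].isin(["fdr", "bonferroni"])]
            else:
                df = df[df[col] == val]
        sort_col = "p_value_uwls" if "p_value_uwls" in df.columns else None
        if sort_col:
            df = df.sort_values(sort_col, kind="stable", na_position="last")
        return df.reset_index(drop=True)

    # ------------------------------------------------------------------
    def export_csv(self, path) -> None:
        """Export associations with the published dotted column names."""
        df = self.associations().rename(columns=CSV_COLUMN_MAP)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)

    @staticmethod
    def import_csv(path) -> pd.DataFrame:
        inverse = {v: k for k, v in CSV_COLUMN_MAP.items()}
        return pd.read_csv(path).rename(columns=inverse)
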