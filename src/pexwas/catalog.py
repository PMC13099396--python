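"""Variable catalog, harmonization helpers, and eligible-pair selection.

The catalog is the canonical map from an analysis variable (one exposure or
phenotype construct) to its role, type, category, units, per-wave column
aliases, and assay limit of detection (LLOD). Laboratory values flagged as
below the LLOD are substituted by LLOD/sqrt(2), the standard convention for
left-censored assay data, and the censored fraction is tracked per analyte
and wave.

Pair selection enforces the eligibility rule used throughout the pipeline:
a (phenotype, exposure) pair enters the association atlas only if it has at
least ``min_n`` complete-case participants accumulated over at least
``min_waves`` survey waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CatalogError",
    "VariableRecord",
    "Catalog",
    "build_catalog",
    "substitute_llod",
    "select_pairs",
]

_ROLES = {"exposure", "phenotype"}
_VARTYPES = {"continuous", "categorical", "ordinal"}
SQRT2 = float(np.sqrt(2.0))


class CatalogError(ValueError):
    pass


@dataclass
class VariableRecord:
    name: str
    role: str
    vartype: str
    category: str = ""
    subcategory: str = ""
    units: str = ""
    aliases: dict = field(default_factory=dict)   # wave -> column name
    llod: dict = field(default_factory=dict)      # wave -> positive real
    comment_flag_column: str | None = None
    panel: str | None = None                      # subsample panel, None = full sample
    si_factor: float = 1.0

    def __post_init__(self):
        if self.role not in _ROLES:
            raise CatalogError(f"{self.name}: unknown role {self.role!r}")
        if self.vartype not in _VARTYPES:
            raise CatalogError(f"{self.name}: unknown vartype {self.vartype!r}")
        for wave, llod in self.llod.items():
            if not llod > 0:
                raise CatalogError(f"{self.name}: LLOD must be positive (wave {wave})")

    def alias(self, wave) -> str:
        return self.aliases.get(wave, self.name)


class Catalog:
    """Mapping of canonical variable name -> :class:`VariableRecord`."""

    def __init__(self, records: list[VariableRecord]):
        self._records: dict[str, VariableRecord] = {}
        for rec in records:
            self._records[rec.name] = rec

    def __getitem__(self, name: str) -> VariableRecord:
        return self._records[name]

    def __contains__(self, name) -> bool:
        return name in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def by_role(self, role: str) -> list[VariableRecord]:
        return [r for r in self._records.values() if r.role == role]

    @property
    def exposures(self) -> list[str]:
        return [r.name for r in self.by_role("exposure")]

    @property
    def phenotypes(self) -> list[str]:
        return [r.name for r in self.by_role("phenotype")]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self:
            rows.append(
                dict(name=r.name, role=r.role, vartype=r.vartype,
                     category=r.category, subcategory=r.subcategory,
                     units=r.units, panel=r.panel,
                     n_aliases=len(r.aliases) or 1)
            )
        return pd.DataFrame(rows)


def catalog_to_json(catalog: Catalog, path) -> None:
    import json

    rows = []
    for r in catalog:
        rows.append(dict(
            name=r.name, role=r.role, vartype=r.vartype, category=r.category,
            subcategory=r.subcategory, units=r.units,
            aliases={str(k): v for k, v in r.aliases.items()},
            llod={str(k): v for k, v in r.llod.items()},
            comment_flag_column=r.comment_flag_column, panel=r.panel,
            si_factor=r.si_factor,
        ))
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1)


def catalog_from_json(path) -> Catalog:
    import json

    with open(path) as fh:
        rows = json.load(fh)

    def _intkeys(d):
        return {int(k) if str(k).isdigit() else k: v for k, v in d.items()}

    records = []
    for row in rows:
        records.append(VariableRecord(
            name=row["name"], role=row["role"], vartype=row["vartype"],
            category=row.get("category", ""),
            subcategory=row.get("subcategory", ""),
            units=row.get("units", ""),
            aliases=_intkeys(row.get("aliases", {})),
            llod=_intkeys(row.get("llod", {})),
            comment_flag_column=row.get("comment_flag_column"),
            panel=row.get("panel"), si_factor=row.get("si_factor", 1.0),
        ))
    return Catalog(records)


def build_catalog(dictionary_rows) -> Catalog:
    """Build the canonical catalog from per-wave dictionary rows.

    Rows referring to the same canonical ``name`` across waves are merged
    into a single record; their per-wave ``alias`` and ``llod`` entries are
    collected. Conflicting ``vartype`` or ``role`` declarations across waves
    raise :class:`CatalogError`.
    """
    merged: dict[str, VariableRecord] = {}
    rows = list(dictionary_rows)
    if not rows:
        raise CatalogError("empty dictionary")
    for row in rows:
        row = dict(row)
        name = row["name"]
        wave = row.pop("wave", None)
        alias = row.pop("alias", None)
        llod = row.pop("llod", None)
        if name in merged:
            rec = merged[name]
            for attr in ("role", "vartype"):
                if attr in row and row[attr] != getattr(rec, attr):
                    raise CatalogError(
                        f"{name}: conflicting {attr} across waves "
                        f"({getattr(rec, attr)!r} vs {row[attr]!r})"
                    )
        else:
            rec = VariableRecord(
                name=name,
                role=row["role"],
                vartype=row["vartype"],
                category=row.get("category", ""),
                subcategory=row.get("subcategory", ""),
                units=row.get("units", ""),
                comment_flag_column=row.get("comment_flag_column"),
                panel=row.get("panel"),
                si_factor=row.get("si_factor", 1.0),
            )
            merged[name] = rec
        if wave is not None and alias is not None:
            rec.aliases[wave] = alias
        if wave is not None and llod is not None:
            if not llod > 0:
                raise CatalogError(f"{name}: LLOD must be positive (wave {wave})")
            rec.llod[wave] = float(llod)
    return Catalog(list(merged.values()))


def substitute_llod(values, llod, below_flags) -> tuple[pd.Series, float]:
    """Replace below-detection values by LLOD/sqrt(2).

    Returns the substituted values and the proportion of non-missing values
    that were below the limit of detection.
    """
    v = pd.Series(values, dtype=float).copy()
    flags = np.asarray(below_flags, dtype=bool)
    if len(flags) != len(v):
        raise CatalogError("flags must align with values")
    if flags.any():
        if llod is None or not llod > 0:
            raise CatalogError("flagged values present but LLOD missing or non-positive")
        v.iloc[np.where(flags)[0]] = float(llod) / SQRT2
    n_obs = int(v.notna().sum())
    prop = float(flags[v.notna().to_numpy()].sum() / n_obs) if n_obs else float("nan")
    return v, prop


@dataclass
class PairManifest:
    """Eligible (phenotype, exposure) pairs with per-wave sample sizes."""

    table: pd.DataFrame  # phenotype, exposure, waves_available, n_per_wave, n_total

    def __len__(self) -> int:
        return len(self.table)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["phenotype"], self.table["exposure"]))

    def row(self, phenotype: str, exposure: str) -> pd.Series:
        t = self.table
        m = (t["phenotype"] == phenotype) & (t["exposure"] == exposure)
        return t.loc[m].iloc[0]


def select_pairs(catalog: Catalog, data, min_n: int = 500, min_waves: int = 2,
                 covariates: tuple = ()) -> PairManifest:
    """Select eligible pairs from a multi-wave dataset.

    Eligibility counts pairwise-complete participants — phenotype, exposure
    and all requested covariates observed — and requires ``n_total >= min_n``
    accumulated over at least ``min_waves`` waves with any complete cases.
    """
    if len(catalog) == 0:
        raise CatalogError("empty catalog")
    rows = []
    for pheno in catalog.phenotypes:
        for expo in catalog.exposures:
            n_per_wave = data.pair_counts(pheno, expo, covariates=covariates)
            waves = [w for w, n in n_per_wave.items() if n > 0]
            n_total = int(sum(n_per_wave.values()))
            if n_total >= min_n and len(waves) >= min_waves:
                rows.append(
                    dict(phenotype=pheno, exposure=expo,
                         waves_available=waves,
                         n_per_wave={w: int(n) for w, n in n_per_wave.items() if n > 0},
                         n_total=n_total)
                )
    cols = ["phenotype", "exposure", "waves_available", "n_per_wave", "n_total"]
    return PairManifest(pd.DataFrame(rows, columns=cols))
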