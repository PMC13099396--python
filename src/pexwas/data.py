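"""Multi-wave survey data container and pair assembly.

A :class:`MultiWaveData` holds, per survey wave, the component tables the
pipeline consumes — demographics (with stratum/PSU/full-sample weight),
phenotypes, and one exposure table per subsample panel — together with the
variable catalog. Assembling a (phenotype, exposure) pair merges the three
or more component tables on participant id, substitutes below-LLOD values,
harmonizes the analysis weight (the weight of the smallest subsample
involved, divided by the number of waves combined), and returns one analysis
frame ready for the design engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import Catalog, substitute_llod
from .design import WeightComponent, harmonize_weights

__all__ = ["MultiWaveData", "DEMOGRAPHIC_COLUMNS"]

DEMOGRAPHIC_COLUMNS = ("age", "sex", "ethnicity", "education", "income")
_DESIGN_COLUMNS = ("stratum", "psu", "wt_full")


@dataclass
class MultiWaveData:
    """Per-wave component tables plus the variable catalog.

    ``tables[wave][component]`` is a DataFrame indexed by participant id.
    Components are ``"demographics"``, ``"phenotypes"`` and
    ``"exposures_<panel>"``; each exposure panel table carries its subsample
    weight column ``wt_<panel>`` (absent for panels measured on the full
    sample).
    """

    tables: dict = field(default_factory=dict)
    catalog: Catalog | None = None
    panel_fractions: dict = field(default_factory=dict)

    @property
    def waves(self) -> list:
        return sorted(self.tables.keys())

    def _exposure_component(self, exposure: str) -> str:
        panel = self.catalog[exposure].panel
        return f"exposures_{panel}" if panel else "exposures_core"

    def _merge_wave(self, wave, phenotype: str, exposure: str) -> pd.DataFrame | None:
        comps = self.tables.get(wave, {})
        demo = comps.get("demographics")
        pheno_tab = comps.get("phenotypes")
        expo_comp = self._exposure_component(exposure)
        expo_tab = comps.get(expo_comp)
        if demo is None or pheno_tab is None or expo_tab is None:
            return None
        prec = self.catalog[phenotype]
        erec = self.catalog[exposure]
        pcol = prec.alias(wave)
        ecol = erec.alias(wave)
        if pcol not in pheno_tab.columns or ecol not in expo_tab.columns:
            return None

        merged = demo.copy()
        merged[phenotype] = pheno_tab[pcol].reindex(merged.index) * prec.si_factor

        evals = expo_tab[ecol].reindex(merged.index)
        flag_col = f"{ecol}_llod_flag"
        if flag_col in expo_tab.columns and erec.llod.get(wave) is not None:
            flags = (expo_tab[flag_col].reindex(merged.index)
                     .astype(float).fillna(0.0).astype(bool))
            evals, _ = substitute_llod(evals, erec.llod[wave], flags)
        if erec.vartype == "continuous" and erec.si_factor != 1.0:
            evals = evals * erec.si_factor
        merged[exposure] = evals

        components = [WeightComponent("full", merged["wt_full"])]
        wcol = f"wt_{erec.panel}" if erec.panel else None
        if wcol and wcol in expo_tab.columns:
            components.append(
                WeightComponent(erec.panel, expo_tab[wcol].reindex(merged.index))
            )
        merged["_wave_weight"] = harmonize_weights(components)
        merged["wave"] = wave
        return merged

    def assemble_pair(
        self,
        phenotype: str,
        exposure: str,
        covariates: tuple = DEMOGRAPHIC_COLUMNS,
        waves: list | None = None,
    ) -> pd.DataFrame:
        """Merged complete-case analysis frame for one pair.

        The returned frame has columns ``stratum``, ``psu``, ``weight`` (the
        harmonized analysis weight, already divided by the number of waves
        combined), ``wave``, the requested covariates, and the raw
        (LLOD-substituted, SI-converted) phenotype and exposure columns.
        """
        waves = list(waves) if waves is not None else self.waves
        parts = []
        for w in waves:
            m = self._merge_wave(w, phenotype, exposure)
            if m is None:
                continue
            need = [phenotype, exposure, "_wave_weight", *covariates]
            m = m.dropna(subset=[c for c in need if c in m.columns])
            if len(m):
                parts.append(m)
        if not parts:
            return pd.DataFrame()
        out = pd.concat(parts, axis=0)
        k = out["wave"].nunique()
        out["weight"] = out["_wave_weight"] / k
        keep = [*_DESIGN_COLUMNS[:2], "weight", "wave", *covariates,
                phenotype, exposure]
        return out[[c for c in dict.fromkeys(keep)]]

    def assemble_exposures(self, e1: str, e2: str,
                           covariates: tuple = DEMOGRAPHIC_COLUMNS
                           ) -> pd.DataFrame:
        """Pairwise-complete frame for two exposures (correlation globes).

        Merges demographics with both exposures' panel tables per wave; the
        analysis weight is the smallest-subsample weight among the
        components involved, divided by the number of waves combined.
        """
        parts = []
        for wave in self.waves:
            comps = self.tables.get(wave, {})
            demo = comps.get("demographics")
            if demo is None:
                continue
            merged = demo.copy()
            weight_comps = [WeightComponent("full", merged["wt_full"])]
            ok = True
            for e in (e1, e2):
                erec = self.catalog[e]
                tab = comps.get(self._exposure_component(e))
                ecol = erec.alias(wave)
                if tab is None or ecol not in tab.columns:
                    ok = False
                    break
                evals = tab[ecol].reindex(merged.index)
                flag_col = f"{ecol}_llod_flag"
                if flag_col in tab.columns and erec.llod.get(wave) is not None:
                    flags = (tab[flag_col].reindex(merged.index)
                             .astype(float).fillna(0.0).astype(bool))
                    evals, _ = substitute_llod(evals, erec.llod[wave], flags)
                if erec.vartype == "continuous" and erec.si_factor != 1.0:
                    evals = evals * erec.si_factor
                merged[e] = evals
                wcol = f"wt_{erec.panel}" if erec.panel else None
                if wcol and wcol in tab.columns:
                    weight_comps.append(
                        WeightComponent(erec.panel, tab[wcol].reindex(merged.index))
                    )
            if not ok:
                continue
            merged["_wave_weight"] = harmonize_weights(weight_comps)
            merged["wave"] = wave
            need = [e1, e2, "_wave_weight", *covariates]
            merged = merged.dropna(subset=[c for c in need if c in merged.columns])
            if len(merged):
                parts.append(merged)
        if not parts:
            return pd.DataFrame()
        out = pd.concat(parts, axis=0)
        out["weight"] = out["_wave_weight"] / out["wave"].nunique()
        keep = ["stratum", "psu", "weight", "wave", *covariates, e1, e2]
        return out[[c for c in dict.fromkeys(keep)]]

    def pair_counts(self, phenotype: str, exposure: str,
                    covariates: tuple = DEMOGRAPHIC_COLUMNS) -> dict:
        """Complete-case count per wave for one pair."""
        counts = {}
        for w in self.waves:
            m = self._merge_wave(w, phenotype, exposure)
            if m is None:
                counts[w] = 0
                continue
            need = [phenotype, exposure, "_wave_weight",
                    *[c for c in covariates if c in m.columns]]
            counts[w] = int(m.dropna(subset=need).shape[0])
        return counts

    # ------------------------------------------------------------------
    def write_csv(self, outdir) -> None:
        """Write one CSV per wave and component, plus the catalog as JSON."""
        import json

        from .catalog import catalog_to_json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for wave, comps in self.tables.items():
            for comp, tab in comps.items():
                tab.to_csv(outdir / f"wave{wave}_{comp}.csv", index_label="pid")
        if self.catalog is not None:
            catalog_to_json(self.catalog, outdir / "catalog.json")
        with open(outdir / "panels.json", "w") as fh:
            json.dump(self.panel_fractions, fh)

    @classmethod
    def read_csv(cls, indir) -> "MultiWaveData":
        """Load a dataset previously written by :meth:`write_csv`."""
        import json
        import re

        from .catalog import catalog_from_json

        indir = Path(indir)
        tables: dict = {}
        for f in sorted(indir.glob("wave*_*.csv")):
            m = re.match(r"wave(\d+)_(.+)\.csv", f.name)
            if not m:
                continue
            wave, comp = int(m.group(1)), m.group(2)
            tab = pd.read_csv(f, index_col="pid")
            tables.setdefault(wave, {})[comp] = tab
        catalog = None
        if (indir / "catalog.json").exists():
            catalog = catalog_from_json(indir / "catalog.json")
        fractions = {}
        if (indir / "panels.json").exists():
            with open(indir / "panels.json") as fh:
                fractions = json.load(fh)
        return cls(tables=tables, catalog=catalog, panel_fractions=fractions)
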