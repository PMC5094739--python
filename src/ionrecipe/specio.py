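"""Reading and writing target specs, recipes and reports.

Target specs are accepted as YAML::

    targets: {NO3-: 4.7, NH4+: 0.4, PO4_total: 0.005}
    senses: {NO3-: "="}            # optional, per-ion =, <=, >=
    free: [OH-, H+, EDTA 4-]       # optional
    forced_salts: {NH4NO3: 18.25}  # optional, mM

or as CSV with columns ``ion,target_mM[,sense][,free]`` (free rows list a
species with an empty target), optionally followed by rows
``forced:<salt>,<mM>``.

Recipes are written as CSV ``salt,mM,mg_per_l`` (mg/L to 4 decimals) plus a
JSON mirror carrying full precision and solver metadata.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd
import yaml

from .catalog import SaltCatalog
from .solver import Recipe, TargetSpec, to_mg_per_l

__all__ = ["read_targets", "write_recipe_csv", "write_recipe_json"]


def read_targets(path: str | Path) -> TargetSpec:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return TargetSpec(
            targets={str(k): float(v) for k, v in (doc.get("targets") or {}).items()},
            senses={str(k): str(v) for k, v in (doc.get("senses") or {}).items()},
            free=frozenset(doc.get("free") or ()),
            forced_salts={str(k): float(v)
                          for k, v in (doc.get("forced_salts") or {}).items()},
        )
    targets: dict[str, float] = {}
    senses: dict[str, str] = {}
    free: set[str] = set()
    forced: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(r for r in fh if not r.startswith("#")):
            ion = row["ion"].strip()
            if ion.startswith("forced:"):
                forced[ion.removeprefix("forced:").strip()] = float(row["target_mM"])
                continue
            if str(row.get("free", "")).strip().lower() in ("1", "true", "yes"):
                free.add(ion)
                continue
            targets[ion] = float(row["target_mM"])
            sense = (row.get("sense") or "").strip()
            if sense:
                senses[ion] = sense
    return TargetSpec(targets=targets, senses=senses, free=frozenset(free),
                      forced_salts=forced)


def write_recipe_csv(recipe: Recipe, catalog: SaltCatalog, path: str | Path,
                     include_zero: bool = False) -> None:
    mg = to_mg_per_l(recipe.amounts, catalog)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["salt", "mM", "mg_per_l"])
        for name, mM in recipe.amounts.items():
            if mM > 1e-10 or include_zero:
                writer.writerow([name, repr(mM), f"{mg[name]:.4f}"])


def write_recipe_json(recipe: Recipe, catalog: SaltCatalog, path: str | Path) -> None:
    doc = {
        "status": recipe.status,
        "objective_mM": recipe.objective,
        "max_residual": recipe.max_residual,
        "amounts_mM": recipe.nonzero(),
        "amounts_mg_per_l": to_mg_per_l(recipe.nonzero(), catalog),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_recipe_csv(path: str | Path, units: str = "mM") -> dict[str, float]:
    """Read a recipe table; uses the ``mM`` or ``mg_per_l`` column per ``units``."""
    df = pd.read_csv(path, comment="#")
    col = "mM" if units == "mM" else "mg_per_l"
    if col not in df.columns:
        # fall back to two-column salt,value tables
        col = [c for c in df.columns if c != "salt"][0]
    return dict(zip(df["salt"], df[col].astype(float)))
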