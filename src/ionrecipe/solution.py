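"""Deconstruct salt mixtures into ion compositions and compare to targets.

Deconstruction is the inverse view of the recipe solver: dissolving X_j mM
of each salt yields ion i at sum_j a_ij X_j mM.  It turns any published
recipe — including treatments of salt-based experiments — into the ion
levels actually applied, which is how ion confounding in such experiments
is made visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .catalog import CatalogError, IonRegistry, SaltCatalog
from .solver import Recipe, from_mg_per_l

__all__ = [
    "IonComposition",
    "charge_balance",
    "deconstruct",
    "format_deviation",
    "percent_deviation",
]


@dataclass
class IonComposition:
    """Tracked species concentrations (mM) of a dissolved mixture."""

    concentrations: dict[str, float]

    def __getitem__(self, symbol: str) -> float:
        return self.concentrations.get(symbol, 0.0)

    def total(self, species: Iterable[str] | None = None) -> float:
        """Sum of concentrations, optionally over an explicit species subset.

        Each tracked species counts once (ions, not ion pairs); reports
        should state the subset used.
        """
        if species is None:
            return sum(self.concentrations.values())
        return sum(self.concentrations.get(sym, 0.0) for sym in species)

    def pooled(self, registry: IonRegistry) -> dict[str, float]:
        """Concentrations with registry pools summed over their members.

        Pool totals replace member entries (only when a member is present);
        unpooled species pass through unchanged.
        """
        out: dict[str, float] = {}
        pooled_members: set[str] = set()
        for pool, members in registry.pools.items():
            present = [m for m in members if m in self.concentrations]
            if present:
                out[pool] = sum(self.concentrations[m] for m in present)
                pooled_members |= set(members)
        for sym, val in self.concentrations.items():
            if sym not in pooled_members:
                out[sym] = val
        return out

    def resolve(self, key: str, registry: IonRegistry) -> float:
        """Concentration of a species symbol or pooled group."""
        if key in registry.pools:
            return sum(self.concentrations.get(m, 0.0) for m in registry.pools[key])
        return self.concentrations.get(key, 0.0)


def deconstruct(recipe: Recipe | Mapping[str, float], catalog: SaltCatalog,
                units: str = "mM") -> IonComposition:
    """Ion composition (mM) delivered by a recipe given in mM or mg/L.

    Deconstruction is linear in the recipe, and for any recipe of neutral
    salts the resulting composition is exactly electroneutral.
    """
    amounts = dict(recipe.amounts) if isinstance(recipe, Recipe) else dict(recipe)
    if units == "mg_per_l":
        amounts = from_mg_per_l(amounts, catalog)
    elif units != "mM":
        raise ValueError(f"units must be 'mM' or 'mg_per_l', got {units!r}")
    conc: dict[str, float] = {}
    for name, mM in amounts.items():
        salt = catalog[name]  # raises CatalogError for unknown salts
        for sp, count in salt.dissociation.items():
            conc[sp.symbol] = conc.get(sp.symbol, 0.0) + float(count) * float(mM)
    return IonComposition(concentrations=conc)


def percent_deviation(achieved: IonComposition | Mapping[str, float],
                      targets: Mapping[str, float],
                      registry: IonRegistry | None = None) -> dict[str, float | None]:
    """Per-ion 100 * (achieved - target) / target.

    Target keys may be pool names when a registry is given.  A zero target
    with nonzero achieved has no defined relative deviation and maps to
    ``None`` (rendered as "undefined (target 0)" by :func:`format_deviation`);
    a zero target achieved exactly maps to 0.
    """
    if not isinstance(achieved, IonComposition):
        achieved = IonComposition(dict(achieved))
    out: dict[str, float | None] = {}
    for key, target in targets.items():
        value = achieved.resolve(key, registry) if registry else achieved[key]
        if target == 0:
            out[key] = 0.0 if value == 0 else None
        else:
            out[key] = 100.0 * (value - target) / target
    return out


def format_deviation(dev: float | None, integer: bool = True) -> str:
    """Render a deviation in signed display style ("+525", "-47", "0")."""
    if dev is None:
        return "undefined (target 0)"
    if integer:
        # round half away from zero, as conventional for signed percentages
        import math
        rounded = int(math.floor(abs(dev) + 0.5))
        if rounded == 0:
            return "0"
        return f"{'+' if dev > 0 else '-'}{rounded}"
    return f"{dev:+.2f}"


def charge_balance(comp: IonComposition | Mapping[str, float],
                   registry: IonRegistry) -> float:
    """Net charge sum(z_i * c_i) in meq/L; 0 for any neutral-salt recipe."""
    conc = comp.concentrations if isinstance(comp, IonComposition) else comp
    total = 0.0
    for sym, c in conc.items():
        if sym not in registry:
            raise CatalogError(f"species {sym!r} has no registered charge")
        total += registry.charge(sym) * c
    return total
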