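"""Seeded generator of feasible synthetic recipe problems.

Used by property tests and available from the CLI: it samples random
electroneutral salts (cation/anion pairs with stoichiometry fixed by their
charges), draws a random non-negative recipe, and deconstructs it to obtain
a target vector that is feasible by construction.  The generator is a pure
function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import IonRegistry, SaltCatalog, catalog_from_dissociations
from .chem import IonSpecies
from .solution import deconstruct
from .solver import TargetSpec

__all__ = ["SyntheticProblem", "generate_synthetic_problem"]


@dataclass
class SyntheticProblem:
    catalog: SaltCatalog
    targets: TargetSpec
    recipe: dict[str, float]   # a known feasible recipe (mM), not necessarily optimal


def generate_synthetic_problem(seed: int, n_salts: int = 6,
                               n_ions: int = 5) -> SyntheticProblem:
    """Generate a random feasible recipe problem, reproducible by seed.

    Ions get charges in ±{1, 2, 3} (at least one cation and one anion);
    each salt pairs one cation C (charge z+) with one anion A (charge z-)
    as C_{|z-|/g} A_{z+/g}, g = gcd, so every salt column is neutral.
    Targets are the deconstruction of a random recipe in which each salt is
    present with probability 0.7 at a Uniform(0, 10) mM amount.
    """
    if n_salts < 1 or n_ions < 1:
        raise ValueError("n_salts and n_ions must be >= 1")
    n_ions = max(n_ions, 2)  # need a cation and an anion for neutral salts
    rng = np.random.default_rng(seed)

    registry = IonRegistry()
    n_cations = int(rng.integers(1, n_ions))
    charges = [int(rng.integers(1, 4)) for _ in range(n_cations)] + \
              [-int(rng.integers(1, 4)) for _ in range(n_ions - n_cations)]
    symbols = []
    for i, z in enumerate(charges):
        symbol = f"C{i}^{z:+d}" if z > 0 else f"A{i}^{z:+d}"
        registry.add(IonSpecies.make(symbol, z))
        symbols.append(symbol)
    cations = [s for s, z in zip(symbols, charges) if z > 0]
    anions = [s for s, z in zip(symbols, charges) if z < 0]

    entries: dict[str, dict[str, int]] = {}
    for k in range(n_salts):
        cat = cations[int(rng.integers(len(cations)))]
        an = anions[int(rng.integers(len(anions)))]
        zc, za = registry.charge(cat), -registry.charge(an)
        g = math.gcd(zc, za)
        entries[f"S{k}({cat})({an})"] = {cat: za // g, an: zc // g}
    catalog = catalog_from_dissociations(entries, registry)

    amounts = {name: float(rng.uniform(0, 10)) if rng.random() < 0.7 else 0.0
               for name in catalog.names}
    comp = deconstruct(amounts, catalog)
    targets = TargetSpec(targets=dict(comp.concentrations))
    return SyntheticProblem(catalog=catalog, targets=targets, recipe=amounts)
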