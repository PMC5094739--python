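"""Chemical formula parsing, molar masses, and salt stoichiometry.

A :class:`Salt` is a neutral compound that dissolves into a fixed set of
tracked ion species (its *dissociation map*); the per-salt map is one column
of the ion-proportionality matrix used by the recipe solver.  Hydrate waters
("CaCl2.2H2O") count toward the molar mass but dissolve as free water, not
as a tracked species.

Atomic weights are an embedded constant table (IUPAC conventional values,
4 decimals) so that mg/L outputs are reproducible bit-for-bit and the
package has no runtime dependency for element data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

__all__ = [
    "ATOMIC_WEIGHTS",
    "ElementComposition",
    "FormulaError",
    "IonSpecies",
    "Salt",
    "merge_compositions",
    "molar_mass",
    "parse_formula",
    "render_formula",
    "validate_salt",
]

#: IUPAC conventional atomic weights, g/mol, rounded to 4 decimals.  Pinned:
#: changing an entry changes every mg/L figure the package prints.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.9984, "Ne": 20.1797,
    "Na": 22.9898, "Mg": 24.305, "Al": 26.9815, "Si": 28.085, "P": 30.9738,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.0983, "Ca": 40.078,
    "Ti": 47.867, "V": 50.9415, "Cr": 51.9961, "Mn": 54.938, "Fe": 55.845,
    "Co": 58.9332, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38, "As": 74.9216,
    "Se": 78.971, "Br": 79.904, "Rb": 85.4678, "Sr": 87.62, "Mo": 95.95,
    "Ag": 107.8682, "Cd": 112.414, "Sn": 118.71, "I": 126.9045,
    "Cs": 132.9055, "Ba": 137.327, "W": 183.84, "Pt": 195.084,
    "Au": 196.9666, "Hg": 200.592, "Pb": 207.2,
}

# element symbol → count (counts are positive integers)
ElementComposition = dict[str, int]


class FormulaError(ValueError):
    """Raised for malformed or unknown chemical formula text."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)|(\d+)")
_HYDRATE_SPLIT = re.compile(r"[.*·]")  # ".", "*", or "·"


def _parse_fragment(text: str) -> ElementComposition:
    """Parse a formula fragment (no hydrate suffix) into element counts."""
    stack: list[ElementComposition] = [{}]
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            stack.append({})
            pos += 1
        elif ch == ")":
            if len(stack) == 1:
                raise FormulaError(f"unbalanced ')' in {text!r}")
            group = stack.pop()
            m = re.match(r"\d+", text[pos + 1:])
            mult = int(m.group()) if m else 1
            pos += 1 + (m.end() if m else 0)
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", text[pos:])
            if not m:
                raise FormulaError(f"unexpected token {text[pos:]!r} in {text!r}")
            el, digits = m.group(1), m.group(2)
            if el not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
            stack[-1][el] = stack[-1].get(el, 0) + (int(digits) if digits else 1)
            pos += m.end()
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in {text!r}")
    return stack[0]


def parse_formula(formula: str) -> tuple[ElementComposition, int]:
    """Parse ``formula`` into (element composition, hydration count).

    Hydrates are written with a ".", "*" or "·" separator, e.g.
    ``"CaCl2.2H2O"`` or ``"Mg(NO3)2*6H2O"``.  Hydrate H and O are included
    in the returned composition; the water count is returned separately.
    """
    formula = formula.strip()
    if not formula:
        raise FormulaError("empty formula")
    parts = _HYDRATE_SPLIT.split(formula)
    if len(parts) > 2:
        raise FormulaError(f"more than one hydrate separator in {formula!r}")
    comp = _parse_fragment(parts[0])
    hydration = 0
    if len(parts) == 2:
        m = re.fullmatch(r"(\d*)H2O", parts[1].strip())
        if not m:
            raise FormulaError(f"hydrate suffix {parts[1]!r} is not nH2O")
        hydration = int(m.group(1)) if m.group(1) else 1
        comp["H"] = comp.get("H", 0) + 2 * hydration
        comp["O"] = comp.get("O", 0) + hydration
    return comp, hydration


def render_formula(composition: Mapping[str, int], hydration: int = 0) -> str:
    """Render a composition as a formula string (Hill order; hydrate split off)."""
    comp = dict(composition)
    if hydration:
        if comp.get("H", 0) < 2 * hydration or comp.get("O", 0) < hydration:
            raise FormulaError("composition lacks the stated hydrate water")
        comp["H"] -= 2 * hydration
        comp["O"] -= hydration
        comp = {el: n for el, n in comp.items() if n}
    if "C" in comp:
        order = ["C"] + (["H"] if "H" in comp else [])
        order += sorted(el for el in comp if el not in ("C", "H"))
    else:
        order = sorted(comp)
    body = "".join(f"{el}{comp[el] if comp[el] != 1 else ''}" for el in order)
    return f"{body}.{hydration}H2O" if hydration else body


def molar_mass(composition: Mapping[str, int]) -> float:
    """Molar mass in g/mol from the embedded atomic-weight table."""
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in composition.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse
        raise FormulaError(f"unknown element symbol {exc.args[0]!r}") from exc


def merge_compositions(*comps: Mapping[str, int]) -> ElementComposition:
    out: ElementComposition = {}
    for comp in comps:
        for el, n in comp.items():
            out[el] = out.get(el, 0) + n
    return out


@dataclass(frozen=True)
class IonSpecies:
    """A tracked dissolved species: charged ion or explicitly neutral solute.

    ``charge`` is in elementary-charge units; ``composition`` (optional)
    allows mass bookkeeping and element-conservation checks.
    """

    symbol: str
    charge: int
    composition: tuple[tuple[str, int], ...] | None = None

    @staticmethod
    def make(symbol: str, charge: int,
             composition: Mapping[str, int] | None = None) -> "IonSpecies":
        comp = tuple(sorted(composition.items())) if composition else None
        return IonSpecies(symbol, charge, comp)

    @property
    def composition_dict(self) -> ElementComposition | None:
        return dict(self.composition) if self.composition is not None else None

    @property
    def molar_mass(self) -> float | None:
        if self.composition is None:
            return None
        return molar_mass(dict(self.composition))


@dataclass
class Salt:
    """A neutral compound with a parsed formula and a dissociation map.

    ``dissociation`` maps :class:`IonSpecies` to the moles of that species
    released per mole of salt (positive rationals).  ``weight`` is the
    solver's objective coefficient for this salt (mM scale, default 1).
    """

    name: str
    formula: str
    composition: ElementComposition = field(default_factory=dict)
    hydration: int = 0
    molar_mass: float = 0.0
    dissociation: dict[IonSpecies, Fraction] = field(default_factory=dict)
    weight: float = 1.0
    note: str = ""

    @classmethod
    def from_formula(cls, name: str, formula: str,
                     dissociation: Mapping[IonSpecies, int | float | Fraction],
                     weight: float = 1.0, molar_mass_override: float | None = None,
                     note: str = "") -> "Salt":
        comp, hyd = parse_formula(formula)
        mass = molar_mass_override if molar_mass_override is not None else molar_mass(comp)
        diss = {sp: Fraction(n).limit_denominator(10**6)
                for sp, n in dissociation.items()}
        return cls(name=name, formula=formula, composition=comp, hydration=hyd,
                   molar_mass=mass, dissociation=diss, weight=weight, note=note)

    def stoichiometry(self, symbol: str) -> float:
        """Moles of species ``symbol`` released per mole of salt (0 if none)."""
        for sp, n in self.dissociation.items():
            if sp.symbol == symbol:
                return float(n)
        return 0.0


def validate_salt(salt: Salt, charge_tol: float = 1e-9) -> list[str]:
    """Check a salt's dissociation for physical consistency.

    Returns a list of human-readable violations (empty iff valid):

    * electroneutrality: the released species' charges must sum to zero;
    * element conservation: elements of the released species (hydrate water
      excluded) must be present in the salt composition in sufficient count;
    * mass: the summed species mass must not exceed the salt's molar mass.
    """
    violations: list[str] = []
    if salt.molar_mass <= 0:
        violations.append(f"{salt.name}: molar mass must be positive")
    net = sum(float(n) * sp.charge for sp, n in salt.dissociation.items())
    if abs(net) > charge_tol:
        violations.append(f"{salt.name}: charge violation, net {net:+g} per formula unit")

    # element conservation (hydrate waters are not part of any species);
    # skipped for salts declared without a parsed formula (empty composition)
    check_elements = bool(salt.composition)
    available = dict(salt.composition)
    available["H"] = available.get("H", 0) - 2 * salt.hydration
    available["O"] = available.get("O", 0) - salt.hydration
    needed: dict[str, Fraction] = {}
    mass_known = True
    species_mass = 0.0
    for sp, n in salt.dissociation.items():
        if sp.composition is None:
            mass_known = False
            continue
        species_mass += float(n) * molar_mass(dict(sp.composition))
        for el, k in sp.composition:
            needed[el] = needed.get(el, Fraction(0)) + n * k
    if check_elements:
        for el, k in needed.items():
            if Fraction(available.get(el, 0)) < k:
                violations.append(
                    f"{salt.name}: element {el} not conserved "
                    f"(needs {float(k):g}, formula has {available.get(el, 0)})")
    if mass_known and salt.composition and species_mass > salt.molar_mass + 0.5:
        violations.append(
            f"{salt.name}: dissociation species mass {species_mass:.2f} exceeds "
            f"salt molar mass {salt.molar_mass:.2f}")
    return violations
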