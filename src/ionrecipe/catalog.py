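"""Built-in registry of ion species and salts, plus user-catalog CSV I/O.

The built-in catalog covers the salts of common plant tissue-culture media
(MS-type macro- and micronutrient salts), hydroxides and the chloride salts
needed to deconstruct classic KCl/NaCl experiments.  Phosphate occurs as
three protonation states; by default recipes constrain their *pooled* total
("PO4_total"), mirroring how nutrient analyses usually report phosphate.

Catalog CSV format (UTF-8, "." decimal separator)::

    name,formula,dissociation,weight,molar_mass_override,note
    KNO3,KNO3,K+:1;NO3-:1,1,,

``dissociation`` is ``species:count`` pairs joined by ";".  Species symbols
must exist in the ion registry.  ``molar_mass_override`` (g/mol) replaces
the value computed from the formula, for compounds whose exact hydration or
protonation is uncertain but whose effective mass is known.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .chem import IonSpecies, Salt, validate_salt

__all__ = [
    "CatalogError",
    "IonRegistry",
    "SaltCatalog",
    "builtin_catalog",
    "builtin_registry",
    "read_catalog",
    "write_catalog",
]


class CatalogError(ValueError):
    """Malformed catalog data (unknown species, duplicates, bad stoichiometry)."""


@dataclass
class IonRegistry:
    """Symbol → :class:`IonSpecies`, plus pooling rules.

    A *pool* (e.g. ``PO4_total`` → the three phosphate protonation states)
    lets one target constrain the summed concentration of several species.
    Pools must be disjoint and reference registered species only.
    """

    species: dict[str, IonSpecies] = field(default_factory=dict)
    pools: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def add(self, sp: IonSpecies) -> None:
        if sp.symbol in self.species:
            raise CatalogError(f"duplicate species symbol {sp.symbol!r}")
        self.species[sp.symbol] = sp

    def add_pool(self, name: str, members: Iterable[str]) -> None:
        members = tuple(members)
        for m in members:
            if m not in self.species:
                raise CatalogError(f"pool {name!r} member {m!r} not registered")
        for other, ms in self.pools.items():
            overlap = set(ms) & set(members)
            if overlap:
                raise CatalogError(f"pools {name!r} and {other!r} overlap: {overlap}")
        self.pools[name] = members

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.species

    def __getitem__(self, symbol: str) -> IonSpecies:
        try:
            return self.species[symbol]
        except KeyError:
            raise CatalogError(f"unknown ion species {symbol!r}") from None

    def charge(self, symbol: str) -> int:
        return self[symbol].charge

    def resolve(self, key: str) -> tuple[str, ...]:
        """Expand a target key to its species: a pool name or a bare symbol."""
        if key in self.pools:
            return self.pools[key]
        return (self[key].symbol,)


def builtin_registry() -> IonRegistry:
    """The packaged ion registry (macro/micro nutrient ions + chelators)."""
    reg = IonRegistry()
    specs = [
        ("K+", 1, {"K": 1}), ("Na+", 1, {"Na": 1}), ("NH4+", 1, {"N": 1, "H": 4}),
        ("H+", 1, {"H": 1}), ("Ca2+", 2, {"Ca": 1}), ("Mg2+", 2, {"Mg": 1}),
        ("Fe2+", 2, {"Fe": 1}), ("Fe3+", 3, {"Fe": 1}), ("Mn2+", 2, {"Mn": 1}),
        ("Zn2+", 2, {"Zn": 1}), ("Cu2+", 2, {"Cu": 1}), ("Co2+", 2, {"Co": 1}),
        ("NO3-", -1, {"N": 1, "O": 3}), ("Cl-", -1, {"Cl": 1}),
        ("SO4 2-", -2, {"S": 1, "O": 4}), ("OH-", -1, {"O": 1, "H": 1}),
        ("H2PO4-", -1, {"H": 2, "P": 1, "O": 4}),
        ("HPO4 2-", -2, {"H": 1, "P": 1, "O": 4}),
        ("PO4 3-", -3, {"P": 1, "O": 4}),
        ("I-", -1, {"I": 1}), ("BO3 3-", -3, {"B": 1, "O": 3}),
        ("MoO4 2-", -2, {"Mo": 1, "O": 4}),
        # EDTA as released by its di-sodium (di-protonated) and ferric-sodium salts
        ("EDTA 2-", -2, {"C": 10, "H": 14, "N": 2, "O": 8}),
        ("EDTA 4-", -4, {"C": 10, "H": 12, "N": 2, "O": 8}),
    ]
    for symbol, charge, comp in specs:
        reg.add(IonSpecies.make(symbol, charge, comp))
    reg.add_pool("PO4_total", ("H2PO4-", "HPO4 2-", "PO4 3-"))
    reg.add_pool("Fe_total", ("Fe2+", "Fe3+"))
    return reg


#: Species a recipe is usually allowed to release without a target: protons,
#: hydroxide and chelators.  Needed to admit NaOH, NH4OH, Ca(OH)2, H3BO3 and
#: the EDTA salts that standard media contain.
DEFAULT_FREE_SPECIES = frozenset({"H+", "OH-", "EDTA 2-", "EDTA 4-"})


@dataclass
class SaltCatalog:
    """Ordered salt collection with name lookup.

    Order matters: it is the deterministic tie-break among equally optimal
    recipes.  Names are unique; "·" and "*" in hydrate names normalize to ".".
    """

    registry: IonRegistry
    salts: list[Salt] = field(default_factory=list)

    @staticmethod
    def normalize_name(name: str) -> str:
        return name.strip().replace("·", ".").replace("*", ".")

    def add(self, salt: Salt) -> None:
        salt.name = self.normalize_name(salt.name)
        if salt.name in self._index():
            raise CatalogError(f"duplicate salt name {salt.name!r}")
        for sp in salt.dissociation:
            if sp.symbol not in self.registry:
                raise CatalogError(
                    f"salt {salt.name!r} releases unregistered species {sp.symbol!r}")
        problems = validate_salt(salt)
        if problems:
            raise CatalogError("; ".join(problems))
        self.salts.append(salt)

    def _index(self) -> dict[str, Salt]:
        return {s.name: s for s in self.salts}

    def __contains__(self, name: str) -> bool:
        return self.normalize_name(name) in self._index()

    def __getitem__(self, name: str) -> Salt:
        key = self.normalize_name(name)
        try:
            return self._index()[key]
        except KeyError:
            raise CatalogError(f"salt {name!r} not in catalog") from None

    def __len__(self) -> int:
        return len(self.salts)

    def __iter__(self):
        return iter(self.salts)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.salts]

    def subset(self, names: Iterable[str]) -> "SaltCatalog":
        sub = SaltCatalog(registry=self.registry)
        for name in names:
            sub.add(self[name])
        return sub

    def species_symbols(self) -> list[str]:
        """All species any catalog salt can release, in first-seen order."""
        seen: list[str] = []
        for salt in self.salts:
            for sp in salt.dissociation:
                if sp.symbol not in seen:
                    seen.append(sp.symbol)
        return seen


def _parse_dissociation(text: str, registry: IonRegistry) -> dict[IonSpecies, Fraction]:
    out: dict[IonSpecies, Fraction] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise CatalogError(f"malformed dissociation entry {part!r} (need species:count)")
        symbol, _, count = part.rpartition(":")
        symbol = symbol.strip()
        sp = registry[symbol]
        try:
            frac = Fraction(count.strip())
        except (ValueError, ZeroDivisionError):
            raise CatalogError(f"malformed count {count!r} for species {symbol!r}") from None
        if frac <= 0:
            raise CatalogError(f"non-positive count for species {symbol!r}")
        out[sp] = frac
    if not out:
        raise CatalogError(f"empty dissociation {text!r}")
    return out


def _render_dissociation(salt: Salt) -> str:
    return ";".join(f"{sp.symbol}:{n}" for sp, n in salt.dissociation.items())


_CSV_HEADER = ["name", "formula", "dissociation", "weight", "molar_mass_override", "note"]


def read_catalog(source: str | Path | io.TextIOBase,
                 registry: IonRegistry | None = None) -> SaltCatalog:
    """Read a salt catalog from CSV (path or open text stream)."""
    registry = registry or builtin_registry()
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_catalog(fh, registry)
    catalog = SaltCatalog(registry=registry)
    reader = csv.DictReader(row for row in source if not row.startswith("#"))
    if reader.fieldnames is None or "name" not in reader.fieldnames:
        raise CatalogError("catalog CSV lacks a 'name' column")
    for row in reader:
        override = (row.get("molar_mass_override") or "").strip()
        salt = Salt.from_formula(
            name=row["name"].strip(),
            formula=row["formula"].strip(),
            dissociation=_parse_dissociation(row["dissociation"], registry),
            weight=float(row.get("weight") or 1.0),
            molar_mass_override=float(override) if override else None,
            note=(row.get("note") or "").strip(),
        )
        catalog.add(salt)
    return catalog


def write_catalog(catalog: SaltCatalog, dest: str | Path | io.TextIOBase) -> None:
    """Write a catalog to CSV; ``read_catalog`` round-trips it exactly."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_catalog(catalog, fh)
            return
    writer = csv.writer(dest)
    writer.writerow(_CSV_HEADER)
    for salt in catalog:
        from .chem import molar_mass as _mm
        computed = _mm(salt.composition)
        override = "" if abs(salt.molar_mass - computed) < 5e-3 else repr(salt.molar_mass)
        writer.writerow([salt.name, salt.formula, _render_dissociation(salt),
                         repr(salt.weight), override, salt.note])


def builtin_catalog() -> SaltCatalog:
    """The packaged salt catalog (loaded from the bundled CSV)."""
    data = resources.files("ionrecipe.data").joinpath("builtin_catalog.csv")
    with data.open("r", encoding="utf-8") as fh:
        return read_catalog(fh, builtin_registry())


def catalog_from_dissociations(
        entries: Mapping[str, Mapping[str, int | float | Fraction]],
        registry: IonRegistry,
        molar_masses: Mapping[str, float] | None = None) -> SaltCatalog:
    """Build a catalog directly from symbol-keyed dissociation maps.

    Convenience for tests and synthetic problems where salts have no real
    chemical formula; molar masses default to the summed species masses.
    """
    catalog = SaltCatalog(registry=registry)
    for name, diss in entries.items():
        species = {registry[symbol]: Fraction(n).limit_denominator(10**6)
                   for symbol, n in diss.items()}
        if molar_masses and name in molar_masses:
            mass = molar_masses[name]
        else:
            mass = sum((sp.molar_mass or 50.0) * float(n) for sp, n in species.items())
        catalog.add(Salt(name=name, formula=name, composition={}, hydration=0,
                         molar_mass=mass, dissociation=species))
    return catalog
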