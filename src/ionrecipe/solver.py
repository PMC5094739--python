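"""Linear-programming salt recipe solver.

Given target ion concentrations ``b`` (mM) and a salt catalog whose
dissociation maps form the ion-proportionality matrix ``A`` (mol of ion per
mol of salt), find non-negative salt amounts ``X`` (mM) with

    minimize  c @ X    subject to   A @ X  (=, <=, >=)  b,   X >= 0

so that dissolving the recipe meets every constrained ion level exactly (or
as a bound).  ``c`` defaults to 1 per salt, i.e. the total dissolved mmol of
salts is minimized.  Specific salts can be *forced* into the recipe at fixed
amounts, and designated *free species* (typically H+, OH- and chelators) are
exempt from constraints so hydroxide/acid salts can balance charge.

Recipes need not be unique; among optima the solver returns the
lexicographically smallest recipe in catalog order (a secondary sequence of
LPs pins each amount in turn), so outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .catalog import DEFAULT_FREE_SPECIES, CatalogError, IonRegistry, SaltCatalog

__all__ = [
    "InfeasibilityReport",
    "LPProblem",
    "Recipe",
    "SolverError",
    "TargetSpec",
    "UnreachableIonError",
    "build_lp",
    "diagnose_infeasibility",
    "solve",
    "to_mg_per_l",
]

#: |A @ X - b| <= RESIDUAL_TOL * max(1, |b_i|) is required of an optimal recipe.
RESIDUAL_TOL = 1e-8
#: residuals above this trigger a warning even when within tolerance
RESIDUAL_WARN = 1e-10


class SolverError(RuntimeError):
    pass


class UnreachableIonError(SolverError):
    """A targeted species cannot be produced by any catalog salt."""


@dataclass
class TargetSpec:
    """Target ion concentrations plus solver directives.

    ``targets`` maps species symbols or pool names to mM (>= 0).  ``senses``
    optionally relaxes individual targets to "<=" or ">=" (default "=").
    ``free`` lists species exempt from constraints.  ``forced_salts`` fixes
    named salts at given mM in the recipe.  By default every species a
    catalog salt could release that is neither targeted, pooled into a
    target, nor free is constrained to zero.
    """

    targets: dict[str, float] = field(default_factory=dict)
    senses: dict[str, str] = field(default_factory=dict)
    free: frozenset[str] = frozenset()
    forced_salts: dict[str, float] = field(default_factory=dict)
    constrain_untargeted: bool = True

    def __post_init__(self) -> None:
        self.free = frozenset(self.free)
        for ion, value in self.targets.items():
            if value < 0:
                raise ValueError(f"negative target for {ion!r}: {value}")
        bad = set(self.senses) - set(self.targets)
        if bad:
            raise ValueError(f"sense given for untargeted ions: {sorted(bad)}")
        for sense in self.senses.values():
            if sense not in ("=", "<=", ">="):
                raise ValueError(f"invalid constraint sense {sense!r}")
        overlap = self.free & set(self.targets)
        if overlap:
            raise ValueError(f"species both free and targeted: {sorted(overlap)}")

    @classmethod
    def paper_faithful(cls, targets: Mapping[str, float],
                       forced_salts: Mapping[str, float] | None = None,
                       senses: Mapping[str, str] | None = None) -> "TargetSpec":
        """Spec with the conventional free set (H+, OH-, EDTA species)."""
        return cls(targets=dict(targets), senses=dict(senses or {}),
                   free=DEFAULT_FREE_SPECIES,
                   forced_salts=dict(forced_salts or {}))


@dataclass
class LPProblem:
    """Assembled LP: one row per constrained species or pool, one column per salt."""

    rows: list[str]                 # row labels (species symbol or pool name)
    row_species: list[tuple[str, ...]]  # species pooled into each row
    A: np.ndarray                   # (m, n) stoichiometry, mol ion / mol salt
    b: np.ndarray                   # (m,) targets, mM
    senses: list[str]               # per-row "=", "<=", ">="
    c: np.ndarray                   # (n,) objective weights
    bounds: list[tuple[float, float | None]]  # per-salt (lo, hi); forced -> (v, v)
    salts: list[str]
    catalog: SaltCatalog
    free: frozenset[str] = frozenset()

    @property
    def m(self) -> int:
        return len(self.rows)

    @property
    def n(self) -> int:
        return len(self.salts)


@dataclass
class Recipe:
    """Solver result: salt amounts in mM plus status metadata."""

    amounts: dict[str, float]       # salt -> mM (all catalog salts, zeros kept)
    status: str                     # "optimal" | "infeasible" | "unbounded"
    objective: float | None = None
    max_residual: float = 0.0

    def nonzero(self, tol: float = 1e-10) -> dict[str, float]:
        return {k: v for k, v in self.amounts.items() if v > tol}

    def mg_per_l(self, catalog: SaltCatalog) -> dict[str, float]:
        return to_mg_per_l(self.amounts, catalog)


def build_lp(targets: TargetSpec, catalog: SaltCatalog) -> LPProblem:
    """Assemble the LP for a target spec over a catalog.

    Pool targets become single rows summing their member species.  Raises
    :class:`UnreachableIonError` if a positively-targeted species cannot be
    produced by any salt.
    """
    registry = catalog.registry
    salts = list(catalog)
    n = len(salts)

    rows: list[str] = []
    row_species: list[tuple[str, ...]] = []
    b_list: list[float] = []
    senses: list[str] = []
    covered: set[str] = set(targets.free)
    for key, value in targets.targets.items():
        members = registry.resolve(key)
        overlap = set(members) & covered
        if overlap:
            raise ValueError(f"target {key!r} overlaps free/targeted species {sorted(overlap)}")
        rows.append(key)
        row_species.append(members)
        b_list.append(float(value))
        senses.append(targets.senses.get(key, "="))
        covered |= set(members)

    if targets.constrain_untargeted:
        for symbol in catalog.species_symbols():
            if symbol not in covered:
                rows.append(symbol)
                row_species.append((symbol,))
                b_list.append(0.0)
                senses.append("=")

    A = np.zeros((len(rows), n))
    for i, members in enumerate(row_species):
        for j, salt in enumerate(salts):
            A[i, j] = sum(salt.stoichiometry(sym) for sym in members)

    for i, (label, bi, sense) in enumerate(zip(rows, b_list, senses)):
        if bi > 0 and sense in ("=", ">=") and not A[i].any():
            raise UnreachableIonError(
                f"unreachable ion: no catalog salt produces {label!r} "
                f"(target {bi} mM)")

    bounds: list[tuple[float, float | None]] = [(0.0, None)] * n
    names = [s.name for s in salts]
    for forced, amount in targets.forced_salts.items():
        key = catalog.normalize_name(forced)
        if key not in names:
            raise CatalogError(f"forced salt {forced!r} not in catalog")
        if amount < 0:
            raise ValueError(f"negative forced amount for {forced!r}")
        bounds[names.index(key)] = (float(amount), float(amount))

    c = np.array([s.weight for s in salts], float)
    return LPProblem(rows=rows, row_species=row_species, A=A,
                     b=np.array(b_list), senses=senses, c=c, bounds=bounds,
                     salts=names, catalog=catalog, free=targets.free)


def _split_constraints(problem: LPProblem):
    eq = [i for i, s in enumerate(problem.senses) if s == "="]
    le = [i for i, s in enumerate(problem.senses) if s == "<="]
    ge = [i for i, s in enumerate(problem.senses) if s == ">="]
    A_eq = problem.A[eq] if eq else None
    b_eq = problem.b[eq] if eq else None
    A_ub_parts, b_ub_parts = [], []
    if le:
        A_ub_parts.append(problem.A[le])
        b_ub_parts.append(problem.b[le])
    if ge:
        A_ub_parts.append(-problem.A[ge])
        b_ub_parts.append(-problem.b[ge])
    A_ub = np.vstack(A_ub_parts) if A_ub_parts else None
    b_ub = np.concatenate(b_ub_parts) if b_ub_parts else None
    return A_eq, b_eq, A_ub, b_ub


def _linprog(c, problem: LPProblem, bounds, extra_ub=None):
    A_eq, b_eq, A_ub, b_ub = _split_constraints(problem)
    if extra_ub is not None:
        row, rhs = extra_ub
        A_ub = row[None, :] if A_ub is None else np.vstack([A_ub, row])
        b_ub = np.array([rhs]) if b_ub is None else np.concatenate([b_ub, [rhs]])
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                   bounds=bounds, method="highs",
                   options={"primal_feasibility_tolerance": 1e-10,
                            "dual_feasibility_tolerance": 1e-9})


def solve(problem: LPProblem, lexicographic: bool = True) -> Recipe:
    """Solve the LP; on success returns the lexicographically smallest optimum.

    The tie-break pass minimizes each salt amount in catalog order subject
    to the original constraints and objective optimality, so degenerate
    problems (recipes are generally not unique) yield a deterministic,
    reproducible recipe.
    """
    res = _linprog(problem.c, problem, problem.bounds)
    if res.status == 2:
        return Recipe(amounts={}, status="infeasible")
    if res.status == 3:  # pragma: no cover - impossible with c > 0, guarded anyway
        return Recipe(amounts={}, status="unbounded")
    if res.status != 0:  # pragma: no cover
        raise SolverError(f"LP solver failed: {res.message}")

    x = np.asarray(res.x)
    if lexicographic and problem.n > 1:
        f_star = float(problem.c @ x)
        slack = 1e-9 * max(1.0, abs(f_star))
        bounds = list(problem.bounds)
        for j in range(problem.n):
            ej = np.zeros(problem.n)
            ej[j] = 1.0
            sub = _linprog(ej, problem, bounds,
                           extra_ub=(problem.c, f_star + slack))
            if sub.status != 0:
                break  # keep primary solution for remaining components
            xj = max(0.0, float(sub.x[j]))
            bounds[j] = (xj, xj)
            x = np.asarray(sub.x)

    x = np.where(np.abs(x) < 1e-12, 0.0, x)
    resid = problem.A @ x - problem.b
    scale = np.maximum(1.0, np.abs(problem.b))
    eq_mask = np.array([s == "=" for s in problem.senses])
    max_resid = float(np.max(np.abs(resid[eq_mask]) / scale[eq_mask])) if eq_mask.any() else 0.0
    if max_resid > RESIDUAL_TOL:
        raise SolverError(f"constraint residual {max_resid:.3e} exceeds tolerance")
    if max_resid > RESIDUAL_WARN:
        warnings.warn(f"recipe residual {max_resid:.2e} above {RESIDUAL_WARN:.0e}",
                      stacklevel=2)
    amounts = {name: float(v) for name, v in zip(problem.salts, x)}
    return Recipe(amounts=amounts, status="optimal",
                  objective=float(problem.c @ x), max_residual=max_resid)


@dataclass
class InfeasibilityReport:
    """Why no recipe exists, and the closest achievable alternative."""

    imbalance_meq: tuple[float, float]   # (min, max) of sum(z_i * b_i), meq/L
    has_charged_free: bool
    unreachable: list[str]
    relaxed_recipe: dict[str, float]     # least-infeasible recipe, mM
    achieved: dict[str, float]           # row label -> achieved level, mM
    total_violation: float               # sum |deviation| over rows, mM

    def render(self) -> str:
        lo, hi = self.imbalance_meq
        lines = ["recipe infeasible"]
        imb = f"{lo:+.4g}" if abs(hi - lo) < 1e-12 else f"{lo:+.4g} .. {hi:+.4g}"
        if not self.has_charged_free:
            lines.append(
                f"  charge imbalance of targets: {imb} meq/L "
                "(neutral salts cannot reach a charged target vector; "
                "free a counter-species such as OH- or relax a target)")
        if self.unreachable:
            lines.append(f"  unreachable species: {', '.join(self.unreachable)}")
        lines.append(f"  closest achievable composition (total |deviation| "
                     f"{self.total_violation:.4g} mM):")
        for label, val in self.achieved.items():
            lines.append(f"    {label}: {val:.6g}")
        return "\n".join(lines)


def _row_charge_range(problem: LPProblem) -> tuple[float, float]:
    registry = problem.catalog.registry
    lo = hi = 0.0
    for members, bi in zip(problem.row_species, problem.b):
        charges = [registry.charge(sym) for sym in members]
        lo += min(charges) * bi
        hi += max(charges) * bi
    return lo, hi


def diagnose_infeasibility(problem: LPProblem) -> InfeasibilityReport:
    """Explain an infeasible LP.  Raises ``ValueError`` if it is feasible.

    With no free *charged* species every achievable target vector must be
    electroneutral (each salt column is neutral), so the report prints the
    target charge imbalance in meq/L; it also lists targeted-but-unreachable
    species and solves for the least-infeasible recipe (minimum total
    absolute deviation from the targets).
    """
    if solve(problem, lexicographic=False).status == "optimal":
        raise ValueError("problem is feasible")

    registry = problem.catalog.registry
    has_charged_free = any(registry.charge(sym) != 0 for sym in problem.free
                           if sym in registry)
    unreachable = [label for label, bi, row in
                   zip(problem.rows, problem.b, problem.A)
                   if bi > 0 and not row.any()]

    # least-infeasible relaxation: min sum(s+ + s-), A x - b = s+ - s-
    m, n = problem.m, problem.n
    A_eq = np.hstack([problem.A, -np.eye(m), np.eye(m)])
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    bounds = list(problem.bounds) + [(0.0, None)] * (2 * m)
    res = linprog(c, A_eq=A_eq, b_eq=problem.b, bounds=bounds, method="highs")
    if res.status == 0:
        x = res.x[:n]
        achieved_vec = problem.A @ x
        relaxed = {name: float(v) for name, v in zip(problem.salts, x) if v > 1e-10}
        achieved = {label: float(v) for label, v in zip(problem.rows, achieved_vec)}
        total = float(np.abs(achieved_vec - problem.b).sum())
    else:  # pragma: no cover - relaxation is always feasible unless bounds conflict
        relaxed, achieved, total = {}, {}, float("nan")

    return InfeasibilityReport(
        imbalance_meq=_row_charge_range(problem),
        has_charged_free=has_charged_free,
        unreachable=unreachable,
        relaxed_recipe=relaxed,
        achieved=achieved,
        total_violation=total,
    )


def to_mg_per_l(amounts_mM: Mapping[str, float], catalog: SaltCatalog) -> dict[str, float]:
    """Convert a salt->mM map to mg/L via catalog molar masses (full precision)."""
    return {name: float(mM) * catalog[name].molar_mass
            for name, mM in amounts_mM.items()}


def from_mg_per_l(amounts_mg: Mapping[str, float], catalog: SaltCatalog) -> dict[str, float]:
    """Convert a salt->mg/L map to mM."""
    return {name: float(mg) / catalog[name].molar_mass
            for name, mg in amounts_mg.items()}
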