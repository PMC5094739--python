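"""Ion-confounding-free mixture experiment design.

A q-component *blend* is a vector of proportions on the simplex
(x_1 + ... + x_q = 1).  The Scheffé polynomial bases have no intercept:
linear terms x_k, plus (degree 2) the products x_k x_l.  D-optimal point
selection maximizes det(X'X) of the expanded design matrix over a finite
candidate set — exhaustively when the subset count is small, otherwise by
seeded Fedorov exchange.

Designs are turned into experiments by blending a fixed ion *pool total*
(e.g. K+ + Na+ = 23.2 mM) across the components while every other ion of a
base specification is held constant, so the resulting target specs differ
only in the pooled ions: the no-confounding guarantee.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .solver import TargetSpec

__all__ = [
    "Blend",
    "Design",
    "DesignPoint",
    "SingularDesignError",
    "augment",
    "d_optimal_select",
    "default_candidates",
    "scheffe_matrix",
    "scheffe_terms",
    "blend_to_targets",
]

Blend = tuple[float, ...]

_SUM_TOL = 1e-12
#: exhaustive D-optimal search is used while C(candidates, n) stays below this
EXHAUSTIVE_LIMIT = 10**6


class SingularDesignError(ValueError):
    """Too few (or degenerate) points to support the requested model."""


def validate_blend(blend: Sequence[float]) -> Blend:
    blend = tuple(float(x) for x in blend)
    if any(x < -_SUM_TOL or x > 1 + _SUM_TOL for x in blend):
        raise ValueError(f"proportions outside [0, 1]: {blend}")
    if abs(sum(blend) - 1.0) > _SUM_TOL:
        raise ValueError(f"proportions must sum to 1, got {sum(blend)!r}")
    return blend


def default_candidates(q: int = 2, levels: int = 5) -> list[Blend]:
    """Evenly spaced candidate blends; for q=2 the 5-level set
    {0, .25, .5, .75, 1} (as first-component proportion)."""
    if q == 2:
        return [(i / (levels - 1), 1 - i / (levels - 1)) for i in range(levels)]
    # simplex lattice for q > 2
    steps = levels - 1
    out = []
    for combo in itertools.product(range(steps + 1), repeat=q):
        if sum(combo) == steps:
            out.append(tuple(c / steps for c in combo))
    return out


def scheffe_terms(q: int, degree: int) -> list[str]:
    terms = [f"x{k + 1}" for k in range(q)]
    if degree == 2:
        terms += [f"x{k + 1}*x{l + 1}"
                  for k in range(q) for l in range(k + 1, q)]
    elif degree != 1:
        raise ValueError("degree must be 1 or 2")
    return terms


def scheffe_matrix(blends: Iterable[Sequence[float]], degree: int) -> np.ndarray:
    """Expanded (no-intercept) Scheffé model matrix for the given blends."""
    X = np.atleast_2d(np.asarray(list(blends), float))
    q = X.shape[1]
    if degree == 1:
        return X
    if degree != 2:
        raise ValueError("degree must be 1 or 2")
    cross = [X[:, k] * X[:, l] for k in range(q) for l in range(k + 1, q)]
    return np.column_stack([X] + cross)


def _log_det(X: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -math.inf


def d_optimal_select(candidates: Sequence[Sequence[float]], degree: int,
                     n_points: int, seed: int = 1) -> list[Blend]:
    """Select the n-point subset of ``candidates`` maximizing det(X'X).

    Exhaustive over all subsets while their count is at most
    ``EXHAUSTIVE_LIMIT``; otherwise seeded Fedorov exchange.  Ties break to
    the earliest subset in candidate order, so the result is deterministic.
    """
    cands = [validate_blend(b) for b in candidates]
    p = len(scheffe_terms(len(cands[0]), degree))
    if n_points < p:
        raise SingularDesignError(
            f"{n_points} points cannot estimate {p} model terms")
    if math.comb(len(cands), n_points) <= EXHAUSTIVE_LIMIT:
        best, best_val = None, -math.inf
        for combo in itertools.combinations(range(len(cands)), n_points):
            val = _log_det(scheffe_matrix([cands[i] for i in combo], degree))
            if val > best_val + 1e-12:
                best, best_val = combo, val
        if best is None or best_val == -math.inf:
            raise SingularDesignError("no candidate subset supports the model")
        return [cands[i] for i in best]
    return fedorov_exchange(cands, degree, n_points, seed=seed)


def fedorov_exchange(candidates: Sequence[Sequence[float]], degree: int,
                     n_points: int, seed: int = 1, n_starts: int = 5) -> list[Blend]:
    """Fedorov point-exchange D-optimal search (multi-start, seeded).

    From a random starting subset, repeatedly performs the single
    (design point, candidate) swap that most increases det(X'X) until no
    swap improves it; keeps the best of ``n_starts`` restarts.
    """
    cands = [validate_blend(b) for b in candidates]
    rng = np.random.default_rng(seed)
    p = len(scheffe_terms(len(cands[0]), degree))
    if n_points < p:
        raise SingularDesignError(
            f"{n_points} points cannot estimate {p} model terms")
    best_idx, best_val = None, -math.inf
    for _ in range(n_starts):
        idx = list(rng.choice(len(cands), size=n_points, replace=False))
        val = _log_det(scheffe_matrix([cands[i] for i in idx], degree))
        improved = True
        while improved:
            improved = False
            for pos in range(n_points):
                for cand in range(len(cands)):
                    if cand in idx:
                        continue  # designs are subsets: no repeated candidates
                    trial = idx.copy()
                    trial[pos] = cand
                    tval = _log_det(scheffe_matrix([cands[i] for i in trial], degree))
                    if tval > val + 1e-10:
                        idx, val = trial, tval
                        improved = True
        if val > best_val + 1e-10:
            best_idx, best_val = sorted(idx), val
    if best_idx is None or best_val == -math.inf:
        raise SingularDesignError("no candidate subset supports the model")
    return [cands[i] for i in best_idx]


@dataclass(frozen=True)
class DesignPoint:
    blend: Blend
    role: str  # "model" | "lack_of_fit" | "replicate"


@dataclass
class Design:
    """Ordered design points with roles; replicates duplicate earlier blends."""

    points: list[DesignPoint]

    def blends(self) -> list[Blend]:
        return [p.blend for p in self.points]

    def counts_by_role(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.points:
            out[p.role] = out.get(p.role, 0) + 1
        return out

    def distinct_blends(self) -> list[Blend]:
        seen: list[Blend] = []
        for p in self.points:
            if p.blend not in seen:
                seen.append(p.blend)
        return seen

    def replication(self) -> dict[Blend, int]:
        out: dict[Blend, int] = {}
        for p in self.points:
            out[p.blend] = out.get(p.blend, 0) + 1
        return out


def _is_vertex(blend: Blend) -> bool:
    return any(abs(x - 1.0) <= _SUM_TOL for x in blend)


def augment(model_points: Sequence[Sequence[float]], n_lof: int, n_reps: int,
            candidates: Sequence[Sequence[float]], degree: int = 2,
            seed: int = 1) -> Design:
    """Augment model points with lack-of-fit points and replicates.

    Lack-of-fit points are chosen D-optimally (for the same model) from the
    candidates not already in the design.  Replicates are allocated
    round-robin over the distinct blends — vertices first, in design order,
    then interior points — so replicate effort concentrates where response
    variance matters most for a mixture fit.
    """
    model = [validate_blend(b) for b in model_points]
    cands = [validate_blend(b) for b in candidates]
    remaining = [b for b in cands if b not in model]
    if n_lof > len(remaining):
        raise ValueError(f"{n_lof} lack-of-fit points requested but only "
                         f"{len(remaining)} unused candidates")
    lof: list[Blend] = []
    if n_lof:
        best, best_val = None, -math.inf
        for combo in itertools.combinations(range(len(remaining)), n_lof):
            pts = model + [remaining[i] for i in combo]
            val = _log_det(scheffe_matrix(pts, degree))
            if val > best_val + 1e-12:
                best, best_val = combo, val
        lof = [remaining[i] for i in best]

    points = [DesignPoint(b, "model") for b in model]
    points += [DesignPoint(b, "lack_of_fit") for b in lof]

    distinct = [p.blend for p in points]
    order = [b for b in distinct if _is_vertex(b)] + \
            [b for b in distinct if not _is_vertex(b)]
    for i in range(n_reps):
        points.append(DesignPoint(order[i % len(order)], "replicate"))
    return Design(points=points)


def blend_to_targets(blend: Sequence[float], pool_total: float,
                     pooled_ions: Sequence[str], base: TargetSpec) -> TargetSpec:
    """Expand a blend into a full target spec over a constant base.

    Pooled ion k is targeted at x_k * pool_total (mM); all base targets are
    carried through unchanged.  Across a design, the resulting specs differ
    only in the pooled ions, so the experiment varies nothing else.
    """
    blend = validate_blend(blend)
    if len(pooled_ions) != len(blend):
        raise ValueError("one pooled ion per blend component is required")
    conflict = set(pooled_ions) & set(base.targets)
    if conflict:
        raise ValueError(f"pooled ions already targeted in base: {sorted(conflict)}")
    targets = dict(base.targets)
    for ion, x in zip(pooled_ions, blend):
        targets[ion] = x * pool_total
    return TargetSpec(targets=targets, senses=dict(base.senses), free=base.free,
                      forced_salts=dict(base.forced_salts),
                      constrain_untargeted=base.constrain_untargeted)
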