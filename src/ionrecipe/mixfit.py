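"""Scheffé mixture-model fitting and ANOVA.

The two-component quadratic Scheffé model is

    y = b1*x1 + b2*x2 + b12*x1*x2        (no intercept; x1 + x2 = 1)

where b1, b2 estimate the response at the vertices and b12 is the quadratic
*blending* term — positive for synergy, negative for antagonism.  It looks
like an interaction term but is not one: on the simplex the linear terms
already absorb the overall level.

The ANOVA partitions the corrected total sum of squares sequentially into a
linear-mixture line (q-1 df), quadratic blending terms, and a residual that
splits into lack of fit (between replicated blends) and pure error (within
them); lack of fit is tested against pure error, everything else against
the residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import Blend, SingularDesignError, scheffe_matrix, scheffe_terms, validate_blend

__all__ = [
    "AnovaRow",
    "MixtureFit",
    "Observation",
    "anova",
    "fit_scheffe",
    "response_trace",
]


@dataclass(frozen=True)
class Observation:
    """One experimental unit: a blend and its measured response."""

    blend: Blend
    response: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "blend", validate_blend(self.blend))
        if not math.isfinite(self.response):
            raise ValueError(f"non-finite response {self.response!r}")


def _as_observations(observations: Iterable) -> list[Observation]:
    out = []
    for obs in observations:
        if isinstance(obs, Observation):
            out.append(obs)
        else:
            *blend, y = obs
            out.append(Observation(tuple(blend), float(y)))
    return out


@dataclass
class MixtureFit:
    """Least-squares Scheffé fit: coefficients, fitted values, residuals."""

    degree: int
    terms: list[str]
    coefficients: dict[str, float]
    observations: list[Observation]
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def q(self) -> int:
        return len(self.observations[0].blend)

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms])

    def predict(self, blends: Sequence[Sequence[float]]) -> np.ndarray:
        X = scheffe_matrix([validate_blend(b) for b in blends], self.degree)
        return X @ self.coef_vector


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    """Raise naming the first term whose column adds no rank."""
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, :j + 1])
        if new_rank == rank:
            raise SingularDesignError(
                f"design cannot estimate term {terms[j]!r} "
                "(column linearly dependent on earlier terms)")
        rank = new_rank


def fit_scheffe(observations: Iterable, degree: int = 2) -> MixtureFit:
    """Fit the degree-1 or degree-2 Scheffé polynomial by ordinary least squares.

    ``observations`` are :class:`Observation` objects or tuples
    ``(x1, ..., xq, response)``.  Requires at least as many distinct blends
    as model terms; a rank-deficient design raises
    :class:`SingularDesignError` naming the deficient term.
    """
    obs = _as_observations(observations)
    if not obs:
        raise ValueError("no observations")
    q = len(obs[0].blend)
    terms = scheffe_terms(q, degree)
    X = scheffe_matrix([o.blend for o in obs], degree)
    y = np.array([o.response for o in obs])
    _check_rank(X, terms)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return MixtureFit(degree=degree, terms=terms,
                      coefficients=dict(zip(terms, beta.tolist())),
                      observations=obs, fitted=fitted, residuals=y - fitted)


@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "source": r.source, "ss": r.ss, "df": r.df, "ms": r.ms,
            "F": r.f, "p": r.p} for r in self.rows])

    def render(self) -> str:
        """Aligned text table; p-values below 1e-4 print as "<0.0001"."""
        def fmt_p(p):
            if p is None:
                return ""
            return "<0.0001" if p < 1e-4 else f"{p:.4f}"

        def fmt(v, spec=".3G"):
            return "" if v is None else format(v, spec)

        lines = [f"{'Source':<16}{'SS':>10}{'df':>4}{'MS':>10}{'F':>8}{'p':>9}"]
        for r in self.rows:
            lines.append(f"{r.source:<16}{fmt(r.ss):>10}{r.df:>4}"
                         f"{fmt(r.ms):>10}{fmt(r.f, '.4G'):>8}{fmt_p(r.p):>9}")
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def _pure_error(obs: list[Observation]) -> tuple[float, int]:
    """Within-blend SS over replicated blends; df = N - number distinct blends.

    Depends only on the replicate structure, never on the fitted model.
    """
    groups: dict[Blend, list[float]] = {}
    for o in obs:
        groups.setdefault(o.blend, []).append(o.response)
    ss = sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values())
    return ss, len(obs) - len(groups)


def anova(fit: MixtureFit, observations: Iterable | None = None) -> AnovaTable:
    """Mixture ANOVA with sequential linear/quadratic partition and
    lack-of-fit vs pure-error decomposition.

    The model line carries (terms - 1) df: the simplex constraint costs one
    df, so the corrected total has N - 1.  The linear-mixture SS is the
    corrected total minus the linear-only fit's residual SS; the quadratic
    SS is the increment up to the full model.  F ratios are taken against
    the residual MS, except lack of fit, which is tested against pure error.
    """
    obs = _as_observations(observations) if observations is not None \
        else fit.observations
    y = np.array([o.response for o in obs])
    n = len(obs)
    p = len(fit.terms)

    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = float(fit.residuals @ fit.residuals)
    df_resid = n - p
    ss_model = ss_total - ss_resid
    df_model = p - 1  # simplex constraint: one df lost to the mixture total

    rows = [AnovaRow("Model", ss_model, df_model)]
    if fit.degree == 2:
        linear = fit_scheffe(obs, degree=1)
        ss_linear = ss_total - float(linear.residuals @ linear.residuals)
        df_linear = fit.q - 1
        ss_quad = ss_model - ss_linear
        df_quad = df_model - df_linear
        rows.append(AnovaRow("Linear mixture", ss_linear, df_linear))
        rows.append(AnovaRow("Quadratic", ss_quad, df_quad))
    rows.append(AnovaRow("Residual", ss_resid, df_resid))

    notes: list[str] = []
    ss_pe, df_pe = _pure_error(obs)
    if df_pe > 0:
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        rows.append(AnovaRow("Lack of Fit", max(ss_lof, 0.0), df_lof))
        rows.append(AnovaRow("Pure Error", ss_pe, df_pe))
    else:
        notes.append("no replicated blends: lack-of-fit and pure-error lines omitted")
    rows.append(AnovaRow("Cor Total", ss_total, n - 1))

    eps = 1e-12 * max(ss_total, 1.0)  # below this a mean square counts as zero
    ms_resid = ss_resid / df_resid if df_resid > 0 else math.nan
    ms_pe = ss_pe / df_pe if df_pe > 0 else math.nan
    for row in rows:
        if row.source in ("Cor Total",) or row.df <= 0:
            continue
        row.ms = row.ss / row.df
        if row.source in ("Model", "Linear mixture", "Quadratic"):
            denom, ddf = ms_resid, df_resid
        elif row.source == "Lack of Fit":
            denom, ddf = ms_pe, df_pe
        else:
            continue
        if ddf > 0 and denom > eps:
            row.f = row.ms / denom
            row.p = float(stats.f.sf(row.f, row.df, ddf))
        else:
            notes.append(f"{row.source}: F undefined (zero denominator mean square)")
    return AnovaTable(rows=rows, notes=notes)


def response_trace(fit: MixtureFit, resolution: int = 101) -> pd.DataFrame:
    """Predicted response along the simplex edge (q=2) on an even grid.

    Endpoints equal the vertex coefficients.  Columns: one proportion per
    component plus ``predicted``.
    """
    if fit.q != 2:
        raise ValueError("response traces are defined here for 2-component fits")
    x1 = np.linspace(0.0, 1.0, resolution)
    blends = np.column_stack([x1, 1.0 - x1])
    pred = fit.predict(blends)
    return pd.DataFrame({"x1": x1, "x2": 1.0 - x1, "predicted": pred})


def plot_trace(fit: MixtureFit, resolution: int = 101, ax=None):
    """Plot the response trace (requires matplotlib)."""
    import matplotlib.pyplot as plt

    trace = response_trace(fit, resolution)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace["x1"], trace["predicted"])
    x1 = [o.blend[0] for o in fit.observations]
    y = [o.response for o in fit.observations]
    ax.plot(x1, y, "o", alpha=0.6)
    ax.set_xlabel("component-1 proportion")
    ax.set_ylabel("response")
    return ax
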