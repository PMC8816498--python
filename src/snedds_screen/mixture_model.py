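"""Scheffé-style mixture regression over the ternary design.

The proof-of-concept statistics fit each response (droplet size,
transmittance, emulsification grade as ordinal-coded 1–5) to polynomial
terms in the mixture fractions: main terms (x_i), interaction terms
(x_i·x_j) and, where needed, quadratic terms (x_i²).  On simplex-
constrained data the full set of main + interaction + quadratic columns is
rank deficient (x_i = x_i² + Σ_j x_i x_j); fitting goes through a
pseudoinverse least-squares solve, which returns the minimum-norm
coefficient vector in that case, and a pseudo-component transform is
available to improve conditioning of constrained regions.

Significance follows the coefficient-plot reading: a term is significant
when its confidence interval excludes zero.  Samples that failed to
emulsify carry no measurements; worst-case imputation fills them so the
model sees the penalty, and externally studentized residuals flag
statistical outliers for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .geometry import TernaryPoint, lattice
from .specs import EmulsionObservation

__all__ = [
    "TermSpec",
    "ModelFit",
    "ContourGrid",
    "WorstCasePolicy",
    "parse_term",
    "standard_terms",
    "build_design_matrix",
    "impute_failed",
    "fit",
    "fit_terms",
    "significance",
    "observed_vs_predicted",
    "flag_outliers",
    "refit_without",
    "contour_grid",
    "pseudo_components",
]

DEFAULT_AXES = ("x1", "x2", "x3")


@dataclass(frozen=True)
class TermSpec:
    """One model term: main ("Mig"), interaction ("Mig*PS8") or quadratic
    ("Mig*Mig")."""

    kind: str
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("main", "interaction", "quadratic"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        n = len(self.factors)
        if self.kind == "main" and n != 1:
            raise ValueError("main term takes exactly one factor")
        if self.kind == "quadratic" and (n != 1 and not (n == 2 and
                                         self.factors[0] == self.factors[1])):
            raise ValueError("quadratic term repeats a single factor")
        if self.kind == "interaction" and (n != 2 or self.factors[0] == self.factors[1]):
            raise ValueError("interaction term takes two distinct factors")

    @property
    def label(self) -> str:
        if self.kind == "main":
            return self.factors[0]
        if self.kind == "quadratic":
            return f"{self.factors[0]}*{self.factors[0]}"
        return "*".join(self.factors)


def parse_term(text: str) -> TermSpec:
    parts = [p.strip() for p in text.split("*")]
    if len(parts) == 1:
        return TermSpec("main", (parts[0],))
    if len(parts) == 2 and parts[0] == parts[1]:
        return TermSpec("quadratic", (parts[0],))
    if len(parts) == 2:
        return TermSpec("interaction", (parts[0], parts[1]))
    raise ValueError(f"cannot parse model term {text!r}")


def standard_terms(
    axes: Sequence[str] = DEFAULT_AXES, quadratic: bool = False
) -> list[TermSpec]:
    """Mains + pairwise interactions, optionally plus quadratics."""
    terms = [TermSpec("main", (a,)) for a in axes]
    terms += [
        TermSpec("interaction", (axes[i], axes[j]))
        for i in range(len(axes))
        for j in range(i + 1, len(axes))
    ]
    if quadratic:
        terms += [TermSpec("quadratic", (a,)) for a in axes]
    return terms


def _points_to_array(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return np.atleast_2d(points)
    return np.array([p.as_array() for p in points])


def build_design_matrix(
    points,
    terms: Sequence[TermSpec],
    axes: Sequence[str] = DEFAULT_AXES,
) -> np.ndarray:
    """Rows = mixtures, columns = model terms (in the given order)."""
    X = _points_to_array(points)
    if X.shape[0] == 0 or len(terms) == 0:
        raise ValueError("need at least one point and one term")
    index = {name: i for i, name in enumerate(axes)}
    cols = []
    for term in terms:
        try:
            idx = [index[f] for f in term.factors]
        except KeyError as exc:
            raise ValueError(f"unknown axis name {exc.args[0]!r}") from None
        if term.kind == "main":
            cols.append(X[:, idx[0]])
        elif term.kind == "quadratic":
            cols.append(X[:, idx[0]] ** 2)
        else:
            cols.append(X[:, idx[0]] * X[:, idx[1]])
    return np.column_stack(cols)


@dataclass(frozen=True)
class WorstCasePolicy:
    """Values substituted for mixtures that never formed an emulsion.

    Defaults are deliberately pessimistic (droplet size far above any
    passing value, turbid transmittance, grade V) so the fitted surface is
    penalized in the failure region.
    """

    size_nm: float = 300.0
    pdi: float = 0.5
    transmittance_pct: float = 70.0
    grade: int = 5


def impute_failed(
    observations: Sequence[EmulsionObservation],
    policy: WorstCasePolicy = WorstCasePolicy(),
) -> list[EmulsionObservation]:
    """Fill N/D records with the worst-case policy; imputed rows flagged."""
    out = []
    for obs in observations:
        if obs.formed_emulsion and obs.is_complete:
            out.append(obs)
        else:
            out.append(
                replace(
                    obs,
                    size_nm=policy.size_nm,
                    pdi=policy.pdi,
                    transmittance_pct=policy.transmittance_pct,
                    grade=policy.grade,
                    imputed=True,
                )
            )
    return out


@dataclass(frozen=True)
class ModelFit:
    """Fitted mixture model with uncertainty and prediction capability."""

    terms: tuple[TermSpec, ...]
    coefficients: np.ndarray
    conf_int: np.ndarray  # (n_terms, 2) at confidence level alpha
    alpha: float
    r_squared: float
    residuals: np.ndarray
    fitted: np.ndarray
    axes: tuple[str, ...]
    response_name: str = "response"
    excluded_ids: tuple[int, ...] = ()
    X: np.ndarray = None
    y: np.ndarray = None

    def predict(self, points) -> np.ndarray:
        return build_design_matrix(points, self.terms, self.axes) @ self.coefficients

    def to_dict(self) -> dict:
        sig = significance(self)
        return {
            "response": self.response_name,
            "alpha": self.alpha,
            "r_squared": self.r_squared,
            "excluded_ids": list(self.excluded_ids),
            "terms": [
                {
                    "term": t.label,
                    "kind": t.kind,
                    "estimate": float(b),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                    "significant": bool(s),
                }
                for t, b, (lo, hi), s in zip(
                    self.terms, self.coefficients, self.conf_int, sig
                )
            ],
        }


def fit(
    X: np.ndarray,
    y: Sequence[float],
    alpha: float = 0.95,
    terms: Optional[Sequence[TermSpec]] = None,
    axes: Sequence[str] = DEFAULT_AXES,
    response_name: str = "response",
    excluded_ids: Sequence[int] = (),
) -> ModelFit:
    """Least squares with t-based confidence intervals at level ``alpha``.

    R² is computed against the mean of y (1 − SSE/SST); a constant
    response has SST = 0 and R² defined as 0.  Fewer rows than columns is
    rejected — drop terms or add mixtures.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match length of y")
    n, p = X.shape
    if n < p:
        raise ValueError(
            f"{n} mixtures cannot identify {p} terms; remove terms or "
            "add design points"
        )
    if not 0 < alpha < 1:
        raise ValueError("confidence level must be in (0, 1)")
    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(resid @ resid)
    r2 = 0.0 if sst <= np.finfo(float).eps * n else max(0.0, 1.0 - sse / sst)
    if terms is None:
        terms = [TermSpec("main", (f"col{i}",)) for i in range(p)]
        axes = tuple(f"col{i}" for i in range(p))
    ci = np.asarray(res.conf_int(alpha=1.0 - alpha))
    return ModelFit(
        terms=tuple(terms),
        coefficients=np.asarray(res.params),
        conf_int=ci,
        alpha=alpha,
        r_squared=r2,
        residuals=resid,
        fitted=fitted,
        axes=tuple(axes),
        response_name=response_name,
        excluded_ids=tuple(excluded_ids),
        X=X,
        y=y,
    )


def fit_terms(
    points,
    y: Sequence[float],
    terms: Sequence[TermSpec],
    axes: Sequence[str] = DEFAULT_AXES,
    alpha: float = 0.95,
    response_name: str = "response",
) -> ModelFit:
    """Convenience: build the design matrix from mixtures and fit."""
    X = build_design_matrix(points, terms, axes)
    return fit(X, y, alpha=alpha, terms=terms, axes=axes, response_name=response_name)


def significance(model: ModelFit) -> list[bool]:
    """A term is significant iff its confidence interval excludes zero."""
    return [bool(lo > 0 or hi < 0) for lo, hi in model.conf_int]


def observed_vs_predicted(model: ModelFit) -> tuple[np.ndarray, float]:
    """(observed, predicted) pairs for the scatter diagnostic, plus R²."""
    pairs = np.column_stack([model.y, model.fitted])
    return pairs, model.r_squared


def flag_outliers(
    model: ModelFit,
    threshold: float = 2.5,
    sample_ids: Optional[Sequence[int]] = None,
) -> list[int]:
    """Rows whose externally studentized residual exceeds ``threshold``.

    Requires more rows than terms + 1, otherwise the leave-one-out
    residual variance is undefined.
    """
    n, p = model.X.shape
    if n <= p + 1:
        raise ValueError("outlier detection needs more rows than terms + 1")
    if not np.isfinite(threshold):
        return []
    influence = OLSInfluence(sm.OLS(model.y, model.X).fit())
    student = np.asarray(influence.resid_studentized_external)
    ids = list(sample_ids) if sample_ids is not None else list(range(1, n + 1))
    return [ids[i] for i in np.flatnonzero(np.abs(student) > threshold)]


def refit_without(
    model: ModelFit,
    exclude_ids: Sequence[int],
    sample_ids: Optional[Sequence[int]] = None,
) -> ModelFit:
    """Refit with the nominated samples excluded from the data."""
    n = model.X.shape[0]
    ids = list(sample_ids) if sample_ids is not None else list(range(1, n + 1))
    keep = [i for i, sid in enumerate(ids) if sid not in set(exclude_ids)]
    return fit(
        model.X[keep],
        model.y[keep],
        alpha=model.alpha,
        terms=model.terms,
        axes=model.axes,
        response_name=model.response_name,
        excluded_ids=tuple(exclude_ids),
    )


@dataclass(frozen=True)
class ContourGrid:
    """Predicted response on a triangular lattice, binned for contouring."""

    points: np.ndarray  # (n, 3) barycentric
    values: np.ndarray
    bins: np.ndarray  # subrange index per point, 0..n_bins-1
    n_bins: int
    boundaries: np.ndarray  # n_bins + 1 edges partitioning [min, max]


def contour_grid(model: ModelFit, resolution: int = 11, n_bins: int = 8) -> ContourGrid:
    """Evaluate the fitted surface on a lattice with ``resolution`` points
    per edge and bin the predictions into equal-width subranges."""
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    pts = lattice(1.0 / (resolution - 1))
    arr = np.array([p.as_array() for p in pts])
    values = model.predict(arr)
    lo, hi = float(values.min()), float(values.max())
    boundaries = np.linspace(lo, hi, n_bins + 1)
    # a numerically constant surface collapses into the first bin
    if hi - lo <= 1e-12 * max(abs(lo), abs(hi), 1.0):
        bins = np.zeros(len(values), dtype=int)
    else:
        bins = np.minimum(
            ((values - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1
        )
    return ContourGrid(points=arr, values=values, bins=bins, n_bins=n_bins,
                       boundaries=boundaries)


def pseudo_components(points, lower_bounds: Sequence[float]) -> np.ndarray:
    """Pseudo-component transform for constrained mixture regions.

    x'_i = (x_i - L_i) / (1 - ΣL); improves conditioning when every
    component has a lower bound L_i > 0.
    """
    X = _points_to_array(points)
    L = np.asarray(lower_bounds, dtype=float)
    span = 1.0 - L.sum()
    if span <= 0:
        raise ValueError("lower bounds must sum to less than 1")
    return (X - L) / span
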