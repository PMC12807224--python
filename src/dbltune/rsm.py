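"""Second-degree polynomial response-surface model over hyperparameters.

The detection-accuracy data relate a scalar accuracy (e.g., mean AUPRC
across datasets) to the hyperparameter values of a full factorial design.
For three factors (x1, x2, x3) the model is

    y = b0 + b1*x1 + b2*x2 + b3*x3
          + b4*x1^2 + b5*x2^2 + b6*x3^2
          + b7*x1*x2 + b8*x1*x3 + b9*x2*x3 + e

fitted by ordinary least squares on the raw (unstandardised) scale.  Terms
are tested with two-sided t-tests; terms not significant at ``alpha`` are
dropped in a single pass and the reduced model is refitted.  The optimum is
the stationary point of the reduced quadratic (gradient = 0), kept only when
the quadratic-form matrix is negative definite (a maximum) and the point
lies inside the level hull; otherwise the best grid point under the fitted
model is returned as a flagged fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignPoint, HyperparameterSpace, full_factorial

__all__ = [
    "AccuracyMatrix",
    "QuadraticModelFit",
    "OptimizationResult",
    "quadratic_terms",
    "build_design_matrix",
    "fit_ols",
    "fit_quadratic",
    "coefficient_tests",
    "prune_and_refit",
    "fit_from_coefficients",
    "predict",
    "stationary_point",
]


@dataclass
class AccuracyMatrix:
    """Detection-accuracy data: one response value per design point.

    For the canonical scDblFinder pipeline this is the 125 x 4 matrix whose
    first three columns are nf, pc, depth and whose last column is the
    (averaged) AUPRC.
    """

    points: List[DesignPoint]
    response: np.ndarray
    response_name: str = "auprc"
    dataset_id: str = "aggregate"

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if len(self.points) != self.response.size:
            raise ValueError("one response value per design point required")
        if len(self.points) == 0:
            raise ValueError("accuracy matrix must have at least one row")
        names = tuple(self.points[0].keys())
        for p in self.points:
            if tuple(p.keys()) != names:
                raise ValueError("all design points must share factor names")
        keys = [tuple(p[n] for n in names) for p in self.points]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate design points in accuracy matrix")
        if not np.isfinite(self.response).all():
            raise ValueError("responses must be finite")

    @property
    def factor_names(self) -> List[str]:
        return list(self.points[0].keys())

    @property
    def n(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points)
        df[self.response_name] = self.response
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response_name: Optional[str] = None,
        dataset_id: str = "aggregate",
    ) -> "AccuracyMatrix":
        """Build from a data frame whose last column (by default) is the response."""
        if response_name is None:
            response_name = df.columns[-1]
        factors = [c for c in df.columns if c != response_name]
        points = [
            {f: float(row[f]) for f in factors} for _, row in df.iterrows()
        ]
        return cls(points, df[response_name].to_numpy(float), response_name, dataset_id)

    def transformed(self, func, suffix: str) -> "AccuracyMatrix":
        return AccuracyMatrix(
            self.points,
            func(self.response),
            response_name=f"{suffix}({self.response_name})",
            dataset_id=self.dataset_id,
        )


def quadratic_terms(factor_names: Sequence[str]) -> List[str]:
    """Canonical term order: intercept, linear, quadratic, then interactions."""
    names = list(factor_names)
    terms = ["intercept"] + names
    terms += [f"{n}^2" for n in names]
    terms += [
        f"{a}:{b}" for i, a in enumerate(names) for b in names[i + 1 :]
    ]
    return terms


def _term_value(term: str, point: DesignPoint) -> float:
    if term == "intercept":
        return 1.0
    if term.endswith("^2"):
        return float(point[term[:-2]]) ** 2
    if ":" in term:
        a, b = term.split(":")
        return float(point[a]) * float(point[b])
    return float(point[term])


def build_design_matrix(
    points: Sequence[DesignPoint],
    factor_names: Optional[Sequence[str]] = None,
    terms: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Model matrix for the second-degree polynomial, raw scale.

    Columns follow :func:`quadratic_terms` order unless an explicit ``terms``
    subset is given (used when refitting a reduced model).
    """
    if not points:
        raise ValueError("need at least one design point")
    if factor_names is None:
        factor_names = list(points[0].keys())
    missing = [f for f in factor_names if f not in points[0]]
    if missing:
        raise KeyError(f"design points lack factors {missing}")
    if terms is None:
        terms = quadratic_terms(factor_names)
    terms = list(terms)
    X = np.empty((len(points), len(terms)))
    for i, p in enumerate(points):
        for j, t in enumerate(terms):
            X[i, j] = _term_value(t, p)
    return X, terms


@dataclass
class QuadraticModelFit:
    """An OLS fit of the quadratic response surface (full or reduced).

    ``params`` etc. are keyed by term name.  ``retained_terms`` records which
    terms survived significance pruning (equal to ``terms`` for a full fit).
    Fits constructed directly from published coefficients carry no residuals.
    """

    factor_names: List[str]
    terms: List[str]
    params: Dict[str, float]
    bse: Dict[str, float]
    tvalues: Dict[str, float]
    pvalues: Dict[str, float]
    residuals: Optional[np.ndarray]
    fitted: Optional[np.ndarray]
    sigma2: Optional[float]
    r_squared: Optional[float]
    df_resid: Optional[int]
    retained_terms: Tuple[str, ...]
    flags: Dict[str, bool] = field(default_factory=dict)
    response_name: str = "auprc"

    @property
    def n_obs(self) -> Optional[int]:
        return None if self.residuals is None else int(self.residuals.size)

    def coefficient(self, term: str) -> float:
        return self.params.get(term, 0.0)


def _collinear_terms(X: np.ndarray, terms: Sequence[str]) -> List[str]:
    # pivoted QR: pivots past the numerical rank are the collinear columns
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [terms[j] for j in sorted(piv[rank:])]


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    terms: Sequence[str],
    factor_names: Sequence[str],
    response_name: str = "auprc",
) -> QuadraticModelFit:
    """Ordinary least squares via statsmodels (QR/pinv, not normal equations).

    Standard errors come from the unscaled covariance diagonal times the
    residual variance RSS / df_resid.  A zero standard error (exactly
    collinear-free but noise-free data) yields p = 0 with a degeneracy flag.
    """
    y = np.asarray(y, dtype=float)
    terms = list(terms)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than terms ({k})")
    if np.linalg.matrix_rank(X) < k:
        bad = _collinear_terms(X, terms)
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    res = sm.OLS(y, X).fit()
    params = dict(zip(terms, res.params))
    bse = dict(zip(terms, res.bse))
    df_resid = int(res.df_resid)
    tvals: Dict[str, float] = {}
    pvals: Dict[str, float] = {}
    degenerate = False
    for t in terms:
        se = bse[t]
        if se == 0 or not math.isfinite(se):
            degenerate = True
            tvals[t] = math.inf if params[t] != 0 else 0.0
            pvals[t] = 0.0 if params[t] != 0 else 1.0
        else:
            tv = params[t] / se
            tvals[t] = tv
            pvals[t] = 2 * stats.t.sf(abs(tv), df_resid)
    resid = np.asarray(res.resid, dtype=float)
    rss = float(resid @ resid)
    fit = QuadraticModelFit(
        factor_names=list(factor_names),
        terms=terms,
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        residuals=resid,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        sigma2=rss / df_resid,
        r_squared=float(res.rsquared) if y.var() > 0 else 1.0,
        df_resid=df_resid,
        retained_terms=tuple(terms),
        flags={"degenerate_se": degenerate},
        response_name=response_name,
    )
    return fit


def fit_quadratic(data: AccuracyMatrix) -> QuadraticModelFit:
    """Fit the full 10-term quadratic model to detection-accuracy data."""
    X, terms = build_design_matrix(data.points, data.factor_names)
    return fit_ols(X, data.response, terms, data.factor_names, data.response_name)


def coefficient_tests(fit: QuadraticModelFit) -> Dict[str, float]:
    """Two-sided t-test p-values per fitted term (beta / SE, df = df_resid)."""
    if fit.df_resid is None or fit.df_resid < 1:
        raise ValueError("fit has no residual degrees of freedom")
    return dict(fit.pvalues)


def prune_and_refit(
    data: AccuracyMatrix,
    alpha: float = 0.01,
    iterative: bool = False,
) -> QuadraticModelFit:
    """Fit the full quadratic, drop insignificant terms, refit once.

    The default is single-pass: significance is judged in the one full fit,
    the intercept is always retained, and the reduced model is refitted on
    the retained terms only.  ``iterative=True`` switches to backward
    elimination (repeatedly dropping the least significant term at
    ``alpha``), which is not the default behaviour.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    full = fit_quadratic(data)

    def significant(fit: QuadraticModelFit) -> List[str]:
        return [
            t
            for t in fit.terms
            if t == "intercept" or fit.pvalues[t] < alpha
        ]

    if not iterative:
        retained = significant(full)
    else:
        retained = list(full.terms)
        current = full
        while True:
            candidates = {
                t: current.pvalues[t]
                for t in current.terms
                if t != "intercept" and current.pvalues[t] >= alpha
            }
            if not candidates:
                break
            worst = max(candidates, key=candidates.get)
            retained = [t for t in current.terms if t != worst]
            X, _ = build_design_matrix(data.points, data.factor_names, retained)
            current = fit_ols(
                X, data.response, retained, data.factor_names, data.response_name
            )
        retained = list(current.terms)

    flat = retained == ["intercept"]
    if set(retained) == set(full.terms):
        reduced = full
    else:
        X, _ = build_design_matrix(data.points, data.factor_names, retained)
        reduced = fit_ols(
            X, data.response, retained, data.factor_names, data.response_name
        )
    reduced.retained_terms = tuple(retained)
    reduced.flags["flat_surface"] = flat
    return reduced


def fit_from_coefficients(
    coefficients: Dict[str, float],
    factor_names: Sequence[str],
    response_name: str = "auprc",
) -> QuadraticModelFit:
    """Wrap explicit polynomial coefficients (e.g., published estimates).

    The resulting fit supports :func:`predict` and :func:`stationary_point`
    but carries no residuals or inference.
    """
    terms = [t for t in quadratic_terms(factor_names) if t in coefficients]
    extra = set(coefficients) - set(terms)
    if extra:
        raise KeyError(f"unknown terms for factors {list(factor_names)}: {extra}")
    return QuadraticModelFit(
        factor_names=list(factor_names),
        terms=terms,
        params={t: float(coefficients[t]) for t in terms},
        bse={},
        tvalues={},
        pvalues={},
        residuals=None,
        fitted=None,
        sigma2=None,
        r_squared=None,
        df_resid=None,
        retained_terms=tuple(terms),
    )


def predict(fit: QuadraticModelFit, point: DesignPoint) -> float:
    """Evaluate the retained polynomial at one design point."""
    total = 0.0
    for t in fit.retained_terms:
        total += fit.params.get(t, 0.0) * _term_value(t, point)
    return total


@dataclass
class OptimizationResult:
    """Outcome of maximizing the fitted quadratic over the level hull.

    ``stationary`` holds the unrounded gradient-zero coordinates of the
    active (retained) factors.  ``optimum`` is the actionable configuration:
    active factors rounded to the nearest integer and clamped to the hull,
    inactive factors pinned to their defaults.  When the stationary point is
    not an interior maximum, the best full-factorial grid point under the
    fitted model is substituted and ``fallback_used`` is set.
    """

    stationary: Dict[str, float]
    curvature: str  # maximum | minimum | saddle | degenerate
    optimum: Dict[str, float]
    inactive_factors: Dict[str, float]
    objective_at_optimum: float
    fallback_used: bool = False

    @property
    def active_factors(self) -> List[str]:
        return list(self.stationary.keys())


def _round_half_away(x: float) -> float:
    return math.copysign(math.floor(abs(x) + 0.5), x)


def _active_factors(fit: QuadraticModelFit) -> List[str]:
    active = []
    for name in fit.factor_names:
        for t in fit.retained_terms:
            if t == "intercept":
                continue
            parts = t[:-2].split(":") if t.endswith("^2") else t.split(":")
            if name in parts:
                active.append(name)
                break
    return active


def stationary_point(
    fit: QuadraticModelFit, space: HyperparameterSpace
) -> OptimizationResult:
    """Solve grad(quadratic) = 0 over the retained factors and classify it.

    Writes the retained model as b0 + b'x + x'Ax with A symmetric (diagonal
    = quadratic coefficients, off-diagonal = interaction coefficient / 2)
    and solves 2Ax + b = 0.  Curvature follows the eigenvalues of A: all
    negative = maximum, all positive = minimum, mixed = saddle, any (near)
    zero = degenerate.  Interior maxima are rounded to the nearest integers
    and clamped to the level hull; anything else falls back to the design
    grid argmax of the fitted model.  Factors absent from the retained terms
    are reported inactive and set to their defaults.
    """
    active = _active_factors(fit)
    quad_terms = [t for t in fit.retained_terms if t.endswith("^2") or ":" in t]
    if not quad_terms:
        raise ValueError(
            "no quadratic or interaction terms retained; the surface has no "
            "stationary point — use a grid search over the design instead"
        )
    d = len(active)
    A = np.zeros((d, d))
    b = np.zeros(d)
    idx = {name: i for i, name in enumerate(active)}
    for t in fit.retained_terms:
        c = fit.params[t]
        if t == "intercept":
            continue
        if t.endswith("^2"):
            i = idx[t[:-2]]
            A[i, i] = c
        elif ":" in t:
            a_name, b_name = t.split(":")
            i, j = idx[a_name], idx[b_name]
            A[i, j] += c / 2.0
            A[j, i] += c / 2.0
        else:
            b[idx[t]] = c

    eigvals = np.linalg.eigvalsh(A)
    scale = max(1.0, float(np.abs(eigvals).max()))
    tol = 1e-12 * scale
    if np.any(np.abs(eigvals) <= tol):
        curvature = "degenerate"
    elif np.all(eigvals < 0):
        curvature = "maximum"
    elif np.all(eigvals > 0):
        curvature = "minimum"
    else:
        curvature = "saddle"

    inactive = {
        name: space.factor(name).default
        for name in space.factor_names
        if name not in active
    }

    if curvature != "degenerate":
        x_star = np.linalg.solve(2.0 * A, -b)
        stationary = {name: float(x_star[idx[name]]) for name in active}
    else:
        stationary = {name: math.nan for name in active}

    in_hull = curvature == "maximum" and all(
        space.bounds(name)[0] <= stationary[name] <= space.bounds(name)[1]
        for name in active
    )

    if in_hull:
        optimum = {}
        for name in active:
            lo, hi = space.bounds(name)
            optimum[name] = float(min(max(_round_half_away(stationary[name]), lo), hi))
        fallback = False
    else:
        # best design grid point under the fitted model (ties -> first)
        grid = full_factorial(space)
        preds = [predict(fit, p) for p in grid]
        best = grid[int(np.argmax(preds))]
        optimum = {name: float(best[name]) for name in active}
        fallback = True

    full_point = dict(optimum)
    full_point.update(inactive)
    return OptimizationResult(
        stationary=stationary,
        curvature=curvature,
        optimum=optimum,
        inactive_factors=inactive,
        objective_at_optimum=predict(fit, full_point),
        fallback_used=fallback,
    )
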