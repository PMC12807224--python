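"""Model diagnostics for the fitted response surface.

Residual-vs-fitted export, the Breusch-Pagan heteroscedasticity test, and a
sensitivity analysis that refits the model after log and square-root
transformations of the response to check that the significant terms and the
rounded optimum are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import HyperparameterSpace
from .rsm import (
    AccuracyMatrix,
    OptimizationResult,
    QuadraticModelFit,
    build_design_matrix,
    prune_and_refit,
    stationary_point,
)

__all__ = [
    "BPTestResult",
    "SensitivityReport",
    "residuals_vs_fitted",
    "breusch_pagan",
    "sensitivity_analysis",
]


def residuals_vs_fitted(fit: QuadraticModelFit) -> pd.DataFrame:
    """(fitted, residual) pairs for the residual plot, in observation order."""
    if fit.residuals is None or fit.fitted is None:
        raise ValueError("fit carries no residuals (coefficients-only fit)")
    return pd.DataFrame({"fitted": fit.fitted, "residual": fit.residuals})


@dataclass
class BPTestResult:
    """Breusch-Pagan Lagrange-multiplier test for non-constant variance."""

    lm_statistic: float
    df: int
    p_value: float
    variant: str
    degenerate: bool = False
    aux_r_squared: float = 0.0


def breusch_pagan(
    data: AccuracyMatrix,
    fit: QuadraticModelFit,
    variant: str = "classic",
) -> BPTestResult:
    """Test the fitted model's residuals for heteroscedasticity.

    The auxiliary regression uses the *retained* model's non-intercept
    regressors (the regressors of the fit being diagnosed).  The default
    ``classic`` variant regresses the squared residuals, scaled by their
    mean, on those regressors and refers LM = n * R^2_aux to a chi-square
    with df = number of auxiliary regressors.  The ``studentized`` variant
    uses the normality-calibrated statistic LM = ESS / 2 of the same
    auxiliary regression, referred to the same chi-square.  Both are
    monotone in the auxiliary R^2, so they order datasets identically.
    """
    if variant not in ("classic", "studentized"):
        raise ValueError("variant must be 'classic' or 'studentized'")
    if fit.residuals is None:
        raise ValueError("fit carries no residuals")
    if fit.df_resid is None or fit.df_resid < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    resid = fit.residuals
    n = resid.size
    aux_terms = [t for t in fit.retained_terms if t != "intercept"]
    if not aux_terms:
        raise ValueError("no non-intercept regressors to test against")
    Z, _ = build_design_matrix(data.points, fit.factor_names, aux_terms)
    df = len(aux_terms)

    e2 = resid**2
    mean_e2 = e2.mean()
    # degenerate if the residuals are numerically zero relative to the
    # fitted scale (a noise-free fit), or constant relative to their own
    # scale; plain absolute tolerances would flag any small-residual fit
    fitted_scale = max(1.0, float(np.abs(fit.fitted).max())) if fit.fitted is not None else 1.0
    if (
        mean_e2 == 0
        or np.sqrt(mean_e2) <= 1e-12 * fitted_scale
        or np.ptp(e2) <= 1e-10 * mean_e2
    ):
        return BPTestResult(0.0, df, 1.0, variant, degenerate=True)

    g = e2 / mean_e2
    Zc = np.column_stack([np.ones(n), Z])
    coef, *_ = np.linalg.lstsq(Zc, g, rcond=None)
    g_hat = Zc @ coef
    tss = float(((g - g.mean()) ** 2).sum())
    ess = float(((g_hat - g.mean()) ** 2).sum())
    r2 = ess / tss if tss > 0 else 0.0

    if variant == "classic":
        lm = n * r2
    else:
        lm = ess / 2.0
    p = float(stats.chi2.sf(lm, df))
    return BPTestResult(float(lm), df, p, variant, aux_r_squared=r2)


@dataclass
class SensitivityReport:
    """Pruning + optimization results under response transformations.

    One entry per transform in {identity, log, sqrt}; transforms requiring
    positive responses are skipped (and flagged) when any response <= 0.
    Agreement flags compare every completed transform against identity.
    """

    retained_terms: Dict[str, Tuple[str, ...]]
    optima: Dict[str, Dict[str, float]]
    fits: Dict[str, QuadraticModelFit]
    optimizations: Dict[str, OptimizationResult]
    skipped: Dict[str, str] = field(default_factory=dict)

    @property
    def terms_agree(self) -> bool:
        """Exact retained-term agreement.  Stricter than ``factors_agree``:
        a monotone transform bends an exactly quadratic surface, so at very
        low noise extra polynomial terms can absorb the lack of fit without
        changing which hyperparameters matter."""
        ref = self.retained_terms["identity"]
        return all(v == ref for v in self.retained_terms.values())

    @property
    def factors_agree(self) -> bool:
        """Do all transforms agree on which hyperparameters are significant?"""
        ref = sorted(self.optimizations["identity"].active_factors)
        return all(
            sorted(o.active_factors) == ref for o in self.optimizations.values()
        )

    @property
    def optima_agree(self) -> bool:
        ref = self.optima["identity"]
        return all(v == ref for v in self.optima.values())


# transform -> (function, admissibility predicate over the response vector)
_TRANSFORMS = {
    "identity": (lambda y: y, lambda y: True),
    "log": (np.log, lambda y: bool((y > 0).all())),
    "sqrt": (np.sqrt, lambda y: bool((y >= 0).all())),
}


def sensitivity_analysis(
    data: AccuracyMatrix,
    space: HyperparameterSpace,
    alpha: float = 0.01,
) -> SensitivityReport:
    """Re-run pruning and optimization on log/sqrt-transformed responses.

    If the model is robust, the significant hyperparameters and their
    rounded optima should be unchanged by a monotone transformation of the
    response; disagreement suggests the quadratic fit (or its error
    structure) is fragile.
    """
    retained: Dict[str, Tuple[str, ...]] = {}
    optima: Dict[str, Dict[str, float]] = {}
    fits: Dict[str, QuadraticModelFit] = {}
    optimizations: Dict[str, OptimizationResult] = {}
    skipped: Dict[str, str] = {}

    for name, (func, admissible) in _TRANSFORMS.items():
        if not admissible(data.response):
            skipped[name] = "responses violate the transform's positivity requirement"
            continue
        tdata = (
            data if name == "identity" else data.transformed(func, name)
        )
        fit = prune_and_refit(tdata, alpha=alpha)
        opt = stationary_point(fit, space)
        retained[name] = fit.retained_terms
        full_opt = dict(opt.optimum)
        full_opt.update(opt.inactive_factors)
        optima[name] = full_opt
        fits[name] = fit
        optimizations[name] = opt

    return SensitivityReport(
        retained_terms=retained,
        optima=optima,
        fits=fits,
        optimizations=optimizations,
        skipped=skipped,
    )
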