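"""Diagnose a fitted response surface.

Runs the Breusch-Pagan heteroscedasticity test on the pruned fit and the
log/sqrt sensitivity analysis of the optimum.
"""

import dbltune as dt
from dbltune.diagnostics import breusch_pagan, residuals_vs_fitted, sensitivity_analysis

space = dt.scdblfinder_space()
matrices = dt.simulate_response_surface(
    space, dt.SCDBLFINDER_REDUCED_COEFFS, noise_sd=1e-4, n_datasets=16, seed=0
)
accuracy = dt.aggregate(matrices)
fit = dt.prune_and_refit(accuracy, alpha=0.01)

pairs = residuals_vs_fitted(fit)
print(f"residual spread: sd = {pairs['residual'].std():.2e} over {len(pairs)} points")

bp = breusch_pagan(accuracy, fit)
print(f"Breusch-Pagan ({bp.variant}): LM = {bp.lm_statistic:.3f}, "
      f"df = {bp.df}, p = {bp.p_value:.3f}")
# The errors here are homoscedastic by construction, so any p-value is a
# draw from the null; p below alpha would suggest non-constant variance.

sens = sensitivity_analysis(accuracy, space, alpha=0.01)
print(f"significant factors agree across transforms: {sens.factors_agree}")
print(f"rounded optima agree across transforms: {sens.optima_agree}")
for name, opt in sens.optima.items():
    print(f"  {name:8s} -> {opt}")
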