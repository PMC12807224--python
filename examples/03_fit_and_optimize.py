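"""Fit the quadratic response surface and solve for the optimum.

Generates detection-accuracy data from the packaged published surface (plus
noise), averages replicates, prunes insignificant terms at alpha = 0.01,
and locates the stationary point analytically.
"""

import dbltune as dt

space = dt.scdblfinder_space()
matrices = dt.simulate_response_surface(
    space, dt.SCDBLFINDER_REDUCED_COEFFS, noise_sd=1e-4, n_datasets=16, seed=0
)
accuracy = dt.aggregate(matrices)

fit = dt.prune_and_refit(accuracy, alpha=0.01)
print(f"retained terms: {list(fit.retained_terms)}")
print(f"R^2 = {fit.r_squared:.6f}")

opt = dt.stationary_point(fit, space)
print(f"curvature: {opt.curvature}")
print(f"stationary point: { {k: round(v, 2) for k, v in opt.stationary.items()} }")
print(f"rounded optimum:  {opt.optimum}, inactive -> defaults: {opt.inactive_factors}")
print(f"predicted accuracy at the optimum: {opt.objective_at_optimum:.4f}")
# depth carries no signal in the generating surface, so pruning drops all of
# its terms and the optimizer pins it to the default of 4.
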