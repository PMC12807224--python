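# Methods

## The problem

Droplet-based scRNA-seq occasionally captures two cells in one reaction
volume. These doublets look like cells but are mixtures, and they distort
clustering, trajectory and differential-expression analyses downstream.
Computational doublet detectors assign each droplet a doublet score, but
their accuracy depends on hyperparameters whose shipped defaults are not
optimal for every dataset. `dbltune` implements a tuning strategy for such
detectors: treat detection accuracy as a response surface over the
hyperparameters, collect the surface on a full factorial design, and find
the optimum analytically.

## The tuning model

For three hyperparameters — here scDblFinder's `nf` (number of highly
variable genes), `pc` (number of principal components) and `depth` (maximum
gradient-boosting tree depth) — accuracy is modelled as a second-degree
polynomial

    y = b0 + b1·nf + b2·pc + b3·depth
        + b4·nf² + b5·pc² + b6·depth²
        + b7·nf·pc + b8·nf·depth + b9·pc·depth + e

fitted by ordinary least squares on the raw hyperparameter scale to the
detection-accuracy data: one row per design point, the response being the
accuracy metric (mean AUPRC across datasets in the canonical pipeline; TPR
or TNR at a user-specified doublet rate are alternatives). The quadratic is
the classical response-surface compromise: it captures main effects,
curvature and pairwise interactions while staying interpretable; higher
degrees invite overfitting on a 125-point design.

Terms are tested with two-sided t-tests (t = b̂/SE, df = n − p). Pruning is
**single-pass**: significance is judged once in the full 10-term fit at
`alpha` (default 0.01), the intercept is always retained, and the reduced
model is refitted on the surviving terms. Backward elimination is available
behind `iterative=True` but is not the default. No effect hierarchy is
enforced — a quadratic term may survive without its linear term, because the
procedure never needed such a rule.

The optimum solves ∇(b0 + bᵀx + xᵀAx) = 0, i.e. 2Ax = −b, where A is the
symmetric quadratic-form matrix (diagonal = quadratic coefficients,
off-diagonal = half the interaction coefficients) over the **active**
factors — those appearing in any retained term. The stationary point is
accepted only when A is negative definite (all eigenvalues < 0, a maximum;
eigenvalues are compared against a relative tolerance of 1e-12 of the
largest magnitude, below which the surface is classified degenerate) *and*
the point lies inside the level hull. It is then rounded to the nearest
integer (half away from zero) and clamped to the hull — hyperparameters here
are counts. In every other case (saddle, minimum, degenerate, out of hull)
the best full-factorial grid point under the fitted model is returned with
`fallback_used=True`: the tool must always hand back an actionable
configuration. Factors with no retained terms are pinned to their defaults
and reported in `inactive_factors`.

On the packaged published reduced coefficients
(0.5444 + 1.016e-5·nf + 1.336e-3·pc − 3.760e-9·nf² − 3.484e-5·pc²) this
machinery gives the stationary point nf = 1351.06, pc = 19.17, a maximum,
rounding to nf = 1351, pc = 19, with depth inactive at its default of 4.

## Metrics

AUPRC uses the average-precision convention — the sum over positive-going
recall increments of the precision at that threshold, tied scores collapsed
to one threshold — rather than trapezoidal interpolation, so values are
reproducible bit for bit. Binary calls at a doublet rate r call exactly
⌈n·r⌉ droplets (the ceiling guarantees at least one call at tiny rates),
ties at the cutoff broken by input order for determinism. Relative
improvement is 100·(opt − def)/def, i.e. percent of the baseline, not
percentage points. Rank inserts a value among the design-point accuracies
counting only strictly greater values, so a tie with the grid maximum ranks
first; inside a tuning report the rank is additionally capped at the design
size.

## Synthetic data

`simulate_counts` draws a genes × droplets matrix from a gamma-Poisson
(negative binomial) model: a shared log-normal base profile of gene means,
per-cell-type log-normal perturbations (sd `type_spread`, default 1.0),
profiles rescaled so every type has the same expected library size (default
2000 counts — a typical shallow droplet depth at the scaled-down matrix
sizes used here), and NB size `dispersion` (default θ = 2, moderately
overdispersed). Each planted doublet is the element-wise sum of two
independently simulated singlets (types drawn with replacement), binomially
thinned back to the singlet library size because a doublet still occupies a
single reaction volume. The doublet count is exactly
round(n_droplets × doublet_rate) and columns are permuted. All randomness
flows from one integer seed through one `numpy` generator; identical
parameters give byte-identical output. `table2_mini_params` maps the
packaged benchmark-dataset characteristics to these settings at one tenth
the droplet and gene counts with the true doublet rates.

What the simulator does **not** emulate: ambient RNA, empty droplets, UMI
chemistry and saturation, batch effects, or realistic cell-type hierarchy.
Passing tests therefore demonstrate that the tuning machinery is correct and
that the pipeline behaves sensibly on data with the right coarse structure
(counts, overdispersion, mixtures, summed doublets) — not that any specific
detector attains any specific accuracy on real tissue.

## The surrogate detector

`surrogate_detect` is a deliberately small artificial-doublet classifier in
the style of scDblFinder, not a re-implementation of it: (1) build
artificial doublets by summing two random real droplets (default one per
real droplet); (2) normalise (library-size scaling to the median depth, then
log1p), drop all-zero genes, keep the top-`nf` genes by variance; (3) PCA to
`pc` components over the union of real and artificial units; (4) for each
unit, the fraction of artificial doublets among its k nearest neighbours for
each k in {5, 10, 20}; (5) stratified 5-fold cross-validation of an xgboost
classifier (max tree depth = `depth`, 50 rounds, learning rate 0.3) on
real-vs-artificial, returning each real droplet's out-of-fold probability of
being artificial as its doublet score. Ground-truth labels are never read.
Its purpose is a real detector whose accuracy genuinely varies with all
three tuned hyperparameters so the pipeline can be exercised end to end;
tests verify the hyperparameters are live. The thinning of artificial
doublets' library size is not modelled (real droplets are summed without
rescaling), which is one of several respects in which the surrogate is a
skeleton rather than a clone.

`simulate_response_surface` generates detection-accuracy data directly from
a known quadratic plus Gaussian noise — the generative inverse of the
fitting step — which is what the recovery and calibration tests use.

## Diagnostics

`breusch_pagan` regresses the squared residuals (scaled by their mean) of
the fit being diagnosed on that fit's own non-intercept regressors. The
default `classic` variant refers LM = n·R²_aux to χ²(df = number of
auxiliary regressors); the `studentized` variant uses the
normality-calibrated ESS/2 of the same auxiliary regression. Both are
monotone in the auxiliary R², so they order datasets identically. The test
is reported degenerate (LM = 0, p = 1) when residuals are numerically zero
relative to the fitted scale or their squares are constant relative to
their own scale.

`sensitivity_analysis` reruns prune-and-optimize on log- and
sqrt-transformed responses (each applied only when the response satisfies
its positivity requirement). Agreement is judged at two levels: the exact
retained-term sets (`terms_agree`) and the significant *factors* plus the
rounded optima (`factors_agree`, `optima_agree`). The factor-level
comparison is the meaningful robustness statement: a monotone transform
bends an exactly quadratic surface, so at very low noise additional
polynomial terms can become significant purely to absorb that lack of fit,
without changing which hyperparameters matter or where the rounded optimum
lands.

## Numerical choices

- OLS by orthogonal decomposition (statsmodels) on raw-scale regressors;
  nf² reaches 6.25e6 but the design is well-conditioned in double precision,
  verified against a normal-equations oracle to 1e-6 relative.
- Zero standard errors (noise-free data) yield p = 0 for nonzero estimates
  and p = 1 at t = 0, with a `degenerate_se` flag.
- Enumeration order of the factorial is lexicographic, first factor
  slowest; grid-argmax ties resolve to the first point in that order.
- Rank-deficient model matrices raise an error naming the collinear terms
  (detected by pivoted QR); two-level factors are the common cause, since a
  square is then collinear with the intercept and the linear term.
- Floats are serialized at full round-trip precision in CSV/JSON.

## Problem sizes in the test suite

The suite runs entirely on synthetic data: oracle comparisons at n ≤ 80,
type-I calibration at 500–1000 replicates of the 125-point design, detector
checks on an 800-droplet × 1200-gene two-type dataset, and end-to-end tunes
on 27-point designs with ~150–200-droplet datasets. These sizes make the
whole suite run in well under a minute while leaving every statistical
assertion at conventional Monte-Carlo resolution.

## Known limitations

- Only full factorial designs are provided; fractional factorial and
  space-filling designs are out of scope.
- The quadratic is fitted on raw hyperparameter scales; no standardization
  or regularization is offered, and degrees above two are intentionally
  unsupported.
- No heteroscedasticity remedies (WLS, sandwich errors) — the diagnostics
  only detect and characterize.
- The surrogate detector is a testbed, not a production doublet caller;
  to tune a real method, wrap it as a `Detector` callable and pass it to
  `evaluate_design`/`tune`.
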