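"""Synthetic scRNA-seq data with planted doublets, and a surrogate detector.

The simulator draws multi-cell-type count matrices from a gamma-Poisson
(negative binomial) model and plants doublets by summing the counts of two
independently simulated singlets, followed by binomial thinning back to a
singlet-like library size (a doublet occupies one reaction volume, so its
sequencing depth does not double).

The surrogate detector mirrors the architecture of artificial-doublet
classifiers such as scDblFinder: generate artificial doublets, select highly
variable genes, project to principal components, compute
artificial-neighbour fractions at several neighbourhood sizes, and
cross-validate a gradient-boosted tree classifier (real vs artificial) to
obtain an out-of-fold doublet score per real droplet.  It exposes the three
hyperparameters the tuning framework studies — nf (number of highly variable
genes), pc (number of principal components) and depth (maximum tree depth) —
and its accuracy genuinely responds to all three, which is what the tuning
pipeline needs; it does not attempt to reproduce any specific tool's scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from .design import HyperparameterSpace, full_factorial
from .metrics import LabeledScores
from .rsm import AccuracyMatrix, build_design_matrix, quadratic_terms

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "SyntheticDataset",
    "SurrogateConfig",
    "simulate_counts",
    "surrogate_detect",
    "simulate_response_surface",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for one synthetic dataset.

    ``dispersion`` is the negative-binomial size parameter theta
    (var = mu + mu^2 / theta; smaller theta = noisier counts).
    ``library_size`` is the expected total count per singlet.
    ``type_spread`` scales how far apart cell-type expression profiles are
    (log-normal sd of the per-type perturbation of each gene mean); larger
    values give better-separated cell types.
    """

    n_droplets: int = 1000
    n_genes: int = 500
    n_cell_types: int = 3
    doublet_rate: float = 0.1
    dispersion: float = 2.0
    seed: int = 0
    library_size: float = 2000.0
    type_spread: float = 1.0

    def __post_init__(self) -> None:
        if self.n_droplets < 20:
            raise ValueError("need at least 20 droplets")
        if self.n_genes < 50:
            raise ValueError("need at least 50 genes")
        if not 0 < self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in (0, 1)")
        if self.n_cell_types < 1:
            raise ValueError("need at least one cell type")
        if self.dispersion <= 0 or self.library_size <= 0:
            raise ValueError("dispersion and library_size must be positive")


@dataclass
class SyntheticDataset:
    """A genes x droplets count matrix with ground-truth doublet labels."""

    counts: np.ndarray  # (n_genes, n_droplets), nonnegative integers
    labels: np.ndarray  # (n_droplets,), 1 = planted doublet
    params: SimulationParams
    cell_types: Optional[np.ndarray] = None  # singlet type (-1 for doublets)

    @property
    def n_genes(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_droplets(self) -> int:
        return int(self.counts.shape[1])

    @property
    def doublet_rate(self) -> float:
        return float(self.labels.mean())


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and NB size ``theta``."""
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def simulate_counts(params: SimulationParams) -> SyntheticDataset:
    """Simulate a count matrix with planted doublets.

    Per-cell-type gene-mean profiles are log-normal perturbations of a shared
    base profile, rescaled so every type has the same expected library size.
    Singlets are negative-binomial draws from their type profile; each
    doublet is the element-wise sum of two independently simulated singlets
    (types drawn with replacement) binomially thinned back to the singlet
    library size.  The number of planted doublets is exactly
    ``round(n_droplets * doublet_rate)`` and columns are randomly permuted so
    doublets are not positionally clustered.  Identical params (including
    seed) give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n, g, t = params.n_droplets, params.n_genes, params.n_cell_types

    n_doublets = int(round(n * params.doublet_rate))
    if n_doublets == 0:
        raise ValueError(
            f"doublet_rate {params.doublet_rate} yields 0 doublets at "
            f"n_droplets={n}; increase n_droplets or the rate"
        )
    n_singlets = n - n_doublets

    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    profiles = np.empty((t, g))
    for ct in range(t):
        perturb = rng.lognormal(mean=0.0, sigma=params.type_spread, size=g)
        prof = base * perturb
        profiles[ct] = prof / prof.sum() * params.library_size

    singlet_types = rng.integers(0, t, size=n_singlets)
    counts = np.empty((g, n), dtype=np.int64)
    for i, ct in enumerate(singlet_types):
        counts[:, i] = _nb_draw(rng, profiles[ct], params.dispersion)

    # doublets: sum of two fresh singlets, thinned to one droplet's depth
    for j in range(n_doublets):
        t1, t2 = rng.integers(0, t, size=2)
        summed = _nb_draw(rng, profiles[t1], params.dispersion) + _nb_draw(
            rng, profiles[t2], params.dispersion
        )
        total = summed.sum()
        p = min(1.0, params.library_size / total) if total > 0 else 1.0
        counts[:, n_singlets + j] = rng.binomial(summed, p)

    labels = np.concatenate(
        [np.zeros(n_singlets, dtype=int), np.ones(n_doublets, dtype=int)]
    )
    types = np.concatenate([singlet_types, np.full(n_doublets, -1)])

    perm = rng.permutation(n)
    return SyntheticDataset(
        counts=counts[:, perm],
        labels=labels[perm],
        params=params,
        cell_types=types[perm],
    )


@dataclass
class SurrogateConfig:
    """Hyperparameters of the surrogate doublet detector.

    nf, pc and depth are the three tuned hyperparameters.  The remaining
    settings (artificial-doublet count, neighbourhood sizes, folds, boosting
    rounds) are held fixed during tuning; ``n_artificial=None`` means one
    artificial doublet per real droplet.
    """

    nf: int = 1000
    pc: int = 10
    depth: int = 4
    n_artificial: Optional[int] = None
    k_neighbors: Tuple[int, ...] = (5, 10, 20)
    n_folds: int = 5
    n_estimators: int = 50
    seed: int = 0

    def validate(self, n_genes: int, n_droplets: int) -> None:
        n_art = self.n_artificial if self.n_artificial is not None else n_droplets
        if self.nf < 2 or self.nf > n_genes:
            raise ValueError(
                f"nf={self.nf} must be in [2, n_genes={n_genes}]"
            )
        if self.pc < 1 or self.pc > min(self.nf, n_droplets + n_art):
            raise ValueError(
                f"pc={self.pc} exceeds available dimensions "
                f"(min(nf, n_units) = {min(self.nf, n_droplets + n_art)})"
            )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_folds < 2:
            raise ValueError("need at least 2 cross-validation folds")
        if not self.k_neighbors:
            raise ValueError("k_neighbors must be non-empty")


def _normalize_log1p(counts: np.ndarray) -> np.ndarray:
    """Library-size scaling to the median depth, then log1p (genes x units)."""
    lib = counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    target = np.median(lib)
    return np.log1p(counts / lib * target)


def surrogate_detect(
    dataset: SyntheticDataset, config: SurrogateConfig
) -> LabeledScores:
    """Score every real droplet for doubletness with the surrogate detector.

    Steps: (1) build artificial doublets by summing two random real
    droplets' counts; (2) keep the top-nf genes by variance of
    log1p-normalised expression over the union of real and artificial units
    (all-zero genes are dropped first); (3) project the union to pc
    principal components; (4) for each unit and each neighbourhood size k,
    compute the fraction of artificial doublets among its k nearest
    neighbours (Euclidean, PC space) as predictor features; (5) run
    stratified n-fold cross-validation of a gradient-boosted tree classifier
    (max tree depth = depth) on real-vs-artificial and return each real
    droplet's out-of-fold probability of being artificial as its doublet
    score.  Ground-truth labels are never consulted.
    """
    n = dataset.n_droplets
    n_art = config.n_artificial if config.n_artificial is not None else n
    config.validate(dataset.n_genes, n)
    rng = np.random.default_rng(config.seed)

    pairs = rng.integers(0, n, size=(n_art, 2))
    artificial = dataset.counts[:, pairs[:, 0]] + dataset.counts[:, pairs[:, 1]]
    union = np.concatenate([dataset.counts, artificial], axis=1)

    nonzero = union.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d all-zero gene rows before HVG selection", n_dropped)
        union = union[nonzero]
    if config.nf > union.shape[0]:
        raise ValueError(
            f"nf={config.nf} exceeds the {union.shape[0]} non-zero genes"
        )

    lognorm = _normalize_log1p(union)
    gene_var = lognorm.var(axis=1)
    hvg = np.argsort(-gene_var, kind="stable")[: config.nf]
    expr = lognorm[hvg].T  # units x genes

    pca = PCA(
        n_components=config.pc,
        svd_solver="randomized",
        random_state=int(rng.integers(2**31)),
    )
    embedding = pca.fit_transform(expr)

    is_artificial = np.concatenate(
        [np.zeros(n, dtype=int), np.ones(n_art, dtype=int)]
    )
    max_k = max(config.k_neighbors)
    nn = NearestNeighbors(n_neighbors=max_k + 1).fit(embedding)
    _, nbr_idx = nn.kneighbors(embedding)
    nbr_idx = nbr_idx[:, 1:]  # drop self
    nbr_art = is_artificial[nbr_idx]
    features = np.column_stack(
        [nbr_art[:, :k].mean(axis=1) for k in config.k_neighbors]
    )

    scores = np.full(n + n_art, np.nan)
    skf = StratifiedKFold(
        n_splits=config.n_folds,
        shuffle=True,
        random_state=int(rng.integers(2**31)),
    )
    for train, test in skf.split(features, is_artificial):
        clf = XGBClassifier(
            max_depth=config.depth,
            n_estimators=config.n_estimators,
            learning_rate=0.3,
            n_jobs=1,
            random_state=int(config.seed) % (2**31),
            tree_method="hist",
        )
        clf.fit(features[train], is_artificial[train])
        scores[test] = clf.predict_proba(features[test])[:, 1]

    return LabeledScores(
        scores=scores[:n],
        labels=dataset.labels,
        doublet_rate=dataset.doublet_rate,
    )


def simulate_response_surface(
    space: HyperparameterSpace,
    beta: Union[Dict[str, float], Sequence[float]],
    noise_sd: float = 0.0,
    n_datasets: int = 1,
    seed: int = 0,
    response_name: str = "auprc",
) -> List[AccuracyMatrix]:
    """Generate accuracy matrices from a known quadratic surface plus noise.

    ``beta`` is either a mapping from term name to coefficient (missing
    terms are zero) or a length-10 sequence in canonical term order
    (intercept, linear, quadratic, interactions).  Each replicate evaluates
    the polynomial at every full-factorial point and adds independent
    Gaussian noise with sd ``noise_sd``.
    """
    if len(space.factors) != 3:
        raise ValueError("the quadratic surface generator expects 3 factors")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    terms = quadratic_terms(space.factor_names)
    if isinstance(beta, dict):
        extra = set(beta) - set(terms)
        if extra:
            raise KeyError(f"unknown terms in beta: {sorted(extra)}")
        coef = np.array([beta.get(t, 0.0) for t in terms])
    else:
        coef = np.asarray(beta, dtype=float)
        if coef.size != len(terms):
            raise ValueError(f"beta must have {len(terms)} coefficients")
    points = full_factorial(space)
    X, _ = build_design_matrix(points, space.factor_names, terms)
    mean = X @ coef
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_datasets):
        y = mean + (rng.normal(0.0, noise_sd, size=mean.size) if noise_sd > 0 else 0.0)
        out.append(
            AccuracyMatrix(points, y, response_name=response_name, dataset_id=f"sim{i}")
        )
    return out
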