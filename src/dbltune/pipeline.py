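"""End-to-end hyperparameter tuning pipeline.

The canonical workflow: score a detector over a full factorial design on
several labelled datasets, average the per-dataset accuracy matrices into
detection-accuracy data, fit and prune the quadratic response surface, solve
for the stationary point, then re-evaluate the detector at the rounded
optimum and at the method defaults on each dataset to report improvement and
rank among the design points.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .design import (
    DesignPoint,
    HyperparameterSpace,
    default_point,
    full_factorial,
)
from .fixtures import BenchmarkTables
from .metrics import (
    LabeledScores,
    auprc,
    call_doublets_at_rate,
    percentile_rank,
    relative_improvement,
    tpr_tnr,
)
from .rsm import (
    AccuracyMatrix,
    OptimizationResult,
    QuadraticModelFit,
    prune_and_refit,
    stationary_point,
)
from .synthetic import SurrogateConfig, SyntheticDataset, surrogate_detect

logger = logging.getLogger(__name__)

__all__ = [
    "Detector",
    "make_surrogate_detector",
    "evaluate_design",
    "aggregate",
    "TuneConfig",
    "TuningReport",
    "tune",
    "FixtureReport",
    "report_from_fixtures",
]

#: A detector maps (dataset, design point, seed) to one doublet score per droplet.
Detector = Callable[[SyntheticDataset, DesignPoint, int], np.ndarray]


def make_surrogate_detector(base: Optional[SurrogateConfig] = None) -> Detector:
    """Wrap the surrogate detector so design points set nf/pc/depth.

    Settings not named by the design point (artificial-doublet count,
    neighbourhood sizes, folds, boosting rounds) come from ``base``.
    """
    base = base or SurrogateConfig()

    def detector(dataset: SyntheticDataset, point: DesignPoint, seed: int) -> np.ndarray:
        cfg = replace(
            base,
            nf=int(point["nf"]),
            pc=int(point["pc"]),
            depth=int(point["depth"]),
            seed=int(seed),
        )
        return surrogate_detect(dataset, cfg).scores

    return detector


def _point_seed(seed: int, i_dataset: int, j_point: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(i_dataset), int(j_point)])
    return int(ss.generate_state(1)[0] % (2**31))


def _score_metric(
    scores: np.ndarray,
    labels: np.ndarray,
    metric: str,
    rate: Optional[float],
) -> float:
    data = LabeledScores(scores, labels)
    if metric == "auprc":
        return auprc(data)
    if metric in ("tpr", "tnr"):
        if rate is None:
            raise ValueError(f"metric {metric!r} requires a doublet rate")
        calls = call_doublets_at_rate(data, rate)
        tpr, tnr = tpr_tnr(calls, labels)
        return tpr if metric == "tpr" else tnr
    raise ValueError(f"unknown metric {metric!r}; use auprc, tpr or tnr")


def _resolve_rate(
    dataset: SyntheticDataset,
    idx: int,
    metric: str,
    rate_policy: Union[str, Sequence[float]],
) -> Optional[float]:
    if metric == "auprc":
        return None
    if isinstance(rate_policy, str):
        if rate_policy != "true":
            raise ValueError("rate_policy must be 'true' or a sequence of rates")
        return float(dataset.labels.mean())
    return float(rate_policy[idx])


def evaluate_design(
    datasets: Sequence[SyntheticDataset],
    design: Sequence[DesignPoint],
    detector: Detector,
    metric: str = "auprc",
    rate_policy: Union[str, Sequence[float]] = "true",
    seed: int = 0,
    allow_missing: bool = False,
    dataset_ids: Optional[Sequence[str]] = None,
) -> List[AccuracyMatrix]:
    """Score the detector at every design point on every dataset.

    Detector calls are seeded deterministically per (dataset, point) so the
    same invocation always yields identical matrices.  For tpr/tnr the
    doublet rate is either each dataset's true rate (``rate_policy="true"``)
    or a user-supplied sequence of rates, one per dataset.  A detector
    failure on a point aborts unless ``allow_missing``, in which case the
    point is dropped from every dataset to keep the design balanced.
    """
    if dataset_ids is None:
        dataset_ids = [f"dataset{i}" for i in range(len(datasets))]
    failed: set = set()
    per_dataset: List[List[float]] = []
    for i, ds in enumerate(datasets):
        rate = _resolve_rate(ds, i, metric, rate_policy)
        values = []
        t0 = time.perf_counter()
        for j, point in enumerate(design):
            if j in failed:
                values.append(np.nan)
                continue
            try:
                scores = detector(ds, point, _point_seed(seed, i, j))
                values.append(_score_metric(scores, ds.labels, metric, rate))
            except Exception as e:
                if not allow_missing:
                    raise RuntimeError(
                        f"detector failed on dataset {dataset_ids[i]} at "
                        f"design point {point}: {e}"
                    ) from e
                logger.warning(
                    "dropping design point %s from all datasets: %s", point, e
                )
                failed.add(j)
                values.append(np.nan)
        per_dataset.append(values)
        logger.info(
            "stage=evaluate dataset=%s seed=%d points=%d duration=%.2fs",
            dataset_ids[i],
            seed,
            len(design),
            time.perf_counter() - t0,
        )
    keep = [j for j in range(len(design)) if j not in failed]
    return [
        AccuracyMatrix(
            [design[j] for j in keep],
            np.asarray(vals)[keep],
            response_name=metric,
            dataset_id=dataset_ids[i],
        )
        for i, vals in enumerate(per_dataset)
    ]


def aggregate(matrices: Sequence[AccuracyMatrix]) -> AccuracyMatrix:
    """Average the response over datasets, per design point (unweighted)."""
    if not matrices:
        raise ValueError("nothing to aggregate")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.points != ref.points:
            extra = [p for p in m.points if p not in ref.points]
            missing = [p for p in ref.points if p not in m.points]
            raise ValueError(
                f"design mismatch between {ref.dataset_id} and {m.dataset_id}: "
                f"extra={extra[:3]} missing={missing[:3]}"
            )
        if m.response_name != ref.response_name:
            raise ValueError("matrices measure different responses")
    mean = np.mean([m.response for m in matrices], axis=0)
    return AccuracyMatrix(
        ref.points, mean, response_name=ref.response_name, dataset_id="aggregate"
    )


@dataclass
class TuneConfig:
    """Configuration of one tuning run.

    Either ``datasets`` (with a detector) or precomputed accuracy
    ``matrices`` must be supplied.  With matrices only, the per-dataset
    optimum/default responses are read from the grid (the rounded optimum is
    projected to its nearest design point), since no detector is available
    to evaluate off-grid points.
    """

    space: HyperparameterSpace
    datasets: Optional[List[SyntheticDataset]] = None
    matrices: Optional[List[AccuracyMatrix]] = None
    detector: Optional[Detector] = None
    metric: str = "auprc"
    alpha: float = 0.01
    seed: int = 0
    rate_policy: Union[str, Sequence[float]] = "true"
    dataset_ids: Optional[List[str]] = None

    def config_hash(self) -> str:
        payload = {
            "space": [
                (f.name, f.default, list(f.levels)) for f in self.space.factors
            ],
            "metric": self.metric,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_datasets": len(self.datasets or self.matrices or []),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class TuningReport:
    """Per-dataset outcome rows plus the aggregate fit and optimum."""

    rows: pd.DataFrame
    fit: QuadraticModelFit
    optimization: OptimizationResult
    aggregate_matrix: AccuracyMatrix
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def optimum(self) -> Dict[str, float]:
        full = dict(self.optimization.optimum)
        full.update(self.optimization.inactive_factors)
        return full


def _nearest_grid_point(
    point: DesignPoint, matrix: AccuracyMatrix
) -> int:
    """Index of the design row closest to ``point`` (scaled Euclidean)."""
    names = matrix.factor_names
    grid = np.array([[p[n] for n in names] for p in matrix.points])
    target = np.array([point[n] for n in names])
    span = grid.max(axis=0) - grid.min(axis=0)
    span[span == 0] = 1.0
    d = (((grid - target) / span) ** 2).sum(axis=1)
    return int(np.argmin(d))


def tune(config: TuneConfig) -> TuningReport:
    """Run the full tuning strategy and report per-dataset outcomes.

    Stages: evaluate the detector over the design (or take precomputed
    matrices) -> average into detection-accuracy data -> fit and prune the
    quadratic surface -> locate the optimum -> re-evaluate each dataset at
    the rounded optimum (insignificant factors pinned to defaults) and at
    the default point, reporting relative improvement and the rank of the
    optimum's accuracy among that dataset's design-point accuracies.
    """
    design = full_factorial(config.space)
    t0 = time.perf_counter()

    if config.matrices is not None:
        matrices = list(config.matrices)
    elif config.datasets is not None:
        detector = config.detector or make_surrogate_detector()
        matrices = evaluate_design(
            config.datasets,
            design,
            detector,
            metric=config.metric,
            rate_policy=config.rate_policy,
            seed=config.seed,
            dataset_ids=config.dataset_ids,
        )
    else:
        raise ValueError("TuneConfig needs datasets or precomputed matrices")

    agg = aggregate(matrices)
    fit = prune_and_refit(agg, alpha=config.alpha)
    if fit.flags.get("flat_surface"):
        # no significant structure: stay at the defaults
        opt = OptimizationResult(
            stationary={},
            curvature="degenerate",
            optimum={},
            inactive_factors=default_point(config.space),
            objective_at_optimum=fit.params["intercept"],
            fallback_used=True,
        )
    else:
        opt = stationary_point(fit, config.space)
    opt_point = dict(opt.optimum)
    opt_point.update(opt.inactive_factors)
    def_point = default_point(config.space)

    rows = []
    for i, matrix in enumerate(matrices):
        grid_values = matrix.response
        if config.datasets is not None and config.matrices is None:
            ds = config.datasets[i]
            detector = config.detector or make_surrogate_detector()
            rate = _resolve_rate(ds, i, config.metric, config.rate_policy)
            at_opt = _score_metric(
                detector(ds, opt_point, _point_seed(config.seed, i, len(design))),
                ds.labels,
                config.metric,
                rate,
            )
            at_def = _score_metric(
                detector(ds, def_point, _point_seed(config.seed, i, len(design) + 1)),
                ds.labels,
                config.metric,
                rate,
            )
        else:
            at_opt = float(grid_values[_nearest_grid_point(opt_point, matrix)])
            at_def = float(grid_values[_nearest_grid_point(def_point, matrix)])
        # an off-grid optimum worse than every grid point still ranks last
        rank, _ = percentile_rank(at_opt, grid_values)
        rank = min(rank, grid_values.size)
        pct = rank / grid_values.size
        rows.append(
            {
                "dataset_id": matrix.dataset_id,
                f"{config.metric}_at_optimum": at_opt,
                f"{config.metric}_at_default": at_def,
                f"{config.metric}_grid_max": float(grid_values.max()),
                "relative_improvement_pct": relative_improvement(at_opt, at_def),
                "rank": rank,
                "percentile": pct,
            }
        )

    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "metric": config.metric,
        "alpha": config.alpha,
        "n_design_points": len(design),
        "duration_s": round(time.perf_counter() - t0, 3),
    }
    logger.info("stage=tune %s", metadata)
    return TuningReport(
        rows=pd.DataFrame(rows),
        fit=fit,
        optimization=opt,
        aggregate_matrix=agg,
        metadata=metadata,
    )


@dataclass
class FixtureReport:
    """Summary statistics over the packaged benchmark AUPRC table."""

    per_dataset: pd.DataFrame
    n_outperforming: int
    max_improvement_pct: float
    max_improvement_dataset: str


def report_from_fixtures(fixtures: BenchmarkTables) -> FixtureReport:
    """Relative improvement per benchmark dataset, plus headline counts.

    Pure arithmetic on the packaged table: percent improvement of the tuned
    optimum over the default per dataset, the number of datasets where the
    optimum beats the default, and the dataset attaining the maximum
    improvement.
    """
    df = fixtures.auprc.copy()
    df["relative_improvement_pct"] = [
        relative_improvement(o, d) for o, d in zip(df["optimum"], df["default"])
    ]
    n_out = int((df["optimum"] > df["default"]).sum())
    imax = int(df["relative_improvement_pct"].idxmax())
    return FixtureReport(
        per_dataset=df,
        n_outperforming=n_out,
        max_improvement_pct=float(df.loc[imax, "relative_improvement_pct"]),
        max_improvement_dataset=str(df.loc[imax, "dataset"]),
    )
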