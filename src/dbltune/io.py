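"""Readers and writers for the framework's on-disk formats.

* hyperparameter space: YAML (one block per factor: default + levels)
* design and accuracy matrices: CSV (UTF-8, "." decimal separator)
* count matrices: MatrixMarket MTX with genes.tsv / barcodes.tsv sidecars
  (genes as rows, droplets as columns) plus labels.tsv, or a dense CSV for
  tiny fixtures
* model fits, optimization results and tuning reports: JSON

Write-then-read round-trips are identity on the data model; floats are
serialized at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .design import DesignPoint, Factor, HyperparameterSpace
from .rsm import (
    AccuracyMatrix,
    OptimizationResult,
    QuadraticModelFit,
)
from .synthetic import SimulationParams, SyntheticDataset

__all__ = [
    "read_space",
    "write_space",
    "write_design_csv",
    "read_design_csv",
    "write_accuracy_csv",
    "read_accuracy_csv",
    "write_counts",
    "read_counts",
    "write_counts_csv",
    "read_counts_csv",
    "fit_to_dict",
    "fit_from_dict",
    "write_fit_json",
    "read_fit_json",
    "optimization_to_dict",
    "write_optimization_json",
]

PathLike = Union[str, Path]


# -- hyperparameter space -------------------------------------------------

def read_space(path: PathLike) -> HyperparameterSpace:
    """Read a factor-block YAML space definition."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "factors" not in raw:
        raise ValueError(f"{path}: expected a top-level 'factors' list")
    factors = []
    for block in raw["factors"]:
        try:
            factors.append(
                Factor(
                    name=str(block["name"]),
                    default=float(block["default"]),
                    levels=tuple(float(v) for v in block["levels"]),
                )
            )
        except KeyError as e:
            raise ValueError(f"{path}: factor block missing key {e}") from None
    return HyperparameterSpace(factors=tuple(factors))


def write_space(space: HyperparameterSpace, path: PathLike) -> None:
    payload = {
        "factors": [
            {"name": f.name, "default": f.default, "levels": list(f.levels)}
            for f in space.factors
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# -- design & accuracy CSV ------------------------------------------------

def write_design_csv(points: List[DesignPoint], path: PathLike) -> None:
    """Design as CSV: header = factor names, one row per point."""
    pd.DataFrame(points).to_csv(path, index=False)


def read_design_csv(path: PathLike) -> List[DesignPoint]:
    df = pd.read_csv(path)
    return [
        {c: float(v) for c, v in row.items()} for row in df.to_dict("records")
    ]


def write_accuracy_csv(data: AccuracyMatrix, path: PathLike) -> None:
    """Accuracy matrix as CSV: factor columns then the response column."""
    data.to_frame().to_csv(path, index=False)


def read_accuracy_csv(
    path: PathLike,
    response_name: Optional[str] = None,
    dataset_id: str = "aggregate",
) -> AccuracyMatrix:
    """Read an accuracy CSV; the response is the last column by default."""
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ValueError(f"{path}: malformed CSV ({e})") from e
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +2: header + 1-based
        raise ValueError(f"{path}: malformed row near line {bad}")
    return AccuracyMatrix.from_frame(df, response_name, dataset_id)


# -- count matrices --------------------------------------------------------

def write_counts(dataset: SyntheticDataset, outdir: PathLike) -> None:
    """Write counts as MTX + genes.tsv / barcodes.tsv / labels.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(dataset.counts)
    spio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    genes = [f"gene{i}" for i in range(dataset.n_genes)]
    barcodes = [f"droplet{i}" for i in range(dataset.n_droplets)]
    (outdir / "genes.tsv").write_text("\n".join(genes) + "\n", encoding="utf-8")
    (outdir / "barcodes.tsv").write_text(
        "\n".join(barcodes) + "\n", encoding="utf-8"
    )
    labels = pd.DataFrame({"barcode": barcodes, "is_doublet": dataset.labels})
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    with open(outdir / "params.json", "w", encoding="utf-8") as fh:
        json.dump(vars(dataset.params), fh, indent=1)


def read_counts(indir: PathLike) -> SyntheticDataset:
    indir = Path(indir)
    counts = np.asarray(
        spio.mmread(indir / "matrix.mtx").todense(), dtype=np.int64
    )
    labels = pd.read_csv(indir / "labels.tsv", sep="\t")["is_doublet"].to_numpy(int)
    with open(indir / "params.json", "r", encoding="utf-8") as fh:
        params = SimulationParams(**json.load(fh))
    return SyntheticDataset(counts=counts, labels=labels, params=params)


def write_counts_csv(dataset: SyntheticDataset, path: PathLike) -> None:
    """Dense CSV alternative for tiny fixtures (genes x droplets)."""
    df = pd.DataFrame(
        dataset.counts,
        index=[f"gene{i}" for i in range(dataset.n_genes)],
        columns=[f"droplet{i}" for i in range(dataset.n_droplets)],
    )
    df.to_csv(path)


def read_counts_csv(path: PathLike) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(np.int64)


# -- fits, optimization, reports -------------------------------------------

def fit_to_dict(fit: QuadraticModelFit) -> dict:
    per_term = {
        t: {
            "estimate": fit.params.get(t),
            "se": fit.bse.get(t),
            "t": fit.tvalues.get(t),
            "p": fit.pvalues.get(t),
            "retained": t in fit.retained_terms,
        }
        for t in fit.terms
    }
    return {
        "factor_names": fit.factor_names,
        "response_name": fit.response_name,
        "terms": per_term,
        "retained_terms": list(fit.retained_terms),
        "sigma2": fit.sigma2,
        "r_squared": fit.r_squared,
        "df_resid": fit.df_resid,
        "flags": fit.flags,
    }


def write_fit_json(fit: QuadraticModelFit, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1)


def read_fit_json(path: PathLike) -> QuadraticModelFit:
    """Rebuild a coefficients-level fit from JSON (no residual vectors)."""
    with open(path, "r", encoding="utf-8") as fh:
        return fit_from_dict(json.load(fh))


def fit_from_dict(d: dict) -> QuadraticModelFit:
    terms = list(d["terms"].keys())
    return QuadraticModelFit(
        factor_names=d["factor_names"],
        terms=terms,
        params={t: v["estimate"] for t, v in d["terms"].items()},
        bse={t: v["se"] for t, v in d["terms"].items() if v["se"] is not None},
        tvalues={t: v["t"] for t, v in d["terms"].items() if v["t"] is not None},
        pvalues={t: v["p"] for t, v in d["terms"].items() if v["p"] is not None},
        residuals=None,
        fitted=None,
        sigma2=d.get("sigma2"),
        r_squared=d.get("r_squared"),
        df_resid=d.get("df_resid"),
        retained_terms=tuple(d["retained_terms"]),
        flags=d.get("flags", {}),
        response_name=d.get("response_name", "auprc"),
    )


def optimization_to_dict(opt: OptimizationResult) -> dict:
    return {
        "stationary": opt.stationary,
        "curvature": opt.curvature,
        "optimum": opt.optimum,
        "inactive": opt.inactive_factors,
        "objective_at_optimum": opt.objective_at_optimum,
        "fallback_used": opt.fallback_used,
    }


def write_optimization_json(opt: OptimizationResult, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(optimization_to_dict(opt), fh, indent=1)
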