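"""Packaged reference data from the published scDblFinder tuning benchmark.

Two small tables ship with the package:

* ``benchmark_auprc.csv`` — for each of 16 public scRNA-seq datasets with
  experimentally annotated doublets, the AUPRC of scDblFinder under the
  tuned optimum, under the method defaults, and the maximum over the 125
  design points.
* ``benchmark_datasets.csv`` — the characteristics of those datasets
  (cell types, droplet and gene counts, true doublet rate, annotation
  technique).

Also provided are the published reduced response-surface coefficients for
mean AUPRC over the 16 datasets (significant terms only: intercept plus the
first and second orders of nf and pc), usable directly with
:func:`dbltune.rsm.stationary_point`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .rsm import QuadraticModelFit, fit_from_coefficients
from .synthetic import SimulationParams

__all__ = [
    "BenchmarkTables",
    "load_benchmark_tables",
    "SCDBLFINDER_REDUCED_COEFFS",
    "scdblfinder_reduced_model",
    "table2_mini_params",
]

#: Published reduced-model coefficients for mean AUPRC as a quadratic in
#: nf (highly variable genes) and pc (principal components); depth was not
#: significant at alpha = 0.01 and carries no terms.
SCDBLFINDER_REDUCED_COEFFS = {
    "intercept": 5.444e-1,
    "nf": 1.016e-5,
    "pc": 1.336e-3,
    "nf^2": -3.760e-9,
    "pc^2": -3.484e-5,
}


def scdblfinder_reduced_model() -> QuadraticModelFit:
    """The published reduced AUPRC surface as a coefficients-only fit."""
    return fit_from_coefficients(
        SCDBLFINDER_REDUCED_COEFFS, factor_names=["nf", "pc", "depth"]
    )


@dataclass
class BenchmarkTables:
    """The two packaged benchmark tables as data frames.

    ``auprc`` has columns dataset/optimum/default/maximum; ``datasets`` has
    dataset/cell_type/n_droplets/n_genes/doublet_rate/annotation with
    doublet_rate expressed as a fraction in (0, 1).
    """

    auprc: pd.DataFrame
    datasets: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.auprc) != 16 or len(self.datasets) != 16:
            raise ValueError("benchmark tables must each have 16 rows")
        for col in ("optimum", "default", "maximum"):
            vals = self.auprc[col]
            if not ((vals >= 0) & (vals <= 1)).all():
                raise ValueError(f"AUPRC column {col!r} outside [0, 1]")
        rates = self.datasets["doublet_rate"]
        if not ((rates > 0) & (rates < 1)).all():
            raise ValueError("doublet rates must lie in (0, 1)")


def load_benchmark_tables() -> BenchmarkTables:
    """Load the packaged benchmark tables."""
    root = resources.files("dbltune").joinpath("data")
    with resources.as_file(root.joinpath("benchmark_auprc.csv")) as p:
        auprc = pd.read_csv(p)
    with resources.as_file(root.joinpath("benchmark_datasets.csv")) as p:
        datasets = pd.read_csv(p)
    datasets["doublet_rate"] = datasets.pop("doublet_rate_pct") / 100.0
    # keep column order tidy
    datasets = datasets[
        ["dataset", "cell_type", "n_droplets", "n_genes", "doublet_rate", "annotation"]
    ]
    return BenchmarkTables(auprc=auprc, datasets=datasets)


def table2_mini_params(seed: int = 0, scale: int = 10) -> dict:
    """Simulation settings emulating the benchmark datasets, scaled down.

    Each benchmark dataset maps to :class:`SimulationParams` with droplet
    and gene counts divided by ``scale`` (floored at the simulator minima of
    100 droplets / 200 genes), the same doublet rate, and the number of cell
    types taken from the benchmark's cell-type mixture.  Seeds are offset
    per dataset so the collection is jointly reproducible from one seed.
    """
    tables = load_benchmark_tables()
    out = {}
    for i, row in tables.datasets.iterrows():
        n_types = row["cell_type"].count(",") + 1
        out[row["dataset"]] = SimulationParams(
            n_droplets=max(100, int(row["n_droplets"]) // scale),
            n_genes=max(200, int(row["n_genes"]) // scale),
            n_cell_types=n_types,
            doublet_rate=float(row["doublet_rate"]),
            seed=int(seed) + i,
        )
    return out
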