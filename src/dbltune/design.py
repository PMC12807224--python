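"""Hyperparameter spaces and full factorial designs.

A :class:`HyperparameterSpace` declares a small set of named, numeric
hyperparameters (factors), each with a default value and an ordered grid of
exploratory levels.  A full factorial design enumerates every combination of
levels, which is the experimental design used to collect detection-accuracy
data before fitting a response surface.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List

__all__ = [
    "Factor",
    "HyperparameterSpace",
    "DesignPoint",
    "full_factorial",
    "default_point",
    "scdblfinder_space",
    "load_preset",
    "PRESETS",
]

#: A design point maps each factor name to one numeric value.
DesignPoint = Dict[str, float]


@dataclass(frozen=True)
class Factor:
    """One tunable hyperparameter: a name, a default, and a level grid.

    Levels must be strictly increasing.  The default does not have to be a
    member of the level grid (a warning is emitted if it is not, because
    grids are conventionally centered on the default).
    """

    name: str
    default: float
    levels: tuple

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        levels = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 1:
            raise ValueError(f"factor {self.name!r} needs at least one level")
        if any(not math.isfinite(v) for v in levels):
            raise ValueError(f"factor {self.name!r} has non-finite levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(
                f"factor {self.name!r}: levels must be strictly increasing"
            )
        if not math.isfinite(float(self.default)):
            raise ValueError(f"factor {self.name!r}: default must be finite")
        object.__setattr__(self, "default", float(self.default))
        if self.default not in levels:
            warnings.warn(
                f"factor {self.name!r}: default {self.default} is not one of "
                f"its levels; the level grid is not centered on the default",
                stacklevel=3,
            )


@dataclass(frozen=True)
class HyperparameterSpace:
    """An ordered collection of factors with unique names."""

    factors: tuple

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        object.__setattr__(self, "factors", factors)
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {names}")

    @property
    def factor_names(self) -> List[str]:
        return [f.name for f in self.factors]

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def n_points(self) -> int:
        """Size of the full factorial design over this space."""
        n = 1
        for f in self.factors:
            n *= len(f.levels)
        return n

    def bounds(self, name: str) -> tuple:
        """(min level, max level) of one factor — the level hull."""
        f = self.factor(name)
        return (f.levels[0], f.levels[-1])


def full_factorial(space: HyperparameterSpace) -> List[DesignPoint]:
    """Enumerate every combination of factor levels.

    The order is lexicographic with the first declared factor varying
    slowest, so the enumeration is reproducible and joins deterministically
    with accuracy records collected against it.
    """
    if not space.factors:
        raise ValueError("cannot enumerate a design over an empty space")
    names = space.factor_names
    grids = [f.levels for f in space.factors]
    return [dict(zip(names, combo)) for combo in itertools.product(*grids)]


def default_point(space: HyperparameterSpace) -> DesignPoint:
    """The design point with every factor at its default value."""
    if not space.factors:
        raise ValueError("empty space has no default point")
    return {f.name: f.default for f in space.factors}


def scdblfinder_space() -> HyperparameterSpace:
    """The three scDblFinder hyperparameters with their 5-level grids.

    nf is the number of highly variable genes kept, pc the number of
    principal components, and depth the maximum depth of the gradient
    boosting trees.  Each grid is centered on the method default
    (nf=1000, pc=10, depth=4), giving a 5x5x5 = 125-point full factorial.
    """
    return HyperparameterSpace(
        factors=(
            Factor("nf", 1000, (500, 1000, 1500, 2000, 2500)),
            Factor("pc", 10, (5, 10, 15, 20, 25)),
            Factor("depth", 4, (2, 3, 4, 5, 6)),
        )
    )


PRESETS = {
    "scdblfinder3x5": scdblfinder_space,
}


def load_preset(name: str) -> HyperparameterSpace:
    """Look up a packaged hyperparameter-space preset by name."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
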