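"""Phenotype (cultivar) representation, trait bounds and space-filling designs.

A phenotype is a point in a box-bounded 8-dimensional trait space describing a
sunflower-like cultivar: two thermal-time phenology totals (emergence to
flowering TDF1 and to maturity TDM3, degC·day), canopy architecture (leaf
number TLN, light-extinction coefficient K, rank LLH and area LLS (cm2) of the
largest leaf), and two water-stress response thresholds (leaf expansion LE and
stomatal conductance TR, pseudo water potential, bar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

TRAIT_NAMES = ("TDF1", "TDM3", "TLN", "K", "LLH", "LLS", "LE", "TR")

_DEFAULT_BOUNDS = {
    "TDF1": (765.0, 907.0),
    "TDM3": (1540.0, 1830.0),
    "TLN": (22.2, 36.7),
    "K": (0.780, 0.950),
    "LLH": (13.5, 20.6),
    "LLS": (334.0, 670.0),
    "LE": (-15.6, -2.31),
    "TR": (-14.2, -5.81),
}


@dataclass(frozen=True)
class TraitBounds:
    """Box bounds of the trait space (lower/upper per trait)."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not (len(self.names) == lower.size == upper.size):
            raise ValueError("names, lower and upper must have the same length")
        if np.any(upper <= lower):
            raise ValueError("every upper bound must exceed its lower bound")

    @property
    def d(self) -> int:
        return len(self.names)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, traits: np.ndarray, atol: float = 1e-9) -> bool:
        traits = np.asarray(traits, dtype=float)
        return bool(
            np.all(traits >= self.lower - atol) and np.all(traits <= self.upper + atol)
        )

    def clip(self, traits: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(traits, dtype=float), self.lower, self.upper)

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)


def default_trait_bounds() -> TraitBounds:
    """The eight cultivar traits with their optimization bounds."""
    return TraitBounds(
        names=TRAIT_NAMES,
        lower=np.array([_DEFAULT_BOUNDS[n][0] for n in TRAIT_NAMES]),
        upper=np.array([_DEFAULT_BOUNDS[n][1] for n in TRAIT_NAMES]),
    )


@dataclass(frozen=True)
class Phenotype:
    """A trait vector within its box bounds."""

    traits: np.ndarray
    bounds: TraitBounds

    def __post_init__(self) -> None:
        traits = np.asarray(self.traits, dtype=float)
        object.__setattr__(self, "traits", traits)
        if traits.shape != (self.bounds.d,):
            raise ValueError(
                f"expected {self.bounds.d} trait values, got shape {traits.shape}"
            )
        if not self.bounds.contains(traits):
            raise ValueError(f"trait vector {traits} violates its bounds")

    def __getitem__(self, name: str) -> float:
        return float(self.traits[self.bounds.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.bounds.names, self.traits)}


def mid_bounds_phenotype(bounds: TraitBounds | None = None) -> Phenotype:
    bounds = bounds or default_trait_bounds()
    return Phenotype(bounds.midpoint(), bounds)


@dataclass(frozen=True)
class PhenotypeBasis:
    """A learning basis B = {x_1, ..., x_l} of phenotypes."""

    points: tuple[Phenotype, ...]

    def __post_init__(self) -> None:
        points = tuple(self.points)
        object.__setattr__(self, "points", points)
        if len(points) < 1:
            raise ValueError("a basis needs at least one point")

    @property
    def l(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, i: int) -> Phenotype:
        return self.points[i]

    def as_array(self) -> np.ndarray:
        return np.stack([p.traits for p in self.points])


def sample_lhs_basis(
    l: int, bounds: TraitBounds | None = None, seed: int | None = None
) -> PhenotypeBasis:
    """Latin hypercube sample of ``l`` phenotypes.

    Each trait's ``l`` values occupy distinct equal-width strata of its range
    (the Latin property); the design is deterministic given ``seed``.
    """
    if l < 2:
        raise ValueError("a Latin hypercube basis needs l >= 2 points")
    bounds = bounds or default_trait_bounds()
    sampler = qmc.LatinHypercube(d=bounds.d, seed=np.random.default_rng(seed))
    unit = sampler.random(n=l)
    scaled = qmc.scale(unit, bounds.lower, bounds.upper)
    return PhenotypeBasis(tuple(Phenotype(row, bounds) for row in scaled))
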