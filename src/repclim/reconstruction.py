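"""Non-parametric reconstruction of the yield distribution from subset runs.

Running a phenotype on the K representative seasons gives only K yields; the
full distribution over all N seasons is recovered with a mixture model.  Class
k contributes its representative yield plus a scaled residual: during the
learning phase the yields of a basis of phenotypes over *all* seasons provide,
for every season j of class k, the residual of j's yield around the class
medoid's yield, normalized by the size-weighted spread sigma_K of the medoid
yields for that basis phenotype and averaged over the basis.  For a new
phenotype, each stored normalized residual is rescaled by the phenotype's own
sigma_K and added to its class's representative yield, producing N equally
weighted atoms whose empirical mean and lower-tail average (CVaR) are the two
optimization objectives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .clustering import Clustering
from .crop import CountingSimulator, YieldMatrix, crop_yield
from .phenotype import Phenotype
from .weather import ClimateSet


@dataclass(frozen=True)
class ObjectivePair:
    """The two maximized objectives: expected yield and lower-tail CVaR.

    ``alpha`` is the tail level: CVaR_alpha is the average yield over the
    worst alpha-fraction of seasons.  Every estimator in this module returns
    cvar <= mean (a tail average cannot exceed the mean); the container itself
    also serves as a generic bi-objective point for the optimization machinery
    and does not enforce it.
    """

    mean: float
    cvar: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 0.5):
            raise ValueError("alpha must be in (0, 0.5]")

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.cvar])


@dataclass(frozen=True)
class ReconstructedDistribution:
    """N equally weighted yield atoms (class k contributes N^k of them)."""

    atoms: np.ndarray

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=float)
        object.__setattr__(self, "atoms", atoms)
        if atoms.ndim != 1 or atoms.size == 0:
            raise ValueError("atoms must be a non-empty 1-D array")

    @property
    def N(self) -> int:
        return self.atoms.size

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.N, 1.0 / self.N)


def sigma_K(subset_yields: np.ndarray, class_sizes: np.ndarray) -> float:
    """Size-weighted standard deviation of the K representative yields.

    sigma^2 = (1/N) sum_k N^k (y_k - ybar)^2 with ybar = (1/N) sum_k N^k y_k.
    Zero iff all representative yields are equal.
    """
    y = np.asarray(subset_yields, dtype=float)
    sizes = np.asarray(class_sizes, dtype=float)
    if y.shape != sizes.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("subset_yields and class_sizes must be equal-length 1-D arrays")
    N = sizes.sum()
    ybar = float(np.sum(sizes * y) / N)
    var = float(np.sum(sizes * (y - ybar) ** 2) / N)
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class ResidualLibrary:
    """Per-class averaged normalized residuals, aligned with a clustering.

    ``residuals[k]`` has one entry per member of class k (in ascending index
    order of the original set); the entry for the medoid itself is exactly 0.
    ``n_basis_used`` records how many basis phenotypes survived the
    degenerate-spread filter.
    """

    residuals: tuple[np.ndarray, ...]
    class_sizes: np.ndarray
    medoid_indices: np.ndarray
    member_indices: tuple[np.ndarray, ...]
    n_basis_used: int

    def __post_init__(self) -> None:
        sizes = np.asarray(self.class_sizes, dtype=int)
        object.__setattr__(self, "class_sizes", sizes)
        object.__setattr__(self, "medoid_indices", np.asarray(self.medoid_indices, dtype=int))
        object.__setattr__(self, "residuals", tuple(np.asarray(r, float) for r in self.residuals))
        object.__setattr__(self, "member_indices", tuple(np.asarray(m, int) for m in self.member_indices))
        for k, (r, m, nk) in enumerate(zip(self.residuals, self.member_indices, sizes)):
            if r.size != nk or m.size != nk:
                raise ValueError(f"class {k}: residual vector length != class size")

    @property
    def K(self) -> int:
        return self.class_sizes.size

    @property
    def N(self) -> int:
        return int(self.class_sizes.sum())


def build_residual_library(
    Y: YieldMatrix | np.ndarray, clustering: Clustering
) -> ResidualLibrary:
    """Learn the residual library from the basis yield matrix y(B, Omega).

    For every basis phenotype x_i: the residual of member j of class k is
    y(x_i, c_j) - y(x_i, omega_k), divided by sigma_K(x_i) (the size-weighted
    spread of x_i's medoid yields); these normalized residuals are averaged
    over the basis.  Basis phenotypes with sigma_K = 0 carry no scale
    information and are dropped with a warning.
    """
    values = Y.values if isinstance(Y, YieldMatrix) else np.asarray(Y, float)
    if values.ndim != 2:
        raise ValueError("yield matrix must be 2-D (l x N)")
    l, N = values.shape
    if clustering.N != N:
        raise ValueError("clustering size does not match the yield matrix")
    medoids = clustering.medoid_indices
    sizes = clustering.class_sizes

    medoid_yields = values[:, medoids]  # l x K
    sigmas = np.array([sigma_K(medoid_yields[i], sizes) for i in range(l)])
    keep = sigmas > 1e-12
    if not np.any(keep):
        raise ValueError("all basis phenotypes have zero spread over the representatives")
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} basis phenotype(s) with zero spread "
            "over the representative subset",
            RuntimeWarning,
        )
    residuals = []
    member_lists = []
    for k in range(clustering.K):
        members = clustering.members(k)
        eps = values[:, members] - values[:, [medoids[k]]]  # l x N^k
        normalized = eps[keep] / sigmas[keep, None]
        residuals.append(normalized.mean(axis=0))
        member_lists.append(members)
    return ResidualLibrary(
        residuals=tuple(residuals),
        class_sizes=sizes,
        medoid_indices=medoids,
        member_indices=tuple(member_lists),
        n_basis_used=int(keep.sum()),
    )


def reconstruct_atoms(
    subset_yields: np.ndarray, library: ResidualLibrary
) -> ReconstructedDistribution:
    """Materialize all N mixture atoms for a new phenotype.

    Class k contributes the atoms ``y(x, omega_k) + sigma_K(x) * eps_jk`` for
    each stored residual eps_jk, every atom carrying weight 1/N — the
    deterministic enumeration of the uniform-index mixture.
    """
    y = np.asarray(subset_yields, dtype=float)
    if y.shape != (library.K,):
        raise ValueError(f"expected {library.K} subset yields, got shape {y.shape}")
    sigma = sigma_K(y, library.class_sizes)
    atoms = np.concatenate(
        [y[k] + sigma * library.residuals[k] for k in range(library.K)]
    )
    return ReconstructedDistribution(atoms)


def estimate_mean(dist: ReconstructedDistribution | np.ndarray) -> float:
    """Mean of the (uniformly weighted) atoms."""
    atoms = dist.atoms if isinstance(dist, ReconstructedDistribution) else np.asarray(dist, float)
    if atoms.size == 0:
        raise ValueError("empty distribution")
    return float(atoms.mean())


def estimate_cvar(dist: ReconstructedDistribution | np.ndarray, alpha: float) -> float:
    """Lower-tail conditional value-at-risk of the atoms.

    Average of the m = max(1, ceil(alpha * N)) smallest atoms; the ceiling
    makes the tail conservative when alpha * N is not an integer.
    """
    if not (0.0 < alpha <= 0.5):
        raise ValueError("alpha must be in (0, 0.5]")
    atoms = dist.atoms if isinstance(dist, ReconstructedDistribution) else np.asarray(dist, float)
    if atoms.size == 0:
        raise ValueError("empty distribution")
    n = atoms.size
    m = max(1, math.ceil(alpha * n - 1e-12))
    tail = np.partition(atoms, m - 1)[:m]
    return float(tail.mean())


def reconstructed_objectives(
    subset_yields: np.ndarray, library: ResidualLibrary, alpha: float
) -> ObjectivePair:
    """Mean and CVaR of the reconstructed distribution."""
    dist = reconstruct_atoms(subset_yields, library)
    return ObjectivePair(estimate_mean(dist), estimate_cvar(dist, alpha), alpha)


def subset_only_objectives(
    subset_yields: np.ndarray, class_sizes: np.ndarray, alpha: float
) -> ObjectivePair:
    """Baseline estimator using the subset yields alone.

    The representative yields are weighted by their class sizes (the unequal-
    step empirical CDF of the subset), with no residual correction.
    """
    y = np.asarray(subset_yields, dtype=float)
    sizes = np.asarray(class_sizes, dtype=int)
    atoms = np.repeat(y, sizes)
    return ObjectivePair(estimate_mean(atoms), estimate_cvar(atoms, alpha), alpha)


def gaussian_objectives(
    subset_yields: np.ndarray, class_sizes: np.ndarray, alpha: float
) -> ObjectivePair:
    """Baseline estimator fitting a normal distribution to the subset yields.

    Mean and spread are the size-weighted moments of the representative
    yields; the normal lower-tail CVaR is mu - sigma * phi(z_alpha) / alpha.
    """
    y = np.asarray(subset_yields, dtype=float)
    sizes = np.asarray(class_sizes, dtype=float)
    mu = float(np.sum(sizes * y) / sizes.sum())
    sigma = sigma_K(y, sizes)
    z = norm.ppf(alpha)
    cvar = mu - sigma * float(norm.pdf(z)) / alpha
    return ObjectivePair(mu, cvar, alpha)


def empirical_objectives_full(
    x: Phenotype,
    climates: ClimateSet,
    alpha: float,
    simulator: CountingSimulator | None = None,
) -> ObjectivePair:
    """Ground-truth objectives: run the simulator on every season.

    Costs N simulator calls (recorded on ``simulator`` when given).
    """
    sim = simulator if simulator is not None else crop_yield
    yields = np.array([sim(x, c) for c in climates])
    return ObjectivePair(estimate_mean(yields), estimate_cvar(yields, alpha), alpha)
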