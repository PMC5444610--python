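"""k-medoids partitioning of the climate set from a precomputed dissimilarity.

Cluster centroids cannot be averaged when only pairwise dissimilarities are
available, so a k-means-style alternation on medoids is used: assign every
series to its nearest medoid, then recompute each class's medoid as the member
minimizing the within-class sum of dissimilarities, until the assignment is
stable.  The best of several seeded random restarts is kept.  The K medoids
(with their class sizes, which later act as mixture weights) form the
representative subset on which the optimizer runs the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix
from .weather import ClimateSet


@dataclass(frozen=True)
class Clustering:
    """A partition of N elements into K classes with medoid representatives.

    ``assignment`` holds 0-based class labels; ``medoid_indices[k]`` is the
    index (into the original set) of class k's medoid; ``total_cost`` is the
    sum over elements of their dissimilarity to their class medoid.
    """

    assignment: np.ndarray
    medoid_indices: np.ndarray
    total_cost: float

    def __post_init__(self) -> None:
        assignment = np.asarray(self.assignment, dtype=int)
        medoids = np.asarray(self.medoid_indices, dtype=int)
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(self, "medoid_indices", medoids)
        K = medoids.size
        if len(np.unique(medoids)) != K:
            raise ValueError("medoid indices must be distinct")
        if np.any(assignment < 0) or np.any(assignment >= K):
            raise ValueError("assignment labels out of range")
        for k, m in enumerate(medoids):
            if assignment[m] != k:
                raise ValueError(f"medoid {m} is not assigned to its own class {k}")

    @property
    def K(self) -> int:
        return self.medoid_indices.size

    @property
    def N(self) -> int:
        return self.assignment.size

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.K)

    def members(self, k: int) -> np.ndarray:
        return np.nonzero(self.assignment == k)[0]

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        """Cluster report: one row per element with its class and medoid flag."""
        labels = list(labels) if labels is not None else [str(i) for i in range(self.N)]
        is_medoid = np.zeros(self.N, dtype=bool)
        is_medoid[self.medoid_indices] = True
        return pd.DataFrame(
            {"label": labels, "class": self.assignment + 1, "is_medoid": is_medoid}
        )


@dataclass(frozen=True)
class RepresentativeSet:
    """The K medoid series with their class sizes (mixture weights)."""

    climates: ClimateSet
    class_sizes: np.ndarray
    medoid_indices: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.class_sizes, dtype=int)
        object.__setattr__(self, "class_sizes", sizes)
        object.__setattr__(self, "medoid_indices", np.asarray(self.medoid_indices, dtype=int))
        if self.climates.N != sizes.size:
            raise ValueError("one class size per representative series is required")
        if np.any(sizes < 1):
            raise ValueError("class sizes must be positive")

    @property
    def K(self) -> int:
        return self.climates.N

    @property
    def N(self) -> int:
        return int(self.class_sizes.sum())


def medoid_of_class(delta: np.ndarray, member_indices: Sequence[int]) -> int:
    """The member minimizing the sum of dissimilarities to the other members.

    Ties are broken by the lowest index.
    """
    members = np.asarray(member_indices, dtype=int)
    if members.size == 0:
        raise ValueError("empty class has no medoid")
    sub = delta[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])


def _assign(delta: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # nearest medoid; ties go to the first (lowest-position) medoid
    return np.argmin(delta[:, medoids], axis=1)


def _one_run(delta: np.ndarray, K: int, rng: np.random.Generator, max_iter: int) -> tuple:
    N = delta.shape[0]
    medoids = np.sort(rng.choice(N, size=K, replace=False))
    assignment = _assign(delta, medoids)
    for _ in range(max_iter):
        # repair empty classes: reseed with the element farthest from the
        # empty class's current medoid
        for k in range(K):
            if not np.any(assignment == k):
                far = int(np.argmax(delta[medoids[k]]))
                assignment[far] = k
        new_medoids = medoids.copy()
        for k in range(K):
            new_medoids[k] = medoid_of_class(delta, np.nonzero(assignment == k)[0])
        new_assignment = _assign(delta, new_medoids)
        # keep each medoid in its own class even under ties
        new_assignment[new_medoids] = np.arange(K)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_assignment, assignment):
            break
        medoids, assignment = new_medoids, new_assignment
    cost = float(delta[np.arange(N), medoids[assignment]].sum())
    return assignment, medoids, cost


def k_medoids(
    delta: DissimilarityMatrix | np.ndarray,
    K: int,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 200,
) -> Clustering:
    """Best-of-``n_restarts`` k-medoids clustering of a dissimilarity matrix.

    Each restart initializes with K distinct medoids sampled uniformly without
    replacement, then alternates assignment and medoid recomputation to a
    local optimum.  Restart initializations are drawn sequentially from one
    seeded stream, so increasing ``n_restarts`` with the same seed only ever
    adds candidate solutions (the returned cost is non-increasing in
    ``n_restarts``).
    """
    vals = delta.values if isinstance(delta, DissimilarityMatrix) else np.asarray(delta, float)
    N = vals.shape[0]
    if not (1 <= K <= N):
        raise ValueError(f"K must be in [1, {N}], got {K}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        assignment, medoids, cost = _one_run(vals, K, rng, max_iter)
        if best is None or cost < best[2] - 1e-15:
            best = (assignment, medoids, cost)
    assignment, medoids, cost = best
    # canonical labelling: classes ordered by medoid index
    order = np.argsort(medoids)
    relabel = np.empty_like(order)
    relabel[order] = np.arange(K)
    return Clustering(
        assignment=relabel[assignment],
        medoid_indices=medoids[order],
        total_cost=cost,
    )


def representative_subset(climates: ClimateSet, clustering: Clustering) -> RepresentativeSet:
    """Extract the K medoid series with class sizes attached."""
    if clustering.N != climates.N:
        raise ValueError("clustering does not match the climate set")
    medoid_series = climates.subset(clustering.medoid_indices.tolist())
    return RepresentativeSet(
        climates=medoid_series,
        class_sizes=clustering.class_sizes,
        medoid_indices=clustering.medoid_indices,
    )
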