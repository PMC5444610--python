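"""Bi-objective optimization machinery: dominance, MOPSO-CD, LHS search, hypervolume.

Both objectives (expected yield and CVaR) are maximized.  The main solver is a
multi-objective particle swarm with an external nondominated archive whose
leaders are drawn from the most-isolated (highest crowding distance) archive
members and which is truncated at capacity by discarding the most crowded
entries; a Latin-hypercube random search serves as the baseline.  Fronts are
compared with the two-dimensional hypervolume indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .phenotype import Phenotype, TraitBounds
from .reconstruction import ObjectivePair

ObjectiveFn = Callable[[Phenotype], ObjectivePair]


def dominates(a: ObjectivePair, b: ObjectivePair) -> bool:
    """Pareto dominance for maximization: a >= b in both and > in at least one."""
    return (
        a.mean >= b.mean
        and a.cvar >= b.cvar
        and (a.mean > b.mean or a.cvar > b.cvar)
    )


def _dominates_vec(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a >= b) and np.any(a > b))


def pareto_filter(points: Sequence[ObjectivePair]) -> list[int]:
    """Indices of the nondominated points, with exact duplicates deduplicated.

    The result is independent of input order (the lowest index of each
    duplicate group is kept).
    """
    if len(points) == 0:
        raise ValueError("pareto_filter needs at least one point")
    arr = np.array([[p.mean, p.cvar] for p in points])
    keep: list[int] = []
    seen: set[tuple[float, float]] = set()
    for i in range(len(points)):
        key = (arr[i, 0], arr[i, 1])
        if key in seen:
            continue
        if any(_dominates_vec(arr[j], arr[i]) for j in range(len(points)) if j != i):
            continue
        seen.add(key)
        keep.append(i)
    return keep


def crowding_distance(front: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of a nondominated front (n x 2 array).

    Boundary points get infinity; interior points the sum over objectives of
    the neighbour gap normalized by the objective's range.
    """
    front = np.asarray(front, dtype=float)
    n = front.shape[0]
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for m in range(front.shape[1]):
        order = np.argsort(front[:, m], kind="stable")
        span = front[order[-1], m] - front[order[0], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        gaps = (front[order[2:], m] - front[order[:-2], m]) / span
        dist[order[1:-1]] += gaps
    return dist


class ParetoArchive:
    """Bounded external archive of mutually nondominated (phenotype, objectives).

    Insertion rejects dominated candidates and evicts newly dominated members;
    when over capacity the entry with the lowest crowding distance (the most
    crowded) is dropped.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.phenotypes: list[Phenotype] = []
        self.objectives: list[ObjectivePair] = []

    def __len__(self) -> int:
        return len(self.phenotypes)

    def objective_array(self) -> np.ndarray:
        return np.array([[o.mean, o.cvar] for o in self.objectives]).reshape(-1, 2)

    def add(self, x: Phenotype, obj: ObjectivePair) -> bool:
        """Insert a candidate; returns True if it entered the archive."""
        cand = obj.as_array()
        arr = self.objective_array()
        for row in arr:
            if _dominates_vec(row, cand) or np.array_equal(row, cand):
                return False
        keep = [i for i, row in enumerate(arr) if not _dominates_vec(cand, row)]
        self.phenotypes = [self.phenotypes[i] for i in keep]
        self.objectives = [self.objectives[i] for i in keep]
        self.phenotypes.append(x)
        self.objectives.append(obj)
        if len(self.phenotypes) > self.capacity:
            crowd = crowding_distance(self.objective_array())
            drop = int(np.argmin(crowd))
            del self.phenotypes[drop]
            del self.objectives[drop]
        return True

    def crowding(self) -> np.ndarray:
        return crowding_distance(self.objective_array())

    def sorted_by_mean(self) -> list[tuple[Phenotype, ObjectivePair]]:
        order = np.argsort([o.mean for o in self.objectives], kind="stable")
        return [(self.phenotypes[i], self.objectives[i]) for i in order]

    def to_frame(self) -> pd.DataFrame:
        if not self.phenotypes:
            return pd.DataFrame()
        names = self.phenotypes[0].bounds.names
        rows = []
        crowd = self.crowding()
        for i, (x, o) in enumerate(zip(self.phenotypes, self.objectives)):
            row = dict(zip(names, x.traits))
            row.update(mean=o.mean, cvar=o.cvar, crowding=crowd[i])
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SolverConfig:
    """MOPSO-CD parameters.

    The product ``population * (iterations + 1)`` is the number of objective
    evaluations (the initial population counts).
    """

    population: int
    iterations: int
    inertia: float = 0.4
    cognitive: float = 1.0
    social: float = 1.0
    mutation_prob: float = 0.5
    archive_capacity: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def capacity(self) -> int:
        if self.archive_capacity is not None:
            return self.archive_capacity
        return max(100, 2 * self.population)

    @property
    def n_evaluations(self) -> int:
        return self.population * (self.iterations + 1)


def _select_leader(archive: ParetoArchive, rng: np.random.Generator) -> np.ndarray:
    crowd = archive.crowding()
    n_top = max(1, math.ceil(0.1 * len(archive)))
    order = np.argsort(-np.nan_to_num(crowd, posinf=np.finfo(float).max), kind="stable")
    pick = order[int(rng.integers(n_top))]
    return archive.phenotypes[pick].traits


def mopso_cd(
    objective_fn: ObjectiveFn,
    bounds: TraitBounds,
    cfg: SolverConfig,
    init_archive: ParetoArchive | None = None,
) -> tuple[ParetoArchive, int]:
    """Multi-objective particle swarm with crowding-distance archive.

    Velocity update uses inertia plus cognitive (personal best) and social
    (archive leader) pulls; leaders are drawn uniformly from the top-decile
    crowding-distance archive members.  A mutation with linearly decaying
    probability and scope re-seeds single coordinates.  Positions are clipped
    to the bounds with the violating velocity component zeroed.  Entries of
    ``init_archive`` (e.g. a previous phase's front) are injected into the
    archive without re-evaluation.

    Returns the archive and the exact number of objective evaluations,
    ``population * (iterations + 1)``.
    """
    rng = np.random.default_rng(cfg.seed)
    d = bounds.d
    pop = cfg.population
    width = bounds.width

    archive = ParetoArchive(cfg.capacity)
    if init_archive is not None:
        for x, o in zip(init_archive.phenotypes, init_archive.objectives):
            archive.add(x, o)

    pos = bounds.lower + rng.random((pop, d)) * width
    vel = np.zeros((pop, d))
    n_evals = 0

    def evaluate(row: np.ndarray) -> ObjectivePair:
        nonlocal n_evals
        n_evals += 1
        return objective_fn(Phenotype(row.copy(), bounds))

    objs = [evaluate(pos[i]) for i in range(pop)]
    pbest = pos.copy()
    pbest_obj = list(objs)
    for i in range(pop):
        archive.add(Phenotype(pos[i].copy(), bounds), objs[i])

    for it in range(cfg.iterations):
        frac = 1.0 - it / cfg.iterations
        for i in range(pop):
            leader = _select_leader(archive, rng)
            r1 = rng.random(d)
            r2 = rng.random(d)
            vel[i] = (
                cfg.inertia * vel[i]
                + cfg.cognitive * r1 * (pbest[i] - pos[i])
                + cfg.social * r2 * (leader - pos[i])
            )
            pos[i] = pos[i] + vel[i]
            # keep the swarm in the box; kill the velocity that pushed it out
            low = pos[i] < bounds.lower
            high = pos[i] > bounds.upper
            vel[i][low | high] = 0.0
            pos[i] = np.clip(pos[i], bounds.lower, bounds.upper)
            # mutation with decaying probability and scope
            if rng.random() < cfg.mutation_prob * frac:
                j = int(rng.integers(d))
                scope = 0.5 * width[j] * frac
                pos[i, j] = float(
                    np.clip(
                        pos[i, j] + rng.uniform(-scope, scope),
                        bounds.lower[j],
                        bounds.upper[j],
                    )
                )
        for i in range(pop):
            obj = evaluate(pos[i])
            if dominates(obj, pbest_obj[i]) or (
                not dominates(pbest_obj[i], obj) and rng.random() < 0.5
            ):
                pbest[i] = pos[i].copy()
                pbest_obj[i] = obj
            archive.add(Phenotype(pos[i].copy(), bounds), obj)

    assert n_evals == cfg.n_evaluations
    return archive, n_evals


def lhs_random_search(
    objective_fn: ObjectiveFn,
    bounds: TraitBounds,
    n_points: int,
    seed: int | None = None,
) -> tuple[ParetoArchive, int]:
    """Evaluate a Latin-hypercube design and return its Pareto front.

    Exactly ``n_points`` objective evaluations.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points == 1:
        design = (bounds.lower + bounds.upper)[None, :] * 0.5
    else:
        sampler = qmc.LatinHypercube(d=bounds.d, seed=np.random.default_rng(seed))
        design = qmc.scale(sampler.random(n_points), bounds.lower, bounds.upper)
    archive = ParetoArchive(capacity=max(100, n_points))
    n_evals = 0
    for row in design:
        x = Phenotype(row, bounds)
        obj = objective_fn(x)
        n_evals += 1
        archive.add(x, obj)
    return archive, n_evals


def hypervolume(front: Sequence[ObjectivePair] | np.ndarray, reference: tuple[float, float]) -> float:
    """Two-dimensional hypervolume (area dominated by the front above ``reference``).

    Every front point must weakly dominate the reference point.  Dominated or
    duplicate points do not change the value.
    """
    if isinstance(front, np.ndarray):
        arr = np.asarray(front, dtype=float).reshape(-1, 2)
    else:
        arr = np.array([[p.mean, p.cvar] for p in front])
    if arr.size == 0:
        raise ValueError("empty front")
    ref = np.asarray(reference, dtype=float)
    if np.any(arr[:, 0] < ref[0]) or np.any(arr[:, 1] < ref[1]):
        bad = arr[(arr[:, 0] < ref[0]) | (arr[:, 1] < ref[1])][0]
        raise ValueError(f"front point {tuple(bad)} does not dominate the reference {tuple(ref)}")
    # keep the nondominated staircase only
    order = np.argsort(-arr[:, 0], kind="stable")
    area = 0.0
    best_cvar = ref[1]
    prev_mean = None
    for i in order:
        mean_i, cvar_i = arr[i]
        if cvar_i <= best_cvar:
            continue
        area += (mean_i - ref[0]) * (cvar_i - best_cvar)
        best_cvar = cvar_i
        prev_mean = mean_i
    return float(area)
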