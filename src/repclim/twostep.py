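"""End-to-end two-step optimization and the three-budget benchmark.

The two-step strategy: (1) learn — evaluate a space-filling phenotype basis on
every season, build the combined dissimilarity, cluster, and learn the
residual library; (2) optimize on the representative subset with MOPSO-CD
using reconstructed objectives; (3) re-learn — evaluate a new basis taken from
the interim Pareto front on every season and rebuild the residuals (same
clustering); (4) re-optimize.  Each subset objective evaluation costs K
simulator runs instead of N, and each learning phase costs l * N runs, so the
total simulator budget is 2 * (iterations + 1) * population * K + 2 * l * N —
an identity that is asserted, not merely reported.

The benchmark compares the two-step solver against a full-set MOPSO-CD and an
LHS random search at matched simulator budgets, scoring each run by the
hypervolume of its archive's *true* (full-set) objectives; the re-evaluation
cost is reported separately and excluded from the optimization budget.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import Clustering, k_medoids, representative_subset
from .crop import CountingSimulator, CropModelConfig, DEFAULT_CROP_CONFIG, yield_matrix
from .dissimilarity import DistanceWeights, WindowConfig, combined_dissimilarity
from .moo import ParetoArchive, SolverConfig, lhs_random_search, mopso_cd, pareto_filter, hypervolume
from .phenotype import Phenotype, PhenotypeBasis, TraitBounds, default_trait_bounds, sample_lhs_basis
from .reconstruction import (
    ObjectivePair,
    build_residual_library,
    empirical_objectives_full,
    reconstructed_objectives,
)
from .weather import ClimateSet

DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class BudgetPlan:
    """One cell of the benchmark: a method at a computational budget.

    ``population`` is the swarm size for the MOPSO methods and the number of
    design points for ``lhs`` (``iterations`` is ignored there).  For the
    two-step method ``iterations`` is the per-phase iteration count (the two
    phases are identical).
    """

    method: str  # "lhs" | "full" | "twostep"
    label: str
    population: int
    iterations: int = 0
    subset_size: int = 10
    basis_size: int = 10
    n_series: int = 190

    def __post_init__(self) -> None:
        if self.method not in ("lhs", "full", "twostep"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.population < 1:
            raise ValueError("population must be positive")
        if self.method != "lhs" and self.iterations < 1:
            raise ValueError("iterations must be positive for swarm methods")


def budget_accounting(plan: BudgetPlan) -> int:
    """Exact number of simulator calls a plan will consume.

    lhs: points * N; full: (iterations + 1) * population * N (the initial
    swarm evaluation counts); twostep: two swarm phases on K representatives
    plus two learning passes of l * N.
    """
    if plan.method == "lhs":
        return plan.population * plan.n_series
    if plan.method == "full":
        return (plan.iterations + 1) * plan.population * plan.n_series
    if plan.method == "twostep":
        return (
            2 * (plan.iterations + 1) * plan.population * plan.subset_size
            + 2 * plan.basis_size * plan.n_series
        )
    raise ValueError(f"unknown method {plan.method!r}")


def default_plans(n_series: int = 190) -> dict[tuple[str, str], BudgetPlan]:
    """The benchmark's nine (method, budget) cells at full scale."""
    plans = [
        BudgetPlan("lhs", "small", population=125, n_series=n_series),
        BudgetPlan("lhs", "medium", population=500, n_series=n_series),
        BudgetPlan("lhs", "large", population=2000, n_series=n_series),
        BudgetPlan("full", "small", population=5, iterations=25, n_series=n_series),
        BudgetPlan("full", "medium", population=10, iterations=50, n_series=n_series),
        BudgetPlan("full", "large", population=20, iterations=100, n_series=n_series),
        BudgetPlan("twostep", "small", population=14, iterations=71, n_series=n_series),
        BudgetPlan("twostep", "medium", population=30, iterations=152, n_series=n_series),
        BudgetPlan("twostep", "large", population=61, iterations=308, n_series=n_series),
    ]
    return {(p.method, p.label): p for p in plans}


def plan_from_budget(
    method: str,
    budget: int,
    n_series: int,
    subset_size: int = 10,
    basis_size: int = 10,
    label: str = "custom",
) -> BudgetPlan:
    """Derive a plan from a raw simulator budget.

    Swarm sizing follows the rule of thumb iterations ~ 5 * population; the
    realized budget (see :func:`budget_accounting`) is the largest one not
    exceeding ``budget``.
    """
    if method == "lhs":
        return BudgetPlan("lhs", label, population=max(1, budget // n_series), n_series=n_series)
    if method == "full":
        # (5p + 1) * p * N <= budget
        pop = max(2, int((budget / (5 * n_series)) ** 0.5))
        while (5 * pop + 1) * pop * n_series > budget and pop > 2:
            pop -= 1
        return BudgetPlan("full", label, population=pop, iterations=5 * pop, n_series=n_series)
    if method == "twostep":
        learn = 2 * basis_size * n_series
        rest = max(budget - learn, 2 * subset_size * 12)
        pop = max(2, int((rest / (2 * 5 * subset_size)) ** 0.5))
        while 2 * (5 * pop + 1) * pop * subset_size > rest and pop > 2:
            pop -= 1
        return BudgetPlan(
            "twostep", label, population=pop, iterations=5 * pop,
            subset_size=subset_size, basis_size=basis_size, n_series=n_series,
        )
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class RunRecord:
    """Outcome of one optimization run with its audited simulator-call count."""

    method: str
    label: str
    seed: int
    n_calls: int
    archive: ParetoArchive
    clustering: Clustering | None = None
    alpha: float = DEFAULT_ALPHA


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def select_restart_basis(
    archive: ParetoArchive,
    l: int,
    seed: int | np.random.SeedSequence | None = None,
    bounds: TraitBounds | None = None,
) -> PhenotypeBasis:
    """Pick ``l`` phenotypes spread along the archive's Pareto front.

    The archive is sorted by the mean objective and entries are taken at
    equally spaced ranks (endpoints included).  If the archive holds fewer
    than ``l`` entries, all are taken and the remainder filled by seeded
    uniform resampling of archive members.
    """
    if len(archive) == 0:
        raise ValueError("cannot select a restart basis from an empty archive")
    entries = archive.sorted_by_mean()
    n = len(entries)
    if n >= l:
        idx = np.unique(np.round(np.linspace(0, n - 1, l)).astype(int))
        # rounding collisions are impossible for n >= l, but stay safe
        picks = [entries[i][0] for i in idx]
        while len(picks) < l:
            picks.append(entries[-1][0])
    else:
        rng = np.random.default_rng(seed)
        picks = [e[0] for e in entries]
        extra = rng.integers(0, n, size=l - n)
        picks.extend(entries[int(i)][0] for i in extra)
    return PhenotypeBasis(tuple(picks))


def two_step_optimize(
    climates: ClimateSet,
    plan: BudgetPlan,
    bounds: TraitBounds | None = None,
    weights: DistanceWeights | None = None,
    windows: WindowConfig | None = None,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_restarts: int = 20,
    warm_start: bool = True,
    crop_config: CropModelConfig = DEFAULT_CROP_CONFIG,
) -> RunRecord:
    """Run the full two-step pipeline on a climate set.

    Learning, clustering, subset optimization, re-learning on the interim
    front, and re-optimization.  The audited simulator-call count is asserted
    to equal :func:`budget_accounting` exactly.  With ``warm_start`` the
    second swarm's archive is seeded with the interim front (positions only,
    no re-evaluation).  Deterministic given ``seed``.
    """
    if plan.method != "twostep":
        raise ValueError("two_step_optimize requires a 'twostep' plan")
    if plan.n_series != climates.N:
        raise ValueError(f"plan expects N={plan.n_series} but climate set has N={climates.N}")
    bounds = bounds or default_trait_bounds()
    sim = CountingSimulator(crop_config)
    s_basis, s_cluster, s_m1, s_restart, s_m2 = _child_seeds(seed, 5)

    # --- learning phase 1
    basis = sample_lhs_basis(plan.basis_size, bounds, seed=s_basis)
    Y = yield_matrix(basis, climates, sim)
    delta = combined_dissimilarity(climates, Y, weights, windows)
    clustering = k_medoids(delta, plan.subset_size, n_restarts=n_restarts, seed=s_cluster)
    reps = representative_subset(climates, clustering)
    library = build_residual_library(Y, clustering)

    def subset_objective(lib):
        def objective(x: Phenotype) -> ObjectivePair:
            subset_yields = np.array([sim(x, c) for c in reps.climates])
            return reconstructed_objectives(subset_yields, lib, alpha)
        return objective

    cfg1 = SolverConfig(population=plan.population, iterations=plan.iterations,
                        seed=s_m1)
    archive1, _ = mopso_cd(subset_objective(library), bounds, cfg1)

    # --- re-learning on the interim front
    basis2 = select_restart_basis(archive1, plan.basis_size, seed=s_restart, bounds=bounds)
    Y2 = yield_matrix(basis2, climates, sim)
    library2 = build_residual_library(Y2, clustering)

    cfg2 = replace(cfg1, seed=s_m2)
    archive2, _ = mopso_cd(
        subset_objective(library2), bounds, cfg2,
        init_archive=archive1 if warm_start else None,
    )

    expected = budget_accounting(plan)
    if sim.calls != expected:
        raise AssertionError(
            f"simulator-call audit failed: {sim.calls} calls, accounting predicts {expected}"
        )
    return RunRecord(
        method="twostep", label=plan.label, seed=seed, n_calls=sim.calls,
        archive=archive2, clustering=clustering, alpha=alpha,
    )


def full_optimize(
    climates: ClimateSet,
    plan: BudgetPlan,
    bounds: TraitBounds | None = None,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    crop_config: CropModelConfig = DEFAULT_CROP_CONFIG,
) -> RunRecord:
    """Baseline: MOPSO-CD with exact objectives on the full climate set."""
    if plan.method != "full":
        raise ValueError("full_optimize requires a 'full' plan")
    if plan.n_series != climates.N:
        raise ValueError(f"plan expects N={plan.n_series} but climate set has N={climates.N}")
    bounds = bounds or default_trait_bounds()
    sim = CountingSimulator(crop_config)
    (s_m,) = _child_seeds(seed, 1)

    def objective(x: Phenotype) -> ObjectivePair:
        return empirical_objectives_full(x, climates, alpha, sim)

    cfg = SolverConfig(population=plan.population, iterations=plan.iterations, seed=s_m)
    archive, _ = mopso_cd(objective, bounds, cfg)
    expected = budget_accounting(plan)
    if sim.calls != expected:
        raise AssertionError(
            f"simulator-call audit failed: {sim.calls} calls, accounting predicts {expected}"
        )
    return RunRecord(method="full", label=plan.label, seed=seed, n_calls=sim.calls,
                     archive=archive, alpha=alpha)


def lhs_optimize(
    climates: ClimateSet,
    plan: BudgetPlan,
    bounds: TraitBounds | None = None,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    crop_config: CropModelConfig = DEFAULT_CROP_CONFIG,
) -> RunRecord:
    """Baseline: Pareto filter of an LHS design evaluated with exact objectives."""
    if plan.method != "lhs":
        raise ValueError("lhs_optimize requires an 'lhs' plan")
    if plan.n_series != climates.N:
        raise ValueError(f"plan expects N={plan.n_series} but climate set has N={climates.N}")
    bounds = bounds or default_trait_bounds()
    sim = CountingSimulator(crop_config)
    (s_lhs,) = _child_seeds(seed, 1)

    def objective(x: Phenotype) -> ObjectivePair:
        return empirical_objectives_full(x, climates, alpha, sim)

    archive, _ = lhs_random_search(objective, bounds, plan.population, seed=s_lhs)
    expected = budget_accounting(plan)
    if sim.calls != expected:
        raise AssertionError(
            f"simulator-call audit failed: {sim.calls} calls, accounting predicts {expected}"
        )
    return RunRecord(method="lhs", label=plan.label, seed=seed, n_calls=sim.calls,
                     archive=archive, alpha=alpha)


def run_plan(climates: ClimateSet, plan: BudgetPlan, seed: int = 0, **kwargs) -> RunRecord:
    """Dispatch a plan to its solver.

    Learning-stage options (weights, windows, restarts, warm start) only apply
    to the two-step method and are ignored by the baselines.
    """
    if plan.method == "twostep":
        return two_step_optimize(climates, plan, seed=seed, **kwargs)
    for key in ("weights", "windows", "n_restarts", "warm_start"):
        kwargs.pop(key, None)
    if plan.method == "full":
        return full_optimize(climates, plan, seed=seed, **kwargs)
    return lhs_optimize(climates, plan, seed=seed, **kwargs)


def true_front(
    record: RunRecord,
    climates: ClimateSet,
    crop_config: CropModelConfig = DEFAULT_CROP_CONFIG,
) -> tuple[np.ndarray, int]:
    """Re-evaluate every archived phenotype on the full set and Pareto-filter.

    Returns the nondominated true objective points (n x 2) and the number of
    simulator calls spent on re-evaluation (excluded from optimization
    budgets, reported separately).
    """
    sim = CountingSimulator(crop_config)
    objs = [
        empirical_objectives_full(x, climates, record.alpha, sim)
        for x in record.archive.phenotypes
    ]
    keep = pareto_filter(objs)
    pts = np.array([[objs[i].mean, objs[i].cvar] for i in keep])
    return pts, sim.calls


def replicate_benchmark(
    climates: ClimateSet,
    plans: Sequence[BudgetPlan],
    n_replicates: int = 10,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    bounds: TraitBounds | None = None,
    reference_margin: float = 0.05,
    crop_config: CropModelConfig = DEFAULT_CROP_CONFIG,
    **run_kwargs,
) -> pd.DataFrame:
    """Replicated benchmark across (method, budget) cells.

    Every run's archive is re-evaluated with true full-set objectives; all
    runs share one hypervolume reference point, the componentwise minimum over
    every true front minus ``reference_margin`` times the objective range.
    Returns a long-format table with one row per (cell, replicate).
    """
    bounds = bounds or default_trait_bounds()
    rows = []
    fronts = []
    for ci, plan in enumerate(plans):
        for rep in range(n_replicates):
            run_seed = int(
                np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0] % (2**31)
            )
            record = run_plan(
                climates, plan, seed=run_seed, alpha=alpha, bounds=bounds,
                crop_config=crop_config, **run_kwargs,
            )
            front, reval_calls = true_front(record, climates, crop_config)
            fronts.append(front)
            rows.append(
                {
                    "method": plan.method,
                    "budget": plan.label,
                    "replicate": rep,
                    "seed": run_seed,
                    "n_calls": record.n_calls,
                    "reeval_calls": reval_calls,
                    "front_size": front.shape[0],
                }
            )
    allpts = np.vstack(fronts)
    span = allpts.max(axis=0) - allpts.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    reference = allpts.min(axis=0) - reference_margin * span
    for row, front in zip(rows, fronts):
        row["hypervolume"] = hypervolume(front, tuple(reference))
        row["ref_mean"] = reference[0]
        row["ref_cvar"] = reference[1]
    return pd.DataFrame(rows)
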