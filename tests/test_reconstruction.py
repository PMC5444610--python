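import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import repclim as rc
from repclim.reconstruction import (
    ReconstructedDistribution,
    build_residual_library,
    estimate_cvar,
    estimate_mean,
    reconstruct_atoms,
    sigma_K,
)
from conftest import random_phenotypes


class TestSigmaK:
    def test_equal_subset_yields_give_zero_spread(self):
        assert sigma_K(np.full(4, 2.5), np.array([3, 1, 2, 4])) == 0.0

    def test_hand_case_equal_sizes(self):
        # sizes (1,1), yields (0,2): mean 1, var (1+1)/2 = 1
        assert sigma_K(np.array([0.0, 2.0]), np.array([1, 1])) == pytest.approx(1.0)

    def test_hand_case_weighted(self):
        # sizes (3,1), yields (0,4): mean 1, var (3*1 + 1*9)/4 = 3
        assert sigma_K(np.array([0.0, 4.0]), np.array([3, 1])) == pytest.approx(np.sqrt(3.0))

    def test_size_mismatch_is_rejected(self):
        with pytest.raises(ValueError):
            sigma_K(np.zeros(3), np.ones(2))


class TestResidualLibrary:
    def test_singleton_classes_have_zero_residuals(self, yields_small, climate_small, delta_small):
        cl = rc.k_medoids(delta_small, climate_small.N, n_restarts=1, seed=0)
        lib = build_residual_library(yields_small, cl)
        for r in lib.residuals:
            assert np.array_equal(r, np.zeros(1))

    def test_hand_case_single_basis_point(self):
        # one class {medoid, other} with yields (2, 3); a second class fixes
        # sigma_K = 0.5: yields (2, 3) at sizes (2, 2) -> mean 2.5, var 0.25
        from repclim.clustering import Clustering

        Y = np.array([[2.0, 3.0, 3.0, 3.0]])
        cl = Clustering(
            assignment=np.array([0, 0, 1, 1]),
            medoid_indices=np.array([0, 2]),
            total_cost=0.0,
        )
        lib = build_residual_library(Y, cl)
        # residual of member 1 in class 0: (3 - 2)/0.5 = 2
        assert lib.residuals[0].tolist() == pytest.approx([0.0, 2.0])

    def test_medoid_entry_is_exactly_zero(self, yields_small, delta_small):
        cl = rc.k_medoids(delta_small, 3, n_restarts=5, seed=1)
        lib = build_residual_library(yields_small, cl)
        for k in range(cl.K):
            medoid_pos = np.nonzero(lib.member_indices[k] == cl.medoid_indices[k])[0][0]
            assert lib.residuals[k][medoid_pos] == 0.0

    def test_flat_basis_point_is_dropped_with_warning(self, delta_small, climate_small):
        cl = rc.k_medoids(delta_small, 3, n_restarts=5, seed=1)
        rng = np.random.default_rng(0)
        Y = rng.random((3, climate_small.N)) + 1.0
        Y[1] = 2.0  # no spread anywhere for this basis phenotype
        with pytest.warns(RuntimeWarning, match="zero spread"):
            lib = build_residual_library(Y, cl)
        assert lib.n_basis_used == 2

    def test_all_flat_basis_is_an_error(self, delta_small, climate_small):
        cl = rc.k_medoids(delta_small, 3, n_restarts=5, seed=1)
        with pytest.raises(ValueError):
            build_residual_library(np.ones((2, climate_small.N)), cl)


class TestReconstruction:
    def test_zero_residuals_reproduce_class_representatives(self, delta_small, climate_small):
        cl = rc.k_medoids(delta_small, 3, n_restarts=5, seed=1)
        from repclim.reconstruction import ResidualLibrary

        lib = ResidualLibrary(
            residuals=tuple(np.zeros(n) for n in cl.class_sizes),
            class_sizes=cl.class_sizes,
            medoid_indices=cl.medoid_indices,
            member_indices=tuple(cl.members(k) for k in range(cl.K)),
            n_basis_used=1,
        )
        subset_yields = np.array([1.0, 2.0, 4.0])
        dist = reconstruct_atoms(subset_yields, lib)
        expected = np.repeat(subset_yields, cl.class_sizes)
        assert np.allclose(np.sort(dist.atoms), np.sort(expected))

    def test_atom_count_and_weights(self, yields_small, delta_small):
        cl = rc.k_medoids(delta_small, 4, n_restarts=5, seed=2)
        lib = build_residual_library(yields_small, cl)
        dist = reconstruct_atoms(np.array([1.0, 2.0, 3.0, 4.0]), lib)
        assert dist.N == delta_small.N
        assert dist.weights.sum() == pytest.approx(1.0)

    def test_exactness_in_the_k_equals_n_limit(self, climate_small, basis_small,
                                               yields_small, delta_small, bounds):
        """With singleton classes the estimates equal the full-set values."""
        cl = rc.k_medoids(delta_small, climate_small.N, n_restarts=1, seed=0)
        lib = build_residual_library(yields_small, cl)
        reps = rc.representative_subset(climate_small, cl)
        for x in random_phenotypes(bounds, 5, seed=13):
            subset = np.array([rc.crop_yield(x, c) for c in reps.climates])
            est = rc.reconstructed_objectives(subset, lib, alpha=0.25)
            full = rc.empirical_objectives_full(x, climate_small, alpha=0.25)
            assert est.mean == pytest.approx(full.mean, rel=1e-12)
            assert est.cvar == pytest.approx(full.cvar, rel=1e-12)

    def test_mean_identity_with_class_weights(self, yields_small, delta_small):
        """estimate_mean equals sum_k (N^k/N)(y_k + sigma * mean(eps_k))."""
        cl = rc.k_medoids(delta_small, 4, n_restarts=5, seed=2)
        lib = build_residual_library(yields_small, cl)
        y = np.array([1.0, 3.0, 2.0, 5.0])
        dist = reconstruct_atoms(y, lib)
        sigma = sigma_K(y, cl.class_sizes)
        expected = sum(
            (nk / cl.N) * (y[k] + sigma * lib.residuals[k].mean())
            for k, nk in enumerate(cl.class_sizes)
        )
        assert estimate_mean(dist) == pytest.approx(expected)


class TestMeanAndCvar:
    def test_constant_atoms(self):
        dist = ReconstructedDistribution(np.full(7, 3.2))
        assert estimate_mean(dist) == pytest.approx(3.2)
        for alpha in (0.05, 0.25, 0.5):
            assert estimate_cvar(dist, alpha) == pytest.approx(3.2)

    def test_hand_enumerated_tail_averages(self):
        atoms = np.arange(1.0, 11.0)
        assert estimate_cvar(atoms, 0.2) == pytest.approx(1.5)   # worst {1, 2}
        assert estimate_cvar(atoms, 0.5) == pytest.approx(3.0)   # worst {1..5}
        assert estimate_mean(atoms) == pytest.approx(5.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_cvar_is_monotone_in_alpha_and_below_the_mean(self, seed):
        rng = np.random.default_rng(seed)
        atoms = rng.normal(size=rng.integers(2, 40))
        values = [estimate_cvar(atoms, a) for a in (0.05, 0.1, 0.25, 0.4, 0.5)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] <= estimate_mean(atoms) + 1e-12

    def test_alpha_out_of_range_is_rejected(self):
        with pytest.raises(ValueError):
            estimate_cvar(np.arange(5.0), 0.6)
        with pytest.raises(ValueError):
            estimate_cvar(np.arange(5.0), 0.0)


class TestFullSetObjectives:
    def test_single_series_mean_equals_cvar(self, climate_small, bounds):
        single = rc.ClimateSet((climate_small[0],))
        x = rc.mid_bounds_phenotype(bounds)
        obj = rc.empirical_objectives_full(x, single, alpha=0.1)
        assert obj.mean == obj.cvar

    def test_matches_estimators_applied_to_true_yields(self, climate_small, bounds):
        x = rc.mid_bounds_phenotype(bounds)
        yields = np.array([rc.crop_yield(x, c) for c in climate_small])
        obj = rc.empirical_objectives_full(x, climate_small, alpha=0.25)
        assert obj.mean == pytest.approx(estimate_mean(yields))
        assert obj.cvar == pytest.approx(estimate_cvar(yields, 0.25))
        assert obj.cvar <= obj.mean

    def test_counts_n_simulator_calls(self, climate_small, bounds):
        sim = rc.CountingSimulator()
        rc.empirical_objectives_full(rc.mid_bounds_phenotype(bounds), climate_small, 0.1, sim)
        assert sim.calls == climate_small.N
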