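import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import repclim as rc
from repclim.dissimilarity import DissimilarityMatrix, normalize_dissimilarity


def dtw_brute_force(a, b, window):
    """Independent oracle: minimum path cost over every admissible warping path.

    Paths go from (0, 0) to (n-1, m-1) with steps (1,0), (0,1), (1,1), stay in
    the band |i - j| <= window, and each visited cell contributes |a_i - b_j|
    once (unit step weights).
    """
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        if abs(i - j) > window:
            return
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDtwDistance:
    def test_identical_series_have_zero_distance(self):
        rng = np.random.default_rng(0)
        s = rng.random(180)
        assert rc.dtw_distance(s, s, 7) == 0.0

    @pytest.mark.parametrize("window", [0, 1, 2, 3])
    def test_matches_exhaustive_path_enumeration(self, window):
        cases = [
            (np.array([0.0, 0.0, 1.0, 0.0]), np.array([0.0, 1.0, 0.0, 0.0])),
            (np.array([1.0, 2.0, 3.0, 2.0, 1.0]), np.array([2.0, 3.0, 1.0, 0.0, 1.0])),
            (np.array([0.0, 5.0, 0.0, 0.0]), np.array([0.0, 0.0, 5.0, 0.0])),
        ]
        for a, b in cases:
            assert rc.dtw_distance(a, b, window) == pytest.approx(
                dtw_brute_force(a, b, window)
            )

    def test_window_zero_reduces_to_unwarped_l1_distance(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(50), rng.random(50)
        assert rc.dtw_distance(a, b, 0) == pytest.approx(np.abs(a - b).sum())

    def test_symmetry_and_window_monotonicity(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a, b = rng.random(40), rng.random(40)
            prev = np.inf
            for w in (0, 1, 3, 7, 15):
                d = rc.dtw_distance(a, b, w)
                assert d == pytest.approx(rc.dtw_distance(b, a, w))
                assert d <= prev + 1e-12
                prev = d

    def test_invalid_inputs_are_rejected(self):
        with pytest.raises(ValueError):
            rc.dtw_distance(np.zeros(5), np.zeros(6), 1)
        with pytest.raises(ValueError):
            rc.dtw_distance(np.zeros(5), np.zeros(5), -1)


class TestVariableDistanceMatrix:
    def test_matches_pairwise_calls(self, climate_small):
        small = climate_small.subset([0, 1, 2])
        mat = rc.variable_distance_matrix(small, "tmax", 7)
        for i in range(3):
            for j in range(3):
                expected = rc.dtw_distance(small[i].tmax, small[j].tmax, 7)
                assert mat.values[i, j] == pytest.approx(expected)

    def test_identical_channels_give_an_all_zero_matrix(self, climate_small):
        shared = climate_small[0].precipitation
        series = tuple(
            s.replace(precipitation=shared.copy()) for s in list(climate_small)[:4]
        )
        mat = rc.variable_distance_matrix(rc.ClimateSet(series), "precipitation", 3)
        assert np.all(mat.values == 0.0)

    def test_symmetric_with_zero_diagonal(self, climate_small):
        mat = rc.variable_distance_matrix(climate_small, "radiation", 7)
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0.0)

    def test_unknown_variable_is_rejected(self, climate_small):
        with pytest.raises(KeyError):
            rc.variable_distance_matrix(climate_small, "humidity", 7)


class TestModelDistance:
    def test_hand_computed_two_basis_case(self):
        # columns (1, 3) and (2, 5): sqrt((1^2 + 2^2)/2) = sqrt(2.5)
        Y = np.array([[1.0, 2.0], [3.0, 5.0]])
        mat = rc.model_distance_matrix(Y)
        assert mat.values[0, 1] == pytest.approx(np.sqrt(2.5))

    def test_identical_columns_have_zero_distance(self):
        Y = np.array([[1.0, 1.0, 2.0], [3.0, 3.0, 1.0]])
        mat = rc.model_distance_matrix(Y)
        assert mat.values[0, 1] == 0.0
        assert mat.values[0, 2] > 0.0

    def test_permuting_basis_rows_leaves_the_matrix_unchanged(self):
        rng = np.random.default_rng(5)
        Y = rng.random((6, 8))
        a = rc.model_distance_matrix(Y).values
        b = rc.model_distance_matrix(Y[::-1]).values
        assert np.allclose(a, b)


class TestNormalization:
    def test_hand_computed_two_point_case(self):
        D = DissimilarityMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), "raw", "toy")
        out = normalize_dissimilarity(D)
        assert out.values[0, 1] == pytest.approx(4.0)
        assert out.values[0, 0] == 0.0 and out.values[1, 1] == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance_and_zero_diagonal(self, seed, scale):
        rng = np.random.default_rng(seed)
        n = 5
        raw = rng.random((n, n)) + 0.5
        raw = raw + raw.T
        np.fill_diagonal(raw, 0.0)
        base = normalize_dissimilarity(DissimilarityMatrix(raw, "raw", "t")).values
        scaled = normalize_dissimilarity(DissimilarityMatrix(scale * raw, "raw", "t")).values
        assert np.allclose(base, scaled, atol=1e-9)
        assert np.all(np.diag(base) == 0.0)
        assert np.allclose(base, base.T)

    def test_all_zero_matrix_warns_and_returns_zeros(self):
        D = DissimilarityMatrix(np.zeros((3, 3)), "raw", "flat")
        with pytest.warns(RuntimeWarning):
            out = normalize_dissimilarity(D)
        assert np.all(out.values == 0.0)
        assert out.kind == "normalized"


class TestCombination:
    @staticmethod
    def _normalized(values, tag):
        return DissimilarityMatrix(values, "normalized", tag)

    def _matrix_dict(self, mats):
        names = rc.DistanceWeights.ORDER
        return {name: m for name, m in zip(names, mats)}

    def test_equal_matrices_are_a_fixed_point(self):
        rng = np.random.default_rng(1)
        m = rng.random((4, 4))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        mats = self._matrix_dict([self._normalized(m, t) for t in rc.DistanceWeights.ORDER])
        out = rc.combine_dissimilarities(mats, rc.DistanceWeights())
        assert np.allclose(out.values, m)

    def test_degenerate_weight_selects_one_matrix(self):
        rng = np.random.default_rng(2)
        mats = []
        for t in rc.DistanceWeights.ORDER:
            m = rng.random((4, 4))
            m = m + m.T
            np.fill_diagonal(m, 0.0)
            mats.append(self._normalized(m, t))
        w = rc.DistanceWeights(tmin=1.0, tmax=0, precipitation=0, evapotranspiration=0,
                               radiation=0, model=0)
        out = rc.combine_dissimilarities(self._matrix_dict(mats), w)
        assert np.allclose(out.values, mats[0].values)

    def test_default_weights_blend_model_and_weather_evenly(self):
        rng = np.random.default_rng(3)
        A = rng.random((4, 4))
        A = A + A.T
        np.fill_diagonal(A, 0.0)
        B = rng.random((4, 4))
        B = B + B.T
        np.fill_diagonal(B, 0.0)
        mats = [self._normalized(A, t) for t in rc.DistanceWeights.ORDER[:-1]]
        mats.append(self._normalized(B, "model"))
        out = rc.combine_dissimilarities(self._matrix_dict(mats), rc.DistanceWeights())
        assert np.allclose(out.values, 0.5 * A + 0.5 * B)

    def test_combination_stays_within_elementwise_bounds(self, climate_small, yields_small):
        raw = rc.climate_distance_matrices(climate_small)
        raw["model"] = rc.model_distance_matrix(yields_small)
        mats = {k: normalize_dissimilarity(v) for k, v in raw.items()}
        out = rc.combine_dissimilarities(mats, rc.DistanceWeights())
        stack = np.stack([m.values for m in mats.values()])
        assert np.all(out.values >= stack.min(axis=0) - 1e-12)
        assert np.all(out.values <= stack.max(axis=0) + 1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            rc.DistanceWeights(tmin=0.2, tmax=0.2, precipitation=0.2,
                               evapotranspiration=0.2, radiation=0.2, model=0.2)
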