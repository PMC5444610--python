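"""Composite dissimilarity between climatic seasons.

Two seasons are compared through six channels: a windowed dynamic-time-warping
(DTW) distance per weather variable (Tmin, Tmax, radiation, evapotranspiration,
precipitation) plus a model-based distance — the root-mean-square difference of
simulator outputs over a basis of phenotypes.  Each of the six N x N matrices
is normalized by Gower double centering (distance -> similarity -> unit
self-similarity -> dissimilarity), which makes the channels scale-free and
comparable, and the six are then blended with convex weights into a single
combined dissimilarity used for clustering.

The DTW here uses an absolute-difference local cost, unit-weight symmetric
steps (each of the three moves adds the local cost once) and a Sakoe-Chiba band
whose half-width is the maximum allowed alignment shift in days.  With a band
of 0 it reduces to the unwarped L1 distance between the two sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .crop import YieldMatrix
from .weather import ClimateSet

VARIABLES = ("tmin", "tmax", "radiation", "evapotranspiration", "precipitation")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """A symmetric, zero-diagonal N x N dissimilarity matrix.

    ``kind`` tracks the processing stage (raw / normalized / combined) and
    ``tag`` the channel it came from (a weather variable, "model", or "delta"
    for the combined matrix).
    """

    values: np.ndarray
    kind: str
    tag: str
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.kind not in ("raw", "normalized", "combined"):
            raise ValueError(f"unknown kind {self.kind!r}")
        n, m = values.shape
        if n != m or n < 1:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if self.kind == "raw" and np.any(values < -1e-12):
            raise ValueError("raw dissimilarities must be nonnegative")
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != n:
                raise ValueError("labels length must match matrix size")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        labels = self.labels or tuple(str(i) for i in range(self.N))
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(
            path, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path, kind: str = "combined", tag: str = "delta") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), kind=kind, tag=tag, labels=tuple(df.index.astype(str)))


@dataclass(frozen=True)
class DistanceWeights:
    """Convex weights of the six channels (five DTW + model-based).

    Default: the model-based distance carries half the weight and each DTW
    channel one tenth.
    """

    tmin: float = 0.1
    tmax: float = 0.1
    precipitation: float = 0.1
    evapotranspiration: float = 0.1
    radiation: float = 0.1
    model: float = 0.5

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < 0):
            raise ValueError("weights must be nonnegative")
        if abs(float(vec.sum()) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {vec.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tmin, self.tmax, self.precipitation, self.evapotranspiration,
             self.radiation, self.model]
        )

    ORDER = ("tmin", "tmax", "precipitation", "evapotranspiration", "radiation", "model")


@dataclass(frozen=True)
class WindowConfig:
    """Maximum DTW alignment shift (days) per weather variable.

    Default: +/-3 days for precipitation (rain events must nearly coincide to
    have the same agronomic effect), +/-7 days for the smoother variables.
    """

    precipitation: int = 3
    default: int = 7
    overrides: dict = field(default_factory=dict)

    def window(self, variable: str) -> int:
        if variable in self.overrides:
            w = self.overrides[variable]
        elif variable == "precipitation":
            w = self.precipitation
        else:
            w = self.default
        w = int(w)
        if w < 0:
            raise ValueError("DTW window must be >= 0")
        return w


@njit(cache=True)
def _dtw_band(a, b, window):  # pragma: no cover - executed via njit
    n = a.shape[0]
    big = 1e300
    prev = np.full(n, big)
    cur = np.full(n, big)
    for i in range(n):
        lo = i - window
        hi = i + window
        if lo < 0:
            lo = 0
        if hi > n - 1:
            hi = n - 1
        for j in range(n):
            cur[j] = big
        for j in range(lo, hi + 1):
            d = a[i] - b[j]
            if d < 0.0:
                d = -d
            if i == 0 and j == 0:
                best = 0.0
            else:
                best = big
                if i > 0 and prev[j] < best:
                    best = prev[j]
                if j > 0 and cur[j - 1] < best:
                    best = cur[j - 1]
                if i > 0 and j > 0 and prev[j - 1] < best:
                    best = prev[j - 1]
            cur[j] = best + d
        tmp = prev
        prev = cur
        cur = tmp
    return prev[n - 1]


@njit(cache=True)
def _pairwise_dtw(data, window):  # pragma: no cover - executed via njit
    n_series = data.shape[0]
    out = np.zeros((n_series, n_series))
    for i in range(n_series):
        for j in range(i + 1, n_series):
            d = _dtw_band(data[i], data[j], window)
            out[i, j] = d
            out[j, i] = d
    return out


def dtw_distance(a: np.ndarray, b: np.ndarray, window: int) -> float:
    """Banded DTW distance between two equal-length daily sequences.

    Dynamic programming over a Sakoe-Chiba band of half-width ``window`` days,
    absolute-difference local cost, unit symmetric steps.  Zero iff the
    sequences are identical; symmetric in (a, b); never increases when the
    window widens.
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    if window < 0:
        raise ValueError("window must be >= 0")
    return float(_dtw_band(a, b, int(window)))


def variable_distance_matrix(
    climates: ClimateSet, variable: str, window: int
) -> DissimilarityMatrix:
    """Raw DTW distance matrix on one weather channel."""
    if variable not in VARIABLES:
        raise KeyError(f"unknown climate variable {variable!r}; expected one of {VARIABLES}")
    if climates.N < 2:
        raise ValueError("need at least two series")
    if window < 0:
        raise ValueError("window must be >= 0")
    data = np.ascontiguousarray(climates.channel_matrix(variable))
    values = _pairwise_dtw(data, int(window))
    return DissimilarityMatrix(values, kind="raw", tag=variable, labels=tuple(climates.labels()))


def climate_distance_matrices(
    climates: ClimateSet, windows: WindowConfig | None = None
) -> dict[str, DissimilarityMatrix]:
    """The five per-variable raw DTW matrices, keyed by variable name."""
    windows = windows or WindowConfig()
    return {
        v: variable_distance_matrix(climates, v, windows.window(v)) for v in VARIABLES
    }


def model_distance_matrix(Y: YieldMatrix | np.ndarray, labels=None) -> DissimilarityMatrix:
    """Model-based distance: RMS yield difference between two seasons.

    d(ci, cj) = sqrt( (1/l) * sum_k (y(x_k, ci) - y(x_k, cj))^2 ) over the l
    basis phenotypes.
    """
    if isinstance(Y, YieldMatrix):
        if labels is None:
            labels = tuple(Y.climates.labels())
        values = Y.values
    else:
        values = np.asarray(Y, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("yield matrix must be a non-empty l x N array")
    l = values.shape[0]
    # pairwise Euclidean distance between columns, scaled by 1/sqrt(l)
    sq = np.sum(values**2, axis=0)
    gram = values.T @ values
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0) / l
    mat = np.sqrt(d2)
    np.fill_diagonal(mat, 0.0)
    mat = 0.5 * (mat + mat.T)
    return DissimilarityMatrix(mat, kind="raw", tag="model",
                               labels=tuple(labels) if labels is not None else None)


def normalize_dissimilarity(D: DissimilarityMatrix) -> DissimilarityMatrix:
    """Gower-normalize a raw dissimilarity matrix.

    Double-center ``-D/2`` into a similarity S, rescale to unit
    self-similarity (s̄_ij = s_ij / sqrt(s_ii s_jj)), and return the
    dissimilarity d̄_ij = 2 - 2 s̄_ij.  The result has an exactly zero
    diagonal, is symmetric, and is invariant to multiplying D by any positive
    constant.  An all-zero input is returned as all zeros with a warning.
    """
    if D.kind != "raw":
        raise ValueError("normalize_dissimilarity expects a raw matrix")
    vals = D.values
    n = vals.shape[0]
    if n < 2:
        raise ValueError("need at least two series to normalize")
    if not np.any(vals):
        warnings.warn(
            f"all-zero dissimilarity matrix ({D.tag}); returning zeros", RuntimeWarning
        )
        return DissimilarityMatrix(np.zeros_like(vals), kind="normalized", tag=D.tag,
                                   labels=D.labels)
    row_mean = vals.mean(axis=1)
    grand_mean = vals.mean()
    S = -0.5 * (vals - row_mean[:, None] - row_mean[None, :] + grand_mean)
    diag = np.diag(S).copy()
    if np.any(diag <= 0):
        raise ValueError(
            f"degenerate geometry in '{D.tag}' matrix: non-positive self-similarity "
            "after double centering"
        )
    scale = np.sqrt(diag)
    s_bar = S / np.outer(scale, scale)
    d_bar = 2.0 - 2.0 * s_bar
    np.fill_diagonal(d_bar, 0.0)
    d_bar = 0.5 * (d_bar + d_bar.T)
    return DissimilarityMatrix(d_bar, kind="normalized", tag=D.tag, labels=D.labels)


def combine_dissimilarities(
    matrices: dict[str, DissimilarityMatrix], weights: DistanceWeights | None = None
) -> DissimilarityMatrix:
    """Convex combination of the six normalized channel matrices.

    ``matrices`` must contain the five weather variables plus ``"model"``, all
    normalized and of identical shape.
    """
    weights = weights or DistanceWeights()
    expected = set(DistanceWeights.ORDER)
    if set(matrices) != expected:
        raise ValueError(f"expected matrices for {sorted(expected)}, got {sorted(matrices)}")
    shapes = {m.values.shape for m in matrices.values()}
    if len(shapes) != 1:
        raise ValueError(f"matrix shape mismatch: {shapes}")
    for name, m in matrices.items():
        if m.kind != "normalized":
            raise ValueError(f"matrix '{name}' has kind {m.kind!r}, expected 'normalized'")
    w = weights.as_array()
    stack = np.stack([matrices[name].values for name in DistanceWeights.ORDER])
    combined = np.tensordot(w, stack, axes=1)
    np.fill_diagonal(combined, 0.0)
    labels = next(iter(matrices.values())).labels
    return DissimilarityMatrix(combined, kind="combined", tag="delta", labels=labels)


def combined_dissimilarity(
    climates: ClimateSet,
    Y: YieldMatrix,
    weights: DistanceWeights | None = None,
    windows: WindowConfig | None = None,
) -> DissimilarityMatrix:
    """End-to-end: five DTW matrices + model matrix -> normalize -> combine."""
    raw = climate_distance_matrices(climates, windows)
    raw["model"] = model_distance_matrix(Y)
    normalized = {name: normalize_dissimilarity(m) for name, m in raw.items()}
    return combine_dissimilarities(normalized, weights)
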