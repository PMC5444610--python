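"""Deterministic toy crop model mapping (phenotype, season) to grain yield.

The model is a compact, three-compartment annual-crop simulator built so that
every trait and the *timing* of weather events influence yield:

1. **Phenology** — thermal time (daily mean temperature above a base) is
   accumulated from day 1; flowering occurs when it reaches TDF1 and
   physiological maturity at TDM3.
2. **Canopy and light capture** — a potential leaf-area index is built from
   leaf number (TLN), largest-leaf area (LLS) and the position of the largest
   leaf in the profile (LLH); it grows with thermal time until flowering and
   senesces to zero at maturity.  Daily intercepted radiation follows Beer's
   law with extinction coefficient K.
3. **Water stress** — a single-bucket soil-water balance accumulates rain and
   loses a crop-coefficient multiple of reference evapotranspiration; the
   bucket's relative depletion is mapped to a pseudo water potential.  Leaf
   expansion is reduced below the threshold LE and radiation-use efficiency
   (stomatal closure) below TR.

Biomass is intercepted radiation times a radiation-use efficiency times the
stomatal stress factor, and yield is a fixed harvest index times biomass.  Soil
depletion deliberately does not feed back on canopy size, so adding rain can
never reduce yield (a monotonicity the test suite exercises); all remaining
couplings make the *date* of a rain event matter, which is what justifies
windowed time-warping distances between seasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phenotype import Phenotype, PhenotypeBasis, TraitBounds
from .weather import ClimateSeries, ClimateSet


@dataclass(frozen=True)
class CropModelConfig:
    """Constants of the toy crop model (all in one place).

    Units: temperatures degC, radiation MJ/m2/day, water mm, biomass g/m2,
    yield t/ha.
    """

    t_base: float = 4.8          # base temperature for thermal time
    density: float = 6.5         # plants per m2
    profile_spread: float = 0.30  # leaf-size profile width, fraction of TLN
    rue: float = 1.3             # radiation-use efficiency, g biomass per MJ
    harvest_index: float = 0.35
    soil_capacity: float = 180.0  # bucket size, mm
    initial_soil_water: float = 160.0
    crop_coefficient: float = 0.55  # fraction of reference ET withdrawn daily
    psi_min: float = -18.0       # pseudo water potential of an empty bucket, bar
    stress_ramp: float = 4.0     # bar over which a stress response saturates
    # opportunity cost of drought tolerance: a conservative cultivar (stress
    # threshold far below the reference) sacrifices part of its well-watered
    # performance, which is what creates the mean/CVaR trade-off
    tr_reference: float = -5.81  # least tolerant stomatal threshold, bar
    tr_cost: float = 0.030       # RUE fraction lost per bar of stomatal tolerance
    le_reference: float = -2.31  # least tolerant expansion threshold, bar
    le_cost: float = 0.012       # potential-LAI fraction lost per bar of tolerance

    @property
    def yield_potential_per_mj(self) -> float:
        """Upper bound on yield per MJ of seasonal radiation (t/ha per MJ/m2)."""
        return self.rue * self.harvest_index * 0.01


DEFAULT_CROP_CONFIG = CropModelConfig()


def _leaf_profile_factor(tln: float, llh: float, spread: float) -> float:
    """Mean relative leaf size over the profile, in (0, 1].

    Leaf areas follow a Gaussian profile peaking at rank LLH with width
    ``spread * TLN``; the factor is the profile mean relative to the largest
    leaf (LLS).
    """
    ranks = np.arange(1.0, np.floor(tln) + 1.0)
    rel = np.exp(-(((ranks - llh) / (spread * tln)) ** 2))
    return float(rel.mean())


def _soil_water_fraction(
    precipitation: np.ndarray, etp: np.ndarray, cfg: CropModelConfig
) -> np.ndarray:
    """Daily relative soil-water content of the single bucket, in [0, 1]."""
    n = precipitation.size
    frac = np.empty(n)
    w = cfg.initial_soil_water
    cap = cfg.soil_capacity
    kc = cfg.crop_coefficient
    for t in range(n):
        w = w + precipitation[t] - kc * etp[t]
        w = 0.0 if w < 0.0 else (cap if w > cap else w)
        frac[t] = w / cap
    return frac


def _stress_factor(psi: np.ndarray, threshold: float, ramp: float) -> np.ndarray:
    """1 when psi >= threshold, linear down to 0 at threshold - ramp."""
    return np.clip((psi - (threshold - ramp)) / ramp, 0.0, 1.0)


def crop_yield(
    x: Phenotype, c: ClimateSeries, config: CropModelConfig = DEFAULT_CROP_CONFIG
) -> float:
    """Grain yield (t/ha) of phenotype ``x`` under season ``c``.

    Deterministic; nonnegative; bounded above by
    ``config.yield_potential_per_mj * sum(radiation)``.
    """
    if not isinstance(x, Phenotype):
        raise TypeError("x must be a Phenotype")
    if not isinstance(c, ClimateSeries):
        raise TypeError("c must be a ClimateSeries")
    tdf1, tdm3, tln, k_ext, llh, lls, le, tr = (
        x["TDF1"], x["TDM3"], x["TLN"], x["K"], x["LLH"], x["LLS"], x["LE"], x["TR"],
    )

    tmean = 0.5 * (c.tmin + c.tmax)
    dd = np.maximum(tmean - config.t_base, 0.0)
    thermal_time = np.cumsum(dd)

    # water status -> pseudo potential in [psi_min, 0]
    frac = _soil_water_fraction(c.precipitation, c.evapotranspiration, config)
    psi = config.psi_min * (1.0 - frac)
    # a tolerant (low) threshold keeps the plant functioning under drought but
    # costs well-watered performance, so risk protection is not free
    tr_tolerance = max(config.tr_reference - tr, 0.0)
    le_tolerance = max(config.le_reference - le, 0.0)
    expansion = _stress_factor(psi, le, config.stress_ramp)
    stomatal = (1.0 - config.tr_cost * tr_tolerance) * _stress_factor(psi, tr, config.stress_ramp)

    # canopy: thermal-time-driven growth to a potential LAI at flowering,
    # modulated daily by the expansion stress; senescence tied to phenology only
    lai_potential = (
        (1.0 - config.le_cost * le_tolerance)
        * config.density * tln * (lls * 1e-4) * _leaf_profile_factor(tln, llh, config.profile_spread)
    )
    growth_rate = lai_potential * dd / tdf1
    growth_rate = np.where(thermal_time <= tdf1, growth_rate, 0.0)
    green_lai = np.cumsum(growth_rate * expansion)
    senescence = np.clip((tdm3 - thermal_time) / (tdm3 - tdf1), 0.0, 1.0)
    lai = green_lai * senescence

    interception = 1.0 - np.exp(-k_ext * lai)
    biomass = float(np.sum(config.rue * c.radiation * interception * stomatal))
    return config.harvest_index * biomass * 0.01


class CountingSimulator:
    """Callable wrapper around the crop model that audits simulator calls.

    Budget accounting in the optimization benchmark is stated in numbers of
    simulator runs, so every call made on behalf of an optimizer goes through
    one of these counters.
    """

    def __init__(self, config: CropModelConfig = DEFAULT_CROP_CONFIG):
        self.config = config
        self.calls = 0

    def __call__(self, x: Phenotype, c: ClimateSeries) -> float:
        self.calls += 1
        return crop_yield(x, c, self.config)


@dataclass(frozen=True)
class YieldMatrix:
    """The l x N matrix y(B, C) of yields for a basis against a climate set."""

    values: np.ndarray
    basis: PhenotypeBasis
    climates: ClimateSet
    n_calls: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.basis.l, self.climates.N):
            raise ValueError(
                f"yield matrix shape {values.shape} does not match basis "
                f"({self.basis.l}) x climates ({self.climates.N})"
            )
        if np.any(values < 0):
            raise ValueError("negative yields in YieldMatrix")


def yield_matrix(
    basis: PhenotypeBasis,
    climates: ClimateSet,
    simulator: CountingSimulator | None = None,
) -> YieldMatrix:
    """Evaluate the simulator on every (basis point, series) pair.

    Exactly ``l * N`` simulator calls are made and recorded on the returned
    matrix (and on ``simulator`` if one is passed in).
    """
    sim = simulator if simulator is not None else CountingSimulator()
    before = sim.calls
    values = np.array([[sim(x, c) for c in climates] for x in basis])
    return YieldMatrix(values=values, basis=basis, climates=climates, n_calls=sim.calls - before)
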