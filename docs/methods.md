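# Methods

This note documents the models and numerical choices behind `repclim`: what
each stage computes, the defaults and why, what the synthetic testbed does and
does not emulate, and the known limitations.

## Problem setting

A simulator y(**x**, c) maps a phenotype **x** (8 traits in a box, see
`phenotype.default_trait_bounds`) and one growing season c (5 daily weather
variables × 180 days) to grain yield in t/ha. With climate uncertain over a
finite ensemble Ω of N seasons, the package maximizes the pair
(E[Y(**x**)], CVaR_α[Y(**x**)]). CVaR_α is the average of the
m = max(1, ⌈αN⌉) smallest yields; the ceiling makes the tail conservative
when αN is not an integer and reduces to the "(N·α)-th worst seasons" reading
when it is. The tail level defaults to α = 0.1 — a choice, not a calibrated
value; anything in (0, 0.5] is supported.

## Composite dissimilarity

Per weather variable, seasons are compared with banded dynamic time warping:
absolute-difference local cost, steps (1,0), (0,1), (1,1) each adding the
local cost once (unit symmetric weights), Sakoe–Chiba half-width equal to the
maximum admissible shift in days. With a band of 0 the distance is the
unwarped L1 distance; widening the band can only decrease it. Unit step
weights were chosen over diagonal-weight-2 variants so that the zero-window
limit is the plain L1 distance; since every matrix is subsequently normalized,
the choice affects little beyond that identity. Default windows are ±3 days
for precipitation and ±7 days for the smoother variables: a rain event a few
days off has a similar agronomic effect, a week's shift in temperature matters
little.

The sixth, model-based distance is the RMS yield difference between two
seasons over an l-point Latin-hypercube basis (default l = 10). It captures
equivalences the weather channels cannot (different weather, same crop
response), at the price of depending on the basis — which is why the two-step
strategy re-learns it near the optimum later.

Each of the six raw matrices is normalized by Gower double centering:
S = −½ J D J with J = I − 11ᵀ/N, then s̄ᵢⱼ = sᵢⱼ/√(sᵢᵢ·sⱼⱼ), and
d̄ᵢⱼ = 2 − 2·s̄ᵢⱼ. This yields a symmetric, zero-diagonal matrix invariant
under positive rescaling of D, so the six channels are comparable without
per-channel tuning. d̄ is kept as is (no square root), i.e. treated as a
generic dissimilarity, not embedded coordinates. The rescaling uses the
geometric mean √(sᵢᵢ·sⱼⱼ), which is what forces s̄ᵢᵢ = 1 and hence
d̄ᵢᵢ = 0. Degenerate inputs: an all-zero matrix normalizes to all zeros with
a warning; a non-positive centered self-similarity (geometry too degenerate
to rescale) raises. Daily values are not pre-scaled before DTW; the windows
plus per-matrix normalization carry that burden.

The combined dissimilarity is the convex blend δ = Σ α_v d̄^v with default
weights ½ on the model channel and ⅒ on each weather channel, giving the
model-based view the same total weight as the five weather views together.

## Subset selection

k-medoids on δ, PAM-style alternation: assign each season to the nearest
medoid, recompute each class's medoid (the member minimizing the within-class
dissimilarity sum, ties to the lowest index), repeat to a local optimum; best
of n_restarts = 20 seeded uniform initializations (defaults: K = 10).
Restart initializations are drawn sequentially from a single stream, so a
longer restart schedule with the same seed can only improve the returned
cost. An emptied class is reseeded with the element farthest from its
previous medoid. Classes are relabelled by ascending medoid index, making the
output invariant to restart order. Automatic choice of K is out of scope.

## Reconstruction

The learning matrix y(B, Ω) gives residuals ε_j^k(xᵢ) = y(xᵢ, c_j^k) −
y(xᵢ, ω^k) for every member j of class k. Each is normalized by
σ_K(xᵢ) — the class-size-weighted standard deviation of the medoid yields of
xᵢ — then averaged over the basis into ε̄_j^k. For a new phenotype evaluated
on the K medoids only, class k contributes atoms
y(**x**, ω^k) + σ_K(**x**)·ε̄_j^k, j = 1…N^k. The mixture is *enumerated*
(all N atoms at weight 1/N) rather than sampled with a uniform class index:
same distribution, but deterministic, which removes Monte-Carlo noise from the
optimizer's objectives. Basis phenotypes with σ_K = 0 carry no scale and are
dropped with a warning. In the K = N limit every residual is zero and the
estimates coincide with the full-set empirical values to machine precision —
a chained identity the tests assert.

Two deliberately naive baselines are provided for comparison:
`subset_only_objectives` (class-size-weighted empirical CDF of the K medoid
yields) and `gaussian_objectives` (normal fit by weighted moments, CVaR
μ − σ·φ(z_α)/α). Refinements such as intra-class rescaling, bias correction
or basis-distance weighting are intentionally not implemented.

## Optimization

MOPSO-CD: external nondominated archive with crowding-distance bookkeeping.
Leaders are drawn uniformly from the top decile of archive members by
crowding distance; archive overflow evicts the lowest-crowding entry;
dominated candidates are rejected and newly dominated members evicted on
insertion. Velocity update uses inertia 0.4 and cognitive = social = 1.0; a
mutation with probability 0.5·(1 − t/T) perturbs one coordinate within a
linearly shrinking scope. Positions are clipped to the box and the violating
velocity component zeroed. Archive capacity defaults to max(100,
2·population). These internals are exposed in `SolverConfig`; the two
load-bearing parameters are population and iterations. Objective evaluations
count the initial population: population × (iterations + 1) — the reading
under which the package's budget table is internally consistent. The random
baseline evaluates a Latin-hypercube design and Pareto-filters it. The
hypervolume indicator is the exact 2-D staircase area above a reference
point; in benchmarks the reference is the componentwise minimum over all
compared true fronts minus a 5 % margin of the objective range.

The two-step pipeline: learn (basis → yields → δ → clustering → residuals),
optimize on reconstructed objectives, select l new phenotypes at equally
spaced ranks along the interim front (sorted by mean; seeded resampling fills
a short archive), re-evaluate them on all of Ω, rebuild the residual library
*on the same clustering* (only ε̄ is re-estimated; re-clustering would change
the subset mid-run and is not described as part of the procedure), and
restart the swarm from scratch with the interim front injected into the
initial archive (a config flag; injected entries keep their phase-1 objective
estimates and are never re-evaluated, so the budget identity is exact).
Budgets: lhs = points·N; full = (iterations+1)·population·N; twostep =
2·(iterations+1)·population·K + 2·l·N. Every solver audits its simulator
calls through a counter and raises if the audit deviates from the accounting.
One master seed fans out to per-stage child streams, so each stage is
independently reproducible.

## Synthetic testbed

The weather generator emulates a multi-site ensemble of 180-day seasons
(April–October): seasonal sinusoids for temperature and radiation with AR(1)
daily anomalies (lag-1 correlation 0.7); rain as a marked point process
(Bernoulli occurrence ~0.16–0.33 per day by site, gamma amounts, shape 0.8,
scale 7–9.5 mm) so that discrete rain events exist for DTW to align; cloudy
days compress the diurnal range and radiation; evapotranspiration is a
Hargreaves-style proxy 0.0023·(T̄+17.8)·√ΔT·R, increasing in diurnal range
and radiation. Interannual variability enters through a season-wide
temperature anomaly (sd 1.2 °C) and a log-normal wet/dry-year factor
(sd 0.35) on rain-event probability — without the latter, seasonal rain
totals would be unrealistically tight across years and within-class spread
(what the reconstruction models) would be understated. Default profiles give
three cool/wet "northern" and two warm/dry "southern" sites, so clustering
has real structure to find. tmax ≥ tmin holds by construction (mean ± half
of a positive diurnal range). Every (site, year) has its own seeded
substream, making generation bitwise reproducible and order-independent.

The toy crop model is a contract-driven stand-in for a process-based
simulator, not a reimplementation of one. Three compartments: (i) thermal
time above a 4.8 °C base drives phenology against the trait totals TDF1
(flowering) and TDM3 (maturity); (ii) a potential LAI is assembled from leaf
number TLN, largest-leaf area LLS and a Gaussian leaf-size profile peaking at
rank LLH, grows with thermal time to flowering and senesces linearly in
thermal time to maturity, and intercepts radiation by Beer's law with
coefficient K; (iii) a single 180 mm soil bucket gains rain and loses
0.55 × reference evapotranspiration daily, its relative depletion mapped to a
pseudo water potential in [−18, 0] bar that throttles leaf expansion below
threshold LE and radiation-use efficiency (stomatal closure) below threshold
TR, each over a 4-bar ramp. Biomass is RUE (1.3 g/MJ) × intercepted
radiation × stomatal factor; yield is harvest index 0.35 × biomass. All
constants live in `CropModelConfig`.

Two couplings are deliberate: soil depletion does *not* grow with canopy
size, so adding rain can never reduce yield (a clean monotonicity the tests
exercise); and drought tolerance carries an opportunity cost — lowering
TR/LE below their least-tolerant references scales down RUE (3 %/bar) and
potential LAI (1.2 %/bar). Without that cost the most tolerant cultivar would
dominate in every season and the mean/CVaR front would collapse to a point;
with it, risk protection trades against good-year performance and the Pareto
front is genuinely two-dimensional. Rain *timing* matters through the bucket
dynamics interacting with phenology, which is what justifies windowed DTW on
precipitation.

What the testbed does not emulate: spatial correlation between sites,
multi-day synoptic rain structure, real station statistics, and any
within-plant process beyond the three compartments above. Passing tests
therefore demonstrate the machinery and its internal identities on data with
the assumed structure — cluster-separable ensembles, a simulator smooth in
its traits and sensitive to event timing — not performance on real station
records or a real crop model.

## Problem sizes used in the checks

Budget/dataset accounting is exact integer arithmetic at full scale. The
exactness limit runs on N = 60 with 20 random phenotypes; the estimator
comparison at the full study scale (N = 190, K = 10, l = 10, 50 phenotypes);
the optimizer benchmark on N = 60 with K = 6, l = 6, population 10 and 55
iterations per phase (7,440 simulator calls per run, matched by a 124-point
LHS), 5 replicates per method. These sizes keep the whole suite within a few
tens of seconds while leaving each effect measurable.

## Known limitations

- The advantage of the reconstruction over the subset-only estimator on
  *median* CVaR error is material but finite-sample; on particularly easy
  ensembles (mild tails) the two can tie.
- k-medoids returns a local optimum; the exhaustive-search guarantee is only
  tested at toy sizes (N ≤ 8), and 20 restarts are a heuristic at N = 190.
- The hypervolume reference point is data-derived (shared minimum minus
  margin), so hypervolumes are comparable within a benchmark table, not
  across tables.
- DTW is O(window · length) per pair and O(N²) pairs; at N in the thousands
  the distance stage, not the simulator, would dominate.
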