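# repclim

Robust crop-ideotype optimization with representative climate subsets.

## The problem

Designing a cultivar (an *ideotype*) with a process-based crop simulator means
choosing a trait vector **x** in a box X ⊂ R⁸ that performs well over an
uncertain climate. With N historical growing seasons Ω = {c₁, …, c_N}, the
yield Y(**x**) = y(**x**, C) is a random variable (C uniform over Ω), and the
natural bi-objective formulation maximizes both the expectation and the
lower-tail conditional value-at-risk:

    max_x  E[Y(x)] = (1/N) Σᵢ y(x, cᵢ)
    max_x  CVaR_α[Y(x)] = E[Y(x) | Y(x) ≤ Q_α(Y(x))],   α ∈ (0, 0.5]

Each objective evaluation costs N simulator runs, which makes black-box
multi-objective search prohibitively expensive. `repclim` implements a
non-intrusive workaround:

1. **Representative subset selection** — a composite dissimilarity between
   seasons combines five windowed dynamic-time-warping distances (one per
   weather variable: Tmin, Tmax, radiation, evapotranspiration, precipitation)
   with a model-based distance d^M(cᵢ, cⱼ) = √((1/l) Σₖ (y(xₖ, cᵢ) − y(xₖ, cⱼ))²)
   over an l-point Latin-hypercube phenotype basis; each matrix is
   Gower-normalized and blended with convex weights (model weight ½, each DTW
   channel ⅒). k-medoids on the combined matrix yields K classes with medoid
   seasons ω¹…ω^K.
2. **Non-parametric distribution reconstruction** — the learning matrix
   y(B, Ω) provides, per class, averaged normalized residuals around the
   medoid yield; for a new phenotype evaluated on only the K medoids, the
   residuals are rescaled by the size-weighted spread σ_K(**x**) of its medoid
   yields and enumerated into N equally weighted atoms, from which mean and
   CVaR are read off.
3. **Two-step optimization** — MOPSO-CD (multi-objective particle swarm with
   crowding-distance archive) runs on the reconstructed objectives; a second
   basis is then drawn from the interim Pareto front, residuals are re-learned,
   and the search restarts. Each objective evaluation costs K runs instead of
   N, so the total budget is 2·(iterations+1)·population·K + 2·l·N.

Everything is exercised end to end on a built-in synthetic testbed: a
stochastic multi-site daily weather generator and a deterministic toy crop
model (thermal-time phenology, Beer's-law light interception, bucket
water-balance stress) whose eight traits and sensitivity to rain *timing*
mirror the structure the method assumes.

## Worked example

`examples/03_reconstruction.py` learns on N = 120 seasons with K = 8 classes
and an l = 10 basis (1,200 simulator calls), then estimates a random
phenotype's objectives from 8 runs instead of 120:

```
estimator              mean (t/ha) CVaR_0.1 (t/ha)
full set (truth)             5.100           2.303
reconstruction               5.046           2.300
subset-only                  4.959           2.429
Gaussian fit                 4.959           1.985
```

The reconstructed CVaR (average yield over the worst 10 % of seasons) is
within 0.003 t/ha of the truth, while the subset-only estimate misses the
lower tail and the Gaussian fit overshoots it. The other examples cover the
weather generator (`01`), subset selection (`02`) and the equal-budget
benchmark in which the two-step optimizer roughly doubles the median
hypervolume of LHS random search (`04`).

A thin CLI mirrors the pipeline stages:

```bash
repclim simulate-climate --sites 5 --years 1975:2012 --seed 1 --out climate.csv
repclim dissimilarity --climate climate.csv --basis-size 10 --out delta.csv
repclim cluster --delta delta.csv --k 10 --seed 2 --out clusters.csv
repclim optimize --climate climate.csv --method twostep --budget small --seed 3 --out archive.tsv
repclim benchmark --climate climate.csv --methods lhs,twostep --replicates 10 --seed 4 --out bench.tsv
```

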