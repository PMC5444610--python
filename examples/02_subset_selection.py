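"""Select a representative subset of seasons by composite-dissimilarity clustering.

Pipeline: Latin-hypercube phenotype basis -> yield matrix over all seasons ->
five windowed DTW distance matrices + the model-based distance -> Gower
normalization -> convex combination -> k-medoids.  Prints the class sizes and
the medoid (representative) season of each class; with half the weight on the
model-based distance, classes tend to separate hot/dry from cool/wet seasons.
"""

import repclim as rc

cset = rc.generate_climate_set(n_sites=5, years=range(1995, 2007), seed=11)
basis = rc.sample_lhs_basis(10, seed=1)
Y = rc.yield_matrix(basis, cset)
print(f"N = {cset.N} seasons, basis l = {basis.l} -> {Y.n_calls} simulator calls")

delta = rc.combined_dissimilarity(cset, Y)  # defaults: windows P=3/others 7, model weight 1/2
clustering = rc.k_medoids(delta, K=6, n_restarts=20, seed=2)
reps = rc.representative_subset(cset, clustering)

print(f"\nK = {clustering.K} classes, total within-class cost {clustering.total_cost:.2f}")
print(f"{'class':>5}{'size':>6}   medoid (site:year)")
for k in range(clustering.K):
    m = reps.climates[k]
    print(f"{k + 1:>5}{reps.class_sizes[k]:>6}   {m.site_id}:{m.year}")
print("\nclass sizes sum to N and become the mixture weights of the reconstruction.")
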