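"""Select the cluster count and membership exponent by silhouette sweep.

Fits the fuzzy clusterer over a (k, r) grid, hardens each solution, scores
it by mean silhouette width, and reports the selected configuration; on
planted two-family data the sweep should select k = 2 for every r.
"""

import fuzzyfam as ff

records, hits, truth = ff.generate_family_set(ff.FamilySpec(seed=1))
space, vectors = ff.build_feature_matrix(records, hits)
D = ff.dissimilarity_matrix(space, vectors)

result = ff.sweep_parameters(D, k_grid=[2, 3, 4],
                             r_grid=ff.DEFAULT_R_GRID, seed=0)

summary = result.table.groupby("k")["mean_silhouette"].max()
print("best mean silhouette per cluster count:")
for k, s in summary.items():
    print(f"  k={k}: {s:.4f}")
print(f"selected: k*={result.selected_k}, r*={result.selected_r}")
print("The mean silhouette (in [-1, 1], higher = tighter and better "
      "separated clusters) is maximized by the two-group partition. Fits "
      "at k=3 or 4 often collapse onto that same partition after "
      "hardening, tying the statistic; ties break toward the smaller, "
      "simpler model, so the planted family count k=2 is selected.")
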