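"""Encode a small synthetic protein family set and fuzzy-cluster it.

Generates two families of 10 sequences each (family-specific k-mer content
plus distinct domain architectures), encodes them as weighted k-mer +
domain-count feature vectors, and fits the dissimilarity-based fuzzy
clusterer at k=2, r=2.
"""

import numpy as np

import fuzzyfam as ff

spec = ff.FamilySpec(n_families=2, seqs_per_family=10,
                     length_range=(150, 250), seed=42)
records, hits, truth = ff.generate_family_set(spec)
space, vectors = ff.build_feature_matrix(records, hits)
D = ff.dissimilarity_matrix(space, vectors)

res = ff.fanny_fit(D, ff.FannyConfig(k=2, r=2, seed=0))
labels, straddlers = ff.harden(res.membership)
ari = ff.adjusted_rand_index(truth, D.ids, labels)

print(f"{len(records)} sequences encoded into {space.size} features")
print(f"objective {res.objective:.4g} (converged={res.converged})")
print("first rows of the membership matrix (one row per protein):")
for i in range(3):
    u = res.membership.values[i]
    print(f"  {D.ids[i]}: [{u[0]:.4f}, {u[1]:.4f}] -> cluster {labels[i]}")
print(f"group sizes: {np.bincount(labels).tolist()}")
print(f"adjusted Rand index vs planted truth: {ari:.2f}")
print("ARI 1.00 means the fuzzy partition, once hardened by row-wise "
      "argmax, exactly recovers the two planted families.")
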