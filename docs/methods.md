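# Methods

## Feature encoding

A protein sequence is represented by blocks of normalized n-peptide
frequencies for n = 1, 2, 3, 4. Within the length-n block, peptide i gets

    A_i = w · f_i / Σ_j f_j,   w = 10^n,

with f_i the count of peptide i over all L − n + 1 overlapping windows of a
length-L sequence. The denominator is the per-sequence total of *counted*
same-length windows, so every non-empty block sums exactly to its weight
10^n. Windows containing ambiguity letters (B, Z, X, U, O) are skipped by
default and excluded from both numerator and denominator, so the
normalization always covers the same event space as the counts; a strict
policy that raises on ambiguity letters is available. The exponential
weight ladder is deliberate: the n = 4 block carries 1000× the mass of the
n = 1 block, so sharing rare 4-peptides moves two proteins much closer than
sharing amino-acid composition.

Domain architecture enters as a separate block: for each domain model
annotated on the protein (hits retained at E-value ≤ 1, the inclusive
boundary being the conventional reading of "cutoff = 1"), the feature value
is 100 × copy number — counts, not presence, so a two-CXC protein differs
from a one-CXC protein.

Vectors are stored sparsely and embedded into a deterministic common index
(sorted by block then key) only when distances are needed. The
dissimilarity d(i,j) is the euclidean distance on that embedding (the
default of the R `cluster::daisy`/`fanny` ecosystem this method family
comes from); manhattan is available as an option. The metric choice is a
genuine free parameter of the method — nothing in the objective constrains
it — and is therefore exposed in every API and the CLI.

## Fuzzy clustering

Memberships U = (u_iv) ∈ [0,1]^{n×k} with unit row sums minimize

    F(U) = Σ_v [ Σ_ij u_iv^r u_jv^r d(i,j)² ] / [ Σ_j u_jv^r ].

This is the FANNY (fuzzy analysis) objective of Kaufman & Rousseeuw,
written here without the conventional factor 2 in the denominator; the
minimizer is unchanged, and reported objective values follow this
convention throughout. The objective needs only the dissimilarity matrix —
no centroids — which is what lets it run on arbitrary feature-derived
distances.

**Updates.** Stationarity under the row-sum constraints gives
u_iv ∝ e_iv^{−1/(r−1)} with e_iv = (2 (D²W)_iv Q_v − P_v)/Q_v², where
W = U^r, Q_v = Σ_j u_jv^r and P_v the within-cluster weighted sum. Far from
a minimum e_iv can be non-positive; it is floored at 10⁻¹² of its maximum,
and every full update is guarded by backtracking: if the proposed U raises
F, the step is halved toward the current iterate (convex combinations
preserve row-stochasticity) until F does not increase. The recorded
objective trace is therefore non-increasing by construction, and
convergence is declared when the relative decrease falls below `tol`
(default 10⁻⁹) or `max_iter` (500) is reached — non-convergence flags the
result rather than raising.

**Initialization and restarts.** Rows are drawn from a flat Dirichlet; 5
seeded restarts are run and the best objective kept. A deterministic
`spread_medoids` start (greedy farthest-point medoids, memberships 0.9
toward the nearest) is available for reproducibility-sensitive runs. On
tiny instances (k^n ≤ 256) all softened crisp partitions are additionally
used as starts: local basins correspond to hard partitions, and some — a
singleton cluster, for instance — have basins too small for a handful of
random restarts to find reliably. A restart whose converged membership
collapses a cluster (a column with no mass) is re-initialized with a fresh
seed and logged.

**Fuzziness.** r → 1⁺ yields near-crisp partitions; large r drives
memberships toward uniform 1/k, though not exactly to it: minimizers at
large r tilt each cluster's u^r mass onto a single object, whose zero
self-dissimilarity keeps the ratio near zero. The tests assert the
monotone-fuzzification property rather than an exact uniform limit.

**Oracle.** `brute_force_min` enumerates every assignment of each object to
a simplex grid point (spacing 1/resolution, default 1/4), evaluates F for
all g^n combinations in vectorized chunks, and polishes the best point with
a softmax-parameterized Nelder–Mead minimization. It is restricted to
n ≤ 6, k ≤ 3 and exists purely as an independent correctness arbiter for
the iterative fit.

## Silhouette validation and model selection

s_i = (b_i − a_i)/max(a_i, b_i) with a_i the mean dissimilarity of object i
to the other members of its cluster and b_i the smallest mean dissimilarity
to any other cluster; objects in singleton clusters take s_i = 0. This is
Rousseeuw's per-object definition; per-cluster means and the per-object
overall mean (not a mean of cluster means) summarize it. Silhouettes are
computed on the hardened partition — fuzzy memberships have no standard
silhouette. The sweep fits every (k, r) cell, scores the hardened partition
by the overall mean silhouette (or, under the `minmax` rule, the minimum
per-cluster mean), and selects the maximizing cell with ties broken toward
smaller k, then smaller r — preferring the simpler model. Degenerate cells
(all-zero dissimilarities, or a partition collapsing to one cluster) are
flagged with NaN rather than scored. At larger k the fuzzy fit frequently
collapses onto the same two-group partition after hardening; the tie rule
is what makes selection well-defined there.

## EST profiles

Within a gene group, an EST with ≥ 2 retained alignment records (to the
same or different genes — "multiple positions") is redundant; exactly 1,
unique. Records are deduplicated on (EST, gene, coordinates) first, and no
minimum separation between positions is imposed. EST hits are filtered at
E-value < 10⁻⁵ strictly by default; the cutoff is a parameter, since
reported analyses of this kind have used thresholds from 10⁻⁵ to 10⁻¹⁰.
Cross-group overlap intersects the two groups' redundant (resp. unique)
EST id sets; the percentage is taken of an explicit reference group's
count (default: the first group), reported to one decimal. Redundancy is
per group, so an EST unique in each of two groups can still be a common
unique EST.

## Domain composition

Domain intervals (1-based inclusive, overlaps merged) are concatenated and
scored as 100 × class count / length for each residue class. Default
classes: acidic {D, E}, basic {K, R, H}, hydrophobic {A, V, L, I, M, F, W}.
Cysteine is excluded from the hydrophobic class: in Cys-rich domains such
as CXC (~9 C in ~46 residues) including it would inflate hydrophobic
percentages by ~20 points and swamp the signal the statistic is meant to
show. Classes must be disjoint so no residue is double-counted; the scheme
is fully configurable. Display rounding is decimal half-up to 2 places; raw
values are retained. The packaged reference table
(`data/cxc_domain_composition.csv`) carries published per-gene CXC
percentages for the two CPP subfamilies — per-gene values cannot be
re-derived without the original domain sequences, so the table is consumed
as data and the group means are computed from it.

## Synthetic data generator

`generate_family_set` draws one random ancestor (uniform amino-acid
frequencies by default — a deliberate simplification, replaceable by a
supplied frequency table), derives each further family ancestor by
substituting sites at `seed_divergence` (default 0.5), and each member by
substituting at `within_noise` (default 0.05). Substitutions resample until
the letter changes, so rates are exact. Families also differ in domain
architecture (a shared model plus a family-specific one) with E-values
drawn below 1, mirroring the design premise that both short-peptide content
and domain combination carry subfamily signal; either channel can be
disabled by passing explicit architectures. Default conditions — 2 families
× 20 sequences of 300–500 residues — give a planted structure that the
default pipeline (k = 2, r = 2) recovers at ARI = 1 across seeds.

What the generator does *not* emulate: indels and alignment ambiguity,
site-rate heterogeneity, compositional bias, paralog/ortholog structure, or
real Pfam domain boundaries. Passing recovery tests therefore shows the
pipeline extracts planted k-mer/architecture signal correctly — not that
every real protein family separates this cleanly. The EST generator emits
alignment records with planted redundant/unique/common composition and
returns its own expected counts, so profile recovery is checked by exact
round-trip rather than approximation.

## Numerical choices and limitations

- Block sums are exact to ~10⁻¹¹ in floating point (asserted at 10⁻⁹).
- Dissimilarity matrices are symmetrized ((D + Dᵀ)/2) and the diagonal
  zeroed on construction; asymmetry beyond 10⁻¹² relative is rejected.
- Objective monotonicity is enforced to a 10⁻¹² relative slack.
- Membership rows are validated to sum to 1 within 10⁻⁹.
- Seeds: every stage derives its generator from one top-level seed via
  `SeedSequence`, so identical configs reproduce outputs byte for byte.
- Problem sizes in the test and acceptance suites (2 × 20 synthetic
  families; oracle instances with n ≤ 6; 1,000-sequence normalization
  sweeps) were chosen as the smallest sizes at which the respective
  properties are informative.
- The method clusters on global sequence content; it does not model domain
  *position* (N- vs C-terminal placement), which can itself be diagnostic —
  position-aware features are out of scope.
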