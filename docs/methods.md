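# Methods

This note documents the statistical models and procedures implemented in
`comnet`, the parameters that matter, the synthetic-data generator the
test suite relies on, and the design choices made where the design was
genuinely open.

## Diversity analysis

Counts are rarefied to a common depth by exact multivariate
hypergeometric subsampling (sampling reads without replacement); samples
below the target depth are dropped with a logged warning. The Shannon
index H = −Σ p ln p (natural log, nats) is averaged over repeated
rarefactions — 999 by default — to integrate out rarefaction noise.
Beta diversity is Bray-Curtis on relative abundances,
d(x, y) = Σ|x−y| / Σ(x+y); ordination is classical PCoA
(eigendecomposition of the Gower-centered −d²/2), dropping negative
eigenvalues without correction since downstream use is visual and
Procrustes-based.

The *unexplained variance ratio* partitions the distance matrix's sum of
squares over metadata factors the way distance-based redundancy analysis
does: with G the Gower-centered matrix and H_k the hat matrix of the
dummy-coded model containing the first k factors, factor k receives
R²_k = [tr(H_k G) − tr(H_{k−1} G)] / tr(G), and the residual fraction is
the unexplained ratio. The partition is **sequential** (Type-I) in the
user-given factor order; marginal attribution was the open alternative,
and order sensitivity is the price of an exact decomposition
(components always sum to 1). Single-factor results agree with
PERMANOVA's R² (cross-checked against scikit-bio in the test suite).

## Representative-taxon selection

Taxa are ranked by mean relative abundance and by occupancy (fraction of
samples where detected). For cutoffs (i, j) ∈ 1..20 × 1..20 the subset
is the **intersection** of the top-i% abundance and top-j% occupancy
sets (ties at the cutoff included; union available behind a flag). One
fixed rarefaction (default depth 1000) underlies the whole sweep so the
M² values of different cells are comparable; whether to rarefy here at
all was open, and a single shared rarefaction is the choice that makes
the sweep internally consistent. Each subset table is renormalized, its
Bray-Curtis PCoA is superimposed on the full table's by symmetric
Procrustes (both configurations centered and scaled to unit sum of
squares, axes truncated to the smaller count), and the residual M² is
recorded. Subsets are deduplicated and ordered by size; the selected
cell is the one just after the largest decrease in M² per added taxon
(discrete elbow), ties broken toward the smaller subset. M² = 0 exactly
when the subset is the whole table.

## Network inference

Pearson/Spearman networks are computed on relative abundances;
zero-variance taxa keep zero-weight edges rather than being dropped so
that every network in a subsampling ensemble shares one node set. The
diagonal is zeroed immediately: self-correlations of 1 would dominate
Laplacian degrees and clustering attractors.

SparCC follows the Friedman–Alm estimator on raw counts: per inner
iteration (20 by default) component fractions are drawn from the
per-sample Dirichlet posterior with pseudocount 1; log-ratio variances
t_ij are computed; basis variances solve M ω = rowsum(t) with
M = 11ᵀ + (d−2)I (equivalently, least squares on t_ij ≈ ω_i + ω_j);
correlations ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j)) are clipped to
[−1, 1]; and up to 10 exclusion rounds remove the most strongly
correlated pair above |ρ| = 0.1 from the sparsity approximation.
Negative basis-variance solutions are floored at ~0. The reported
network is the element-wise median across inner iterations. At least 4
taxa are required for the basis system.

Edge significance: each taxon's values are permuted across samples
independently (destroying all cross-taxon association, preserving
marginals), the correlation is recomputed, and
P = (#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1) (default n_perm = 1000).
Edges with P ≥ α (after optional Benjamini–Hochberg correction) are set
to zero — the standard reading of "filtering non-significant edges".

## Clustering and cluster-based diversity

Markov Clustering runs on the positive edges only: self-loops of weight
1 are added, columns are normalized, and expansion (matrix power 2) and
inflation (elementwise power, default 2.5, with column renormalization)
alternate, pruning entries below 1e-5, until the update changes by less
than 1e-6 (at most 100 iterations, else an error with the residual).
Clusters are the attractor rows of the limit matrix; overlapping
attractor systems are merged. Affinity Propagation uses the signed
weight matrix as similarity with input preference 0 and damping 0.9,
delegating the message passing to scikit-learn; non-convergence raises
with a suggestion to increase damping. Taxa isolated by significance
filtering end up as singleton clusters, so total relative abundance is
conserved when cluster aRA (sum of member relative abundances per
sample) is formed. Cluster-based beta diversity is Bray-Curtis on the
cluster aRA table followed by the same variance partition, reported
alongside the taxon-level partition.

## Network comparison

The Laplacian is L = D − A with signed degree sums (an absolute-weight
variant is available, since signed Laplacians are not positive
semidefinite); eigenvalues are sorted descending and truncated to
k = min(100, n) by default. The spectral distance between two networks
is the Euclidean distance of their leading-k eigenvalue vectors; the
Jaccard distance is Σ|A−B| / Σ max(|A|,|B|) over off-diagonal entries
(defined as 0 when both networks are empty).

For a comparison between conditions, each condition with at least
g_size samples contributes `bs` observed networks, each inferred from
s_size samples drawn without replacement. Group labels are then
shuffled **once** across the pooled retained samples, and `pm` permuted
networks per pseudo-condition are built by the identical
subsample-and-infer step. This single-shuffle construction matters:
with independent shuffles per permuted replicate, permuted
inter-condition network pairs can share samples while observed pairs
never do, which systematically deflates permuted distances and leaves a
bias that survives even complete randomization of the data. With a
single shuffle, observed and permuted inter-condition pairs are
structurally identical (both compare networks built from disjoint
sample pools).

Replicate i yields one observed inter-condition distance d_i (network i
of condition A vs network i of condition B) and one permuted distance
dp_i. Significance pools all cross comparisons:
P = (#{(i, j): dp_j ≥ d_i} + 1)/(bs·pm + 1) — the proportion of permuted
distances at least as large as observed ones. A variance-ratio F
statistic comparing the dispersions of the two distance samples is
reported as a secondary descriptor; the permutation P is authoritative.
This P is a U-type statistic, not a uniformly distributed p-value: under
the null it concentrates near 0.5, so the test errs on the conservative
side — small P values require near-complete separation of the observed
from the permuted distances, and many replicates (large bs·pm) are
needed for resolution.

`network_pca` embeds any collection of networks by their pairwise
distances (PCoA) and partitions the network-to-network variance by
group labels, quantifying how much of the ensemble variance the
condition structure explains.

## Driver identification

A taxa group (taxonomic family or network cluster) is scored by
permuting its members' counts across samples — one **shared**
permutation for all members, which breaks the group's association with
the conditions while preserving the members' co-occurrence with each
other (independent per-taxon shuffles are available behind a flag) —
rebuilding the observed ensembles, and measuring the drop in mean
inter-condition distance. The decrease ratio is the drop relative to
the unpermuted mean distance. Group features reported alongside:
size, aRA (mean summed relative abundance), normalized aRA (aRA/size —
the mean member abundance; the term needed a definition and this is the
natural one), and occupancy (fraction of samples with any member
present), with Spearman correlations between the distance change and
each feature.

The cumulative scan permutes groups in order of individual impact; for
each prefix it rebuilds both ensembles from the partially permuted
(renormalized) table and computes, per condition pair, the permutation P
and a two-sample rank-sum test (Mann–Whitney) of the observed-ensemble
vs permuted-ensemble distance samples, Benjamini–Hochberg-corrected
across pairs. Once the remaining signal is gone, observed and permuted
distances coincide and P plateaus near 0.5. The *changing point* is the
smallest prefix at which strictly more than half of the condition pairs
are non-significant. The rank-sum comparison treats replicate distances
as samples, so the subsample size must leave replicates weakly
dependent; with s_size close to g_size the replicates become near
copies and the test over-detects split-specific noise (see study
designs below).

## Synthetic communities

The generator is a latent-factor log-normal model with multinomial
sequencing: log x_ts = μ_t + λ·f_{m(t),s}·active(m, group(s)) + ε_ts,
with taxon baselines μ_t ~ N(0, 1), per-sample module factors
f ~ N(0, 1), loading λ (default 1), noise ε ~ N(0, 0.2), closure to
proportions, and multinomial counts at depth 2000. Defaults: 50 taxa,
5 modules of 10, two conditions of 40 samples. Silencing a module in
one condition (active = 0) rewires co-occurrence with only a moderate
shift in mean abundance, isolating network-level signal from
compositional signal. A latent-factor construction was chosen over
Dirichlet-multinomial because the methods under test operate on
covariance, and planting covariance requires explicit factors.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific amplification bias, overdispersion beyond the log-normal
factor structure, phylogenetic correlation, and rare-taxon sparsity
patterns of real amplicon surveys. Passing tests therefore demonstrate
that the algorithms recover structure they are designed for under a
clean compositional model — not that they are robust to every artifact
of real data. One realistic artifact the model does reproduce is
closure leakage: a strong module active in only one condition imprints
itself on the relative abundances of *all* taxa in that condition, so
partial permutation of the module's own rows cannot remove every trace
of condition signal, and no residual-based check should expect it to.

## Study designs (replicated simulations)

All studies run on one core in seconds to a few minutes; sizes are the
package's chosen desk-scale operating points.

* **Type-I error** (50 replicates): null community (all five modules
  shared), spectral test with g_size 40, s_size 20, bs = pm = 10,
  α = 0.05. Measured rejection rate ≈ 0 — the U-type P never
  approaches 0.05 under the null at this replicate count, consistent
  with the conservativeness discussed above.
* **Power** (20 replicates): single-signal community (one 10-taxon
  module, λ = 1, silenced in condition B), s_size 35, bs = pm = 33.
  The larger subsamples stabilize 50-taxon correlation estimates; 33
  replicates give the P formula its resolution (floor ≈ 1/1090).
* **Driver recovery** (20 replicates): same community; groups = the
  planted module plus four 10-taxon decoy groups covering the free
  taxa; impacts and cumulative scan at s_size 20, bs = pm = 10 —
  smaller subsamples deliberately, for the rank-sum flags' sake.
* **Cluster recovery** (3 replicates): 200 samples, no differential
  module; ARI of AP and MCL partitions against planted modules,
  non-module taxa excluded.
* **Cluster diversity** (20 replicates): one module silenced in B; AP
  clusters of the Spearman network; counts replicates where cluster-aRA
  Bray-Curtis leaves strictly less unexplained variance than
  taxon-level. The reduction's magnitude is small under this generator
  (the planted difference is mostly network-borne by design); its sign
  is the reproducible claim.

## Numerical choices and limitations

Tolerances: MCL pruning 1e-5, convergence 1e-6; PCoA eigenvalue cutoff
1e-10 relative; Procrustes requires ≥ 3 samples; distance matrices are
symmetrized and clipped at 0 on construction. All stochastic operations
take an explicit integer seed (default 42) and are bit-reproducible for
a fixed seed; MCL is deterministic. BIOM input is not supported
(TSV only). The sequential R² partition depends on factor order; the
permutation P is conservative by construction; and the changing point
depends on the chosen group ranking, which defaults to descending
single-group impact.
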