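# Methods

## Model and procedure

`snfsig` stratifies a patient cohort from three omics layers —
methylation β values on (0,1), FPKM-like mRNA expression of immune
genes, RPM-like miRNA expression — and derives per-cluster selected
immune gene sets (SIGs) with supporting evidence. The stages, their
assumptions and the numerical choices behind them are documented here;
nothing in this note states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

### Preprocessing

*Missingness filter.* Patients are removed first: a patient whose
missing fraction exceeds the threshold (default 0.2) **in any single
layer** is dropped from **all** layers. Features are filtered second,
per layer, against the remaining patients. The pass is applied once, in
that order; at realistic missingness (≤ 10 % MCAR) it is a fixpoint,
but it is not guaranteed to be idempotent for adversarial masks because
removing features can raise a surviving patient's missing fraction.

*KNN imputation* runs per layer (not on the concatenation — the choice
is deliberate and keeps layers independent before fusion). The distance
between two patients is the root-mean-square difference over their
co-observed features; dividing by the co-observation count makes
patients with different amounts of missingness comparable. A missing
entry is replaced by Σwᵢxᵢ/Σwᵢ over the K = 20 nearest patients that
observe the feature, with wᵢ = 1/(dᵢ + 10⁻¹²). Distance ties break by
patient column order; observed entries are never altered. A patient
sharing no observed feature with anyone is an error naming the patient.

*Normalization* is x → log2(x + 1) then a per-feature Z-transform with
the **population** SD (so the three-point example [1,3,7] maps exactly
to [−√(3/2), 0, √(3/2)]). The same transform is applied to methylation
β values — no logit is taken first. This is a deliberate literal
choice; β values on (0,1) survive log2(x+1) monotonically, so distances
are compressed but order-preserved. Constant features map to all-zero
rows rather than dividing by zero. Expression layers must be
nonnegative.

### Similarity network fusion

Per layer, Euclidean patient distances feed the scaled exponential
kernel W(i,j) = exp(−d²/(α·ε(i,j))) with
ε(i,j) = (μᵢ + μⱼ + d(i,j))/3, where μᵢ is the mean distance from i to
its K nearest neighbours (self excluded, ties by patient index). The
full kernel P puts half the transition mass on the diagonal
(P(i,i) = 1/2, off-diagonal rows normalized to 1/2); the local kernel S
is row-normalized over each patient's K nearest neighbours only.
Fusion iterates P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v} P⁽ᵘ⁾ · S⁽ᵛ⁾ᵀ for T rounds;
after each update the matrix is symmetrized ((P+Pᵀ)/2) and
re-normalized to the half-diagonal row-stochastic form to control
floating-point drift. The fused network is the entrywise mean of the
final matrices, symmetrized. Defaults α = 0.5, K = 20, T = 20. With a
single input network the update self-fuses; with T = 0 the output is
the mean of the full kernels. ε ≤ 0 (duplicate-degenerate input) is
floored at 10⁻²⁰ with a warning.

### Spectral clustering and model selection

NCut is realized as Ng–Jordan–Weiss spectral clustering: k-means
(20 restarts, seeded) on the row-normalized leading k eigenvectors of
the symmetric normalized Laplacian. Labels are renumbered 1..k by first
patient appearance, making the assignment deterministic for a fixed
seed and equivariant under patient permutation up to label names.

Two cluster-count heuristics are surfaced and **neither is silently
preferred**: the eigengap λ_{k+1} − λ_k (ranked descending) and a
rotation-alignment cost obtained by Yu–Shi discretization of the
embedding (cost n − Σσ, ranked ascending; zero for an exactly
block-diagonal network). The discretization is initialized greedily
from the first patient's embedding row, keeping it deterministic.

`partition_accuracy` is the maximum co-assignment fraction over
one-to-one cluster matchings, computed by optimal assignment on the
contingency table; it equals exhaustive label-permutation search (the
test suite checks this for k ≤ 5) and is reported alongside the ARI.

### Feature ranking and selection

The NDE index of a feature for cluster k (size m) in a cohort of n is
the pooled-variance two-sample statistic

    NDE = (μ_k − μ_rest) / sqrt( ((m−1)s²_k + (n−m−1)s²_rest)/(n−2) · (1/m + 1/(n−m)) )

with sample (ddof = 1) group variances; for an even split with equal
variances this is exactly the classical two-sample t statistic. Ranking
uses |NDE| — separation in either direction counts — with ties broken
by (layer, feature id). A zero pooled variance scores 0 with a warning:
a constant feature cannot separate anything. Both groups need at least
two members.

`preservation_search` walks a grid of per-cluster top-m values (default
{25, 50, 75, 100, 125, 150, 200}), restricts every layer to the union
of the clusters' top-m features, re-runs fusion + NCut at the same k
and seed, and reports the accuracy curve plus the smallest m reaching
the threshold (default 0.95). The curve is reported for every grid
point; monotonicity is not assumed. If no grid point reaches the
threshold the best achieved accuracy is reported and flagged.

### Hi-C strong interactions and target mapping

Contacts are bin-pair count triplets at 40 kb. Genomic intervals map to
**every** bin they overlap (BED 0-based half-open; strand ignored).
Intra-chromosomal strong calls require (a) presence in **all**
replicates and (b) a consensus count — the mean across replicates; the
choice of consensus is deliberate since no single replicate is
canonical — at or above the empirical (1 − tail) quantile of that
chromosome's consensus counts (tail default 0.05, i.e. "5 % of pairs",
not 5 % of read mass). A degenerate all-equal distribution keeps every
pair (count ≥ threshold), deterministically. Inter-chromosomal calls
require all-replicate presence only. Per-chromosome thresholds are
reported and are monotone non-increasing in the tail fraction.

A methylation locus's candidate targets are the immune genes
overlapping (i) bins strongly interacting with the locus's bin
(`hic-intra`/`hic-inter`), (ii) the locus's own bin (`same-bin`), and
(iii) rows of an optional proximal-target table (`proximal-table`).
Provenance is recorded per gene; with the immune filter on, non-immune
genes never appear.

### Evidence integration

A cluster's SIG is the deduplicated union of immune genes among the top
expression features, targets of top methylation loci, and targets of
top miRNAs, each gene carrying its provenance tags and source feature
ids. Gene-set overlap against GMT collections is plain intersection
counting — no term-hierarchy statistics are attempted.

Mutation annotation flags each SIG gene as harboring a somatic
mutation, harboring a germline variant (sharing a 40-kb bin with an LD
block), or affected via interaction (a gene bin strongly interacts
with an LD-block bin); summary counts include both "both" categories.

The 2×2 association test defaults to the exact two-sided Fisher test
(minimum-likelihood convention; verified in the tests against full
hypergeometric enumeration). A `chi2-cc` method — the χ² test with
Yates continuity correction, the convention many R-based analyses
apply to large gene-count tables — is provided as well, and is the
convention that reproduces the reference enrichment p-values used in
the acceptance checks; for the large tables involved the two agree to
well within an order of magnitude. The odds ratio is the sample odds
ratio, with 0.5 continuity added (and flagged) only when a cell is 0.

PPI hubs are genes whose degree reaches the empirical (1 − f) degree
quantile for f ∈ {0.05, 0.01}; ties are included, so a tier can exceed
its nominal count and a regular graph is all-hubs by construction.
Degrees are taken on the SIG-induced subgraph by default (per-cluster
connection counts), with a flag for full-graph degrees.

### Survival

Kaplan–Meier curves per cluster; the k-sample log-rank test
(equivalently the score test of a proportional-hazards model on cluster
indicators — no coefficients are fit) with a χ²_{k−1} reference; ties
handled by the standard aggregated-increment formulation. Cluster
survival ordering for the rank-agreement check uses the KM survival
probability at the last common follow-up time (configurable — the
functional is genuinely open and this choice is the package's own);
agreement with the per-cluster favorable-risk fraction is Spearman's ρ
with an exact permutation p for k ≤ 7 (all k! permutations enumerated)
and the asymptotic p otherwise.

## Synthetic data: what it emulates and what it does not

The generator plants k clusters of configurable sizes. Informative
features are **disjoint across clusters** — each is mean-shifted by
effect_size·noise_sd in exactly one cluster — which makes per-cluster
top-feature recovery directly checkable against the truth. Methylation
values are a logistic transform of the Gaussian latent (β-like, in
(0,1)); expression values are 2^latent (FPKM/RPM-like), so the log2+Z
normalization path is genuinely exercised. Missingness is injected
completely at random. Survival is exponential with hazards increasing
geometrically in cluster index (defaults: base 5·10⁻⁴/day, ratio 2) and
uniform administrative censoring on [0, 2000] days; risk categories are
drawn with a favorable-prognosis probability decreasing in the cluster
hazard. Hi-C replicates plant strong pairs (count ≥ strong_count
everywhere) over Uniform{1..100} background pairs that drop out of
individual replicates at random. PPI graphs are preferential-attachment
(heavy-tailed degrees); miRNA targets and curated sets are uniform
draws.

Defaults are the study conditions the package is tested under: 90
patients, 3 clusters, 400/200/100 features, 10 % informative features,
effect size 2 SD, 5 % missing. These sizes keep the full pipeline and
its tests fast on a single CPU while preserving the recoverability
regime; the acceptance script states the sizes it used alongside each
quantity.

What the generator does **not** emulate: correlated features,
batch/platform effects, informative missingness, realistic LD
structure, copy-number or fusion events, distance-decay in Hi-C
backgrounds, and degree-assortative PPI structure. Passing tests
therefore demonstrate correctness of the algorithms under the planted
model, not performance on real cohorts.

## Known limitations and open choices

- With fewer than ~200 features or clusters smaller than the SNF
  neighbourhood K, fusion degrades; scaled-down runs should scale K
  with the expected cluster size (the pipeline test does).
- The missingness filter is one-pass by design (see above).
- β values are log2-transformed without logit; a logit front-end would
  be a one-line extension.
- The eigengap and rotation-cost heuristics can disagree on noisy
  networks; both rankings are emitted and the pipeline takes the
  eigengap top candidate only when no k is configured.
- The Hi-C tail rule operates on raw counts; no matrix balancing or
  distance-decay modeling (Fit-Hi-C-style callers) is attempted.
- Gene-set scoring is overlap counting only; q-value-corrected
  pathway enrichment is out of scope.
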