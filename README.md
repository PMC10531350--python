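# snfsig

Multi-omics patient stratification by similarity network fusion (SNF),
with per-cluster feature ranking, minimal-feature-set selection, Hi-C
based target mapping, and evidence scoring of the resulting gene sets.

`snfsig` is aimed at computational biologists who want to (a) cluster a
patient cohort from several omics layers at once — DNA methylation
(β values), mRNA expression of immune genes (FPKM) and miRNA expression
(RPM) — and (b) turn the clustering into *biologically interpretable*
per-cluster gene sets by following three provenance paths: immune genes
ranked as informative expression features, candidate targets of
informative methylation loci (via strong chromatin interactions), and
candidate targets of informative miRNAs. The gene sets are then scored
by curated-set overlap, somatic/germline mutation enrichment, PPI
hubness and cluster survival separation.

## The method

1. **Preprocessing.** Patients with more than 20 % missing values in any
   single omics layer are removed from all layers; features with more
   than 20 % missing values across the remaining patients are dropped.
   Remaining gaps are imputed by weighted K-nearest-neighbour averaging
   (K = 20), and every layer is normalized by `log2(x + 1)` followed by
   a per-feature Z-transform.
2. **Fusion.** Each layer yields a patient similarity network
   W(i,j) = exp(−d(i,j)² / (α·ε(i,j))) on Euclidean distances, with the
   locally adaptive scale ε(i,j) = (mean d(i, KNN(i)) + mean d(j, KNN(j))
   + d(i,j))/3. Cross-diffusion P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v} P⁽ᵘ⁾ · S⁽ᵛ⁾ᵀ
   (T = 20 rounds, α = 0.5, K = 20) merges the layers into one fused
   network.
3. **Clustering.** Normalized-cut spectral clustering (k-means on the
   row-normalized leading k eigenvectors of L = I − D^{−1/2} W D^{−1/2});
   the number of clusters is suggested by the Laplacian eigengap and by
   a rotation-alignment cost, and both rankings are reported.
4. **Feature ranking.** Every feature of every layer is scored per
   cluster by the NDE index — the pooled-variance two-sample statistic
   (μ_cluster − μ_rest) / √(s²_pooled (1/m + 1/(n−m))) — and the smallest
   per-cluster top-m whose re-clustering reproduces the full-feature
   partition at ≥ 95 % accuracy is selected.
5. **Target mapping.** The genome is binned at 40 kb. Strong
   intra-chromosomal interactions are bin pairs present in all Hi-C
   replicates whose consensus count lies in the top 5 % of their
   chromosome's distribution; inter-chromosomal pairs need all-replicate
   presence only. Top methylation loci map to immune genes in their own
   or strongly interacting bins; top miRNAs map through a target table.
6. **Evidence.** Per-cluster selected immune gene sets (SIGs) are scored
   by curated-set overlap (GMT), somatic/germline mutation flags with
   Fisher 2×2 enrichment, PPI hub calling (top 5 %/1 % degree, ties
   included), and the k-sample log-rank test across clusters.

Every input can be generated synthetically (`snfsig.simulate`) with the
statistical structure the method assumes — planted patient clusters,
replicated contact maps with planted strong pairs, scale-free PPI
graphs, cluster-dependent exponential survival — so the whole pipeline
is testable without any external download.

## Worked example

```sh
snfsig run-all --run-dir runs/demo --seed 1
```

```
[snfsig:INFO] simulate: 90 patients, 597 genes
[snfsig:INFO] preprocess: {'methylation': (400, 90), 'mrna': (200, 90), 'mirna': (100, 90)}
[snfsig:INFO] fuse: 90 patients
[snfsig:INFO] cluster: k=3 (eigengap top=3)
[snfsig:INFO] rank: 3 clusters x 700 features
[snfsig:INFO] select: minimal top_m=125, union size=208
[snfsig:INFO] hic-call: 9 intra, 239 inter pairs
[snfsig:INFO] hic-map: 312 locus-gene links
[snfsig:INFO] sig: sizes [178, 178, 177]
[snfsig:INFO] evidence: 34 hub rows
[snfsig:INFO] survival: logrank p=0.00156
```

The run simulates a 90-patient cohort with three planted clusters,
fuses the three omics layers, recovers k = 3 as the top eigengap
candidate, finds that 125 top-ranked features per cluster (208 unique)
reproduce the full-feature clustering, calls 9 strong intra- and 239
inter-chromosomal 40-kb bin pairs from four simulated Hi-C replicates,
assembles three SIGs of ~178 immune genes each, and confirms that the
planted hazard differences separate the clusters' survival curves
(log-rank χ² = 12.9 on 2 df, p = 0.0016). All outputs (cluster
assignments, rankings, selection curve, SIG tables, hub lists, survival
report, reproducibility manifest) are TSV/JSON files in `runs/demo/`.

Each stage is also available as its own subcommand (`simulate`,
`preprocess`, `fuse`, `cluster`, `rank`, `select`, `hic-call`,
`hic-map`, `sig`, `evidence`, `survival`) over the same run directory,
and the whole library is importable (`import snfsig`).

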