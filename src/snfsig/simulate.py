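"""Synthetic multi-omics cohort, genome, Hi-C, PPI and mutation generators.

Every input the stratification pipeline consumes can be generated here
with the statistical structure the analysis assumes: planted patient
clusters with per-cluster informative features, replicated contact maps
with planted strong bin pairs, scale-free PPI graphs, and
cluster-dependent exponential survival. All generators are deterministic
given their seed.

The default cohort emulates the study conditions of a multi-omics AML
stratification: three data types (methylation beta values on (0,1),
FPKM-like mRNA of immune genes, RPM-like miRNA), missing values injected
completely at random, and per-cluster mean shifts on a disjoint set of
informative features per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ConfigurationError,
    OmicsMatrix,
    SyntheticGenome,
)

RISK_LEVELS = ("poor", "normal", "favorable")


@dataclass
class SyntheticCohortConfig:
    """Configuration for :func:`generate_cohort`.

    ``effect_size`` is the cluster-specific mean shift of informative
    features, in units of ``noise_sd``. Informative features are disjoint
    across clusters: each is shifted in exactly one cluster.
    """

    n_patients: int = 90
    k_clusters: int = 3
    cluster_sizes: list[int] | None = None
    n_methylation: int = 400
    n_mrna: int = 200
    n_mirna: int = 100
    informative_fraction: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    hazard_base: float = 5e-4       # per day, cluster 1
    hazard_ratio: float = 2.0       # hazard multiplier per cluster index
    censor_horizon: float = 2000.0  # administrative censoring ~ U(0, horizon)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            base = self.n_patients // self.k_clusters
            sizes = [base] * self.k_clusters
            for i in range(self.n_patients - base * self.k_clusters):
                sizes[i] += 1
            self.cluster_sizes = sizes
        if len(self.cluster_sizes) != self.k_clusters:
            raise ConfigurationError("cluster_sizes length != k_clusters")
        if sum(self.cluster_sizes) != self.n_patients:
            raise ConfigurationError("cluster_sizes must sum to n_patients")
        if not (0 < self.informative_fraction <= 1):
            raise ConfigurationError("informative_fraction must be in (0,1]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0,1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def informative_features(n_features: int, k: int, fraction: float) -> dict[int, list[int]]:
    """Deterministic disjoint split of the first round(n*fraction) feature
    indices across the k clusters (round-robin)."""
    n_inf = int(round(n_features * fraction))
    assign: dict[int, list[int]] = {c: [] for c in range(1, k + 1)}
    for i in range(n_inf):
        assign[(i % k) + 1].append(i)
    return assign


def _latent_block(rng: np.random.Generator, n_features: int, labels: np.ndarray,
                  cfg: SyntheticCohortConfig) -> tuple[np.ndarray, dict[int, list[int]]]:
    latent = rng.normal(0.0, cfg.noise_sd, size=(n_features, cfg.n_patients))
    inf = informative_features(n_features, cfg.k_clusters, cfg.informative_fraction)
    shift = cfg.effect_size * cfg.noise_sd
    for cluster, feats in inf.items():
        cols = labels == cluster
        for f in feats:
            latent[f, cols] += shift
    return latent, inf


def _inject_missing(rng: np.random.Generator, values: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0:
        mask = rng.random(values.shape) < rate
        values = values.copy()
        values[mask] = np.nan
    return values


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort: planted labels and the informative
    feature ids per data type and cluster."""

    labels: np.ndarray
    informative: dict[str, dict[int, list[str]]]


def generate_cohort(
    config: SyntheticCohortConfig,
    genome: SyntheticGenome | None = None,
) -> tuple[dict[str, OmicsMatrix], CohortTruth, ClinicalTable]:
    """Generate the three omics matrices, planted truth and clinical table.

    If ``genome`` is given, mRNA feature ids are drawn from its immune
    genes and methylation locus ids from its loci, so that downstream
    target mapping can resolve features to coordinates.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(np.arange(1, cfg.k_clusters + 1), cfg.cluster_sizes)
    patients = [f"P{i:04d}" for i in range(1, cfg.n_patients + 1)]

    if genome is not None:
        immune = sorted(genome.immune_genes)
        if len(immune) < cfg.n_mrna:
            raise ConfigurationError("genome has fewer immune genes than n_mrna")
        if len(genome.loci) < cfg.n_methylation:
            raise ConfigurationError("genome has fewer loci than n_methylation")
        mrna_ids = immune[: cfg.n_mrna]
        meth_ids = list(genome.loci["name"])[: cfg.n_methylation]
    else:
        mrna_ids = _feature_ids("IMMG", cfg.n_mrna)
        meth_ids = _feature_ids("cg", cfg.n_methylation)
    mirna_ids = [f"hsa-mir-{i:04d}" for i in range(1, cfg.n_mirna + 1)]

    matrices: dict[str, OmicsMatrix] = {}
    informative: dict[str, dict[int, list[str]]] = {}
    for data_type, ids in (("methylation", meth_ids), ("mrna", mrna_ids),
                           ("mirna", mirna_ids)):
        latent, inf = _latent_block(rng, len(ids), labels, cfg)
        if data_type == "methylation":
            values = 1.0 / (1.0 + np.exp(-latent))  # beta-like, in (0,1)
        else:
            values = np.exp2(latent)  # FPKM/RPM-like, nonnegative
        values = _inject_missing(rng, values, cfg.missing_rate)
        matrices[data_type] = OmicsMatrix(
            data=pd.DataFrame(values, index=ids, columns=patients),
            data_type=data_type,
        )
        informative[data_type] = {c: [ids[i] for i in feats] for c, feats in inf.items()}

    clinical = _generate_clinical(rng, patients, labels, cfg)
    return matrices, CohortTruth(labels=labels, informative=informative), clinical


def _generate_clinical(rng: np.random.Generator, patients: list[str],
                       labels: np.ndarray, cfg: SyntheticCohortConfig) -> ClinicalTable:
    """Exponential survival with hazards increasing in cluster index;
    uniform administrative censoring; risk category drawn with a
    favorable-prognosis probability that decreases with the hazard."""
    hazards = cfg.hazard_base * cfg.hazard_ratio ** (labels - 1)
    t_event = rng.exponential(1.0 / hazards)
    t_censor = rng.uniform(0, cfg.censor_horizon, size=len(patients))
    os_days = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)

    # P(favorable) highest in the lowest-hazard cluster, P(poor) in the highest
    frac = (labels - 1) / max(cfg.k_clusters - 1, 1)
    p_fav = 0.7 - 0.6 * frac
    p_poor = 0.1 + 0.6 * frac
    risk = []
    for pf, pp in zip(p_fav, p_poor):
        u = rng.random()
        risk.append("favorable" if u < pf else ("poor" if u < pf + pp else "normal"))
    df = pd.DataFrame(
        {"patient_id": patients, "os_days": np.round(os_days, 1),
         "os_event": os_event, "risk": risk, "cluster_true": labels}
    )
    return ClinicalTable(df)


def default_genome(
    n_chromosomes: int = 3,
    chrom_length: int = 4_000_000,
    gene_spacing: int = 20_000,
    gene_length: int = 5_000,
    immune_fraction: float = 0.5,
    n_ld_blocks: int = 30,
    seed: int = 0,
) -> SyntheticGenome:
    """Small artificial genome with tiled genes (a fraction flagged immune),
    one promoter methylation locus per gene, and random LD blocks."""
    rng = np.random.default_rng(seed)
    chromosomes = {f"chr{i+1}": chrom_length for i in range(n_chromosomes)}
    genes, loci, blocks = [], [], []
    g = 0
    for chrom, length in chromosomes.items():
        for start in range(gene_spacing, length - gene_length, gene_spacing):
            g += 1
            name = f"GENE{g:05d}"
            genes.append({"chrom": chrom, "start": start, "end": start + gene_length,
                          "name": name, "immune": bool(rng.random() < immune_fraction)})
            pos = max(start - 1_500, 0)  # promoter-proximal CpG
            loci.append({"chrom": chrom, "start": pos, "end": pos + 1,
                         "name": f"cg{g:07d}"})
    for b in range(n_ld_blocks):
        chrom = f"chr{rng.integers(1, n_chromosomes + 1)}"
        start = int(rng.integers(0, chromosomes[chrom] - 50_000))
        blocks.append({"chrom": chrom, "start": start,
                       "end": start + int(rng.integers(5_000, 50_000)),
                       "name": f"LD{b+1:04d}"})
    return SyntheticGenome(
        chromosomes=chromosomes,
        genes=pd.DataFrame(genes),
        loci=pd.DataFrame(loci),
        ld_blocks=pd.DataFrame(blocks),
    )


def generate_contacts(
    genome: SyntheticGenome,
    n_replicates: int,
    planted_pairs: list[tuple[str, int, str, int]],
    background_rate: float = 0.02,
    strong_count: int = 150,
    bin_size: int = 40_000,
    background_max: int = 100,
    replicate_presence: float = 0.8,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Replicated contact maps with planted strong pairs.

    Planted pairs get a count >= ``strong_count`` in every replicate.
    Background pairs are sampled at ``background_rate`` over all bin pairs,
    draw counts from Uniform{1..background_max}, and appear in each
    replicate independently with probability ``replicate_presence`` (so
    some are absent from at least one replicate).
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_bins = {c: -(-length // bin_size) for c, length in genome.chromosomes.items()}
    for chrom_a, bin_a, chrom_b, bin_b in planted_pairs:
        for chrom, b in ((chrom_a, bin_a), (chrom_b, bin_b)):
            if chrom not in n_bins or not (0 <= b < n_bins[chrom]):
                raise ConfigurationError(f"planted pair bin ({chrom},{b}) outside genome")

    chroms = sorted(n_bins)
    background: list[tuple[str, int, str, int]] = []
    planted_set = {_canonical(p) for p in planted_pairs}
    for i, ca in enumerate(chroms):
        for cb in chroms[i:]:
            na, nb = n_bins[ca], n_bins[cb]
            n_pairs = na * (na + 1) // 2 if ca == cb else na * nb
            n_bg = rng.binomial(n_pairs, background_rate)
            for _ in range(n_bg):
                a = int(rng.integers(0, na))
                b = int(rng.integers(0, nb))
                pair = _canonical((ca, a, cb, b))
                if pair not in planted_set:
                    background.append(pair)
    background = sorted(set(background))

    replicates = []
    for _ in range(n_replicates):
        rows = []
        for pair in sorted(planted_set):
            rows.append(pair + (int(strong_count + rng.poisson(10)),))
        for pair in background:
            if rng.random() < replicate_presence:
                rows.append(pair + (int(rng.integers(1, background_max + 1)),))
        replicates.append(
            pd.DataFrame(rows, columns=["chrom_a", "bin_a", "chrom_b", "bin_b", "count"])
        )
    return replicates


def _canonical(pair: tuple[str, int, str, int]) -> tuple[str, int, str, int]:
    ca, a, cb, b = pair
    if (ca, a) <= (cb, b):
        return (ca, int(a), cb, int(b))
    return (cb, int(b), ca, int(a))


def generate_ppi(genes: list[str], attachment_parameter: int = 3,
                 seed: int = 0) -> nx.Graph:
    """Simple undirected scale-free (preferential attachment) PPI graph on
    the given gene names."""
    if not genes:
        raise ConfigurationError("empty gene list")
    m = min(attachment_parameter, max(len(genes) - 1, 1))
    g = nx.barabasi_albert_graph(len(genes), m, seed=seed)
    return nx.relabel_nodes(g, dict(enumerate(genes)))


def generate_mutations(
    genome: SyntheticGenome,
    patients: list[str],
    somatic_rate: float = 0.002,
    germline_block_count: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic mutation table (patient_id, gene, class=somatic) plus the LD
    blocks treated as carrying germline risk variants.

    Each (patient, gene) cell mutates independently with ``somatic_rate``.
    ``germline_block_count`` subsamples the genome's LD blocks (all by
    default).
    """
    if len(genome.genes) == 0:
        raise ConfigurationError("empty gene list")
    rng = np.random.default_rng(seed)
    gene_names = list(genome.genes["name"])
    rows = []
    if somatic_rate > 0:
        hits = rng.random((len(patients), len(gene_names))) < somatic_rate
        for i, p in enumerate(patients):
            for j in np.flatnonzero(hits[i]):
                rows.append({"patient_id": p, "gene": gene_names[j], "class": "somatic"})
    mutations = pd.DataFrame(rows, columns=["patient_id", "gene", "class"])
    blocks = genome.ld_blocks
    if germline_block_count is not None and germline_block_count < len(blocks):
        idx = rng.choice(len(blocks), size=germline_block_count, replace=False)
        blocks = blocks.iloc[np.sort(idx)].reset_index(drop=True)
    return mutations, blocks


def generate_mirna_targets(mirna_ids: list[str], genes: list[str],
                           targets_per_mirna: int = 5, seed: int = 0) -> pd.DataFrame:
    """Random miRNA -> gene target table; each miRNA maps to
    ``targets_per_mirna`` distinct genes."""
    if not genes:
        raise ConfigurationError("empty gene list")
    if targets_per_mirna < 1:
        raise ConfigurationError("targets_per_mirna must be >= 1")
    rng = np.random.default_rng(seed)
    k = min(targets_per_mirna, len(genes))
    rows = []
    for m in mirna_ids:
        for g in rng.choice(genes, size=k, replace=False):
            rows.append({"mirna_id": m, "gene": g})
    return pd.DataFrame(rows, columns=["mirna_id", "gene"])


def generate_gene_sets(genes: list[str], n_sets: int = 3, set_size: int = 40,
                       seed: int = 0) -> dict[str, list[str]]:
    """Random curated-style gene sets (GMT content) drawn from ``genes``."""
    rng = np.random.default_rng(seed)
    k = min(set_size, len(genes))
    return {
        f"CURATED_SET_{i+1}": sorted(rng.choice(genes, size=k, replace=False))
        for i in range(n_sets)
    }
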