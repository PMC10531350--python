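"""Hi-C contact binning, replicate-consistent strong-interaction calling,
and methylation-locus -> target-gene mapping.

Contacts are bin-pair count triplets at a fixed bin size (default
40 kb). A strong intra-chromosomal interaction is a bin pair present in
ALL replicates whose consensus (mean across replicates) count lies in
the top ``tail`` fraction of its chromosome's consensus-count
distribution (count >= the empirical (1 - tail) quantile). Significant
inter-chromosomal interactions are simply the pairs present in all
replicates. Genomic features map to every bin they overlap (BED
convention, 0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, SyntheticGenome

DEFAULT_BIN_SIZE = 40_000
DEFAULT_TAIL = 0.05

Pair = tuple[str, int, str, int]


@dataclass
class BinIndex:
    """Feature -> overlapped 40 kb bins, plus per-chromosome bin counts."""

    bin_size: int
    chrom_bins: dict[str, int]
    feature_bins: dict[str, set[tuple[str, int]]] = field(default_factory=dict)

    def bins_of(self, feature: str) -> set[tuple[str, int]]:
        if feature not in self.feature_bins:
            raise ConfigurationError(f"feature {feature} not binned")
        return self.feature_bins[feature]


def bin_features(intervals: pd.DataFrame, chromosomes: dict[str, int],
                 bin_size: int = DEFAULT_BIN_SIZE) -> BinIndex:
    """Map BED-like intervals (chrom, start, end, name) to all overlapped
    bins; point features (end = start + 1) land in exactly one bin."""
    chrom_bins = {c: -(-length // bin_size) for c, length in chromosomes.items()}
    index = BinIndex(bin_size=bin_size, chrom_bins=chrom_bins)
    for row in intervals.itertuples(index=False):
        chrom, start, end, name = row.chrom, int(row.start), int(row.end), row.name
        if chrom not in chromosomes:
            raise ConfigurationError(f"feature {name} on unknown chromosome {chrom}")
        if not (0 <= start < end <= chromosomes[chrom]):
            raise ConfigurationError(f"feature {name} outside chromosome bounds")
        bins = {(chrom, b) for b in range(start // bin_size, (end - 1) // bin_size + 1)}
        index.feature_bins[name] = index.feature_bins.get(name, set()) | bins
    return index


def _canonical_pairs(contacts: pd.DataFrame) -> dict[Pair, float]:
    """Canonically ordered pair -> count for one replicate (duplicate rows
    of the same pair are summed)."""
    out: dict[Pair, float] = {}
    for row in contacts.itertuples(index=False):
        a = (row.chrom_a, int(row.bin_a))
        b = (row.chrom_b, int(row.bin_b))
        if a > b:
            a, b = b, a
        pair = (a[0], a[1], b[0], b[1])
        out[pair] = out.get(pair, 0.0) + float(row.count)
    return out


@dataclass
class StrongInteractionSet:
    """Replicate-consistent strong intra pairs (with per-chromosome
    thresholds) and all-replicate inter pairs."""

    intra: pd.DataFrame          # chrom, bin_a, bin_b, count (consensus mean)
    inter: pd.DataFrame          # chrom_a, bin_a, chrom_b, bin_b, count
    thresholds: dict[str, float]
    tail: float
    n_replicates: int

    def partner_bins(self, bin_: tuple[str, int]) -> dict[tuple[str, int], str]:
        """Bins strongly interacting with ``bin_``; values are the
        interaction class ('intra' or 'inter')."""
        chrom, b = bin_
        partners: dict[tuple[str, int], str] = {}
        sub = self.intra[self.intra["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            if row.bin_a == b:
                partners[(chrom, int(row.bin_b))] = "intra"
            elif row.bin_b == b:
                partners[(chrom, int(row.bin_a))] = "intra"
        for row in self.inter.itertuples(index=False):
            if (row.chrom_a, int(row.bin_a)) == bin_:
                partners[(row.chrom_b, int(row.bin_b))] = "inter"
            elif (row.chrom_b, int(row.bin_b)) == bin_:
                partners[(row.chrom_a, int(row.bin_a))] = "inter"
        return partners


def _consensus(replicates: list[pd.DataFrame]) -> dict[Pair, float]:
    """Pairs present in every replicate, with mean count."""
    per_rep = [_canonical_pairs(r) for r in replicates]
    common = set(per_rep[0])
    for rep in per_rep[1:]:
        common &= set(rep)
    return {p: float(np.mean([rep[p] for rep in per_rep])) for p in common}


def call_strong_intra(replicates: list[pd.DataFrame],
                      tail: float = DEFAULT_TAIL) -> StrongInteractionSet:
    """Intra-chromosomal strong-interaction calls.

    Per chromosome, the all-replicate pairs whose consensus count is >=
    the empirical (1 - tail) quantile of that chromosome's consensus
    counts are kept. A degenerate all-equal count distribution keeps
    every pair (count >= threshold).
    """
    if not replicates:
        raise ConfigurationError("need at least one replicate")
    if not (0 < tail < 1):
        raise ConfigurationError("tail must be in (0,1)")
    consensus = _consensus(replicates)
    all_chroms = {r for rep in replicates for r in rep["chrom_a"]} | \
                 {r for rep in replicates for r in rep["chrom_b"]}
    by_chrom: dict[str, list[tuple[Pair, float]]] = {}
    for pair, count in consensus.items():
        if pair[0] == pair[2]:
            by_chrom.setdefault(pair[0], []).append((pair, count))
    for chrom in sorted(all_chroms):
        if chrom not in by_chrom:
            warnings.warn(f"no all-replicate intra pairs for chromosome {chrom}")

    thresholds: dict[str, float] = {}
    rows = []
    for chrom in sorted(by_chrom):
        pairs = by_chrom[chrom]
        counts = np.array([c for _, c in pairs])
        thr = float(np.quantile(counts, 1.0 - tail))
        thresholds[chrom] = thr
        for (ca, a, cb, b), count in sorted(pairs):
            if count >= thr:
                rows.append({"chrom": chrom, "bin_a": a, "bin_b": b, "count": count})
    intra = pd.DataFrame(rows, columns=["chrom", "bin_a", "bin_b", "count"])
    inter = pd.DataFrame(columns=["chrom_a", "bin_a", "chrom_b", "bin_b", "count"])
    return StrongInteractionSet(intra=intra, inter=inter, thresholds=thresholds,
                                tail=tail, n_replicates=len(replicates))


def call_significant_inter(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Inter-chromosomal pairs present in every replicate (no count
    threshold); counts are consensus means."""
    if not replicates:
        raise ConfigurationError("need at least one replicate")
    consensus = _consensus(replicates)
    rows = [
        {"chrom_a": ca, "bin_a": a, "chrom_b": cb, "bin_b": b, "count": count}
        for (ca, a, cb, b), count in sorted(consensus.items()) if ca != cb
    ]
    return pd.DataFrame(rows, columns=["chrom_a", "bin_a", "chrom_b", "bin_b", "count"])


def call_strong_interactions(replicates: list[pd.DataFrame],
                             tail: float = DEFAULT_TAIL) -> StrongInteractionSet:
    """Joint intra (tail-filtered) + inter (all-replicate) calls."""
    strong = call_strong_intra(replicates, tail)
    strong.inter = call_significant_inter(replicates)
    return strong


PROVENANCE_ORDER = ("hic-intra", "hic-inter", "same-bin", "proximal-table")


def map_methylation_targets(
    loci: list[str],
    locus_bins: BinIndex,
    strong: StrongInteractionSet,
    gene_bins: BinIndex,
    immune_genes: set[str] | None = None,
    proximal_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate target genes of methylation loci.

    For each locus: genes overlapping any bin strongly interacting with
    the locus's bin ('hic-intra' / 'hic-inter'), genes sharing the
    locus's own bin ('same-bin'), and genes from the supplied proximal
    table ('proximal-table'). With ``immune_genes`` given, non-immune
    genes are excluded. Returns (locus_id, gene, provenance) rows.
    """
    bin_to_genes: dict[tuple[str, int], set[str]] = {}
    for gene, bins in gene_bins.feature_bins.items():
        if immune_genes is not None and gene not in immune_genes:
            continue
        for b in bins:
            bin_to_genes.setdefault(b, set()).add(gene)

    rows = []
    for locus in loci:
        own_bins = locus_bins.bins_of(locus)
        hits: dict[tuple[str, str], None] = {}
        for bin_ in sorted(own_bins):
            for gene in sorted(bin_to_genes.get(bin_, ())):
                hits[(gene, "same-bin")] = None
            for partner, kind in sorted(strong.partner_bins(bin_).items()):
                for gene in sorted(bin_to_genes.get(partner, ())):
                    hits[(gene, f"hic-{kind}")] = None
        if proximal_table is not None and len(proximal_table):
            sub = proximal_table[proximal_table["locus_id"] == locus]
            for gene in sub["gene"]:
                if immune_genes is None or gene in immune_genes:
                    hits[(gene, "proximal-table")] = None
        for gene, prov in sorted(hits, key=lambda t: (t[0], PROVENANCE_ORDER.index(t[1]))):
            rows.append({"locus_id": locus, "gene": gene, "provenance": prov})
    return pd.DataFrame(rows, columns=["locus_id", "gene", "provenance"])


def bin_genome(genome: SyntheticGenome,
               bin_size: int = DEFAULT_BIN_SIZE) -> tuple[BinIndex, BinIndex, BinIndex]:
    """Convenience: bin a genome's genes, methylation loci and LD blocks."""
    genes = bin_features(genome.genes, genome.chromosomes, bin_size)
    loci = bin_features(genome.loci, genome.chromosomes, bin_size)
    blocks = bin_features(genome.ld_blocks, genome.chromosomes, bin_size)
    return genes, loci, blocks
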