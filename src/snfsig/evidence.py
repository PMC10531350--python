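"""Selected-immune-gene-set (SIG) assembly and evidence scoring.

A cluster's SIG is the union of three provenance paths over its
top-ranked features: immune genes appearing directly as expression
features, candidate targets of top methylation loci (via strong Hi-C
interactions / same-bin / a supplied proximal table), and candidate
targets of top miRNAs. SIGs are scored by curated-gene-set overlap,
somatic/germline mutation annotation with 2x2 enrichment tests, and PPI
hub identification at top-degree quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, chi2_contingency, hypergeom

from .datatypes import SIG, ConfigurationError
from .hic import BinIndex, StrongInteractionSet


def assemble_sig(
    cluster: int,
    top_features: pd.DataFrame,           # columns: feature_id, data_type
    immune_genes: set[str],
    methylation_targets: pd.DataFrame,    # locus_id, gene, provenance
    mirna_targets: pd.DataFrame,          # mirna_id, gene
) -> SIG:
    """Union of the three provenance paths, deduplicated, with per-gene
    provenance tags and source feature ids."""
    known_types = {"methylation", "mrna", "mirna"}
    bad = set(top_features["data_type"]) - known_types
    if bad:
        raise ConfigurationError(f"unresolvable feature data types: {sorted(bad)}")

    genes: dict[str, set[str]] = {}
    sources: dict[str, set[str]] = {}

    def add(gene: str, tag: str, source: str) -> None:
        genes.setdefault(gene, set()).add(tag)
        sources.setdefault(gene, set()).add(source)

    expr = top_features.loc[top_features["data_type"] == "mrna", "feature_id"]
    for g in expr:
        if g in immune_genes:
            add(g, "expression-feature", g)

    top_loci = set(top_features.loc[top_features["data_type"] == "methylation",
                                    "feature_id"])
    if len(methylation_targets):
        sub = methylation_targets[methylation_targets["locus_id"].isin(top_loci)]
        for row in sub.itertuples(index=False):
            if row.gene in immune_genes:
                add(row.gene, "methylation-target", row.locus_id)

    top_mirnas = set(top_features.loc[top_features["data_type"] == "mirna",
                                      "feature_id"])
    if len(mirna_targets):
        sub = mirna_targets[mirna_targets["mirna_id"].isin(top_mirnas)]
        for row in sub.itertuples(index=False):
            if row.gene in immune_genes:
                add(row.gene, "mirna-target", row.mirna_id)

    return SIG(
        cluster=cluster,
        genes={g: sorted(tags) for g, tags in genes.items()},
        sources={g: sorted(srcs) for g, srcs in sources.items()},
    )


def geneset_overlap(sig: SIG, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per curated set: |SIG intersection set| and the shared genes."""
    if not gene_sets:
        raise ConfigurationError("empty gene-set collection")
    rows = []
    for name in sorted(gene_sets):
        shared = sorted(sig.gene_set & set(gene_sets[name]))
        rows.append({"cluster": sig.cluster, "gene_set": name,
                     "set_size": len(set(gene_sets[name])),
                     "n_shared": len(shared), "shared_genes": ";".join(shared)})
    return pd.DataFrame(rows)


@dataclass
class MutationAnnotation:
    """Per-gene mutation flags for one SIG, plus summary counts.

    Flags: harbors_somatic (gene appears in the somatic table),
    harbors_germline (gene shares a bin with an LD block),
    affected_via_interaction (a gene bin strongly interacts with an LD
    bin). Summary rows: harboring germline / affected via interactions /
    harboring somatic / harboring both / affected by both.
    """

    cluster: int
    flags: pd.DataFrame  # gene, harbors_somatic, harbors_germline, affected_via_interaction

    def summary(self) -> pd.Series:
        f = self.flags
        return pd.Series({
            "in_sig": len(f),
            "harboring_germline": int(f["harbors_germline"].sum()),
            "affected_via_interaction": int(f["affected_via_interaction"].sum()),
            "harboring_somatic": int(f["harbors_somatic"].sum()),
            "harboring_both": int((f["harbors_germline"] & f["harbors_somatic"]).sum()),
            "affected_by_both": int((f["affected_via_interaction"]
                                     & f["harbors_somatic"]).sum()),
        })


def annotate_mutations(
    sig: SIG,
    somatic: pd.DataFrame,              # patient_id, gene, class
    ld_bins: set[tuple[str, int]],
    strong: StrongInteractionSet,
    gene_bins: BinIndex,
) -> MutationAnnotation:
    """Flag each SIG gene for somatic / germline / interaction-mediated
    germline involvement; genes without coordinates are warned about and
    excluded."""
    somatic_genes = set(somatic.loc[somatic["class"] == "somatic", "gene"]) \
        if len(somatic) else set()
    # bins strongly interacting with any LD bin
    interacting: set[tuple[str, int]] = set()
    for b in ld_bins:
        interacting.update(strong.partner_bins(b))

    rows = []
    skipped = []
    for gene in sorted(sig.gene_set):
        if gene not in gene_bins.feature_bins:
            skipped.append(gene)
            continue
        bins = gene_bins.bins_of(gene)
        rows.append({
            "gene": gene,
            "harbors_somatic": gene in somatic_genes,
            "harbors_germline": bool(bins & ld_bins),
            "affected_via_interaction": bool(bins & interacting),
        })
    if skipped:
        warnings.warn(f"{len(skipped)} SIG gene(s) absent from genome annotation; excluded")
    flags = pd.DataFrame(rows, columns=["gene", "harbors_somatic", "harbors_germline",
                                        "affected_via_interaction"])
    return MutationAnnotation(cluster=sig.cluster, flags=flags)


def fisher_enrichment(table: list[list[int]] | np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p). The p-value is the minimum-likelihood
    two-sided exact hypergeometric p (sum of probabilities of tables, at
    fixed margins, no more probable than the observed one). The odds
    ratio is the sample odds ratio, with 0.5 added to every cell (with a
    warning) when any cell is zero.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConfigurationError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ConfigurationError("zero margin in contingency table")
    _, p = fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    if 0 in (a, b, c, d):
        warnings.warn("zero cell: odds ratio uses 0.5 continuity correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), float(p)


def fisher_enumeration_oracle(table: list[list[int]] | np.ndarray) -> float:
    """Independent two-sided exact p by full enumeration of all tables
    with the observed margins (practical for small totals)."""
    t = np.asarray(table, dtype=np.int64)
    r1, r2 = t.sum(axis=1)
    c1, _ = t.sum(axis=0)
    n = int(t.sum())
    p_obs = hypergeom.pmf(int(t[0, 0]), n, int(r1), int(c1))
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_a = hypergeom.pmf(a, n, int(r1), int(c1))
        if p_a <= p_obs * (1 + 1e-10):
            total += p_a
    return float(min(total, 1.0))


def association_test(table: list[list[int]] | np.ndarray,
                     method: str = "exact") -> tuple[float, float]:
    """2x2 association test with a choice of convention.

    method='exact': two-sided Fisher's exact test (default).
    method='chi2-cc': chi-square with Yates continuity correction, the
    convention common in R workflows for large 2x2 tables (and the one
    that reproduces the reference values this package's acceptance
    checks use for large gene-count tables).
    """
    if method == "exact":
        return fisher_enrichment(table)
    if method == "chi2-cc":
        t = np.asarray(table, dtype=np.int64)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            raise ConfigurationError("zero margin in contingency table")
        res = chi2_contingency(t, correction=True)
        a, b, c, d = t.ravel().astype(float)
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return float(a * d / (b * c)), float(res.pvalue)
    raise ConfigurationError(f"unknown method {method!r}")


def enrichment_table(n_in_a: int, n_out_a: int, n_in_b: int, n_out_b: int) -> np.ndarray:
    """Assemble the (group x in/out-of-condition) 2x2 table."""
    return np.array([[n_in_a, n_out_a], [n_in_b, n_out_b]], dtype=np.int64)


@dataclass
class HubReport:
    """Degree summary and hub tiers of a SIG's PPI subgraph."""

    cluster: int
    n_genes_in_ppi: int
    n_edges: int
    mean_degree: float
    degrees: pd.Series                  # per gene
    hubs: dict[float, list[str]]        # top fraction -> hub genes
    thresholds: dict[float, float]


def ppi_hubs(graph: nx.Graph, sig: SIG,
             top_fractions: tuple[float, ...] = (0.05, 0.01),
             on_full_graph: bool = False) -> HubReport:
    """Hubs of the SIG-induced PPI subgraph at top-degree quantiles.

    A hub at fraction f is a gene whose degree is >= the empirical
    (1 - f) quantile of the degree distribution; ties are included, so a
    tier can exceed its nominal count. With ``on_full_graph`` degrees are
    taken from the full graph instead of the induced subgraph.
    """
    members = sorted(sig.gene_set & set(graph.nodes))
    if not members:
        raise ConfigurationError("no SIG gene appears in the PPI graph")
    sub = graph.subgraph(members)
    deg_source = graph if on_full_graph else sub
    degrees = pd.Series({g: deg_source.degree(g) for g in members}).sort_index()
    hubs: dict[float, list[str]] = {}
    thresholds: dict[float, float] = {}
    for f in top_fractions:
        thr = float(np.quantile(degrees.to_numpy(), 1.0 - f))
        thresholds[f] = thr
        hubs[f] = sorted(degrees.index[degrees >= thr])
    return HubReport(
        cluster=sig.cluster,
        n_genes_in_ppi=len(members),
        n_edges=sub.number_of_edges(),
        mean_degree=float(2 * sub.number_of_edges() / max(len(members), 1)),
        degrees=degrees,
        hubs=hubs,
        thresholds=thresholds,
    )
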