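"""SIG assembly, overlaps, Fisher enrichment, mutation flags, PPI hubs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from snfsig.datatypes import SIG, ConfigurationError
from snfsig.evidence import (
    annotate_mutations,
    assemble_sig,
    association_test,
    enrichment_table,
    fisher_enrichment,
    fisher_enumeration_oracle,
    geneset_overlap,
    ppi_hubs,
)
from snfsig.hic import StrongInteractionSet, bin_features


def top(rows):
    return pd.DataFrame(rows, columns=["feature_id", "data_type"])


EMPTY_TARGETS = pd.DataFrame(columns=["locus_id", "gene", "provenance"])
EMPTY_MIRNA = pd.DataFrame(columns=["mirna_id", "gene"])


class TestAssembleSig:
    def test_expression_only(self):
        sig = assemble_sig(1, top([("IMM1", "mrna"), ("OTHER", "mrna")]),
                           {"IMM1"}, EMPTY_TARGETS, EMPTY_MIRNA)
        assert sig.gene_set == {"IMM1"}
        assert sig.genes["IMM1"] == ["expression-feature"]

    def test_union_with_multi_provenance(self):
        meth = pd.DataFrame([{"locus_id": "cg1", "gene": "A",
                              "provenance": "hic-intra"},
                             {"locus_id": "cg1", "gene": "B",
                              "provenance": "same-bin"}])
        mirna = pd.DataFrame([{"mirna_id": "mir1", "gene": "B"},
                              {"mirna_id": "mir1", "gene": "C"}])
        sig = assemble_sig(2, top([("cg1", "methylation"), ("mir1", "mirna")]),
                           {"A", "B", "C"}, meth, mirna)
        assert sig.gene_set == {"A", "B", "C"}
        assert sig.genes["B"] == ["methylation-target", "mirna-target"]

    def test_matches_bruteforce_union_of_three_paths(self):
        rng = np.random.default_rng(0)
        immune = {f"G{i}" for i in range(30)}
        loci = [f"cg{i}" for i in range(10)]
        mirnas = [f"mir{i}" for i in range(5)]
        meth = pd.DataFrame([
            {"locus_id": rng.choice(loci), "gene": f"G{rng.integers(40)}",
             "provenance": "hic-intra"} for _ in range(40)])
        mir = pd.DataFrame([
            {"mirna_id": rng.choice(mirnas), "gene": f"G{rng.integers(40)}"}
            for _ in range(25)])
        features = ([(l, "methylation") for l in loci[:4]]
                    + [(m, "mirna") for m in mirnas[:3]]
                    + [("G1", "mrna"), ("G99", "mrna")])
        sig = assemble_sig(1, top(features), immune, meth, mir)
        expected = {"G1"} if "G1" in immune else set()
        sel_loci = {l for l, _ in features[:4]}
        expected |= {g for _, row in meth.iterrows()
                     if row["locus_id"] in sel_loci
                     for g in [row["gene"]] if g in immune}
        sel_mir = {m for m, _ in features[4:7]}
        expected |= {row["gene"] for _, row in mir.iterrows()
                     if row["mirna_id"] in sel_mir and row["gene"] in immune}
        assert sig.gene_set == expected

    def test_unknown_data_type_rejected(self):
        with pytest.raises(ConfigurationError):
            assemble_sig(1, top([("x", "proteomics")]), set(),
                         EMPTY_TARGETS, EMPTY_MIRNA)


class TestGenesetOverlap:
    def _sig(self, genes):
        return SIG(cluster=1, genes={g: ["expression-feature"] for g in genes})

    def test_disjoint_and_subset(self):
        sig = self._sig(["A", "B"])
        res = geneset_overlap(sig, {"S1": ["C", "D"], "S2": ["A", "B", "C"]})
        n = dict(zip(res["gene_set"], res["n_shared"]))
        assert n == {"S1": 0, "S2": 2}

    def test_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(50)]
        sig = self._sig(list(rng.choice(genes, 20, replace=False)))
        sets = {f"S{i}": list(rng.choice(genes, 15, replace=False))
                for i in range(4)}
        res = geneset_overlap(sig, sets)
        for _, row in res.iterrows():
            assert row["n_shared"] == len(sig.gene_set & set(sets[row["gene_set"]]))

    def test_empty_collection_rejected(self):
        with pytest.raises(ConfigurationError):
            geneset_overlap(self._sig(["A"]), {})


class TestFisher:
    def test_exact_matches_enumeration_small_tables(self):
        """Exact two-sided p equals full hypergeometric enumeration for
        all margins with total <= 40 (sampled grid)."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            t = rng.integers(0, 11, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            _, p = fisher_enrichment(t)
            assert p == pytest.approx(fisher_enumeration_oracle(t), abs=1e-10)

    def test_specific_enumeration_case(self):
        _, p = fisher_enrichment([[3, 1], [1, 3]])
        assert p == pytest.approx(fisher_enumeration_oracle([[3, 1], [1, 3]]),
                                  abs=1e-12)

    def test_no_association_table(self):
        odds, p = fisher_enrichment([[5, 5], [50, 50]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_row_column_transpose_invariance(self):
        t = [[7, 2], [3, 11]]
        assert fisher_enrichment(t)[1] == pytest.approx(
            fisher_enrichment(np.transpose(t))[1], abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ConfigurationError):
            fisher_enrichment([[0, 0], [1, 2]])

    def test_zero_cell_continuity_correction_flagged(self):
        with pytest.warns(UserWarning):
            odds, _ = fisher_enrichment([[0, 5], [5, 5]])
        assert odds == pytest.approx(0.5 * 5.5 / (5.5 * 5.5))

    def test_chi2_cc_convention_available(self):
        _, p_exact = association_test([[20, 80], [40, 60]], "exact")
        _, p_cc = association_test([[20, 80], [40, 60]], "chi2-cc")
        assert 0 < p_cc < 0.05 and 0 < p_exact < 0.05


def make_sig(genes):
    return SIG(cluster=1, genes={g: ["expression-feature"] for g in genes})


class TestAnnotateMutations:
    CHROMS = {"chr1": 400_000}

    def test_flags_and_both_categories(self):
        genes = pd.DataFrame([
            {"chrom": "chr1", "start": 10_000, "end": 12_000, "name": "G1"},
            {"chrom": "chr1", "start": 200_000, "end": 202_000, "name": "G2"},
            {"chrom": "chr1", "start": 300_000, "end": 302_000, "name": "G3"},
        ])
        gene_bins = bin_features(genes, self.CHROMS, 40_000)
        ld_bins = {("chr1", 0)}  # G1's bin
        strong = StrongInteractionSet(
            intra=pd.DataFrame([{"chrom": "chr1", "bin_a": 0, "bin_b": 5,
                                 "count": 300.0}]),
            inter=pd.DataFrame(columns=["chrom_a", "bin_a", "chrom_b",
                                        "bin_b", "count"]),
            thresholds={"chr1": 100.0}, tail=0.05, n_replicates=4)
        somatic = pd.DataFrame([{"patient_id": "P1", "gene": "G2",
                                 "class": "somatic"}])
        ann = annotate_mutations(make_sig(["G1", "G2", "G3"]), somatic,
                                 ld_bins, strong, gene_bins)
        f = ann.flags.set_index("gene")
        assert bool(f.loc["G1", "harbors_germline"])
        assert bool(f.loc["G2", "affected_via_interaction"])  # bin 5
        assert bool(f.loc["G2", "harbors_somatic"])
        assert not bool(f.loc["G3", "harbors_germline"])
        s = ann.summary()
        assert s["affected_by_both"] == 1  # G2
        assert s["harboring_both"] == 0

    def test_counts_match_bruteforce_recount(self, genome):
        from snfsig.hic import bin_genome, call_strong_interactions
        from snfsig.simulate import generate_contacts, generate_mutations

        reps = generate_contacts(genome, 4, [("chr1", 0, "chr1", 30)], seed=7)
        strong = call_strong_interactions(reps, tail=0.1)
        gene_bins, _, block_bins = bin_genome(genome)
        ld_bins = set().union(*block_bins.feature_bins.values())
        somatic, _ = generate_mutations(genome, [f"P{i}" for i in range(30)],
                                        somatic_rate=0.005, seed=8)
        sig = make_sig(sorted(genome.immune_genes)[:100])
        ann = annotate_mutations(sig, somatic, ld_bins, strong, gene_bins)
        interacting = set()
        for b in ld_bins:
            interacting |= set(strong.partner_bins(b))
        som_genes = set(somatic["gene"])
        expect = {"harboring_germline": 0, "affected_via_interaction": 0,
                  "harboring_somatic": 0, "harboring_both": 0,
                  "affected_by_both": 0}
        for g in sig.gene_set:
            bins = gene_bins.bins_of(g)
            germ = bool(bins & ld_bins)
            via = bool(bins & interacting)
            som = g in som_genes
            expect["harboring_germline"] += germ
            expect["affected_via_interaction"] += via
            expect["harboring_somatic"] += som
            expect["harboring_both"] += germ and som
            expect["affected_by_both"] += via and som
        s = ann.summary()
        for key, val in expect.items():
            assert s[key] == val
        assert s["harboring_both"] <= min(s["harboring_germline"],
                                          s["harboring_somatic"])


class TestPpiHubs:
    def test_star_graph_top_1pct_is_center(self):
        g = nx.star_graph(99)  # center 0, leaves 1..99
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(100)})
        sig = make_sig([f"G{i}" for i in range(100)])
        report = ppi_hubs(g, sig, (0.01,))
        assert report.hubs[0.01] == ["G0"]

    def test_regular_graph_all_are_hubs(self):
        g = nx.cycle_graph(20)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(20)})
        sig = make_sig([f"G{i}" for i in range(20)])
        report = ppi_hubs(g, sig, (0.05, 0.01))
        assert len(report.hubs[0.05]) == 20
        assert len(report.hubs[0.01]) == 20

    def test_hub_tiers_monotone_and_match_sort_oracle(self):
        from snfsig.simulate import generate_ppi

        genes = [f"G{i}" for i in range(150)]
        g = generate_ppi(genes, 3, seed=5)
        sig = make_sig(genes[:120])
        report = ppi_hubs(g, sig, (0.05, 0.01))
        assert set(report.hubs[0.01]) <= set(report.hubs[0.05])
        degrees = report.degrees
        for f in (0.05, 0.01):
            thr = np.quantile(degrees.to_numpy(), 1 - f)
            expected = sorted(degrees.index[degrees >= thr])
            assert report.hubs[f] == expected

    def test_summary_degrees_on_induced_subgraph(self):
        g = nx.path_graph(5)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(5)})
        sig = make_sig(["G0", "G1", "G2"])
        report = ppi_hubs(g, sig, (0.05,))
        assert report.n_genes_in_ppi == 3
        assert report.n_edges == 2
        assert report.degrees["G2"] == 1  # G2-G3 edge outside subgraph
        full = ppi_hubs(g, sig, (0.05,), on_full_graph=True)
        assert full.degrees["G2"] == 2

    def test_empty_intersection_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ConfigurationError):
            ppi_hubs(g, make_sig(["X"]), (0.05,))
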