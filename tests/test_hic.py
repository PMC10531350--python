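"""Binning, strong-interaction calling and methylation-target mapping."""

import numpy as np
import pandas as pd
import pytest

from snfsig.datatypes import ConfigurationError
from snfsig.hic import (
    StrongInteractionSet,
    bin_features,
    call_significant_inter,
    call_strong_interactions,
    call_strong_intra,
    map_methylation_targets,
)
from snfsig.simulate import generate_contacts


def contacts(rows):
    return pd.DataFrame(rows, columns=["chrom_a", "bin_a", "chrom_b", "bin_b",
                                       "count"])


class TestBinFeatures:
    CHROMS = {"chr1": 1_000_000}

    def test_point_at_zero_maps_to_bin_zero(self):
        iv = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1, "name": "x"}])
        idx = bin_features(iv, self.CHROMS, 40_000)
        assert idx.bins_of("x") == {("chr1", 0)}

    def test_interval_spanning_boundary_maps_to_both_bins(self):
        iv = pd.DataFrame([{"chrom": "chr1", "start": 79_000, "end": 81_000,
                            "name": "g"}])
        idx = bin_features(iv, self.CHROMS, 40_000)
        assert idx.bins_of("g") == {("chr1", 1), ("chr1", 2)}

    def test_matches_per_base_scan_on_toy_chromosome(self):
        rng = np.random.default_rng(0)
        bin_size = 1_000
        chroms = {"chr1": 100_000}
        rows = []
        for i in range(30):
            start = int(rng.integers(0, 99_000))
            end = start + int(rng.integers(1, 5_000))
            rows.append({"chrom": "chr1", "start": start,
                         "end": min(end, 100_000), "name": f"iv{i}"})
        iv = pd.DataFrame(rows)
        idx = bin_features(iv, chroms, bin_size)
        for row in rows:
            scanned = {("chr1", pos // bin_size)
                       for pos in range(row["start"], row["end"])}
            assert idx.bins_of(row["name"]) == scanned

    def test_interval_beyond_chromosome_end_rejected(self):
        iv = pd.DataFrame([{"chrom": "chr1", "start": 990_000, "end": 1_000_001,
                            "name": "bad"}])
        with pytest.raises(ConfigurationError, match="bad"):
            bin_features(iv, self.CHROMS, 40_000)


class TestStrongIntra:
    def test_pair_missing_from_one_replicate_excluded(self):
        base = [("chr1", 0, "chr1", 1, 500), ("chr1", 2, "chr1", 3, 400)]
        reps = [contacts(base), contacts(base), contacts(base),
                contacts(base[:1])]
        strong = call_strong_intra(reps, tail=0.5)
        pairs = set(zip(strong.intra["bin_a"], strong.intra["bin_b"]))
        assert (2, 3) not in pairs
        assert (0, 1) in pairs

    def test_uniform_counts_give_095_quantile_threshold(self):
        """Counts Uniform{1..100}: threshold ~96, ~5% of pairs kept."""
        rng = np.random.default_rng(1)
        n = 4000
        rows = [("chr1", 2 * i, "chr1", 2 * i + 1, int(rng.integers(1, 101)))
                for i in range(n)]
        rep = contacts(rows)
        strong = call_strong_intra([rep], tail=0.05)
        assert abs(strong.thresholds["chr1"] - 96) <= 2
        kept = len(strong.intra) / n
        assert abs(kept - 0.05) <= 0.01

    def test_all_equal_counts_keep_everything(self):
        rep = contacts([("chr1", 0, "chr1", 1, 7), ("chr1", 2, "chr1", 3, 7)])
        strong = call_strong_intra([rep], tail=0.05)
        assert len(strong.intra) == 2  # count >= threshold for all

    def test_thresholds_monotone_in_tail(self):
        rng = np.random.default_rng(2)
        rep = contacts([("chr1", 2 * i, "chr1", 2 * i + 1,
                         int(rng.integers(1, 500))) for i in range(500)])
        thr = [call_strong_intra([rep], tail=t).thresholds["chr1"]
               for t in (0.01, 0.05, 0.1, 0.25)]
        assert all(a >= b for a, b in zip(thr, thr[1:]))

    def test_replicate_consistency_and_tail_vs_nested_loop_oracle(self, genome):
        """Synthetic 4-replicate contacts: calls equal a brute-force
        intersection + per-chromosome quantile filter."""
        planted = [("chr1", 1, "chr1", 50), ("chr2", 3, "chr2", 60)]
        reps = generate_contacts(genome, 4, planted, background_rate=0.05,
                                 seed=3)
        tail = 0.05
        strong = call_strong_intra(reps, tail=tail)

        def pair_map(rep):
            out = {}
            for r in rep.itertuples(index=False):
                key = tuple(sorted([(r.chrom_a, r.bin_a), (r.chrom_b, r.bin_b)]))
                out[key] = out.get(key, 0) + r.count
            return out

        maps = [pair_map(r) for r in reps]
        common = set(maps[0])
        for m in maps[1:]:
            common &= set(m)
        expected = set()
        for chrom in genome.chromosomes:
            pairs = [(k, np.mean([m[k] for m in maps])) for k in common
                     if k[0][0] == chrom and k[1][0] == chrom]
            if not pairs:
                continue
            thr = np.quantile([c for _, c in pairs], 1 - tail)
            expected |= {k for k, c in pairs if c >= thr}
        got = {((r.chrom, r.bin_a), (r.chrom, r.bin_b))
               for r in strong.intra.itertuples(index=False)}
        assert got == expected
        for ca, a, cb, b in planted:
            assert tuple(sorted([(ca, a), (cb, b)])) in got


class TestSignificantInter:
    def test_single_replicate_returns_its_inter_pairs(self):
        rep = contacts([("chr1", 0, "chr2", 1, 5), ("chr1", 0, "chr1", 1, 9)])
        inter = call_significant_inter([rep])
        assert len(inter) == 1
        assert inter.iloc[0]["chrom_b"] == "chr2"

    def test_matches_set_intersection_oracle(self, genome):
        reps = generate_contacts(genome, 4, [("chr1", 0, "chr2", 5)],
                                 background_rate=0.03, seed=4)
        inter = call_significant_inter(reps)
        sets = []
        for rep in reps:
            s = set()
            for r in rep.itertuples(index=False):
                if r.chrom_a != r.chrom_b:
                    s.add(tuple(sorted([(r.chrom_a, r.bin_a),
                                        (r.chrom_b, r.bin_b)])))
            sets.append(s)
        expected = set.intersection(*sets)
        got = {tuple(sorted([(r.chrom_a, r.bin_a), (r.chrom_b, r.bin_b)]))
               for r in inter.itertuples(index=False)}
        assert got == expected
        assert (("chr1", 0), ("chr2", 5)) in got


class TestTargetMapping:
    CHROMS = {"chr1": 400_000, "chr2": 400_000}
    BIN = 40_000

    def _bins(self, genes):
        return bin_features(pd.DataFrame(genes), self.CHROMS, self.BIN)

    def test_intra_partner_same_bin_and_provenance(self):
        genes = [
            {"chrom": "chr1", "start": 250_000, "end": 255_000, "name": "IMM1"},
            {"chrom": "chr1", "start": 10_000, "end": 12_000, "name": "IMM2"},
            {"chrom": "chr2", "start": 90_000, "end": 95_000, "name": "IMM3"},
        ]
        loci = [{"chrom": "chr1", "start": 5_000, "end": 5_001, "name": "cg1"}]
        gene_bins = self._bins(genes)
        locus_bins = self._bins(loci)
        strong = StrongInteractionSet(
            intra=pd.DataFrame([{"chrom": "chr1", "bin_a": 0, "bin_b": 6,
                                 "count": 200.0}]),
            inter=pd.DataFrame([{"chrom_a": "chr1", "bin_a": 0,
                                 "chrom_b": "chr2", "bin_b": 2, "count": 8.0}]),
            thresholds={"chr1": 100.0}, tail=0.05, n_replicates=4)
        targets = map_methylation_targets(
            ["cg1"], locus_bins, strong, gene_bins,
            immune_genes={"IMM1", "IMM2", "IMM3"})
        by_gene = dict(zip(targets["gene"], targets["provenance"]))
        assert by_gene == {"IMM1": "hic-intra", "IMM2": "same-bin",
                           "IMM3": "hic-inter"}

    def test_no_strong_pairs_yields_only_same_bin_genes(self):
        genes = [{"chrom": "chr1", "start": 1_000, "end": 2_000, "name": "G1"}]
        loci = [{"chrom": "chr1", "start": 500, "end": 501, "name": "cg1"}]
        strong = StrongInteractionSet(
            intra=pd.DataFrame(columns=["chrom", "bin_a", "bin_b", "count"]),
            inter=pd.DataFrame(columns=["chrom_a", "bin_a", "chrom_b",
                                        "bin_b", "count"]),
            thresholds={}, tail=0.05, n_replicates=4)
        targets = map_methylation_targets(["cg1"], self._bins(loci), strong,
                                          self._bins(genes), {"G1"})
        assert list(targets["provenance"]) == ["same-bin"]

    def test_proximal_table_and_immune_filter(self):
        genes = [{"chrom": "chr1", "start": 1_000, "end": 2_000, "name": "G1"},
                 {"chrom": "chr1", "start": 3_000, "end": 4_000, "name": "NONIMM"}]
        loci = [{"chrom": "chr1", "start": 500, "end": 501, "name": "cg1"}]
        strong = StrongInteractionSet(
            intra=pd.DataFrame(columns=["chrom", "bin_a", "bin_b", "count"]),
            inter=pd.DataFrame(columns=["chrom_a", "bin_a", "chrom_b",
                                        "bin_b", "count"]),
            thresholds={}, tail=0.05, n_replicates=4)
        prox = pd.DataFrame([{"locus_id": "cg1", "gene": "G1"},
                             {"locus_id": "cg1", "gene": "NONIMM"}])
        targets = map_methylation_targets(["cg1"], self._bins(loci), strong,
                                          self._bins(genes), {"G1"},
                                          proximal_table=prox)
        assert "NONIMM" not in set(targets["gene"])
        provs = set(targets.loc[targets["gene"] == "G1", "provenance"])
        assert provs == {"same-bin", "proximal-table"}

    def test_matches_nested_loop_join_oracle(self, genome):
        from snfsig.hic import bin_genome

        planted = [("chr1", 1, "chr1", 40), ("chr1", 2, "chr2", 7)]
        reps = generate_contacts(genome, 4, planted, background_rate=0.03,
                                 seed=6)
        strong = call_strong_interactions(reps, tail=0.05)
        gene_bins, locus_bins, _ = bin_genome(genome)
        immune = genome.immune_genes
        loci = list(genome.loci["name"])[:40]
        targets = map_methylation_targets(loci, locus_bins, strong, gene_bins,
                                          immune)
        strong_pairs = set()
        for r in strong.intra.itertuples(index=False):
            strong_pairs.add(((r.chrom, r.bin_a), (r.chrom, r.bin_b)))
        for r in strong.inter.itertuples(index=False):
            strong_pairs.add(((r.chrom_a, r.bin_a), (r.chrom_b, r.bin_b)))
        expected = set()
        for locus in loci:
            for lb in locus_bins.bins_of(locus):
                for gene in immune:
                    gb = gene_bins.bins_of(gene)
                    if lb in gb:
                        expected.add((locus, gene))
                    for x, y in strong_pairs:
                        if (lb == x and y in gb) or (lb == y and x in gb):
                            expected.add((locus, gene))
        got = set(zip(targets["locus_id"], targets["gene"]))
        assert got == expected

    def test_unbinned_locus_rejected(self):
        genes = [{"chrom": "chr1", "start": 1_000, "end": 2_000, "name": "G1"}]
        strong = StrongInteractionSet(
            intra=pd.DataFrame(columns=["chrom", "bin_a", "bin_b", "count"]),
            inter=pd.DataFrame(columns=["chrom_a", "bin_a", "chrom_b",
                                        "bin_b", "count"]),
            thresholds={}, tail=0.05, n_replicates=4)
        with pytest.raises(ConfigurationError):
            map_methylation_targets(["nope"], self._bins(genes), strong,
                                    self._bins(genes), {"G1"})
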