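"""End-to-end pipeline over a run directory.

Stages (each independently invocable on the previous stage's outputs):
simulate -> preprocess -> fuse -> cluster -> rank -> select ->
hic-call -> hic-map -> sig -> evidence -> survival. Every run writes a
manifest with the config hash, per-stage seeds, package version and
input checksums; re-running with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .cluster import (
    estimate_k_eigengap,
    estimate_k_rotationcost,
    ncut_cluster,
    partition_accuracy,
)
from .datatypes import ClusterAssignment, ConfigurationError, SIG
from .evidence import (
    annotate_mutations,
    assemble_sig,
    association_test,
    enrichment_table,
    geneset_overlap,
    ppi_hubs,
)
from .hic import bin_features, call_strong_interactions, map_methylation_targets
from .preprocess import preprocess_all
from .ranking import (
    SelectionParams,
    preservation_search,
    rank_all_clusters,
    restrict_matrices,
    select_top,
)
from .simulate import (
    SyntheticCohortConfig,
    default_genome,
    generate_cohort,
    generate_contacts,
    generate_gene_sets,
    generate_mirna_targets,
    generate_mutations,
    generate_ppi,
)
from .snf import SNFParams, fuse_omics, network_from_omics
from .survival import survival_report

log = logging.getLogger("snfsig")

STAGES = ("simulate", "preprocess", "fuse", "cluster", "rank", "select",
          "hic-call", "hic-map", "sig", "evidence", "survival")

OMICS_TYPES = ("methylation", "mrna", "mirna")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; loadable from YAML."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SyntheticCohortConfig overrides
    inputs: dict = field(default_factory=dict)     # explicit file paths (alternative)
    alpha: float = 0.5
    k_neighbors: int = 20
    iterations: int = 20
    k: int | None = None          # cluster count; None -> eigengap top candidate
    k_min: int = 2
    k_max: int = 6
    top_m: int = 125
    accuracy_threshold: float = 0.95
    grid: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 200)
    bin_size: int = 40_000
    tail: float = 0.05
    hub_fractions: tuple[float, ...] = (0.05, 0.01)
    with_hic: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.grid:
            cfg.grid = tuple(int(g) for g in cfg.grid)
        cfg.hub_fractions = tuple(float(f) for f in cfg.hub_fractions)
        return cfg

    def snf_params(self) -> SNFParams:
        return SNFParams(alpha=self.alpha, K=self.k_neighbors, T=self.iterations)

    def stage_seed(self, stage: str) -> int:
        """One global seed fans out to per-stage seeds via a counter."""
        return (self.seed * 1009 + STAGES.index(stage)) % (2**31)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_paths(run_dir: str | Path) -> dict[str, Path]:
    run_dir = Path(run_dir)
    inputs = run_dir / "inputs"
    return {"run": run_dir, "inputs": inputs}


def stage_simulate(config: PipelineConfig, run_dir: str | Path) -> None:
    """Generate every pipeline input into <run_dir>/inputs."""
    paths = _run_paths(run_dir)
    paths["inputs"].mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("simulate")
    genome = default_genome(seed=seed)
    cohort_cfg = SyntheticCohortConfig(**{**config.simulate, "seed": seed})
    matrices, truth, clinical = generate_cohort(cohort_cfg, genome=genome)

    for dtype, m in matrices.items():
        sio.write_omics_tsv(m, paths["inputs"] / f"{dtype}.tsv")
    sio.write_clinical_tsv(clinical, paths["inputs"] / "clinical.tsv")
    sio.write_bed(genome.genes.assign(immune=genome.genes["immune"].astype(int)),
                  paths["inputs"] / "genes.bed", extra_cols=["immune"])
    sio.write_bed(genome.loci, paths["inputs"] / "loci.bed")
    sio.write_bed(genome.ld_blocks, paths["inputs"] / "ld_blocks.bed")
    with open(paths["inputs"] / "chromosomes.tsv", "w") as fh:
        for chrom, length in genome.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")
    pd.DataFrame(
        [{"feature_id": fid, "data_type": dtype, "cluster": c}
         for dtype, per_cluster in truth.informative.items()
         for c, fids in per_cluster.items() for fid in fids]
    ).to_csv(paths["inputs"] / "truth_informative.tsv", sep="\t", index=False)
    pd.DataFrame({"patient_id": clinical.patient_ids,
                  "cluster_true": truth.labels}).to_csv(
        paths["inputs"] / "truth_labels.tsv", sep="\t", index=False)

    if config.with_hic:
        rng = np.random.default_rng(seed)
        n_bins = {c: -(-l // config.bin_size) for c, l in genome.chromosomes.items()}
        chroms = sorted(n_bins)
        planted = []
        for i in range(10):
            ca = chroms[i % len(chroms)]
            a, b = sorted(rng.choice(n_bins[ca], size=2, replace=False).tolist())
            planted.append((ca, int(a), ca, int(b)))
        for i in range(5):
            ca, cb = chroms[0], chroms[-1]
            planted.append((ca, int(rng.integers(n_bins[ca])),
                            cb, int(rng.integers(n_bins[cb]))))
        replicates = generate_contacts(genome, n_replicates=4, planted_pairs=planted,
                                       bin_size=config.bin_size, seed=seed)
        for r, rep in enumerate(replicates, start=1):
            sio.write_contacts_tsv(rep, paths["inputs"] / f"contacts_rep{r}.tsv")

    gene_names = list(genome.genes["name"])
    immune = sorted(genome.immune_genes)
    graph = generate_ppi(immune, seed=seed)
    sio.write_ppi_tsv(graph, paths["inputs"] / "ppi.tsv")
    mutations, blocks = generate_mutations(genome, clinical.patient_ids, seed=seed)
    sio.write_mutations_tsv(mutations, paths["inputs"] / "mutations.tsv")
    mirna_ids = matrices["mirna"].feature_ids
    targets = generate_mirna_targets(mirna_ids, immune, seed=seed)
    sio.write_targets_tsv(targets, paths["inputs"] / "mirna_targets.tsv")
    sio.write_gmt(generate_gene_sets(immune, seed=seed),
                  paths["inputs"] / "gene_sets.gmt")
    log.info("simulate: %d patients, %d genes", cohort_cfg.n_patients, len(gene_names))


def _input_path(config: PipelineConfig, run_dir: Path, key: str, default: str) -> Path:
    if key in config.inputs:
        return Path(config.inputs[key])
    return run_dir / "inputs" / default


def _load_omics(config: PipelineConfig, run_dir: Path) -> list:
    return [
        sio.read_omics_tsv(_input_path(config, run_dir, dtype, f"{dtype}.tsv"), dtype)
        for dtype in OMICS_TYPES
    ]


def stage_preprocess(config: PipelineConfig, run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    matrices = _load_omics(config, run_dir)
    processed = preprocess_all(matrices)
    for m in processed:
        sio.write_omics_tsv(m, run_dir / f"normalized_{m.data_type}.tsv")
    log.info("preprocess: %s", {m.data_type: m.data.shape for m in processed})


def _load_normalized(run_dir: Path) -> list:
    return [sio.read_omics_tsv(run_dir / f"normalized_{t}.tsv", t) for t in OMICS_TYPES]


def stage_fuse(config: PipelineConfig, run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    matrices = _load_normalized(run_dir)
    params = config.snf_params()
    for m in matrices:
        sio.write_network_tsv(network_from_omics(m, params),
                              run_dir / f"network_{m.data_type}.tsv")
    fused = fuse_omics(matrices, params)
    sio.write_network_tsv(fused, run_dir / "network_fused.tsv")
    log.info("fuse: %d patients", len(fused.patient_ids))


def stage_cluster(config: PipelineConfig, run_dir: str | Path) -> ClusterAssignment:
    run_dir = Path(run_dir)
    fused = sio.read_network_tsv(run_dir / "network_fused.tsv")
    gap = estimate_k_eigengap(fused, config.k_min, config.k_max)
    rot = estimate_k_rotationcost(fused, config.k_min, config.k_max)
    report = gap.merge(rot, on="k").sort_values("k")
    report.to_csv(run_dir / "model_selection.tsv", sep="\t", index=False)
    k = config.k if config.k is not None else int(gap["k"].iloc[0])
    assignment = ncut_cluster(fused, k, seed=config.stage_seed("cluster"))
    assignment.to_series().rename_axis("patient_id").reset_index().to_csv(
        run_dir / "clusters.tsv", sep="\t", index=False)
    log.info("cluster: k=%d (eigengap top=%d)", k, int(gap["k"].iloc[0]))
    return assignment


def _load_assignment(run_dir: Path) -> ClusterAssignment:
    df = pd.read_csv(run_dir / "clusters.tsv", sep="\t", dtype={"patient_id": str})
    return ClusterAssignment(patient_ids=list(df["patient_id"]),
                             labels=df["cluster"].to_numpy(),
                             k=int(df["cluster"].max()))


def stage_rank(config: PipelineConfig, run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    matrices = _load_normalized(run_dir)
    assignment = _load_assignment(run_dir)
    rankings = rank_all_clusters(matrices, assignment)
    frames = [df.assign(cluster=c) for c, df in sorted(rankings.items())]
    pd.concat(frames, ignore_index=True)[
        ["cluster", "rank", "feature_id", "data_type", "nde"]
    ].to_csv(run_dir / "rankings.tsv", sep="\t", index=False)
    log.info("rank: %d clusters x %d features", len(rankings), len(frames[0]))


def _load_rankings(run_dir: Path) -> dict[int, pd.DataFrame]:
    df = pd.read_csv(run_dir / "rankings.tsv", sep="\t")
    return {int(c): sub.drop(columns="cluster").reset_index(drop=True)
            for c, sub in df.groupby("cluster")}


def stage_select(config: PipelineConfig, run_dir: str | Path) -> None:
    """Preservation search plus the final top-m selection report."""
    run_dir = Path(run_dir)
    matrices = _load_normalized(run_dir)
    assignment = _load_assignment(run_dir)
    params = SelectionParams(top_m=config.top_m,
                             accuracy_threshold=config.accuracy_threshold,
                             grid=config.grid)
    snf_params = config.snf_params()
    seed = config.stage_seed("cluster")

    def recluster(sub_matrices):
        fused = fuse_omics(sub_matrices, snf_params)
        return ncut_cluster(fused, assignment.k, seed=seed)

    minimal, curve = preservation_search(matrices, assignment, params, recluster)
    curve.to_csv(run_dir / "preservation_curve.tsv", sep="\t", index=False)
    chosen = minimal if minimal is not None else params.top_m
    rankings = _load_rankings(run_dir)
    selection = select_top(rankings, chosen)
    selection.to_csv(run_dir / "selection.tsv", sep="\t", index=False)
    with open(run_dir / "selection_report.json", "w") as fh:
        json.dump({"minimal_top_m": minimal, "chosen_top_m": chosen,
                   "n_selected": len(selection),
                   "threshold": params.accuracy_threshold}, fh, indent=1)
    log.info("select: minimal top_m=%s, union size=%d", minimal, len(selection))


def _load_genome_tables(config: PipelineConfig, run_dir: Path):
    chrom_path = _input_path(config, run_dir, "chromosomes", "chromosomes.tsv")
    chroms = {}
    with open(chrom_path) as fh:
        for line in fh:
            name, length = line.split()
            chroms[name] = int(length)
    genes = sio.read_bed(_input_path(config, run_dir, "genes", "genes.bed"),
                         extra_cols=["immune"])
    loci = sio.read_bed(_input_path(config, run_dir, "loci", "loci.bed"))
    blocks = sio.read_bed(_input_path(config, run_dir, "ld_blocks", "ld_blocks.bed"))
    return chroms, genes, loci, blocks


def stage_hic_call(config: PipelineConfig, run_dir: str | Path):
    run_dir = Path(run_dir)
    if "contacts" in config.inputs:
        contact_paths = [Path(p) for p in config.inputs["contacts"]]
    else:
        contact_paths = sorted((run_dir / "inputs").glob("contacts_rep*.tsv"))
    if not contact_paths:
        raise ConfigurationError("no Hi-C contact files found")
    replicates = [sio.read_contacts_tsv(p) for p in contact_paths]
    strong = call_strong_interactions(replicates, tail=config.tail)
    strong.intra.to_csv(run_dir / "strong_intra.tsv", sep="\t", index=False)
    strong.inter.to_csv(run_dir / "strong_inter.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": c, "threshold": t,
          "n_pairs_kept": int((strong.intra["chrom"] == c).sum())}
         for c, t in sorted(strong.thresholds.items())]
    ).to_csv(run_dir / "hic_thresholds.tsv", sep="\t", index=False)
    log.info("hic-call: %d intra, %d inter pairs", len(strong.intra), len(strong.inter))
    return strong


def _load_strong(run_dir: Path, config: PipelineConfig):
    from .hic import StrongInteractionSet

    intra = pd.read_csv(run_dir / "strong_intra.tsv", sep="\t")
    inter = pd.read_csv(run_dir / "strong_inter.tsv", sep="\t")
    thr = pd.read_csv(run_dir / "hic_thresholds.tsv", sep="\t")
    return StrongInteractionSet(
        intra=intra, inter=inter,
        thresholds=dict(zip(thr["chrom"], thr["threshold"])),
        tail=config.tail, n_replicates=4,
    )


def stage_hic_map(config: PipelineConfig, run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    chroms, genes, loci, _ = _load_genome_tables(config, run_dir)
    strong = _load_strong(run_dir, config)
    selection = pd.read_csv(run_dir / "selection.tsv", sep="\t")
    top_loci = list(selection.loc[selection["data_type"] == "methylation", "feature_id"])
    gene_bins = bin_features(genes, chroms, config.bin_size)
    locus_bins = bin_features(loci, chroms, config.bin_size)
    immune = set(genes.loc[genes["immune"].astype(bool), "name"])
    targets = map_methylation_targets(top_loci, locus_bins, strong, gene_bins, immune)
    sio.write_targets_tsv(targets, run_dir / "methylation_targets.tsv")
    log.info("hic-map: %d locus-gene links", len(targets))


def stage_sig(config: PipelineConfig, run_dir: str | Path) -> list[SIG]:
    run_dir = Path(run_dir)
    _, genes, _, _ = _load_genome_tables(config, run_dir)
    immune = set(genes.loc[genes["immune"].astype(bool), "name"])
    rankings = _load_rankings(run_dir)
    with open(run_dir / "selection_report.json") as fh:
        chosen = json.load(fh)["chosen_top_m"]
    meth_path = run_dir / "methylation_targets.tsv"
    meth_targets = (sio.read_targets_tsv(meth_path) if meth_path.exists()
                    else pd.DataFrame(columns=["locus_id", "gene", "provenance"]))
    mirna_targets = sio.read_targets_tsv(
        _input_path(config, run_dir, "mirna_targets", "mirna_targets.tsv"))
    sigs = []
    for cluster, ranking in sorted(rankings.items()):
        top = ranking.head(chosen)[["feature_id", "data_type"]]
        sigs.append(assemble_sig(cluster, top, immune, meth_targets, mirna_targets))
    pd.concat([s.to_frame() for s in sigs], ignore_index=True).to_csv(
        run_dir / "sigs.tsv", sep="\t", index=False)
    log.info("sig: sizes %s", [len(s) for s in sigs])
    return sigs


def _load_sigs(run_dir: Path) -> list[SIG]:
    df = pd.read_csv(run_dir / "sigs.tsv", sep="\t")
    sigs = []
    for cluster, sub in df.groupby("cluster"):
        genes = {r.gene: r.provenance.split(";") for r in sub.itertuples(index=False)}
        sources = {r.gene: str(r.sources).split(";") for r in sub.itertuples(index=False)}
        sigs.append(SIG(cluster=int(cluster), genes=genes, sources=sources))
    return sigs


def stage_evidence(config: PipelineConfig, run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    chroms, genes, _, blocks = _load_genome_tables(config, run_dir)
    sigs = _load_sigs(run_dir)
    gene_sets = sio.read_gmt(_input_path(config, run_dir, "gene_sets", "gene_sets.gmt"))
    pd.concat([geneset_overlap(s, gene_sets) for s in sigs], ignore_index=True).to_csv(
        run_dir / "geneset_overlap.tsv", sep="\t", index=False)

    mutations = sio.read_mutations_tsv(
        _input_path(config, run_dir, "mutations", "mutations.tsv"))
    immune = set(genes.loc[genes["immune"].astype(bool), "name"])
    gene_bins = bin_features(genes, chroms, config.bin_size)
    block_bins = bin_features(blocks, chroms, config.bin_size)
    ld_bins = set().union(*block_bins.feature_bins.values()) if len(blocks) else set()
    have_hic = (run_dir / "strong_intra.tsv").exists()
    rows, enrich_rows = [], []
    if have_hic:
        strong = _load_strong(run_dir, config)
        for sig in sigs:
            ann = annotate_mutations(sig, mutations, ld_bins, strong, gene_bins)
            rows.append(ann.summary().rename(f"cluster_{sig.cluster}"))
        # enrichment of immune vs non-immune genes in interacting regions
        interacting = set()
        for b in ld_bins:
            interacting.update(strong.partner_bins(b))
        immune_in = sum(1 for g, bs in gene_bins.feature_bins.items()
                        if g in immune and bs & interacting)
        immune_out = len(immune) - immune_in
        non_immune = set(genes["name"]) - immune
        non_in = sum(1 for g, bs in gene_bins.feature_bins.items()
                     if g in non_immune and bs & interacting)
        non_out = len(non_immune) - non_in
        table = enrichment_table(immune_in, immune_out, non_in, non_out)
        odds, p = association_test(table, method="exact")
        enrich_rows.append({"comparison": "immune_vs_nonimmune_interacting",
                            "a": immune_in, "b": immune_out, "c": non_in,
                            "d": non_out, "odds_ratio": odds, "p": p})
    if rows:
        pd.DataFrame(rows).to_csv(run_dir / "mutation_summary.tsv", sep="\t")
    if enrich_rows:
        pd.DataFrame(enrich_rows).to_csv(run_dir / "enrichment.tsv", sep="\t",
                                         index=False)

    graph = sio.read_ppi_tsv(_input_path(config, run_dir, "ppi", "ppi.tsv"))
    hub_rows = []
    for sig in sigs:
        try:
            report = ppi_hubs(graph, sig, config.hub_fractions)
        except ConfigurationError:
            continue
        for f, hubs in report.hubs.items():
            for g in hubs:
                hub_rows.append({"cluster": sig.cluster, "gene": g,
                                 "degree": int(report.degrees[g]),
                                 "tier": f"top{int(f*100)}pct"})
    pd.DataFrame(hub_rows, columns=["cluster", "gene", "degree", "tier"]).to_csv(
        run_dir / "hubs.tsv", sep="\t", index=False)
    log.info("evidence: %d hub rows", len(hub_rows))


def stage_survival(config: PipelineConfig, run_dir: str | Path) -> dict:
    run_dir = Path(run_dir)
    clinical = sio.read_clinical_tsv(
        _input_path(config, run_dir, "clinical", "clinical.tsv"))
    assignment = _load_assignment(run_dir)
    # patients may have been filtered during preprocessing
    clinical.data = clinical.data[clinical.data["patient_id"].isin(
        assignment.patient_ids)].reset_index(drop=True)
    report = survival_report(clinical, assignment)
    report["per_cluster"].to_csv(run_dir / "survival_per_cluster.tsv", sep="\t",
                                 index=False)
    with open(run_dir / "survival_report.json", "w") as fh:
        json.dump({k: v for k, v in report.items() if k != "per_cluster"}, fh, indent=1)
    log.info("survival: logrank p=%.3g", report["logrank_p"])
    return report


def write_manifest(config: PipelineConfig, run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    checksums = {}
    inputs = run_dir / "inputs"
    if inputs.is_dir():
        for p in sorted(inputs.iterdir()):
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "package": "snfsig",
        "version": _pkg_version("snfsig"),
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "input_checksums": checksums,
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> None:
    """Run every stage in order; abort names the failing stage."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages: list[tuple[str, callable]] = []
    if not config.inputs:
        stages.append(("simulate", stage_simulate))
    stages += [("preprocess", stage_preprocess), ("fuse", stage_fuse),
               ("cluster", stage_cluster), ("rank", stage_rank),
               ("select", stage_select)]
    if config.with_hic:
        stages += [("hic-call", stage_hic_call), ("hic-map", stage_hic_map)]
    stages += [("sig", stage_sig), ("evidence", stage_evidence),
               ("survival", stage_survival)]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            fn(config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    write_manifest(config, run_dir)
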