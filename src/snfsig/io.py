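"""Readers and writers for the pipeline's plain-text formats.

Formats: omics TSV (rows=features, cols=patients, first column = feature
id), clinical TSV, BED (0-based half-open), Hi-C contact triplet TSV (one
file per replicate), PPI edge TSV, miRNA target TSV, mutation TSV, GMT
gene sets, and patient-similarity-network TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .datatypes import ClinicalTable, OmicsMatrix, PatientSimilarityNetwork


def write_omics_tsv(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def read_omics_tsv(path: str | Path, data_type: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id", na_values=["NA"])
    df.index.name = None
    return OmicsMatrix(data=df, data_type=data_type)


def write_clinical_tsv(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index=False)


def read_clinical_tsv(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t", dtype={"patient_id": str}))


def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: list[str] | None = None) -> None:
    """Write BED-like intervals (chrom, start, end, name [, extras])."""
    cols = ["chrom", "start", "end", "name"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name"] + (extra_cols or [])
    return pd.read_csv(path, sep="\t", header=None, names=names)


CONTACT_COLUMNS = ["chrom_a", "bin_a", "chrom_b", "bin_b", "count"]


def write_contacts_tsv(contacts: pd.DataFrame, path: str | Path) -> None:
    contacts[CONTACT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_contacts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[CONTACT_COLUMNS]


def write_ppi_tsv(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted(tuple(sorted(e)) for e in graph.edges())
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_ppi_tsv(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(df[["gene_a", "gene_b"]].itertuples(index=False, name=None))
    return g


def write_targets_tsv(targets: pd.DataFrame, path: str | Path) -> None:
    targets.to_csv(path, sep="\t", index=False)


def read_targets_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mutations_tsv(mutations: pd.DataFrame, path: str | Path) -> None:
    mutations[["patient_id", "gene", "class"]].to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = _gseapy_read_gmt(str(path))
    if not sets:
        raise ValueError(f"empty or unparsable GMT file: {path}")
    return sets


def write_network_tsv(net: PatientSimilarityNetwork, path: str | Path) -> None:
    net.data.to_csv(path, sep="\t", index_label="patient_id")


def read_network_tsv(path: str | Path) -> PatientSimilarityNetwork:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return PatientSimilarityNetwork(df)
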