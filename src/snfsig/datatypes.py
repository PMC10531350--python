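"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas objects; thin dataclasses add the
domain invariants (id uniqueness, symmetry, label ranges) that a bare
DataFrame cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_OMICS_TYPES = ("methylation", "mrna", "mirna")


class ConfigurationError(ValueError):
    """Raised for invalid generator or pipeline configuration."""


@dataclass
class OmicsMatrix:
    """One omics data type as a features x patients matrix.

    Missing entries are encoded as NaN in ``data``; ``mask`` (missingness)
    is derived, not stored.
    """

    data: pd.DataFrame  # rows = features, columns = patients
    data_type: str

    def __post_init__(self) -> None:
        if self.data_type not in VALID_OMICS_TYPES:
            raise ConfigurationError(
                f"data_type must be one of {VALID_OMICS_TYPES}, got {self.data_type!r}"
            )
        if self.data.index.has_duplicates:
            raise ConfigurationError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ConfigurationError("duplicate patient ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask, same shape as ``data``."""
        return self.data.isna()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_patients(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """Per-patient survival and risk metadata.

    Columns: patient_id, os_days (>= 0), os_event (0/1),
    risk in {poor, normal, favorable}.
    """

    data: pd.DataFrame

    REQUIRED = ("patient_id", "os_days", "os_event", "risk")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"clinical table missing columns {missing}")
        if self.data["patient_id"].duplicated().any():
            raise ConfigurationError("duplicate patient ids in clinical table")
        if (self.data["os_days"] < 0).any():
            raise ConfigurationError("negative survival times")
        if not self.data["os_event"].isin([0, 1]).all():
            raise ConfigurationError("os_event must be 0/1")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data["patient_id"])


@dataclass
class PatientSimilarityNetwork:
    """Symmetric nonnegative patient x patient similarity matrix."""

    data: pd.DataFrame  # index == columns == patient ids

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.data.columns):
            raise ConfigurationError("similarity matrix index/columns mismatch")
        w = self.data.to_numpy(dtype=float)
        if not np.isfinite(w).all():
            raise ConfigurationError("non-finite similarity values")
        if (w < 0).any():
            raise ConfigurationError("negative similarity values")
        if not np.allclose(w, w.T, atol=1e-8):
            raise ConfigurationError("similarity matrix not symmetric within 1e-8")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClusterAssignment:
    """Cluster labels in {1..k}, one per patient; every cluster nonempty."""

    patient_ids: list[str]
    labels: np.ndarray  # int labels, 1-based
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.patient_ids) != len(self.labels):
            raise ConfigurationError("labels/patients length mismatch")
        present = set(self.labels.tolist())
        if not present.issubset(set(range(1, self.k + 1))):
            raise ConfigurationError("labels outside 1..k")
        if len(present) != self.k:
            raise ConfigurationError("empty cluster in assignment")

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.patient_ids, name="cluster")

    def members(self, cluster: int) -> list[str]:
        return [p for p, l in zip(self.patient_ids, self.labels) if l == cluster]


@dataclass
class SyntheticGenome:
    """Small artificial genome: chromosome sizes plus gene / methylation-locus
    / LD-block coordinates (BED convention: 0-based, half-open)."""

    chromosomes: dict[str, int]  # name -> length in bp
    genes: pd.DataFrame          # chrom, start, end, name, immune (bool)
    loci: pd.DataFrame           # chrom, start, end, name  (point: end=start+1)
    ld_blocks: pd.DataFrame      # chrom, start, end, name

    def __post_init__(self) -> None:
        for tbl, label in ((self.genes, "gene"), (self.loci, "locus"),
                           (self.ld_blocks, "ld block")):
            for _, row in tbl.iterrows():
                if row["chrom"] not in self.chromosomes:
                    raise ConfigurationError(f"{label} {row['name']} on unknown chromosome")
                if not (0 <= row["start"] < row["end"] <= self.chromosomes[row["chrom"]]):
                    raise ConfigurationError(f"{label} {row['name']} outside chromosome bounds")
        if self.genes["name"].duplicated().any():
            raise ConfigurationError("duplicate gene names")

    @property
    def immune_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["immune"].astype(bool), "name"])


@dataclass
class SIG:
    """Selected immune gene set for one cluster, with per-gene provenance.

    ``genes`` maps gene -> sorted list of provenance tags drawn from
    {expression-feature, methylation-target, mirna-target}; ``sources``
    maps gene -> sorted list of the feature ids that contributed it.
    """

    cluster: int
    genes: dict[str, list[str]]
    sources: dict[str, list[str]] = field(default_factory=dict)

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": self.cluster, "gene": g,
             "provenance": ";".join(tags),
             "sources": ";".join(self.sources.get(g, []))}
            for g, tags in sorted(self.genes.items())
        ]
        return pd.DataFrame(rows, columns=["cluster", "gene", "provenance", "sources"])
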