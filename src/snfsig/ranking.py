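"""Per-cluster feature ranking by the NDE separation statistic, top-m
selection, and the minimal-feature-set preservation search.

The NDE (normalized differential expression) index for feature x and
cluster k of size m_k in a cohort of n patients is the pooled-variance
two-sample statistic

    NDE = (mu_k - mu_rest) /
          sqrt( ((m_k - 1) Var_k + (n - m_k - 1) Var_rest) / (n - 2)
                * (1/m_k + 1/(n - m_k)) ),

with sample (ddof=1) group variances. Features are ranked per cluster by
|NDE| (direction-agnostic separation), ties broken by (data type,
feature id) for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import ClusterAssignment, ConfigurationError, OmicsMatrix

RANKING_COLUMNS = ["rank", "feature_id", "data_type", "nde"]


@dataclass
class SelectionParams:
    """Top-m per cluster and the accuracy threshold for preservation."""

    top_m: int = 125
    accuracy_threshold: float = 0.95
    grid: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 200)

    def __post_init__(self) -> None:
        if self.top_m < 1:
            raise ConfigurationError("top_m must be >= 1")
        if not (0 < self.accuracy_threshold <= 1):
            raise ConfigurationError("accuracy_threshold must be in (0,1]")


def nde_index(values: np.ndarray, in_cluster: np.ndarray) -> float:
    """NDE statistic for one feature; 0 (with a warning) when the pooled
    variance vanishes (a constant feature cannot separate)."""
    values = np.asarray(values, dtype=float)
    in_cluster = np.asarray(in_cluster, dtype=bool)
    n = values.size
    m_k = int(in_cluster.sum())
    if m_k < 2 or n - m_k < 2:
        raise ConfigurationError("both groups need >= 2 members")
    x1, x2 = values[in_cluster], values[~in_cluster]
    var1, var2 = x1.var(ddof=1), x2.var(ddof=1)
    pooled = ((m_k - 1) * var1 + (n - m_k - 1) * var2) / (n - 2)
    denom_sq = pooled * (1.0 / m_k + 1.0 / (n - m_k))
    if denom_sq <= 0:
        warnings.warn("zero pooled variance; NDE set to 0")
        return 0.0
    return float((x1.mean() - x2.mean()) / np.sqrt(denom_sq))


def _nde_matrix(values: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Vectorized NDE over all rows of a features x patients matrix."""
    n = values.shape[1]
    m_k = int(in_cluster.sum())
    x1, x2 = values[:, in_cluster], values[:, ~in_cluster]
    var1, var2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    pooled = ((m_k - 1) * var1 + (n - m_k - 1) * var2) / (n - 2)
    denom_sq = pooled * (1.0 / m_k + 1.0 / (n - m_k))
    out = np.zeros(values.shape[0])
    ok = denom_sq > 0
    out[ok] = (x1.mean(axis=1) - x2.mean(axis=1))[ok] / np.sqrt(denom_sq[ok])
    return out


def rank_features(matrices: list[OmicsMatrix], labels: ClusterAssignment,
                  cluster_id: int) -> pd.DataFrame:
    """Rank every feature of every data type by |NDE| for one cluster.

    Returns a DataFrame (rank, feature_id, data_type, nde) sorted by
    descending |NDE|, ties by (data type, feature id).
    """
    patients = labels.patient_ids
    in_cluster = np.asarray(labels.labels == cluster_id)
    m_k = int(in_cluster.sum())
    if m_k < 2 or len(patients) - m_k < 2:
        raise ConfigurationError(f"cluster {cluster_id} too small to rank against")
    frames = []
    for m in matrices:
        if list(m.data.columns) != patients:
            aligned = m.data[patients]
        else:
            aligned = m.data
        scores = np.abs(_nde_matrix(aligned.to_numpy(dtype=float), in_cluster))
        frames.append(pd.DataFrame({
            "feature_id": aligned.index,
            "data_type": m.data_type,
            "nde": scores,
        }))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["nde", "data_type", "feature_id"],
                        ascending=[False, True, True], kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def rank_all_clusters(matrices: list[OmicsMatrix],
                      labels: ClusterAssignment) -> dict[int, pd.DataFrame]:
    return {c: rank_features(matrices, labels, c) for c in range(1, labels.k + 1)}


def select_top(rankings: dict[int, pd.DataFrame], top_m: int) -> pd.DataFrame:
    """Union of each cluster's top-m features with per-cluster membership
    and per-type composition.

    Returns a DataFrame (feature_id, data_type, clusters) where
    ``clusters`` is a sorted semicolon-joined list of the clusters in
    whose top-m the feature appears.
    """
    membership: dict[tuple[str, str], set[int]] = {}
    for cluster in sorted(rankings):
        head = rankings[cluster].head(top_m)
        for fid, dtype in zip(head["feature_id"], head["data_type"]):
            membership.setdefault((fid, dtype), set()).add(cluster)
    rows = [
        {"feature_id": fid, "data_type": dtype,
         "clusters": ";".join(str(c) for c in sorted(cs))}
        for (fid, dtype), cs in sorted(membership.items())
    ]
    return pd.DataFrame(rows, columns=["feature_id", "data_type", "clusters"])


def composition(selection: pd.DataFrame) -> pd.Series:
    """Per-data-type counts of a selection; sums to the union size."""
    return selection["data_type"].value_counts().sort_index()


def restrict_matrices(matrices: list[OmicsMatrix],
                      selection: pd.DataFrame) -> list[OmicsMatrix]:
    """Restrict each matrix to its selected features (types with no
    selected features are dropped)."""
    out = []
    for m in matrices:
        keep = selection.loc[selection["data_type"] == m.data_type, "feature_id"]
        sub = m.data.loc[m.data.index.intersection(keep, sort=False)]
        if len(sub) > 0:
            out.append(OmicsMatrix(data=sub, data_type=m.data_type))
    return out


def preservation_search(
    matrices: list[OmicsMatrix],
    labels: ClusterAssignment,
    params: SelectionParams,
    recluster: Callable[[list[OmicsMatrix]], ClusterAssignment],
    accuracy_fn: Callable[[ClusterAssignment, ClusterAssignment], float] | None = None,
) -> tuple[int | None, pd.DataFrame]:
    """Find the smallest top-m whose re-clustering preserves the original
    partition at the accuracy threshold.

    ``recluster`` re-runs fusion + NCut (same k, same seed) on restricted
    matrices. Returns (minimal top_m or None if no grid point reaches the
    threshold, accuracy curve over the whole grid).
    """
    from .cluster import partition_accuracy

    if accuracy_fn is None:
        def accuracy_fn(a, b):
            return partition_accuracy(a, b).accuracy

    rankings = rank_all_clusters(matrices, labels)
    rows = []
    for top_m in sorted(params.grid):
        selection = select_top(rankings, top_m)
        restricted = restrict_matrices(matrices, selection)
        relabels = recluster(restricted)
        acc = accuracy_fn(labels, relabels)
        rows.append({"top_m": top_m, "n_features": len(selection), "accuracy": acc})
    curve = pd.DataFrame(rows)
    passing = curve[curve["accuracy"] >= params.accuracy_threshold]
    if passing.empty:
        warnings.warn(
            "no grid point reaches the accuracy threshold; best achieved "
            f"{curve['accuracy'].max():.3f}"
        )
        return None, curve
    return int(passing["top_m"].iloc[0]), curve
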