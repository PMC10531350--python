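"""Normalized-cut spectral clustering and cluster-count estimation.

The NCut partition is realized as Ng-Jordan-Weiss spectral clustering:
k-means on the row-normalized leading k eigenvectors of the symmetric
normalized Laplacian L = I - D^{-1/2} W D^{-1/2}. The number of clusters
is estimated by the eigengap of the Laplacian spectrum and by a
rotation-alignment cost (Zelnik-Manor / Perona style, via the Yu-Shi
discretization of the spectral embedding); both rankings are surfaced
and neither is silently preferred.
"""

from __future__ import annotations

import warnings
from itertools import permutations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.linalg import eigh, svd
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .datatypes import ClusterAssignment, ConfigurationError, PatientSimilarityNetwork


def _laplacian_eig(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    deg = w.sum(axis=1)
    if (deg <= 0).any():
        raise ConfigurationError("zero-degree patient in similarity network")
    inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(w.shape[0]) - inv_sqrt[:, None] * w * inv_sqrt[None, :]
    lap = (lap + lap.T) / 2.0
    vals, vecs = eigh(lap)
    return vals, vecs


def _spectral_embedding(w: np.ndarray, k: int) -> np.ndarray:
    _, vecs = _laplacian_eig(w)
    u = vecs[:, :k]
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return u / norms


def ncut_cluster(w: PatientSimilarityNetwork, k: int, seed: int = 0) -> ClusterAssignment:
    """Spectral (NCut) clustering into k clusters; deterministic for a
    fixed seed (20 k-means restarts). Labels are renumbered 1..k by first
    patient appearance."""
    n = len(w.patient_ids)
    if not (2 <= k <= n):
        raise ConfigurationError("need 2 <= k <= n")
    mat = w.values()
    off = mat.copy()
    np.fill_diagonal(off, 0.0)
    n_comp, _ = connected_components((off > 0).astype(int), directed=False)
    if n_comp > k:
        warnings.warn(f"similarity network has {n_comp} components > k={k}")
    emb = _spectral_embedding(mat, k)
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    raw = km.fit_predict(emb)
    # canonical relabeling: clusters numbered by first appearance
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = np.array([relabel[lab] for lab in raw])
    return ClusterAssignment(patient_ids=w.patient_ids, labels=labels, k=k)


def estimate_k_eigengap(w: PatientSimilarityNetwork, k_min: int = 2,
                        k_max: int = 8) -> pd.DataFrame:
    """Candidate cluster counts ranked by descending eigengap
    lambda_{k+1} - lambda_k of the normalized Laplacian spectrum."""
    n = len(w.patient_ids)
    if k_min < 2:
        raise ConfigurationError("k_min must be >= 2")
    if k_max >= n:
        raise ConfigurationError("k_max must be < n_patients")
    vals, _ = _laplacian_eig(w.values())
    rows = [{"k": k, "eigengap": float(vals[k] - vals[k - 1])}
            for k in range(k_min, k_max + 1)]
    df = pd.DataFrame(rows).sort_values("eigengap", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def _discretize_cost(u: np.ndarray, max_iter: int = 30) -> float:
    """Yu-Shi discretization of a spectral embedding; returns the
    rotation-alignment cost n - sum(singular values) >= 0 (0 when the
    embedding is exactly rotatable to cluster indicators)."""
    n, k = u.shape
    # deterministic greedy init: start from row 0, then most orthogonal rows
    r = np.zeros((k, k))
    r[:, 0] = u[0]
    c = np.zeros(n)
    for j in range(1, k):
        c += np.abs(u @ r[:, j - 1])
        r[:, j] = u[int(np.argmin(c))]
    last = None
    cost = float(n)
    for _ in range(max_iter):
        x = u @ r
        discrete = np.zeros_like(x)
        discrete[np.arange(n), np.argmax(x, axis=1)] = 1.0
        uu, s, vh = svd(discrete.T @ u)
        cost = float(n - s.sum())
        if last is not None and abs(cost - last) < 1e-10:
            break
        last = cost
        r = (uu @ vh).T
    return max(cost, 0.0)


def estimate_k_rotationcost(w: PatientSimilarityNetwork, k_min: int = 2,
                            k_max: int = 8) -> pd.DataFrame:
    """Candidate cluster counts ranked by ascending rotation cost of the
    row-normalized spectral embedding."""
    n = len(w.patient_ids)
    if k_min < 2:
        raise ConfigurationError("k_min must be >= 2")
    if k_max >= n:
        raise ConfigurationError("k_max must be < n_patients")
    mat = w.values()
    rows = [{"k": k, "rotation_cost": _discretize_cost(_spectral_embedding(mat, k))}
            for k in range(k_min, k_max + 1)]
    df = pd.DataFrame(rows).sort_values("rotation_cost", ascending=True, kind="stable")
    return df.reset_index(drop=True)


class PartitionAgreement(NamedTuple):
    accuracy: float
    ari: float


def partition_accuracy(a: ClusterAssignment, b: ClusterAssignment) -> PartitionAgreement:
    """Maximum co-assignment fraction over one-to-one cluster matchings
    (optimal assignment on the contingency table), plus the ARI."""
    if a.patient_ids != b.patient_ids:
        raise ConfigurationError("partitions cover different patients")
    n = len(a.patient_ids)
    table = pd.crosstab(a.labels, b.labels).to_numpy()
    rows, cols = linear_sum_assignment(-table)
    acc = float(table[rows, cols].sum()) / n
    ari = float(adjusted_rand_score(a.labels, b.labels))
    return PartitionAgreement(accuracy=acc, ari=ari)


def partition_accuracy_bruteforce(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Exhaustive label-permutation oracle (k <= 8 practical)."""
    if a.patient_ids != b.patient_ids:
        raise ConfigurationError("partitions cover different patients")
    n = len(a.patient_ids)
    k = max(a.k, b.k)
    best = 0
    for perm in permutations(range(1, k + 1)):
        mapped = np.array([perm[l - 1] for l in b.labels])
        best = max(best, int((a.labels == mapped).sum()))
    return best / n
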