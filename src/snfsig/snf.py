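"""Similarity network fusion: scaled exponential kernels, full/local
transition matrices, and cross-diffusion fusion.

The construction follows the message-passing fusion scheme of Wang et
al. (2014, Nature Methods): a scaled exponential similarity kernel on
Euclidean patient distances,

    W(i,j) = exp( -d(i,j)^2 / (alpha * eps(i,j)) ),
    eps(i,j) = ( mean d(i, KNN(i)) + mean d(j, KNN(j)) + d(i,j) ) / 3,

a row-stochastic full kernel P with half the mass on the diagonal, a
sparse local kernel S restricted to each patient's K nearest neighbors,
and T rounds of the cross-diffusion update

    P(v) <- S(v) . mean_{u != v} P(u) . S(v)^T,

with symmetrization and row renormalization after each round. The fused
network is the entrywise mean of the final matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .datatypes import ConfigurationError, OmicsMatrix, PatientSimilarityNetwork

EPS_FLOOR = 1e-20


@dataclass
class SNFParams:
    """Kernel scaling alpha, neighborhood size K, fusion iterations T."""

    alpha: float = 0.5
    K: int = 20
    T: int = 20

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if self.T < 0:
            raise ConfigurationError("T must be >= 0")


def pairwise_distance(matrix: OmicsMatrix) -> pd.DataFrame:
    """Euclidean distances between patients (columns)."""
    values = matrix.values()
    if np.isnan(values).any():
        raise ConfigurationError("distance requires a complete matrix")
    d = squareform(pdist(values.T, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.data.columns, columns=matrix.data.columns)


def _knn_mean_distance(d: np.ndarray, k: int) -> np.ndarray:
    """Mean distance from each patient to its K nearest other patients
    (ties broken by patient index)."""
    n = d.shape[0]
    k = min(k, n - 1)
    means = np.empty(n)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        order = others[np.argsort(d[i, others], kind="stable")]
        means[i] = d[i, order[:k]].mean()
    return means


def affinity(dist: pd.DataFrame, params: SNFParams) -> PatientSimilarityNetwork:
    """Scaled exponential similarity kernel on a distance matrix."""
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-8):
        raise ConfigurationError("distance matrix not symmetric")
    mu = _knn_mean_distance(d, params.K)
    eps = (mu[:, None] + mu[None, :] + d) / 3.0
    degenerate = eps <= 0
    if degenerate.any():
        warnings.warn("degenerate (zero) kernel scale; flooring")
        eps = np.maximum(eps, EPS_FLOOR)
    w = np.exp(-(d**2) / (params.alpha * eps))
    w = (w + w.T) / 2.0
    return PatientSimilarityNetwork(
        pd.DataFrame(w, index=dist.index, columns=dist.columns)
    )


def _full_kernel_array(w: np.ndarray) -> np.ndarray:
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    if (rowsum == 0).any():
        raise ConfigurationError("isolated patient (all-zero off-diagonal row)")
    p = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def full_kernel(w: PatientSimilarityNetwork) -> pd.DataFrame:
    """Row-stochastic full kernel: P(i,i)=1/2, off-diagonal mass 1/2."""
    p = _full_kernel_array(w.values())
    return pd.DataFrame(p, index=w.data.index, columns=w.data.columns)


def _local_kernel_array(w: np.ndarray, k: int) -> np.ndarray:
    n = w.shape[0]
    k = min(k, n - 1)
    s = np.zeros_like(w)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        # largest affinities first; ties broken by patient index
        order = others[np.argsort(-w[i, others], kind="stable")]
        neigh = order[:k]
        total = w[i, neigh].sum()
        if total <= 0:
            raise ConfigurationError("isolated patient in local kernel")
        s[i, neigh] = w[i, neigh] / total
    return s


def local_kernel(w: PatientSimilarityNetwork, k: int) -> pd.DataFrame:
    """Sparse local kernel over each patient's K nearest neighbors
    (self excluded); rows sum to 1 over the neighborhood."""
    s = _local_kernel_array(w.values(), k)
    return pd.DataFrame(s, index=w.data.index, columns=w.data.columns)


def fuse(networks: list[PatientSimilarityNetwork], params: SNFParams) -> PatientSimilarityNetwork:
    """Cross-diffusion fusion of per-data-type similarity networks."""
    if not networks:
        raise ConfigurationError("need at least one network")
    ids = networks[0].patient_ids
    for net in networks[1:]:
        if net.patient_ids != ids:
            raise ConfigurationError("patient order mismatch between networks")

    ws = [net.values() for net in networks]
    ps = [_full_kernel_array(w) for w in ws]
    ss = [_local_kernel_array(w, params.K) for w in ws]
    m = len(ps)

    if m == 1:
        p = ps[0]
        for _ in range(params.T):
            p = ss[0] @ p @ ss[0].T
            p = _renormalize(p)
        fused = (p + p.T) / 2.0
    else:
        for _ in range(params.T):
            new_ps = []
            for v in range(m):
                others = np.mean([ps[u] for u in range(m) if u != v], axis=0)
                p = ss[v] @ others @ ss[v].T
                new_ps.append(_renormalize(p))
            ps = new_ps
        fused = np.mean(ps, axis=0)
        fused = (fused + fused.T) / 2.0
    fused = np.maximum(fused, 0.0)
    return PatientSimilarityNetwork(pd.DataFrame(fused, index=ids, columns=ids))


def _renormalize(p: np.ndarray) -> np.ndarray:
    """Symmetrize then restore the half-diagonal row-stochastic form."""
    p = (p + p.T) / 2.0
    return _full_kernel_array(np.maximum(p, 0.0))


def network_from_omics(matrix: OmicsMatrix, params: SNFParams) -> PatientSimilarityNetwork:
    """Convenience: distance -> affinity for one normalized data type."""
    return affinity(pairwise_distance(matrix), params)


def fuse_omics(matrices: list[OmicsMatrix], params: SNFParams) -> PatientSimilarityNetwork:
    """Convenience: per-type affinities, then fusion."""
    return fuse([network_from_omics(m, params) for m in matrices], params)
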