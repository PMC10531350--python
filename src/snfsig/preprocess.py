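"""Missingness filtering, KNN imputation and log2 + Z normalization.

The filter order is patients first (a patient is dropped from ALL data
types if it exceeds the missingness threshold in ANY single data type),
then features within each data type across the remaining patients.
Imputation runs per data type: each missing entry is replaced by the
inverse-distance-weighted mean over the K nearest patients (Euclidean on
co-observed features, scaled to the per-feature RMS so patients with
different co-observation counts are comparable) that have the feature
observed. Normalization is x -> log2(x + pseudocount) followed by a
per-feature Z-transform with population SD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, OmicsMatrix

EPS_WEIGHT = 1e-12


class EmptyCohortError(ValueError):
    """All patients were removed by the missingness filter."""


def filter_missing(
    matrices: list[OmicsMatrix],
    patient_threshold: float = 0.2,
    feature_threshold: float = 0.2,
) -> list[OmicsMatrix]:
    """Drop patients with > patient_threshold missing in any single data
    type (from all matrices), then features with > feature_threshold
    missing across the remaining patients."""
    for thr in (patient_threshold, feature_threshold):
        if not (0 < thr <= 1):
            raise ConfigurationError("thresholds must be in (0,1]")
    patients = list(matrices[0].data.columns)
    for m in matrices[1:]:
        if list(m.data.columns) != patients:
            raise ConfigurationError("matrices do not share a patient universe")

    keep = pd.Series(True, index=patients)
    for m in matrices:
        frac = m.mask.mean(axis=0)  # per patient, within this data type
        keep &= frac <= patient_threshold
    if not keep.any():
        raise EmptyCohortError("missingness filter removed every patient")
    kept_patients = [p for p in patients if keep[p]]

    out = []
    for m in matrices:
        sub = m.data[kept_patients]
        feat_frac = sub.isna().mean(axis=1)
        sub = sub.loc[feat_frac <= feature_threshold]
        out.append(OmicsMatrix(data=sub, data_type=m.data_type))
    return out


def _patient_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise patient distances on co-observed features.

    values: features x patients, NaN = missing. Distance is the root mean
    squared difference over co-observed features (so counts of
    co-observed features do not bias the comparison); infinite when two
    patients share no observed feature.
    """
    obs = ~np.isnan(values)
    filled = np.where(obs, values, 0.0)
    # sum of squared diffs restricted to co-observed features
    prod = filled.T @ filled
    sq = (filled**2).T
    co_sq_a = sq @ obs          # sum_i x_ai^2 over co-observed
    co_count = obs.T.astype(float) @ obs.astype(float)
    ss = co_sq_a + co_sq_a.T - 2 * prod
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(ss, 0.0) / co_count)
    d[co_count == 0] = np.inf
    np.fill_diagonal(d, 0.0)
    return d


def impute_knn(matrix: OmicsMatrix, k: int = 20) -> OmicsMatrix:
    """Weighted KNN imputation; observed entries are never altered.

    Weights are 1/(d + 1e-12) over the K nearest patients (by the
    co-observed-feature distance) that have the target feature observed.
    Ties in distance are broken by patient column order.
    """
    if k < 1:
        raise ConfigurationError("K must be >= 1")
    values = matrix.values()
    obs = ~np.isnan(values)
    if not (obs.sum(axis=1) >= 1).all():
        bad = matrix.data.index[obs.sum(axis=1) == 0][0]
        raise ConfigurationError(f"feature {bad} has no observed value")
    if obs.all():
        return matrix

    d = _patient_distances(values)
    n = values.shape[1]
    isolated = np.isinf(d).sum(axis=0) >= n - 1
    if isolated.any():
        who = matrix.data.columns[np.flatnonzero(isolated)[0]]
        raise ConfigurationError(
            f"patient {who} shares no observed features with any other patient"
        )

    out = values.copy()
    order = np.argsort(d, axis=1, kind="stable")  # ties -> patient column order
    for f in range(values.shape[0]):
        missing_cols = np.flatnonzero(~obs[f])
        if missing_cols.size == 0:
            continue
        donors_ok = obs[f]
        for j in missing_cols:
            cand = [c for c in order[j] if c != j and donors_ok[c] and np.isfinite(d[j, c])]
            neigh = cand[:k]
            if not neigh:
                raise ConfigurationError(
                    f"no donor patients for feature {matrix.data.index[f]}"
                )
            w = 1.0 / (d[j, neigh] + EPS_WEIGHT)
            out[f, j] = float(np.sum(w * values[f, neigh]) / np.sum(w))
    return OmicsMatrix(
        data=pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        data_type=matrix.data_type,
    )


def normalize(matrix: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """log2(x + pseudocount) then per-feature Z-score (population SD).

    Constant features map to all-zero rows. Expression types must be
    nonnegative. Applied uniformly to every data type, methylation
    included.
    """
    values = matrix.values()
    if np.isnan(values).any():
        raise ConfigurationError("normalize requires an imputed (complete) matrix")
    if matrix.data_type in ("mrna", "mirna") and (values < 0).any():
        raise ConfigurationError(f"negative values in {matrix.data_type} matrix")
    logv = np.log2(values + pseudocount)
    mean = logv.mean(axis=1, keepdims=True)
    sd = logv.std(axis=1, keepdims=True)  # population SD
    constant = sd.ravel() == 0
    sd[sd == 0] = 1.0
    z = (logv - mean) / sd
    z[constant, :] = 0.0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) set to zero")
    return OmicsMatrix(
        data=pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns),
        data_type=matrix.data_type,
    )


def preprocess_all(
    matrices: list[OmicsMatrix],
    patient_threshold: float = 0.2,
    feature_threshold: float = 0.2,
    impute_k: int = 20,
    pseudocount: float = 1.0,
) -> list[OmicsMatrix]:
    """Full preprocessing chain: filter -> impute (per type) -> normalize."""
    filtered = filter_missing(matrices, patient_threshold, feature_threshold)
    return [normalize(impute_knn(m, impute_k), pseudocount) for m in filtered]
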