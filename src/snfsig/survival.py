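"""Kaplan-Meier estimation, k-sample log-rank testing, and rank agreement
between cluster survival and favorable-prognosis composition.

The k-sample log-rank test is the score test of a proportional-hazards
model on cluster indicators (observed-minus-expected events at each
distinct event time), with a chi-square reference on k-1 degrees of
freedom. Cluster survival is summarized by the KM survival probability
at the last common follow-up time (configurable), and compared with the
per-cluster proportion of favorable-risk patients by Spearman rank
correlation with an exact permutation p-value for small k.
"""

from __future__ import annotations

from itertools import permutations
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import spearmanr

from .datatypes import ClinicalTable, ClusterAssignment, ConfigurationError


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival curve: DataFrame (time, survival), right-
    continuous, non-increasing, starting at S(0)=1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ConfigurationError("empty group")
    if (times < 0).any():
        raise ConfigurationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def km_at(curve: pd.DataFrame, t: float) -> float:
    """Right-continuous evaluation of a KM curve at time t."""
    sub = curve[curve["time"] <= t]
    return float(sub["survival"].iloc[-1]) if len(sub) else 1.0


class LogrankResult(NamedTuple):
    statistic: float
    df: int
    p: float


def logrank_test(times: np.ndarray, events: np.ndarray,
                 groups: np.ndarray) -> LogrankResult:
    """k-sample log-rank test; chi-square with k-1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ConfigurationError("log-rank needs >= 2 groups")
    if events.sum() < 1:
        raise ConfigurationError("log-rank needs >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(statistic=float(res.test_statistic),
                         df=len(uniq) - 1, p=float(res.p_value))


def cluster_survival_summary(clinical: ClinicalTable,
                             assignment: ClusterAssignment,
                             reference_time: float | None = None) -> pd.DataFrame:
    """Per-cluster KM survival at the reference time (default: last
    common follow-up across clusters) and favorable-risk proportion."""
    df = clinical.data.set_index("patient_id").loc[assignment.patient_ids]
    df = df.assign(cluster=assignment.labels)
    if reference_time is None:
        reference_time = float(df.groupby("cluster")["os_days"].max().min())
    rows = []
    for cluster, sub in df.groupby("cluster"):
        curve = km_estimate(sub["os_days"].to_numpy(), sub["os_event"].to_numpy())
        rows.append({
            "cluster": int(cluster),
            "n": len(sub),
            "survival_at_ref": km_at(curve, reference_time),
            "favorable_fraction": float((sub["risk"] == "favorable").mean()),
        })
    out = pd.DataFrame(rows)
    out.attrs["reference_time"] = reference_time
    return out


class RankAgreement(NamedTuple):
    rho: float
    p: float


def rank_agreement(survival_scores: np.ndarray,
                   favorable_fractions: np.ndarray) -> RankAgreement:
    """Spearman rank correlation between cluster survival ordering and
    favorable-risk composition; exact two-sided permutation p for k <= 7,
    otherwise the asymptotic p."""
    x = np.asarray(survival_scores, dtype=float)
    y = np.asarray(favorable_fractions, dtype=float)
    k = x.size
    if k < 3:
        raise ConfigurationError("need >= 3 clusters for rank agreement")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ConfigurationError("constant ranks: correlation undefined")
    rho = float(spearmanr(x, y).statistic)
    if k <= 7:
        null = [spearmanr(x, np.asarray(perm)).statistic
                for perm in permutations(y)]
        null = np.array(null, dtype=float)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(spearmanr(x, y).pvalue)
    return RankAgreement(rho=rho, p=p)


def survival_report(clinical: ClinicalTable, assignment: ClusterAssignment,
                    reference_time: float | None = None) -> dict:
    """Log-rank across clusters plus rank agreement, in one record."""
    df = clinical.data.set_index("patient_id").loc[assignment.patient_ids]
    lr = logrank_test(df["os_days"].to_numpy(), df["os_event"].to_numpy(),
                      assignment.labels)
    summary = cluster_survival_summary(clinical, assignment, reference_time)
    try:
        agreement = rank_agreement(summary["survival_at_ref"].to_numpy(),
                                   summary["favorable_fraction"].to_numpy())
        rho, rho_p = agreement.rho, agreement.p
    except ConfigurationError:
        rho, rho_p = float("nan"), float("nan")
    return {
        "logrank_statistic": lr.statistic,
        "logrank_df": lr.df,
        "logrank_p": lr.p,
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "per_cluster": summary,
    }
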