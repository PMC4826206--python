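"""Subtype discovery: spectral clustering of the fused network and
survival-guided selection of the number of subtypes.

The fused similarity matrix W is clustered through its normalized graph
Laplacian L = I - D^{-1/2} W D^{-1/2}: the C eigenvectors with smallest
eigenvalues are row-normalized and partitioned by k-means with many restarts
(the standard relaxation of the trace-minimization objective
min Trace(Q^T L Q) s.t. Q^T Q = I).  The number of subtypes is chosen as the
candidate C whose patient partition gives the smallest log-rank p-value on
overall survival — subtype structure is only interesting here if it
stratifies outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .snf import FusedNetwork

__all__ = [
    "SubtypeAssignment",
    "KMCurve",
    "LogRankResult",
    "spectral_clusters",
    "km_estimate",
    "logrank_test",
    "select_cluster_number",
]


@dataclass
class SubtypeAssignment:
    """Patient -> subtype labels (1..C, largest cluster first) and the scaled
    partition indicator Q = Y (Y^T Y)^{-1/2} with orthonormal columns."""

    labels: pd.Series
    C: int
    indicator: np.ndarray

    def members(self, subtype: int) -> list[str]:
        return list(self.labels.index[self.labels == subtype])


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct death times."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    dof: int


def _fused_matrix(F: FusedNetwork | pd.DataFrame) -> pd.DataFrame:
    return F.matrix if isinstance(F, FusedNetwork) else F


def spectral_clusters(
    F: FusedNetwork | pd.DataFrame, C: int, seed: int = 0
) -> SubtypeAssignment:
    """Normalized-Laplacian spectral clustering of the fused network into C
    groups.  Labels are canonicalized by descending cluster size, ties by the
    lexicographically smallest contained patient id.  A disconnected fused
    graph is handled naturally: each component spans Laplacian null space and
    k-means separates the components."""
    W = _fused_matrix(F)
    n = W.shape[0]
    if not 2 <= C <= n:
        raise ValueError(f"C must satisfy 2 <= C <= n = {n}, got {C}")
    A = np.asarray(W, dtype=float)
    A = (A + A.T) / 2.0
    d = A.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("fused matrix has a zero-degree patient")
    d_isqrt = 1.0 / np.sqrt(d)
    L = np.eye(n) - d_isqrt[:, None] * A * d_isqrt[None, :]
    L = (L + L.T) / 2.0
    vals, vecs = eigh(L, subset_by_index=(0, C - 1))
    U = vecs[:, :C]
    norms = np.linalg.norm(U, axis=1)
    norms[norms == 0] = 1.0
    U = U / norms[:, None]
    km = KMeans(n_clusters=C, n_init=50, random_state=int(seed) % (2**31))
    raw = km.fit_predict(U)

    ids = list(W.index)
    clusters = {}
    for lab in np.unique(raw):
        members = [ids[i] for i in np.where(raw == lab)[0]]
        clusters[lab] = members
    order = sorted(clusters, key=lambda lab: (-len(clusters[lab]), min(clusters[lab])))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[lab] for lab in raw], index=W.index, name="subtype")

    Y = np.zeros((n, C))
    Y[np.arange(n), labels.to_numpy() - 1] = 1.0
    sizes = Y.sum(axis=0)
    sizes[sizes == 0] = 1.0
    Q = Y / np.sqrt(sizes)
    return SubtypeAssignment(labels=labels, C=C, indicator=Q)


def km_estimate(clinical: pd.DataFrame, group: list[str] | None = None) -> KMCurve:
    """Kaplan-Meier estimate for the patients in ``group`` (all if None)."""
    sub = clinical if group is None else clinical.loc[list(group)]
    if sub.shape[0] == 0:
        raise ValueError("group is empty")
    if (sub["os_time"] < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["os_time"], event_observed=sub["os_event"])
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    times = death_rows.index.to_numpy(dtype=float)
    at_risk = death_rows["at_risk"].to_numpy(dtype=float)
    if len(times):
        survival = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]]
        survival = survival.to_numpy(dtype=float)
    else:
        survival = np.array([])
    return KMCurve(times=times, at_risk=at_risk, survival=survival)


def logrank_test(clinical: pd.DataFrame, labels: pd.Series | SubtypeAssignment) -> LogRankResult:
    """Multi-group Mantel-Haenszel log-rank test of equal survival curves."""
    if isinstance(labels, SubtypeAssignment):
        labels = labels.labels
    common = clinical.index.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("no patients shared between clinical table and labels")
    clin = clinical.loc[common]
    grp = labels.loc[common]
    counts = grp.value_counts()
    if len(counts) < 2:
        raise ValueError("log-rank needs >= 2 non-empty groups")
    if (counts == 0).any():
        raise ValueError("log-rank group with zero members")
    res = multivariate_logrank_test(clin["os_time"], grp, clin["os_event"])
    stat = float(max(res.test_statistic, 0.0))
    p = float(np.clip(res.p_value, 5e-324, 1.0))
    return LogRankResult(statistic=stat, p_value=p, dof=len(counts) - 1)


def select_cluster_number(
    F: FusedNetwork | pd.DataFrame,
    clinical: pd.DataFrame,
    c_range: tuple[int, ...] = (2, 3, 4, 5),
    seed: int = 0,
) -> tuple[int, SubtypeAssignment, pd.DataFrame]:
    """Cluster at each candidate C and keep the partition with the smallest
    log-rank p; ties go to the smaller C.  Returns the winner, its assignment
    and the full (C, statistic, p) scan table."""
    if not c_range:
        raise ValueError("cluster range is empty")
    rows = []
    assignments: dict[int, SubtypeAssignment] = {}
    for C in sorted(set(int(c) for c in c_range)):
        assign = spectral_clusters(F, C, seed=seed)
        res = logrank_test(clinical, assign)
        assignments[C] = assign
        rows.append({"C": C, "statistic": res.statistic, "logrank_p": res.p_value})
    table = pd.DataFrame(rows)
    best_idx = int(table["logrank_p"].idxmin())  # first minimum -> smallest C on ties
    best_C = int(table.loc[best_idx, "C"])
    return best_C, assignments[best_C], table
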