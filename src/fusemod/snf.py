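"""Similarity network fusion (SNF) over per-view patient affinity graphs.

Each omics view is turned into a patient-by-patient affinity matrix with a
locally scaled exponential kernel

    W(i, j) = exp(-rho^2(x_i, x_j) / (mu * eps_ij)),

where rho is the Euclidean distance and the scale

    eps_ij = [mean(rho(x_i, N_i)) + mean(rho(x_j, N_j)) + rho(x_i, x_j)] / 3

averages each patient's distance to its k nearest neighbors (self excluded),
making the kernel insensitive to per-view scaling.  Two operators are derived
from W: a full transition matrix P (off-diagonal mass normalized to 1/2, the
diagonal fixed at 1/2) and a sparse local operator S supported on the k
nearest neighbors of each patient.  Fusion then runs the cross-diffusion
update

    P^(v) <- S^(v) (mean of the other views' P) S^(v)^T

for T synchronous rounds, re-symmetrizing and re-normalizing each view after
every round; the fused network is the mean of the final per-view matrices.
Similarity supported in every view is reinforced; view-specific noise decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FusedNetwork",
    "euclidean_distances",
    "scaled_affinity",
    "full_kernel",
    "local_kernel",
    "snf_fuse",
    "fuse_feature_views",
    "default_neighborhood",
]

_EPS = 1e-300


@dataclass
class FusedNetwork:
    """Fused patient similarity matrix plus fusion diagnostics."""

    matrix: pd.DataFrame
    n_views: int
    iterations_run: int
    converged: bool
    max_rel_change: float

    @property
    def patients(self) -> list[str]:
        return list(self.matrix.index)


def euclidean_distances(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between patients (rows of ``X``)."""
    values = np.asarray(X, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("feature matrix contains non-finite values")
    D = squareform(pdist(values, metric="euclidean"))
    return pd.DataFrame(D, index=X.index, columns=X.index)


def default_neighborhood(n: int) -> int:
    """Data-dependent k: ceil(n/10) clipped to [10, 30], capped at n - 1."""
    k = int(np.ceil(n / 10))
    k = min(max(k, 10), 30)
    return max(min(k, n - 1), 1)


def _knn_index(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of each row, self excluded.

    Ties are broken by (distance, position); under the canonical lexicographic
    patient order this is the (distance, patient-id) rule.
    """
    n = D.shape[0]
    out = np.empty((n, k), dtype=int)
    positions = np.arange(n)
    for i in range(n):
        order = np.lexsort((positions, D[i]))
        order = order[order != i]
        out[i] = order[:k]
    return out


def _as_array(M: pd.DataFrame | np.ndarray) -> np.ndarray:
    return np.asarray(M, dtype=float)


def scaled_affinity(D: pd.DataFrame, mu: float, k: int) -> pd.DataFrame:
    """Locally scaled exponential affinity from a distance matrix."""
    Dv = _as_array(D)
    n = Dv.shape[0]
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if not 0 < k <= n - 1:
        raise ValueError(f"k must satisfy 0 < k <= n - 1 = {n - 1}, got {k}")
    nn = _knn_index(Dv, k)
    mean_k = np.take_along_axis(Dv, nn, axis=1).mean(axis=1)
    eps = (mean_k[:, None] + mean_k[None, :] + Dv) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(Dv**2) / (mu * eps))
    W[Dv == 0] = 1.0  # coincident points (incl. diagonal): zero distance, full affinity
    np.fill_diagonal(W, 1.0)
    W = (W + W.T) / 2.0
    return pd.DataFrame(W, index=D.index, columns=D.columns)


def _transition_normalize(W: np.ndarray) -> np.ndarray:
    # sum off-diagonal mass with the diagonal zeroed first: subtracting the
    # diagonal from the row sum would absorb tiny affinities (~1e-20) into
    # the diagonal's floating-point neighborhood and cancel them to zero
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    off_sums = off.sum(axis=1)
    if np.any(off_sums <= 0):
        i = int(np.argmax(off_sums <= 0))
        raise ValueError(f"row {i} has no positive off-diagonal affinity")
    P = W / (2.0 * off_sums[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def full_kernel(W: pd.DataFrame) -> pd.DataFrame:
    """Row-stochastic transition matrix: half the mass on the diagonal, the
    rest spread over the off-diagonal affinities."""
    Wv = _as_array(W)
    if Wv.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    P = _transition_normalize(Wv)
    return pd.DataFrame(P, index=W.index, columns=W.columns)


def local_kernel(D: pd.DataFrame, W: pd.DataFrame, k: int) -> pd.DataFrame:
    """Sparse row-stochastic operator supported on each patient's k nearest
    neighbors (self excluded); all other entries are exactly zero."""
    Dv, Wv = _as_array(D), _as_array(W)
    n = Dv.shape[0]
    if not 0 < k <= n - 1:
        raise ValueError(f"k must satisfy 0 < k <= n - 1 = {n - 1}, got {k}")
    nn = _knn_index(Dv, k)
    S = np.zeros_like(Wv)
    rows = np.repeat(np.arange(n), k)
    cols = nn.ravel()
    vals = Wv[rows, cols]
    S[rows, cols] = vals
    row_sums = S.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    S /= row_sums[:, None]
    return pd.DataFrame(S, index=D.index, columns=D.columns)


def snf_fuse(
    P_list: list[pd.DataFrame],
    S_list: list[pd.DataFrame],
    T: int = 20,
    tol: float = 1e-6,
) -> FusedNetwork:
    """Cross-diffuse the per-view transition matrices for T rounds.

    All views are updated synchronously; after each update every view is
    re-symmetrized and re-normalized (the update alone does not preserve row
    stochasticity).  Returns the mean of the final status matrices.
    """
    m = len(P_list)
    if m < 2:
        raise ValueError("fusion needs >= 2 views")
    if len(S_list) != m:
        raise ValueError("P_list and S_list must be index-aligned")
    index = P_list[0].index
    shapes = {M.shape for M in [*P_list, *S_list]}
    if len(shapes) != 1:
        raise ValueError(f"mismatched matrix dimensions: {sorted(shapes)}")
    if T < 1:
        raise ValueError("T must be a positive integer")

    Ps = [_as_array(P).copy() for P in P_list]
    Ss = [_as_array(S) for S in S_list]
    avg_prev = sum(Ps) / m
    rel_change = np.inf
    for _ in range(T):
        new = []
        for v in range(m):
            others = sum(Ps[u] for u in range(m) if u != v) / (m - 1)
            M = Ss[v] @ others @ Ss[v].T
            M = (M + M.T) / 2.0
            new.append(_transition_normalize(M))
        Ps = new
        avg = sum(Ps) / m
        rel_change = float(
            np.linalg.norm(avg - avg_prev) / max(np.linalg.norm(avg_prev), _EPS)
        )
        avg_prev = avg
    fused = sum(Ps) / m
    fused = (fused + fused.T) / 2.0
    return FusedNetwork(
        matrix=pd.DataFrame(fused, index=index, columns=index),
        n_views=m,
        iterations_run=T,
        converged=rel_change < tol,
        max_rel_change=rel_change,
    )


def fuse_feature_views(
    views: list[pd.DataFrame],
    mu: float = 0.5,
    k: int | None = None,
    iters: int = 20,
) -> FusedNetwork:
    """Convenience pipeline: views -> distances -> kernels -> fused network.

    All views must share the same patient index (use ``align_cohort`` first).
    """
    if len(views) < 2:
        raise ValueError("fusion needs >= 2 views")
    index = views[0].index
    for v in views[1:]:
        if not index.equals(v.index):
            raise ValueError("views must share an identical patient index")
    n = len(index)
    if k is None:
        k = default_neighborhood(n)
    P_list, S_list = [], []
    for X in views:
        D = euclidean_distances(X)
        W = scaled_affinity(D, mu=mu, k=k)
        P_list.append(full_kernel(W))
        S_list.append(local_kernel(D, W, k=k))
    return snf_fuse(P_list, S_list, T=iters)
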