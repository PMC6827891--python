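"""Temporal-pattern analytics: trajectory clustering and response scores.

Treated cells fall into qualitatively different temporal classes: genes
that keep rising or falling after treatment ("monotonic response") and
genes that transiently change and then return toward baseline ("adaptive
response", the hallmark of resistant cells).  This module clusters
z-scored trajectories with k-means (nine clusters by default) and assigns
every gene two scores in [0, 1]:

* S_M, monotonic response — absolute Spearman correlation between time and
  expression (1 for strictly monotone trajectories);
* S_A, adaptive response — (peak deviation - final deviation) / peak
  deviation from baseline (1 when a pulse returns exactly to baseline).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .preprocess import DenseTrajectories, TimeCourseMatrix

__all__ = ["cluster_trajectories", "response_scores", "pattern_scores", "pca_embed"]

_EPS = 1e-12


def _as_matrix(trajs: TimeCourseMatrix | DenseTrajectories | np.ndarray) -> np.ndarray:
    if isinstance(trajs, TimeCourseMatrix):
        return trajs.values
    if isinstance(trajs, DenseTrajectories):
        return trajs.X
    return np.asarray(trajs, dtype=float)


def cluster_trajectories(
    trajs: TimeCourseMatrix | DenseTrajectories | np.ndarray,
    k: int = 9,
    seed: int = 0,
    n_init: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means over per-gene z-scored trajectories.

    Returns (cluster labels, centroid curves).  Clustering is run on the
    measured shape (rows standardized to mean 0, sd 1; constant rows map
    to zero) with k-means++ initialisation and ``n_init`` restarts under a
    fixed seed, so assignments are reproducible.
    """
    X = _as_matrix(trajs)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes ({X.shape[0]})")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    return labels, km.cluster_centers_


def response_scores(
    values: np.ndarray, times: np.ndarray | None = None
) -> tuple[float, float]:
    """(S_M, S_A) of one trajectory.

    With deviations d_k = x(t_k) - x(t_0), peak P = max|d_k| and final
    F = |d_K|: S_A = (P - F) / P and S_M = |Spearman rho(time, x)|, both
    clipped to [0, 1].  A constant trajectory scores (0, 0) by convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 timepoints")
    t = np.arange(x.size) if times is None else np.asarray(times, dtype=float)
    d = x - x[0]
    P = float(np.max(np.abs(d)))
    if P < _EPS or np.all(x == x[0]):
        return 0.0, 0.0
    F = float(abs(d[-1]))
    s_a = (P - F) / max(P, _EPS)
    rho = spearmanr(t, x).statistic
    s_m = 0.0 if np.isnan(rho) else abs(float(rho))
    return float(np.clip(s_m, 0.0, 1.0)), float(np.clip(s_a, 0.0, 1.0))


def pattern_scores(expr: TimeCourseMatrix) -> pd.DataFrame:
    """Per-gene S_M / S_A table for a whole matrix."""
    rows = [response_scores(expr.values[i], expr.times) for i in range(expr.n_genes)]
    return pd.DataFrame(rows, columns=["S_M", "S_A"], index=list(expr.gene_ids))


def pca_embed(*matrices: TimeCourseMatrix | np.ndarray) -> pd.DataFrame:
    """2-D PCA of timepoint samples pooled over one or more conditions.

    Samples are timepoint columns (features = genes), centered before the
    eigendecomposition; component signs are fixed so the largest-magnitude
    loading is positive, making the embedding deterministic.
    """
    cols, labels = [], []
    for m, mat in enumerate(matrices):
        X = _as_matrix(mat)
        times = mat.times if isinstance(mat, TimeCourseMatrix) else np.arange(X.shape[1])
        for j in range(X.shape[1]):
            cols.append(X[:, j])
            labels.append((m, float(times[j])))
    S = np.asarray(cols, dtype=float)  # samples x genes
    if S.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    Sc = S - S.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Sc, full_matrices=False)
    coords = U[:, :2] * sv[:2]
    for c in range(min(2, coords.shape[1])):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            coords[:, c] = -coords[:, c]
    total = float(np.sum(sv**2)) or 1.0
    out = pd.DataFrame(coords[:, :2], columns=["PC1", "PC2"])
    out["condition"] = [c for c, _ in labels]
    out["time"] = [t for _, t in labels]
    out.attrs["explained_variance_ratio"] = (sv[:2] ** 2 / total).tolist()
    return out
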