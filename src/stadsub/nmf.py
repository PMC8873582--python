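"""Nonnegative matrix factorization consensus subtyping.

Samples are clustered by repeated KL-divergence NMF (the multiplicative
Brunet update) from random restarts; the restart-averaged co-clustering
(consensus) matrix is summarized by the cophenetic correlation of its
average-linkage dendrogram and by the mean silhouette width, the standard
diagnostics for choosing the cluster count k.

Signed input (centred copy-number or methylation differences) is made
nonnegative by the row-wise positive/negative split, which preserves all
information: each feature contributes a gain row max(x, 0) and a loss row
max(-x, 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io import OmicsLayer

logger = logging.getLogger(__name__)

_EPS = 1e-12


def to_nonnegative(layer) -> tuple[np.ndarray, list]:
    """Row-wise positive/negative split of a signed matrix.

    Each feature row x becomes two rows, max(x, 0) and max(-x, 0); the
    returned row map lists ``(feature, '+')`` / ``(feature, '-')`` so the
    original matrix can be reconstructed as pos - neg.
    """
    if isinstance(layer, OmicsLayer):
        X = layer.data.to_numpy(dtype=float)
        features = list(layer.feature_ids)
    else:
        X = np.asarray(layer, dtype=float)
        features = list(range(X.shape[0]))
    if not np.isfinite(X).all():
        raise ValueError("to_nonnegative requires a finite matrix (impute first)")
    V = np.empty((2 * X.shape[0], X.shape[1]))
    V[0::2] = np.maximum(X, 0.0)
    V[1::2] = np.maximum(-X, 0.0)
    row_map = []
    for f in features:
        row_map.extend([(f, "+"), (f, "-")])
    return V, row_map


@dataclass
class NMFFactorization:
    W: np.ndarray
    H: np.ndarray
    objective: list  # generalized KL divergence per iteration
    seed: int
    converged: bool


def _kl_divergence(V, WH) -> float:
    # generalized KL: sum(V log(V/WH) - V + WH), with 0 log 0 = 0
    mask = V > 0
    d = float(WH.sum() - V.sum())
    d += float((V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))).sum())
    return d


class _KLTracker:
    """Precomputes the V-dependent part of the KL objective for speed."""

    def __init__(self, V: np.ndarray):
        self.v_sum = float(V.sum())
        flat = V.ravel()
        self.idx = np.flatnonzero(flat > 0)
        self.v_pos = flat[self.idx]
        self.vlogv = float((self.v_pos * np.log(self.v_pos)).sum())

    def __call__(self, WH: np.ndarray) -> float:
        wh = np.maximum(WH.ravel()[self.idx], _EPS)
        return self.vlogv - float((self.v_pos * np.log(wh)).sum()) - self.v_sum + float(WH.sum())


def nmf_brunet(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFFactorization:
    """KL-divergence NMF by multiplicative updates (Brunet variant).

    Random uniform initialization from ``seed``; stops when the relative
    change of the KL objective falls below ``tol`` or after ``max_iter``
    updates.  The objective trace is recorded each iteration and is
    non-increasing up to floating-point tolerance.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    if (V.sum(axis=0) == 0).any():
        raise ValueError("V has an all-zero column")
    p, n = V.shape
    if not 2 <= k < min(p, n):
        raise ValueError(f"k={k} out of range for a {p}x{n} matrix")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(p, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale
    kl = _KLTracker(V)
    trace = []
    converged = False
    for it in range(max_iter):
        WH = W @ H
        H *= W.T @ (V / np.maximum(WH, _EPS)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        W *= (V / np.maximum(WH, _EPS)) @ H.T / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = kl(W @ H)
        trace.append(obj)
        if it > 0 and abs(trace[-2] - obj) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    return NMFFactorization(W=W, H=H, objective=trace, seed=seed, converged=converged)


def hard_labels(H: np.ndarray) -> np.ndarray:
    """Cluster assignment by the maximal H entry per sample (ties -> lowest index)."""
    return np.argmax(H, axis=0) + 1


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray  # n x n, symmetric, unit diagonal
    cophenetic: float
    mean_silhouette: float
    labels: np.ndarray  # 1..k
    sample_ids: list = field(default_factory=list)
    n_runs: int = 0


def consensus_cluster(
    V,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    sample_ids=None,
) -> ConsensusResult:
    """Restart-averaged consensus clustering at one k.

    ``n_runs`` random-restart factorizations each yield hard labels; the
    consensus matrix is the mean co-membership indicator.  Final labels come
    from average-linkage hierarchical clustering of 1 - C cut at k; the
    cophenetic correlation compares 1 - C with the dendrogram's cophenetic
    distances, and the mean silhouette uses 1 - C as dissimilarity.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    C = np.zeros((n, n))
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    for run_seed in child_seeds:
        fit = nmf_brunet(V, k, seed=int(run_seed % (2**31)), max_iter=max_iter, tol=tol)
        lab = hard_labels(fit.H)
        if len(np.unique(lab)) < k:
            logger.info("consensus run produced %d < k clusters (kept)", len(np.unique(lab)))
        C += (lab[:, None] == lab[None, :]).astype(float)
    C /= n_runs
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    condensed = squareform(D, checks=False)
    Z = hierarchy.average(condensed)
    coph_corr, _ = hierarchy.cophenet(Z, condensed)
    if not np.isfinite(coph_corr):  # zero-variance distances (perfect single block)
        coph_corr = 1.0
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if 1 < len(np.unique(labels)) < n:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    else:
        sil = float("nan")
    return ConsensusResult(
        k=k,
        consensus=C,
        cophenetic=float(coph_corr),
        mean_silhouette=sil,
        labels=labels,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
        n_runs=n_runs,
    )


def select_k(
    V,
    k_range=range(2, 11),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    sample_ids=None,
) -> tuple[int, pd.DataFrame, dict]:
    """Scan k, returning the best k and the per-k diagnostics table.

    Best k is the smallest k maximizing the cophenetic correlation; exact
    ties are broken by the larger mean silhouette.
    """
    results = {}
    rows = []
    for k in k_range:
        res = consensus_cluster(
            V, k, n_runs=n_runs, seed=seed + k, max_iter=max_iter, tol=tol, sample_ids=sample_ids
        )
        results[k] = res
        rows.append({"k": k, "cophenetic": res.cophenetic, "mean_silhouette": res.mean_silhouette})
    table = pd.DataFrame(rows)
    best_coph = table["cophenetic"].max()
    tied = table[table["cophenetic"] == best_coph]
    sil = tied["mean_silhouette"].fillna(-2.0)
    best_k = int(tied.loc[sil == sil.max(), "k"].min())
    return best_k, table, results
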