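"""Joint latent-variable integrative clustering across omics layers.

The model stacks the per-feature-standardized layers X_t (features x
samples) into one Gaussian latent-variable model

    X = W Z + eps,   Z ~ N(0, I_{k-1}),   eps ~ N(0, Psi)  (diagonal),

with lasso-shrunken loadings W.  Estimation is EM: the E-step gives the
latent posterior moments in closed form; the penalized M-step solves the
per-feature lasso problem by coordinate descent (soft-thresholding), and
Psi is updated with the exact residual variances, so the penalized
objective (per-sample log-likelihood minus lambda * ||W||_1) is
non-decreasing across iterations.  Cluster labels come from k-means on the
rows of the latent posterior mean E[Z|X]; the best of ``n_init`` random
restarts (by penalized objective) is returned.

A latent dimension of k-1 supports k clusters, matching the convention of
joint latent-variable clustering of tumor cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io import OmicsLayer

logger = logging.getLogger(__name__)

_PSI_FLOOR = 1e-6


def _as_matrix(layer) -> np.ndarray:
    if isinstance(layer, OmicsLayer):
        return layer.data.to_numpy(dtype=float)
    return np.asarray(layer, dtype=float)


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance per feature (row); constant rows stay zero."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


@dataclass
class IntegrativeFit:
    k: int
    W: list  # per-layer loadings, p_t x (k-1)
    psi: list  # per-layer diagonal noise variances
    EZ: np.ndarray  # n x (k-1) latent posterior means
    lam: float
    labels: np.ndarray  # 1..k
    objective: list  # penalized objective per EM iteration (best restart)
    n_init: int
    sample_ids: list = field(default_factory=list)
    restart_objectives: list = field(default_factory=list)


def _em_fit(X, q, lam, rng, max_em_iter, tol, init=None):
    """One EM run on the stacked matrix X (p x n). Returns (W, psi, EZ, trace)."""
    p, n = X.shape
    if init is not None:
        W = init[0].copy()
        psi = init[1].copy()
    else:
        W = rng.normal(0.0, 0.1, size=(p, q))
        psi = np.ones(p)
    Sxx_diag = (X**2).mean(axis=1)
    trace = []
    EZ = None
    for _ in range(max_em_iter):
        # E-step (Woodbury): M = I + W' Psi^-1 W
        G = W / psi[:, None]  # Psi^-1 W, p x q
        M = np.eye(q) + W.T @ G
        Minv = np.linalg.inv(M)
        B = Minv @ G.T  # q x p
        EZ = B @ X  # q x n
        Szz = EZ @ EZ.T / n + Minv
        Sxz = X @ EZ.T / n  # p x q

        # objective before updating parameters would lag one step; compute
        # the penalized observed-data log-likelihood for the current (W, psi)
        sign, logdet_M = np.linalg.slogdet(M)
        logdet_sigma = float(np.log(psi).sum() + logdet_M)
        GX = G.T @ X  # q x n
        tr_term = float((Sxx_diag / psi).sum() - np.trace(Minv @ (GX @ GX.T) / n))
        loglik_per_sample = -0.5 * (p * np.log(2 * np.pi) + logdet_sigma + tr_term)
        obj = loglik_per_sample - lam * float(np.abs(W).sum())
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite objective")
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * max(1.0, abs(trace[-2])):
            break

        # M-step: per-feature lasso by coordinate descent on
        #   (1/(2 psi_j)) (w' Szz w - 2 s_j' w) + lam |w|_1
        W_new = W.copy()
        for _sweep in range(50):
            max_delta = 0.0
            for m_ in range(q):
                resid = Sxz[:, m_] - W_new @ Szz[:, m_] + W_new[:, m_] * Szz[m_, m_]
                thresh = lam * psi
                updated = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0.0) / Szz[m_, m_]
                max_delta = max(max_delta, float(np.max(np.abs(updated - W_new[:, m_]), initial=0.0)))
                W_new[:, m_] = updated
            if max_delta < 1e-10:
                break
        W = W_new
        psi = Sxx_diag - 2.0 * (W * Sxz).sum(axis=1) + ((W @ Szz) * W).sum(axis=1)
        psi = np.maximum(psi, _PSI_FLOOR)
    return W, psi, EZ.T, trace


def icluster_fit(
    layers,
    k: int,
    lam: float = 0.2,
    n_init: int = 20,
    seed: int = 0,
    max_em_iter: int = 200,
    tol: float = 1e-6,
    standardize: bool = True,
    init=None,
) -> IntegrativeFit:
    """Fit the joint latent-variable model and cluster the latent posteriors.

    ``layers`` is a list of :class:`OmicsLayer` or arrays sharing sample
    columns.  Features are standardized per row unless ``standardize`` is
    False.  ``init=(W0, psi0)`` fixes the starting point (then a single
    restart is run), which also makes the unpenalized single-layer case
    directly comparable with a factor-analysis EM.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mats = [_as_matrix(l) for l in layers]
    if len({m.shape[1] for m in mats}) != 1:
        raise ValueError("layers must share the same samples")
    sizes = [m.shape[0] for m in mats]
    X = np.vstack([standardize_features(m) if standardize else m for m in mats])
    q = k - 1
    ss = np.random.SeedSequence(seed)
    restarts = 1 if init is not None else n_init
    child = ss.generate_state(restarts + 1)
    best = None
    restart_objs = []
    for r in range(restarts):
        rng = np.random.default_rng(int(child[r] % (2**31)))
        try:
            W, psi, EZ, trace = _em_fit(X, q, lam, rng, max_em_iter, tol, init=init)
        except (FloatingPointError, np.linalg.LinAlgError) as err:
            logger.warning("integrative restart %d discarded: %s", r, err)
            continue
        restart_objs.append(trace[-1])
        if best is None or trace[-1] > best[3][-1]:
            best = (W, psi, EZ, trace)
    if best is None:
        raise RuntimeError("all integrative-clustering restarts failed")
    W, psi, EZ, trace = best
    km_seed = int(child[-1] % (2**31))
    if np.allclose(EZ, 0.0):
        labels = np.ones(EZ.shape[0], dtype=int)
        logger.warning("latent posteriors collapsed to 0 (lambda too large); labels degenerate")
    else:
        labels = KMeans(n_clusters=k, n_init=10, random_state=km_seed).fit_predict(EZ) + 1
    bounds = np.cumsum([0] + sizes)
    W_layers = [W[bounds[t] : bounds[t + 1]] for t in range(len(sizes))]
    psi_layers = [psi[bounds[t] : bounds[t + 1]] for t in range(len(sizes))]
    sample_ids = (
        list(layers[0].sample_ids) if isinstance(layers[0], OmicsLayer) else []
    )
    return IntegrativeFit(
        k=k,
        W=W_layers,
        psi=psi_layers,
        EZ=EZ,
        lam=lam,
        labels=labels,
        objective=trace,
        n_init=restarts,
        sample_ids=sample_ids,
        restart_objectives=restart_objs,
    )


def choose_k_integrative(
    layers,
    k_range=(2, 3, 4),
    lam: float = 0.2,
    n_init: int = 10,
    seed: int = 0,
    max_em_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[int, pd.DataFrame]:
    """Stability scan over cluster counts.

    Per k, every restart's labels are compared pairwise by adjusted Rand
    index; the mean pairwise ARI is the stability score.  Best k maximizes
    stability, ties broken by the higher penalized objective.
    """
    rows = []
    for k in k_range:
        ss = np.random.SeedSequence(seed + 1000 * k)
        seeds = ss.generate_state(n_init)
        labelings, objs = [], []
        for s in seeds:
            fit = icluster_fit(
                layers, k, lam=lam, n_init=1, seed=int(s % (2**31)),
                max_em_iter=max_em_iter, tol=tol,
            )
            labelings.append(fit.labels)
            objs.append(fit.objective[-1])
        aris = [
            adjusted_rand_score(labelings[i], labelings[j])
            for i in range(len(labelings))
            for j in range(i + 1, len(labelings))
        ]
        rows.append(
            {"k": k, "stability": float(np.mean(aris)) if aris else 1.0,
             "objective": float(np.max(objs))}
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(["stability", "objective"], ascending=False).iloc[0]
    return int(best["k"]), table
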