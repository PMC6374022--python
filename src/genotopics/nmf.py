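"""Elastic-net regularized non-negative matrix factorization of the phenome.

The model approximates the binary individual x phecode matrix X (n x m) by
the product of two non-negative factors, W (n x k, individual-topic
loadings) and H (k x m, topic-phenotype weights), minimising

    ||X - WH||_F^2  +  lam * [ gamma * (||W||_1 + ||H||_1)
                               + (1 - gamma)/2 * (||W||_F^2 + ||H||_F^2) ]

over W >= 0, H >= 0.  ``lam`` weighs the elastic-net penalty and ``gamma``
is the L1 ratio within it.  The penalty is applied literally as written —
no rescaling by n, m or k (some libraries fold such factors in; here lam is
the knob, exactly).

The solver is HALS-style block coordinate descent: each column of W (row of
H) is minimised exactly with the rest held fixed, the L1 term entering as a
constant shift in the numerator and the L2 term inflating the denominator,
followed by projection onto the non-negative orthant.  Exact per-block
minimisation makes the objective trace non-increasing, which is asserted
after every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, DegenerateInputError
from .phecodes import PhenotypeMatrix

__all__ = [
    "NMFConfig",
    "TopicModel",
    "objective",
    "fit_nmf",
    "normalize_rows_l2",
    "scree",
    "assign_topics",
]

# Matrices no larger than this are densified for exact SVD in scree().
_DENSE_SVD_MAX_CELLS = 2_000_000


@dataclass(frozen=True)
class NMFConfig:
    """Hyperparameters of the regularized factorization.

    Defaults follow the analysis this package reproduces: k=6 topics,
    lam=0.2, gamma=0.5.
    """

    k: int = 6
    lam: float = 0.2
    gamma: float = 0.5
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init: str = "random"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.lam < 0:
            raise ConfigurationError("lam must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError("gamma must lie in [0,1]")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.init not in ("random", "nndsvd"):
            raise ConfigurationError("init must be 'random' or 'nndsvd'")


@dataclass
class TopicModel:
    """Fitted factor pair with its objective trace and provenance."""

    W: np.ndarray
    H: np.ndarray
    config: NMFConfig
    objective_trace: list[float]
    converged: bool
    n_iter: int
    individual_ids: list[str] | None = None
    phecodes: list[str] | None = None

    @property
    def k(self) -> int:
        return self.W.shape[1]


def _as_csr(X) -> sp.csr_matrix:
    if isinstance(X, PhenotypeMatrix):
        X = X.X
    return sp.csr_matrix(X, dtype=np.float64)


def objective(X, W: np.ndarray, H: np.ndarray, lam: float, gamma: float) -> float:
    """Evaluate the penalized objective at (W, H).

    The residual term is expanded as ||X||^2 - 2<X, WH> + tr(W'W H H') so the
    dense product WH is never materialised.
    """
    if np.any(W < 0) or np.any(H < 0):
        raise ValueError("W and H must be elementwise non-negative")
    Xs = _as_csr(X)
    x_sq = float((Xs.data ** 2).sum())
    if Xs.nnz:
        coo = Xs.tocoo()
        wh_at_nnz = np.einsum("ek,ke->e", W[coo.row], H[:, coo.col])
        cross = float(coo.data @ wh_at_nnz)
    else:
        cross = 0.0
    wh_sq = float(np.sum((W.T @ W) * (H @ H.T)))
    resid = x_sq - 2.0 * cross + wh_sq
    penalty = lam * (
        gamma * (W.sum() + H.sum())
        + 0.5 * (1.0 - gamma) * (float((W ** 2).sum()) + float((H ** 2).sum()))
    )
    # resid is mathematically >= 0; clip tiny negative round-off
    return max(resid, 0.0) + penalty


def objective_gradients(
    X, W: np.ndarray, H: np.ndarray, lam: float, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`objective` w.r.t. W and H.

    Valid in the interior (strictly positive entries); used by the
    finite-difference correctness checks.
    """
    Xs = _as_csr(X)
    WH_minus_X_Ht = W @ (H @ H.T) - Xs @ H.T
    gW = 2.0 * WH_minus_X_Ht + lam * gamma + lam * (1.0 - gamma) * W
    Wt_WH_minus_X = (W.T @ W) @ H - (Xs.T @ W).T
    gH = 2.0 * Wt_WH_minus_X + lam * gamma + lam * (1.0 - gamma) * H
    return gW, gH


def _init_factors(
    X: sp.csr_matrix, config: NMFConfig
) -> tuple[np.ndarray, np.ndarray]:
    n, m = X.shape
    k = config.k
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        scale = np.sqrt(X.mean() / k)
        W = rng.uniform(0.0, scale, size=(n, k))
        H = rng.uniform(0.0, scale, size=(k, m))
        return W, H
    return _nndsvd(X, k)


def _nndsvd(X: sp.csr_matrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialisation (Boutsidis & Gallopoulos)."""
    from scipy.sparse.linalg import svds

    kk = min(k, min(X.shape) - 1)
    U, S, Vt = svds(X, k=kk, random_state=0)
    idx = np.argsort(S)[::-1]
    U, S, Vt = U[:, idx], S[idx], Vt[idx]
    n, m = X.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, kk):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            u_, v_ = up / max(n_up, 1e-12), vp / max(n_vp, 1e-12)
        else:
            sigma = n_un * n_vn
            u_, v_ = un / max(n_un, 1e-12), vn / max(n_vn, 1e-12)
        W[:, j] = np.sqrt(S[j] * sigma) * u_
        H[j] = np.sqrt(S[j] * sigma) * v_
    # fill any unused components with the data mean scale
    mean = X.mean()
    for j in range(kk, k):
        W[:, j] = np.sqrt(mean / k)
        H[j] = np.sqrt(mean / k)
    return W, H


def fit_nmf(X, config: NMFConfig) -> TopicModel:
    """Fit the regularized NMF by HALS block coordinate descent.

    Stops when the relative objective change drops below ``config.tol`` or
    after ``config.max_iter`` sweeps.  Deterministic given the config seed.
    """
    ids = phe = None
    if isinstance(X, PhenotypeMatrix):
        ids, phe = X.individual_ids, X.phecodes
    Xs = _as_csr(X)
    n, m = Xs.shape
    if config.k > min(n, m):
        raise ConfigurationError(
            f"k={config.k} exceeds min(n, m)={min(n, m)}"
        )
    if Xs.nnz == 0:
        raise DegenerateInputError("cannot factorize an all-zero matrix")

    lam, gamma, k = config.lam, config.gamma, config.k
    l1 = 0.5 * lam * gamma          # constant numerator shift per entry
    l2 = 0.5 * lam * (1.0 - gamma)  # denominator inflation
    W, H = _init_factors(Xs, config)
    XT = Xs.T.tocsr()

    trace: list[float] = [objective(Xs, W, H, lam, gamma)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # --- update W column-wise ---
        XHt = Xs @ H.T                      # n x k
        HHt = H @ H.T                       # k x k
        for t in range(k):
            denom = HHt[t, t] + l2
            if denom <= 0.0:
                if lam > 0:
                    W[:, t] = 0.0
                continue
            numer = XHt[:, t] - W @ HHt[:, t] + W[:, t] * HHt[t, t] - l1
            W[:, t] = np.maximum(numer / denom, 0.0)
        # --- update H row-wise ---
        XtW = XT @ W                        # m x k
        WtW = W.T @ W                       # k x k
        for t in range(k):
            denom = WtW[t, t] + l2
            if denom <= 0.0:
                if lam > 0:
                    H[t] = 0.0
                continue
            numer = XtW[:, t] - (H.T @ WtW[:, t]) + H[t] * WtW[t, t] - l1
            H[t] = np.maximum(numer / denom, 0.0)

        trace.append(objective(Xs, W, H, lam, gamma))
        prev, cur = trace[-2], trace[-1]
        if prev > 0 and (prev - cur) / prev < config.tol:
            converged = True
            break

    return TopicModel(
        W=W,
        H=H,
        config=config,
        objective_trace=trace,
        converged=converged,
        n_iter=it,
        individual_ids=ids,
        phecodes=phe,
    )


def normalize_rows_l2(W: np.ndarray) -> np.ndarray:
    """Scale each non-zero row of W to unit Euclidean norm (zero rows kept)."""
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    out = W / np.where(norms > 0, norms, 1.0)
    return out


def scree(X, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Singular-value scree of the column-mean-centered matrix.

    Returns the top ``k_max`` singular values (descending) and the cumulative
    explained-variance fractions, the usual diagnostic for choosing the
    number of topics k: the elbow where singular values flatten marks the
    effective rank of the phenome.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    Xs = _as_csr(X)
    n, m = Xs.shape
    if k_max > min(n, m):
        raise ValueError(f"k_max={k_max} exceeds min(n, m)={min(n, m)}")
    if n * m <= _DENSE_SVD_MAX_CELLS:
        Xc = Xs.toarray() - Xs.mean(axis=0)
        s = np.linalg.svd(np.asarray(Xc), compute_uv=False)
        ev = s ** 2
    else:
        # eigendecomposition of the centered Gram matrix X'X - n mu mu'
        mu = np.asarray(Xs.mean(axis=0)).ravel()
        G = np.asarray((Xs.T @ Xs).todense()) - n * np.outer(mu, mu)
        ev = np.linalg.eigvalsh(G)[::-1]
        ev = np.maximum(ev, 0.0)
        s = np.sqrt(ev)
    total = ev.sum()
    shares = np.cumsum(ev) / total if total > 0 else np.zeros_like(ev)
    return s[:k_max], shares[:k_max]


def assign_topics(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Assign each individual to the topic with maximal loading.

    Ties break to the lowest topic index; an all-zero row gets the sentinel
    label -1 ("unassigned").  Returns (labels, per-topic counts, n_unassigned);
    counts.sum() + n_unassigned == n.
    """
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    labels = np.argmax(W, axis=1)
    labels[~W.any(axis=1)] = -1
    k = W.shape[1]
    counts = np.bincount(labels[labels >= 0], minlength=k)
    return labels, counts, int((labels == -1).sum())
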