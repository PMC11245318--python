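"""Multi-view graph pooling (MVPool).

Three node-importance views are scored per pooling layer:

* structure view     ``p_c = sigma(alpha * log(deg(A) + eps) + beta)``
* feature view       ``p_f = sigma(MLP(Z))``
* structure-feature  ``p_cf = sigma(delta * (I - (1-delta) * A_tilde)^{-1} PR)``
  with the personalised-PageRank seed
  ``PR = sigma(D_hat^{-1/2} A_hat^k D_hat^{-1/2} Z Phi)``,
  ``A_hat = A + I`` and ``A_tilde`` its symmetric normalisation.

An adaptive attention mechanism turns the three views into a convex
combination ``p = sum_j g_j p_j`` with per-view weights
``g = softmax_j(sigma(s^T w_j + b_j))`` where ``s`` is the fixed-length
summary (per-view means) of the concatenated scores.  The top ``ceil(r*N)``
nodes by ``p`` are retained; retained rows of ``Z`` are multiplied by the
sigmoid gate ``p_hat`` so that node selection stays differentiable, and the
adjacency is coarsened by sub-indexing.

The functional API below works on plain NumPy arrays (used for analysis and
oracle checks); :class:`MVPool` is the trainable layer on autodiff tensors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Tuple, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import NonConvergenceWarning
from .nn import MLP, Module, Parameter


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class ViewScores:
    """Per-node importance from the structure, feature and
    structure-feature views; all entries lie in (0, 1)."""
    p_c: np.ndarray
    p_f: np.ndarray
    p_cf: np.ndarray


@dataclass
class PoolResult:
    ind: np.ndarray          # retained node indices, ascending
    Z_next: np.ndarray       # gated feature rows of the retained nodes
    A_next: np.ndarray       # coarsened adjacency A[ind][:, ind]
    gate: np.ndarray         # sigmoid(p[ind])
    fused_p: np.ndarray      # fused importance score p
    view_weights: np.ndarray  # g_j, sums to 1


# ---------------------------------------------------------------------------
# functional (NumPy) API
# ---------------------------------------------------------------------------

def structure_score(A: np.ndarray, alpha: float, beta: float,
                    eps: float = 1e-5) -> np.ndarray:
    """Degree-centrality view: ``sigma(alpha * log(deg + eps) + beta)``.

    ``eps`` guards the logarithm for isolated nodes.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    deg = np.asarray(A, dtype=float).sum(axis=1)
    return _sigmoid(alpha * np.log(deg + eps) + beta)


def feature_score(Z: np.ndarray,
                  mlp: Union[Callable[[np.ndarray], np.ndarray], Tuple]) -> np.ndarray:
    """Feature view ``sigma(MLP(Z))``; the scorer has output dimension 1.

    ``mlp`` is a callable mapping (N, d) -> (N,) or (N, 1), or a ``(w, b)``
    pair describing the single-layer case ``sigma(Z @ w + b)``.
    """
    Z = np.asarray(Z, dtype=float)
    if isinstance(mlp, tuple):
        w, b = mlp
        raw = Z @ np.asarray(w, dtype=float) + b
    else:
        raw = np.asarray(mlp(Z), dtype=float)
    raw = raw.reshape(Z.shape[0])
    return _sigmoid(raw)


def _normalized_adjacency(A: np.ndarray, k_power: int = 1) -> np.ndarray:
    """``D_hat^{-1/2} A_hat^k D_hat^{-1/2}`` with ``A_hat = A + I``."""
    A = np.asarray(A, dtype=float)
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    D_inv_sqrt = np.diag(1.0 / np.sqrt(d))
    return D_inv_sqrt @ np.linalg.matrix_power(A_hat, k_power) @ D_inv_sqrt


def pagerank_score(A: np.ndarray, Z: np.ndarray, phi: np.ndarray,
                   delta: float = 0.2, k_power: int = 1,
                   n_iter: int = 100, tol: float = 1e-6,
                   method: str = "power") -> np.ndarray:
    """Structure-feature view via personalised PageRank.

    The seed ``PR = sigma(D_hat^{-1/2} A_hat^k D_hat^{-1/2} Z Phi)`` is
    propagated to the stationary solution of
    ``x = delta * PR + (1 - delta) * A_tilde x`` and squashed once:
    ``p_cf = sigma(x)``.  ``method="dense"`` solves the linear system
    directly; ``method="power"`` iterates until the max-abs update falls
    below ``tol`` (a :class:`NonConvergenceWarning` is emitted, and the last
    iterate returned, if ``n_iter`` is exhausted).  ``delta = 1`` performs no
    propagation, so ``p_cf = sigma(PR)`` exactly.
    """
    if not (0 < delta <= 1):
        raise ValueError("delta must be in (0, 1]")
    A = np.asarray(A, dtype=float)
    Z = np.asarray(Z, dtype=float)
    phi = np.asarray(phi, dtype=float).reshape(Z.shape[1])
    seed = _sigmoid(_normalized_adjacency(A, k_power) @ (Z @ phi))
    if delta == 1.0:
        return _sigmoid(seed)
    A_tilde = _normalized_adjacency(A, 1)
    if method == "dense":
        n = A.shape[0]
        x = delta * np.linalg.solve(np.eye(n) - (1.0 - delta) * A_tilde, seed)
    elif method == "power":
        x = seed.copy()
        for _ in range(n_iter):
            x_new = delta * seed + (1.0 - delta) * (A_tilde @ x)
            change = np.max(np.abs(x_new - x))
            x = x_new
            if change < tol:
                break
        else:
            warnings.warn("PageRank power iteration did not converge "
                          f"within {n_iter} iterations", NonConvergenceWarning)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _sigmoid(x)


def attention_fuse(scores: ViewScores,
                   attn_w: np.ndarray, attn_b: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Fuse the three views into one score vector.

    Each view's logit is ``sigma(s^T w_j + b_j)`` where ``s`` is the
    three-vector of per-view score means (a size-invariant summary of the
    concatenated scores); ``g = softmax`` over the three logits and
    ``p = sum_j g_j p_j``.  Returns ``(g, p)``.
    """
    views = [np.asarray(scores.p_c, float), np.asarray(scores.p_f, float),
             np.asarray(scores.p_cf, float)]
    if not (views[0].shape == views[1].shape == views[2].shape):
        raise ValueError("view score vectors must have equal length")
    s = np.array([v.mean() for v in views])
    logits = _sigmoid(s @ np.asarray(attn_w, float) + np.asarray(attn_b, float))
    e = np.exp(logits - logits.max())
    g = e / e.sum()
    p = g[0] * views[0] + g[1] * views[1] + g[2] * views[2]
    return g, p


def top_rank(p: np.ndarray, r: float) -> np.ndarray:
    """Indices of the top ``ceil(r * N)`` nodes by score.

    Ties break towards the lower original index (stable sort); the returned
    indices are sorted ascending so coarsened matrices keep relative order.
    """
    if not (0 < r <= 1):
        raise ValueError("pool ratio r must be in (0, 1]")
    p = np.asarray(p, dtype=float)
    k = math.ceil(r * p.shape[0])
    order = np.argsort(-p, kind="stable")
    return np.sort(order[:k])


def top_rank_pool(Z: np.ndarray, A: np.ndarray, p: np.ndarray, r: float,
                  view_weights: np.ndarray | None = None) -> PoolResult:
    """Retain the top ``ceil(r*N)`` nodes and gate their features.

    ``Z_next = Z[ind, :] * sigmoid(p[ind])`` (multiplicative gating keeps the
    selection differentiable end to end) and ``A_next = A[ind][:, ind]``.
    """
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A)
    p = np.asarray(p, dtype=float)
    ind = top_rank(p, r)
    gate = _sigmoid(p[ind])
    return PoolResult(
        ind=ind,
        Z_next=Z[ind] * gate[:, None],
        A_next=A[np.ix_(ind, ind)],
        gate=gate,
        fused_p=p,
        view_weights=(np.full(3, 1.0 / 3) if view_weights is None
                      else np.asarray(view_weights, float)),
    )


# ---------------------------------------------------------------------------
# trainable layer
# ---------------------------------------------------------------------------

class MVPool(Module):
    """Trainable multi-view pooling layer.

    Parameters: the structure-view scale/shift ``alpha, beta``; the
    feature-view MLP; the PageRank projection ``Phi``; the per-view attention
    weights ``w_j in R^3`` and biases ``b_j``.  Hyperparameters ``r`` (pool
    ratio), ``delta`` (restart probability), ``k_power`` and ``eps`` come
    from the encoder configuration.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 pool_ratio: float = 0.8, delta: float = 0.2,
                 k_power: int = 1, eps: float = 1e-5):
        if not (0 < pool_ratio <= 1):
            raise ValueError("pool_ratio must be in (0, 1]")
        if not (0 < delta <= 1):
            raise ValueError("delta must be in (0, 1]")
        if k_power < 1:
            raise ValueError("k_power must be >= 1")
        self.pool_ratio = pool_ratio
        self.delta = delta
        self.k_power = k_power
        self.eps = eps
        self.alpha = Parameter(np.array(1.0))
        self.beta = Parameter(np.array(0.0))
        self.score_mlp = MLP(dim, dim, 1, rng)
        self.phi = Parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(dim, 1)))
        self.attn_w = Parameter(np.zeros((3, 3)))
        self.attn_b = Parameter(np.zeros(3))

    def view_scores(self, Z: Tensor, A: np.ndarray) -> Tuple[Tensor, Tensor, Tensor]:
        n = A.shape[0]
        deg = np.asarray(A, dtype=float).sum(axis=1)
        log_deg = Tensor(np.log(deg + self.eps))
        p_c = (self.alpha * log_deg + self.beta).sigmoid()
        p_f = self.score_mlp(Z).sigmoid().reshape(n)
        seed_mat = Tensor(_normalized_adjacency(A, self.k_power))
        seed = (seed_mat @ (Z @ self.phi)).sigmoid().reshape(n)
        if self.delta == 1.0:
            p_cf = seed.sigmoid()
        else:
            A_tilde = _normalized_adjacency(A, 1)
            M = Tensor(np.eye(n) - (1.0 - self.delta) * A_tilde)
            x = ad.solve(M, seed.reshape(n, 1)) * self.delta
            p_cf = x.reshape(n).sigmoid()
        return p_c, p_f, p_cf

    def fuse(self, p_c: Tensor, p_f: Tensor, p_cf: Tensor) -> Tuple[Tensor, Tensor]:
        s = ad.stack([p_c.mean(), p_f.mean(), p_cf.mean()])
        logits = (s @ self.attn_w + self.attn_b).sigmoid()
        g = ad.softmax(logits, axis=0)
        p = g[0] * p_c + g[1] * p_f + g[2] * p_cf
        return g, p

    def __call__(self, Z: Tensor, A: np.ndarray,
                 edges: tuple | None = None):
        """Score, fuse and pool; returns ``(Z_next, A_next, edges_next, ind)``.

        ``edges`` is an optional COO pair ``(idx, feat)``; edges whose
        endpoints are not both retained are dropped and indices relabelled.
        """
        p_c, p_f, p_cf = self.view_scores(Z, A)
        _, p = self.fuse(p_c, p_f, p_cf)
        ind = top_rank(p.data, self.pool_ratio)
        gate = p[ind].sigmoid()
        k = ind.shape[0]
        Z_next = Z[ind] * gate.reshape(k, 1)
        A_next = np.asarray(A)[np.ix_(ind, ind)]
        edges_next = None
        if edges is not None:
            idx, feat = edges
            n = A.shape[0]
            keep = np.zeros(n, dtype=bool)
            keep[ind] = True
            new_id = np.full(n, -1, dtype=np.int64)
            new_id[ind] = np.arange(k)
            if idx.shape[0]:
                sel = keep[idx[:, 0]] & keep[idx[:, 1]]
                edges_next = (new_id[idx[sel]], feat[sel])
            else:
                edges_next = (idx, feat)
        return Z_next, A_next, edges_next, ind
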