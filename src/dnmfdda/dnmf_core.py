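"""Deep NMF engine: pretraining, multiplicative updates, objective, stopping.

The model factorizes a nonnegative integrated matrix X through l layers,
X ≈ W_l H_l … H_1, minimizing

    ||X − W_l H_l … H_1||_F²  +  α Σ_i Tr(W_iᵀ L W_i)
    + β Σ_{i<l} ||W_i − W_{i+1} H_{i+1}||_F²
    + λ Σ_i ||W_i||_F²  +  μ Σ_i ||H_i||_F²        (W_i, H_i ≥ 0)

where L is the graph Laplacian of the fused similarity.  Each factor is
updated by a KKT-derived multiplicative rule of the form
W ← W · sqrt(numerator / denominator), with every signed product split into
its positive and negative parts so both sides stay nonnegative.  Layers are
initialized by plain NMF applied layer-by-layer (X ≈ W₁H₁, W₁ ≈ W₂H₂, …).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .preprocess import GraphLaplacian, IntegratedMatrix

__all__ = [
    "Hyperparams",
    "FactorStack",
    "NumericFailure",
    "pos_neg_split",
    "basic_nmf",
    "layer_dims",
    "pretrain_stack",
    "phi_product",
    "update_W",
    "update_H",
    "objective",
    "convergence_check",
    "fit_dnmf",
    "reconstruct",
]

logger = logging.getLogger(__name__)

# Division guard for the multiplicative rules: denominator entries are floored
# at EPS rather than shifted by it, so an exact fixed point (numerator equal
# to denominator) stays a fixed point to machine precision.
EPS = 1e-10


class NumericFailure(RuntimeError):
    """NaN/Inf appeared in a factor during optimization."""


@dataclass
class Hyperparams:
    """Model and optimizer settings.

    alpha
        Weight of the graph-Laplacian terms Tr(W_iᵀ L W_i) (local structure).
    beta
        Weight of the layer-consistency (relaxation) terms
        ||W_i − W_{i+1}H_{i+1}||².
    lam, mu
        Ridge weights on the basis and coefficient matrices.  Tuned as one
        value in practice but independently settable.
    taus
        Per-layer dimension fractions: layer i has l_i = round(τ_i · min(m, n))
        latent dimensions, m×n being the association matrix shape.
    k, decay
        KNN-fill neighbor count and rank-decay factor.
    xi1, xi2
        Stopping tolerances on the relative change h of the reconstructed
        association block and on the change of h itself.
    max_iter, pretrain_iters
        Caps on update sweeps and on per-layer pretraining iterations.
    sweep_order
        "layer" updates W_i then H_i per layer; "factors" updates all W then
        all H.  The rules themselves are identical.
    """

    alpha: float = 0.01
    beta: float = 1.0
    lam: float = 1.0
    mu: float = 1.0
    taus: tuple[float, ...] = (0.8, 0.6)
    k: int = 10
    decay: float = 0.9
    xi1: float = 5e-4
    xi2: float = 5e-7
    max_iter: int = 500
    pretrain_iters: int = 200
    sweep_order: str = "layer"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.taus or any(not 0 < t <= 1 for t in self.taus):
            raise ValueError("each tau must lie in (0, 1]")
        if self.xi1 <= 0 or self.xi2 <= 0:
            raise ValueError("stopping tolerances must be positive")
        if self.sweep_order not in ("layer", "factors"):
            raise ValueError("sweep_order must be 'layer' or 'factors'")


@dataclass
class FactorStack:
    """Per-view factorization state.

    ``W[i]`` is rows(X)×l_{i+1}; ``H[0]`` is l_1×cols(X) and ``H[i]`` is
    l_{i+1}×l_i for deeper layers, so W_l H_l … H_1 has the shape of X.
    """

    layer_dims: list[int]
    W: list[np.ndarray]
    H: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims)

    def copy(self) -> "FactorStack":
        return FactorStack(list(self.layer_dims), [w.copy() for w in self.W], [h.copy() for h in self.H])


def _values(X) -> np.ndarray:
    if isinstance(X, IntegratedMatrix):
        return X.values
    return np.asarray(getattr(X, "values", X), dtype=float)


def pos_neg_split(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split M into its positive and negative parts.

    Returns ``(M⁺, M⁻)`` with M⁺ = (|M|+M)/2 and M⁻ = (|M|−M)/2, both
    nonnegative, satisfying M⁺ − M⁻ = M with disjoint supports.
    """
    M = np.asarray(M, dtype=float)
    a = np.abs(M)
    return (a + M) / 2.0, (a - M) / 2.0


def _mu_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return num / np.maximum(den, EPS)


def basic_nmf(
    M: np.ndarray, r: int, iters: int = 200, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Plain NMF by the classical Frobenius multiplicative updates.

    Factors are initialized uniform(0, 1) from ``seed``; the squared
    reconstruction error is nonincreasing across iterations.
    """
    M = np.asarray(M, dtype=float)
    if M.size and M.min() < 0:
        raise ValueError("basic_nmf requires a nonnegative matrix")
    if not 1 <= r <= min(M.shape):
        raise ValueError(f"rank {r} outside [1, {min(M.shape)}]")
    rng = np.random.default_rng(seed)
    W = rng.uniform(size=(M.shape[0], r))
    H = rng.uniform(size=(r, M.shape[1]))
    for _ in range(iters):
        H *= _mu_divide(W.T @ M, W.T @ W @ H)
        W *= _mu_divide(M @ H.T, W @ (H @ H.T))
    return W, H


def layer_dims(rows: int, cols: int, taus: tuple[float, ...]) -> list[int]:
    """Layer dimensions l_i = round(τ_i · min(rows, cols)), floored at 1."""
    if not taus:
        raise ValueError("taus must be nonempty")
    base = min(rows, cols)
    return [max(1, int(math.floor(t * base + 0.5))) for t in taus]


def _layer_seed(seed: int, i: int) -> int:
    return (seed * 1_000_003 + 7919 * (i + 1)) % (2**31)


def pretrain_stack(X, dims: list[int], params: Hyperparams) -> FactorStack:
    """Layer-wise NMF pretraining: X ≈ W₁H₁, then W₁ ≈ W₂H₂, and so on.

    Each layer's rank is clamped to the dimensions of the matrix it
    factorizes.  Per-layer seeds are derived from ``params.seed``.
    """
    Xv = _values(X)
    Ws: list[np.ndarray] = []
    Hs: list[np.ndarray] = []
    used_dims: list[int] = []
    current = Xv
    for i, d in enumerate(dims):
        r = min(d, min(current.shape))
        W, H = basic_nmf(current, r, params.pretrain_iters, _layer_seed(params.seed, i))
        Ws.append(W)
        Hs.append(H)
        used_dims.append(r)
        current = W
    return FactorStack(used_dims, Ws, Hs)


def random_stack(X, dims: list[int], seed: int) -> FactorStack:
    """Uniform(0, 1)-initialized stack of the same shapes as pretraining."""
    Xv = _values(X)
    rng = np.random.default_rng(seed)
    Ws, Hs, used = [], [], []
    rows = Xv.shape[0]
    prev_cols = Xv.shape[1]
    prev_dim = min(Xv.shape)
    for d in dims:
        r = min(d, prev_dim)
        Ws.append(rng.uniform(size=(rows, r)))
        Hs.append(rng.uniform(size=(r, prev_cols)))
        used.append(r)
        prev_cols = r
        prev_dim = r
    return FactorStack(used, Ws, Hs)


def phi_product(stack: FactorStack, i: int) -> np.ndarray:
    """Φ_i = H_i H_{i−1} … H_1 (just H_1 when i = 1)."""
    if not 1 <= i <= stack.n_layers:
        raise ValueError(f"layer index {i} outside [1, {stack.n_layers}]")
    phi = stack.H[0]
    for p in range(1, i):
        phi = stack.H[p] @ phi
    return phi


def update_W(stack: FactorStack, i: int, X, L: GraphLaplacian, params: Hyperparams) -> np.ndarray:
    """One multiplicative update of W_i; returns the new matrix.

    The numerator collects positive parts of attracting products and negative
    parts of repelling ones (and vice versa in the denominator): the data
    term XΦᵀ vs WΦΦᵀ, the Laplacian term αLW, the ridge, and — when the
    adjacent layers exist — the β layer-consistency couplings
    W_{i−1}H_iᵀ, W_iH_iH_iᵀ and W_{i+1}H_{i+1}.
    """
    Xv = _values(X)
    Lv = L.values if isinstance(L, GraphLaplacian) else np.asarray(L, dtype=float)
    l = stack.n_layers
    W = stack.W[i - 1]
    phi = phi_product(stack, i)

    xp_p, xp_n = pos_neg_split(Xv @ phi.T)
    wpp_p, wpp_n = pos_neg_split(W @ (phi @ phi.T))
    lw_p, lw_n = pos_neg_split(Lv @ W)
    w_p, w_n = pos_neg_split(W)

    has_next = i < l
    has_prev = i > 1
    ridge = params.beta + params.lam if has_next else params.lam

    num = xp_p + wpp_n + params.alpha * lw_n + ridge * w_n
    den = xp_n + wpp_p + params.alpha * lw_p + ridge * w_p
    if has_next:
        nxt_p, nxt_n = pos_neg_split(stack.W[i] @ stack.H[i])
        num += params.beta * nxt_p
        den += params.beta * nxt_n
    if has_prev:
        prv_p, prv_n = pos_neg_split(stack.W[i - 2] @ stack.H[i - 1].T)
        whh_p, whh_n = pos_neg_split(W @ (stack.H[i - 1] @ stack.H[i - 1].T))
        num += params.beta * prv_p + params.beta * whh_n
        den += params.beta * prv_n + params.beta * whh_p

    new_W = W * np.sqrt(_mu_divide(num, den))
    if not np.all(np.isfinite(new_W)):
        raise NumericFailure(f"non-finite values updating W_{i}")
    return new_W


def update_H(stack: FactorStack, i: int, X, params: Hyperparams) -> np.ndarray:
    """One multiplicative update of H_i; returns the new matrix.

    The first layer sees the data through X ≈ W₁H₁; deeper layers through
    X ≈ W_i H_i Φ_{i−1} plus the β coupling to W_{i−1}.
    """
    Xv = _values(X)
    W = stack.W[i - 1]
    H = stack.H[i - 1]
    WtW = W.T @ W

    if i == 1:
        wwh_p, wwh_n = pos_neg_split(WtW @ H)
        wx_p, wx_n = pos_neg_split(W.T @ Xv)
        h_p, h_n = pos_neg_split(H)
        num = wwh_n + wx_p + params.mu * h_n
        den = wwh_p + wx_n + params.mu * h_p
    else:
        phi = phi_product(stack, i - 1)
        wwhpp_p, wwhpp_n = pos_neg_split(WtW @ H @ (phi @ phi.T))
        wxp_p, wxp_n = pos_neg_split(W.T @ Xv @ phi.T)
        h_p, h_n = pos_neg_split(H)
        wprev_p, wprev_n = pos_neg_split(W.T @ stack.W[i - 2])
        wwh_p, wwh_n = pos_neg_split(WtW @ H)
        num = wwhpp_n + wxp_p + params.mu * h_n + params.beta * wprev_p + params.beta * wwh_n
        den = wwhpp_p + wxp_n + params.mu * h_p + params.beta * wprev_n + params.beta * wwh_p

    new_H = H * np.sqrt(_mu_divide(num, den))
    if not np.all(np.isfinite(new_H)):
        raise NumericFailure(f"non-finite values updating H_{i}")
    return new_H


def reconstruct(stack: FactorStack) -> np.ndarray:
    """Back-fill the approximation W_l H_l H_{l−1} … H_1."""
    out = stack.W[-1]
    for H in reversed(stack.H):
        out = out @ H
    return out


def objective(stack: FactorStack, X, L: GraphLaplacian, params: Hyperparams) -> float:
    """Value of the regularized deep-factorization objective."""
    Xv = _values(X)
    Lv = L.values if isinstance(L, GraphLaplacian) else np.asarray(L, dtype=float)
    l = stack.n_layers
    total = float(np.linalg.norm(Xv - reconstruct(stack)) ** 2)
    for i in range(l):
        Wi = stack.W[i]
        total += params.alpha * float(np.trace(Wi.T @ Lv @ Wi))
        total += params.lam * float(np.linalg.norm(Wi) ** 2)
        total += params.mu * float(np.linalg.norm(stack.H[i]) ** 2)
        if i < l - 1:
            total += params.beta * float(
                np.linalg.norm(Wi - stack.W[i + 1] @ stack.H[i + 1]) ** 2
            )
    return total


def convergence_check(history: list[float], params: Hyperparams) -> bool:
    """Stopping rule on the relative-change series h of the score matrix.

    Stops when the latest h is at or below ξ₁ AND h itself has stabilized:
    |h_latest − h_previous| / max(1, |h_previous|) ≤ ξ₂.  With fewer than two
    entries the answer is always "continue".
    """
    if len(history) < 2:
        return False
    h_prev, h_last = history[-2], history[-1]
    if h_last > params.xi1:
        return False
    return abs(h_last - h_prev) / max(1.0, abs(h_prev)) <= params.xi2


def _association_block(recon: np.ndarray, X) -> np.ndarray:
    if isinstance(X, IntegratedMatrix):
        return recon[:, X.sim_width :]
    return recon


def fit_dnmf(
    X,
    L: GraphLaplacian,
    params: Hyperparams,
    dims: list[int] | None = None,
    pretrain: bool = True,
) -> FactorStack:
    """Fit the regularized deep factorization of one integrated matrix.

    Layers are pretrained (or, with ``pretrain=False``, randomly
    initialized), then refined by repeated sweeps of the multiplicative
    rules.  After each sweep the relative change h of the reconstructed
    association block is appended to the stopping history; iteration ends on
    the stopping rule or at ``params.max_iter``.  Deterministic given
    ``params.seed``.
    """
    Xv = _values(X)
    if Xv.size and Xv.min() < 0:
        raise ValueError("integrated matrix must be nonnegative")
    if dims is None:
        dims = layer_dims(*Xv.shape, params.taus)
    if pretrain:
        stack = pretrain_stack(X, dims, params)
    else:
        stack = random_stack(X, dims, _layer_seed(params.seed, 99))

    history: list[float] = []
    prev_block = _association_block(reconstruct(stack), X)
    for sweep in range(params.max_iter):
        try:
            if params.sweep_order == "layer":
                for i in range(1, stack.n_layers + 1):
                    stack.W[i - 1] = update_W(stack, i, X, L, params)
                    stack.H[i - 1] = update_H(stack, i, X, params)
            else:
                for i in range(1, stack.n_layers + 1):
                    stack.W[i - 1] = update_W(stack, i, X, L, params)
                for i in range(1, stack.n_layers + 1):
                    stack.H[i - 1] = update_H(stack, i, X, params)
        except NumericFailure as exc:
            raise NumericFailure(f"{exc} (sweep {sweep + 1})") from exc
        block = _association_block(reconstruct(stack), X)
        denom = float(np.linalg.norm(prev_block))
        h = float(np.linalg.norm(block - prev_block)) / denom if denom > 0 else 0.0
        history.append(h)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "sweep %d: h=%.3e objective=%.6e", sweep + 1, h, objective(stack, X, L, params)
            )
        prev_block = block
        if convergence_check(history, params):
            break
    return stack
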