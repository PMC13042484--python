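"""Dual-view graph autoencoder with attention fusion and SwAV consistency.

Two 2-layer GCN encoders with shared weights embed the HSG expression matrix
under the spatial view (SAG) and the feature view (FAG):

    H1 = ReLU(Ã X W1),   E = H1 W2 + b2,

with Ã = D^{-1/2}(A + I)D^{-1/2}.  A self-attention layer fuses the two
embeddings (v = tanh(E W_omega), alpha = softmax(v u_omega) over views), and
three symmetric decoders reconstruct X from E_v1, E_v2 and the fused E_att
using the transposed encoder weights.  The training objective combines

* reconstruction MSE over the three decoders,
* binary cross-entropy between sigmoid(E_att E_attᵀ) and both adjacencies,
* symmetric KL between Sinkhorn-normalized per-view prototype assignments
  (the SwAV term), and
* an attention-balance penalty mean((alpha - 1/2)^2),

weighted by lambda = (10, 10, 5, 1) with a reconstruction warm-up stage in
which the SwAV weight is held at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .autodiff import Adam, Tensor, exp, log, relu, tanh

__all__ = [
    "ModelParams",
    "Embeddings",
    "LossBreakdown",
    "TrainConfig",
    "normalize_adjacency",
    "encode_views",
    "fuse_attention",
    "decode_views",
    "sinkhorn_normalize",
    "swav_assignments",
    "compute_losses",
    "train_model",
]


@dataclass
class ModelParams:
    """Learnable weights, shared across the two views."""

    W1: Tensor
    W2: Tensor
    b2: Tensor
    W_omega: Tensor
    u_omega: Tensor

    @classmethod
    def init(cls, d_in: int, d_hid: int, d_out: int, seed: int = 0) -> "ModelParams":
        rng = np.random.default_rng(seed)

        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-s, s, (fan_in, fan_out)), requires_grad=True)

        return cls(
            W1=glorot(d_in, d_hid),
            W2=glorot(d_hid, d_out),
            b2=Tensor(np.zeros((1, d_out)), requires_grad=True),
            W_omega=glorot(d_out, d_out),
            u_omega=glorot(d_out, 1),
        )

    def all(self):
        return [self.W1, self.W2, self.b2, self.W_omega, self.u_omega]


@dataclass
class Embeddings:
    E_v1: np.ndarray
    E_v2: np.ndarray
    E_att: np.ndarray
    alpha: np.ndarray


@dataclass
class LossBreakdown:
    recon: float
    graph: float
    swav: float
    att: float
    total: float
    lambdas: tuple = (10.0, 10.0, 5.0, 1.0)


@dataclass
class TrainConfig:
    d_hid: int = 256
    d_out: int = 64
    epochs: int = 600
    lr: float = 1e-3
    seed: int = 0
    lambdas: tuple = (10.0, 10.0, 5.0, 1.0)
    # staged dynamic weighting: after the warm-up stage each lambda is
    # multiplied by the matching factor (graph weight decays 10x once the
    # adjacency logits have settled and the SwAV term switches on)
    stage_two_scale: tuple = (1.0, 0.1, 1.0, 1.0)
    warmup_frac: float = 0.2
    n_prototypes: int | None = None  # default: target cluster count, else 15
    temperature: float = 0.1
    sinkhorn_iters: int = 3
    prototype_refresh: int = 20
    dual_view: bool = True


def normalize_adjacency(A) -> np.ndarray:
    """Symmetric normalization with self-loops: D^{-1/2}(A + I)D^{-1/2}."""
    A = A.toarray() if sp.issparse(A) else np.asarray(A, dtype=float)
    A = A + np.eye(A.shape[0])
    d = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return A * dinv[:, None] * dinv[None, :]


# ---------------------------------------------------------------------------
# tensor-level building blocks (shared by public API and training loop)
# ---------------------------------------------------------------------------


def _encode(AX: Tensor, params: ModelParams) -> Tensor:
    return relu(AX @ params.W1) @ params.W2 + params.b2


def _fuse(E1: Tensor, E2: Tensor, params: ModelParams):
    s1 = tanh(E1 @ params.W_omega) @ params.u_omega  # (N, 1)
    s2 = tanh(E2 @ params.W_omega) @ params.u_omega
    m = Tensor(np.maximum(s1.data, s2.data))  # detached max for stability
    e1, e2 = exp(s1 - m), exp(s2 - m)
    tot = e1 + e2
    a1, a2 = e1 / tot, e2 / tot
    E_att = a1 * E1 + a2 * E2
    return E_att, a1, a2


def _decode(E: Tensor, params: ModelParams) -> Tensor:
    return relu(E @ params.W2.T) @ params.W1.T


def _softplus(z: Tensor) -> Tensor:
    az = relu(z) + relu(-z)  # |z|
    return relu(z) + log(Tensor(1.0) + exp(-az))


def _bce_logits(A: np.ndarray, z: Tensor) -> Tensor:
    """Mean binary cross-entropy of sigmoid(z) against targets A."""
    return (_softplus(z) - Tensor(A) * z).mean()


def _kl(Q1: Tensor, Q2: Tensor, eps: float = 1e-12) -> Tensor:
    q1 = Q1 + eps
    q2 = Q2 + eps
    return (q1 * (log(q1) - log(q2))).sum()


def _sinkhorn_core(P: Tensor, n_iters: int) -> Tensor:
    """Alternating normalization to uniform marginals (rows 1/N, cols 1/K)."""
    n, k = P.shape
    for _ in range(n_iters):
        P = P / (P.sum(axis=0, keepdims=True) * k)
        P = P / (P.sum(axis=1, keepdims=True) * n)
    return P


def _row_softmax(S: Tensor) -> Tensor:
    m = Tensor(S.data.max(axis=1, keepdims=True))
    E = exp(S - m)
    return E / E.sum(axis=1, keepdims=True)


def _cosine(E: Tensor, centers: np.ndarray) -> Tensor:
    norms = ((E * E).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    Cn = centers / np.maximum(np.linalg.norm(centers, axis=1, keepdims=True), 1e-12)
    return (E / norms) @ Tensor(Cn.T)


def _view_assignment(E: Tensor, centers: np.ndarray, cfg: TrainConfig) -> Tensor:
    P = _row_softmax(_cosine(E, centers) / cfg.temperature)
    return _sinkhorn_core(P, cfg.sinkhorn_iters)


def _fit_prototypes(E_att: np.ndarray, n_prototypes: int, seed: int) -> np.ndarray:
    """K-Means centers on the fused embedding; re-seed on an empty cluster."""
    for attempt in range(5):
        km = KMeans(
            n_clusters=n_prototypes, n_init=3, random_state=seed + attempt
        ).fit(E_att)
        if np.unique(km.labels_).size == n_prototypes:
            return km.cluster_centers_
    return km.cluster_centers_  # pragma: no cover - sklearn avoids empties


# ---------------------------------------------------------------------------
# public operations (numpy in, numpy out)
# ---------------------------------------------------------------------------


def encode_views(X_HSG, A_coord, A_feat, params: ModelParams):
    """View-specific embeddings from the two normalized adjacencies."""
    X = np.asarray(X_HSG, dtype=float)
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError("dimension-error: X columns must match W1 rows")
    out = []
    for A in (A_coord, A_feat):
        At = normalize_adjacency(A) if _needs_norm(A) else _as_dense(A)
        out.append(_encode(Tensor(At @ X), params).data)
    return tuple(out)


def _as_dense(A):
    return A.toarray() if sp.issparse(A) else np.asarray(A, dtype=float)


def _needs_norm(A):
    Ad = _as_dense(A)
    # a raw adjacency has zero diagonal; a normalized one has positive diagonal
    return np.all(np.diag(Ad) == 0)


def fuse_attention(E_v1, E_v2, params: ModelParams):
    E_att, a1, a2 = _fuse(Tensor(E_v1), Tensor(E_v2), params)
    alpha = np.hstack([a1.data, a2.data])
    return E_att.data, alpha


def decode_views(E_v1, E_v2, E_att, params: ModelParams):
    return tuple(
        _decode(Tensor(E), params).data for E in (E_v1, E_v2, E_att)
    )


def sinkhorn_normalize(
    scores: np.ndarray, n_iters: int = 3, epsilon: float = 0.05
) -> np.ndarray:
    """Sinkhorn-Knopp normalization of exp(scores / epsilon) to uniform
    marginals: every row sums to 1/N, every column to 1/K."""
    S = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("scores must be finite")
    P = np.exp((S - S.max()) / epsilon)  # max-subtraction avoids overflow
    return _sinkhorn_core(Tensor(P), n_iters).data


def swav_assignments(
    E_v1,
    E_v2,
    E_att,
    n_prototypes: int = 15,
    seed: int = 0,
    temperature: float = 0.1,
    sinkhorn_iters: int = 3,
):
    """Per-view Sinkhorn-normalized soft assignments to K-Means prototypes
    fitted on the fused embedding."""
    if n_prototypes < 2:
        raise ValueError("n_prototypes must be >= 2")
    centers = _fit_prototypes(np.asarray(E_att, dtype=float), n_prototypes, seed)
    cfg = TrainConfig(temperature=temperature, sinkhorn_iters=sinkhorn_iters)
    Q1 = _view_assignment(Tensor(np.asarray(E_v1, float)), centers, cfg).data
    Q2 = _view_assignment(Tensor(np.asarray(E_v2, float)), centers, cfg).data
    return Q1, Q2


def compute_losses(
    X_HSG,
    reconstructions,
    A_coord,
    A_feat,
    E_att,
    alpha,
    Q_v1=None,
    Q_v2=None,
    lambdas=(10.0, 10.0, 5.0, 1.0),
) -> LossBreakdown:
    """Assemble the four-part objective from precomputed pieces."""
    X = Tensor(np.asarray(X_HSG, float))
    recon = Tensor(0.0)
    for Xr in reconstructions:
        d = X - Tensor(np.asarray(Xr, float))
        recon = recon + (d * d).mean()
    E = Tensor(np.asarray(E_att, float))
    z = E @ E.T
    graph = _bce_logits(_as_dense(A_coord), z) + _bce_logits(_as_dense(A_feat), z)
    if Q_v1 is not None and Q_v2 is not None:
        q1, q2 = Tensor(np.asarray(Q_v1, float)), Tensor(np.asarray(Q_v2, float))
        swav = _kl(q1, q2) + _kl(q2, q1)
    else:
        swav = Tensor(0.0)
    a = Tensor(np.asarray(alpha, float)) - Tensor(0.5)
    att = (a * a).mean()
    l1, l2, l3, l4 = lambdas
    total = (
        l1 * float(recon.data)
        + l2 * float(graph.data)
        + l3 * float(swav.data)
        + l4 * float(att.data)
    )
    return LossBreakdown(
        recon=float(recon.data),
        graph=float(graph.data),
        swav=float(swav.data),
        att=float(att.data),
        total=total,
        lambdas=tuple(lambdas),
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_model(
    X_HSG: np.ndarray,
    A_coord,
    A_feat=None,
    config: TrainConfig | None = None,
    n_clusters: int | None = None,
):
    """Gradient-based minimization of the joint objective.

    Returns ``(params, embeddings, history)`` where ``history`` is the
    per-epoch :class:`LossBreakdown`.  Fully reproducible under
    ``config.seed`` (single-threaded deterministic numpy path).
    """
    cfg = config or TrainConfig()
    X = np.asarray(X_HSG, dtype=float)
    n, d_in = X.shape
    params = ModelParams.init(d_in, cfg.d_hid, cfg.d_out, seed=cfg.seed)
    opt = Adam(params.all(), lr=cfg.lr)

    A1d = _as_dense(A_coord)
    AX1 = Tensor(normalize_adjacency(A1d) @ X)  # layer-1 input is constant
    dual = cfg.dual_view and A_feat is not None
    if dual:
        A2d = _as_dense(A_feat)
        AX2 = Tensor(normalize_adjacency(A2d) @ X)

    n_proto = cfg.n_prototypes or n_clusters or 15
    n_proto = min(n_proto, max(2, n - 1))
    warmup = int(np.floor(cfg.warmup_frac * cfg.epochs))
    Xt = Tensor(X)
    centers = None
    history: list[LossBreakdown] = []

    for epoch in range(cfg.epochs):
        in_warmup = epoch < warmup
        if in_warmup:
            lam = list(cfg.lambdas)
            lam[2] = 0.0
        else:
            lam = [l * s for l, s in zip(cfg.lambdas, cfg.stage_two_scale)]

        E1 = _encode(AX1, params)
        if dual:
            E2 = _encode(AX2, params)
            E_att, a1, a2 = _fuse(E1, E2, params)
            alpha = np.hstack([a1.data, a2.data])
        else:
            E2, E_att = E1, E1
            a1 = Tensor(np.ones((n, 1)))
            alpha = np.hstack([a1.data, 1 - a1.data])

        # reconstruction term
        recons = [_decode(E1, params)]
        if dual:
            recons += [_decode(E2, params), _decode(E_att, params)]
        recon = Tensor(0.0)
        for Xr in recons:
            d = Xt - Xr
            recon = recon + (d * d).mean()

        # graph term on the fused embedding
        z = E_att @ E_att.T
        graph = _bce_logits(A1d, z)
        if dual:
            graph = graph + _bce_logits(A2d, z)

        # SwAV term
        if dual and not in_warmup and lam[2] > 0:
            if centers is None or epoch % cfg.prototype_refresh == 0:
                centers = _fit_prototypes(E_att.data, n_proto, cfg.seed)
            Q1 = _view_assignment(E1, centers, cfg)
            Q2 = _view_assignment(E2, centers, cfg)
            swav = _kl(Q1, Q2) + _kl(Q2, Q1)
        else:
            swav = Tensor(0.0)

        # attention balance
        if dual:
            da = a1 - Tensor(0.5)
            db = (Tensor(1.0) - a1) - Tensor(0.5)
            att = ((da * da).sum() + (db * db).sum()) / (2 * n)
        else:
            att = Tensor(0.25)  # alpha pinned at (1, 0); no gradient

        total = lam[0] * recon + lam[1] * graph + lam[2] * swav + lam[3] * att
        if not np.isfinite(total.data):
            raise ValueError(
                "divergence: loss became non-finite; reduce the learning rate"
            )
        history.append(
            LossBreakdown(
                recon=float(recon.data),
                graph=float(graph.data),
                swav=float(swav.data),
                att=float(att.data),
                total=float(total.data),
                lambdas=tuple(lam),
            )
        )
        opt.zero_grad()
        total.backward()
        opt.step()

    # final forward pass with trained weights
    E1 = _encode(AX1, params)
    if dual:
        E2 = _encode(AX2, params)
        E_att, a1, a2 = _fuse(E1, E2, params)
        alpha = np.hstack([a1.data, a2.data])
    else:
        E2, E_att = E1, E1
        alpha = np.hstack([np.ones((n, 1)), np.zeros((n, 1))])
    emb = Embeddings(
        E_v1=E1.data, E_v2=E2.data, E_att=E_att.data, alpha=alpha
    )
    return params, emb, history
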