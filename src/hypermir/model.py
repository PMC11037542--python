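"""The trainable network: dual-view hypergraph encoders, cross-view
contrastive objective, view-aware attention, inter-view attention
integration, and a neural matrix-completion decoder.

Forward pass per entity type (miRNAs and diseases are handled
symmetrically):

1. two hypergraph-convolution encoders (KNN view, K-means view) map node
   features through ``X -> ReLU(P X Theta)`` per layer (no biases);
2. an InfoNCE-style contrastive loss ties the two views together: for each
   node, its embedding in one view is the anchor, the same node in the other
   view is the positive, and all other nodes in both views are negatives;
   the critic is cosine similarity after a two-layer projection head, at
   temperature ``tau``;
3. view-aware attention pools each view over the vertex axis and gates it
   with a scalar in (0,1) from a small feedforward network;
4. per-node inter-view attention (multi-head scaled dot product over the
   two gated view vectors) fuses the views into one embedding;
5. one-layer decoders with ReLU produce factor matrices whose product is
   the reconstructed association score matrix ``T_hat``.

The composite loss is a weighted Frobenius reconstruction term (trade-off
``alpha`` between observed and unobserved entries) plus the two contrastive
terms weighted by ``lam`` and ``gam``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, glorot_uniform
from .io import Config, InvalidInputError

__all__ = [
    "ViewEmbeddings", "ModelState", "LossBreakdown",
    "init_params", "hgcn_forward", "project",
    "contrastive_pair_loss", "symmetric_contrastive_loss",
    "view_attention", "inter_view_attention", "integrate_all",
    "reconstruct", "reconstruction_loss", "total_loss", "forward",
    "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_MAGIC = "HYPERMIR-CKPT-v1"


@dataclass
class ViewEmbeddings:
    """Per-entity embeddings from the two hypergraph views."""

    view_knn: Tensor
    view_kmeans: Tensor
    weighted_knn: Tensor | None = None
    weighted_kmeans: Tensor | None = None
    alphas: tuple | None = None


@dataclass
class LossBreakdown:
    """Components of the composite training objective."""

    reconstruction: float
    contrastive_mirna: float
    contrastive_disease: float
    total: float


@dataclass
class ModelState:
    """Trained parameters plus everything needed to score associations."""

    params: dict
    config: Config
    mirna_ids: list
    disease_ids: list
    t_hat: np.ndarray | None = None
    t_train: np.ndarray | None = None
    loss_trace: list = field(default_factory=list)


# ------------------------------------------------------------ initialization

def init_params(config: Config, feat_dim_m: int, feat_dim_d: int,
                rng: np.random.Generator) -> dict:
    """Seeded Glorot-uniform parameter set for the full network.

    Weight matrices use fan-in/fan-out scaling; biases start at zero.
    Projection heads are per entity type, shared across that entity's two
    views, so the critic compares across views in a common space.
    """
    d = config.embed_dim
    d_f = d // config.n_heads
    h = config.proj_hidden
    dec_in = 2 * d if config.ablation == "hgclam_concat" else d
    params: dict = {}

    def W(name, fan_in, fan_out):
        params[name] = Tensor(glorot_uniform(rng, fan_in, fan_out),
                              requires_grad=True)

    def b(name, size):
        params[name] = Tensor(np.zeros((1, size)), requires_grad=True)

    for ent, feat in (("m", feat_dim_m), ("d", feat_dim_d)):
        for view in (1, 2):
            widths = [feat] + [d] * config.n_layers
            for layer in range(config.n_layers):
                W(f"hgcn_{ent}{view}_l{layer}", widths[layer],
                  widths[layer + 1])
        # projection head g (two-layer perceptron)
        W(f"g_{ent}_W1", d, h); b(f"g_{ent}_b1", h)
        W(f"g_{ent}_W2", h, d); b(f"g_{ent}_b2", d)
        # view-aware attention FNN: d -> d/2 -> 1
        W(f"va_{ent}_W1", d, max(d // 2, 1)); b(f"va_{ent}_b1", max(d // 2, 1))
        W(f"va_{ent}_W2", max(d // 2, 1), 1); b(f"va_{ent}_b2", 1)
        # inter-view attention heads
        for p in range(config.n_heads):
            W(f"att_{ent}_Wq{p}", d, d_f)
            W(f"att_{ent}_Wk{p}", d, d_f)
            W(f"att_{ent}_Wv{p}", d, d_f)
        W(f"att_{ent}_Wh", 2 * d_f, d); b(f"att_{ent}_bh", d)
        # matrix-completion decoder
        W(f"dec_{ent}_W", dec_in, d); b(f"dec_{ent}_b", d)
    return params


# ------------------------------------------------------------------ encoders

def hgcn_forward(X0, P, thetas: list) -> Tensor:
    """Stacked hyperedge convolutions ``X -> ReLU(P X Theta)``."""
    X = Tensor._lift(X0)
    P = Tensor._lift(P)
    if P.shape[0] != P.shape[1] or P.shape[1] != X.shape[0]:
        raise InvalidInputError(
            f"operator shape {P.shape} incompatible with features "
            f"{X.shape}")
    for theta in thetas:
        theta = Tensor._lift(theta)
        if theta.shape[0] != X.shape[1]:
            raise InvalidInputError(
                f"layer width {theta.shape[0]} does not chain from feature "
                f"width {X.shape[1]}")
        X = (P @ X @ theta).relu()
    return X


def project(params: dict, ent: str, Z) -> Tensor:
    """Two-layer perceptron projection head for the contrastive critic."""
    Z = Tensor._lift(Z)
    hidden = (Z @ params[f"g_{ent}_W1"] + params[f"g_{ent}_b1"]).relu()
    return hidden @ params[f"g_{ent}_W2"] + params[f"g_{ent}_b2"]


# --------------------------------------------------------------- contrastive

def _info_nce(C_av: Tensor, C_aa: Tensor, reduction: str) -> Tensor:
    """InfoNCE from temperature-scaled cosine logits: `C_av` anchor-vs-other
    view, `C_aa` anchor-vs-same view (diagonal excluded from negatives)."""
    m = C_av.shape[0]
    eye = np.eye(m)
    pos = (C_av * eye).sum(axis=1)                     # theta(u_i, v_i)/tau
    denom = C_av.exp().sum(axis=1) + (C_aa.exp() * (1.0 - eye)).sum(axis=1)
    losses = denom.log() - pos
    return losses.sum() if reduction == "sum" else losses.mean()


def contrastive_pair_loss(U, V, tau: float, projector=None,
                          reduction: str = "sum") -> Tensor:
    """InfoNCE loss anchored on `U` against positives in `V` and
    intra-/inter-view negatives (2m-1 denominator terms per anchor).

    `projector`, if given, maps embeddings into the critic space first.
    The critic is cosine similarity; zero-norm projections yield cosine 0.
    """
    U = Tensor._lift(U)
    V = Tensor._lift(V)
    m = U.shape[0]
    if m < 2:
        raise InvalidInputError("need at least 2 nodes for contrastive loss")
    if tau <= 0:
        raise InvalidInputError("tau must be > 0")
    Gu = projector(U) if projector is not None else U
    Gv = projector(V) if projector is not None else V
    Nu = Gu.l2_normalize(axis=1)
    Nv = Gv.l2_normalize(axis=1)
    Cuv = (Nu @ Nv.T) * (1.0 / tau)
    Cuu = (Nu @ Nu.T) * (1.0 / tau)
    return _info_nce(Cuv, Cuu, reduction)


def symmetric_contrastive_loss(Z1, Z2, tau: float, eta: float,
                               projector=None,
                               reduction: str = "sum") -> Tensor:
    """View-balanced contrastive loss: ``eta`` anchors on the KNN view,
    ``1-eta`` anchors on the K-means view."""
    if not 0.0 <= eta <= 1.0:
        raise InvalidInputError("eta must be in [0, 1]")
    Z1 = Tensor._lift(Z1)
    Z2 = Tensor._lift(Z2)
    if Z1.shape[0] < 2:
        raise InvalidInputError("need at least 2 nodes for contrastive loss")
    if tau <= 0:
        raise InvalidInputError("tau must be > 0")
    # project/normalize each view once; both anchoring directions share the
    # cross-view cosine matrix (transposed)
    G1 = projector(Z1) if projector is not None else Z1
    G2 = projector(Z2) if projector is not None else Z2
    N1 = G1.l2_normalize(axis=1)
    N2 = G2.l2_normalize(axis=1)
    C12 = (N1 @ N2.T) * (1.0 / tau)
    loss = 0.0
    if eta > 0:
        C11 = (N1 @ N1.T) * (1.0 / tau)
        loss = loss + eta * _info_nce(C12, C11, reduction)
    if eta < 1:
        C22 = (N2 @ N2.T) * (1.0 / tau)
        loss = loss + (1.0 - eta) * _info_nce(C12.T, C22, reduction)
    return loss


# ----------------------------------------------------------------- attention

def view_attention(Z1, Z2, params: dict, ent: str):
    """Scalar gate per view: global average pooling over the vertex axis,
    then a two-layer FNN (ReLU, Sigmoid).  Returns the gated embeddings
    ``ReLU(alpha * Z)`` and the two gates."""
    Z1 = Tensor._lift(Z1)
    Z2 = Tensor._lift(Z2)
    gates = []
    for Z in (Z1, Z2):
        pooled = Z.mean(axis=0, keepdims=True)                     # 1 x d
        hidden = (pooled @ params[f"va_{ent}_W1"]
                  + params[f"va_{ent}_b1"]).relu()
        gates.append((hidden @ params[f"va_{ent}_W2"]
                      + params[f"va_{ent}_b2"]).sigmoid())         # 1 x 1
    a1, a2 = gates
    return (Z1 * a1).relu(), (Z2 * a2).relu(), (a1, a2)


def _two_way_softmax(s1: Tensor, s2: Tensor):
    """Row-wise softmax over two score columns (numerically stabilized
    with a detached max shift)."""
    shift = Tensor(np.maximum(s1.data, s2.data))
    e1 = (s1 - shift).exp()
    e2 = (s2 - shift).exp()
    total = e1 + e2
    return e1 / total, e2 / total


def _attend(Zt1: Tensor, Zt2: Tensor, params: dict, ent: str,
            config: Config, collect_A: bool = False):
    """Vectorized per-node inter-view attention over all nodes at once.

    For each head, the two gated view vectors of a node are projected to
    queries/keys/values; a 2x2 row-stochastic attention matrix mixes the
    value vectors; head outputs are averaged, vectorized row-wise and
    passed through the output map.
    """
    N = config.n_heads
    d_f = config.embed_dim // N
    scale = 1.0 / np.sqrt(d_f)
    m = Zt1.shape[0]
    # all heads share the batched matmul; column block p is head p
    Wq = concat([params[f"att_{ent}_Wq{p}"] for p in range(N)], axis=1)
    Wk = concat([params[f"att_{ent}_Wk{p}"] for p in range(N)], axis=1)
    Wv = concat([params[f"att_{ent}_Wv{p}"] for p in range(N)], axis=1)
    Q1 = (Zt1 @ Wq).reshape(m, N, d_f)
    Q2 = (Zt2 @ Wq).reshape(m, N, d_f)
    K1 = (Zt1 @ Wk).reshape(m, N, d_f)
    K2 = (Zt2 @ Wk).reshape(m, N, d_f)
    V1 = (Zt1 @ Wv).reshape(m, N, d_f)
    V2 = (Zt2 @ Wv).reshape(m, N, d_f)
    s11 = (Q1 * K1).sum(axis=2, keepdims=True) * scale    # m x N x 1
    s12 = (Q1 * K2).sum(axis=2, keepdims=True) * scale
    s21 = (Q2 * K1).sum(axis=2, keepdims=True) * scale
    s22 = (Q2 * K2).sum(axis=2, keepdims=True) * scale
    A11, A12 = _two_way_softmax(s11, s12)
    A21, A22 = _two_way_softmax(s21, s22)
    inv_n = 1.0 / N
    # Eq-style head average of the 2 x d_f mixed value matrix per node
    O1 = ((A11 * V1 + A12 * V2).sum(axis=1)) * inv_n      # m x d_f
    O2 = ((A21 * V1 + A22 * V2).sum(axis=1)) * inv_n
    vec = concat([O1, O2], axis=1)                        # row-wise Vec
    H = vec @ params[f"att_{ent}_Wh"] + params[f"att_{ent}_bh"]
    if collect_A:
        A_first = (A11.data[0, 0, 0], A12.data[0, 0, 0],
                   A21.data[0, 0, 0], A22.data[0, 0, 0])
        return H, A_first
    return H


def inter_view_attention(z1, z2, params: dict, ent: str, config: Config):
    """Single-node inter-view attention: returns the 2x2 attention matrix
    (first head) and the integrated embedding vector."""
    Zt1 = Tensor._lift(np.atleast_2d(np.asarray(
        z1.data if isinstance(z1, Tensor) else z1, dtype=float)))
    Zt2 = Tensor._lift(np.atleast_2d(np.asarray(
        z2.data if isinstance(z2, Tensor) else z2, dtype=float)))
    H, A_parts = _attend(Zt1, Zt2, params, ent, config, collect_A=True)
    A11, A12, A21, A22 = (float(a) for a in A_parts)
    A = np.array([[A11, A12], [A21, A22]])
    return A, H.data[0]


def integrate_all(views_m: ViewEmbeddings, views_d: ViewEmbeddings,
                  params: dict, config: Config):
    """Fuse the gated views into one embedding per miRNA and per disease.

    The ``hgclam_concat`` ablation replaces attention fusion with plain
    concatenation of the two views.
    """
    if config.ablation == "hgclam_concat":
        H_m = concat([views_m.weighted_knn, views_m.weighted_kmeans], axis=1)
        G_d = concat([views_d.weighted_knn, views_d.weighted_kmeans], axis=1)
        return H_m, G_d
    H_m = _attend(views_m.weighted_knn, views_m.weighted_kmeans, params,
                  "m", config)
    G_d = _attend(views_d.weighted_knn, views_d.weighted_kmeans, params,
                  "d", config)
    return H_m, G_d


# ------------------------------------------------------------------- decoder

def reconstruct(H_m, G_d, params: dict) -> Tensor:
    """One-layer ReLU decoders to factor matrices, then ``X_m Y_d^T``."""
    H_m = Tensor._lift(H_m)
    G_d = Tensor._lift(G_d)
    if H_m.shape[1] != params["dec_m_W"].shape[0]:
        raise InvalidInputError("miRNA decoder input width mismatch")
    if G_d.shape[1] != params["dec_d_W"].shape[0]:
        raise InvalidInputError("disease decoder input width mismatch")
    X_m = (H_m @ params["dec_m_W"] + params["dec_m_b"]).relu()
    Y_d = (G_d @ params["dec_d_W"] + params["dec_d_b"]).relu()
    return X_m @ Y_d.T


def reconstruction_loss(T, T_hat, alpha: float,
                        omega: np.ndarray | None = None) -> Tensor:
    """Weighted Frobenius loss: ``(1-alpha)/2`` on observed entries,
    ``alpha/2`` on unobserved ones.

    `omega` defaults to ``T == 1``; evaluation positives masked out of the
    training matrix are zeros there and therefore weighted as unobserved.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must be in (0, 1)")
    T_arr = np.asarray(T.data if isinstance(T, Tensor) else T, dtype=float)
    if omega is None:
        omega = T_arr == 1
    omega = omega.astype(float)
    T_hat = Tensor._lift(T_hat)
    diff = Tensor(T_arr) - T_hat
    sq = diff * diff
    return ((1.0 - alpha) / 2.0) * (sq * omega).sum() \
        + (alpha / 2.0) * (sq * (1.0 - omega)).sum()


def total_loss(l_re: Tensor, l_cl_m, l_cl_d, lam: float,
               gam: float):
    """Composite objective and its breakdown."""
    if lam < 0 or gam < 0:
        raise InvalidInputError("lam and gam must be >= 0")
    l_cl_m = Tensor._lift(l_cl_m)
    l_cl_d = Tensor._lift(l_cl_d)
    total = l_re + lam * l_cl_m + gam * l_cl_d
    breakdown = LossBreakdown(
        reconstruction=float(l_re.data),
        contrastive_mirna=float(l_cl_m.data),
        contrastive_disease=float(l_cl_d.data),
        total=float(total.data),
    )
    return total, breakdown


# -------------------------------------------------------------- full forward

def forward(params: dict, config: Config, Xm, Xd, Pm1, Pm2, Pd1, Pd2,
            T_train: np.ndarray, omega: np.ndarray | None = None):
    """Full forward pass; returns (total loss Tensor, breakdown, T_hat)."""
    lam, gam = config.lam, config.gam
    if config.ablation == "hgcn_amir":
        lam = gam = 0.0

    views = {}
    for ent, X, P1, P2 in (("m", Xm, Pm1, Pm2), ("d", Xd, Pd1, Pd2)):
        thetas1 = [params[f"hgcn_{ent}1_l{l}"] for l in range(config.n_layers)]
        thetas2 = [params[f"hgcn_{ent}2_l{l}"] for l in range(config.n_layers)]
        Z1 = hgcn_forward(X, P1, thetas1)
        Z2 = hgcn_forward(X, P2, thetas2)
        ve = ViewEmbeddings(Z1, Z2)
        if config.ablation == "hgcl_ir":
            # no view gating: alpha fixed to 1
            ve.weighted_knn, ve.weighted_kmeans = Z1.relu(), Z2.relu()
            ve.alphas = (1.0, 1.0)
        else:
            ve.weighted_knn, ve.weighted_kmeans, ve.alphas = \
                view_attention(Z1, Z2, params, ent)
        views[ent] = ve

    if lam > 0:
        l_cl_m = symmetric_contrastive_loss(
            views["m"].view_knn, views["m"].view_kmeans, config.tau,
            config.eta, projector=lambda Z: project(params, "m", Z),
            reduction=config.contrastive_reduction)
    else:
        l_cl_m = Tensor(0.0)
    if gam > 0:
        l_cl_d = symmetric_contrastive_loss(
            views["d"].view_knn, views["d"].view_kmeans, config.tau,
            config.eta, projector=lambda Z: project(params, "d", Z),
            reduction=config.contrastive_reduction)
    else:
        l_cl_d = Tensor(0.0)

    H_m, G_d = integrate_all(views["m"], views["d"], params, config)
    T_hat = reconstruct(H_m, G_d, params)
    l_re = reconstruction_loss(T_train, T_hat, config.alpha, omega=omega)
    total, breakdown = total_loss(l_re, l_cl_m, l_cl_d, lam, gam)
    return total, breakdown, T_hat


# ---------------------------------------------------------------- checkpoint

def save_checkpoint(state: ModelState, path) -> None:
    """Single-file checkpoint: config snapshot + parameter arrays."""
    meta = {
        "magic": CHECKPOINT_MAGIC,
        "config": {f: getattr(state.config, f)
                   for f in state.config.__dataclass_fields__},
        "mirna_ids": state.mirna_ids,
        "disease_ids": state.disease_ids,
    }
    arrays = {f"param::{k}": v.data for k, v in state.params.items()}
    if state.t_hat is not None:
        arrays["t_hat"] = state.t_hat
    if state.t_train is not None:
        arrays["t_train"] = state.t_train
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"].tobytes()).decode())
        if meta.get("magic") != CHECKPOINT_MAGIC:
            raise InvalidInputError(f"{path}: not a recognized checkpoint")
        params = {k[len("param::"):]: Tensor(zf[k], requires_grad=True)
                  for k in zf.files if k.startswith("param::")}
        t_hat = zf["t_hat"] if "t_hat" in zf.files else None
        t_train = zf["t_train"] if "t_train" in zf.files else None
    return ModelState(params=params, config=Config(**meta["config"]),
                      mirna_ids=meta["mirna_ids"],
                      disease_ids=meta["disease_ids"],
                      t_hat=t_hat, t_train=t_train)
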