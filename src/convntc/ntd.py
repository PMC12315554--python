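"""Neural tensor decomposition (NTD): the nonlinear stage.

Each query cell (i, j, k) is represented twice: by trainable index embeddings
(one shared table for the two symmetric A-modes, one for the B-mode) and by
the frozen factor rows from the multilinear stage.  Both 1 x r x 3 stacks run
through a shared two-layer convolutional encoder — a (1, 3) filter bank mixing
the three mode vectors componentwise, then an (r, 1) filter bank collapsing
the rank axis, ReLU after each — which preserves the rank-one multiplicative
structure while adding nonlinearity.  Each branch's n_C-dimensional code feeds
its own single-layer FastKAN head: layer normalization, Gaussian radial basis
features on a fixed grid of centers, a linear read-out of the flattened RBF
features plus a SiLU-gated linear base path.  The two branch scores are mixed
by gamma and squashed with a logistic to give a probability; training
minimizes binary cross-entropy with Adam, mini-batches, a stratified
validation split and early stopping.

Implemented in NumPy with explicit reverse-mode gradients; everything is
seeded and deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .data_model import TripletDataset
from .mctd import FactorSet

__all__ = [
    "EmbeddingTables",
    "ConvEncoderParams",
    "FastKANParams",
    "NTDModel",
    "TrainConfig",
    "init_ntd_model",
    "embed_indices",
    "gather_factors",
    "conv_encode",
    "rbf_features",
    "fastkan_head",
    "predict_entry",
    "predict_batch",
    "bce_loss",
    "ntd_train",
]

_LN_EPS = 1e-5


@dataclass
class EmbeddingTables:
    """Trainable index embeddings; table_A is shared by both symmetric modes."""

    table_A: np.ndarray  # n_A x r
    table_B: np.ndarray  # n_B x r


@dataclass
class ConvEncoderParams:
    """Two-layer 2D conv stack on a 1 x r x 3 input (channels, height, width).

    filter1: (n_C, 3) kernels of shape (1, 3), 1 -> n_C channels.
    filter2: (n_C, n_C, r) kernels of shape (r, 1), n_C -> n_C channels.
    """

    filter1: np.ndarray
    bias1: np.ndarray
    filter2: np.ndarray
    bias2: np.ndarray
    use_bias: bool = True

    @property
    def n_channels(self) -> int:
        return self.filter1.shape[0]


@dataclass
class FastKANParams:
    """Single FastKAN layer: layernorm -> Gaussian RBF grid -> linear read-outs."""

    centers: np.ndarray      # n_g grid points
    bandwidth: float
    ln_scale: np.ndarray     # n_C layernorm gain
    ln_shift: np.ndarray     # n_C layernorm bias
    w_s: np.ndarray          # (n_C * n_g,) RBF read-out, or (1,) if scalar
    w_b: np.ndarray          # (n_C,) SiLU base read-out, or (1,) if scalar
    ln_affine: bool = True
    scalar_readout: bool = False  # mean-reduce each path, scale by a scalar

    @property
    def n_grid(self) -> int:
        return self.centers.shape[0]


@dataclass
class NTDModel:
    tables: EmbeddingTables
    encoder: ConvEncoderParams          # shared by both embedding streams
    head_index: FastKANParams
    head_factor: FastKANParams
    gamma: float
    factors: FactorSet                  # frozen multilinear factors
    finetune_factors: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class TrainConfig:
    batch_size: int = 256
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def init_ntd_model(factors: FactorSet, n_A: int, n_B: int,
                   n_channels: int = 16, n_grid: int = 8, gamma: float = 0.5,
                   seed: int = 0, use_bias: bool = True, ln_affine: bool = True,
                   scalar_readout: bool = False,
                   finetune_factors: bool = False) -> NTDModel:
    """Seeded initialization: N(0, 0.01) embeddings, He-scaled conv filters,
    RBF centers uniform on [-2, 2] with bandwidth equal to the grid spacing."""
    r = factors.rank
    rng = np.random.default_rng(seed)
    tables = EmbeddingTables(
        table_A=0.01 * rng.standard_normal((n_A, r)),
        table_B=0.01 * rng.standard_normal((n_B, r)),
    )
    encoder = ConvEncoderParams(
        filter1=rng.standard_normal((n_channels, 3)) * np.sqrt(2.0 / 3.0),
        bias1=np.zeros(n_channels),
        filter2=rng.standard_normal((n_channels, n_channels, r))
        * np.sqrt(2.0 / (n_channels * r)),
        bias2=np.zeros(n_channels),
        use_bias=use_bias,
    )

    def head() -> FastKANParams:
        centers = np.linspace(-2.0, 2.0, n_grid) if n_grid > 1 else np.zeros(1)
        bw = (centers[1] - centers[0]) if n_grid > 1 else 1.0
        n_ws = 1 if scalar_readout else n_channels * n_grid
        n_wb = 1 if scalar_readout else n_channels
        return FastKANParams(
            centers=centers, bandwidth=float(bw),
            ln_scale=np.ones(n_channels), ln_shift=np.zeros(n_channels),
            w_s=0.1 * rng.standard_normal(n_ws),
            w_b=0.1 * rng.standard_normal(n_wb),
            ln_affine=ln_affine, scalar_readout=scalar_readout,
        )

    return NTDModel(tables=tables, encoder=encoder,
                    head_index=head(), head_factor=head(),
                    gamma=gamma, factors=factors,
                    finetune_factors=finetune_factors)


# ---------------------------------------------------------------------------
# forward pieces (public single-sample views wrap the batched internals)


def embed_indices(t, tables: EmbeddingTables) -> np.ndarray:
    """Stack [table_A[i], table_A[j], table_B[k]] into a 1 x r x 3 array."""
    i, j, k = t
    if not (0 <= i < tables.table_A.shape[0] and 0 <= j < tables.table_A.shape[0]
            and 0 <= k < tables.table_B.shape[0]):
        raise IndexError(f"triple {t} out of range")
    return np.stack([tables.table_A[i], tables.table_A[j], tables.table_B[k]],
                    axis=-1)[None]


def gather_factors(t, factors: FactorSet) -> np.ndarray:
    """Stack [M[i], C[j], D[k]] into a 1 x r x 3 array (values frozen)."""
    i, j, k = t
    if not (0 <= i < factors.M.shape[0] and 0 <= j < factors.C.shape[0]
            and 0 <= k < factors.D.shape[0]):
        raise IndexError(f"triple {t} out of range")
    return np.stack([factors.M[i], factors.C[j], factors.D[k]], axis=-1)[None]


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def _conv_forward(Q: np.ndarray, p: ConvEncoderParams):
    """Batched encoder: Q (B, r, 3) -> code (B, n_C), with caches."""
    Z1 = np.einsum("bhw,cw->bch", Q, p.filter1)
    if p.use_bias:
        Z1 = Z1 + p.bias1[None, :, None]
    A1 = np.maximum(Z1, 0.0)
    Z2 = np.einsum("bch,och->bo", A1, p.filter2)
    if p.use_bias:
        Z2 = Z2 + p.bias2[None, :]
    A2 = np.maximum(Z2, 0.0)
    return A2, (Q, Z1, A1, Z2)


def _conv_backward(dA2: np.ndarray, cache, p: ConvEncoderParams, grads: dict):
    Q, Z1, A1, Z2 = cache
    dZ2 = dA2 * (Z2 > 0)
    grads["filter2"] += np.einsum("bo,bch->och", dZ2, A1)
    if p.use_bias:
        grads["bias2"] += dZ2.sum(axis=0)
    dA1 = np.einsum("bo,och->bch", dZ2, p.filter2)
    dZ1 = dA1 * (Z1 > 0)
    grads["filter1"] += np.einsum("bch,bhw->cw", dZ1, Q)
    if p.use_bias:
        grads["bias1"] += dZ1.sum(axis=(0, 2))
    return np.einsum("bch,cw->bhw", dZ1, p.filter1)


def _head_forward(q: np.ndarray, p: FastKANParams):
    """Batched FastKAN head: q (B, n_C) -> scalar score per sample, with caches."""
    mu = q.mean(axis=1, keepdims=True)
    var = q.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (q - mu) * inv_std
    u = xhat * p.ln_scale + p.ln_shift if p.ln_affine else xhat
    t = (u[:, :, None] - p.centers[None, None, :]) / p.bandwidth
    phi = np.exp(-t * t)                       # (B, n_C, n_g)
    flat = phi.reshape(q.shape[0], -1)         # feature-major (c, g) flattening
    if p.scalar_readout:
        y = p.w_b[0] * _silu(q).mean(axis=1) + p.w_s[0] * flat.mean(axis=1)
    else:
        y = _silu(q) @ p.w_b + flat @ p.w_s
    return y, (q, xhat, inv_std, u, phi, flat)


def _head_backward(dy: np.ndarray, cache, p: FastKANParams, grads: dict):
    q, xhat, inv_std, u, phi, flat = cache
    if p.scalar_readout:
        grads["w_s"] += np.array([flat.mean(axis=1) @ dy])
        grads["w_b"] += np.array([_silu(q).mean(axis=1) @ dy])
        dflat = np.outer(dy, np.full(flat.shape[1], p.w_s[0] / flat.shape[1]))
        base_w = np.full(q.shape[1], p.w_b[0] / q.shape[1])
    else:
        grads["w_s"] += flat.T @ dy
        grads["w_b"] += _silu(q).T @ dy
        dflat = dy[:, None] * p.w_s[None, :]
        base_w = p.w_b
    dphi = dflat.reshape(phi.shape)
    du = np.sum(dphi * phi * (-2.0 * (u[:, :, None] - p.centers[None, None, :])
                              / p.bandwidth ** 2), axis=2)
    if p.ln_affine:
        grads["ln_scale"] += (du * xhat).sum(axis=0)
        grads["ln_shift"] += du.sum(axis=0)
        dxhat = du * p.ln_scale
    else:
        dxhat = du
    m1 = dxhat.mean(axis=1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
    dq_ln = inv_std * (dxhat - m1 - xhat * m2)
    dq_base = dy[:, None] * base_w[None, :] * _silu_grad(q)
    return dq_ln + dq_base


def conv_encode(Q: np.ndarray, params: ConvEncoderParams) -> np.ndarray:
    """Encode a single 1 x r x 3 stack into a nonnegative length-n_C code."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] != 1 or Q.shape[2] != 3:
        raise ValueError(f"expected shape (1, r, 3), got {Q.shape}")
    A2, _ = _conv_forward(Q, params)
    return A2[0]


def rbf_features(x: np.ndarray, params: FastKANParams) -> np.ndarray:
    """Gaussian features exp(-((x_c - center_g) / bandwidth)^2), shape n_C x n_g."""
    x = np.asarray(x, dtype=float)
    t = (x[:, None] - params.centers[None, :]) / params.bandwidth
    return np.exp(-t * t)


def fastkan_head(q: np.ndarray, params: FastKANParams) -> float:
    """Single FastKAN layer score: SiLU base read-out + RBF read-out."""
    q = np.asarray(q, dtype=float)
    y, _ = _head_forward(q[None], params)
    return float(y[0])


def predict_entry(t, model: NTDModel) -> float:
    """Probability for one cell: sigmoid of the gamma-mixed branch scores."""
    return float(predict_batch(np.asarray([t]), model)[0])


def predict_batch(triples: np.ndarray, model: NTDModel) -> np.ndarray:
    triples = np.asarray(triples)
    s, _ = _forward(triples, model)
    return 1.0 / (1.0 + np.exp(-s))


def _gather_batch(triples: np.ndarray, model: NTDModel):
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    tab = model.tables
    Qi = np.stack([tab.table_A[i], tab.table_A[j], tab.table_B[k]], axis=-1)
    f = model.factors
    Qf = np.stack([f.M[i], f.C[j], f.D[k]], axis=-1)
    return Qi, Qf


def _forward(triples: np.ndarray, model: NTDModel):
    Qi, Qf = _gather_batch(triples, model)
    code_i, cache_ci = _conv_forward(Qi, model.encoder)
    code_f, cache_cf = _conv_forward(Qf, model.encoder)
    y_i, cache_hi = _head_forward(code_i, model.head_index)
    y_f, cache_hf = _head_forward(code_f, model.head_factor)
    s = model.gamma * y_f + (1.0 - model.gamma) * y_i
    return s, (triples, cache_ci, cache_cf, cache_hi, cache_hf)


# ---------------------------------------------------------------------------
# training


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with probability clamping."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _zero_grads(model: NTDModel) -> dict:
    enc, hi, hf = model.encoder, model.head_index, model.head_factor
    g = {
        "table_A": np.zeros_like(model.tables.table_A),
        "table_B": np.zeros_like(model.tables.table_B),
        "enc": {"filter1": np.zeros_like(enc.filter1), "bias1": np.zeros_like(enc.bias1),
                "filter2": np.zeros_like(enc.filter2), "bias2": np.zeros_like(enc.bias2)},
        "head_index": {"w_s": np.zeros_like(hi.w_s), "w_b": np.zeros_like(hi.w_b),
                       "ln_scale": np.zeros_like(hi.ln_scale),
                       "ln_shift": np.zeros_like(hi.ln_shift)},
        "head_factor": {"w_s": np.zeros_like(hf.w_s), "w_b": np.zeros_like(hf.w_b),
                        "ln_scale": np.zeros_like(hf.ln_scale),
                        "ln_shift": np.zeros_like(hf.ln_shift)},
    }
    if model.finetune_factors:
        g["factors"] = {"M": np.zeros_like(model.factors.M),
                        "C": np.zeros_like(model.factors.C),
                        "D": np.zeros_like(model.factors.D)}
    return g


def _loss_and_grads(triples: np.ndarray, y: np.ndarray, model: NTDModel):
    s, (trip, cache_ci, cache_cf, cache_hi, cache_hf) = _forward(triples, model)
    p = 1.0 / (1.0 + np.exp(-s))
    # numerically stable BCE-with-logits
    loss = float(np.mean(np.maximum(s, 0.0) - s * y + np.log1p(np.exp(-np.abs(s)))))
    B = len(y)
    ds = (p - y) / B

    grads = _zero_grads(model)
    dcode_i = _head_backward((1.0 - model.gamma) * ds, cache_hi,
                             model.head_index, grads["head_index"])
    dcode_f = _head_backward(model.gamma * ds, cache_hf,
                             model.head_factor, grads["head_factor"])
    dQi = _conv_backward(dcode_i, cache_ci, model.encoder, grads["enc"])
    dQf = _conv_backward(dcode_f, cache_cf, model.encoder, grads["enc"])

    i, j, k = trip[:, 0], trip[:, 1], trip[:, 2]
    np.add.at(grads["table_A"], i, dQi[:, :, 0])
    np.add.at(grads["table_A"], j, dQi[:, :, 1])
    np.add.at(grads["table_B"], k, dQi[:, :, 2])
    if model.finetune_factors:
        np.add.at(grads["factors"]["M"], i, dQf[:, :, 0])
        np.add.at(grads["factors"]["C"], j, dQf[:, :, 1])
        np.add.at(grads["factors"]["D"], k, dQf[:, :, 2])
    return loss, grads


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flat_params(model: NTDModel) -> dict[str, np.ndarray]:
    enc, hi, hf = model.encoder, model.head_index, model.head_factor
    p = {
        "table_A": model.tables.table_A, "table_B": model.tables.table_B,
        "enc.filter1": enc.filter1, "enc.bias1": enc.bias1,
        "enc.filter2": enc.filter2, "enc.bias2": enc.bias2,
        "hi.w_s": hi.w_s, "hi.w_b": hi.w_b,
        "hf.w_s": hf.w_s, "hf.w_b": hf.w_b,
    }
    if hi.ln_affine:
        p.update({"hi.ln_scale": hi.ln_scale, "hi.ln_shift": hi.ln_shift,
                  "hf.ln_scale": hf.ln_scale, "hf.ln_shift": hf.ln_shift})
    if model.finetune_factors:
        p.update({"f.M": model.factors.M, "f.C": model.factors.C,
                  "f.D": model.factors.D})
    return p


def _flat_grads(model: NTDModel, grads: dict) -> dict[str, np.ndarray]:
    g = {
        "table_A": grads["table_A"], "table_B": grads["table_B"],
        "enc.filter1": grads["enc"]["filter1"], "enc.bias1": grads["enc"]["bias1"],
        "enc.filter2": grads["enc"]["filter2"], "enc.bias2": grads["enc"]["bias2"],
        "hi.w_s": grads["head_index"]["w_s"], "hi.w_b": grads["head_index"]["w_b"],
        "hf.w_s": grads["head_factor"]["w_s"], "hf.w_b": grads["head_factor"]["w_b"],
    }
    if model.head_index.ln_affine:
        g.update({"hi.ln_scale": grads["head_index"]["ln_scale"],
                  "hi.ln_shift": grads["head_index"]["ln_shift"],
                  "hf.ln_scale": grads["head_factor"]["ln_scale"],
                  "hf.ln_shift": grads["head_factor"]["ln_shift"]})
    if model.finetune_factors:
        g.update({"f.M": grads["factors"]["M"], "f.C": grads["factors"]["C"],
                  "f.D": grads["factors"]["D"]})
    return g


def _stratified_split(labels: np.ndarray, val_fraction: float, rng) -> tuple:
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def ntd_train(train: TripletDataset, model: NTDModel, cfg: TrainConfig
              ) -> tuple[NTDModel, dict]:
    """Mini-batch Adam training with early stopping on a validation split.

    A stratified ``val_fraction`` of the training triplets is held out; the
    model with the best validation BCE is returned.  The log records per-epoch
    train and validation loss.  Raises if training data is single-class.
    """
    labels = np.asarray(train.labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    triples = np.asarray(train.triplets)
    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx = _stratified_split(labels, cfg.val_fraction, rng)
    X_tr, y_tr = triples[tr_idx], labels[tr_idx]
    X_va, y_va = triples[va_idx], labels[va_idx]

    opt = _Adam(cfg.learning_rate)
    log = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = copy.deepcopy(_flat_params(model))
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(y_tr))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            loss, grads = _loss_and_grads(X_tr[sel], y_tr[sel], model)
            opt.step(_flat_params(model), _flat_grads(model, grads))
            ep_loss += loss
            n_batches += 1
        val_loss = bce_loss(predict_batch(X_va, model), y_va)
        log["train_loss"].append(ep_loss / max(n_batches, 1))
        log["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = copy.deepcopy(_flat_params(model))
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    # restore best-validation weights in place
    live = _flat_params(model)
    for name, arr in best_params.items():
        live[name][...] = arr
    log["best_val_loss"] = best_val
    log["n_epochs"] = len(log["train_loss"])
    return model, log
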