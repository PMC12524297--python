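"""Attention-based autoencoder + mixture-of-experts hazard classifier.

The network consumes a standardized 516-dim feature vector x and is trained
in two stages:

1. Autoencoder with attention.  Encoder: h1 = ReLU(W1 x + b1),
   z = ReLU(W2 h1 + b2).  Attention over the latent code:
   u = tanh(Wa z + ba), α = softmax(u), z′ = α ⊙ z.  The decoder maps z′
   back to feature space and the whole stack minimizes mean-squared
   reconstruction error L_A = mean((x − x̂)²).
2. Mixture of experts on the frozen attention-weighted latent code z′.
   Each of M experts is a small feed-forward net ending in a sigmoid,
   y_m ∈ [0, 1]; a gating network produces g = softmax(h(z′)) and the
   mixture prediction y = Σ_m g_m·y_m is trained with binary cross-entropy.

Everything is plain NumPy: forward passes, analytic gradients (verified
against finite differences in the test suite) and an Adam optimizer.
Training is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import TrainingConfig
from .featurize import (
    FEATURE_COLUMNS,
    FeaturizationResult,
    MoleculeRecord,
    StandardizationParams,
    apply_standardizer,
    featurize_dataset,
    fit_standardizer,
)

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when a training loss becomes NaN or infinite."""


def stable_softmax(u: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax with max-subtraction; overflow-free for any finite input."""
    shifted = u - np.max(u, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderParams:
    """Weights of encoder (W1, W2), attention (Wa, ba) and decoder (W3, W4)."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (latent, hidden)
    b2: np.ndarray  # (latent,)
    Wa: np.ndarray  # (latent, latent)
    ba: np.ndarray  # (latent,)
    W3: np.ndarray  # (hidden, latent)
    b3: np.ndarray  # (hidden,)
    W4: np.ndarray  # (n_in, hidden)
    b4: np.ndarray  # (n_in,)

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W2.shape[0]

    @classmethod
    def init(cls, n_in: int, hidden_dim: int, latent_dim: int,
             rng: np.random.Generator) -> "AutoencoderParams":
        def he(shape):
            return rng.normal(0.0, np.sqrt(2.0 / shape[1]), shape)

        def xavier(shape):
            return rng.normal(0.0, np.sqrt(1.0 / shape[1]), shape)

        return cls(
            W1=he((hidden_dim, n_in)), b1=np.zeros(hidden_dim),
            W2=he((latent_dim, hidden_dim)), b2=np.zeros(latent_dim),
            Wa=xavier((latent_dim, latent_dim)), ba=np.zeros(latent_dim),
            W3=he((hidden_dim, latent_dim)), b3=np.zeros(hidden_dim),
            W4=xavier((n_in, hidden_dim)), b4=np.zeros(n_in),
        )

    def to_dict(self) -> dict[str, np.ndarray]:
        """Named views of the live parameter arrays (not copies)."""
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)}


@dataclass
class MoEParams:
    """M expert networks (latent → expert_hidden → sigmoid) plus gating."""

    Wg: np.ndarray  # (M, latent) gating scores
    bg: np.ndarray  # (M,)
    U: np.ndarray   # (M, expert_hidden, latent) expert first layer
    c: np.ndarray   # (M, expert_hidden)
    v: np.ndarray   # (M, expert_hidden) expert output layer
    d: np.ndarray   # (M,)

    @property
    def n_experts(self) -> int:
        return self.Wg.shape[0]

    @classmethod
    def init(cls, latent_dim: int, expert_hidden: int, n_experts: int,
             rng: np.random.Generator) -> "MoEParams":
        if n_experts < 1:
            raise ValueError("need at least one expert")
        return cls(
            Wg=rng.normal(0.0, np.sqrt(1.0 / latent_dim), (n_experts, latent_dim)),
            bg=np.zeros(n_experts),
            U=rng.normal(0.0, np.sqrt(2.0 / latent_dim),
                         (n_experts, expert_hidden, latent_dim)),
            c=np.zeros((n_experts, expert_hidden)),
            v=rng.normal(0.0, np.sqrt(1.0 / expert_hidden),
                         (n_experts, expert_hidden)),
            d=np.zeros(n_experts),
        )

    def to_dict(self) -> dict[str, np.ndarray]:
        """Named views of the live parameter arrays (not copies)."""
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)}


@dataclass
class LossTrace:
    """Per-epoch training/validation losses for one training phase."""

    train: list[float] = field(default_factory=list)
    val: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Forward operations (spec surface; accept a single vector or a batch)
# ---------------------------------------------------------------------------

def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def encode(x: np.ndarray, p: AutoencoderParams) -> np.ndarray:
    """z = ReLU(W2·ReLU(W1 x + b1) + b2); entries are non-negative."""
    X, single = _as_batch(x)
    if X.shape[1] != p.n_in:
        raise ValueError(f"expected {p.n_in} features, got {X.shape[1]}")
    H1 = _relu(X @ p.W1.T + p.b1)
    Z = _relu(H1 @ p.W2.T + p.b2)
    return Z[0] if single else Z


def attention_weights(z: np.ndarray, Wa: np.ndarray,
                      ba: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """u = tanh(Wa z + ba); α = softmax(u); z′ = α ⊙ z.

    Returns (α, z′); α sums to 1 over the latent dimensions.
    """
    Z, single = _as_batch(z)
    if Z.shape[1] != Wa.shape[1]:
        raise ValueError(f"latent size {Z.shape[1]} does not match Wa {Wa.shape}")
    U = np.tanh(Z @ Wa.T + ba)
    alpha = stable_softmax(U, axis=1)
    Zp = alpha * Z
    if single:
        return alpha[0], Zp[0]
    return alpha, Zp


def decode(z_prime: np.ndarray, p: AutoencoderParams) -> np.ndarray:
    """Reconstruct the weighted latent code back to feature space."""
    Zp, single = _as_batch(z_prime)
    if Zp.shape[1] != p.latent_dim:
        raise ValueError(f"expected latent dim {p.latent_dim}, got {Zp.shape[1]}")
    H3 = _relu(Zp @ p.W3.T + p.b3)
    Xhat = H3 @ p.W4.T + p.b4
    return Xhat[0] if single else Xhat


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """MSE averaged over samples and feature dimensions; 0 iff X == X_hat."""
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.mean((X - X_hat) ** 2))


def encode_weighted(x: np.ndarray, p: AutoencoderParams) -> np.ndarray:
    """Full encoder path x → z → z′ (the MoE input)."""
    z = encode(x, p)
    _, zp = attention_weights(z, p.Wa, p.ba)
    return zp


def gate(z_prime: np.ndarray, m: MoEParams) -> np.ndarray:
    """Gating weights g = softmax over M expert scores; sums to 1."""
    Zp, single = _as_batch(z_prime)
    G = stable_softmax(Zp @ m.Wg.T + m.bg, axis=1)
    return G[0] if single else G


def expert_outputs(z_prime: np.ndarray, m: MoEParams) -> np.ndarray:
    """Per-expert probabilities y_m = sigmoid(v_m·ReLU(U_m z′ + c_m) + d_m)."""
    Zp, single = _as_batch(z_prime)
    # (N, M, E): batch × expert × expert-hidden
    B = np.einsum("nl,mel->nme", Zp, m.U) + m.c
    H = _relu(B)
    S = np.einsum("nme,me->nm", H, m.v) + m.d
    Y = _sigmoid(S)
    return Y[0] if single else Y


def moe_predict(z_prime: np.ndarray, m: MoEParams) -> np.ndarray | float:
    """Mixture probability y = Σ_m g_m·y_m ∈ [0, 1]."""
    Zp, single = _as_batch(z_prime)
    G = gate(Zp, m)
    Y = expert_outputs(Zp, m)
    y = np.sum(G * Y, axis=1)
    return float(y[0]) if single else y


# ---------------------------------------------------------------------------
# Losses with analytic gradients
# ---------------------------------------------------------------------------

def _ae_loss_and_grads(p: AutoencoderParams,
                       X: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
    """Reconstruction MSE and its gradient w.r.t. every autoencoder weight."""
    N, D = X.shape
    A1 = X @ p.W1.T + p.b1
    H1 = _relu(A1)
    A2 = H1 @ p.W2.T + p.b2
    Z = _relu(A2)
    S = Z @ p.Wa.T + p.ba
    U = np.tanh(S)
    alpha = stable_softmax(U, axis=1)
    Zp = alpha * Z
    A3 = Zp @ p.W3.T + p.b3
    H3 = _relu(A3)
    Xhat = H3 @ p.W4.T + p.b4
    loss = float(np.mean((X - Xhat) ** 2))

    dXhat = 2.0 * (Xhat - X) / (N * D)
    gW4 = dXhat.T @ H3
    gb4 = dXhat.sum(axis=0)
    dH3 = dXhat @ p.W4
    dA3 = dH3 * (A3 > 0)
    gW3 = dA3.T @ Zp
    gb3 = dA3.sum(axis=0)
    dZp = dA3 @ p.W3
    # z′ = α ⊙ z: gradient splits into the α path (through softmax/tanh)
    # and the direct z path.
    dAlpha = dZp * Z
    dZ = dZp * alpha
    dU = alpha * (dAlpha - np.sum(dAlpha * alpha, axis=1, keepdims=True))
    dS = dU * (1.0 - U ** 2)
    gWa = dS.T @ Z
    gba = dS.sum(axis=0)
    dZ = dZ + dS @ p.Wa
    dA2 = dZ * (A2 > 0)
    gW2 = dA2.T @ H1
    gb2 = dA2.sum(axis=0)
    dH1 = dA2 @ p.W2
    dA1 = dH1 * (A1 > 0)
    gW1 = dA1.T @ X
    gb1 = dA1.sum(axis=0)
    grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
             "Wa": gWa, "ba": gba, "W3": gW3, "b3": gb3,
             "W4": gW4, "b4": gb4}
    return loss, grads


def bce_loss(y_prob: np.ndarray, y_true: np.ndarray,
             eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of mixture probabilities."""
    yp = np.clip(np.asarray(y_prob, dtype=np.float64), eps, 1.0 - eps)
    t = np.asarray(y_true, dtype=np.float64)
    return float(-np.mean(t * np.log(yp) + (1.0 - t) * np.log(1.0 - yp)))


def _moe_loss_and_grads(
    m: MoEParams, Zp: np.ndarray, t: np.ndarray, want_dzp: bool = False,
) -> tuple[float, dict[str, np.ndarray], np.ndarray | None]:
    """BCE of the mixture output with gradients w.r.t. MoE weights.

    With want_dzp the gradient w.r.t. the latent input z′ is also returned
    (used by the optional joint fine-tuning stage).
    """
    N = Zp.shape[0]
    eps = 1e-12
    Gs = Zp @ m.Wg.T + m.bg
    G = stable_softmax(Gs, axis=1)
    B = np.einsum("nl,mel->nme", Zp, m.U) + m.c
    H = _relu(B)
    S = np.einsum("nme,me->nm", H, m.v) + m.d
    Y = _sigmoid(S)
    y = np.sum(G * Y, axis=1)
    yc = np.clip(y, eps, 1.0 - eps)
    t = np.asarray(t, dtype=np.float64)
    loss = float(-np.mean(t * np.log(yc) + (1.0 - t) * np.log(1.0 - yc)))

    dy = (-(t / yc) + (1.0 - t) / (1.0 - yc)) / N
    dY = dy[:, None] * G
    dG = dy[:, None] * Y
    dGs = G * (dG - np.sum(dG * G, axis=1, keepdims=True))
    gWg = dGs.T @ Zp
    gbg = dGs.sum(axis=0)
    dS = dY * Y * (1.0 - Y)
    gv = np.einsum("nm,nme->me", dS, H)
    gd = dS.sum(axis=0)
    dH = dS[:, :, None] * m.v[None, :, :]
    dB = dH * (B > 0)
    gU = np.einsum("nme,nl->mel", dB, Zp)
    gc = dB.sum(axis=0)
    grads = {"Wg": gWg, "bg": gbg, "U": gU, "c": gc, "v": gv, "d": gd}
    dZp = None
    if want_dzp:
        dZp = dGs @ m.Wg + np.einsum("nme,mel->nl", dB, m.U)
    return loss, grads, dZp


# ---------------------------------------------------------------------------
# Optimizer and training loops
# ---------------------------------------------------------------------------

class Adam:
    """Adam over a named dict of parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain stochastic gradient descent (available as optimizer: sgd)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3):
        self.params = params
        self.lr = lr

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            self.params[k] -= self.lr * g


def _make_optimizer(cfg: TrainingConfig, params: dict[str, np.ndarray]):
    if cfg.optimizer == "adam":
        return Adam(params, lr=cfg.learning_rate)
    return SGD(params, lr=cfg.learning_rate)


def _check_finite(loss: float, phase: str, epoch: int) -> None:
    if not np.isfinite(loss):
        raise TrainingDivergedError(
            f"{phase} loss became {loss} at epoch {epoch}; "
            "lower the learning rate or check the input scaling"
        )


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_autoencoder(
    X_train: np.ndarray,
    X_val: np.ndarray,
    cfg: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AutoencoderParams, LossTrace]:
    """Train the attention autoencoder on standardized features.

    Returns the fitted parameters and per-epoch full-batch train/val MSE.
    Deterministic given cfg.seed (when rng is not supplied).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = AutoencoderParams.init(X_train.shape[1], cfg.hidden_dim,
                               cfg.latent_dim, rng)
    params = p.to_dict()
    p = AutoencoderParams(**params)  # share the arrays the optimizer updates
    opt = _make_optimizer(cfg, params)
    trace = LossTrace()
    for epoch in range(cfg.ae_epochs):
        for idx in _minibatches(X_train.shape[0], cfg.batch_size, rng):
            _, grads = _ae_loss_and_grads(p, X_train[idx])
            opt.step(grads)
        train_loss, _ = _ae_loss_and_grads(p, X_train)
        val_loss = reconstruction_loss(X_val, decode(encode_weighted(X_val, p), p))
        _check_finite(train_loss, "autoencoder", epoch)
        trace.train.append(train_loss)
        trace.val.append(val_loss)
    return p, trace


def train_moe(
    Zp_train: np.ndarray,
    y_train: np.ndarray,
    Zp_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MoEParams, LossTrace]:
    """Train the mixture of experts on attention-weighted latent codes."""
    Zp_train = np.asarray(Zp_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m = MoEParams.init(Zp_train.shape[1], cfg.expert_hidden, cfg.n_experts, rng)
    params = m.to_dict()
    m = MoEParams(**params)
    opt = _make_optimizer(cfg, params)
    trace = LossTrace()
    for epoch in range(cfg.moe_epochs):
        for idx in _minibatches(Zp_train.shape[0], cfg.batch_size, rng):
            _, grads, _ = _moe_loss_and_grads(m, Zp_train[idx], y_train[idx])
            opt.step(grads)
        train_loss, _, _ = _moe_loss_and_grads(m, Zp_train, y_train)
        val_loss = bce_loss(moe_predict(Zp_val, m), y_val)
        _check_finite(train_loss, "mixture-of-experts", epoch)
        trace.train.append(train_loss)
        trace.val.append(val_loss)
    return m, trace


def joint_finetune(
    ae: AutoencoderParams,
    moe: MoEParams,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> LossTrace:
    """Optional third stage: backprop BCE end to end (encoder+attention+MoE).

    Updates ae and moe in place; the decoder is left untouched.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    enc_names = ("W1", "b1", "W2", "b2", "Wa", "ba")
    ae_params = ae.to_dict()
    ae_live = {k: ae_params[k] for k in enc_names}
    for k in enc_names:  # re-bind so the optimizer mutates the caller's arrays
        setattr(ae, k, ae_params[k])
    moe_params = moe.to_dict()
    for k, v in moe_params.items():
        setattr(moe, k, v)
    merged = {**{f"ae.{k}": v for k, v in ae_live.items()},
              **{f"moe.{k}": v for k, v in moe_params.items()}}
    opt = _make_optimizer(cfg, merged)
    trace = LossTrace()
    for epoch in range(cfg.finetune_epochs):
        for idx in _minibatches(X_train.shape[0], cfg.batch_size, rng):
            Xb, tb = X_train[idx], y_train[idx]
            A1 = Xb @ ae.W1.T + ae.b1
            H1 = _relu(A1)
            A2 = H1 @ ae.W2.T + ae.b2
            Z = _relu(A2)
            S = Z @ ae.Wa.T + ae.ba
            U = np.tanh(S)
            alpha = stable_softmax(U, axis=1)
            Zp = alpha * Z
            _, moe_grads, dZp = _moe_loss_and_grads(moe, Zp, tb, want_dzp=True)
            dAlpha = dZp * Z
            dZ = dZp * alpha
            dU = alpha * (dAlpha - np.sum(dAlpha * alpha, axis=1, keepdims=True))
            dS = dU * (1.0 - U ** 2)
            dZ = dZ + dS @ ae.Wa
            dA2 = dZ * (A2 > 0)
            dH1 = dA2 @ ae.W2
            dA1 = dH1 * (A1 > 0)
            grads = {
                "ae.W1": dA1.T @ Xb, "ae.b1": dA1.sum(0),
                "ae.W2": dA2.T @ H1, "ae.b2": dA2.sum(0),
                "ae.Wa": dS.T @ Z, "ae.ba": dS.sum(0),
            }
            grads.update({f"moe.{k}": v for k, v in moe_grads.items()})
            opt.step(grads)
        loss = bce_loss(moe_predict(encode_weighted(X_train, ae), moe), y_train)
        _check_finite(loss, "fine-tuning", epoch)
        trace.train.append(loss)
    return trace


# ---------------------------------------------------------------------------
# Full model bundle
# ---------------------------------------------------------------------------

@dataclass
class HazChemNet:
    """Trained pipeline: standardizer + autoencoder + MoE + config."""

    standardizer: StandardizationParams
    autoencoder: AutoencoderParams
    moe: MoEParams
    config: TrainingConfig
    columns: tuple[str, ...] = FEATURE_COLUMNS
    ae_trace: LossTrace | None = None
    moe_trace: LossTrace | None = None

    @classmethod
    def fit(
        cls,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        cfg: TrainingConfig | None = None,
        columns: tuple[str, ...] = FEATURE_COLUMNS,
    ) -> "HazChemNet":
        """Train the full two-stage pipeline on RAW (unstandardized) features.

        The standardizer is fitted on X_train only and applied unchanged to
        the validation data.  Without an explicit validation set a 10%
        tail of a seeded shuffle of the training data is held out for the
        loss traces.
        """
        cfg = cfg or TrainingConfig()
        rng = np.random.default_rng(cfg.seed)
        X_train = np.asarray(X_train, dtype=np.float64)
        y_train = np.asarray(y_train, dtype=np.int64)
        if X_val is None:
            n = X_train.shape[0]
            order = rng.permutation(n)
            n_val = max(1, n // 10)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_train, X_val = X_train[tr_idx], X_train[val_idx]
            y_train, y_val = y_train[tr_idx], y_train[val_idx]
        std = fit_standardizer(X_train, fit_on="train")
        Xs_train = apply_standardizer(X_train, std)
        Xs_val = apply_standardizer(X_val, std)
        ae, ae_trace = train_autoencoder(Xs_train, Xs_val, cfg, rng=rng)
        Zp_train = encode_weighted(Xs_train, ae)
        Zp_val = encode_weighted(Xs_val, ae)
        moe, moe_trace = train_moe(Zp_train, y_train, Zp_val,
                                   np.asarray(y_val, dtype=np.int64), cfg,
                                   rng=rng)
        if cfg.joint_finetune and cfg.finetune_epochs > 0:
            joint_finetune(ae, moe, Xs_train, y_train, cfg, rng=rng)
        return cls(standardizer=std, autoencoder=ae, moe=moe, config=cfg,
                   columns=tuple(columns), ae_trace=ae_trace,
                   moe_trace=moe_trace)

    def predict_proba(self, X_raw: np.ndarray) -> np.ndarray:
        """Hazard probabilities for raw (unstandardized) feature rows."""
        X_raw = np.asarray(X_raw, dtype=np.float64)
        if X_raw.size == 0:
            return np.empty(0)
        Xs = apply_standardizer(X_raw, self.standardizer)
        return np.atleast_1d(moe_predict(encode_weighted(Xs, self.autoencoder),
                                         self.moe))

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Binary class: 1 (hazardous) iff probability ≥ decision threshold.

        Ties at the threshold classify as hazardous, favouring recall.
        """
        return (self.predict_proba(X_raw)
                >= self.config.decision_threshold).astype(np.int64)

    def predict_records(
        self, records: list[MoleculeRecord]
    ) -> tuple[FeaturizationResult, np.ndarray, np.ndarray]:
        """Featurize and classify records; rejects carry no prediction."""
        feats = featurize_dataset(records)
        proba = self.predict_proba(feats.X)
        classes = (proba >= self.config.decision_threshold).astype(np.int64)
        return feats, proba, classes

    # -- serialization ------------------------------------------------------

    def schema_hash(self) -> str:
        return hashlib.sha256(",".join(self.columns).encode()).hexdigest()[:12]

    def save(self, directory: str | Path) -> None:
        """Write weights (one .npy per tensor), config, standardizer, manifest."""
        d = Path(directory)
        (d / "weights").mkdir(parents=True, exist_ok=True)
        for prefix, params in (("ae", self.autoencoder.to_dict()),
                               ("moe", self.moe.to_dict())):
            for name, arr in params.items():
                np.save(d / "weights" / f"{prefix}_{name}.npy", arr)
        (d / "config.json").write_text(json.dumps(self.config.to_dict(),
                                                  indent=2))
        (d / "standardizer.json").write_text(self.standardizer.to_json())
        manifest = {
            "seed": self.config.seed,
            "config_hash": self.config.hash(),
            "feature_schema_hash": self.schema_hash(),
            "columns": list(self.columns),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "HazChemNet":
        d = Path(directory)
        cfg = TrainingConfig(**json.loads((d / "config.json").read_text()))
        std = StandardizationParams.from_json(
            (d / "standardizer.json").read_text())
        manifest = json.loads((d / "manifest.json").read_text())

        def load_group(prefix: str, names: tuple[str, ...]) -> dict:
            return {n: np.load(d / "weights" / f"{prefix}_{n}.npy")
                    for n in names}

        ae = AutoencoderParams(**load_group(
            "ae", ("W1", "b1", "W2", "b2", "Wa", "ba", "W3", "b3", "W4", "b4")))
        moe = MoEParams(**load_group("moe", ("Wg", "bg", "U", "c", "v", "d")))
        return cls(standardizer=std, autoencoder=ae, moe=moe, config=cfg,
                   columns=tuple(manifest["columns"]))
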