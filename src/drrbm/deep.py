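"""Two-block deep residual RBM classifiers (DRRBM, DRSVM, ADRSVM).

The network maps a feature vector x in R^d through two residual blocks

    x1 = x  + W2 . sigma(W1 . LayerNorm(x))
    x2 = x1 + W4 . sigma(W3 . LayerNorm(x1))

where W1, W3 are d x d/2 and W2, W4 are d/2 x d weight matrices
initialised by greedy layer-wise RBM pretraining, sigma is ReLU, and each
block opens with layer normalisation.  An optional feature-attention gate
reweights the second block's output; the head is either a softmax layer
(DRRBM) or a one-vs-rest squared-hinge margin layer (DRSVM / ADRSVM).
Fine-tuning is end-to-end gradient descent with Adam.

All forward passes after pretraining are deterministic mean-field
computations; stochasticity enters only through seeded initialisation,
pretraining Gibbs chains and mini-batch shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rbm import RBM, RBMTrainConfig, fit_rbm, hidden_activation

__all__ = [
    "LayerNormParams",
    "ResidualBlock",
    "AttentionGate",
    "DeepModel",
    "DeepTrainConfig",
    "layer_norm",
    "block_forward",
    "attention_forward",
    "softmax_head",
    "predict",
    "hinge_head_loss",
    "forward",
    "pretrain_deep",
    "finetune",
    "VARIANTS",
]

_FORMAT_VERSION = 1

#: head kind / attention flag per published variant name
VARIANTS = {
    "DRRBM": ("softmax", False),
    "DRSVM": ("hinge", False),
    "ADRSVM": ("hinge", True),
}


@dataclass
class LayerNormParams:
    gain: np.ndarray
    bias: np.ndarray
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.gain.shape != self.bias.shape:
            raise ValueError("gain and bias must have equal length")

    @classmethod
    def identity(cls, d: int) -> "LayerNormParams":
        return cls(np.ones(d), np.zeros(d))


@dataclass
class ResidualBlock:
    """One residual block: d -> d/2 -> d with an entry layer norm and ReLU."""

    W_in: np.ndarray   # (d, d/2)
    W_out: np.ndarray  # (d/2, d)
    ln: LayerNormParams

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        d, h = self.W_in.shape
        if d % 2 != 0 or h != d // 2:
            raise ValueError(f"W_in must be d x d/2 with d even, got {self.W_in.shape}")
        if self.W_out.shape != (h, d):
            raise ValueError(f"W_out must be {(h, d)}, got {self.W_out.shape}")
        if self.ln.gain.shape != (d,):
            raise ValueError("layer-norm parameters must have length d")

    @property
    def d(self) -> int:
        return self.W_in.shape[0]


@dataclass
class AttentionGate:
    """Feature-wise soft attention over the d features of the second block's output.

    Each feature i carries an embedding row W_score[i]; its score is
    s_i = v_score . tanh(x2_i * W_score[i]).  alpha = softmax(s) and the
    gated output is d * (alpha * x2), so uniform attention (W_score = 0,
    or the gate disabled) is the exact identity.
    """

    W_score: np.ndarray  # (d, d_att)
    v_score: np.ndarray  # (d_att,)
    enabled: bool = True

    def __post_init__(self) -> None:
        self.W_score = np.asarray(self.W_score, dtype=float)
        self.v_score = np.asarray(self.v_score, dtype=float)
        if self.W_score.ndim != 2 or self.v_score.shape != (self.W_score.shape[1],):
            raise ValueError("W_score must be d x d_att and v_score length d_att")

    @classmethod
    def disabled_gate(cls, d: int, d_att: int = 1) -> "AttentionGate":
        return cls(np.zeros((d, d_att)), np.zeros(d_att), enabled=False)


@dataclass
class DeepModel:
    block1: ResidualBlock
    block2: ResidualBlock
    attention: AttentionGate
    head_kind: str          # "softmax" or "hinge"
    W_head: np.ndarray      # (d, k)
    b_head: np.ndarray      # (k,)

    def __post_init__(self) -> None:
        self.W_head = np.asarray(self.W_head, dtype=float)
        self.b_head = np.asarray(self.b_head, dtype=float)
        if self.head_kind not in ("softmax", "hinge"):
            raise ValueError(f"unknown head kind {self.head_kind!r}")
        if self.block1.d != self.block2.d or self.W_head.shape[0] != self.block1.d:
            raise ValueError("block and head dimensions disagree")
        if self.k < 2:
            raise ValueError("need at least two classes")

    @property
    def d(self) -> int:
        return self.block1.d

    @property
    def k(self) -> int:
        return self.W_head.shape[1]

    def copy(self) -> "DeepModel":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- serialization --

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "kind": "deep_model",
            "d": self.d,
            "k": self.k,
            "head_kind": self.head_kind,
            "blocks": [
                {
                    "W_in": b.W_in.tolist(),
                    "W_out": b.W_out.tolist(),
                    "ln_gain": b.ln.gain.tolist(),
                    "ln_bias": b.ln.bias.tolist(),
                    "ln_epsilon": b.ln.epsilon,
                }
                for b in (self.block1, self.block2)
            ],
            "attention": {
                "W_score": self.attention.W_score.tolist(),
                "v_score": self.attention.v_score.tolist(),
                "enabled": bool(self.attention.enabled),
            },
            "W_head": self.W_head.tolist(),
            "b_head": self.b_head.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeepModel":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {d.get('format_version')!r}")
        blocks = [
            ResidualBlock(
                np.array(b["W_in"], dtype=float),
                np.array(b["W_out"], dtype=float),
                LayerNormParams(
                    np.array(b["ln_gain"], dtype=float),
                    np.array(b["ln_bias"], dtype=float),
                    b["ln_epsilon"],
                ),
            )
            for b in d["blocks"]
        ]
        att = d["attention"]
        return cls(
            blocks[0],
            blocks[1],
            AttentionGate(
                np.array(att["W_score"], dtype=float),
                np.array(att["v_score"], dtype=float),
                att["enabled"],
            ),
            d["head_kind"],
            np.array(d["W_head"], dtype=float),
            np.array(d["b_head"], dtype=float),
        )


@dataclass
class DeepTrainConfig:
    """Pretraining + fine-tuning settings (study defaults: batch 100,
    600 fine-tuning epochs, learning rate 1e-3, Adam)."""

    pretrain: RBMTrainConfig = field(default_factory=lambda: RBMTrainConfig(learning_rate=0.05, epochs=15))
    finetune_epochs: int = 600
    finetune_lr: float = 1e-3
    batch_size: int = 100
    hinge_C: float = 1.0
    weight_decay: float = 1e-2
    attention_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.finetune_lr <= 0 or self.hinge_C <= 0:
            raise ValueError("rates must be positive")


# ---------------------------------------------------------------------------
# forward primitives (accept a single vector or a batch in the leading axis)
# ---------------------------------------------------------------------------


def layer_norm(x: np.ndarray, p: LayerNormParams) -> np.ndarray:
    """Per-sample standardisation over the feature axis, then gain and bias."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)  # population variance
    xhat = (x - mu) / np.sqrt(var + p.epsilon)
    return p.gain * xhat + p.bias


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def block_forward(block: ResidualBlock, x: np.ndarray) -> np.ndarray:
    """x + W_out . ReLU(W_in . LayerNorm(x)) — the residual block map."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != block.d:
        raise ValueError(f"input length {x.shape[-1]} != block width {block.d}")
    h = layer_norm(x, block.ln)
    return x + _relu(h @ block.W_in) @ block.W_out


def attention_forward(gate: AttentionGate, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (gated output, attention weights alpha); alpha sums to 1 per sample."""
    x2 = np.asarray(x2, dtype=float)
    d = x2.shape[-1]
    if not gate.enabled:
        alpha = np.full_like(x2, 1.0 / d)
        return x2.copy(), alpha
    if gate.W_score.shape[0] != d:
        raise ValueError(f"input length {d} != gate width {gate.W_score.shape[0]}")
    T = np.tanh(x2[..., None] * gate.W_score)  # (..., d, d_att)
    s = T @ gate.v_score                       # (..., d)
    s = s - s.max(axis=-1, keepdims=True)
    alpha = np.exp(s)
    alpha /= alpha.sum(axis=-1, keepdims=True)
    return d * alpha * x2, alpha


def _softmax(o: np.ndarray) -> np.ndarray:
    o = o - o.max(axis=-1, keepdims=True)
    p = np.exp(o)
    return p / p.sum(axis=-1, keepdims=True)


def softmax_head(x2: np.ndarray, model: DeepModel) -> np.ndarray:
    """Class probabilities p = softmax(x2 W_head + b_head)."""
    return _softmax(np.asarray(x2, dtype=float) @ model.W_head + model.b_head)


def predict(p: np.ndarray) -> np.ndarray | int:
    """1-based argmax; ties broken by the lowest class index."""
    p = np.asarray(p, dtype=float)
    if p.shape[-1] == 0:
        raise ValueError("empty score vector")
    idx = p.argmax(axis=-1) + 1  # np.argmax already returns the first maximum
    return idx if p.ndim > 1 else int(idx)


def hinge_head_loss(scores: np.ndarray, y: int, C: float) -> float:
    """One-vs-rest squared hinge: C * sum_j max(0, 1 - t_j s_j)^2, t_y = +1, else -1."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[-1]
    if not (1 <= y <= k):
        raise ValueError(f"label {y} outside 1..{k}")
    t = -np.ones(k)
    t[y - 1] = 1.0
    margins = np.maximum(0.0, 1.0 - t * scores)
    return float(C * np.sum(margins**2))


def forward(model: DeepModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray | int]:
    """Full forward pass: blocks, optional attention, head.

    Returns (class probabilities for the softmax head / margin scores for
    the hinge head, predicted 1-based class).
    """
    x1 = block_forward(model.block1, x)
    x2 = block_forward(model.block2, x1)
    x2, _ = attention_forward(model.attention, x2)
    o = x2 @ model.W_head + model.b_head
    out = _softmax(o) if model.head_kind == "softmax" else o
    return out, predict(out)


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------


def _clip01(x: np.ndarray) -> np.ndarray:
    # pretraining treats inputs as Bernoulli means, so clamp to [0, 1]
    return np.clip(x, 0.0, 1.0)


def _pretrain_block(
    data: np.ndarray, config: DeepTrainConfig, rng: np.random.Generator
) -> tuple[ResidualBlock, np.ndarray]:
    """Fit the two stacked RBMs of one block; return the block and its output."""
    d = data.shape[1]
    ln = LayerNormParams.identity(d)
    x_ln = _clip01(layer_norm(data, ln))

    cfg = RBMTrainConfig(
        learning_rate=config.pretrain.learning_rate,
        cd_k=config.pretrain.cd_k,
        epochs=config.pretrain.epochs,
        batch_size=config.pretrain.batch_size,
        seed=int(rng.integers(2**31)),
    )
    rbm_in = RBM.initialise(d, d // 2, rng)
    rbm_in, _ = fit_rbm(rbm_in, x_ln, cfg)
    hidden = hidden_activation(rbm_in, x_ln)

    cfg2 = RBMTrainConfig(
        learning_rate=config.pretrain.learning_rate,
        cd_k=config.pretrain.cd_k,
        epochs=config.pretrain.epochs,
        batch_size=config.pretrain.batch_size,
        seed=int(rng.integers(2**31)),
    )
    rbm_out = RBM.initialise(d // 2, d, rng)
    rbm_out, _ = fit_rbm(rbm_out, hidden, cfg2)

    block = ResidualBlock(rbm_in.W.copy(), rbm_out.W.copy(), ln)
    return block, block_forward(block, data)


def pretrain_deep(
    data: np.ndarray,
    config: DeepTrainConfig,
    n_classes: int = 5,
    head_kind: str = "hinge",
    attention: bool = True,
) -> DeepModel:
    """Greedy layer-wise RBM pretraining of both residual blocks.

    Block 1's W_in is the weight matrix of a d-visible / d/2-hidden RBM fit
    on the layer-normalised data; its W_out is a d/2-visible / d-hidden RBM
    fit on the first RBM's hidden activations.  Block 2 repeats the scheme
    on block 1's output.  Attention and head weights start at small random
    values (attention scores at zero, making the gate an identity).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 1:
        raise ValueError("empty pretraining data")
    d = data.shape[1]
    if d % 2 != 0:
        raise ValueError(f"feature dimension must be even, got {d}")
    rng = np.random.default_rng(config.seed)

    block1, out1 = _pretrain_block(data, config, rng)
    block2, _ = _pretrain_block(_clip01(out1), config, rng)

    if attention:
        gate = AttentionGate(np.zeros((d, config.attention_dim)),
                             rng.normal(0.0, 0.01, config.attention_dim), enabled=True)
    else:
        gate = AttentionGate.disabled_gate(d)
    W_head = rng.normal(0.0, 0.01, size=(d, n_classes))
    b_head = np.zeros(n_classes)
    return DeepModel(block1, block2, gate, head_kind, W_head, b_head)


# ---------------------------------------------------------------------------
# end-to-end fine-tuning (manual backprop + Adam)
# ---------------------------------------------------------------------------


def _params(model: DeepModel) -> dict[str, np.ndarray]:
    p = {
        "b1.W_in": model.block1.W_in, "b1.W_out": model.block1.W_out,
        "b1.g": model.block1.ln.gain, "b1.beta": model.block1.ln.bias,
        "b2.W_in": model.block2.W_in, "b2.W_out": model.block2.W_out,
        "b2.g": model.block2.ln.gain, "b2.beta": model.block2.ln.bias,
        "W_head": model.W_head, "b_head": model.b_head,
    }
    if model.attention.enabled:
        p["att.W"] = model.attention.W_score
        p["att.v"] = model.attention.v_score
    return p


def _ln_forward(x, g, beta, eps):
    mu = x.mean(axis=1, keepdims=True)
    std = np.sqrt(x.var(axis=1, keepdims=True) + eps)
    xhat = (x - mu) / std
    return g * xhat + beta, xhat, std


def _ln_backward(dh, g, xhat, std):
    dg = (dh * xhat).sum(axis=0)
    dbeta = dh.sum(axis=0)
    dxhat = dh * g
    dx = (dxhat - dxhat.mean(axis=1, keepdims=True)
          - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)) / std
    return dx, dg, dbeta


def _block_fb(x, Wi, Wo, g, beta, eps):
    """Forward through one block; returns output and a closure computing gradients."""
    h, xhat, std = _ln_forward(x, g, beta, eps)
    z = h @ Wi
    r = _relu(z)
    y = x + r @ Wo

    def backward(dy):
        dWo = r.T @ dy
        dz = (dy @ Wo.T) * (z > 0)
        dWi = h.T @ dz
        dx_ln, dg, dbeta = _ln_backward(dz @ Wi.T, g, xhat, std)
        return dy + dx_ln, {"W_in": dWi, "W_out": dWo, "g": dg, "beta": dbeta}

    return y, backward


def _attention_fb(x, W, v):
    d = x.shape[1]
    T = np.tanh(x[:, :, None] * W[None, :, :])
    s = T @ v
    s = s - s.max(axis=1, keepdims=True)
    alpha = np.exp(s)
    alpha /= alpha.sum(axis=1, keepdims=True)
    y = d * alpha * x

    def backward(dy):
        dalpha = d * dy * x
        dx = d * dy * alpha
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dpre = ds[:, :, None] * v[None, None, :] * (1.0 - T**2)
        dx += (dpre * W[None, :, :]).sum(axis=2)
        dW = (dpre * x[:, :, None]).sum(axis=0)
        dv = (T * ds[:, :, None]).sum(axis=(0, 1))
        return dx, dW, dv

    return y, backward


#: weight matrices subject to the L2 / margin penalty (biases, layer-norm
#: and attention parameters are exempt, the usual convention)
_DECAYED = ("b1.W_in", "b1.W_out", "b2.W_in", "b2.W_out", "W_head")


def _loss_and_grads(model: DeepModel, X: np.ndarray, y: np.ndarray, C: float,
                    l2: float = 0.0):
    """Mean loss over the batch and gradients for every trainable array.

    ``l2`` is the coefficient of the margin-regularisation term
    (l2/2) * sum of squared weight-matrix entries that turns the hinge
    data term into the usual SVM trade-off objective; zero for the
    softmax head."""
    B, k = X.shape[0], model.k
    eps1, eps2 = model.block1.ln.epsilon, model.block2.ln.epsilon
    x1, back1 = _block_fb(X, model.block1.W_in, model.block1.W_out,
                          model.block1.ln.gain, model.block1.ln.bias, eps1)
    x2, back2 = _block_fb(x1, model.block2.W_in, model.block2.W_out,
                          model.block2.ln.gain, model.block2.ln.bias, eps2)
    if model.attention.enabled:
        xa, back_att = _attention_fb(x2, model.attention.W_score, model.attention.v_score)
    else:
        xa, back_att = x2, None

    o = xa @ model.W_head + model.b_head
    if model.head_kind == "softmax":
        p = _softmax(o)
        rows = np.arange(B)
        loss = float(-np.mean(np.log(np.clip(p[rows, y - 1], 1e-300, None))))
        do = p.copy()
        do[rows, y - 1] -= 1.0
        do /= B
    else:
        t = -np.ones((B, k))
        t[np.arange(B), y - 1] = 1.0
        m = np.maximum(0.0, 1.0 - t * o)
        loss = float(C * np.mean(np.sum(m**2, axis=1)))
        do = C * 2.0 * m * (-t) / B

    grads = {"W_head": xa.T @ do, "b_head": do.sum(axis=0)}
    dxa = do @ model.W_head.T
    if back_att is not None:
        dx2, dW_att, dv_att = back_att(dxa)
        grads["att.W"] = dW_att
        grads["att.v"] = dv_att
    else:
        dx2 = dxa
    dx1, g2 = back2(dx2)
    _, g1 = back1(dx1)
    for name, g in g2.items():
        grads[f"b2.{name}"] = g
    for name, g in g1.items():
        grads[f"b1.{name}"] = g
    if l2 > 0.0:
        mats = {"b1.W_in": model.block1.W_in, "b1.W_out": model.block1.W_out,
                "b2.W_in": model.block2.W_in, "b2.W_out": model.block2.W_out,
                "W_head": model.W_head}
        for name in _DECAYED:
            loss += 0.5 * l2 * float(np.sum(mats[name] ** 2))
            grads[name] = grads[name] + l2 * mats[name]
    return loss, grads


def finetune(
    model: DeepModel,
    X: np.ndarray,
    y: np.ndarray,
    config: DeepTrainConfig,
    callback=None,
) -> tuple[DeepModel, np.ndarray]:
    """End-to-end Adam fine-tuning; returns (trained model, per-epoch mean loss).

    Minimises cross-entropy for the softmax head or the mean one-vs-rest
    squared hinge loss for the hinge head.  Deterministic given
    ``config.seed``.  ``callback(epoch, model)``, if given, is invoked after
    every epoch (e.g. for validation tracking); it must not mutate the model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if y.min() < 1 or y.max() > model.k:
        raise ValueError(f"labels must lie in 1..{model.k}")
    if X.shape[1] != model.d:
        raise ValueError(f"feature dimension {X.shape[1]} != model d={model.d}")
    if config.finetune_epochs == 0:
        return model.copy(), np.empty(0)

    out = model.copy()
    params = _params(out)
    m_t = {k: np.zeros_like(v) for k, v in params.items()}
    v_t = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    lr = config.finetune_lr
    rng = np.random.default_rng(config.seed)
    N = X.shape[0]
    # SVM-style trade-off objective (lambda/2)||W||^2 + C * mean hinge for
    # the hinge head; for the softmax head the same lambda acts as ordinary
    # L2 regularisation of the weight matrices
    l2 = config.weight_decay
    trace = np.empty(config.finetune_epochs)
    step = 0
    for epoch in range(config.finetune_epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = _loss_and_grads(out, X[idx], y[idx], config.hinge_C, l2)
            losses.append(loss)
            step += 1
            for name, p in params.items():
                g = grads[name]
                m_t[name] = beta1 * m_t[name] + (1 - beta1) * g
                v_t[name] = beta2 * v_t[name] + (1 - beta2) * g**2
                mhat = m_t[name] / (1 - beta1**step)
                vhat = v_t[name] / (1 - beta2**step)
                p -= lr * mhat / (np.sqrt(vhat) + adam_eps)
        trace[epoch] = float(np.mean(losses))
        if callback is not None:
            callback(epoch, out)
    return out, trace
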