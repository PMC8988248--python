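"""Bernoulli restricted Boltzmann machines.

An RBM is a bipartite energy-based model over binary visible units ``u``
(length ``m``) and binary hidden units ``l`` (length ``n``) with no
intra-layer connections:

    E(u, l) = - a.u - b.l - u' W l
    p(u, l) = exp(-E(u, l)) / Z

Training maximises the visible marginal log-likelihood.  The data
expectation of the gradient is computed analytically (hidden units
marginalise in closed form); the model expectation is approximated by
k-step contrastive divergence (:func:`cd_update`) or computed exactly by
enumeration for small machines (:func:`exact_gradient`), which serves as
the test oracle.

Survey features normalised to [0, 1] are accepted on the data side as
Bernoulli means: conditionals are evaluated at the real-valued inputs
rather than at binary samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RBM",
    "ParamDelta",
    "RBMTrainConfig",
    "energy",
    "partition_function",
    "joint_probability",
    "hidden_activation",
    "visible_activation",
    "free_energy",
    "log_likelihood",
    "cd_update",
    "exact_gradient",
    "fit_rbm",
]

#: Largest m + n for which exhaustive enumeration over 2**(m+n) states is allowed.
ENUMERATION_LIMIT = 20

_FORMAT_VERSION = 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow warnings for large |x|
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBM:
    """Weights ``W`` (m visible x n hidden), visible biases ``a``, hidden biases ``b``."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be a 2-D matrix")
        m, n = self.W.shape
        if self.a.shape != (m,) or self.b.shape != (n,):
            raise ValueError(
                f"bias shapes {self.a.shape}/{self.b.shape} do not match W {self.W.shape}"
            )
        if not (np.isfinite(self.W).all() and np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("RBM parameters must be finite")

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBM":
        return RBM(self.W.copy(), self.a.copy(), self.b.copy())

    @classmethod
    def initialise(cls, m: int, n: int, rng: np.random.Generator, weight_sd: float = 0.01) -> "RBM":
        """Gaussian(0, weight_sd) weights, zero biases — the conventional start."""
        return cls(rng.normal(0.0, weight_sd, size=(m, n)), np.zeros(m), np.zeros(n))

    # -- serialization (plain-text JSON-compatible container, bit-exact) --

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "kind": "rbm",
            "m": self.m,
            "n": self.n,
            "W": self.W.tolist(),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBM":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported RBM format version: {d.get('format_version')!r}")
        rbm = cls(np.array(d["W"], dtype=float), np.array(d["a"], dtype=float), np.array(d["b"], dtype=float))
        if rbm.m != d["m"] or rbm.n != d["n"]:
            raise ValueError("stored shapes disagree with stored matrices")
        return rbm


@dataclass
class ParamDelta:
    """Parameter increments (dW, da, db) as produced by one learning step."""

    dW: np.ndarray
    da: np.ndarray
    db: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.dW.ravel(), self.da, self.db])


@dataclass
class RBMTrainConfig:
    """Contrastive-divergence training settings.

    ``learning_rate`` is the step size applied to the CD statistics;
    ``cd_k`` the number of Gibbs steps; ``batch_size`` defaults to 100.
    """

    learning_rate: float = 1e-3
    cd_k: int = 1
    epochs: int = 10
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.cd_k < 1:
            raise ValueError("cd_k must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _check_config(rbm: RBM, u: np.ndarray, l: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    l = np.asarray(l, dtype=float)
    if u.shape[-1] != rbm.m or l.shape[-1] != rbm.n:
        raise ValueError(f"configuration shapes {u.shape}/{l.shape} do not match RBM ({rbm.m},{rbm.n})")
    return u, l


def energy(rbm: RBM, u: np.ndarray, l: np.ndarray) -> float:
    """E(u, l) = -a.u - b.l - u' W l for one joint configuration."""
    u, l = _check_config(rbm, u, l)
    return float(-(rbm.a @ u) - (rbm.b @ l) - u @ rbm.W @ l)


def _all_states(bits: int) -> np.ndarray:
    """All 2**bits binary vectors, one per row, lexicographic."""
    idx = np.arange(2**bits)
    return ((idx[:, None] >> np.arange(bits - 1, -1, -1)) & 1).astype(float)


def _guard_enumeration(rbm: RBM) -> None:
    if rbm.m + rbm.n > ENUMERATION_LIMIT:
        raise ValueError(
            f"enumeration over 2**{rbm.m + rbm.n} states exceeds the m+n <= {ENUMERATION_LIMIT} guard"
        )


def _energy_table(rbm: RBM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(visible states, hidden states, energy matrix over all joint configs)."""
    U = _all_states(rbm.m)
    L = _all_states(rbm.n)
    # E[v, h] for every pair of rows
    E = -(U @ rbm.a)[:, None] - (L @ rbm.b)[None, :] - U @ rbm.W @ L.T
    return U, L, E


def partition_function(rbm: RBM) -> float:
    """Z = sum over all 2**(m+n) configurations of exp(-E); exact enumeration."""
    _guard_enumeration(rbm)
    _, _, E = _energy_table(rbm)
    return float(np.exp(-E).sum())


def joint_probability(rbm: RBM, u: np.ndarray, l: np.ndarray) -> float:
    """p(u, l) = exp(-E(u, l)) / Z via exact enumeration of Z."""
    Z = partition_function(rbm)
    return float(np.exp(-energy(rbm, u, l)) / Z)


def hidden_activation(rbm: RBM, u: np.ndarray) -> np.ndarray:
    """p(l_j = 1 | u) = logistic(b_j + sum_i u_i w_ij); accepts a batch in the leading axis."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != rbm.m:
        raise ValueError(f"visible vector length {u.shape[-1]} != m={rbm.m}")
    return _sigmoid(u @ rbm.W + rbm.b)


def visible_activation(rbm: RBM, l: np.ndarray) -> np.ndarray:
    """p(u_i = 1 | l) = logistic(a_i + sum_j w_ij l_j); accepts a batch in the leading axis."""
    l = np.asarray(l, dtype=float)
    if l.shape[-1] != rbm.n:
        raise ValueError(f"hidden vector length {l.shape[-1]} != n={rbm.n}")
    return _sigmoid(l @ rbm.W.T + rbm.a)


def free_energy(rbm: RBM, u: np.ndarray) -> np.ndarray:
    """F(u) = -a.u - sum_j softplus(b_j + u.W_j); log p(u) = -F(u) - log Z."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    pre = u @ rbm.W + rbm.b
    return -(u @ rbm.a) - np.logaddexp(0.0, pre).sum(axis=1)


def log_likelihood(rbm: RBM, data: np.ndarray) -> float:
    """Exact mean visible-marginal log-likelihood (enumeration of Z; small RBMs only)."""
    _guard_enumeration(rbm)
    logZ = np.log(partition_function(rbm))
    return float(np.mean(-free_energy(rbm, data) - logZ))


def _validate_batch(rbm: RBM, batch: np.ndarray) -> np.ndarray:
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] < 1:
        raise ValueError("batch must contain at least one row")
    if batch.shape[1] != rbm.m:
        raise ValueError(f"batch has {batch.shape[1]} columns, expected m={rbm.m}")
    if batch.min() < 0 or batch.max() > 1:
        raise ValueError("batch values must lie in [0, 1] (Bernoulli means)")
    return batch


def cd_update(
    rbm: RBM, batch: np.ndarray, config: RBMTrainConfig, rng: np.random.Generator
) -> ParamDelta:
    """One contrastive-divergence (CD-k) step on a mini-batch.

    Hidden states are sampled binary to drive the Gibbs chain; the
    sufficient statistics use activation probabilities, and reconstructed
    visible layers use probabilities rather than samples (the standard
    variance-reduction convention).  Statistics are means over the batch.
    """
    v0 = _validate_batch(rbm, batch)
    B = v0.shape[0]
    h0 = hidden_activation(rbm, v0)

    h_prob = h0
    v = v0
    for _ in range(config.cd_k):
        h_sample = (rng.random(h_prob.shape) < h_prob).astype(float)
        v = visible_activation(rbm, h_sample)
        h_prob = hidden_activation(rbm, v)

    eps = config.learning_rate
    dW = eps * (v0.T @ h0 - v.T @ h_prob) / B
    da = eps * (v0.mean(axis=0) - v.mean(axis=0))
    db = eps * (h0.mean(axis=0) - h_prob.mean(axis=0))
    return ParamDelta(dW, da, db)


def exact_gradient(rbm: RBM, batch: np.ndarray) -> ParamDelta:
    """Exact log-likelihood gradient (unit learning rate) by enumeration.

    Data term marginalises hidden units analytically; model term sums over
    all visible configurations weighted by their marginal probability.
    """
    _guard_enumeration(rbm)
    v0 = _validate_batch(rbm, batch)
    B = v0.shape[0]
    h0 = hidden_activation(rbm, v0)

    U = _all_states(rbm.m)
    logp = -free_energy(rbm, U)
    logp -= np.log(np.exp(logp - logp.max()).sum()) + logp.max()  # normalise
    pv = np.exp(logp)
    hU = hidden_activation(rbm, U)

    dW = v0.T @ h0 / B - (U * pv[:, None]).T @ hU
    da = v0.mean(axis=0) - pv @ U
    db = h0.mean(axis=0) - pv @ hU
    return ParamDelta(dW, da, db)


def reconstruction_error(rbm: RBM, data: np.ndarray) -> float:
    """Mean squared error between data and its one-step mean-field reconstruction."""
    h = hidden_activation(rbm, data)
    v = visible_activation(rbm, h)
    return float(np.mean((np.atleast_2d(data) - v) ** 2))


def fit_rbm(
    rbm: RBM,
    data: np.ndarray,
    config: RBMTrainConfig,
    update_fn=cd_update,
) -> tuple[RBM, np.ndarray]:
    """Mini-batch CD training; returns the trained RBM and per-epoch reconstruction error.

    Deterministic given ``config.seed``.  ``update_fn`` may be replaced
    (e.g. by a wrapper around :func:`exact_gradient`) for oracle-driven
    training in tests.
    """
    data = _validate_batch(rbm, data)
    rng = np.random.default_rng(config.seed)
    out = rbm.copy()
    N = data.shape[0]
    errors = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        for start in range(0, N, config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            delta = update_fn(out, batch, config, rng)
            out.W += delta.dW
            out.a += delta.da
            out.b += delta.db
        errors[epoch] = reconstruction_error(out, data)
    return out, errors
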