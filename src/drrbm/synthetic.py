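"""Synthetic CGSS-like survey tables with ordinal class structure.

The generator emulates the shape of a happiness-survey extract: 105
numeric features (cycling through binary, 1-5 ordinal, 1-7 ordinal and
positive-continuous "income" archetypes), five ordinal happiness classes
whose latent means are equally spaced along one latent axis, MCAR missing
cells, and the -8 "can't answer" sentinel in the label column.

Draw order from the single seeded PCG64 stream (reproducibility contract):
(1) latent-to-feature mixing matrix, (2) class labels, (3) latent noise,
(4) feature noise.  Missingness injection opens its own stream derived
from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import LabeledTable

__all__ = [
    "SyntheticConfig",
    "generate",
    "inject_missingness",
    "class_means_latent",
    "archetype_columns",
]


@dataclass
class SyntheticConfig:
    n_samples: int = 1200
    n_features: int = 105
    n_classes: int = 5
    class_separation: float = 4.0  # spacing of adjacent class means, units of noise_sd=1
    latent_dim: int = 10
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    sentinel_rate: float = 0.02
    class_probs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_probs is None:
            self.class_probs = np.full(self.n_classes, 1.0 / self.n_classes)
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        if abs(self.class_probs.sum() - 1.0) > 1e-9 or (self.class_probs < 0).any():
            raise ValueError("class_probs must be a probability vector")
        if not (0 <= self.missing_rate < 1 and 0 <= self.sentinel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.noise_sd <= 0 or self.class_separation < 0:
            raise ValueError("noise_sd must be positive, class_separation non-negative")


def class_means_latent(config: SyntheticConfig) -> np.ndarray:
    """Latent class means: ordinal classes equally spaced along latent axis 0."""
    k = config.n_classes
    means = np.zeros((k, config.latent_dim))
    means[:, 0] = (np.arange(1, k + 1) - (k + 1) / 2.0) * config.class_separation
    return means


_ARCHETYPES = ("binary", "ordinal5", "ordinal7", "income")


def archetype_columns(n_features: int) -> dict[str, list[str]]:
    """Column names per survey archetype (columns cycle through the four
    archetypes in order); used to attach the survey imputation rules."""
    out: dict[str, list[str]] = {a: [] for a in _ARCHETYPES}
    for j in range(n_features):
        out[_ARCHETYPES[j % 4]].append(f"f{j + 1:03d}")
    return out


def _quantile_bins(g: np.ndarray, levels: int) -> np.ndarray:
    """Monotone quantile binning of a column into codes 1..levels."""
    qs = np.quantile(g, np.linspace(0, 1, levels + 1)[1:-1])
    return np.digitize(g, qs) + 1.0


def _squash_features(F: np.ndarray) -> np.ndarray:
    """Map raw continuous features onto survey archetypes, column-cycled:
    binary {1,2}, ordinal 1-5, ordinal 1-7, positive continuous income.

    Ordinal codes come from quantile binning (a monotone transform, so
    class-conditional ordering in the latent projection is preserved)."""
    out = np.empty_like(F)
    scale = np.maximum(F.std(axis=0), 1e-12)
    G = F / scale  # roughly unit-scale per column
    for j in range(F.shape[1]):
        g = G[:, j]
        kind = j % 4
        if kind == 0:      # binary coded 1/2 (gender-style)
            out[:, j] = _quantile_bins(g, 2)
        elif kind == 1:    # 1..5 ordinal (satisfaction-style)
            out[:, j] = _quantile_bins(g, 5)
        elif kind == 2:    # 1..7 ordinal (frequency-style)
            out[:, j] = _quantile_bins(g, 7)
        else:              # positive continuous (income-style, mildly lognormal)
            out[:, j] = np.exp(1.0 + 0.25 * g) * 1e4
    return out


def generate(config: SyntheticConfig) -> LabeledTable:
    """Draw a complete labeled table (no missingness; see inject_missingness)."""
    rng = np.random.default_rng(config.seed)
    p, q = config.n_features, config.latent_dim
    A = rng.normal(0.0, 1.0 / np.sqrt(q), size=(q, p))          # mixing matrix
    labels = rng.choice(config.n_classes, size=config.n_samples, p=config.class_probs) + 1
    means = class_means_latent(config)
    Z = means[labels - 1] + rng.normal(0.0, config.noise_sd, size=(config.n_samples, q))
    F = Z @ A + rng.normal(0.0, 0.5 * config.noise_sd, size=(config.n_samples, p))
    X = _squash_features(F)
    names = [f"f{j + 1:03d}" for j in range(p)]
    return LabeledTable(X, names, labels.astype(int))


def inject_missingness(table: LabeledTable, config: SyntheticConfig) -> LabeledTable:
    """MCAR-mask feature cells at missing_rate; replace labels by the -8
    sentinel at sentinel_rate.  Sentinels appear only in the label column."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = table.copy()
    mask = rng.random(out.X.shape) < config.missing_rate
    out.missing_mask = out.missing_mask | mask
    out.X = out.X.copy()
    out.X[mask] = np.nan
    sent = rng.random(out.n) < config.sentinel_rate
    y = out.y.copy()
    y[sent] = -8
    out.y = y
    return out
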