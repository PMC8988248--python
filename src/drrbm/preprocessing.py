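"""Survey-table preprocessing: sentinel recoding, rule-based imputation,
min-max normalisation, PCA reduction, and seeded ratio splits.

The pipeline mirrors common practice for CGSS-style survey extracts: the
"can't answer" sentinel (-8) in the happiness label is recoded to the
neutral class 3; missing feature cells are filled per-column (a constant,
the observed column mean, or zero); features are scaled to [0, 1] with
statistics fitted on the training split only; PCA is fitted on the
training split and applied to both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "LabeledTable",
    "ImputationRules",
    "NormalizationState",
    "PCAState",
    "recode_sentinels",
    "impute_missing",
    "fit_minmax",
    "apply_minmax",
    "pca_reduce",
    "apply_pca",
    "shuffle_split",
    "read_table",
    "write_table",
]

LABEL_COLUMN = "happiness"


@dataclass
class LabeledTable:
    """Feature matrix X (N x p) with column names, integer labels y (1..k
    after recoding, possibly sentinel-coded before), and a missingness mask."""

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    missing_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.X)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.X.shape != self.missing_mask.shape:
            raise ValueError("missing_mask shape must match X")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match X rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "LabeledTable":
        return LabeledTable(self.X.copy(), list(self.feature_names), self.y.copy(),
                            self.missing_mask.copy())

    def column(self, name: str) -> np.ndarray:
        if name not in self.feature_names:
            raise KeyError(f"unknown column {name!r}")
        return self.X[:, self.feature_names.index(name)]


def read_table(path, label_column: str = LABEL_COLUMN, sep: str = ",") -> LabeledTable:
    """Read a delimited text table with a header row; empty cells are missing."""
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in file")
    y = df[label_column].to_numpy()
    feats = [c for c in df.columns if c != label_column]
    X = df[feats].to_numpy(dtype=float)
    return LabeledTable(X, feats, y.astype(int))


def write_table(table: LabeledTable, path, label_column: str = LABEL_COLUMN, sep: str = ",") -> None:
    X = table.X.copy()
    X[table.missing_mask] = np.nan
    df = pd.DataFrame(X, columns=table.feature_names)
    df[label_column] = table.y
    df.to_csv(path, sep=sep, index=False)


def recode_sentinels(
    table: LabeledTable,
    sentinel_map: Mapping[float, float],
    columns: list[str] | None = None,
) -> LabeledTable:
    """Replace sentinel codes by their mapped values.

    By default the map applies to the label column only (the survey's -8
    "can't answer" code recodes to the neutral class); pass feature column
    names to recode those instead.
    """
    out = table.copy()
    if columns is None:
        y = out.y.astype(float)
        for code, value in sentinel_map.items():
            y[y == code] = value
        out.y = y.astype(int)
    else:
        for name in columns:
            col = out.column(name)  # raises on unknown names
            j = out.feature_names.index(name)
            for code, value in sentinel_map.items():
                out.X[col == code, j] = value
    return out


@dataclass
class ImputationRules:
    """Per-feature missing-value rules; unruled features fall back to ``default``.

    A rule is ``("constant", c)``, ``"column_mean"`` or ``"zero"``.
    """

    per_feature: dict = field(default_factory=dict)
    default: object = "zero"

    def rule_for(self, name: str):
        return self.per_feature.get(name, self.default)


def _fill_value(rule, observed: np.ndarray, name: str) -> float:
    if rule == "zero":
        return 0.0
    if rule == "column_mean":
        if observed.size == 0:
            raise ValueError(f"column {name!r}: all values missing under column_mean rule")
        return float(observed.mean())
    if isinstance(rule, tuple) and rule[0] == "constant":
        return float(rule[1])
    raise ValueError(f"unknown imputation rule {rule!r} for column {name!r}")


def impute_missing(table: LabeledTable, rules: ImputationRules) -> LabeledTable:
    """Fill every masked cell per its column rule; clears the mask."""
    out = table.copy()
    for j, name in enumerate(out.feature_names):
        mask = out.missing_mask[:, j]
        if not mask.any():
            continue
        observed = out.X[~mask, j]
        out.X[mask, j] = _fill_value(rules.rule_for(name), observed, name)
    out.missing_mask = np.zeros_like(out.missing_mask)
    return out


@dataclass
class NormalizationState:
    min_: np.ndarray
    max_: np.ndarray


def fit_minmax(table: LabeledTable) -> NormalizationState:
    if table.missing_mask.any():
        raise ValueError("impute before fitting normalisation")
    return NormalizationState(table.X.min(axis=0), table.X.max(axis=0))


def apply_minmax(table: LabeledTable, state: NormalizationState) -> LabeledTable:
    """(x - min) / (max - min); constant features map to 0; results clipped to [0, 1]."""
    out = table.copy()
    span = state.max_ - state.min_
    safe = np.where(span == 0, 1.0, span)
    out.X = np.clip((out.X - state.min_) / safe, 0.0, 1.0)
    out.X[:, span == 0] = 0.0
    return out


@dataclass
class PCAState:
    pca: PCA
    feature_names: list[str]


def pca_reduce(fit_table: LabeledTable, n_components: int) -> tuple[PCAState, LabeledTable]:
    """Fit PCA (centred, components by decreasing explained variance) on one
    table and return the state plus the reduced table."""
    if n_components > min(fit_table.n, fit_table.p):
        raise ValueError(f"n_components={n_components} exceeds min(N, p)")
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(fit_table.X)
    names = [f"pc{i + 1}" for i in range(n_components)]
    state = PCAState(pca, names)
    return state, LabeledTable(Z, names, fit_table.y.copy())


def apply_pca(state: PCAState, table: LabeledTable) -> LabeledTable:
    Z = state.pca.transform(table.X)
    return LabeledTable(Z, list(state.feature_names), table.y.copy())


def shuffle_split(
    table: LabeledTable, ratio: tuple[int, int], seed: int
) -> tuple[LabeledTable, LabeledTable]:
    """Seeded shuffle into train:test sizes following ``ratio``; the integer
    remainder goes to the training split."""
    r_train, r_test = ratio
    if r_train <= 0 or r_test <= 0:
        raise ValueError("ratio parts must be positive")
    if table.n < r_train + r_test:
        raise ValueError("fewer rows than ratio parts")
    n_test = (table.n * r_test) // (r_train + r_test)
    rng = np.random.default_rng(seed)
    order = rng.permutation(table.n)
    test_idx, train_idx = order[:n_test], order[n_test:]

    def take(idx):
        return LabeledTable(table.X[idx], list(table.feature_names), table.y[idx],
                            table.missing_mask[idx])

    return take(train_idx), take(test_idx)
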