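"""Evaluation harness: classification metrics, 10-fold CV, train:test
ratio sweeps and pairwise paired t-tests across methods.

The comparison design follows the ratio experiment common in survey-ML
studies: the data are shuffled into four equal subsets; the last is the
fixed test set and the first one / two / three serve as training sets,
giving train:test ratios of 1:1, 2:1 and 3:1.  Significance between
methods is assessed by paired two-tailed t-tests over per-fold metric
vectors from a common 10-fold split of the full training portion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import stats

from .preprocessing import LabeledTable

__all__ = [
    "Metrics",
    "ComparisonReport",
    "ClassifierContract",
    "SklearnClassifier",
    "MajorityClassifier",
    "confusion_metrics",
    "kfold_indices",
    "paired_ttest",
    "compare_methods",
    "report_text",
]


@dataclass
class Metrics:
    acc: float
    precision_macro: float
    f1_macro: float
    confusion: np.ndarray


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> Metrics:
    """Accuracy plus macro-averaged precision and F1 (0/0 counted as 0).

    Macro averaging weights every class equally regardless of support,
    the usual convention for imbalanced ordinal labels.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, what in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 1 or arr.max() > k:
            raise ValueError(f"{what} contains classes outside 1..{k}")
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (y_true - 1, y_pred - 1), 1)
    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return Metrics(
        acc=float(tp.sum() / len(y_true)),
        precision_macro=float(prec.mean()),
        f1_macro=float(f1.mean()),
        confusion=conf,
    )


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Disjoint, exhaustive, seed-shuffled folds whose sizes differ by at most 1."""
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    order = np.random.default_rng(seed).permutation(n)
    return list(np.array_split(order, folds))


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test on matched metric vectors.

    Degenerate cases: all-zero differences give (t=0, p=1); constant
    non-zero differences give (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@runtime_checkable
class ClassifierContract(Protocol):
    """Anything with a name, fit(LabeledTable) and predict(X) -> 1..k classes."""

    name: str

    def fit(self, train: LabeledTable) -> "ClassifierContract": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


class SklearnClassifier:
    """Adapter wrapping any scikit-learn estimator into the contract."""

    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator

    def fit(self, train: LabeledTable):
        import sklearn.base

        self.estimator = sklearn.base.clone(self.estimator)
        self.estimator.fit(train.X, train.y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=int)


class MajorityClassifier:
    """Predicts the most frequent training class; the chance-rate baseline."""

    name = "majority"

    def __init__(self):
        self.class_ = 1

    def fit(self, train: LabeledTable):
        vals, counts = np.unique(train.y, return_counts=True)
        self.class_ = int(vals[counts.argmax()])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(X).shape[0], self.class_, dtype=int)


METRIC_NAMES = ("acc", "precision", "f1")


@dataclass
class ComparisonReport:
    """Per-method metrics per ratio (plus the row average), CV fold scores,
    and all pairwise paired t-tests per metric."""

    methods: list[str]
    ratios: list[str]
    cells: dict            # cells[method][ratio] -> Metrics; ratio "avg" -> dict of floats
    cv_scores: dict        # cv_scores[method][metric] -> np.ndarray of fold values
    ttests: dict           # ttests[(m1, m2)][metric] -> (t, p)
    seed: int = 0


def _metric_dict(m: Metrics) -> dict:
    return {"acc": m.acc, "precision": m.precision_macro, "f1": m.f1_macro}


def compare_methods(
    methods: Sequence[ClassifierContract],
    table: LabeledTable,
    ratios: Sequence[tuple[int, int]] = ((1, 1), (2, 1), (3, 1)),
    seed: int = 0,
    cv_folds: int = 10,
) -> ComparisonReport:
    """Run the four-subset ratio experiment and CV-based significance tests.

    Rows are shuffled into 4 equal subsets (the remainder is dropped); the
    last subset is the test set and the first 1/2/3 subsets the training
    set for ratios 1:1, 2:1, 3:1.  t-tests pair methods over ``cv_folds``
    folds of the full (3-subset) training portion.
    """
    if len(methods) == 0:
        raise ValueError("need at least one method")
    k = int(table.y.max())
    rng = np.random.default_rng(seed)
    n_use = (table.n // 4) * 4
    order = rng.permutation(table.n)[:n_use]
    subsets = np.array_split(order, 4)
    test_idx = subsets[3]

    def sub(idx):
        return LabeledTable(table.X[idx], list(table.feature_names), table.y[idx])

    test = sub(test_idx)
    ratio_names = [f"{a}:{b}" for a, b in ratios]
    cells: dict = {m.name: {} for m in methods}
    for (a, b), rname in zip(ratios, ratio_names):
        if not (1 <= a <= 3 and b == 1):
            raise ValueError(f"unsupported ratio {a}:{b}; use 1:1, 2:1 or 3:1")
        train_idx = np.concatenate(subsets[:a])
        train = sub(train_idx)
        for method in methods:
            method.fit(train)
            pred = method.predict(test.X)
            cells[method.name][rname] = confusion_metrics(test.y, pred, k)
    for method in methods:
        cells[method.name]["avg"] = {
            metric: float(np.mean([_metric_dict(cells[method.name][r])[metric] for r in ratio_names]))
            for metric in METRIC_NAMES
        }

    # per-fold metric vectors on the full training portion, common folds
    full_train_idx = np.concatenate(subsets[:3])
    full_train = sub(full_train_idx)
    folds = kfold_indices(full_train.n, cv_folds, seed=int(rng.integers(2**31)))
    cv_scores: dict = {m.name: {metric: [] for metric in METRIC_NAMES} for m in methods}
    for fold in folds:
        mask = np.ones(full_train.n, dtype=bool)
        mask[fold] = False
        tr = sub(full_train_idx[mask])
        va = sub(full_train_idx[fold])
        for method in methods:
            method.fit(tr)
            m = confusion_metrics(va.y, method.predict(va.X), k)
            for metric, value in _metric_dict(m).items():
                cv_scores[method.name][metric].append(value)
    for name in cv_scores:
        for metric in METRIC_NAMES:
            cv_scores[name][metric] = np.asarray(cv_scores[name][metric])

    ttests: dict = {}
    names = [m.name for m in methods]
    for i, m1 in enumerate(names):
        for m2 in names[i + 1 :]:
            ttests[(m1, m2)] = {
                metric: paired_ttest(cv_scores[m1][metric], cv_scores[m2][metric])
                for metric in METRIC_NAMES
            }
    return ComparisonReport(names, ratio_names, cells, cv_scores, ttests, seed)


def report_text(report: ComparisonReport) -> str:
    """Plain-text rendering: metrics table, ratio table with row averages,
    and the pairwise p-value grid.  Best value per column is marked **."""
    lines: list[str] = []
    last_ratio = report.ratios[-1]

    def fmt_row(cells_: list[str], widths: list[int]) -> str:
        return "  ".join(c.ljust(w) for c, w in zip(cells_, widths))

    def pct(v: float) -> str:
        return f"{100 * v:.2f}%"

    # Table A: metrics at the largest ratio (methods x metrics)
    lines.append(f"== Classification metrics (train:test {last_ratio}) ==")
    header = ["metric"] + report.methods
    rows = []
    for metric in METRIC_NAMES:
        vals = [_metric_dict(report.cells[m][last_ratio])[metric] for m in report.methods]
        best = max(vals)
        rows.append([metric.upper()] + [
            ("**" + pct(v) + "**") if v == best else pct(v) for v in vals
        ])
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines.append(fmt_row(header, widths))
    lines.extend(fmt_row(r, widths) for r in rows)

    # Table B: accuracy per ratio with averages (methods x ratios)
    lines.append("")
    lines.append("== Accuracy by train:test ratio ==")
    header = ["method"] + report.ratios + ["avg"]
    rows = []
    col_vals = {r: [_metric_dict(report.cells[m][r])["acc"] for m in report.methods]
                for r in report.ratios}
    col_vals["avg"] = [report.cells[m]["avg"]["acc"] for m in report.methods]
    for i, m in enumerate(report.methods):
        row = [m]
        for r in report.ratios + ["avg"]:
            v = col_vals[r][i]
            row.append(("**" + pct(v) + "**") if v == max(col_vals[r]) else pct(v))
        rows.append(row)
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines.append(fmt_row(header, widths))
    lines.extend(fmt_row(r, widths) for r in rows)

    # Table C: pairwise p-values per metric
    lines.append("")
    lines.append("== Pairwise two-tailed t-test p-values (10-fold CV) ==")
    header = ["metric"] + [f"{a} vs {b}" for (a, b) in report.ttests]
    rows = []
    for metric in METRIC_NAMES:
        row = [metric.upper()]
        for pair in report.ttests:
            _, p = report.ttests[pair][metric]
            cell = f"{p:.4f}"
            row.append(("**" + cell + "**") if p < 0.05 else cell)
        rows.append(row)
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines.append(fmt_row(header, widths))
    lines.extend(fmt_row(r, widths) for r in rows)
    return "\n".join(lines) + "\n"
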