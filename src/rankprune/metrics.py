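"""Evaluation metrics: classification, selection effectiveness, efficiency.

Classification metrics follow the usual confusion-count definitions
(accuracy, precision, recall/sensitivity, specificity); zero-denominator
ratios are reported as 0 together with a warning flag rather than raising,
so batch evaluation never aborts on a degenerate predictor. Multiclass
input is macro-averaged over one-vs-rest problems.

The feature reduction ratio (FRR) is the fraction of the original features
retained after selection; it is stored as a fraction in [0, 1] and rendered
as a percentage only at the reporting layer. The relevance score (RS)
averages weight * performance-gain over the selected features, where the
gain of a feature is the cross-validated accuracy delta from adding it to
the remaining selected set (add-one-in ablation with fixed folds).

Wall-clock instrumentation (computational time, speedup against a
single-partition reference, and normalized memory usage) is hardware
dependent and is reported for information only.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .data_io import Dataset
from .exceptions import ConfigurationError, InputError


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for a designated positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    undefined: frozenset = frozenset()  # names of zero-denominator ratios

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
        }


@dataclass
class EffMetrics:
    """Selection-effectiveness plus efficiency figures for one run."""

    frr: float
    rs: float
    ct_ms: float
    speedup: float
    mu_mb: float

    def __post_init__(self):
        if not (0.0 <= self.frr <= 1.0):
            raise InputError("frr must lie in [0, 1]")
        if self.speedup <= 0:
            raise InputError("speedup must be positive")


def _counts(y_true: np.ndarray, y_pred: np.ndarray, positive) -> ConfusionCounts:
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def metrics_from_counts(c: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, precision, recall, specificity from confusion counts."""
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    return ClassificationMetrics(
        accuracy=ratio(c.TP + c.TN, c.total, "accuracy"),
        precision=ratio(c.TP, c.TP + c.FP, "precision"),
        recall=ratio(c.TP, c.TP + c.FN, "recall"),
        specificity=ratio(c.TN, c.TN + c.FP, "specificity"),
        undefined=frozenset(undefined),
    )


def classification_metrics(
    y_true: Sequence, y_pred: Sequence, positive=None
) -> ClassificationMetrics:
    """Accuracy, precision, recall and specificity of a prediction.

    Binary data uses the larger (sorted-last) label as the positive class
    unless ``positive`` is given; more than two classes are macro-averaged
    over one-vs-rest problems.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise InputError("empty label vectors")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if positive is not None or len(classes) <= 2:
        pos = positive if positive is not None else classes[-1]
        return metrics_from_counts(_counts(y_true, y_pred, pos))
    per_class = [metrics_from_counts(_counts(y_true, y_pred, c))
                 for c in classes]
    return ClassificationMetrics(
        accuracy=float(np.mean(y_true == y_pred)),
        precision=float(np.mean([m.precision for m in per_class])),
        recall=float(np.mean([m.recall for m in per_class])),
        specificity=float(np.mean([m.specificity for m in per_class])),
        undefined=frozenset().union(*[m.undefined for m in per_class]),
    )


def feature_reduction_ratio(n_selected: int, n_total: int) -> float:
    """Fraction of the original features retained after selection."""
    if n_total < 1:
        raise InputError("n_total must be >= 1")
    if not (0 <= n_selected <= n_total):
        raise InputError(
            f"n_selected={n_selected} outside [0, n_total={n_total}]"
        )
    return n_selected / n_total


@dataclass(frozen=True)
class AblationConfig:
    """Cross-validation settings for the add-one-in relevance ablation."""

    cv_folds: int = 3
    svm_C: float = 1.0
    seed: int = 0


def _cv_accuracy(X: np.ndarray, y: np.ndarray, cfg: AblationConfig) -> float:
    _, counts = np.unique(y, return_counts=True)
    folds = min(cfg.cv_folds, counts.min())
    if folds < 2:
        raise InputError("too few samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            cross_val_score(SVC(kernel="linear", C=cfg.svm_C), X, y, cv=cv).mean()
        )


def relevance_score_from_gains(
    weights: Sequence[float], gains: Sequence[float]
) -> float:
    """RS = (1/n) sum_i weight_i * gain_i."""
    weights = np.asarray(weights, dtype=float)
    gains = np.asarray(gains, dtype=float)
    if weights.shape != gains.shape:
        raise InputError("weights and gains must share length")
    if weights.size == 0:
        raise InputError("empty selection")
    if (weights < 0).any() or (weights > 1).any():
        raise InputError("weights must be normalized to [0, 1]")
    return float(np.mean(weights * gains))


def performance_gains(
    selected: Sequence[int],
    ds: Dataset,
    eval_cfg: AblationConfig = AblationConfig(),
) -> np.ndarray:
    """Add-one-in CV accuracy delta of each selected feature.

    gain_i = acc(selected) - acc(selected without i), with folds and seed
    fixed so the result is invariant to the ordering of the selection.
    """
    selected = list(selected)
    if len(selected) == 0:
        raise InputError("empty selection")
    X = ds.numeric_matrix()
    acc_full = _cv_accuracy(X[:, selected], ds.y, eval_cfg)
    gains = np.empty(len(selected))
    for i, col in enumerate(selected):
        rest = [c for c in selected if c != col]
        if not rest:
            # a single selected feature: gain relative to the chance rate
            _, counts = np.unique(ds.y, return_counts=True)
            base = counts.max() / counts.sum()
        else:
            base = _cv_accuracy(X[:, rest], ds.y, eval_cfg)
        gains[i] = acc_full - base
    return gains


def relevance_score(
    selected: Sequence[int],
    weights: Sequence[float],
    ds: Dataset,
    eval_cfg: AblationConfig = AblationConfig(),
) -> float:
    """Average weighted contribution of the selected features.

    ``weights`` are the selector's normalized relevance scores in [0, 1]
    for the selected columns, in the same order.
    """
    gains = performance_gains(selected, ds, eval_cfg)
    return relevance_score_from_gains(weights, gains)


# ---------------------------------------------------------------------------
# instrumentation


@dataclass(frozen=True)
class TaskRecord:
    """One task type: how many times it ran, per-run time and memory."""

    name: str
    count: int
    duration_ms: float
    memory_mb: float = 0.0


def computational_time_ms(records: Sequence[TaskRecord]) -> float:
    """CT = sum_j N_j * T[q_j] over recorded task types, in milliseconds."""
    return float(sum(r.count * r.duration_ms for r in records))


def instrumentation(
    records: Sequence[TaskRecord],
    ct_single_ms: Optional[float] = None,
    frr: float = 0.0,
    rs: float = 0.0,
    total_cycles: int = 1,
) -> EffMetrics:
    """Aggregate run records into efficiency metrics.

    ``ct_single_ms`` is the single-partition reference time required for
    the speedup ratio S = CT_single / CT_cluster. Memory usage is the
    allocation-weighted sum over task types normalized by the number of
    execution cycles. All wall-clock figures are hardware dependent.
    """
    ct = computational_time_ms(records)
    if ct_single_ms is None:
        raise ConfigurationError(
            "speedup requires a single-partition reference run (ct_single_ms)"
        )
    if ct <= 0:
        raise InputError("cluster computational time must be positive")
    if total_cycles < 1:
        raise InputError("total_cycles must be >= 1")
    mu = sum(r.memory_mb * r.count for r in records) / total_cycles
    return EffMetrics(frr=frr, rs=rs, ct_ms=ct, speedup=ct_single_ms / ct,
                      mu_mb=mu)


class Stopwatch:
    """Context manager collecting named task durations in milliseconds."""

    def __init__(self):
        self.records: list[TaskRecord] = []
        self._t0: Optional[float] = None
        self._name: Optional[str] = None

    def task(self, name: str) -> "Stopwatch":
        self._name = name
        return self

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        elapsed = (time.perf_counter() - self._t0) * 1000.0
        self.records.append(
            TaskRecord(name=self._name or "task", count=1, duration_ms=elapsed)
        )
        self._name = None
        return False

    def total_ms(self) -> float:
        return computational_time_ms(self.records)


# ---------------------------------------------------------------------------
# aggregation


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_report(
    per_dataset: Sequence[dict],
    ndigits: Optional[dict | int] = None,
) -> dict:
    """Arithmetic mean of each metric across datasets.

    ``ndigits`` optionally maps metric names (or sets one value for all)
    to the precision at which the mean is rounded half-up; unrounded means
    are returned otherwise.
    """
    if len(per_dataset) == 0:
        raise InputError("need at least one dataset result")
    keys = per_dataset[0].keys()
    out = {}
    for k in keys:
        mean = float(np.mean([d[k] for d in per_dataset]))
        if ndigits is not None:
            nd = ndigits if isinstance(ndigits, int) else ndigits.get(k)
            if nd is not None:
                mean = round_half_up(mean, nd)
        out[k] = mean
    return out
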