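"""Kruskal-rank relevance scoring and SVM recursive feature elimination.

Stage one scores every feature by a weighted combination of its spread and
its class separability:

* variance contribution ``V_i = (1/N) sum_j (x_ij - mu_i)^2`` (population
  variance);
* rank metric ``R_i = sum_c (n_c/N) (rbar_c - rbar)^2`` where ranks run
  1..N with average ties, ``rbar_c`` is the mean rank within class c and
  ``rbar`` the overall mean rank. With no ties this is a rescaling of the
  Kruskal-Wallis H statistic: ``R = H (N+1) / 12``;
* relevance ``S_i = alpha * Vhat_i + beta * Rhat_i`` where by default V and
  R are each min-max rescaled to [0, 1] across features (they live on
  incomparable scales); the literal un-normalized sum is available too.

Stage two is SVM-RFE: a linear soft-margin SVM is refit on the retained
columns, per-feature importance is the magnitude of the corresponding
primal weight component, and the ``gamma`` least important features are
dropped per iteration (schedule T_t = T - gamma * t). Every iteration is
scored by a joint objective L balancing mean relevance, cross-validated
accuracy, and the fraction of features discarded; the returned subset is
the L-maximizing iteration's.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .data_io import Dataset
from .exceptions import ConfigurationError, InputError, NumericError


@dataclass(frozen=True)
class RankingWeights:
    """Relative importance of variance (alpha) vs rank separability (beta)."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ConfigurationError("alpha and beta must be nonnegative")
        if self.alpha + self.beta <= 0:
            raise ConfigurationError("alpha + beta must be positive")


@dataclass
class FeatureRanking:
    """Per-feature variance V, rank metric R, and combined relevance S."""

    V: np.ndarray
    R: np.ndarray
    S: np.ndarray
    normalized: bool = True

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if not (len(self.V) == len(self.R) == len(self.S)):
            raise InputError("V, R, S must share length")
        if (self.V < 0).any() or (self.R < 0).any():
            raise InputError("V and R entries must be nonnegative")


@dataclass(frozen=True)
class RFEConfig:
    """Recursive-elimination schedule and objective weights.

    ``gamma`` features are removed per iteration; the loop halts at
    ``t_max`` iterations or when the retained count would drop below
    ``T_min``. ``lambdas`` weight (relevance, accuracy, efficiency) in the
    joint objective; ``objective_form='normalized'`` keeps all three terms
    in [0, 1]. ``gamma``/``T_min`` default to None, resolved against M as
    max(1, floor(0.1 M)) and max(2, ceil(0.05 M)).
    """

    gamma: Optional[int] = None
    t_max: int = 50
    T_min: Optional[int] = None
    svm_C: float = 1.0
    cv_folds: int = 3
    lambdas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    objective_form: Literal["normalized", "literal"] = "normalized"
    seed: int = 0

    def __post_init__(self):
        if self.gamma is not None and self.gamma < 1:
            raise ConfigurationError("gamma must be >= 1")
        if self.T_min is not None and self.T_min < 1:
            raise ConfigurationError("T_min must be >= 1")
        if self.t_max < 0:
            raise ConfigurationError("t_max must be >= 0")
        if self.svm_C <= 0:
            raise ConfigurationError("svm_C must be positive")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if any(l < 0 for l in self.lambdas):
            raise ConfigurationError("lambdas must be nonnegative")
        if self.objective_form not in ("normalized", "literal"):
            raise ConfigurationError(
                f"unknown objective_form {self.objective_form!r}"
            )

    def resolved(self, M: int) -> "RFEConfig":
        """Fill gamma/T_min defaults for a dataset with M features."""
        gamma = self.gamma if self.gamma is not None else max(1, int(0.1 * M))
        t_min = self.T_min if self.T_min is not None else max(2, -(-M // 20))
        return RFEConfig(gamma=gamma, t_max=self.t_max, T_min=t_min,
                         svm_C=self.svm_C, cv_folds=self.cv_folds,
                         lambdas=self.lambdas,
                         objective_form=self.objective_form, seed=self.seed)


@dataclass
class RFEIteration:
    """One elimination step: retained columns, weights, objective terms."""

    retained: list[int]
    weights: np.ndarray
    terms: tuple[float, float, float]  # (relevance, accuracy, efficiency)
    L: float


@dataclass
class SelectionTrace:
    """Ordered record of the elimination path and the best iteration."""

    iterations: list[RFEIteration] = field(default_factory=list)
    best_index: int = 0

    def best(self) -> RFEIteration:
        return self.iterations[self.best_index]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "best_index": self.best_index,
            "iterations": [
                {
                    "retained": list(map(int, it.retained)),
                    "weights": [float(w) for w in it.weights],
                    "terms": {
                        "relevance": it.terms[0],
                        "accuracy": it.terms[1],
                        "efficiency": it.terms[2],
                    },
                    "L": it.L,
                }
                for it in self.iterations
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def variance_contribution(ds: Dataset) -> np.ndarray:
    """Population variance of each feature (divide-by-N)."""
    X = ds.numeric_matrix()
    if X.size == 0:
        raise InputError("empty feature matrix")
    return np.var(X, axis=0)


def rank_metric(ds: Dataset) -> np.ndarray:
    """Between-class spread of mean ranks, per feature.

    Values of each feature are ranked 1..N (ties averaged); the metric is
    the class-size-weighted squared deviation of within-class mean ranks
    from the overall mean rank. Zero for a constant feature; equals
    H (N+1)/12 of the Kruskal-Wallis statistic when there are no ties.
    """
    X = ds.numeric_matrix()
    y = ds.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("rank metric requires at least 2 classes")
    n = X.shape[0]
    out = np.empty(X.shape[1])
    class_masks = [y == c for c in classes]
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j])
        rbar = ranks.mean()
        out[j] = sum(
            (m.sum() / n) * (ranks[m].mean() - rbar) ** 2 for m in class_masks
        )
    return out


def relevance_scores(
    V: np.ndarray,
    R: np.ndarray,
    w: RankingWeights = RankingWeights(),
    normalize: bool = True,
) -> FeatureRanking:
    """Combine variance and rank metrics into relevance scores S.

    With ``normalize`` (default), V and R are each min-max rescaled to
    [0, 1] across features (a constant vector maps to all-zeros) before
    S = alpha * Vhat + beta * Rhat; otherwise the literal weighted sum.
    """
    V = np.asarray(V, dtype=float)
    R = np.asarray(R, dtype=float)
    if V.shape != R.shape:
        raise InputError(f"length mismatch: V has {V.shape}, R has {R.shape}")

    def _minmax(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    if normalize:
        S = w.alpha * _minmax(V) + w.beta * _minmax(R)
    else:
        S = w.alpha * V + w.beta * R
    return FeatureRanking(V=V, R=R, S=S, normalized=normalize)


def _binary_svm_weights(X: np.ndarray, y01: np.ndarray, C: float) -> np.ndarray:
    svm = SVC(kernel="linear", C=C)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svm.fit(X, y01)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise NumericError(f"linear SVM failed to converge: {exc}") from exc
    return np.abs(np.asarray(svm.coef_).ravel())


def svm_feature_weights(ds_subset: Dataset, C: float = 1.0) -> np.ndarray:
    """Per-feature importance |w_i| from a linear soft-margin SVM.

    Binary labels only; multiclass callers run one-vs-rest and take the
    per-feature maximum over the binary problems.
    """
    if C <= 0:
        raise ConfigurationError("C must be positive")
    X = ds_subset.numeric_matrix()
    classes = np.unique(ds_subset.y)
    if len(classes) < 2:
        raise InputError("SVM feature weights require >= 2 classes in subset")
    if len(classes) > 2:
        raise InputError(
            "binary labels required; use one-vs-rest and per-feature maxima"
        )
    y = np.where(ds_subset.y == classes[1], 1, -1)
    return _binary_svm_weights(X, y, C)


def _importance(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """|w_i| importance, one-vs-rest maximum when more than 2 classes."""
    classes = np.unique(y)
    if len(classes) < 2:
        raise InputError("feature weighting requires >= 2 classes")
    if len(classes) == 2:
        return _binary_svm_weights(X, np.where(y == classes[1], 1, -1), C)
    per_class = [
        _binary_svm_weights(X, np.where(y == c, 1, -1), C) for c in classes
    ]
    return np.max(per_class, axis=0)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, cfg: RFEConfig) -> float:
    """Stratified cross-validated accuracy of a linear SVM, fixed seed."""
    _, counts = np.unique(y, return_counts=True)
    folds = min(cfg.cv_folds, counts.min())
    if folds < 2:
        raise InputError("too few samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(SVC(kernel="linear", C=cfg.svm_C), X, y, cv=cv)
    return float(scores.mean())


def objective_terms(
    S_retained: np.ndarray,
    accuracy: float,
    T: int,
    T_total: int,
    form: Literal["normalized", "literal"] = "normalized",
) -> tuple[float, float, float]:
    """Compute the (relevance, accuracy, efficiency) triple for one subset.

    Normalized form: mean relevance of retained features, accuracy, and
    1 - T/T_total, all in [0, 1]. Literal form: sum of S over retained,
    accuracy, and 1/T (retained count proxies the evaluation time so the
    objective stays machine-independent).
    """
    if T <= 0:
        raise InputError("T must be positive")
    S_retained = np.asarray(S_retained, dtype=float)
    if form == "normalized":
        return (float(S_retained.mean()), float(accuracy), 1.0 - T / T_total)
    return (float(S_retained.sum()), float(accuracy), 1.0 / T)


def objective_value(
    terms: tuple[float, float, float],
    lambdas: tuple[float, float, float] = (1.0, 1.0, 1.0),
    form: Literal["normalized", "literal"] = "normalized",
) -> float:
    """Joint objective L = l1 * relevance + l2 * accuracy + l3 * efficiency."""
    relevance, accuracy, efficiency = terms
    if not (0.0 <= accuracy <= 1.0):
        raise InputError(f"accuracy must lie in [0, 1], got {accuracy}")
    l1, l2, l3 = lambdas
    return float(l1 * relevance + l2 * accuracy + l3 * efficiency)


def rfe_run(ds: Dataset, ranking: FeatureRanking, cfg: RFEConfig) -> SelectionTrace:
    """Recursive elimination guided by SVM weights.

    Each iteration removes the ``gamma`` features with the smallest |w_i|
    (ties broken by lower relevance S, then lower column index); the loop
    halts at ``t_max`` iterations or when the next removal would drop the
    retained count below ``T_min``. Every visited subset is scored by the
    joint objective; retained sets strictly shrink and are nested.
    """
    X = ds.numeric_matrix()
    y = ds.y
    M = X.shape[1]
    if len(ranking.S) != M:
        raise InputError("ranking length does not match feature count")
    cfg = cfg.resolved(M)
    if cfg.T_min > M:
        raise ConfigurationError(f"T_min={cfg.T_min} exceeds M={M}")

    retained = list(range(M))
    trace = SelectionTrace()
    t = 0
    while True:
        Xs = X[:, retained]
        W = _importance(Xs, y, cfg.svm_C)
        acc = _cv_accuracy(Xs, y, cfg)
        terms = objective_terms(ranking.S[retained], acc, len(retained), M,
                                cfg.objective_form)
        L = objective_value(terms, cfg.lambdas, cfg.objective_form)
        trace.iterations.append(
            RFEIteration(retained=list(retained), weights=W, terms=terms, L=L)
        )
        if t >= cfg.t_max or len(retained) - cfg.gamma < cfg.T_min:
            break
        # order by (importance, relevance, index); drop the first gamma
        order = sorted(
            range(len(retained)),
            key=lambda i: (W[i], ranking.S[retained[i]], retained[i]),
        )
        drop = {retained[i] for i in order[: cfg.gamma]}
        retained = [c for c in retained if c not in drop]
        t += 1

    ls = [it.L for it in trace.iterations]
    trace.best_index = int(np.argmax(ls))  # argmax takes first on ties
    return trace


def select(
    ds: Dataset,
    w: RankingWeights = RankingWeights(),
    cfg: RFEConfig = RFEConfig(),
) -> tuple[list[int], SelectionTrace, FeatureRanking]:
    """End-to-end selection: rank, recursively eliminate, pick the best subset.

    The dataset is expected to be preprocessed (numeric, standardized).
    Deterministic given ``cfg.seed``.
    """
    V = variance_contribution(ds)
    R = rank_metric(ds)
    ranking = relevance_scores(V, R, w, normalize=True)
    trace = rfe_run(ds, ranking, cfg)
    return list(trace.best().retained), trace, ranking


def write_scores_csv(
    ranking: FeatureRanking,
    selected: Sequence[int],
    feature_names: Sequence[str],
    path: str | Path,
) -> None:
    """Per-feature V, R, S, and selection flag as CSV."""
    sel = set(selected)
    lines = ["feature,V,R,S,selected"]
    for j, name in enumerate(feature_names):
        lines.append(
            f"{name},{ranking.V[j]:.10g},{ranking.R[j]:.10g},"
            f"{ranking.S[j]:.10g},{int(j in sel)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
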