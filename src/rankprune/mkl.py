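"""Distributed multi-kernel SVM trained by consensus ADMM.

The classifier is a hinge-loss kernel machine whose decision function is
expressed on a shared set of L landmark samples,

    f(x) = sum_l z_l K(x, landmark_l) + b,

with a composite kernel K = sum_m beta_m k_m, beta on the probability
simplex. Training data is partitioned across P simulated compute nodes;
each node repeatedly minimizes its local objective

    (1/2)||a_j||^2 + C sum_{i in D_j} max(0, 1 - y_i f(x_i)) + rho ||c_j - a_j||^2

(ridge on the landmark coefficients, bias excluded) where the proximal
center c_j = z - u_j carries the consensus variable and the node's scaled
dual u_j; z is then re-estimated by averaging and the duals updated — the
standard scaled-dual consensus ADMM sweep. The shared landmark basis makes
every node's coefficient vector the same length, so the averaging step is
well defined even for unequal partitions. With P=1 the sweep reduces to
the proximal-point iteration on the centralized hinge+ridge problem and
converges to its exact minimizer.

Each node subproblem is solved exactly through its dual: with the diagonal
ridge D and Q = D + 2 rho I, the dual is the smooth concave box-constrained
QP  max_{0<=lam<=C} sum(lam) - (1/2) v'Q^{-1}v,  v = 2 rho c + A'lam,
A = diag(y) [K_j | 1]. L-BFGS-B plus an exact coordinate-ascent polish
drives the KKT residual to ~1e-9.

Kernel weights beta are re-estimated once per outer iteration by centered
kernel alignment against the label target yy' on a bounded subsample;
alignment is static given the data, so beta settles after one update.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel

from .data_io import Dataset
from .exceptions import ConfigurationError, InputError, NumericError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# kernel machinery


@dataclass(frozen=True)
class KernelSpec:
    """One base kernel: linear, polynomial, or rbf (Gaussian).

    ``degree``/``coef0`` apply to the polynomial kernel only, ``bandwidth``
    (the Gaussian sigma) to rbf only.
    """

    kind: Literal["linear", "polynomial", "rbf"]
    degree: int = 3
    coef0: float = 1.0
    bandwidth: float = 1.0

    def __post_init__(self):
        if self.kind not in ("linear", "polynomial", "rbf"):
            raise ConfigurationError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ConfigurationError("polynomial degree must be >= 1")
        if self.kind == "rbf" and self.bandwidth <= 0:
            raise ConfigurationError("rbf bandwidth must be positive")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "polynomial":
            d.update(degree=self.degree, coef0=self.coef0)
        if self.kind == "rbf":
            d.update(bandwidth=self.bandwidth)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


@dataclass
class CompositeKernel:
    """Convex combination of base kernels with simplex weights beta."""

    specs: list[KernelSpec]
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.specs) == 0:
            raise ConfigurationError("at least one base kernel required")
        if self.beta.shape != (len(self.specs),):
            raise ConfigurationError("beta length must match number of kernels")
        if (self.beta < 0).any():
            raise ConfigurationError("beta entries must be nonnegative")
        if abs(self.beta.sum() - 1.0) > 1e-9:
            raise ConfigurationError("beta must sum to 1 within 1e-9")

    @classmethod
    def uniform(cls, specs: Sequence[KernelSpec]) -> "CompositeKernel":
        m = len(specs)
        return cls(specs=list(specs), beta=np.full(m, 1.0 / m))

    def with_beta(self, beta: np.ndarray) -> "CompositeKernel":
        return CompositeKernel(specs=list(self.specs), beta=beta)


def base_kernel(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram block between sample sets A (rows) and B (columns)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise InputError(
            f"feature-dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    if spec.kind == "linear":
        return linear_kernel(A, B)
    if spec.kind == "polynomial":
        # (x'x + coef0)^degree, i.e. sklearn's polynomial kernel at gamma=1
        return polynomial_kernel(A, B, degree=spec.degree, gamma=1.0,
                                 coef0=spec.coef0)
    return rbf_kernel(A, B, gamma=1.0 / (2.0 * spec.bandwidth ** 2))


def composite_kernel_matrix(
    ck: CompositeKernel, A: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """Weighted sum of the base kernel blocks."""
    out = None
    for w, spec in zip(ck.beta, ck.specs):
        K = base_kernel(spec, A, B)
        out = w * K if out is None else out + w * K
    return out


def median_bandwidth(X: np.ndarray, max_points: int = 200, seed: int = 0) -> float:
    """Median pairwise Euclidean distance heuristic for the rbf bandwidth."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_points, replace=False)]
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    return med if med > 0 else 1.0


def default_kernels(X: np.ndarray, seed: int = 0) -> CompositeKernel:
    """Linear + cubic polynomial + rbf at the median-distance bandwidth."""
    specs = [
        KernelSpec(kind="linear"),
        KernelSpec(kind="polynomial", degree=3, coef0=1.0),
        KernelSpec(kind="rbf", bandwidth=median_bandwidth(X, seed=seed)),
    ]
    return CompositeKernel.uniform(specs)


# ---------------------------------------------------------------------------
# configuration and model containers


@dataclass(frozen=True)
class ConsensusConfig:
    """Node count, regularization, ADMM penalty and stopping parameters."""

    P: int = 1
    C: float = 1.0
    rho: float = 1.0
    epsilon: float = 1e-4
    max_iter: int = 100
    n_landmarks: int = 100
    landmark_seed: int = 0
    partition_mode: Literal["stratified", "random"] = "stratified"

    def __post_init__(self):
        if self.P < 1:
            raise ConfigurationError("P must be >= 1")
        if self.C < 0:
            raise ConfigurationError("C must be nonnegative")
        if self.rho <= 0:
            raise ConfigurationError("rho must be positive")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.n_landmarks < 1:
            raise ConfigurationError("n_landmarks must be >= 1")
        if self.partition_mode not in ("stratified", "random"):
            raise ConfigurationError(
                f"unknown partition_mode {self.partition_mode!r}"
            )


@dataclass
class ConsensusModel:
    """Fitted consensus model: landmarks, coefficients, kernel, history."""

    landmarks: np.ndarray
    z: np.ndarray  # length L+1; last entry is the bias b
    per_node_alpha: list[np.ndarray]
    kernel: CompositeKernel
    kernel_scales: np.ndarray  # per-base-kernel trace normalizers
    history: list[dict]
    converged: bool
    classes_: np.ndarray
    config: ConsensusConfig
    n_features: int

    @property
    def bias(self) -> float:
        return float(self.z[-1])


# ---------------------------------------------------------------------------
# partitioning


def _partition_indices(
    y: np.ndarray, P: int, mode: str, rng: np.random.Generator
) -> list[np.ndarray]:
    n = len(y)
    if mode == "random":
        perm = rng.permutation(n)
        base, rem = divmod(n, P)
        sizes = [base + (1 if i < rem else 0) for i in range(P)]
        out, start = [], 0
        for s in sizes:
            out.append(np.sort(perm[start:start + s]))
            start += s
        return out
    # stratified: deal each class out contiguously, rotating which nodes
    # absorb the remainder so overall node sizes stay within +-1
    parts: list[list[int]] = [[] for _ in range(P)]
    offset = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        base, rem = divmod(len(idx), P)
        start = 0
        for i in range(P):
            extra = 1 if ((i - offset) % P) < rem else 0
            parts[i].extend(idx[start:start + base + extra].tolist())
            start += base + extra
        offset = (offset + rem) % P
    return [np.sort(np.asarray(p, dtype=int)) for p in parts]


def partition(ds: Dataset, cfg: ConsensusConfig) -> list[np.ndarray]:
    """Disjoint cover of the sample indices across P nodes.

    Stratified mode preserves per-node class proportions within one sample;
    deterministic given ``cfg.landmark_seed``.
    """
    n = ds.n_samples
    if cfg.P > n:
        raise ConfigurationError(f"P={cfg.P} exceeds sample count {n}")
    rng = np.random.default_rng(cfg.landmark_seed)
    return _partition_indices(ds.y, cfg.P, cfg.partition_mode, rng)


def local_kernel_matrix(
    ck: CompositeKernel,
    ds: Dataset,
    node_indices: Sequence[int],
    landmarks: np.ndarray,
) -> np.ndarray:
    """Composite kernel block between one node's samples and the landmarks."""
    idx = np.asarray(node_indices, dtype=int)
    if idx.size == 0:
        raise InputError("node has no samples")
    X = ds.numeric_matrix()
    return composite_kernel_matrix(ck, X[idx], np.asarray(landmarks, float))


# ---------------------------------------------------------------------------
# the node subproblem: ridge + hinge + proximal term, solved via its dual


def _solve_prox_hinge(
    Kb: np.ndarray,
    y: np.ndarray,
    C: float,
    rho: float,
    center: np.ndarray,
    bias_reg: float = 0.0,
    return_dual: bool = False,
):
    """Exact minimizer of
    (1/2)||a[:-1]||^2 + C sum_i max(0, 1 - y_i (Kb a)_i) + rho ||center - a||^2.

    ``Kb`` is the node kernel block with a trailing ones column (bias).
    Solved through the box-constrained concave dual; Q is diagonal on this
    basis so the primal recovery a = Q^{-1}(2 rho center + A'lam) is exact.
    """
    Kb = np.asarray(Kb, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = Kb.shape
    center = np.asarray(center, dtype=float)
    if center.shape != (d,):
        raise InputError(f"center length {center.shape} != basis size {d}")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise InputError("labels must be in {-1, +1}")

    ridge = np.ones(d)
    ridge[-1] = bias_reg  # bias excluded from the ridge term
    qdiag = ridge + 2.0 * rho

    if C == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(qdiag > 0, 2.0 * rho * center / qdiag, 0.0)
        return (alpha, np.zeros(n)) if return_dual else alpha
    if (qdiag <= 0).any():
        raise ConfigurationError(
            "singular subproblem: need rho > 0 or a bias regularizer"
        )

    A = y[:, None] * Kb
    AQ = A / qdiag  # rows a_i Q^{-1}
    v0 = 2.0 * rho * center

    def neg_g(lam):
        v = v0 + A.T @ lam
        alpha = v / qdiag
        g = lam.sum() - 0.5 * float(v @ alpha)
        grad = 1.0 - A @ alpha
        return -g, -grad

    def primal_value(alpha):
        margins = A @ alpha
        return (
            0.5 * float((qdiag * alpha) @ alpha)
            - float(v0 @ alpha)
            + C * float(np.maximum(0.0, 1.0 - margins).sum())
        )

    res = minimize(
        neg_g,
        x0=np.zeros(n),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, C)] * n,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam = np.clip(res.x, 0.0, C)

    # exact coordinate-ascent polish with a scale-free stopping rule: the
    # relative duality gap bounds the primal suboptimality directly
    alpha = (v0 + A.T @ lam) / qdiag
    curv = np.einsum("ij,ij->i", A, AQ)
    gap_tol, rel_gap = 1e-9, np.inf
    for sweep in range(2000):
        for i in range(n):
            gi = 1.0 - float(A[i] @ alpha)
            new = min(max(lam[i] + gi / curv[i], 0.0), C)
            delta = new - lam[i]
            if delta != 0.0:
                lam[i] = new
                alpha = alpha + delta * AQ[i]
        if sweep % 5 == 4 or sweep == 0:
            dual = float(lam.sum()) - 0.5 * float((qdiag * alpha) @ alpha)
            rel_gap = (primal_value(alpha) - dual) / max(1.0, abs(dual))
            if rel_gap < gap_tol:
                break
    if rel_gap > 1e-4:
        raise NumericError(
            f"node subproblem did not reach optimality: relative duality "
            f"gap {rel_gap:.3e}"
        )
    return (alpha, lam) if return_dual else alpha


def hinge_ridge_objective(
    Kb: np.ndarray, y: np.ndarray, alpha: np.ndarray, C: float
) -> float:
    """(1/2)||a[:-1]||^2 + C sum hinge, on the landmark basis (bias free)."""
    margins = y * (Kb @ alpha)
    return float(
        0.5 * np.dot(alpha[:-1], alpha[:-1])
        + C * np.maximum(0.0, 1.0 - margins).sum()
    )


def solve_hinge_ridge(Kb: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Direct (single-shot) solve of the centralized hinge+ridge problem.

    On the landmark basis the problem min (1/2)||a[:-1]||^2 + C sum hinge
    is exactly a linear soft-margin SVM over the empirical kernel map
    (columns of Kb bar the trailing ones column), with an unregularized
    bias; it is solved by libsvm's SMO, an independent route from the
    consensus iteration.
    """
    from sklearn.svm import SVC

    phi = Kb[:, :-1]
    svm = SVC(kernel="linear", C=C, tol=1e-8)
    svm.fit(phi, y)
    return np.append(np.asarray(svm.coef_).ravel(), float(svm.intercept_[0]))


def _trace_scales(specs: Sequence[KernelSpec], landmarks: np.ndarray) -> np.ndarray:
    """1 / mean self-similarity of the landmarks, per base kernel."""
    landmarks = np.atleast_2d(np.asarray(landmarks, float))
    scales = np.empty(len(specs))
    for m, spec in enumerate(specs):
        diag_mean = float(
            np.mean([base_kernel(spec, p[None, :], p[None, :])[0, 0]
                     for p in landmarks])
        )
        scales[m] = 1.0 / diag_mean if abs(diag_mean) > 1e-12 else 1.0
    return scales


def local_admm_update(
    X_node: np.ndarray,
    y_node: np.ndarray,
    z: np.ndarray,
    cfg: ConsensusConfig,
    ck: CompositeKernel,
    landmarks: np.ndarray,
) -> np.ndarray:
    """One node's exact proximal update toward the consensus vector z.

    Labels must already be in {-1, +1}. The bias is the last coefficient
    and carries no ridge penalty. The kernel block is trace-normalized the
    same way :func:`fit` normalizes it, so a standalone call reproduces one
    step of the training loop.
    """
    X_node = np.atleast_2d(np.asarray(X_node, dtype=float))
    landmarks = np.asarray(landmarks, float)
    scales = _trace_scales(ck.specs, landmarks)
    K = sum(
        (w * s) * base_kernel(spec, X_node, landmarks)
        for w, s, spec in zip(ck.beta, scales, ck.specs)
    )
    Kb = np.column_stack([K, np.ones(K.shape[0])])
    return _solve_prox_hinge(Kb, np.asarray(y_node, float), cfg.C, cfg.rho, z)


def consensus_update(alphas: Sequence[np.ndarray]) -> np.ndarray:
    """Average the per-node coefficient vectors: z = (1/P) sum_j a_j."""
    if len(alphas) == 0:
        raise InputError("no node coefficient vectors to average")
    lengths = {len(a) for a in alphas}
    if len(lengths) != 1:
        raise InputError("node coefficient vectors differ in length")
    return np.mean(np.asarray(alphas, dtype=float), axis=0)


# ---------------------------------------------------------------------------
# kernel-weight update: centered kernel alignment


def _centered(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    return H @ K @ H


def _alignment_beta(grams: Sequence[np.ndarray], y_pm: np.ndarray) -> np.ndarray:
    target = np.outer(y_pm, y_pm)
    Tc = _centered(target)
    t_norm = np.linalg.norm(Tc)
    scores = np.empty(len(grams))
    for m, K in enumerate(grams):
        Kc = _centered(K)
        denom = np.linalg.norm(Kc) * t_norm
        scores[m] = float((Kc * Tc).sum() / denom) if denom > 0 else 0.0
    scores = np.clip(scores, 0.0, None)
    total = scores.sum()
    if total <= 1e-12:
        return np.full(len(grams), 1.0 / len(grams))
    return scores / total


def update_kernel_weights(
    ck: CompositeKernel,
    ds: Dataset,
    landmarks: Optional[np.ndarray] = None,
    max_points: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Centered-kernel-alignment weights against the label target yy'.

    Alignments are computed on a bounded subsample, negatives clipped to
    zero, and the result renormalized onto the simplex; all-zero alignments
    fall back to uniform weights. Multiclass data is aligned against the
    one-vs-rest target of the first (sorted) class.
    """
    X = ds.numeric_matrix()
    classes = np.unique(ds.y)
    if len(classes) < 2:
        raise InputError("kernel alignment requires >= 2 classes")
    y_pm = np.where(ds.y == classes[0], 1.0, -1.0)
    n = X.shape[0]
    if n > max_points:
        rng = np.random.default_rng(seed)
        sub = np.sort(rng.choice(n, max_points, replace=False))
        X, y_pm = X[sub], y_pm[sub]
    grams = [base_kernel(spec, X, X) for spec in ck.specs]
    return _alignment_beta(grams, y_pm)


# ---------------------------------------------------------------------------
# training


def fit(ds: Dataset, ck: CompositeKernel, cfg: ConsensusConfig) -> ConsensusModel:
    """Consensus-ADMM training of the composite-kernel hinge classifier.

    Initialization: uniform beta, all node coefficients and z at zero.
    Each outer iteration runs the node proximal updates, averages into z,
    updates the scaled duals, re-estimates beta by kernel alignment, and
    stops once both the z step ||z_{t+1} - z_t|| and the consensus residual
    max_j ||z - a_j|| fall below epsilon. Rows are reordered internally to
    a canonical order so the fit is invariant to input sample order.
    """
    X = ds.numeric_matrix()
    classes = np.unique(ds.y)
    if len(classes) != 2:
        raise InputError(
            "binary labels required; wrap with OneVsRestConsensus for multiclass"
        )
    n = X.shape[0]
    if cfg.P > n:
        raise ConfigurationError(f"P={cfg.P} exceeds sample count {n}")

    y_pm = np.where(ds.y == classes[1], 1.0, -1.0)
    # canonical sample order: makes the fit independent of input row order
    order = np.lexsort(np.vstack([y_pm[None, :], X.T[::-1]]))
    X, y_pm = X[order], y_pm[order]

    rng = np.random.default_rng(cfg.landmark_seed)
    L = min(cfg.n_landmarks, n)
    lm_idx = np.arange(n) if L >= n else np.sort(rng.choice(n, L, replace=False))
    landmarks = X[lm_idx]

    # trace-normalize each base kernel (mean self-similarity of the
    # landmarks -> 1) so no kernel dominates the composite by raw scale and
    # the node subproblems stay well conditioned
    scales = _trace_scales(ck.specs, landmarks)

    parts = _partition_indices(y_pm, cfg.P, cfg.partition_mode, rng)

    node_blocks: list[list[np.ndarray]] = []
    node_y: list[np.ndarray] = []
    for idx in parts:
        node_blocks.append(
            [s * base_kernel(spec, X[idx], landmarks)
             for s, spec in zip(scales, ck.specs)]
        )
        node_y.append(y_pm[idx])

    sub = (np.sort(rng.choice(n, 500, replace=False))
           if n > 500 else np.arange(n))
    sub_grams = [base_kernel(s, X[sub], X[sub]) for s in ck.specs]
    y_sub = y_pm[sub]

    d = L + 1
    beta = np.full(len(ck.specs), 1.0 / len(ck.specs))
    alphas = [np.zeros(d) for _ in range(cfg.P)]
    duals = [np.zeros(d) for _ in range(cfg.P)]
    z = np.zeros(d)
    history: list[dict] = []
    converged = False

    for t in range(1, cfg.max_iter + 1):
        kbs = []
        for j in range(cfg.P):
            K = sum(b * B for b, B in zip(beta, node_blocks[j]))
            Kb = np.column_stack([K, np.ones(K.shape[0])])
            kbs.append(Kb)
            alphas[j] = _solve_prox_hinge(
                Kb, node_y[j], cfg.C, cfg.rho, center=z - duals[j]
            )
        z_new = consensus_update([a + u for a, u in zip(alphas, duals)])
        for j in range(cfg.P):
            duals[j] = duals[j] + alphas[j] - z_new

        z_change = float(np.linalg.norm(z_new - z))
        residual = max(
            float(np.linalg.norm(z_new - a)) for a in alphas
        )
        Kb_full = np.vstack(kbs)
        y_full = np.concatenate(node_y)
        objective = hinge_ridge_objective(Kb_full, y_full, z_new, cfg.C)

        beta = _alignment_beta(sub_grams, y_sub)
        history.append({
            "iteration": t,
            "z_change": z_change,
            "consensus_residual": residual,
            "objective": objective,
            "beta": [float(b) for b in beta],
        })
        z = z_new
        if z_change < cfg.epsilon and residual <= cfg.epsilon:
            converged = True
            break

    if not converged:
        logger.warning(
            "consensus ADMM did not converge within %d iterations "
            "(last z step %.3e, residual %.3e)",
            cfg.max_iter, history[-1]["z_change"],
            history[-1]["consensus_residual"],
        )

    return ConsensusModel(
        landmarks=landmarks,
        z=z,
        per_node_alpha=[a.copy() for a in alphas],
        kernel=ck.with_beta(beta),
        kernel_scales=scales,
        history=history,
        converged=converged,
        classes_=classes,
        config=cfg,
        n_features=X.shape[1],
    )


def model_kernel_matrix(model: ConsensusModel, A: np.ndarray) -> np.ndarray:
    """Trace-normalized composite block between new samples and landmarks."""
    out = None
    for w, s, spec in zip(model.kernel.beta, model.kernel_scales,
                          model.kernel.specs):
        K = (w * s) * base_kernel(spec, A, model.landmarks)
        out = K if out is None else out + K
    return out


def decision_function(model: ConsensusModel, X_new: np.ndarray) -> np.ndarray:
    """Scores f(x) = sum_l z_l K(x, landmark_l) + b."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise InputError(
            f"expected {model.n_features} features, got {X_new.shape[1]}"
        )
    K = model_kernel_matrix(model, X_new)
    return K @ model.z[:-1] + model.z[-1]


def predict(model: ConsensusModel, X_new: np.ndarray) -> np.ndarray:
    """Labels by the sign of the score; a score of exactly zero maps to the
    positive class."""
    scores = decision_function(model, X_new)
    return model.classes_[(scores >= 0).astype(int)]


class OneVsRestConsensus:
    """Thin one-vs-rest wrapper: one binary consensus model per class."""

    def __init__(self, ck: CompositeKernel, cfg: ConsensusConfig):
        self.ck = ck
        self.cfg = cfg
        self.models_: dict = {}
        self.classes_: Optional[np.ndarray] = None

    def fit(self, ds: Dataset) -> "OneVsRestConsensus":
        self.classes_ = np.unique(ds.y)
        for c in self.classes_:
            binary = Dataset(
                X=ds.X,
                y=(ds.y == c).astype(int),
                feature_meta=ds.feature_meta,
            )
            self.models_[c] = fit(binary, self.ck, self.cfg)
        return self

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise InputError("model is not fitted")
        scores = np.column_stack(
            [decision_function(self.models_[c], X_new) for c in self.classes_]
        )
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# serialization


def save_model(model: ConsensusModel, path: str | Path) -> None:
    """Serialize a fitted model to a versioned JSON document."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "kernel": {
            "specs": [s.to_dict() for s in model.kernel.specs],
            "beta": [float(b) for b in model.kernel.beta],
        },
        "kernel_scales": model.kernel_scales.tolist(),
        "landmarks": model.landmarks.tolist(),
        "z": model.z.tolist(),
        "per_node_alpha": [a.tolist() for a in model.per_node_alpha],
        "history": model.history,
        "converged": model.converged,
        "classes": model.classes_.tolist(),
        "n_features": model.n_features,
        "config": {
            "P": model.config.P,
            "C": model.config.C,
            "rho": model.config.rho,
            "epsilon": model.config.epsilon,
            "max_iter": model.config.max_iter,
            "n_landmarks": model.config.n_landmarks,
            "landmark_seed": model.config.landmark_seed,
            "partition_mode": model.config.partition_mode,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path) -> ConsensusModel:
    """Load a model serialized by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no model file at {path}")
    doc = json.loads(path.read_text())
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ConfigurationError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    ck = CompositeKernel(
        specs=[KernelSpec.from_dict(s) for s in doc["kernel"]["specs"]],
        beta=np.asarray(doc["kernel"]["beta"], dtype=float),
    )
    return ConsensusModel(
        landmarks=np.asarray(doc["landmarks"], dtype=float),
        z=np.asarray(doc["z"], dtype=float),
        per_node_alpha=[np.asarray(a, dtype=float)
                        for a in doc["per_node_alpha"]],
        kernel=ck,
        kernel_scales=np.asarray(doc["kernel_scales"], dtype=float),
        history=doc["history"],
        converged=doc["converged"],
        classes_=np.asarray(doc["classes"]),
        config=ConsensusConfig(**doc["config"]),
        n_features=int(doc["n_features"]),
    )
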