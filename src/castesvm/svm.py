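"""Support-vector regression engine.

Caste identity is treated as a numeric response (worker = 0, queen = 1) and
fitted with epsilon-insensitive support-vector regression, so that classifier
estimates are continuous and may fall outside [0, 1]. The engine provides the
four classical kernels, repeated k-fold cross-validation with randomly
assigned bins, hyperparameter grid search, and the linear-primal feature
weights ``w = alpha^T S`` (dual coefficients times support vectors) used by
recursive feature elimination.

The quadratic program itself is solved by libsvm via scikit-learn;
predictions are recomputed here from the dual expansion
``f(x) = sum_i alpha_i k(s_i, x) + b`` so the stored model is self-contained.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR as _SKSVR

from .preprocess import Scaler

__all__ = [
    "KernelSpec",
    "SVRModel",
    "CVResult",
    "GridSearchResult",
    "kernel_value",
    "kernel_matrix",
    "fit_svr",
    "predict",
    "feature_weights",
    "cross_validation_error",
    "grid_search",
    "study_scaled_gamma",
    "default_refined_grid",
]

_KINDS = ("radial", "linear", "sigmoid", "polynomial")
_SK_KERNEL = {"radial": "rbf", "linear": "linear", "sigmoid": "sigmoid",
              "polynomial": "poly"}

#: gamma * n_features at the reference operating point (gamma = 1e-6 fitted on
#: a 10,734-gene transcriptome); used to transfer the radial kernel's length
#: scale to feature spaces of different dimension.
STUDY_GAMMA_TIMES_GENES = 1e-6 * 10734


def study_scaled_gamma(n_features: int) -> float:
    """Radial-kernel gamma scaled inversely with feature count.

    Keeps ``gamma * ||x - y||^2`` at the regime of the reference operating
    point (gamma = 1e-6 at 10,734 standardized genes), so the kernel neither
    collapses to a constant nor becomes needle-like as the gene set shrinks.
    """
    if n_features < 1:
        raise ValueError("n_features must be positive")
    return STUDY_GAMMA_TIMES_GENES / n_features


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind plus its parameters.

    radial:     exp(-gamma * ||x - y||^2)
    linear:     x . y
    sigmoid:    tanh(gamma * x . y + coef0)
    polynomial: (gamma * x . y + coef0) ** degree
    """

    kind: str
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; choose from {_KINDS}")
        if self.kind != "linear":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError(f"{self.kind} kernel requires gamma > 0")
        if self.kind == "polynomial" and (self.degree < 1 or int(self.degree) != self.degree):
            raise ValueError("polynomial degree must be a positive integer")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "gamma": self.gamma, "degree": self.degree,
                "coef0": self.coef0}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(kind=d["kind"], gamma=d.get("gamma"),
                   degree=int(d.get("degree", 3)), coef0=float(d.get("coef0", 0.0)))


def kernel_value(spec: KernelSpec, x, y) -> float:
    """Kernel similarity between two feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(kernel_matrix(spec, x[None, :], y[None, :])[0, 0])


def kernel_matrix(spec: KernelSpec, X, Y) -> np.ndarray:
    """Kernel Gram matrix between the rows of ``X`` and ``Y``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimension mismatch")
    if spec.kind == "radial":
        d2 = (
            np.sum(X * X, axis=1)[:, None]
            + np.sum(Y * Y, axis=1)[None, :]
            - 2.0 * X @ Y.T
        )
        np.maximum(d2, 0.0, out=d2)
        return np.exp(-spec.gamma * d2)
    dot = X @ Y.T
    if spec.kind == "linear":
        return dot
    if spec.kind == "sigmoid":
        return np.tanh(spec.gamma * dot + spec.coef0)
    return (spec.gamma * dot + spec.coef0) ** spec.degree


@dataclass
class SVRModel:
    """Fitted epsilon-SVR in dual form.

    ``dual_coef`` holds one signed alpha per support vector (``|alpha| <= C``);
    ``support_vectors`` the corresponding standardized training rows in
    ``gene_ids`` column order. ``scaler`` carries the training
    standardization statistics so queries can be placed on the training scale.
    """

    kernel: KernelSpec
    C: float
    epsilon: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gene_ids: list[str]
    scaler: Scaler | None = None
    normalization: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "kernel": self.kernel.to_dict(),
            "C": self.C,
            "epsilon": self.epsilon,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gene_ids": list(self.gene_ids),
            "scaler": self.scaler.to_dict() if self.scaler is not None else None,
            "normalization": self.normalization,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SVRModel":
        d = json.loads(text)
        return cls(
            kernel=KernelSpec.from_dict(d["kernel"]),
            C=float(d["C"]),
            epsilon=float(d["epsilon"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float).reshape(
                len(d["dual_coef"]), len(d["gene_ids"])),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gene_ids=[str(g) for g in d["gene_ids"]],
            scaler=Scaler.from_dict(d["scaler"]) if d.get("scaler") else None,
            normalization=d.get("normalization", {}),
        )


def fit_svr(X, y, spec: KernelSpec, C: float, epsilon: float,
            gene_ids=None, tol: float = 1e-6) -> SVRModel:
    """Fit epsilon-insensitive SVR on samples x features matrix ``X``.

    Deterministic for fixed inputs (the underlying SMO solver has no random
    state). ``tol`` is the solver's KKT stopping tolerance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be samples x features matching y")
    if X.shape[0] < 1:
        raise ValueError("at least 1 training sample is required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if C <= 0 or epsilon < 0:
        raise ValueError("require C > 0 and epsilon >= 0")
    if gene_ids is None:
        gene_ids = [f"f{i}" for i in range(X.shape[1])]
    gamma = spec.gamma if spec.kind != "linear" else "scale"
    sk = _SKSVR(kernel=_SK_KERNEL[spec.kind], C=C, epsilon=epsilon,
                gamma=gamma, degree=spec.degree, coef0=spec.coef0,
                tol=tol, max_iter=-1, cache_size=64)
    sk.fit(X, y)
    return SVRModel(
        kernel=spec,
        C=float(C),
        epsilon=float(epsilon),
        support_vectors=np.array(sk.support_vectors_, dtype=float),
        dual_coef=np.array(sk.dual_coef_, dtype=float).ravel(),
        intercept=float(sk.intercept_[0]),
        gene_ids=list(gene_ids),
    )


def predict(model: SVRModel, X, gene_ids=None) -> np.ndarray:
    """Evaluate the dual expansion ``sum_i alpha_i k(s_i, x) + b``.

    Estimates are deliberately not clipped to [0, 1]: a sample can be scored
    slightly above a queen or below a worker. If ``gene_ids`` is given it must
    match the model's feature order exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if gene_ids is not None and list(gene_ids) != list(model.gene_ids):
        raise ValueError("query gene order does not match the model's gene order")
    if X.shape[1] != len(model.gene_ids):
        raise ValueError(
            f"query has {X.shape[1]} features; model expects {len(model.gene_ids)}")
    if model.dual_coef.size == 0:
        return np.full(X.shape[0], model.intercept)
    K = kernel_matrix(model.kernel, X, model.support_vectors)
    return K @ model.dual_coef + model.intercept


def feature_weights(model: SVRModel) -> dict[str, float]:
    """Per-gene weights ``w = alpha^T S`` (dual coefficients x support vectors).

    This is the linear-primal weight vector; it is applied regardless of
    kernel as the elimination heuristic, exactly as in classical SVM-RFE.
    """
    if model.dual_coef.size == 0:
        w = np.zeros(len(model.gene_ids))
    else:
        w = model.dual_coef @ model.support_vectors
    return {g: float(v) for g, v in zip(model.gene_ids, w)}


@dataclass
class CVResult:
    """Repeated k-fold validation summary.

    ``mse`` is the mean over repeats of each repeat's mean squared error
    pooled across its held-out folds; ``rmse`` is its square root (the scale
    on which validation error is conventionally quoted for this classifier).
    """

    fold_errors: list[list[float]]  # per repeat, per fold: fold MSE
    repeat_errors: list[float]      # per repeat: pooled MSE over held-out samples
    mse: float
    rmse: float
    k: int
    repeats: int
    seed: int

    def to_dict(self) -> dict:
        return {"mse": self.mse, "rmse": self.rmse, "k": self.k,
                "repeats": self.repeats, "seed": self.seed,
                "repeat_errors": self.repeat_errors}


def _fold_assignment(n: int, k: int, rng: np.random.Generator,
                     canonical: np.ndarray) -> list[np.ndarray]:
    """Randomly assign ``n`` samples to ``k`` as-even-as-possible bins.

    ``canonical`` maps a canonical sample order to row positions so the
    partition depends only on the seed and the canonical order, not on the
    row order of the matrix.
    """
    perm = canonical[rng.permutation(n)]
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds, start = [], 0
    for s in sizes:
        folds.append(np.sort(perm[start:start + s]))
        start += s
    return folds


def cross_validation_error(X, y, spec: KernelSpec, C: float, epsilon: float,
                           k: int = 3, repeats: int = 20, seed: int = 0,
                           sample_ids=None) -> CVResult:
    """Repeated k-fold cross-validation error of an SVR configuration.

    For each repeat the samples are randomly partitioned into ``k`` bins;
    each bin is predicted by a model trained on the remaining bins, and the
    repeat's error is the mean squared error over all held-out predictions.
    The reported error is the mean over repeats. When ``sample_ids`` is
    supplied the partition is drawn after seeding on the *sorted* identifier
    order, making the result invariant to row permutations of ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples n={n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if sample_ids is not None:
        canonical = np.argsort(np.asarray(sample_ids, dtype=str), kind="stable")
    else:
        canonical = np.arange(n)
    rank_of_pos = np.empty(n, dtype=int)
    rank_of_pos[canonical] = np.arange(n)
    rng = np.random.default_rng(seed)
    fold_errors: list[list[float]] = []
    repeat_errors: list[float] = []
    for _ in range(repeats):
        folds = _fold_assignment(n, k, rng, canonical)
        per_fold = []
        sq_sum, count = 0.0, 0
        for held in folds:
            mask = np.ones(n, dtype=bool)
            mask[held] = False
            # rows in canonical order so the solver sees identical inputs
            # regardless of how the caller ordered the samples
            train_idx = np.flatnonzero(mask)
            train_idx = train_idx[np.argsort(rank_of_pos[train_idx])]
            held = held[np.argsort(rank_of_pos[held])]
            model = fit_svr(X[train_idx], y[train_idx], spec, C, epsilon)
            pred = predict(model, X[held])
            err = pred - y[held]
            per_fold.append(float(np.mean(err ** 2)))
            sq_sum += float(np.sum(err ** 2))
            count += held.size
        fold_errors.append(per_fold)
        repeat_errors.append(sq_sum / count)
    mse = float(np.mean(repeat_errors))
    return CVResult(fold_errors=fold_errors, repeat_errors=repeat_errors,
                    mse=mse, rmse=math.sqrt(mse), k=k, repeats=repeats,
                    seed=int(seed))


@dataclass
class GridSearchResult:
    grid: list[tuple[KernelSpec, float]]
    results: list[CVResult]
    selected_index: int

    @property
    def selected(self) -> tuple[KernelSpec, float]:
        return self.grid[self.selected_index]

    @property
    def selected_error(self) -> float:
        return self.results[self.selected_index].mse


def grid_search(X, y, grid, k: int = 3, repeats: int = 20, seed: int = 0,
                epsilon: float = 0.1, sample_ids=None) -> GridSearchResult:
    """Evaluate every ``(KernelSpec, C)`` grid point by repeated k-fold CV.

    All points share the same seed (hence the same fold assignments); the
    minimum mean validation error wins, ties broken by grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    results = [
        cross_validation_error(X, y, spec, C, epsilon, k=k, repeats=repeats,
                               seed=seed, sample_ids=sample_ids)
        for spec, C in grid
    ]
    errors = [r.mse for r in results]
    selected = int(np.argmin(errors))  # argmin returns the first minimum
    return GridSearchResult(grid=grid, results=results, selected_index=selected)


def default_refined_grid(n_points_c: int = 5, n_points_gamma: int = 5
                         ) -> list[tuple[KernelSpec, float]]:
    """Radial-kernel grid within the refined bounds 2^4 < C < 2^6, 1e-7 < gamma < 1e-5.

    Log-spaced interior points (the bounds are open), iterated gamma ascending
    then C ascending, matching the documented tie-break order.
    """
    log2_c = np.linspace(4, 6, n_points_c + 2)[1:-1]
    log10_g = np.linspace(-7, -5, n_points_gamma + 2)[1:-1]
    return [
        (KernelSpec(kind="radial", gamma=float(10.0 ** lg)), float(2.0 ** lc))
        for lg in log10_g
        for lc in log2_c
    ]
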