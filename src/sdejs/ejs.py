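"""Single-layer embedded joint-sparse selector (E-JS regression).

Fits the transformation matrix ``W`` of

.. math::

    \\min_W \\; \\tfrac{1}{\\theta}\\,\\|\\tilde X W - Y\\|_{2,1}
            + \\|W\\|_{2,1},

where ``X~`` is the ``n x d`` (possibly shifted) sample matrix and ``Y``
the ``n x c`` one-hot label matrix.  Introducing the scaled residual
``Q = (Y - X~ W) / theta`` turns this into the equality-constrained
problem ``min ||[W; Q]||_2,1 s.t. [X~, theta*I] [W; Q] = Y`` handled by
:mod:`sdejs.solver`.  The l2,1 penalty zeroes whole rows of ``W``, so the
surviving row norms rank features consistently across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solver import ConstraintSystem, SolverConfig, SolverResult, solve_constrained_l21

SCORE_MODES = ("row-l2", "abs-sum")


@dataclass
class FeatureMatrix:
    """A ``d features x n samples`` data matrix with identifiers."""

    values: np.ndarray
    feature_ids: list = None
    sample_ids: list = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x samples)")
        d, n = self.values.shape
        if d < 1 or n < 2:
            raise ValueError(f"need >=1 feature and >=2 samples, got {d} x {n}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")
        if self.feature_ids is None:
            self.feature_ids = [f"f{i}" for i in range(d)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{j}" for j in range(n)]
        if len(self.feature_ids) != d or len(self.sample_ids) != n:
            raise ValueError("identifier lengths do not match the matrix shape")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[:, idx],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[j] for j in idx],
        )

    def subset_features(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx, :],
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class LabelMatrix:
    """``n samples x c classes`` one-hot class indicator matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("label matrix entries must be 0 or 1")
        if not (self.values.sum(axis=1) == 1).all():
            raise ValueError("each label row must have exactly one unit entry")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def labels(self) -> np.ndarray:
        return self.values.argmax(axis=1)


@dataclass
class RankingResult:
    """Per-feature scores and the descending-score feature permutation."""

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        d = self.scores.shape[0]
        if sorted(self.order.tolist()) != list(range(d)):
            raise ValueError("order is not a permutation of 0..d-1")
        s = self.scores[self.order]
        if np.any(np.diff(s) > 0):
            raise ValueError("order does not sort scores in descending order")

    def top_k(self, k: int) -> np.ndarray:
        if not 1 <= k <= len(self.order):
            raise ValueError(f"k={k} out of range 1..{len(self.order)}")
        return self.order[:k]


@dataclass
class EjsFit:
    """A fitted single layer: ``W`` ranks features, ``Q`` absorbs the
    scaled residual, and ``X~ W + theta Q = Y`` holds at the solution."""

    W: np.ndarray
    Q: np.ndarray
    theta: float
    solver_result: SolverResult = field(repr=False, default=None)

    def ranking(self, mode: str = "row-l2") -> RankingResult:
        return rank_features(feature_scores(self.W, mode=mode))


def build_augmented_system(
    X_shifted: np.ndarray, Y: LabelMatrix | np.ndarray, theta: float
) -> ConstraintSystem:
    """Assemble ``K = [X~, theta * I_n]`` and pair it with ``Y``.

    The ``theta * I`` block guarantees full row rank for any ``X~`` when
    ``theta > 0``, so the IRLS closed form always applies.
    """
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    X_shifted = np.asarray(X_shifted, dtype=float)
    Yv = Y.values if isinstance(Y, LabelMatrix) else np.asarray(Y, dtype=float)
    n = X_shifted.shape[0]
    if Yv.shape[0] != n:
        raise ValueError(
            f"sample counts disagree: X~ has {n} rows, Y has {Yv.shape[0]}"
        )
    K = np.hstack([X_shifted, theta * np.eye(n)])
    return ConstraintSystem(K=K, Y=Yv)


def fit_on_shifted(
    X_shifted: np.ndarray,
    Y: LabelMatrix,
    theta: float,
    config: SolverConfig | None = None,
) -> EjsFit:
    """Fit one E-JS layer on an already-transposed (and possibly shifted)
    ``n x d`` input; used directly by the stacked selector."""
    d = X_shifted.shape[1]
    system = build_augmented_system(X_shifted, Y, theta)
    result = solve_constrained_l21(system, config)
    W = result.V[:d, :]
    Q = result.V[d:, :]
    return EjsFit(W=W, Q=Q, theta=theta, solver_result=result)


def fit_ejs(
    X: FeatureMatrix,
    Y: LabelMatrix,
    theta: float,
    config: SolverConfig | None = None,
    standardize: bool = False,
) -> EjsFit:
    """Fit E-JS regression on raw features (no shift, ``X~ = X^T``).

    Parameters
    ----------
    X, Y
        Feature matrix (d x n) and one-hot labels (n x c); sample counts
        must agree.
    theta
        Trade-off between the fitting loss and the row-sparsity penalty;
        larger values push more rows of ``W`` toward zero.
    standardize
        Optionally z-score each feature before fitting.  Off by default:
        raw amplitudes are a meaningful common scale for signal data.
    """
    if X.n_samples != Y.n_samples:
        raise ValueError(
            f"X has {X.n_samples} samples but Y has {Y.n_samples}"
        )
    Xt = X.values.T
    if standardize:
        Xt = _zscore(Xt)
    return fit_on_shifted(Xt, Y, theta, config)


def _zscore(Xt: np.ndarray) -> np.ndarray:
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xt - mu) / sd


def scale_features(X: FeatureMatrix) -> FeatureMatrix:
    """Scale every feature to unit standard deviation (no centering).

    Row norms of ``W`` are only comparable across features that share a
    scale, so heterogeneous-scale data should be scaled before ranking.
    Centering is deliberately not applied: the regression has no
    intercept, and removing feature means strips signal the model can
    otherwise use to fit the label offsets.
    """
    sd = X.values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return FeatureMatrix(
        X.values / sd,
        feature_ids=list(X.feature_ids),
        sample_ids=list(X.sample_ids),
    )


def feature_scores(W: np.ndarray, mode: str = "row-l2") -> np.ndarray:
    """Collapse ``W`` (d x c) to one nonnegative score per feature.

    ``row-l2`` (default) scores feature ``i`` by ``||w^i||_2``, matching
    the row-sparsity structure of the penalty; ``abs-sum`` uses
    ``sum_j |w_ij|`` instead.
    """
    W = np.asarray(W, dtype=float)
    if not np.isfinite(W).all():
        raise ValueError("W must be finite")
    if mode == "row-l2":
        return np.sqrt((W * W).sum(axis=1))
    if mode == "abs-sum":
        return np.abs(W).sum(axis=1)
    raise ValueError(f"unknown score mode {mode!r}; expected one of {SCORE_MODES}")


def rank_features(scores: np.ndarray) -> RankingResult:
    """Descending-score permutation; ties broken by ascending feature
    index so rankings are reproducible."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    order = np.argsort(-scores, kind="stable")
    return RankingResult(scores=scores, order=order)
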