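"""Stacked deep joint-sparse selector (SDE-JS regression).

Chains E-JS layers: the base layer fits on the raw transposed features;
each subsequent layer ``s`` re-fits on the shifted input

.. math::

    X_s^T = X^T + \\sigma\\, Y_{s-1} Z_s,

where ``Y_{s-1} = X^T W_{s-1}`` is the previous layer's predicted output
and ``Z_s`` is a fresh ``c x d`` random projection with entries uniform
on [0, 1].  Following the stacked-generalization principle, these random
shifts progressively "open" the manifold of the training distribution so
the input becomes more linearly separable; the final feature ranking is
read from the last layer's ``W``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ejs import (
    SCORE_MODES,
    EjsFit,
    FeatureMatrix,
    LabelMatrix,
    RankingResult,
    _zscore,
    fit_ejs,
    fit_on_shifted,
)
from .solver import SolverConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StackConfig:
    """Hyperparameters of the stacked selector.

    ``m`` counts the stacked refinement layers fitted after the base
    layer, so a model holds ``m + 1`` layers in total.  ``sigma`` scales
    the random shift; at ``sigma = 0`` (or ``m = 0``) the model reduces
    exactly to single-layer E-JS.  One seed drives all per-layer ``Z``
    draws through a single generator stream.
    """

    theta: float = 0.01
    sigma: float = 0.1
    m: int = 5
    seed: int = 0
    solver: SolverConfig = field(default_factory=SolverConfig)
    score_mode: str = "row-l2"
    standardize: bool = False

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.m < 0:
            raise ValueError(f"m must be nonnegative, got {self.m}")
        if self.score_mode not in SCORE_MODES:
            raise ValueError(f"score_mode must be one of {SCORE_MODES}")


@dataclass
class StackedLayer:
    """One fitted layer: its ``W``, the projection ``Z`` that shifted its
    input (absent for the base layer), and its propagated output
    ``Y_s = X^T W``."""

    fit: EjsFit
    Z: np.ndarray | None
    Y_out: np.ndarray

    @property
    def W(self) -> np.ndarray:
        return self.fit.W

    @property
    def objective_trace(self) -> list:
        return self.fit.solver_result.objective_trace


@dataclass
class StackedModel:
    layers: list
    final_ranking: RankingResult
    feature_ids: list

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def W(self) -> np.ndarray:
        """The last layer's transformation matrix (the ranking source)."""
        return self.layers[-1].W


def make_random_projection(c: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a ``c x d`` projection with i.i.d. entries uniform on [0, 1]."""
    if c < 1 or d < 1:
        raise ValueError("projection dimensions must be >= 1")
    return rng.random((c, d))


def shift_input(
    X: FeatureMatrix | np.ndarray,
    Y_prev: np.ndarray,
    Z: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Compute the shifted layer input ``X^T + sigma * Y_prev @ Z``.

    Warns when the Frobenius norm of the shift exceeds that of the
    original input — the regime where too aggressive shifting distorts
    the training distribution instead of opening it.
    """
    Xt = (X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)).T
    Y_prev = np.asarray(Y_prev, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Y_prev.shape[0] != Xt.shape[0] or Z.shape != (Y_prev.shape[1], Xt.shape[1]):
        raise ValueError(
            f"inconsistent shapes: X^T {Xt.shape}, Y_prev {Y_prev.shape}, Z {Z.shape}"
        )
    shift = sigma * (Y_prev @ Z)
    x_norm = np.linalg.norm(Xt)
    if x_norm > 0 and np.linalg.norm(shift) > x_norm:
        warnings.warn(
            "random shift norm exceeds the input norm; the shifted "
            "distribution may be heavily distorted (consider smaller "
            "sigma or fewer layers)",
            RuntimeWarning,
            stacklevel=2,
        )
    return Xt + shift


def fit_sdejs(
    X: FeatureMatrix, Y: LabelMatrix, config: StackConfig | None = None
) -> StackedModel:
    """Fit the stacked selector.

    The base layer is plain E-JS (zero previous output, no shift); each
    of the ``config.m`` refinement layers draws a fresh projection,
    shifts the input, re-fits, and propagates ``Y_s = X^T W``.  With a
    fixed seed the whole procedure, including every ``Z`` draw, is
    deterministic.
    """
    if config is None:
        config = StackConfig()
    if X.n_samples != Y.n_samples:
        raise ValueError(f"X has {X.n_samples} samples but Y has {Y.n_samples}")

    rng = np.random.default_rng(config.seed)
    Xt = X.values.T
    if config.standardize:
        Xt = _zscore(Xt)
    d, c = X.n_features, Y.n_classes

    layers: list[StackedLayer] = []
    try:
        base = fit_on_shifted(Xt, Y, config.theta, config.solver)
    except Exception as exc:
        raise RuntimeError(f"solver failed at base layer (layer 0): {exc}") from exc
    Y_out = Xt @ base.W
    layers.append(StackedLayer(fit=base, Z=None, Y_out=Y_out))
    logger.info(
        "layer 0 (base): %d iterations, objective %.6g",
        base.solver_result.iterations,
        base.solver_result.objective_trace[-1],
    )
    logger.debug("layer 0 objective trace: %s", base.solver_result.objective_trace)

    for s in range(1, config.m + 1):
        Z = make_random_projection(c, d, rng)
        X_s = shift_input(Xt.T, layers[-1].Y_out, Z, config.sigma)
        try:
            fit = fit_on_shifted(X_s, Y, config.theta, config.solver)
        except Exception as exc:
            raise RuntimeError(f"solver failed at stacked layer {s}: {exc}") from exc
        Y_out = Xt @ fit.W
        layers.append(StackedLayer(fit=fit, Z=Z, Y_out=Y_out))
        logger.info(
            "layer %d: %d iterations, objective %.6g",
            s,
            fit.solver_result.iterations,
            fit.solver_result.objective_trace[-1],
        )
        logger.debug("layer %d objective trace: %s", s, fit.solver_result.objective_trace)

    final_ranking = layers[-1].fit.ranking(mode=config.score_mode)
    return StackedModel(
        layers=layers, final_ranking=final_ranking, feature_ids=list(X.feature_ids)
    )


def select_top_k(model: StackedModel, k: int) -> list:
    """The ``k`` highest-ranked feature identifiers, best first."""
    idx = model.final_ranking.top_k(k)
    return [model.feature_ids[i] for i in idx]
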