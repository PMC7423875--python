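"""Equality-constrained :math:`\\ell_{2,1}` minimization via iteratively
reweighted least squares (IRLS).

The core problem is

.. math::

    \\min_V \\; \\|V\\|_{2,1} \\quad \\text{s.t.} \\quad K V = Y,

where :math:`\\|V\\|_{2,1} = \\sum_i \\|v^i\\|_2` sums the Euclidean norms of
the rows of ``V``.  Each IRLS step freezes a diagonal row-weight matrix
``G`` (``g_ii = 1 / (2 sqrt(||v^i||^2 + delta))``) and solves the weighted
least-norm problem in closed form,

.. math::

    V^{(t+1)} = G^{-1} K^T (K G^{-1} K^T)^{-1} Y,

which satisfies the constraint exactly by construction.  The small damping
``delta`` smooths the weight update at zero rows; the iteration then
monotonically decreases the smoothed objective
:math:`\\sum_i \\sqrt{\\|v^i\\|_2^2 + \\delta}` by the standard
majorize-minimize argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve


@dataclass(frozen=True)
class SolverConfig:
    """Convergence controls for the IRLS iteration.

    Parameters
    ----------
    tol
        Stop when the absolute change of the (smoothed) objective between
        consecutive iterates falls below this threshold.
    max_iter
        Hard cap on the number of IRLS steps.
    damping
        Smoothing constant ``delta`` added under the square root of the
        row-weight update; removes the division-by-zero at all-zero rows
        while leaving the fixed point unchanged as ``delta -> 0``.
    """

    tol: float = 1e-6
    max_iter: int = 100
    damping: float = 1e-12

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if not self.damping > 0:
            raise ValueError(f"damping must be positive, got {self.damping}")


@dataclass(frozen=True)
class ConstraintSystem:
    """The pair ``(K, Y)`` of an equality-constrained l2,1 problem.

    ``K`` is ``n x h`` (for the selector modules ``h = n + d``) and must
    have full row rank for the closed-form update to exist; ``Y`` is
    ``n x c``.
    """

    K: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if K.ndim != 2 or Y.ndim != 2:
            raise ValueError("K and Y must be 2-D arrays")
        if K.shape[0] != Y.shape[0]:
            raise ValueError(
                f"row counts of K and Y disagree: {K.shape[0]} vs {Y.shape[0]}"
            )
        if not (np.isfinite(K).all() and np.isfinite(Y).all()):
            raise ValueError("K and Y must be finite")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "Y", Y)

    @property
    def n_constraints(self) -> int:
        return self.K.shape[0]

    @property
    def n_variables(self) -> int:
        return self.K.shape[1]


@dataclass
class SolverResult:
    """Outcome of :func:`solve_constrained_l21`.

    ``V`` stacks the selector's transformation matrix on top of the slack
    block; ``objective_trace`` records the smoothed l2,1 objective after
    each closed-form update and is non-increasing up to numerical noise.
    """

    V: np.ndarray
    objective_trace: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def l21_norm(M: np.ndarray) -> float:
    """Sum of the Euclidean norms of the rows of ``M``.

    Penalizing this norm drives entire rows to zero, i.e. joint sparsity
    across columns.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("l21_norm requires a non-empty 2-D matrix")
    return float(np.sqrt((M * M).sum(axis=1)).sum())


def smoothed_l21_norm(M: np.ndarray, damping: float) -> float:
    """``sum_i sqrt(||m^i||^2 + damping)`` — the objective IRLS decreases."""
    M = np.asarray(M, dtype=float)
    return float(np.sqrt((M * M).sum(axis=1) + damping).sum())


def update_row_weights(V: np.ndarray, damping: float) -> np.ndarray:
    """Diagonal of the IRLS weight matrix ``G`` for the current iterate.

    Row ``i`` gets ``g_ii = 1 / (2 sqrt(||v^i||^2 + damping))``; ``damping``
    keeps every entry finite and positive even for all-zero rows.
    """
    if not damping > 0:
        raise ValueError("damping must be positive")
    V = np.asarray(V, dtype=float)
    return 1.0 / (2.0 * np.sqrt((V * V).sum(axis=1) + damping))


def _solve_spd(M: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve ``M B = Y`` for symmetric positive-definite ``M``.

    One retry with a trace-scaled jitter covers near-singular systems;
    beyond that the constraint matrix is effectively rank deficient.
    """
    try:
        return cho_solve(cho_factor(M), Y)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(M)
        try:
            return cho_solve(cho_factor(M + jitter * np.eye(M.shape[0])), Y)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "K G^-1 K^T is not positive definite even after jitter; "
                "K is likely rank deficient (the constrained problem needs "
                "full row rank)"
            ) from exc


def solve_constrained_l21(
    system: ConstraintSystem, config: SolverConfig | None = None
) -> SolverResult:
    """Minimize ``||V||_2,1`` subject to ``K V = Y`` by IRLS.

    The weight matrix starts at the identity, so the first iterate is the
    minimum-Frobenius-norm feasible point; every subsequent iterate stays
    exactly feasible and the smoothed objective is non-increasing.  The
    diagonal of ``G`` is kept as a vector — it is never materialized as a
    dense ``h x h`` matrix.

    Returns
    -------
    SolverResult
        with ``converged`` set when the objective change dropped below
        ``config.tol`` within ``config.max_iter`` steps.
    """
    if config is None:
        config = SolverConfig()
    K, Y = system.K, system.Y
    h = K.shape[1]

    g = np.ones(h)  # diagonal of G, identity start
    V = np.zeros((h, Y.shape[1]))
    trace: list[float] = []
    prev_obj = np.inf
    converged = False
    iterations = 0

    for _ in range(config.max_iter):
        inv_g = 1.0 / g
        KGinv = K * inv_g  # K G^{-1}, n x h
        M = KGinv @ K.T  # K G^{-1} K^T, SPD for full-row-rank K
        B = _solve_spd(M, Y)
        V = inv_g[:, None] * (K.T @ B)
        iterations += 1

        if iterations == 1:
            # Feasibility holds by construction only when K has full row
            # rank; a large first-iterate residual flags a deficient or
            # inconsistent system that the jitter retry papered over.
            y_norm = np.linalg.norm(Y)
            resid = np.linalg.norm(K @ V - Y)
            if resid > 1e-8 * max(y_norm, 1.0):
                raise np.linalg.LinAlgError(
                    f"constraint residual {resid:.3e} after the closed-form "
                    "update; K is rank deficient or the system K V = Y is "
                    "inconsistent"
                )

        obj = smoothed_l21_norm(V, config.damping)
        trace.append(obj)
        if abs(prev_obj - obj) < config.tol:
            converged = True
            break
        prev_obj = obj
        g = update_row_weights(V, config.damping)

    return SolverResult(
        V=V, objective_trace=trace, iterations=iterations, converged=converged
    )
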