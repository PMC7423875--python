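"""Independent reference solution of min ||V||_2,1 s.t. KV = Y.

Deliberately shares no machinery with the package's IRLS solver: the
feasible set is parametrized explicitly as V = V0 + N T (V0 a
least-squares particular solution, N an orthonormal null-space basis of
K), and the smoothed objective sum_i sqrt(||v^i||^2 + delta) is
minimized without constraints by L-BFGS.  The problem is convex, so any
local minimum is global.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import lstsq, null_space
from scipy.optimize import minimize


def oracle_min_l21(K: np.ndarray, Y: np.ndarray, delta: float = 1e-12):
    """Return ``(V_opt, objective)`` for min ||V||_2,1 s.t. KV = Y."""
    V0 = lstsq(K, Y)[0]
    N = null_space(K)
    c = Y.shape[1]
    if N.shape[1] == 0:  # constraint determines V uniquely
        return V0, float(np.sqrt((V0 * V0).sum(axis=1)).sum())

    def fun(tflat):
        T = tflat.reshape(N.shape[1], c)
        V = V0 + N @ T
        row = np.sqrt((V * V).sum(axis=1) + delta)
        grad = N.T @ (V / row[:, None])
        return float(row.sum()), grad.ravel()

    res = minimize(
        fun,
        np.zeros(N.shape[1] * c),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 50000, "maxfun": 100000, "ftol": 1e-15, "gtol": 1e-10},
    )
    V = V0 + N @ res.x.reshape(N.shape[1], c)
    return V, float(np.sqrt((V * V).sum(axis=1)).sum())
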