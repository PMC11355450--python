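"""Fast fixed-step integration of the normal geodesic system.

The shooting solver evaluates the endpoint map thousands of times inside
a root search, so the inner loop is a jitted classical RK4 over the
8-dimensional state ``(x, y, theta, sigma, h1, h2, h3, h4)``.  With the
step counts used by the solver the local truncation error is orders of
magnitude below the shooting residual tolerance; converged candidates
are re-integrated with an adaptive high-order scheme before being
returned to callers.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rhs(y: np.ndarray) -> np.ndarray:
    """Right-hand side of the normal Hamiltonian system (arc length)."""
    out = np.empty(8)
    es = np.exp(y[3])
    c = np.cos(y[2])
    s = np.sin(y[2])
    h1, h2, h3, h4 = y[4], y[5], y[6], y[7]
    out[0] = h1 * es * c
    out[1] = h1 * es * s
    out[2] = h3
    out[3] = h4
    out[4] = h3 * h2 + h4 * h1
    out[5] = -h3 * h1 + h4 * h2
    out[6] = -h1 * h2
    out[7] = -h1 * h1
    return out


@njit(cache=True)
def rk4_endpoint(y0: np.ndarray, T: float, n_steps: int) -> tuple:
    """Integrate to time T; return (state, total variation of theta)."""
    y = y0.copy()
    h = T / n_steps
    tv = 0.0
    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        step = (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        tv += abs(step[2])
        y += step
    return y, tv


def endpoint(y0: np.ndarray, T: float, steps_per_unit: float = 400.0) -> tuple:
    """Endpoint of the geodesic flow after time T (fixed-step RK4).

    Returns ``(state, theta_total_variation)``.
    """
    if T == 0.0:
        return y0.copy(), 0.0
    n = max(32, int(abs(T) * steps_per_unit))
    return rk4_endpoint(np.asarray(y0, dtype=float), float(T), n)
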