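"""Accelerated proximal-gradient solver shared by the two penalized
pseudo-likelihood fits (graph structure learning and CRF training).

Monotone FISTA: Nesterov momentum on the proximal-gradient step with a
backtracking (adaptive) line search for the step size, and a monotonicity
safeguard so the accepted objective never increases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["ProxGradResult", "prox_gradient"]


@dataclass
class ProxGradResult:
    x: np.ndarray
    objective: float
    trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def prox_gradient(
    smooth: Callable[[np.ndarray], tuple[float, np.ndarray]],
    penalty: Callable[[np.ndarray], float],
    prox: Callable[[np.ndarray, float], np.ndarray],
    x0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    step0: float = 1.0,
) -> ProxGradResult:
    """Minimize smooth(x) + penalty(x) with penalty handled by its prox.

    ``smooth`` returns (value, gradient); ``prox(v, t)`` solves
    argmin_u penalty(u) + ||u - v||^2 / (2 t).  The line search halves the
    step until the quadratic upper bound holds, and grows it slowly between
    iterations; a candidate that would increase the total objective is
    rejected in favour of the previous iterate (momentum still advances).
    """
    x = np.asarray(x0, dtype=float).copy()
    y = x.copy()
    t_mom = 1.0
    step = step0
    f_x, _ = smooth(x)
    best_obj = f_x + penalty(x)
    trace = [best_obj]
    converged = False
    stalls = 0
    it = 0
    for it in range(1, max_iter + 1):
        f_y, g_y = smooth(y)
        # backtracking line search on the smooth part
        for _ in range(60):
            z = prox(y - step * g_y, step)
            dz = z - y
            f_z, _ = smooth(z)
            if f_z <= f_y + g_y @ dz + (dz @ dz) / (2.0 * step) + 1e-12:
                break
            step *= 0.5
        obj_z = f_z + penalty(z)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        if obj_z <= best_obj:
            accepted = True
            x_next = z
            obj_next = obj_z
            stalls = 0
        else:  # monotone safeguard
            accepted = False
            x_next = x
            obj_next = best_obj
            stalls += 1
        y = x_next + (t_mom / t_next) * (z - x_next) + ((t_mom - 1.0) / t_next) * (x_next - x)
        rel_change = abs(best_obj - obj_next) / max(1.0, abs(best_obj))
        x, best_obj, t_mom = x_next, obj_next, t_next
        trace.append(best_obj)
        step = min(step * 1.2, 1e6)
        if (accepted and rel_change < tol and it > 1) or stalls >= 10:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"proximal gradient did not converge in {it} iterations "
            f"(last objective {best_obj:.6g}); returning best iterate",
            RuntimeWarning,
        )
    return ProxGradResult(x=x, objective=best_obj, trace=trace, n_iter=it,
                          converged=converged)
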