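"""Damped Gauss-Newton for small dense nonlinear least-squares problems.

Each fitting stage of the pipeline minimises a sum of squared residuals.  The
residual callback returns both the residual vector and its analytic Jacobian;
the solver iterates ``p <- p - (J'J + mu*I)^-1 J'r`` with Levenberg damping
``mu`` adapted so that accepted steps never increase the objective.  Plain
Gauss-Newton (``mu = 0``) is tried first, so linear problems converge in a
single undamped iteration; damping only engages when a step would increase
the cost, which preserves the fixed points of the undamped method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Tuple

import numpy as np

from .errors import NonConvergenceError


@dataclass
class SolverConfig:
    max_iter: int = 100
    xtol: float = 1e-10  # parameter-step tolerance (relative)
    ftol: float = 1e-14  # cost-decrease tolerance (relative)
    mu_init: float = 0.0  # initial Levenberg damping
    mu_up: float = 10.0
    mu_down: float = 3.0
    mu_min: float = 1e-10
    mu_max: float = 1e10
    fd_step: float = 1e-6  # finite-difference step, used only by checks

    def __post_init__(self):
        if self.xtol <= 0 or self.ftol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ConvergenceReport:
    converged: bool
    reason: str
    n_iter: int
    cost: float
    cost_trace: List[float] = field(default_factory=list)

    def __bool__(self):
        return self.converged


ResidualFn = Callable[[np.ndarray], Tuple[np.ndarray, np.ndarray]]


def gauss_newton(
    residual_fn: ResidualFn,
    x0: np.ndarray,
    config: SolverConfig | None = None,
    raise_on_failure: bool = False,
) -> Tuple[np.ndarray, ConvergenceReport]:
    """Minimise ``0.5 * ||r(x)||^2`` given ``residual_fn(x) -> (r, J)``.

    Returns the final parameters and a convergence report whose ``cost_trace``
    contains the accepted (never increasing) objective values.
    """
    cfg = config or SolverConfig()
    x = np.asarray(x0, dtype=float).copy()
    r, J = residual_fn(x)
    cost = float(r @ r)
    trace = [cost]
    mu = cfg.mu_init
    reason = "max_iter"
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        while True:
            try:
                step = np.linalg.solve(JtJ + mu * np.eye(JtJ.shape[0]), g)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and np.all(np.isfinite(step)):
                x_new = x - step
                r_new, J_new = residual_fn(x_new)
                cost_new = float(r_new @ r_new)
                if np.isfinite(cost_new) and cost_new <= cost:
                    accepted = True
                    break
            if mu >= cfg.mu_max:
                break
            mu = max(cfg.mu_min, mu * cfg.mu_up) if mu > 0 else cfg.mu_min * 1e4
        if not accepted:
            reason = "damping_exhausted"
            break
        decrease = cost - cost_new
        step_small = np.linalg.norm(step) <= cfg.xtol * (1.0 + np.linalg.norm(x))
        x, r, J, cost = x_new, r_new, J_new, cost_new
        trace.append(cost)
        mu = 0.0 if mu <= cfg.mu_min else mu / cfg.mu_down
        if step_small or decrease <= cfg.ftol * (1.0 + cost):
            converged = True
            reason = "step_tol" if step_small else "ftol"
            break
    report = ConvergenceReport(converged, reason, it, cost, trace)
    if not converged and raise_on_failure:
        raise NonConvergenceError(f"Gauss-Newton failed to converge: {reason}", report)
    return x, report


def numerical_jacobian(residual_fn: ResidualFn, x: np.ndarray, step: float = 1e-6):
    """Central finite-difference Jacobian (testing aid for analytic Jacobians)."""
    x = np.asarray(x, dtype=float)
    r0, _ = residual_fn(x)
    J = np.zeros((r0.shape[0], x.shape[0]))
    for k in range(x.shape[0]):
        h = step * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        rp, _ = residual_fn(xp)
        rm, _ = residual_fn(xm)
        J[:, k] = (rp - rm) / (2 * h)
    return J
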