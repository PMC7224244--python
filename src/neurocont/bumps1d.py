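"""Stationary bumps of a 1D neural field on the circle, via a cosine-Galerkin basis.

The field equation on ``[-pi, pi]`` with periodic boundary conditions,

    du/dt = -u(x) + int_{-pi}^{pi} w(x - y) f(u(y) - h) dy,

is translation invariant, so we restrict to even solutions and expand
``u(x) = sum_i u_i cos(i x)``, ``w(x) = sum_i w_i cos(i x)``.  Projecting
onto each cosine mode gives the steady-state system

    0 = -u_j + w_j * int cos(j y) f(sum_i u_i cos(i y) - h) dy,

truncated at ``N`` modes.  If the kernel's cosine series is finite
(``w_i = 0`` for ``i > NF``), truncation at ``N = NF + 1`` is exact.
Integrals use the trapezoidal rule on the periodic domain, where it is
spectrally accurate.

Continuation in the firing threshold ``h`` traces the classic pair of
bump branches (one stable, one unstable) that annihilate in a saddle-node
bifurcation; the translational zero mode is absent by construction since
only even perturbations are represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .continuation import (
    BranchPoint,
    ContinuationProblem,
    ContinuationSettings,
    NewtonFailure,
    continue_branch,
)
from .models import CouplingKernel, firing_rate, kernel_eval, mexican_hat_1d

__all__ = [
    "BumpProblem",
    "kernel_cosine_coefficients",
    "bump_residual",
    "bump_jacobian",
    "reconstruct_field",
    "time_step_modes",
    "initial_bump",
    "continue_bumps_in_h",
]


def kernel_cosine_coefficients(kernel, N, M=128):
    """Cosine-series coefficients ``w_0 .. w_{N-1}`` of an even 1D kernel.

    ``w_0 = (1/2pi) int w``, ``w_j = (1/pi) int w cos(jx) dx`` for j >= 1,
    computed by the trapezoidal rule on ``M`` equispaced nodes over
    ``[-pi, pi)``.  Requires ``M >= 4N`` to keep the modes alias-free.
    """
    if callable(kernel) and not isinstance(kernel, CouplingKernel):
        w_fun = kernel
    else:
        w_fun = lambda x: kernel_eval(kernel, x)
    if M < 4 * N:
        raise ValueError(f"quadrature resolution M={M} < 4N={4*N}: aliasing risk")
    x = -np.pi + 2.0 * np.pi * np.arange(M) / M
    wx = np.asarray(w_fun(x), dtype=float)
    j = np.arange(N)
    # trapezoid on a periodic grid == plain mean * interval length
    proj = (2.0 * np.pi / M) * (np.cos(np.outer(j, x)) @ wx)
    coeffs = proj / np.pi
    coeffs[0] *= 0.5
    return coeffs


@dataclass
class BumpProblem:
    """Discretised even-bump steady-state problem.

    N : number of cosine modes; beta, h : firing-rate steepness/threshold;
    kernel : the coupling kernel (cosine coefficients are precomputed);
    M : trapezoid nodes on [-pi, pi).
    """

    N: int = 15
    beta: float = 20.0
    h: float = 0.3
    kernel: CouplingKernel = field(default_factory=mexican_hat_1d)
    M: int = 128

    def __post_init__(self):
        self.kernel_coeffs = kernel_cosine_coefficients(self.kernel, self.N, self.M)
        self.quad_nodes = -np.pi + 2.0 * np.pi * np.arange(self.M) / self.M
        # M x N cosine design matrix: C[m, i] = cos(i * y_m)
        self.cos_table = np.cos(np.outer(self.quad_nodes, np.arange(self.N)))


def reconstruct_field(coeffs, x):
    """Evaluate ``u(x) = sum_i u_i cos(i x)`` at arbitrary points."""
    coeffs = np.asarray(coeffs, float)
    x = np.asarray(x, float)
    return np.cos(np.multiply.outer(x, np.arange(coeffs.size))) @ coeffs


def bump_residual(coeffs, problem, h=None):
    """Galerkin residual: ``-u_j + w_j int cos(jy) f(u(y) - h) dy`` for each mode."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size != problem.N:
        raise ValueError(f"expected {problem.N} coefficients, got {coeffs.size}")
    if h is None:
        h = problem.h
    u_y = problem.cos_table @ coeffs
    f, _ = firing_rate(u_y - h, problem.beta)
    dy = 2.0 * np.pi / problem.M
    integrals = dy * (problem.cos_table.T @ f)
    return -coeffs + problem.kernel_coeffs * integrals


def bump_jacobian(coeffs, problem, h=None):
    """Assembled N x N Jacobian of :func:`bump_residual` with respect to the modes."""
    coeffs = np.asarray(coeffs, dtype=float)
    if h is None:
        h = problem.h
    u_y = problem.cos_table @ coeffs
    _, fp = firing_rate(u_y - h, problem.beta)
    dy = 2.0 * np.pi / problem.M
    J = dy * (problem.kernel_coeffs[:, None]
              * (problem.cos_table.T @ (fp[:, None] * problem.cos_table)))
    return J - np.eye(problem.N)


def _bump_dh(coeffs, problem, h):
    """Derivative of the residual with respect to the threshold h."""
    u_y = problem.cos_table @ coeffs
    _, fp = firing_rate(u_y - h, problem.beta)
    dy = 2.0 * np.pi / problem.M
    return -problem.kernel_coeffs * (dy * (problem.cos_table.T @ fp))


def time_step_modes(problem, coeffs0, T=60.0, dt=0.01, settle_tol=1e-8):
    """Integrate the truncated mode ODEs ``du_j/dt = residual_j`` by classical RK4.

    Returns the state at time ``T`` (earlier if the time-derivative norm
    drops below ``settle_tol``) together with the final derivative norm.
    """
    u = np.asarray(coeffs0, dtype=float).copy()
    rhs = lambda c: bump_residual(c, problem)
    n_steps = int(np.ceil(T / dt))
    drift = np.linalg.norm(rhs(u))
    for _ in range(n_steps):
        k1 = rhs(u)
        k2 = rhs(u + 0.5 * dt * k1)
        k3 = rhs(u + 0.5 * dt * k2)
        k4 = rhs(u + dt * k3)
        u = u + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.linalg.norm(u) > 1e6:
            raise FloatingPointError("mode time-stepping blew up")
        drift = np.linalg.norm(k1)
        if drift < settle_tol:
            break
    return u, drift


def initial_bump(problem, width=0.5, amplitude=3.0, T=60.0, newton_tol=1e-12):
    """Construct a converged bump: project a Gaussian onto the cosine modes,
    time-step the mode ODEs until settled, then Newton-polish."""
    x = problem.quad_nodes
    guess_field = amplitude * np.exp(-(x / width) ** 2)
    dy = 2.0 * np.pi / problem.M
    coeffs = dy * (problem.cos_table.T @ guess_field) / np.pi
    coeffs[0] *= 0.5
    coeffs, _ = time_step_modes(problem, coeffs, T=T)
    for _ in range(50):
        r = bump_residual(coeffs, problem)
        if np.linalg.norm(r) < newton_tol:
            break
        coeffs = coeffs - np.linalg.solve(bump_jacobian(coeffs, problem), r)
    else:
        raise NewtonFailure("initial bump polish did not converge",
                            state=coeffs, parameter=problem.h)
    if np.linalg.norm(coeffs) < 1e-6:
        raise NewtonFailure("time stepping settled to the trivial state, not a bump",
                            state=coeffs, parameter=problem.h)
    return coeffs


def make_continuation_problem(problem):
    """Wrap the bump system as a :class:`ContinuationProblem` in the threshold h."""
    return ContinuationProblem(
        residual=lambda v, h: bump_residual(v, problem, h),
        jacobian_state=lambda v, h: bump_jacobian(v, problem, h),
        jacobian_param=lambda v, h: _bump_dh(v, problem, h),
        parameter_name="h",
    )


def continue_bumps_in_h(problem, initial_coeffs, settings=None, stability=True):
    """Continue the even bump branch in the threshold ``h``.

    ``initial_coeffs`` must solve the residual at ``problem.h``.  Stability
    is read from the eigenvalues of the assembled N x N Jacobian; no
    structural mode needs excluding (evenness removed the translational
    zero).  Returns a :class:`Branch` with folds flagged and refined.
    """
    settings = settings or ContinuationSettings(ds=0.05, max_steps=200)
    cp = make_continuation_problem(problem)
    init = BranchPoint(state=np.asarray(initial_coeffs, float),
                       parameter=problem.h)
    return continue_branch(cp, init, settings, stability=stability)
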