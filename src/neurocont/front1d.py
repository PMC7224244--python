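"""Travelling fronts of the 1D neural field with exponential coupling.

With ``w(x) = (1/2) exp(-|x|)`` (unit integral), spatially uniform steady
states satisfy ``u = f(u - h)``; for moderate thresholds three coexist and a
front connecting the outer two travels at constant speed ``c``.  In the
co-moving frame ``xi = x - c t`` the front is a fixed point of

    0 = c du/dxi - u + int w(xi - y) f(u(y) - h) dy,

posed on a truncated domain with ``N`` grid points.  The unknown speed
makes ``N + 1`` unknowns, balanced by the scalar pinning condition

    int (u - uhat) uhat_xi dxi = 0

against a fixed monotone template ``uhat``, which removes the translation
invariance.  The continuation state is ``v = (u_1..u_N, c)`` and the
continuation parameter is the threshold ``h``; the resulting speed-versus-
threshold curve is antisymmetric about ``h = 1/2`` because the model is
invariant under ``u -> 1 - u``, ``h -> 1 - h`` there.

The linearisation about a front has a near-zero eigenvalue with eigenvector
proportional to ``du/dxi`` (the remnant of translation invariance on the
truncated domain); front stability is judged on the remaining spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .continuation import (
    BranchPoint,
    ContinuationProblem,
    ContinuationSettings,
    EigenSummary,
    NewtonFailure,
    continue_branch,
    dense_solve,
)
from .models import CouplingKernel, exponential_1d, firing_rate, kernel_eval

__all__ = [
    "FrontProblem",
    "FrontState",
    "uniform_steady_states",
    "front_residual",
    "front_jacobian",
    "front_stability",
    "time_step_front",
    "initial_front",
    "continue_front_in_h",
    "speed_zero_crossing",
]


def uniform_steady_states(beta, h, lo=-0.5, hi=1.5, scan_res=1e-4):
    """All roots of ``u = f(u - h)`` in ``[lo, hi]``.

    Located by a sign scan at resolution ``scan_res`` followed by bisection
    (Brent) polish to ~1e-12.  For a steep sigmoid the count is 1 or 3
    (2 exactly at the saddle-node of uniform states).
    """
    def g(u):
        f, _ = firing_rate(u - h, beta)
        return u - f

    grid = np.arange(lo, hi + scan_res, scan_res)
    vals = g(grid)
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(scipy.optimize.brentq(g, grid[i], grid[i + 1],
                                               xtol=1e-14, rtol=1e-15))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # dedupe near-identical roots from scan ties
    out = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > 10 * scan_res:
            out.append(r)
    return np.array(out)


@dataclass
class FrontState:
    """A co-moving-frame front: grid profile plus frame speed."""

    profile: np.ndarray
    speed: float

    def as_vector(self):
        return np.append(self.profile, self.speed)


def default_template(xi):
    """Monotone reference profile ``0.5 (1 + tanh(25 - xi))`` on [0, 50]."""
    return 0.5 * (1.0 + np.tanh(25.0 - xi))


def default_template_deriv(xi):
    return -0.5 / np.cosh(25.0 - xi) ** 2


@dataclass
class FrontProblem:
    """Truncated-domain front problem.

    Defaults: domain [0, 50] with 1000 equispaced points, exponential
    coupling, beta = 20, and the tanh template centred at xi = 25.
    """

    N: int = 1000
    L_dom: float = 50.0
    beta: float = 20.0
    h: float = 0.3
    kernel: CouplingKernel = field(default_factory=exponential_1d)
    template: callable = None
    template_deriv: callable = None

    def __post_init__(self):
        self.xi = np.linspace(0.0, self.L_dom, self.N)
        self.dxi = self.xi[1] - self.xi[0]
        if self.template is None:
            scale = self.L_dom / 50.0
            if scale == 1.0:
                self.template = default_template
                self.template_deriv = default_template_deriv
            else:
                mid = self.L_dom / 2.0
                self.template = lambda x: 0.5 * (1.0 + np.tanh(mid - x))
                self.template_deriv = lambda x: -0.5 / np.cosh(mid - x) ** 2
        self.uhat = self.template(self.xi)
        self.uhat_xi = self.template_deriv(self.xi)
        # trapezoid quadrature weights on the (non-periodic) truncated domain
        self.quad_w = np.full(self.N, self.dxi)
        self.quad_w[0] *= 0.5
        self.quad_w[-1] *= 0.5
        # dense convolution matrix W[i, j] = w(xi_i - xi_j) * quad_w[j]
        diffs = self.xi[:, None] - self.xi[None, :]
        self.W = kernel_eval(self.kernel, diffs) * self.quad_w[None, :]
        # constant-extension boundary closure: the field is taken to continue
        # at its end values outside [0, L_dom], contributing the kernel tail
        # masses int_{-inf}^0 w(xi - y) dy and int_L^inf w(xi - y) dy.  This
        # keeps the spatially uniform states exact solutions of the truncated
        # problem (plain truncation loses ~half the kernel mass at the ends,
        # which distorts the front branch near its speed reversal).
        self.tail_left = _tail_mass(self.kernel, self.xi)
        self.tail_right = _tail_mass(self.kernel, self.L_dom - self.xi)
        if self.kernel.kind == "exponential_1d":
            # renormalise every discrete row to unit total mass: the kernel
            # integrates to 1 exactly, but the trapezoid rule has an O(dxi^2)
            # error at the |x| kink.  Exact unit rows make the uniform states
            # exact discrete solutions and preserve the u -> 1 - u symmetry
            # (hence c(h=1/2) = 0) at machine precision.
            total = self.W.sum(axis=1) + self.tail_left + self.tail_right
            self.W /= total[:, None]
            self.tail_left /= total
            self.tail_right /= total
        self.D = _derivative_matrix(self.N, self.dxi)


def _tail_mass(kernel, dist, depth=40.0, dy=0.01):
    """int_{-inf}^{0} w(d - y) dy for each distance d >= 0 (numeric, generic
    in the kernel; the tail beyond ``depth`` is negligible for the
    exponentially decaying kernels used here)."""
    y = np.arange(-depth, 0.0 + 0.5 * dy, dy)
    wts = np.full(y.size, dy)
    wts[0] *= 0.5
    wts[-1] *= 0.5
    vals = kernel_eval(kernel, np.subtract.outer(np.asarray(dist, float), y))
    return vals @ wts


def _derivative_matrix(N, dxi):
    """Second-order central d/dxi with constant-extension ghost nodes.

    The end rows use ghost values ``u_{-1} = u_0`` and ``u_N = u_{N-1}``,
    matching the convolution's boundary closure.  This also regularises the
    truncation: with one-sided end differences the growing solution
    ``exp(xi/c)`` of ``c u' = u`` (excluded by boundedness on the infinite
    line) is nearly annihilated and leaves the Jacobian close to singular.
    """
    D = np.zeros((N, N))
    idx = np.arange(1, N - 1)
    D[idx, idx - 1] = -0.5 / dxi
    D[idx, idx + 1] = 0.5 / dxi
    D[0, 0], D[0, 1] = -0.5 / dxi, 0.5 / dxi
    D[-1, -2], D[-1, -1] = -0.5 / dxi, 0.5 / dxi
    return D


def front_residual(state, problem, h=None):
    """``N + 1`` residuals: the co-moving steady-state equation at each node
    plus the template pinning integral."""
    if isinstance(state, FrontState):
        u, c = state.profile, state.speed
    else:
        state = np.asarray(state, float)
        u, c = state[:-1], state[-1]
    if u.size != problem.N:
        raise ValueError(f"profile length {u.size} != grid size {problem.N}")
    if h is None:
        h = problem.h
    f, _ = firing_rate(u - h, problem.beta)
    conv = problem.W @ f + problem.tail_left * f[0] + problem.tail_right * f[-1]
    interior = c * (problem.D @ u) - u + conv
    pinning = np.dot(problem.quad_w, (u - problem.uhat) * problem.uhat_xi)
    return np.append(interior, pinning)


def front_jacobian(state, problem, h=None):
    """Assembled ``(N+1) x (N+1)`` Jacobian of :func:`front_residual`
    with respect to ``(u, c)``."""
    state = np.asarray(state, float)
    u, c = state[:-1], state[-1]
    if h is None:
        h = problem.h
    _, fp = firing_rate(u - h, problem.beta)
    N = problem.N
    J = np.zeros((N + 1, N + 1))
    J[:N, :N] = c * problem.D - np.eye(N) + problem.W * fp[None, :]
    J[:N, 0] += problem.tail_left * fp[0]
    J[:N, N - 1] += problem.tail_right * fp[-1]
    J[:N, N] = problem.D @ u
    J[N, :N] = problem.quad_w * problem.uhat_xi
    return J


def _front_dh(state, problem, h):
    state = np.asarray(state, float)
    u = state[:-1]
    _, fp = firing_rate(u - h, problem.beta)
    conv_fp = (problem.W @ fp + problem.tail_left * fp[0]
               + problem.tail_right * fp[-1])
    return np.append(-conv_fp, 0.0)


def linearisation(state, problem, h=None):
    """The ``N x N`` state-block linearisation about a front (profile part only)."""
    state = np.asarray(state, float) if not isinstance(state, FrontState) \
        else state.as_vector()
    return front_jacobian(state, problem, h)[:problem.N, :problem.N]


def front_stability(state, problem, h=None, stability_tol=1e-8):
    """Spectrum of the front linearisation with the translational mode excluded.

    Returns ``(summary, translational_eigenvalue)``.  The translational mode
    is identified as the eigenvalue whose eigenvector has the largest
    |cosine similarity| with the discretised ``du/dxi``; stability is judged
    on the remaining eigenvalues.
    """
    vec = state.as_vector() if isinstance(state, FrontState) else np.asarray(state, float)
    u = vec[:-1]
    A = linearisation(vec, problem, h)
    vals, vecs = scipy.linalg.eig(A)
    du = problem.D @ u
    du = du / np.linalg.norm(du)
    sims = np.abs(vecs.conj().T @ du) / np.linalg.norm(vecs, axis=0)
    k_trans = int(np.argmax(sims))
    lam_trans = vals[k_trans]
    order = np.argsort(-vals.real)
    vals_sorted = vals[order]
    kept = vals[np.arange(len(vals)) != k_trans]
    mx = kept.real.max()
    summary = EigenSummary(eigenvalues=vals_sorted,
                           stable=bool(mx < -stability_tol),
                           marginal=bool(-stability_tol <= mx <= stability_tol),
                           n_excluded=1)
    return summary, lam_trans


def time_step_front(problem, u0=None, T=15.0, dt=0.05, h=None):
    """Integrate the field equation on the truncated domain from a step
    initial condition, semi-implicitly (decay implicit, convolution explicit).

    Returns ``(u_final, c_estimate)`` where the speed estimate comes from
    the displacement of the half-level interface over the final quarter of
    the horizon.
    """
    if h is None:
        h = problem.h
    roots = uniform_steady_states(problem.beta, h)
    if len(roots) < 3:
        raise ValueError(f"no bistable pair at h={h}: {len(roots)} uniform state(s)")
    u1, u3 = roots[0], roots[-1]
    if u0 is None:
        u = np.where(problem.xi < problem.L_dom / 2.0, u3, u1)
    else:
        u = np.asarray(u0, float).copy()
    n_steps = int(np.ceil(T / dt))
    mark = int(0.75 * n_steps)
    level = 0.5 * (u1 + u3)
    pos0, t0 = None, None
    for k in range(n_steps):
        f = firing_rate(u - h, problem.beta)[0]
        conv = problem.W @ f + problem.tail_left * f[0] + problem.tail_right * f[-1]
        u = (u + dt * conv) / (1.0 + dt)
        if np.linalg.norm(u) > 1e6:
            raise FloatingPointError("front time-stepping blew up")
        if k == mark:
            pos0, t0 = _interface_position(problem.xi, u, level), k * dt
    pos1 = _interface_position(problem.xi, u, level)
    c_est = (pos1 - pos0) / (n_steps * dt - t0) if pos0 is not None else 0.0
    return u, c_est


def _interface_position(xi, u, level, margin=5.0):
    """xi where the profile crosses ``level``.

    Crossings within ``margin`` of the domain ends are ignored (the
    truncated-domain boundary layers graze the mid level); among the
    interior ones the steepest is taken.
    """
    s = np.sign(u - level)
    idx = np.where(s[:-1] * s[1:] <= 0)[0]
    interior = idx[(xi[idx] > xi[0] + margin) & (xi[idx] < xi[-1] - margin)]
    if len(interior):
        idx = interior
    if len(idx) == 0:
        raise ValueError("no interface crossing found")
    i = idx[np.argmax(np.abs(u[idx + 1] - u[idx]))]
    frac = (level - u[i]) / (u[i + 1] - u[i])
    return xi[i] + frac * (xi[i + 1] - xi[i])


def initial_front(problem, h=None, T=15.0, newton_tol=1e-11):
    """A converged ``FrontState``: time-step to form a front, re-centre it on
    the template's interface, then Newton-polish the ``(profile, c)`` pair.

    The truncated-domain solution carries small boundary layers at the two
    ends (the kernel mass lost outside the domain); after re-centring, a
    short extra settling pass regenerates them before the damped Newton
    polish.
    """
    if h is None:
        h = problem.h
    u, c_est = time_step_front(problem, T=T, h=h)
    roots = uniform_steady_states(problem.beta, h)
    level = 0.5 * (roots[0] + roots[-1])
    # shift so that after the boundary-layer resettling pass (during which
    # the front keeps moving at ~c_est) the interface lands on the template's
    T_resettle = 3.0
    target = _interface_position(problem.xi, problem.uhat,
                                 0.5 * (problem.uhat.min() + problem.uhat.max()))
    shift = (_interface_position(problem.xi, u, level) - target
             + c_est * T_resettle)
    u = np.interp(problem.xi + shift, problem.xi, u)
    u, _ = time_step_front(problem, u0=u, T=T_resettle, h=h)
    vec = np.append(u, c_est)
    vec = _damped_newton_front(vec, problem, h, newton_tol)
    return FrontState(profile=vec[:-1], speed=vec[-1])


def _damped_newton_front(vec, problem, h, tol, max_iter=60):
    """Newton with backtracking line search on the residual norm."""
    r = front_residual(vec, problem, h)
    rnorm = np.linalg.norm(r)
    for _ in range(max_iter):
        if rnorm < tol:
            return vec
        step = dense_solve(front_jacobian(vec, problem, h), r)
        alpha = 1.0
        while alpha >= 1.0 / 128.0:
            trial = vec - alpha * step
            r_trial = front_residual(trial, problem, h)
            n_trial = np.linalg.norm(r_trial)
            if n_trial < (1.0 - 0.25 * alpha) * rnorm or n_trial < tol:
                vec, r, rnorm = trial, r_trial, n_trial
                break
            alpha *= 0.5
        else:
            raise NewtonFailure("front polish stalled (line search exhausted)",
                                state=vec, parameter=h, residual_norm=rnorm)
    raise NewtonFailure("front polish did not converge",
                        state=vec, parameter=h, residual_norm=rnorm)


def solve_front_at_h(problem, h, seed, h_seed=None, max_dh=0.05, newton_tol=1e-11):
    """Solve the pinned front system at a fixed threshold ``h`` (natural
    continuation), walking from a converged seed in steps of ``max_dh``.

    ``h_seed`` is the threshold the seed solves (default: ``problem.h``).
    """
    vec = (seed.as_vector() if isinstance(seed, FrontState)
           else np.asarray(seed, float).copy())
    h_cur = problem.h if h_seed is None else float(h_seed)
    while abs(h - h_cur) > 1e-14:
        step = np.clip(h - h_cur, -max_dh, max_dh)
        h_cur = h_cur + step
        vec = _damped_newton_front(vec, problem, h_cur, newton_tol)
    return FrontState(profile=vec[:-1], speed=vec[-1])


def make_continuation_problem(problem):
    """Wrap the pinned front system as a :class:`ContinuationProblem` in h."""
    return ContinuationProblem(
        residual=lambda v, h: front_residual(v, problem, h),
        jacobian_state=lambda v, h: front_jacobian(v, problem, h),
        jacobian_param=lambda v, h: _front_dh(v, problem, h),
        parameter_name="h",
    )


def continue_front_in_h(problem, initial, settings=None, stability=False):
    """Continue the front branch in the threshold ``h``.

    ``initial`` is a converged :class:`FrontState` at ``problem.h``.  With
    ``stability=True`` each point carries the spectrum of the profile
    linearisation with the translational mode excluded (slow for large N).
    The speed at each point is the last state component.
    """
    settings = settings or ContinuationSettings(ds=0.25, max_steps=60,
                                                newton_tol=1e-9)
    cp = make_continuation_problem(problem)
    init = BranchPoint(state=initial.as_vector(), parameter=problem.h)
    stab = None
    if stability:
        def stab(cprob, pt):
            summary, _ = front_stability(pt.state, problem, h=pt.parameter)
            return summary
    return continue_branch(cp, init, settings, stability=stab)


def branch_speeds(branch):
    """Per-point wave speed (the last state component) along a front branch."""
    return np.array([p.state[-1] for p in branch.points])


def speed_zero_crossing(problem, branch, tol=1e-10):
    """The threshold ``h`` at which the front speed crosses zero.

    Brackets a sign change of ``c`` between adjacent branch points and
    refines by solving the pinned front system at fixed (natural) ``h`` with
    Brent's method on ``c(h)``.
    """
    speeds = branch_speeds(branch)
    hs = branch.parameters
    idx = np.where(speeds[:-1] * speeds[1:] < 0)[0]
    if len(idx) == 0:
        raise ValueError("branch does not bracket a speed sign change")
    i = idx[0]
    vec_cache = {"vec": branch.points[i].state.copy()}

    def c_of_h(h):
        vec = vec_cache["vec"].copy()
        for _ in range(30):
            r = front_residual(vec, problem, h)
            if np.linalg.norm(r) < 1e-11:
                break
            vec = vec - dense_solve(front_jacobian(vec, problem, h), r)
        vec_cache["vec"] = vec
        return vec[-1]

    return scipy.optimize.brentq(c_of_h, hs[i], hs[i + 1], xtol=tol)
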