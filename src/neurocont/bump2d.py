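"""Travelling bumps of a 2D neural field with adaptation, solved matrix-free.

The model couples an activity field ``u(x, y, t)`` to a slow adaptation
field ``a``, on the periodic square ``[0, L)^2``:

    du/dt   = A (w * f(u - h)) - u - a,
    tau da/dt = B u - a,

with Mexican-hat coupling ``w(r) = exp(-r^2) - 0.17 exp(-0.2 r^2)``.  With
no adaptation (``B = 0``) stationary bumps exist; for large enough drive
``B`` they move at constant speed.  For a bump travelling in the negative
``x`` direction, set ``xi = x + c t``: the wave solves

    0 = A (w * f(u - h)) - u - a - c du/dxi,
    0 = B u - a - c tau da/dxi,

(the ``c tau`` transport term acts on ``a``; a ``strict_paper`` flag
substitutes ``du/dxi`` there for comparison).  Translation invariance in
``y`` is removed by enforcing reflection symmetry about ``y = L/2``
(projection after every Newton update); invariance in ``xi`` by the scalar
phase condition

    u(L/2, L/2) - (1/L) int_0^L u(xi, L/2) dxi = 0.

That gives ``2 N^2 + 1`` unknowns ``(u, a, c)``.  The system is far too
large for dense linear algebra at useful resolutions, so the Jacobian is
never formed: Newton steps solve ``J delta = G`` by restarted GMRES, with
``J phi ~= [G(V + eps phi) - G(V)] / eps`` costing one extra residual
evaluation, and stability comes from the few rightmost eigenvalues of the
state-block linearisation via implicitly restarted Arnoldi iteration on the
same products.  The convolution is evaluated spectrally (periodic FFT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .continuation import (
    BranchPoint,
    ContinuationProblem,
    ContinuationSettings,
    EigenSummary,
    NewtonFailure,
    continue_branch,
    newton_correct,
)
from .models import CouplingKernel, firing_rate, kernel_eval, mexican_hat_2d

__all__ = [
    "Problem2D",
    "TravellingBump2DState",
    "residual_2d",
    "jacobian_vector_product",
    "symmetrize",
    "newton_krylov_correct",
    "leading_eigenvalues",
    "time_step_2d",
    "initial_bump_2d",
    "continue_bump_2d_in_A",
]


@dataclass
class Problem2D:
    """Discretised 2D travelling-bump problem on the periodic square.

    Defaults match the worked example: ``L = 15``, ``A = 2``, ``beta = 5``,
    ``h = 0.8``, ``B = 0.4``, ``tau = 3``; the test-scale resolution is
    ``N = 64`` per dimension.
    """

    L: float = 15.0
    N: int = 64
    A: float = 2.0
    B: float = 0.4
    tau: float = 3.0
    beta: float = 5.0
    h: float = 0.8
    kernel: CouplingKernel = field(default_factory=mexican_hat_2d)
    eps_jv: float = 1e-7
    krylov_tol: float = 1e-8
    krylov_restart: int = 300
    strict_paper: bool = False

    def __post_init__(self):
        N, L = self.N, self.L
        self.dx = L / N
        self.dA = self.dx**2
        self.coords = self.dx * np.arange(N)
        # minimum-image displacement for each grid offset
        wrap = np.where(np.arange(N) <= N // 2, np.arange(N), np.arange(N) - N) * self.dx
        X, Y = np.meshgrid(wrap, wrap, indexing="xy")
        self.w_grid = kernel_eval(self.kernel, X, Y)
        self.w_hat = np.fft.rfft2(self.w_grid)

    # ----- field operators ------------------------------------------------
    def convolve(self, field2):
        """Periodic convolution ``w * field`` via the FFT (exact circular sum)."""
        return np.fft.irfft2(self.w_hat * np.fft.rfft2(field2), s=field2.shape) * self.dA

    def d_dxi(self, field2):
        """Second-order central d/dxi with periodic wrap (xi is axis 1)."""
        return (np.roll(field2, -1, axis=1) - np.roll(field2, 1, axis=1)) / (2 * self.dx)

    def d_dy(self, field2):
        return (np.roll(field2, -1, axis=0) - np.roll(field2, 1, axis=0)) / (2 * self.dx)

    def unpack(self, V):
        """Split a ``(2 N^2 + 1,)`` vector into ``(u, a, c)``."""
        N = self.N
        V = np.asarray(V, float)
        return V[:N * N].reshape(N, N), V[N * N:2 * N * N].reshape(N, N), float(V[-1])

    def pack(self, u, a, c):
        return np.concatenate([u.ravel(), a.ravel(), [c]])


@dataclass
class TravellingBump2DState:
    """A co-moving 2D bump: activity and adaptation grids plus frame speed."""

    u_field: np.ndarray
    a_field: np.ndarray
    speed: float

    def as_vector(self, problem):
        return problem.pack(self.u_field, self.a_field, self.speed)


def reflect_y(field2):
    """Reflection about y = L/2 on the periodic grid (index j -> N - j mod N)."""
    return np.roll(field2[::-1, :], 1, axis=0)


def symmetrize(field2):
    """Idempotent projection onto fields symmetric about ``y = L/2``."""
    return 0.5 * (field2 + reflect_y(field2))


def state_projector(problem):
    """Projector for full state vectors: symmetrise both fields, keep c."""

    def project(V):
        u, a, c = problem.unpack(V)
        return problem.pack(symmetrize(u), symmetrize(a), c)

    return project


def residual_2d(state, problem, A=None):
    """The ``2 N^2 + 1`` co-moving-frame residuals (wave equations + phase).

    ``state`` is a :class:`TravellingBump2DState` or packed vector; ``A``
    overrides the problem's synaptic gain (the continuation parameter).
    """
    if isinstance(state, TravellingBump2DState):
        u, a, c = state.u_field, state.a_field, state.speed
    else:
        u, a, c = problem.unpack(state)
    if A is None:
        A = problem.A
    f, _ = firing_rate(u - problem.h, problem.beta)
    G_u = A * problem.convolve(f) - u - a - c * problem.d_dxi(u)
    transport = problem.d_dxi(u) if problem.strict_paper else problem.d_dxi(a)
    G_a = problem.B * u - a - c * problem.tau * transport
    m = problem.N // 2
    phase = u[m, m] - np.mean(u[m, :])
    return np.concatenate([G_u.ravel(), G_a.ravel(), [phase]])


def jacobian_vector_product(G, V, phi, eps=1e-7):
    """Matrix-free ``J phi ~ [G(V + eps_s phi) - G(V)] / eps_s`` with the probe
    scale ``eps_s = eps (1 + |V|) / |phi|`` (one extra residual evaluation)."""
    V = np.asarray(V, float)
    phi = np.asarray(phi, float)
    nrm = np.linalg.norm(phi)
    if nrm == 0:
        raise ValueError("zero probe vector")
    eps_s = eps * (1.0 + np.linalg.norm(V)) / nrm
    return (G(V + eps_s * phi) - G(V)) / eps_s


def make_continuation_problem(problem):
    """Wrap the 2D wave system as an operator-form :class:`ContinuationProblem`
    in the gain ``A`` (Jacobian available only through matrix-vector products)."""
    n = 2 * problem.N**2 + 1

    def resid(V, A):
        return residual_2d(V, problem, A)

    def jac_state(V, A):
        G = lambda x: residual_2d(x, problem, A)
        G0 = G(V)

        def matvec(phi):
            nrm = np.linalg.norm(phi)
            if nrm == 0:
                return np.zeros_like(phi)
            eps_s = problem.eps_jv * (1.0 + np.linalg.norm(V)) / nrm
            return (G(V + eps_s * phi) - G0) / eps_s

        return spla.LinearOperator((n, n), matvec=matvec, dtype=float)

    def jac_param(V, A):
        dA = 1e-6 * (1.0 + abs(A))
        return (residual_2d(V, problem, A + dA)
                - residual_2d(V, problem, A - dA)) / (2 * dA)

    return ContinuationProblem(residual=resid, jacobian_state=jac_state,
                               jacobian_param=jac_param, parameter_name="A",
                               projector=state_projector(problem))


def newton_krylov_correct(problem, prediction, anchor, ds, settings=None):
    """Pseudo-arclength Newton corrector for the 2D problem, with each linear
    solve done by restarted GMRES on Jacobian-vector products (the Jacobian
    is never materialised; peak memory is O(N^2 * restart))."""
    settings = settings or ContinuationSettings(
        ds=ds, newton_tol=1e-8, krylov_tol=problem.krylov_tol,
        krylov_restart=problem.krylov_restart)
    from .continuation import newton_correct

    return newton_correct(make_continuation_problem(problem), prediction,
                          anchor, ds, settings)


# ----------------------------------------------------------------------
# stability

def dynamics_operator(problem, state, A=None):
    """LinearOperator for the ``2 N^2``-dimensional state-block linearisation
    of the co-moving dynamics about a wave (JVP by finite differences)."""
    if isinstance(state, TravellingBump2DState):
        u0, a0, c = state.u_field, state.a_field, state.speed
    else:
        u0, a0, c = problem.unpack(state)
    if A is None:
        A = problem.A
    N = problem.N
    n = 2 * N * N
    base = problem.pack(u0, a0, c)[:-1]

    def rhs(x):
        u = x[:N * N].reshape(N, N)
        a = x[N * N:].reshape(N, N)
        f, _ = firing_rate(u - problem.h, problem.beta)
        du = A * problem.convolve(f) - u - a - c * problem.d_dxi(u)
        transport = problem.d_dxi(u) if problem.strict_paper else problem.d_dxi(a)
        da = (problem.B * u - a - c * problem.tau * transport) / problem.tau
        return np.concatenate([du.ravel(), da.ravel()])

    rhs0 = rhs(base)

    def matvec(phi):
        nrm = np.linalg.norm(phi)
        if nrm == 0:
            return np.zeros_like(phi)
        eps_s = problem.eps_jv * (1.0 + np.linalg.norm(base)) / nrm
        return (rhs(base + eps_s * phi) - rhs0) / eps_s

    return spla.LinearOperator((n, n), matvec=matvec, dtype=float)


def leading_eigenvalues(problem, state, k=6, A=None, tol=1e-7, return_vectors=False):
    """The ``k`` rightmost eigenvalues of the state-block linearisation,
    matrix-free (implicitly restarted Arnoldi on J.phi products).

    Raises with partial results attached if the iteration fails to converge.
    """
    op = dynamics_operator(problem, state, A)
    try:
        vals, vecs = spla.eigs(op, k=k, which="LR", tol=tol, maxiter=3000,
                               ncv=max(4 * k, 30))
    except spla.ArpackNoConvergence as exc:
        if len(exc.eigenvalues) == 0:
            raise
        vals, vecs = exc.eigenvalues, exc.eigenvectors
    order = np.argsort(-vals.real)
    if return_vectors:
        return vals[order], vecs[:, order]
    return vals[order]


def fold_eigenvalue(problem, state, A, iters=6, tol=1e-4, seed_vec=None):
    """Signed eigenvalue of the wave-system Jacobian nearest zero, matrix-free.

    The (2N^2+1)-block Jacobian of the co-moving system (fields, speed and
    phase row included) is singular exactly at a saddle-node of the wave, so
    the sign of its smallest-magnitude eigenvalue is the fold test function.
    Computed by inverse power iteration (GMRES solves on J.phi products)
    restricted to the reflection-symmetric subspace, which excludes the
    permanent y-translation null vector; the eigenvalue is read off as a
    Rayleigh quotient.  Returns ``(eigenvalue, eigenvector)``.
    """
    cp = make_continuation_problem(problem)
    V = state.as_vector(problem) if isinstance(state, TravellingBump2DState) \
        else np.asarray(state, float)
    J = cp.jacobian_state(V, A)
    proj = state_projector(problem)
    n = J.shape[0]
    if seed_vec is not None:
        x = np.asarray(seed_vec, float).copy()
    else:
        rng = np.random.default_rng(0)
        x = rng.standard_normal(n)
    x = proj(x)
    x /= np.linalg.norm(x)
    for _ in range(iters):
        y, info = spla.gmres(J, x, rtol=tol, atol=0.0,
                             restart=problem.krylov_restart, maxiter=5)
        y = proj(y)
        nrm = np.linalg.norm(y)
        if nrm == 0:
            break
        x = y / nrm
    lam = float(np.dot(x, J.matvec(x)))
    return lam, x


def structural_modes(problem, state):
    """The two translational neutral directions of the state block:
    d(u,a)/dxi and d(u,a)/dy."""
    if isinstance(state, TravellingBump2DState):
        u, a = state.u_field, state.a_field
    else:
        u, a, _ = problem.unpack(state)
    mode_xi = np.concatenate([problem.d_dxi(u).ravel(), problem.d_dxi(a).ravel()])
    mode_y = np.concatenate([problem.d_dy(u).ravel(), problem.d_dy(a).ravel()])
    return [mode_xi / np.linalg.norm(mode_xi), mode_y / np.linalg.norm(mode_y)]


def wave_stability(problem, state, A=None, k=6, structural_tol=0.9):
    """Rightmost non-structural eigenvalue and a stability verdict.

    Eigenvectors with |cosine similarity| > ``structural_tol`` against the
    xi- or y-translation modes are treated as neutral remnants and excluded.
    Returns ``(rightmost_real, stable, eigenvalues)``.
    """
    vals, vecs = leading_eigenvalues(problem, state, k=k, A=A, return_vectors=True)
    modes = structural_modes(problem, state)
    keep = []
    for i in range(len(vals)):
        v = vecs[:, i]
        v = v / np.linalg.norm(v)
        sim = max(abs(np.vdot(v, m)) for m in modes)
        if sim <= structural_tol:
            keep.append(vals[i])
    if not keep:
        return 0.0, False, vals
    rightmost = max(x.real for x in keep)
    return float(rightmost), bool(rightmost < -1e-8), vals


# ----------------------------------------------------------------------
# initial data

def time_step_2d(problem, u0=None, a0=None, T=60.0, dt=0.05, track=True):
    """Integrate the lab-frame model semi-implicitly (decay implicit,
    convolution explicit) from a localised blob.

    Returns ``(u, a, drift_speed)`` where ``drift_speed`` is the signed
    dx/dt of the bump peak over the final quarter of the horizon (negative
    for the leftward-travelling bump; ``c = -drift_speed``).
    """
    N, L = problem.N, problem.L
    if u0 is None:
        X, Y = np.meshgrid(problem.coords, problem.coords, indexing="xy")
        r2 = (X - L / 2) ** 2 + (Y - L / 2) ** 2
        u = 2.0 * np.exp(-r2)
    else:
        u = np.asarray(u0, float).copy()
    if a0 is None:
        # adaptation seeded slightly ahead (in +x) of the activity blob:
        # an x-symmetric start is a stationary state of the symmetric
        # dynamics and would never start moving; the displaced recovery
        # field pushes the bump in the -x direction
        shift = max(1, problem.N // 16)
        a = problem.B * np.roll(u, shift, axis=1)
    else:
        a = np.asarray(a0, float).copy()
    n_steps = int(np.ceil(T / dt))
    mark = int(0.75 * n_steps)
    pos0 = None
    pos_prev, unwrapped = None, 0.0
    for kstep in range(n_steps):
        f, _ = firing_rate(u - problem.h, problem.beta)
        conv = problem.convolve(f)
        u_new = (u + dt * (problem.A * conv - a)) / (1.0 + dt)
        a_new = (a + (dt / problem.tau) * problem.B * u) / (1.0 + dt / problem.tau)
        u, a = u_new, a_new
        if np.linalg.norm(u) > 1e6:
            raise FloatingPointError("2D time-stepping blew up")
        if track and kstep >= mark:
            pos = _peak_position(problem, u)
            if pos_prev is not None:
                d = pos - pos_prev
                d -= L * np.round(d / L)  # unwrap periodic jumps
                unwrapped += d
            else:
                pos0, t0 = kstep * dt, kstep * dt
            pos_prev = pos
    drift = unwrapped / (n_steps * dt - t0) if (track and pos_prev is not None
                                                and n_steps * dt > t0) else 0.0
    return u, a, drift


def _peak_position(problem, u):
    """Sub-grid x-position of the bump along the y = L/2 row: circular
    centroid of the suprathreshold activity (robust for flat-topped bumps,
    where the discrete argmax flips between twin maxima)."""
    row = u[problem.N // 2, :]
    w = np.clip(row - row.min(), 0.0, None) ** 2
    theta = 2.0 * np.pi * np.arange(problem.N) / problem.N
    z = np.sum(w * np.exp(1j * theta))
    return (np.angle(z) % (2.0 * np.pi)) * problem.L / (2.0 * np.pi)


def initial_bump_2d(problem, T=60.0, dt=0.05, newton_tol=1e-8, settings=None):
    """A converged travelling bump: time-step the lab-frame model, align the
    state with the phase condition, then Newton--Krylov polish ``(u, a, c)``.
    """
    u, a, drift = time_step_2d(problem, T=T, dt=dt)
    c_est = -drift
    u, a = symmetrize(u), symmetrize(a)
    u, a = _align_phase(problem, u, a)
    V = problem.pack(u, a, c_est)
    cp = make_continuation_problem(problem)
    settings = settings or ContinuationSettings(
        newton_tol=newton_tol, max_newton=30,
        krylov_tol=problem.krylov_tol, krylov_restart=problem.krylov_restart)
    # plain Newton at fixed A: anchor the arclength condition trivially
    anchor = BranchPoint(state=V, parameter=problem.A,
                         tangent=np.append(np.zeros(V.size), 1.0))
    pt = newton_correct(cp, (V, problem.A), anchor, 0.0, settings)
    u, a, c = problem.unpack(pt.state)
    return TravellingBump2DState(u_field=u, a_field=a, speed=c)


def _align_phase(problem, u, a):
    """Roll the fields along xi so the phase condition is (nearly) satisfied
    at a transversal crossing of the row mean."""
    m = problem.N // 2
    row = u[m, :]
    target = row.mean()
    d = row - target
    # crossing with the steepest slope for transversality
    crossings = [i for i in range(problem.N)
                 if d[i] * d[(i + 1) % problem.N] <= 0 and d[i] != d[(i + 1) % problem.N]]
    if not crossings:
        return u, a
    slopes = [abs(d[(i + 1) % problem.N] - d[i]) for i in crossings]
    i_star = crossings[int(np.argmax(slopes))]
    shift = m - i_star
    return np.roll(u, shift, axis=1), np.roll(a, shift, axis=1)


def continue_bump_2d_in_A(problem, initial, settings=None, stability_every=1,
                          k_eigs=5):
    """Continue the travelling bump in the gain ``A``, matrix-free.

    ``initial`` is a converged :class:`TravellingBump2DState` at
    ``problem.A``.  Stability (rightmost non-structural eigenvalue) is
    attached every ``stability_every`` points; set 0 to skip.  Returns a
    :class:`~neurocont.continuation.Branch`; the per-point speed is the last
    state component.
    """
    settings = settings or ContinuationSettings(
        ds=0.5, max_steps=40, newton_tol=1e-8, max_newton=12,
        krylov_tol=problem.krylov_tol, krylov_restart=problem.krylov_restart,
        fold_refine_tol=1e-3)
    cp = make_continuation_problem(problem)
    init = BranchPoint(state=initial.as_vector(problem), parameter=problem.A)

    counter = {"i": -1}

    def stab(cprob, pt):
        counter["i"] += 1
        if stability_every and counter["i"] % stability_every == 0:
            rightmost, stable, vals = wave_stability(problem, pt.state,
                                                     A=pt.parameter, k=k_eigs)
            return EigenSummary(eigenvalues=np.atleast_1d(
                np.asarray([rightmost], dtype=complex)), stable=stable)
        return EigenSummary(eigenvalues=np.array([], dtype=complex),
                            stable=None)

    stability = stab if stability_every else None
    return continue_branch(cp, init, settings, stability=stability)
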