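"""Front speed via heteroclinic shooting in the travelling-wave ODE.

Because the exponential kernel ``(1/2) e^{-|x|}`` is the Green function of
``1 - d^2/dx^2``, the nonlocal co-moving front equation collapses to the
third-order ODE

    c u''' - u'' - c u' + u = f(u - h),

written as the first-order system ``u' = v``, ``v' = z``,
``z' = [f(u - h) - u]/c + v + z/c`` (singular at ``c = 0``).  Its fixed
points are ``(u*, 0, 0)`` with ``u* = f(u* - h)``; a front of the field
equation is a heteroclinic connection between the outer two.  Linearising
at a fixed point, the eigenvalues solve the cubic

    lam^3 - lam^2/c - lam + (1 - f'(u* - h))/c = 0,

which for ``f' ~ 0`` factorises as ``(lam-1)(lam+1)(lam-1/c) = 0``: for
``c > 0`` each outer fixed point has a 2D unstable and 1D stable manifold
(swapped for ``c < 0``), so the connection is a codimension-one event in
``c``.  The speed is found by shooting: integrate along the one-dimensional
transverse manifold and bisect ``c`` on a signed mismatch from the far
fixed point.  This gives an oracle for the grid-based front continuation,
independent of the truncation, the pinning condition and the quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .front1d import uniform_steady_states
from .models import firing_rate

__all__ = [
    "wave_ode_rhs",
    "fixedpoint_eigenvalues",
    "shoot_mismatch",
    "shoot_front_speed",
    "default_speed_bracket",
]

# exit-tube radius around the heteroclinic corridor (in u units)
TUBE_RADIUS = 0.05


def wave_ode_rhs(state, c, beta, h):
    """Right-hand side of the travelling-wave system at ``(u, v, z)``."""
    if c == 0:
        raise ValueError("wave ODE is singular at c = 0")
    u, v, z = state
    f, _ = firing_rate(u - h, beta)
    return np.array([v, z, (f - u) / c + v + z / c])


def _fp_jacobian(u_star, c, beta, h):
    _, fp = firing_rate(u_star - h, beta)
    return np.array([
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [(fp - 1.0) / c, 1.0, 1.0 / c],
    ])


def fixedpoint_eigenvalues(u_star, c, beta, h):
    """The three linearisation eigenvalues at a fixed point ``(u*, 0, 0)``,
    computed as the eigenvalues of the 3x3 Jacobian (a companion-type
    matrix of the characteristic cubic)."""
    if c == 0:
        raise ValueError("wave ODE is singular at c = 0")
    vals = np.linalg.eigvals(_fp_jacobian(u_star, c, beta, h))
    return vals[np.argsort(vals.real)]


def _transverse_eigenpair(u_star, c, beta, h):
    """Eigenpair spanning the one-dimensional manifold transverse to the
    2D one: stable (Re < 0) for c > 0, unstable (Re > 0) for c < 0."""
    J = _fp_jacobian(u_star, c, beta, h)
    vals, vecs = np.linalg.eig(J)
    want_stable = c > 0
    mask = vals.real < 0 if want_stable else vals.real > 0
    idx = np.where(mask)[0]
    if len(idx) != 1:
        raise RuntimeError(
            f"expected a one-dimensional {'stable' if want_stable else 'unstable'} "
            f"manifold at u*={u_star:.4f}, c={c:.4f}; got dimension {len(idx)}")
    i = idx[0]
    return vals[i].real, vecs[:, i].real


def shoot_mismatch(c, beta, h, span=2000.0, displacement=1e-6,
                   rtol=1e-10, atol=1e-10, return_trajectory=False):
    """Signed miss distance of the shot trajectory from the far fixed point.

    For ``c > 0`` the trajectory is launched a small displacement along the
    stable eigenvector of the "ahead" (low-u) fixed point and integrated
    backwards in the travelling coordinate; for ``c < 0`` it is launched
    along the unstable eigenvector of the high-u fixed point and integrated
    forwards.  Integration stops when the trajectory exits a tube of radius
    ``TUBE_RADIUS`` around the heteroclinic corridor; the mismatch is the
    ``u``-deviation from the target fixed point there.  A root in ``c``
    marks the connection.
    """
    roots = uniform_steady_states(beta, h)
    if len(roots) < 3:
        raise ValueError(f"h={h} is outside the bistable range")
    u1, u3 = roots[0], roots[-1]
    if c > 0:
        start, target, direction = u1, u3, -1.0
    else:
        start, target, direction = u3, u1, +1.0
    _, evec = _transverse_eigenpair(start, c, beta, h)
    # launch into the corridor: u must move toward the target
    if np.sign(evec[0]) != np.sign(target - start):
        evec = -evec
    y0 = np.array([start, 0.0, 0.0]) + displacement * evec

    lo, hi = u1 - TUBE_RADIUS, u3 + TUBE_RADIUS

    def rhs(t, y):
        return direction * wave_ode_rhs(y, c, beta, h)

    def exit_low(t, y):
        return y[0] - lo

    def exit_high(t, y):
        return y[0] - hi

    def near_target(t, y):
        return np.linalg.norm(y - [target, 0.0, 0.0]) - 1e-9

    exit_low.terminal = exit_high.terminal = near_target.terminal = True
    sol = solve_ivp(rhs, (0.0, span), y0, rtol=rtol, atol=atol,
                    events=[exit_low, exit_high, near_target],
                    dense_output=return_trajectory, max_step=1.0)
    mismatch = sol.y[0, -1] - target
    if return_trajectory:
        return mismatch, sol
    return mismatch


def default_speed_bracket(h, c_max=5.0, c_min=0.02):
    """A conservative speed bracket: positive speeds below the symmetry
    threshold ``h = 1/2``, negative above (excluding ``|c| <= c_min``)."""
    if h < 0.5:
        return (c_min, c_max)
    return (-c_max, -c_min)


def shoot_front_speed(beta, h, c_bracket=None, tol=1e-8):
    """Front speed at threshold ``h`` by bisection on the shooting mismatch.

    ``c_bracket`` must exclude a neighbourhood of ``c = 0`` (the ODE
    reduction is singular there; the grid continuation covers ``h ~ 1/2``).
    Raises ``ValueError`` if the mismatch does not change sign across the
    bracket.
    """
    if c_bracket is None:
        c_bracket = default_speed_bracket(h)
    a, b = c_bracket
    if a == 0 or b == 0 or (a < 0 < b):
        raise ValueError("bracket must exclude c = 0 (singular reduction)")
    fa = shoot_mismatch(a, beta, h)
    fb = shoot_mismatch(b, beta, h)
    if fa * fb > 0:
        raise ValueError(
            f"mismatch does not change sign on bracket ({a}, {b}): "
            f"({fa:.3e}, {fb:.3e})")
    while abs(b - a) > tol:
        m = 0.5 * (a + b)
        fm = shoot_mismatch(m, beta, h)
        if fm == 0.0:
            return m
        if fa * fm < 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)
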