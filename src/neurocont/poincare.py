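"""Periodic orbits located as fixed points of a Poincare return map.

For a planar ODE with a limit cycle, place a transversal section -- here a
coordinate hyperplane ``{x_k = level}`` gated to a half-space (e.g.
``v > 0.5``) with a prescribed crossing direction -- and define the return
map ``psi`` by integrating from a section point until the next gated,
direction-matched crossing.  A periodic orbit is a fixed point
``V* = psi(V*)`` of this scalar map, stable iff ``|psi'(V*)| < 1``; the
algebraic equation ``V - psi(V) = 0`` is continued in a model parameter
with the same pseudo-arclength machinery as everything else.

The worked system is a FitzHugh--Nagumo model

    dv/dt = (v (v + 0.1)(1 - v) - w + i_app) / tau_v,
    dw/dt = v - 0.5 w,

with a fast voltage timescale ``tau_v = 0.1`` and applied drive
``i_app = 1`` by default, which sustains a stable relaxation oscillation
crossing the section ``{(v, w): v > 0.5, w = 1}``.  The cubic's
coefficients are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .continuation import (
    BranchPoint,
    ContinuationProblem,
    ContinuationSettings,
    NewtonFailure,
    continue_branch,
)

__all__ = [
    "PlanarODE",
    "fhn_default",
    "fhn_rhs",
    "PoincareSection",
    "SectionEscapeError",
    "TangentCrossingError",
    "poincare_map",
    "iterate_to_fixed_point",
    "map_derivative",
    "continue_periodic_orbit",
]


class SectionEscapeError(RuntimeError):
    """Trajectory failed to re-cross the section within the time cap."""


class TangentCrossingError(RuntimeError):
    """Crossing is tangential (non-transversal) at event tolerance."""


@dataclass
class PlanarODE:
    """A planar vector field ``(v, w)`` with configurable FHN-type coefficients.

    ``dv/dt = (v (v - a)(1 - v)... `` -- concretely:
    ``dv/dt = (v (v + cubic_shift)(1 - v) - w + i_app) / tau_v`` and
    ``dw/dt = v - gamma * w``.  The w-nullcline is ``w = v / gamma``.
    """

    cubic_shift: float = 0.1
    i_app: float = 1.0
    tau_v: float = 0.1
    gamma: float = 0.5
    rtol: float = 1e-10
    atol: float = 1e-10

    def rhs(self, state, i_app=None):
        v, w = state
        ia = self.i_app if i_app is None else i_app
        dv = (v * (v + self.cubic_shift) * (1.0 - v) - w + ia) / self.tau_v
        dw = v - self.gamma * w
        return np.array([dv, dw])


def fhn_default() -> PlanarODE:
    return PlanarODE()


def fhn_rhs(state, params=None):
    """Time derivatives of the FHN system (module-level convenience)."""
    ode = params if isinstance(params, PlanarODE) else fhn_default()
    return ode.rhs(np.asarray(state, float))


@dataclass
class PoincareSection:
    """A transversal hyperplane ``{x[coord] = level}`` with a half-space gate
    and a crossing direction (+1: coordinate increasing through the level)."""

    coord: int = 1
    level: float = 1.0
    gate_coord: int = 0
    gate_min: float = 0.5
    direction: int = 1

    def embed(self, V):
        """Map a section coordinate to a full phase-space point."""
        x = np.empty(2)
        x[self.gate_coord] = V
        x[self.coord] = self.level
        return x


def poincare_map(ode, section, V0, time_cap=100.0, i_app=None,
                 event_tol=1e-10, return_time=False, t_min=1e-6):
    """One application of the return map: the next gated, direction-matched
    section crossing of the trajectory from ``(V0 on section)``.

    The crossing is located by the integrator's root-finding on dense output
    (to ``|x[coord] - level| < event_tol``).  Raises
    :class:`SectionEscapeError` when no admissible crossing occurs within
    ``time_cap`` and :class:`TangentCrossingError` for a tangential hit.
    """
    x = section.embed(float(V0))

    def rhs(t, y):
        return ode.rhs(y, i_app=i_app)

    def cross(t, y):
        return y[section.coord] - section.level

    cross.terminal = True
    cross.direction = section.direction
    t = 0.0
    while t < time_cap:
        sol = solve_ivp(rhs, (t, time_cap), x, rtol=ode.rtol, atol=ode.atol,
                        events=cross, max_step=1.0)
        if sol.t_events[0].size == 0:
            break
        t_ev = float(sol.t_events[0][0])
        y_ev = sol.y_events[0][0]
        if t_ev > t_min and y_ev[section.gate_coord] > section.gate_min:
            speed = ode.rhs(y_ev, i_app=i_app)[section.coord]
            if abs(speed) < event_tol:
                raise TangentCrossingError(
                    f"tangential section crossing at t={t_ev:.4f}")
            V1 = float(y_ev[section.gate_coord])
            if return_time:
                return V1, t_ev
            return V1
        # un-gated crossing: nudge off the section and keep integrating
        dt = 1e-9
        x = y_ev + dt * ode.rhs(y_ev, i_app=i_app)
        t = t_ev + dt
    raise SectionEscapeError(
        f"no gated section crossing within t <= {time_cap} from V0={V0}")


def iterate_to_fixed_point(ode, section, V0, tol=1e-10, max_iter=200, i_app=None):
    """Iterate the return map to a fixed point ``V* = psi(V*)`` (requires a
    stable orbit; use Newton on ``V - psi(V)`` for unstable ones)."""
    V = float(V0)
    for _ in range(max_iter):
        V_next = poincare_map(ode, section, V, i_app=i_app)
        if abs(V_next - V) < tol:
            return V_next
        V = V_next
    raise RuntimeError(f"map iteration did not converge (last |dV|="
                       f"{abs(V_next - V):.3e})")


def map_derivative(ode, section, V, dV=1e-6, i_app=None):
    """Centred finite-difference derivative ``psi'(V)`` of the return map."""
    up = poincare_map(ode, section, V + dV, i_app=i_app)
    dn = poincare_map(ode, section, V - dV, i_app=i_app)
    return (up - dn) / (2.0 * dV)


def continue_periodic_orbit(ode, section, V_star0, settings=None):
    """Continue the periodic orbit in the applied drive ``i_app``.

    The scalar residual is ``r(V, i_app) = V - psi(V; i_app)``; its zero set
    is followed by pseudo-arclength continuation (finite-difference scalar
    Jacobian, which handles unstable orbits as well).  Map stability
    (``|psi'(V*)| < 1``) is attached per point.  Returns
    ``(branch, derivatives)`` with ``derivatives[k] = psi'`` at point ``k``.
    """
    settings = settings or ContinuationSettings(ds=0.05, max_steps=20,
                                                newton_tol=1e-8)

    def residual(v, p):
        try:
            return np.array([v[0] - poincare_map(ode, section, v[0], i_app=p)])
        except (SectionEscapeError, TangentCrossingError) as exc:
            # surface as a corrector failure so a mid-branch loss of the
            # orbit truncates the branch with a diagnostic
            raise NewtonFailure(str(exc), state=np.asarray(v, float),
                                parameter=p) from exc

    cp = ContinuationProblem(residual=residual, parameter_name="i_app",
                             fd_eps=1e-6)
    init = BranchPoint(state=np.array([float(V_star0)]), parameter=ode.i_app)
    branch = continue_branch(cp, init, settings)
    derivs = np.array([map_derivative(ode, section, p.state[0],
                                      i_app=p.parameter)
                       for p in branch.points])
    for p, d in zip(branch.points, derivs):
        p.stable = bool(abs(d) < 1.0)
    return branch, derivs
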