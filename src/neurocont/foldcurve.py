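"""Two-parameter continuation of saddle-node bifurcations of 1D bumps.

At a fold of the bump branch the Galerkin Jacobian ``J = F_v(v, h, B)`` is
singular.  Appending the null-vector conditions

    F(v, h, B) = 0,   J phi = 0,   phi^T phi - 1 = 0

gives ``2N + 1`` equations for the ``2N + 1`` unknowns ``W = (v, phi, h)``;
solutions of ``H(W, B) = 0`` trace the fold curve in the ``(h, B)`` plane as
the kernel's inhibition amplitude ``B`` (in ``w(x) = 10 e^{-4x^2} -
B e^{-x^2}``) is varied by pseudo-arclength continuation.  The product
``J phi`` is formed matrix-free by a directional finite difference of ``F``
by default; the assembled Jacobian route exists for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .bumps1d import (
    BumpProblem,
    bump_jacobian,
    bump_residual,
    kernel_cosine_coefficients,
)
from .continuation import (
    BranchPoint,
    ContinuationProblem,
    ContinuationSettings,
    NewtonFailure,
    continue_branch,
)
from .models import parametric_mexican_hat_1d

__all__ = [
    "BumpFamily",
    "ExtendedFoldState",
    "extended_residual",
    "fold_state_from_branch_fold",
    "newton_polish_fold",
    "continue_fold_curve",
]


@dataclass
class BumpFamily:
    """The bump problem with the parametric kernel, closed over ``B``.

    Kernel cosine coefficients are recomputed (and cached) per ``B``.
    """

    N: int = 15
    beta: float = 20.0
    M: int = 128

    def __post_init__(self):
        self._cache = {}

    def problem(self, B) -> BumpProblem:
        key = round(float(B), 14)
        if key not in self._cache:
            self._cache[key] = BumpProblem(
                N=self.N, beta=self.beta, M=self.M,
                kernel=parametric_mexican_hat_1d(B))
            if len(self._cache) > 64:
                self._cache.pop(next(iter(self._cache)))
        return self._cache[key]

    def F(self, v, h, B):
        return bump_residual(v, self.problem(B), h)

    def J(self, v, h, B):
        return bump_jacobian(v, self.problem(B), h)


@dataclass
class ExtendedFoldState:
    """Concatenation ``W = (v, phi, h)`` of bump modes, unit null vector, and
    threshold, for two-parameter fold tracking."""

    v: np.ndarray
    phi: np.ndarray
    h: float

    def as_vector(self):
        return np.concatenate([self.v, self.phi, [self.h]])

    @classmethod
    def from_vector(cls, W, N):
        W = np.asarray(W, float)
        return cls(v=W[:N], phi=W[N:2 * N], h=float(W[2 * N]))


def extended_residual(W, B, family, eps_jv=1e-6, assembled=False):
    """The ``2N + 1`` fold-system residuals at ``W = (v, phi, h)``.

    Rows 1..N: the bump residual; rows N+1..2N: ``J phi``, formed matrix-free
    as a centred directional finite difference of the residual along ``phi``
    (O(eps^2) truncation keeps the residual floor near roundoff) unless
    ``assembled`` selects the explicit-Jacobian product; last row:
    ``phi^T phi - 1``.
    """
    N = family.N
    st = W if isinstance(W, ExtendedFoldState) else ExtendedFoldState.from_vector(W, N)
    F0 = family.F(st.v, st.h, B)
    if assembled:
        Jphi = family.J(st.v, st.h, B) @ st.phi
    else:
        nrm = np.linalg.norm(st.phi)
        if nrm == 0:
            Jphi = np.zeros(N)
        else:
            eps = eps_jv * (1.0 + np.linalg.norm(st.v)) / nrm
            Jphi = (family.F(st.v + eps * st.phi, st.h, B)
                    - family.F(st.v - eps * st.phi, st.h, B)) / (2.0 * eps)
    return np.concatenate([F0, Jphi, [np.dot(st.phi, st.phi) - 1.0]])


def fold_state_from_branch_fold(family, B, fold_record):
    """Seed an :class:`ExtendedFoldState` from a one-parameter fold.

    ``phi`` is the eigenvector of the assembled ``F_v`` belonging to the
    smallest-magnitude eigenvalue, normalised, with its largest-magnitude
    entry made positive (lowest index on ties).
    """
    v, h = np.asarray(fold_record.state, float), float(fold_record.parameter)
    J = family.J(v, h, B)
    vals, vecs = scipy.linalg.eig(J)
    k = int(np.argmin(np.abs(vals)))
    phi = np.real(vecs[:, k])
    phi = phi / np.linalg.norm(phi)
    imax = int(np.argmax(np.abs(phi)))
    if phi[imax] < 0:
        phi = -phi
    return ExtendedFoldState(v=v, phi=phi, h=h)


def newton_polish_fold(state, B, family, tol=1e-10, max_iter=20, assembled=False):
    """Newton on the extended fold system at fixed ``B`` (dense FD Jacobian)."""
    W = state.as_vector() if isinstance(state, ExtendedFoldState) else np.asarray(state, float)
    for it in range(max_iter):
        R = extended_residual(W, B, family, assembled=assembled)
        if np.linalg.norm(R) < tol:
            return ExtendedFoldState.from_vector(W, family.N), it
        J = _extended_jacobian(W, B, family, assembled=assembled)
        W = W - scipy.linalg.solve(J, R)
    raise NewtonFailure("extended fold system did not converge",
                        state=W, parameter=B,
                        residual_norm=float(np.linalg.norm(
                            extended_residual(W, B, family, assembled=assembled))))


def _extended_jacobian(W, B, family, eps=1e-7, assembled=False):
    """Dense central-difference Jacobian of the extended system w.r.t. W."""
    W = np.asarray(W, float)
    n = W.size
    R0 = extended_residual(W, B, family, assembled=assembled)
    J = np.empty((n, n))
    for j in range(n):
        hstep = eps * (1.0 + abs(W[j]))
        Wp, Wm = W.copy(), W.copy()
        Wp[j] += hstep
        Wm[j] -= hstep
        J[:, j] = (extended_residual(Wp, B, family, assembled=assembled)
                   - extended_residual(Wm, B, family, assembled=assembled)) / (2 * hstep)
    return J


def _extended_dB(W, B, family, eps=1e-6, assembled=False):
    return (extended_residual(W, B + eps, family, assembled=assembled)
            - extended_residual(W, B - eps, family, assembled=assembled)) / (2 * eps)


def continue_fold_curve(family, initial, B0, settings=None, assembled=False):
    """Trace the fold curve in the ``(h, B)`` plane.

    ``initial`` is a converged :class:`ExtendedFoldState` at ``B0`` (seed it
    with :func:`fold_state_from_branch_fold` + :func:`newton_polish_fold`).
    Returns a :class:`~neurocont.continuation.Branch` whose points hold
    ``W = (v, phi, h)`` with parameter ``B``; read the fold threshold per
    point from ``state[-1]``.
    """
    settings = settings or ContinuationSettings(ds=0.2, max_steps=60,
                                                newton_tol=1e-9)
    cp = ContinuationProblem(
        residual=lambda W, B: extended_residual(W, B, family, assembled=assembled),
        jacobian_state=lambda W, B: _extended_jacobian(W, B, family, assembled=assembled),
        jacobian_param=lambda W, B: _extended_dB(W, B, family, assembled=assembled),
        parameter_name="B",
    )
    init = BranchPoint(state=initial.as_vector(), parameter=float(B0))
    return continue_branch(cp, init, settings)


def curve_thresholds(branch):
    """Per-point fold threshold ``h`` (last state component) along a fold curve."""
    return np.array([p.state[-1] for p in branch.points])


def smallest_jacobian_eigenvalue(family, point):
    """|lambda|_min of the bump Jacobian at a fold-curve point (should be ~0)."""
    st = ExtendedFoldState.from_vector(point.state, family.N)
    vals = scipy.linalg.eigvals(family.J(st.v, st.h, point.parameter))
    return float(np.min(np.abs(vals)))
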