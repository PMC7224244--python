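"""Generic pseudo-arclength predictor--corrector continuation engine.

Given a residual map ``F(v, lam) = 0`` with ``v`` an n-vector and ``lam`` a
scalar parameter, the engine follows the solution curve in ``(v, lam)``
space.  The curve is parametrised by arclength ``s``: at a converged point
``(v0, lam0)`` with unit tangent ``(vdot, lamdot)`` the next point is
required to satisfy both ``F = 0`` and the pseudo-arclength condition

    theta^2 (v - v0)^T vdot + (lam - lam0) lamdot - ds = 0,

which keeps the augmented Newton system nonsingular through saddle-node
(fold) bifurcations, where natural-parameter continuation fails.  The
predictor is linear extrapolation along the tangent; the corrector is
Newton's method on the augmented system, solved directly when the Jacobian
block is dense and by restarted GMRES when it is supplied in operator
(matrix-free) form.

Stability of each computed point is judged from the eigenvalues of the
state-block Jacobian ``F_v``; structural neutral modes (e.g. translational
zeros) can be excluded by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import scipy.linalg
import scipy.sparse.linalg as spla

__all__ = [
    "ContinuationProblem",
    "ContinuationSettings",
    "BranchPoint",
    "Branch",
    "FoldRecord",
    "EigenSummary",
    "NewtonFailure",
    "SingularJacobianError",
    "DegenerateTangentError",
    "compute_tangent",
    "newton_correct",
    "continue_branch",
    "assess_stability",
    "detect_folds",
    "finite_difference_jacobian",
    "dense_solve",
]


class NewtonFailure(RuntimeError):
    """Newton corrector failed to converge; carries the last iterate."""

    def __init__(self, message, state=None, parameter=None, residual_norm=None):
        super().__init__(message)
        self.state = state
        self.parameter = parameter
        self.residual_norm = residual_norm


class SingularJacobianError(RuntimeError):
    """The augmented Jacobian is singular (to working precision)."""


class DegenerateTangentError(RuntimeError):
    """The extended Jacobian has a null space of dimension > 1 (branch point)."""


@dataclass
class ContinuationProblem:
    """Contract bundling a residual map and Jacobian-block access.

    Parameters
    ----------
    residual : callable ``(v, lam) -> (n,) array``
    jacobian_state : callable ``(v, lam) -> (n, n) array`` or
        ``scipy.sparse.linalg.LinearOperator``; ``None`` selects a dense
        finite-difference approximation (small problems only).
    jacobian_param : callable ``(v, lam) -> (n,) array``; ``None`` selects a
        finite-difference approximation.
    parameter_name : label for the continuation parameter slot.
    """

    residual: Callable[[np.ndarray, float], np.ndarray]
    jacobian_state: Optional[Callable] = None
    jacobian_param: Optional[Callable] = None
    parameter_name: str = "lambda"
    fd_eps: float = 1e-7
    #: optional state projector (e.g. onto a symmetry subspace), applied to
    #: predictions and after every Newton update
    projector: Optional[Callable] = None

    def project(self, v):
        return v if self.projector is None else self.projector(v)

    def F(self, v, lam):
        return np.atleast_1d(np.asarray(self.residual(np.asarray(v, float), lam), float))

    def F_v(self, v, lam):
        if self.jacobian_state is not None:
            return self.jacobian_state(v, lam)
        return finite_difference_jacobian(lambda x: self.F(x, lam), np.asarray(v, float), self.fd_eps)

    def F_lam(self, v, lam):
        if self.jacobian_param is not None:
            return np.asarray(self.jacobian_param(v, lam), float)
        h = self.fd_eps * (1.0 + abs(lam))
        return (self.F(v, lam + h) - self.F(v, lam - h)) / (2.0 * h)


def dense_solve(A, b):
    """Linear solve with a residual guard.

    LU with partial pivoting can suffer catastrophic element growth on the
    advection-dominated Jacobians that arise here (large first-derivative
    off-diagonals); the computed solution is verified and redone by
    least squares (SVD) when the residual betrays instability.
    """
    try:
        x = scipy.linalg.solve(A, b)
    except scipy.linalg.LinAlgError as exc:
        raise SingularJacobianError(str(exc)) from exc
    # backward-error check: a stable solve has |Ax-b| ~ eps * (|A||x| + |b|)
    scale = np.linalg.norm(A, ord="fro") * np.linalg.norm(x) + np.linalg.norm(b)
    if np.linalg.norm(A @ x - b) <= 1e-9 * max(scale, 1e-300):
        return x
    x, _, rank, _ = scipy.linalg.lstsq(A, b, lapack_driver="gelsy")
    if rank < A.shape[0]:
        raise SingularJacobianError(
            f"rank-deficient dense system (rank {rank} < {A.shape[0]})")
    return x


def finite_difference_jacobian(fun, x, eps=1e-7):
    """Dense central-difference Jacobian of ``fun`` at ``x``."""
    x = np.asarray(x, dtype=float)
    f0 = np.atleast_1d(fun(x))
    J = np.empty((f0.size, x.size))
    for j in range(x.size):
        h = eps * (1.0 + abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.atleast_1d(fun(xp)) - np.atleast_1d(fun(xm))) / (2.0 * h)
    return J


@dataclass
class ContinuationSettings:
    """Knobs for the predictor--corrector loop.

    ds : pseudo-arclength stepsize (> 0).
    max_newton : corrector iteration cap.
    newton_tol : augmented-residual 2-norm tolerance for acceptance.
    theta : state/parameter scaling weight; ``theta=1`` is the plain
        arclength condition.
    max_steps : branch length cap.
    direction : +1/-1, sign applied to the initial tangent.
    fold_refine_tol : arclength tolerance for fold bisection.
    tangent_method : "nullspace" (exact null-vector solve) or "secant".
    adapt_step : halve ds on corrector failure / double after fast
        convergence (within [ds_min, ds_max]).
    krylov_tol, krylov_restart : GMRES controls for operator-form Jacobians.
    stability_tol : eigenvalue real-part band treated as marginal.
    """

    ds: float = 0.1
    max_newton: int = 10
    newton_tol: float = 1e-10
    theta: float = 1.0
    max_steps: int = 100
    direction: int = 1
    fold_refine_tol: float = 1e-8
    tangent_method: str = "nullspace"
    adapt_step: bool = False
    ds_min: float = 1e-5
    ds_max: float = 1.0
    krylov_tol: float = 1e-8
    krylov_restart: int = 300
    stability_tol: float = 1e-8

    def __post_init__(self):
        if self.ds <= 0:
            raise ValueError("ds must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.max_newton < 1:
            raise ValueError("max_newton must be >= 1")
        if self.tangent_method not in ("nullspace", "secant"):
            raise ValueError("tangent_method must be 'nullspace' or 'secant'")


@dataclass
class EigenSummary:
    """Leading eigenvalues of ``F_v``, sorted by descending real part."""

    eigenvalues: np.ndarray
    stable: bool
    marginal: bool = False
    n_excluded: int = 0

    @property
    def rightmost(self):
        return self.eigenvalues[0] if len(self.eigenvalues) else np.nan


@dataclass
class BranchPoint:
    """A converged solution with its tangent and stability summary."""

    state: np.ndarray
    parameter: float
    tangent: Optional[np.ndarray] = None
    eigen_summary: Optional[EigenSummary] = None
    stable: Optional[bool] = None
    newton_iterations: int = 0
    #: arclength step from the previous accepted point (0 for the first)
    step_ds: float = 0.0

    def extended(self):
        return np.append(self.state, self.parameter)


@dataclass
class FoldRecord:
    """A saddle-node bifurcation located on a branch."""

    parameter: float
    state: np.ndarray
    index: int  # branch point index just before the fold
    tangent_parameter_component: float = 0.0


@dataclass
class Branch:
    """Ordered branch points plus refined fold locations."""

    points: list = field(default_factory=list)
    folds: list = field(default_factory=list)
    diagnostic: Optional[str] = None

    def __len__(self):
        return len(self.points)

    @property
    def parameters(self):
        return np.array([p.parameter for p in self.points])

    @property
    def states(self):
        return np.array([p.state for p in self.points])

    @property
    def norms(self):
        return np.array([np.linalg.norm(p.state) for p in self.points])


# ----------------------------------------------------------------------
# weighted inner products (theta scaling)

def _wdot(a, b, theta):
    """theta-weighted inner product of extended vectors (state part, param)."""
    return theta**2 * np.dot(a[:-1], b[:-1]) + a[-1] * b[-1]


def _wnorm(a, theta):
    return np.sqrt(_wdot(a, a, theta))


def _is_operator(J):
    return not isinstance(J, np.ndarray)


# ----------------------------------------------------------------------
# tangent

def compute_tangent(problem, point, reference=None, settings=None):
    """Unit tangent ``(vdot, lamdot)`` to the solution curve at a converged point.

    The tangent is the null vector of the n x (n+1) extended Jacobian
    ``[F_v | F_lam]``, normalised to unit theta-weighted length.  Its sign is
    chosen so the weighted dot product with ``reference`` is >= 0; with no
    reference, the parameter component is made nonnegative (largest state
    entry positive at a fold).

    Raises ``DegenerateTangentError`` when the null space is
    multi-dimensional (a branch point).
    """
    settings = settings or ContinuationSettings()
    v, lam = np.asarray(point.state, float), point.parameter
    n = v.size
    Flam = problem.F_lam(v, lam)
    Jv = problem.F_v(v, lam)

    if _is_operator(Jv):
        t = _operator_tangent(Jv, Flam, n, reference, settings)
    else:
        M = np.hstack([np.asarray(Jv, float), Flam.reshape(-1, 1)])
        t = None
        if reference is not None and n > 64:
            # bordered solve: O(n^3/3) LU instead of the SVD null-space
            # route; nonsingular whenever the curve is regular and the
            # reference is not orthogonal to the tangent
            A = np.vstack([M, np.asarray(reference, float)])
            rhs = np.zeros(n + 1)
            rhs[-1] = 1.0
            try:
                cand = dense_solve(A, rhs)
                scale = max(1.0, np.linalg.norm(M, ord="fro"))
                if np.linalg.norm(M @ cand) <= 1e-8 * scale * np.linalg.norm(cand):
                    t = cand
            except SingularJacobianError:
                t = None
        if t is None:
            ns = scipy.linalg.null_space(M, rcond=1e-10)
            if ns.shape[1] > 1:
                raise DegenerateTangentError(
                    f"extended Jacobian null space has dimension {ns.shape[1]}"
                )
            if ns.shape[1] == 1:
                t = ns[:, 0]
            else:
                # numerically nonzero smallest singular value: take its right
                # singular vector as the closest-to-null direction
                _, _, Vt = scipy.linalg.svd(M)
                t = Vt[-1]

    t = t / _wnorm(t, settings.theta)
    if reference is not None:
        if _wdot(t, np.asarray(reference, float), settings.theta) < 0:
            t = -t
    else:
        if abs(t[-1]) > 1e-12:
            if t[-1] < 0:
                t = -t
        elif t[np.argmax(np.abs(t[:-1]))] < 0:
            t = -t
    return t


def _operator_tangent(Jv, Flam, n, reference, settings):
    """Tangent for operator-form Jacobians via a bordered GMRES solve.

    Solves ``[[F_v, F_lam], [b_v, b_lam]] t = e_{n+1}`` where the bordering
    row ``b`` is the previous tangent (or the parameter axis when starting),
    then normalises.  The bordered matrix is nonsingular whenever the curve
    is regular and ``b`` is not orthogonal to the tangent.
    """
    if reference is not None:
        b = np.asarray(reference, float)
    else:
        b = np.zeros(n + 1)
        b[-1] = 1.0
    A = _augmented_operator(Jv, Flam, b, settings.theta)
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    t, info = spla.gmres(A, rhs, rtol=settings.krylov_tol, atol=0.0,
                         restart=settings.krylov_restart, maxiter=5)
    if info != 0:
        # a tangent only steers the predictor and the arclength hyperplane
        # (Newton re-corrects both), so the finite-difference noise floor of
        # the J.phi products is an acceptable accuracy here
        rel = (np.linalg.norm(A.matvec(t) - rhs)
               / max(np.linalg.norm(rhs), 1e-300))
        if rel > 1e-4:
            raise SingularJacobianError(
                f"GMRES failed on tangent bordered solve (info={info}, "
                f"relative residual {rel:.2e})")
    return t


def _augmented_operator(Jv, Flam, bottom, theta):
    """(n+1) x (n+1) LinearOperator [[F_v, F_lam], [theta^2*b_v, b_lam]]."""
    n = Flam.size

    def matvec(x):
        xv, xl = x[:-1], x[-1]
        top = Jv.matvec(xv) + Flam * xl
        bot = theta**2 * np.dot(bottom[:-1], xv) + bottom[-1] * xl
        return np.append(top, bot)

    return spla.LinearOperator((n + 1, n + 1), matvec=matvec, dtype=float)


# ----------------------------------------------------------------------
# corrector

def _augmented_residual(problem, v, lam, anchor, ds, settings):
    Fv = problem.F(v, lam)
    t = anchor.tangent
    arc = (settings.theta**2 * np.dot(v - anchor.state, t[:-1])
           + (lam - anchor.parameter) * t[-1] - ds)
    return np.append(Fv, arc)


def newton_correct(problem, prediction, anchor, ds, settings):
    """Newton-correct a predicted point onto the curve.

    Solves ``F(v, lam) = 0`` together with the pseudo-arclength condition
    anchored at ``anchor`` (whose tangent supplies the hyperplane normal).
    Terminates early once the augmented residual 2-norm drops below
    ``newton_tol``; raises :class:`NewtonFailure` after ``max_newton``
    iterations without convergence.

    Returns a :class:`BranchPoint` (tangent not yet attached).
    """
    v = problem.project(np.asarray(prediction[0], dtype=float).copy())
    lam = float(prediction[1])
    if not (np.all(np.isfinite(v)) and np.isfinite(lam)):
        raise ValueError("newton_correct: non-finite prediction")

    R = _augmented_residual(problem, v, lam, anchor, ds, settings)
    for it in range(settings.max_newton + 1):
        rnorm = np.linalg.norm(R)
        if rnorm <= settings.newton_tol:
            return BranchPoint(state=v, parameter=lam, newton_iterations=it)
        if it == settings.max_newton:
            break
        Jv = problem.F_v(v, lam)
        Flam = problem.F_lam(v, lam)
        t = anchor.tangent
        if _is_operator(Jv):
            A = _augmented_operator(Jv, Flam, t, settings.theta)
            delta, info = spla.gmres(A, R, rtol=settings.krylov_tol, atol=0.0,
                                     restart=settings.krylov_restart, maxiter=5)
            if info != 0:
                # scipy's internal estimate can report failure at the
                # finite-difference noise floor of the J.phi products;
                # accept when the directly evaluated residual is close
                rel = (np.linalg.norm(A.matvec(delta) - R)
                       / max(np.linalg.norm(R), 1e-300))
                if rel > 100.0 * settings.krylov_tol:
                    raise SingularJacobianError(
                        f"GMRES stagnated in Newton step (info={info}, "
                        f"relative residual {rel:.2e})")
        else:
            A = np.zeros((v.size + 1, v.size + 1))
            A[:-1, :-1] = Jv
            A[:-1, -1] = Flam
            A[-1, :-1] = settings.theta**2 * t[:-1]
            A[-1, -1] = t[-1]
            delta = dense_solve(A, R)
        v = problem.project(v - delta[:-1])
        lam = lam - delta[-1]
        R = _augmented_residual(problem, v, lam, anchor, ds, settings)

    raise NewtonFailure(
        f"no convergence in {settings.max_newton} Newton iterations "
        f"(|R| = {np.linalg.norm(R):.3e})",
        state=v, parameter=lam, residual_norm=np.linalg.norm(R),
    )


# ----------------------------------------------------------------------
# stability

def assess_stability(problem, point, exclude=None, k=6, settings=None):
    """Eigenvalue summary of the state-block Jacobian ``F_v`` at a point.

    ``exclude`` is an optional list of structural-mode vectors (e.g. the
    discretised spatial derivative of a travelling wave); eigenvalues whose
    eigenvector has |cosine similarity| > 0.98 with any of them are dropped
    before judging stability.  Stable iff ``max Re < -stability_tol`` of the
    remainder; real parts within the tolerance band are flagged marginal.

    For operator-form Jacobians the ``k`` rightmost eigenvalues are found by
    implicitly restarted Arnoldi iteration using only matrix--vector
    products.
    """
    settings = settings or ContinuationSettings()
    Jv = problem.F_v(np.asarray(point.state, float), point.parameter)
    if _is_operator(Jv):
        vals, vecs = spla.eigs(Jv, k=min(k, Jv.shape[0] - 2), which="LR",
                               tol=1e-7, maxiter=5000)
    else:
        Jv = np.asarray(Jv, float)
        if Jv.shape[0] == 1:
            vals = Jv[0, :1].astype(complex)
            vecs = np.ones((1, 1), dtype=complex)
        else:
            vals, vecs = scipy.linalg.eig(Jv)

    order = np.argsort(-vals.real)
    vals, vecs = vals[order], vecs[:, order]

    keep = np.ones(len(vals), dtype=bool)
    if exclude:
        for mode in exclude:
            m = np.asarray(mode, float)
            m = m / np.linalg.norm(m)
            for i in range(len(vals)):
                vec = vecs[:, i]
                sim = abs(np.vdot(vec, m)) / np.linalg.norm(vec)
                if sim > 0.98:
                    keep[i] = False
    kept = vals[keep]
    tol = settings.stability_tol
    if len(kept) == 0:
        stable, marginal = True, True
    else:
        mx = kept.real.max()
        stable = mx < -tol
        marginal = -tol <= mx <= tol
    return EigenSummary(eigenvalues=vals, stable=bool(stable),
                        marginal=bool(marginal),
                        n_excluded=int((~keep).sum()))


# ----------------------------------------------------------------------
# branch stepping

def _step_tangent(problem, point, prev, settings):
    """Tangent at an accepted point: exact null-space solve, or the secant
    through the previous point, sign-referenced to the previous tangent."""
    ref = prev.tangent if prev is not None else None
    if settings.tangent_method == "secant" and prev is not None:
        t = point.extended() - prev.extended()
        t = t / _wnorm(t, settings.theta)
        if ref is not None and _wdot(t, ref, settings.theta) < 0:
            t = -t
        return t
    return compute_tangent(problem, point, reference=ref, settings=settings)


def continue_branch(problem, initial, settings, stability=None, exclude_modes=None,
                    callback=None):
    """Follow a solution branch from a converged initial point.

    Parameters
    ----------
    problem : ContinuationProblem
    initial : BranchPoint (residual norm must already be <= newton_tol) --
        its tangent is computed if absent; ``settings.direction`` flips it.
    settings : ContinuationSettings
    stability : None | True | callable(problem, point) -> EigenSummary.
        ``True`` uses :func:`assess_stability` with ``exclude_modes``.
    callback : optional ``callback(step_index, point)`` progress hook.

    Returns a :class:`Branch`.  Mid-branch corrector failure (after optional
    stepsize halving) truncates the branch and records a diagnostic rather
    than raising.  Folds -- sign changes of the tangent's parameter
    component -- are refined by bisection in arclength and recorded.
    """
    r0 = np.linalg.norm(problem.F(initial.state, initial.parameter))
    if r0 > max(settings.newton_tol, 1e-8):
        raise ValueError(f"initial point is not converged (|F| = {r0:.3e})")

    point = replace(initial)
    if point.tangent is None:
        point.tangent = compute_tangent(problem, point, settings=settings)
    if settings.direction < 0:
        point.tangent = -point.tangent

    stab_fn = None
    if stability is True:
        stab_fn = lambda pr, pt: assess_stability(pr, pt, exclude=exclude_modes,
                                                  settings=settings)
    elif callable(stability):
        stab_fn = stability
    if stab_fn is not None and point.eigen_summary is None:
        point.eigen_summary = stab_fn(problem, point)
        point.stable = point.eigen_summary.stable

    branch = Branch(points=[point])
    ds = settings.ds
    fast_streak = 0

    for step in range(1, settings.max_steps):
        anchor = branch.points[-1]
        accepted = None
        while True:
            pred = (anchor.state + ds * anchor.tangent[:-1],
                    anchor.parameter + ds * anchor.tangent[-1])
            try:
                accepted = newton_correct(problem, pred, anchor, ds, settings)
                break
            except (NewtonFailure, SingularJacobianError) as exc:
                if settings.adapt_step and ds / 2.0 >= settings.ds_min:
                    ds /= 2.0
                    fast_streak = 0
                    continue
                branch.diagnostic = f"corrector failure at step {step}: {exc}"
                _refine_branch_folds(problem, branch, settings)
                return branch

        try:
            accepted.tangent = _step_tangent(problem, accepted, anchor, settings)
        except (DegenerateTangentError, SingularJacobianError) as exc:
            branch.diagnostic = f"tangent failure at step {step}: {exc}"
            branch.points.append(accepted)
            _refine_branch_folds(problem, branch, settings)
            return branch

        accepted.step_ds = ds
        if stab_fn is not None:
            accepted.eigen_summary = stab_fn(problem, accepted)
            accepted.stable = accepted.eigen_summary.stable
        branch.points.append(accepted)
        if callback is not None:
            callback(step, accepted)

        if settings.adapt_step:
            if accepted.newton_iterations <= 3:
                fast_streak += 1
                if fast_streak >= 2 and ds * 2.0 <= settings.ds_max:
                    ds *= 2.0
                    fast_streak = 0
            else:
                fast_streak = 0

    _refine_branch_folds(problem, branch, settings)
    return branch


# ----------------------------------------------------------------------
# folds

def detect_folds(branch, problem=None, settings=None):
    """Locate saddle-node bifurcations on a branch.

    One record per sign change of the tangent's parameter component between
    consecutive points.  With ``problem`` given, each fold is refined by
    bisection in arclength from the bracketing anchor (tolerance
    ``settings.fold_refine_tol``); otherwise the parameter extremum is
    estimated by linear interpolation of the tangent component.
    """
    settings = settings or ContinuationSettings()
    if len(branch.points) < 2:
        return []
    records = []
    pts = branch.points
    for i in range(len(pts) - 1):
        ta, tb = pts[i].tangent, pts[i + 1].tangent
        if ta is None or tb is None:
            continue
        la, lb = ta[-1], tb[-1]
        if la == 0.0 or la * lb >= 0.0:
            continue
        if problem is not None:
            rec = _bisect_fold(problem, pts[i], pts[i + 1], settings)
        else:
            # linear interpolation of lamdot in arclength
            frac = la / (la - lb)
            par = (1 - frac) * pts[i].parameter + frac * pts[i + 1].parameter
            st = (1 - frac) * pts[i].state + frac * pts[i + 1].state
            rec = FoldRecord(parameter=par, state=st, index=i)
        rec.index = i
        records.append(rec)
    return records


def _bisect_fold(problem, pa, pb, settings):
    """Bisection in arclength between two points bracketing a fold."""
    ds_full = _wdot(pb.extended() - pa.extended(), pa.tangent, settings.theta)
    lo, hi = 0.0, ds_full
    sign_lo = np.sign(pa.tangent[-1])
    pt_mid = pb
    while hi - lo > settings.fold_refine_tol:
        mid = 0.5 * (lo + hi)
        pred = (pa.state + mid * pa.tangent[:-1],
                pa.parameter + mid * pa.tangent[-1])
        try:
            pt_mid = newton_correct(problem, pred, pa, mid, settings)
            t_mid = compute_tangent(problem, pt_mid, reference=pa.tangent,
                                    settings=settings)
        except (NewtonFailure, SingularJacobianError, DegenerateTangentError):
            break
        if np.sign(t_mid[-1]) == sign_lo:
            lo = mid
        else:
            hi = mid
    return FoldRecord(parameter=pt_mid.parameter, state=pt_mid.state, index=0,
                      tangent_parameter_component=float(
                          compute_tangent(problem, pt_mid, reference=pa.tangent,
                                          settings=settings)[-1])
                      if pt_mid is not pb else 0.0)


def _refine_branch_folds(problem, branch, settings):
    branch.folds = detect_folds(branch, problem=problem, settings=settings)
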