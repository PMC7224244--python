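"""Pseudo-arclength engine: tangents, corrector, branches, folds, stability."""

import numpy as np
import pytest
from scipy.optimize import brentq

from neurocont.continuation import (
    BranchPoint,
    ContinuationProblem,
    ContinuationSettings,
    DegenerateTangentError,
    NewtonFailure,
    assess_stability,
    compute_tangent,
    continue_branch,
    detect_folds,
    newton_correct,
)
from neurocont.models import toy_residual

# ----------------------------------------------------------------------
# problem factories


def linear_problem():
    """F(v, lam) = v - lam: the solution curve is the diagonal."""
    return ContinuationProblem(
        residual=lambda v, lam: np.array([v[0] - lam]),
        jacobian_state=lambda v, lam: np.array([[1.0]]),
        jacobian_param=lambda v, lam: np.array([-1.0]),
    )


def toy_problem():
    return ContinuationProblem(
        residual=lambda v, mu: np.array([toy_residual(v[0], mu)[0]]),
        jacobian_state=lambda v, mu: np.array([[toy_residual(v[0], mu)[1]]]),
        jacobian_param=lambda v, mu: np.array([toy_residual(v[0], mu)[2]]),
        parameter_name="mu",
    )


def toy_roots_at_mu_zero():
    lo = brentq(lambda u: u**4 - u - 1, -1.0, 0.0, xtol=1e-14)
    hi = brentq(lambda u: u**4 - u - 1, 1.0, 2.0, xtol=1e-14)
    return lo, hi


def fold_oracle():
    """Simultaneous root of g = 0, g_u = 0: u* = 4**(-1/3),
    mu*^2 = 1 + u* - u*^4."""
    u_star = 4.0 ** (-1.0 / 3.0)
    mu_star = np.sqrt(1.0 + u_star - u_star**4)
    return u_star, mu_star


# ----------------------------------------------------------------------


class TestComputeTangent:
    def test_linear_problem_diagonal_tangent(self):
        t = compute_tangent(linear_problem(), BranchPoint(np.array([0.0]), 0.0))
        assert np.allclose(np.abs(t), 1.0 / np.sqrt(2.0))

    def test_parameter_component_vanishes_at_fold(self):
        u_star, mu_star = fold_oracle()
        t = compute_tangent(toy_problem(), BranchPoint(np.array([u_star]), mu_star))
        assert abs(t[-1]) < 1e-6
        assert abs(t[0]) == pytest.approx(1.0, abs=1e-10)

    def test_pure_parameter_tangent_where_g_mu_vanishes(self):
        # at mu = 0 on the upper root, g_mu = 0, g_u != 0: the curve is
        # locally parametrised by mu alone
        _, hi = toy_roots_at_mu_zero()
        t = compute_tangent(toy_problem(), BranchPoint(np.array([hi]), 0.0))
        assert abs(t[0]) < 1e-10
        assert abs(t[-1]) == pytest.approx(1.0, abs=1e-10)

    def test_sign_follows_reference(self):
        prob = linear_problem()
        pt = BranchPoint(np.array([0.0]), 0.0)
        ref = np.array([-1.0, -1.0]) / np.sqrt(2.0)
        t = compute_tangent(prob, pt, reference=ref)
        assert np.dot(t, ref) > 0

    def test_two_dimensional_null_space_signals(self):
        # F(v, lam) = v * lam has extended Jacobian [0, 0] at the origin
        prob = ContinuationProblem(
            residual=lambda v, lam: np.array([v[0] * lam]),
            jacobian_state=lambda v, lam: np.array([[lam]]),
            jacobian_param=lambda v, lam: np.array([v[0]]),
        )
        with pytest.raises(DegenerateTangentError):
            compute_tangent(prob, BranchPoint(np.array([0.0]), 0.0))

    def test_theta_weighted_norm_is_one(self):
        settings = ContinuationSettings(theta=3.0)
        t = compute_tangent(linear_problem(), BranchPoint(np.array([0.0]), 0.0),
                            settings=settings)
        assert settings.theta**2 * t[0] ** 2 + t[-1] ** 2 == pytest.approx(1.0)


class TestNewtonCorrect:
    def settings(self):
        return ContinuationSettings(ds=0.1)

    def anchor(self, prob, v, lam):
        pt = BranchPoint(np.asarray(v, float), lam)
        pt.tangent = compute_tangent(prob, pt)
        return pt

    def test_affine_map_converges_in_one_iteration(self):
        prob = linear_problem()
        anchor = self.anchor(prob, [0.0], 0.0)
        pt = newton_correct(prob, (np.array([0.4]), 0.2), anchor, 0.1,
                            self.settings())
        assert pt.newton_iterations == 1
        assert abs(pt.state[0] - pt.parameter) < 1e-12

    def test_converged_prediction_returned_unchanged(self):
        prob = linear_problem()
        anchor = self.anchor(prob, [0.0], 0.0)
        exact = anchor.extended() + 0.1 * anchor.tangent
        pt = newton_correct(prob, (exact[:-1], exact[-1]), anchor, 0.1,
                            self.settings())
        assert pt.newton_iterations == 0
        assert np.allclose(np.append(pt.state, pt.parameter), exact)

    def test_toy_correction_lands_on_curve_and_arclength_plane(self):
        lo, _ = toy_roots_at_mu_zero()
        prob = toy_problem()
        anchor = self.anchor(prob, [lo], 0.0)
        ds = 0.1
        pred = anchor.extended() + ds * anchor.tangent
        pt = newton_correct(prob, (pred[:-1], pred[-1]), anchor, ds, self.settings())
        assert abs(toy_residual(pt.state[0], pt.parameter)[0]) < 1e-10
        arc = (np.dot(pt.state - anchor.state, anchor.tangent[:-1])
               + (pt.parameter - anchor.parameter) * anchor.tangent[-1] - ds)
        assert abs(arc) < 1e-10

    def test_failure_carries_last_iterate(self):
        # no solution within reach: g has no root near mu = 5
        prob = toy_problem()
        anchor = BranchPoint(np.array([0.0]), 5.0,
                             tangent=np.array([0.0, 1.0]))
        with pytest.raises(NewtonFailure) as err:
            newton_correct(prob, (np.array([0.0]), 5.0), anchor, 0.1,
                           ContinuationSettings(ds=0.1, max_newton=4))
        assert err.value.state is not None


class TestContinueBranch:
    def test_linear_branch_collinear_with_uniform_spacing(self):
        prob = linear_problem()
        settings = ContinuationSettings(ds=0.1, max_steps=10)
        br = continue_branch(prob, BranchPoint(np.array([0.0]), 0.0), settings)
        assert len(br) == 10
        ext = np.array([p.extended() for p in br.points])
        assert np.allclose(ext[:, 0], ext[:, 1], atol=1e-12)  # on the diagonal
        steps = np.linalg.norm(np.diff(ext, axis=0), axis=1)
        assert np.allclose(steps, 0.1, atol=1e-10)
        assert detect_folds(br) == []

    def test_direction_reversal_traverses_opposite_way(self):
        prob = linear_problem()
        fwd = continue_branch(prob, BranchPoint(np.array([0.0]), 0.0),
                              ContinuationSettings(ds=0.1, max_steps=5))
        bwd = continue_branch(prob, BranchPoint(np.array([0.0]), 0.0),
                              ContinuationSettings(ds=0.1, max_steps=5,
                                                   direction=-1))
        assert np.allclose(fwd.parameters, -bwd.parameters)

    def test_toy_closed_curve_has_two_symmetric_folds(self):
        lo, _ = toy_roots_at_mu_zero()
        settings = ContinuationSettings(ds=0.1, max_steps=80)
        br = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0),
                             settings)
        assert len(br.folds) == 2
        _, mu_star = fold_oracle()
        mus = sorted(f.parameter for f in br.folds)
        assert mus[1] == pytest.approx(mu_star, abs=1e-6)
        assert mus[0] == pytest.approx(-mu_star, abs=1e-6)
        assert abs(mus[0] + mus[1]) < 1e-6  # symmetric pair

    def test_pseudo_arclength_condition_at_every_accepted_point(self):
        lo, _ = toy_roots_at_mu_zero()
        settings = ContinuationSettings(ds=0.1, max_steps=60)
        br = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0),
                             settings)
        for a, b in zip(br.points[:-1], br.points[1:]):
            arc = (np.dot(b.state - a.state, a.tangent[:-1])
                   + (b.parameter - a.parameter) * a.tangent[-1] - settings.ds)
            assert abs(arc) < 1e-8

    def test_tangent_continuity_along_branch(self):
        lo, _ = toy_roots_at_mu_zero()
        br = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0),
                             ContinuationSettings(ds=0.1, max_steps=60))
        for a, b in zip(br.points[:-1], br.points[1:]):
            assert np.dot(a.tangent, b.tangent) > 0

    def test_theta_one_matches_unscaled_branch(self):
        lo, _ = toy_roots_at_mu_zero()
        s1 = ContinuationSettings(ds=0.1, max_steps=30)
        s2 = ContinuationSettings(ds=0.1, max_steps=30, theta=1.0)
        b1 = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0), s1)
        b2 = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0), s2)
        assert np.array_equal(b1.parameters, b2.parameters)
        assert np.array_equal(b1.states, b2.states)

    def test_reversal_symmetry(self):
        lo, _ = toy_roots_at_mu_zero()
        fwd = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0),
                              ContinuationSettings(ds=0.1, max_steps=20))
        bwd = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0),
                              ContinuationSettings(ds=0.1, max_steps=20,
                                                   direction=-1))
        # both runs stay on the solution curve and traverse it in opposite
        # senses from the shared start
        for p in list(fwd.points) + list(bwd.points):
            assert abs(toy_residual(p.state[0], p.parameter)[0]) < 1e-9
        assert np.allclose(fwd.points[0].tangent, -bwd.points[0].tangent)
        # re-running forward from the far end of the reversed branch lands
        # back on the forward branch (chord-stepping drift only, O(ds^2))
        re_fwd = continue_branch(toy_problem(),
                                 BranchPoint(bwd.points[-1].state.copy(),
                                             bwd.points[-1].parameter),
                                 ContinuationSettings(ds=0.1, max_steps=39))
        assert np.allclose(re_fwd.points[-1].extended(),
                           fwd.points[19].extended(), atol=1e-3)

    def test_unconverged_initial_point_rejected(self):
        with pytest.raises(ValueError):
            continue_branch(toy_problem(), BranchPoint(np.array([0.5]), 0.0),
                            ContinuationSettings(ds=0.1))

    def test_secant_tangent_follows_same_curve(self):
        lo, _ = toy_roots_at_mu_zero()
        exact = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0),
                                ContinuationSettings(ds=0.05, max_steps=20))
        secant = continue_branch(toy_problem(), BranchPoint(np.array([lo]), 0.0),
                                 ContinuationSettings(ds=0.05, max_steps=20,
                                                      tangent_method="secant"))
        # both runs stay on g = 0; points differ only via parametrisation
        for p in secant.points:
            assert abs(toy_residual(p.state[0], p.parameter)[0]) < 1e-9
        assert abs(secant.points[-1].parameter
                   - exact.points[-1].parameter) < 0.05


class TestStability:
    def test_toy_stability_signs_match_gu(self):
        lo, hi = toy_roots_at_mu_zero()
        prob = toy_problem()
        s_lo = assess_stability(prob, BranchPoint(np.array([lo]), 0.0))
        s_hi = assess_stability(prob, BranchPoint(np.array([hi]), 0.0))
        assert s_lo.stable and not s_hi.stable
        assert s_lo.eigenvalues[0].real == pytest.approx(4 * lo**3 - 1, abs=1e-10)
        assert s_hi.eigenvalues[0].real == pytest.approx(4 * hi**3 - 1, abs=1e-10)

    def test_near_zero_eigenvalue_at_fold(self):
        u_star, mu_star = fold_oracle()
        s = assess_stability(toy_problem(), BranchPoint(np.array([u_star]), mu_star))
        assert abs(s.eigenvalues[np.argmin(np.abs(s.eigenvalues))]) < 1e-10
        assert s.marginal


class TestSettingsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"ds": -0.1}, {"ds": 0.0}, {"theta": 0.0}, {"max_newton": 0},
        {"tangent_method": "spline"},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContinuationSettings(**kwargs)
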