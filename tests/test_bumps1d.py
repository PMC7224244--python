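"""Cosine-Galerkin stationary bumps and their continuation in threshold."""

import numpy as np
import pytest
from scipy.integrate import quad

from neurocont import bumps1d
from neurocont.continuation import ContinuationSettings, finite_difference_jacobian
from neurocont.models import firing_rate, kernel_eval, mexican_hat_1d


@pytest.fixture(scope="module")
def problem():
    return bumps1d.BumpProblem()  # N=15, beta=20, h=0.3, Mexican hat


@pytest.fixture(scope="module")
def bump(problem):
    return bumps1d.initial_bump(problem)


@pytest.fixture(scope="module")
def branch(problem, bump):
    return bumps1d.continue_bumps_in_h(
        problem, bump, ContinuationSettings(ds=0.05, max_steps=120))


class TestKernelCoefficients:
    def test_pure_mode_recovered(self):
        c = bumps1d.kernel_cosine_coefficients(lambda x: np.cos(2 * x), N=6, M=64)
        expect = np.zeros(6)
        expect[2] = 1.0
        assert np.max(np.abs(c - expect)) < 1e-12

    def test_constant_kernel(self):
        c = bumps1d.kernel_cosine_coefficients(lambda x: np.ones_like(x), N=4, M=32)
        assert np.max(np.abs(c - [1, 0, 0, 0])) < 1e-12

    def test_against_adaptive_quadrature_oracle(self):
        # M large enough that the trapezoid error from the kernel's small
        # derivative jump across +-pi sits below the comparison tolerance
        kern = mexican_hat_1d()
        c = bumps1d.kernel_cosine_coefficients(kern, N=15, M=1024)
        for j in (0, 1, 5, 14):
            val, _ = quad(lambda x: kernel_eval(kern, x) * np.cos(j * x),
                          -np.pi, np.pi, limit=200, epsabs=1e-12)
            val /= (2 * np.pi) if j == 0 else np.pi
            assert c[j] == pytest.approx(val, abs=1e-8)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError):
            bumps1d.kernel_cosine_coefficients(mexican_hat_1d(), N=15, M=32)


class TestResidual:
    def test_zero_coefficients(self, problem):
        r = bumps1d.bump_residual(np.zeros(problem.N), problem)
        f0, _ = firing_rate(-problem.h, problem.beta)
        assert r[0] == pytest.approx(2 * np.pi * problem.kernel_coeffs[0] * f0,
                                     abs=1e-12)
        assert np.max(np.abs(r[1:])) < 1e-12

    def test_huge_threshold_silences_firing(self, problem, rng):
        coeffs = rng.normal(size=problem.N)
        r = bumps1d.bump_residual(coeffs, problem, h=1e3)
        assert np.max(np.abs(r + coeffs)) < 1e-12

    def test_converged_bump(self, problem, bump):
        assert np.linalg.norm(bumps1d.bump_residual(bump, problem)) < 1e-10

    def test_wrong_size_rejected(self, problem):
        with pytest.raises(ValueError):
            bumps1d.bump_residual(np.zeros(3), problem)

    def test_jacobian_matches_finite_differences(self, problem, bump):
        J = bumps1d.bump_jacobian(bump, problem)
        J_fd = finite_difference_jacobian(
            lambda c: bumps1d.bump_residual(c, problem), bump)
        assert np.max(np.abs(J - J_fd)) / np.max(np.abs(J_fd)) < 1e-5

    def test_reconstruction_solves_integral_equation_off_grid(self):
        # substitute the reconstructed field into the continuum fixed-point
        # equation at points that are not quadrature nodes; the displacement
        # wraps onto [-pi, pi) because the model lives on the circle.  M is
        # raised so the steep sigmoid (beta = 20) is fully resolved by the
        # trapezoid rule and only mode truncation remains.
        prob = bumps1d.BumpProblem(M=512)
        coeffs = bumps1d.initial_bump(prob)

        def wrapped_kernel(d):
            return kernel_eval(prob.kernel, (d + np.pi) % (2 * np.pi) - np.pi)

        for x in (0.123, 0.87, 2.0):
            lhs = bumps1d.reconstruct_field(coeffs, x)
            rhs, _ = quad(
                lambda y: wrapped_kernel(x - y)
                * firing_rate(bumps1d.reconstruct_field(coeffs, y) - prob.h,
                              prob.beta)[0],
                -np.pi, np.pi, limit=400)
            assert lhs == pytest.approx(rhs, abs=1e-4)


class TestContinuation:
    def test_two_coexisting_bumps_one_stable_one_unstable(self, branch):
        h_probe = 0.6  # inside the existence interval
        hs = branch.parameters
        hits = [p for p, h0, h1 in zip(branch.points[:-1], hs[:-1], hs[1:])
                if min(h0, h1) <= h_probe < max(h0, h1)]
        assert len(hits) == 2
        assert sorted(p.stable for p in hits) == [False, True]

    def test_branch_terminates_in_fold(self, branch):
        assert len(branch.folds) >= 1

    def test_no_translational_zero_eigenvalue(self, branch):
        # evenness removed the neutral mode: away from the fold no
        # eigenvalue sits at zero
        h_fold = branch.folds[0].parameter
        for p in branch.points:
            if abs(p.parameter - h_fold) > 0.05:
                assert np.min(np.abs(p.eigen_summary.eigenvalues)) > 1e-3

    def test_fold_location_against_refined_stepsize(self, problem, bump, branch):
        fine = bumps1d.continue_bumps_in_h(
            problem, bump, ContinuationSettings(ds=0.005, max_steps=400),
            stability=False)
        assert fine.folds and branch.folds
        assert abs(fine.folds[0].parameter - branch.folds[0].parameter) < 1e-4


class TestFiniteFourierExactness:
    def test_truncation_at_kernel_band_limit_is_exact(self):
        # kernel with an exactly finite cosine series (NF = 4): branches
        # computed with N = NF + 1 and N = 2 NF + 1 coincide pointwise
        NF = 4
        base = bumps1d.kernel_cosine_coefficients(mexican_hat_1d(), N=NF + 1, M=128)

        def kern(x):
            return bumps1d.reconstruct_field(base, x)

        settings = ContinuationSettings(ds=0.05, max_steps=40)
        sols = {}
        for N in (NF + 1, 2 * NF + 1):
            prob = bumps1d.BumpProblem(N=N, h=0.3, kernel=kern, M=128)
            c0 = bumps1d.initial_bump(prob)
            sols[N] = bumps1d.continue_bumps_in_h(prob, c0, settings,
                                                  stability=False)
        small, big = sols[NF + 1], sols[2 * NF + 1]
        assert np.allclose(small.parameters, big.parameters, atol=1e-8)
        # higher modes vanish at steady state; shared modes agree
        assert np.max(np.abs(big.states[:, NF + 1:])) < 1e-8
        assert np.max(np.abs(big.states[:, :NF + 1] - small.states)) < 1e-8
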