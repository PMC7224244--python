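"""2D travelling bumps: residuals, matrix-free products, Krylov correction."""

import numpy as np
import pytest

from neurocont import bump2d
from neurocont.continuation import (
    BranchPoint,
    ContinuationSettings,
    finite_difference_jacobian,
)
from neurocont.models import kernel_eval


@pytest.fixture(scope="module")
def tiny():
    return bump2d.Problem2D(N=8)


class TestResidual:
    def test_quiescent_state_with_silenced_firing(self):
        prob = bump2d.Problem2D(N=16, h=1e3)
        V = prob.pack(np.zeros((16, 16)), np.zeros((16, 16)), 0.0)
        assert np.max(np.abs(bump2d.residual_2d(V, prob))) < 1e-12

    def test_phase_residual_vanishes_for_xi_constant_row(self, tiny, rng):
        u = rng.normal(size=(8, 8))
        u[4, :] = 0.7  # constant along xi at y = L/2
        V = tiny.pack(u, rng.normal(size=(8, 8)), 0.1)
        assert bump2d.residual_2d(V, tiny)[-1] == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_input_gives_symmetric_residual(self, tiny, rng):
        u = bump2d.symmetrize(rng.normal(size=(8, 8)))
        a = bump2d.symmetrize(rng.normal(size=(8, 8)))
        V = tiny.pack(u, a, 0.3)
        R = bump2d.residual_2d(V, tiny)
        Ru, Ra, _ = tiny.unpack(np.append(R[:-1], 0.0))
        assert np.max(np.abs(Ru - bump2d.symmetrize(Ru))) < 1e-12
        assert np.max(np.abs(Ra - bump2d.symmetrize(Ra))) < 1e-12

    def test_spectral_convolution_equals_direct_sum(self, tiny, rng):
        field = rng.normal(size=(8, 8))
        spectral = tiny.convolve(field)
        direct = np.zeros_like(field)
        N = 8
        for j in range(N):
            for i in range(N):
                acc = 0.0
                for jp in range(N):
                    for ip in range(N):
                        dx = tiny.coords[i] - tiny.coords[ip]
                        dy = tiny.coords[j] - tiny.coords[jp]
                        # periodic minimum image
                        dx -= tiny.L * np.round(dx / tiny.L)
                        dy -= tiny.L * np.round(dy / tiny.L)
                        acc += kernel_eval(tiny.kernel, dx, dy) * field[jp, ip]
                direct[j, i] = acc * tiny.dA
        assert np.max(np.abs(spectral - direct)) < 1e-10


class TestSymmetry:
    def test_projection_idempotent(self, rng):
        f = rng.normal(size=(12, 12))
        s = bump2d.symmetrize(f)
        assert np.allclose(bump2d.symmetrize(s), s, atol=1e-15)

    def test_projection_commutes_with_residual_on_symmetric_states(self, tiny, rng):
        u = bump2d.symmetrize(rng.normal(size=(8, 8)))
        a = bump2d.symmetrize(rng.normal(size=(8, 8)))
        V = tiny.pack(u, a, 0.2)
        proj = bump2d.state_projector(tiny)
        R = bump2d.residual_2d(V, tiny)
        R_proj = bump2d.residual_2d(proj(V), tiny)
        assert np.max(np.abs(R - R_proj)) < 1e-12


class TestJacobianVectorProduct:
    def test_exact_on_affine_map(self, rng):
        M = rng.normal(size=(6, 6))
        b = rng.normal(size=6)
        G = lambda x: M @ x + b
        V = rng.normal(size=6)
        phi = rng.normal(size=6)
        jv = bump2d.jacobian_vector_product(G, V, phi, eps=1e-4)
        assert np.allclose(jv, M @ phi, atol=1e-9)

    def test_quadratic_map_first_order_error(self):
        G = lambda x: x * x
        V = np.ones(5)
        phi = np.zeros(5)
        phi[0] = 1.0
        eps_base = 1e-7
        jv = bump2d.jacobian_vector_product(G, V, phi, eps=eps_base)
        eps_s = eps_base * (1.0 + np.linalg.norm(V)) / 1.0
        expect = np.zeros(5)
        expect[0] = 2.0 + eps_s
        assert np.allclose(jv, expect, atol=1e-12)

    def test_zero_probe_rejected(self):
        with pytest.raises(ValueError):
            bump2d.jacobian_vector_product(lambda x: x, np.ones(3), np.zeros(3))

    def test_matches_dense_jacobian_on_small_instance(self, tiny, rng):
        X, Y = np.meshgrid(tiny.coords, tiny.coords)
        u = 1.5 * np.exp(-((X - 7.5) ** 2 + (Y - 7.5) ** 2) / 4.0)
        V = tiny.pack(u, 0.4 * u, 0.1)
        G = lambda x: bump2d.residual_2d(x, tiny)
        J_dense = finite_difference_jacobian(G, V)
        for _ in range(3):
            phi = rng.normal(size=V.size)
            jv = bump2d.jacobian_vector_product(G, V, phi)
            ref = J_dense @ phi
            assert np.linalg.norm(jv - ref) / np.linalg.norm(ref) < 1e-5


class TestNewtonKrylov:
    def test_linear_augmented_system_single_iteration(self):
        # an affine residual: one Newton step, inner GMRES solves exactly
        n = 20
        rng = np.random.default_rng(7)
        M = rng.normal(size=(n, n)) + 4 * np.eye(n)
        b = rng.normal(size=n)
        fl = rng.normal(size=n)
        import scipy.sparse.linalg as spla

        from neurocont.continuation import ContinuationProblem, newton_correct

        prob = ContinuationProblem(
            residual=lambda v, lam: M @ v + fl * lam + b,
            jacobian_state=lambda v, lam: spla.aslinearoperator(M),
            jacobian_param=lambda v, lam: fl,
        )
        anchor = BranchPoint(state=np.zeros(n), parameter=0.0,
                             tangent=np.append(np.zeros(n), 1.0))
        pt = newton_correct(prob, (np.zeros(n), 0.0), anchor, 0.0,
                            ContinuationSettings(ds=0.1, newton_tol=1e-9))
        assert pt.newton_iterations == 1
        assert np.linalg.norm(M @ pt.state + b) < 1e-8

    def test_matrix_free_matches_dense_newton(self, rng):
        # the GMRES-corrected bump and a dense assembled-Jacobian Newton
        # started from a perturbation of it land on the same solution.
        # N = 32 is the coarsest grid on this domain that resolves a
        # genuine travelling bump (at N = 16 the state degenerates to a
        # near-uniform profile whose speed is ill-determined).
        prob = bump2d.Problem2D(N=32)
        krylov = bump2d.initial_bump_2d(prob, T=60.0,
                                        newton_tol=1e-10).as_vector(prob)
        assert abs(krylov[-1]) < 1.0  # a resolved, slowly drifting bump

        from neurocont.continuation import (
            ContinuationProblem,
            newton_correct,
        )

        dense_prob = ContinuationProblem(
            residual=lambda v, A: bump2d.residual_2d(v, prob, A),
            projector=bump2d.state_projector(prob),
        )
        pert = 1e-3 * rng.normal(size=krylov.size)
        anchor = BranchPoint(state=krylov.copy(), parameter=prob.A,
                             tangent=np.append(np.zeros(krylov.size), 1.0))
        dense_pt = newton_correct(dense_prob, (krylov + pert, prob.A), anchor,
                                  0.0,
                                  ContinuationSettings(ds=0.1, newton_tol=1e-10,
                                                       max_newton=20))
        assert np.linalg.norm(krylov - dense_pt.state) < 1e-8

    def test_stationary_limit_without_adaptation_drive(self):
        prob = bump2d.Problem2D(N=48, B=0.0)
        st = bump2d.initial_bump_2d(prob, T=60.0)
        assert np.max(np.abs(st.a_field)) < 1e-12  # B = 0 forces a = 0
        # the bump is stationary up to the O(dx^2) phase-condition offset
        assert abs(st.speed) < 2 * prob.dx**2


class TestStability:
    def test_arnoldi_matches_dense_eigensolve_small(self):
        prob = bump2d.Problem2D(N=12)
        u, a, drift = bump2d.time_step_2d(prob, T=50.0)
        state = prob.pack(bump2d.symmetrize(u), bump2d.symmetrize(a), -drift)
        op = bump2d.dynamics_operator(prob, state)
        n = 2 * 12 * 12
        dense = np.column_stack([op.matvec(e) for e in np.eye(n)])
        dense_vals = np.linalg.eigvals(dense)
        dense_top = np.sort_complex(dense_vals[np.argsort(-dense_vals.real)][:4])
        arnoldi = bump2d.leading_eigenvalues(prob, state, k=4)
        assert np.allclose(np.sort_complex(arnoldi), dense_top, atol=1e-4)

    def test_translational_modes_near_zero(self, bump2d_problem, bump2d_state):
        # the full-space linearisation retains both translations as
        # near-neutral modes (zero up to the O(dx^2) differencing error),
        # with eigenvectors correlated with the field derivatives
        vals, vecs = bump2d.leading_eigenvalues(bump2d_problem, bump2d_state,
                                                k=6, return_vectors=True)
        modes = bump2d.structural_modes(bump2d_problem, bump2d_state)
        best = {}
        for i in range(len(vals)):
            v = vecs[:, i] / np.linalg.norm(vecs[:, i])
            for m_idx, m in enumerate(modes):
                corr = abs(np.vdot(v, m))
                if corr > best.get(m_idx, (0.0, None))[0]:
                    best[m_idx] = (corr, vals[i])
        for m_idx, (corr, lam) in best.items():
            assert corr > 0.7
            assert abs(lam) < 10 * bump2d_problem.dx**2

    def test_reference_bump_is_stable(self, bump2d_problem, bump2d_state):
        rightmost, stable, _ = bump2d.wave_stability(bump2d_problem, bump2d_state)
        assert stable
        assert rightmost < -1e-3


class TestResolutionRobustness:
    def test_speed_consistent_between_resolutions(self, bump2d_state):
        fine = bump2d.Problem2D(N=128)
        st = bump2d.initial_bump_2d(fine, T=80.0)
        assert abs(st.speed - bump2d_state.speed) < 1e-2
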