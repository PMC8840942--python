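"""Macroscopic limit coefficients and finite-volume limit solvers."""

import numpy as np
import pytest

import kinetaxis as kx
from kinetaxis.exceptions import ConfigurationError
from kinetaxis.macrolimits import (advection_solve, caseii_coeffs, casei_drift,
                                   caseiii_drift, caseiv_drift,
                                   drift_diffusion_solve, tensor_divergence)


@pytest.fixture
def psi():
    return kx.SpeedDistribution.uniform(1.0)


@pytest.fixture
def tilted_fields():
    """Globally asymmetric cue fields (no degenerate normalizations)."""
    d = kx.Domain2D(nx=24, ny=24)
    S = kx.linear_chemoattractant(d, 10.0)
    X, Y = d.mesh()
    fib = kx.FiberField(d, 2.0 + 0.3 * X + 0.5 * Y, np.pi / 3)
    return d, fib, S


def interior(domain, margin):
    X, Y = domain.mesh()
    return ((X > domain.x_min + margin) & (X < domain.x_max - margin)
            & (Y > domain.y_min + margin) & (Y < domain.y_max - margin))


class TestCaseII:
    def test_isotropic_homogeneous_fibers_reduce_to_chemotactic_drift(self, psi):
        d = kx.Domain2D(nx=24, ny=24)
        S = kx.gaussian_chemoattractant(d, 10.0, 1.0, (2.5, 2.5))
        fib = kx.uniform_fibers(d, 0.0)
        gS = kx.SensingKernel("heaviside", 0.1)
        gq = kx.SensingKernel("heaviside", 0.1)
        co = caseii_coeffs("independent", fib, S, (gq, gS), psi)
        gx, gy = S.gradient_grid()
        expected = psi.Ubar * 0.05 * 0.5 * np.stack([gx, gy], -1) / S.values[..., None]
        assert np.allclose(co.drift, expected, atol=1e-12)
        assert np.allclose(co.diffusion, psi.D * 0.5 * np.eye(2))

    def test_drift_parallel_to_gradS_when_eigenvector(self, psi):
        d = kx.Domain2D(nx=24, ny=24)
        S = kx.linear_chemoattractant(d, 10.0)  # grad S along ey
        fib = kx.uniform_fibers(d, 50.0, np.pi / 2)  # leading axis ey
        gS = kx.SensingKernel("dirac_at_R", 0.1)
        co = caseii_coeffs("independent", fib, S,
                           (kx.SensingKernel("dirac_at_R", 0.1), gS), psi)
        assert np.allclose(co.drift[..., 0], 0.0, atol=1e-12)
        Dq = kx.fiber_diffusion_tensor(fib, 2.5, 2.5)
        lam = Dq[1, 1]  # eigenvalue along grad S
        gx, gy = S.gradient_grid()
        assert np.allclose(co.drift[..., 1],
                           psi.Ubar * 0.1 * lam * gy / S.values, rtol=1e-10)

    def test_dependent_equals_independent_for_shared_kernel(self, psi,
                                                            tilted_fields):
        d, fib, S = tilted_fields
        g = kx.SensingKernel("heaviside", 0.3)
        ci = caseii_coeffs("independent", fib, S, (g, g), psi)
        cd = caseii_coeffs("dependent", fib, S, g, psi)
        assert np.abs(ci.drift - cd.drift).max() < 1e-12
        assert np.abs(ci.diffusion - cd.diffusion).max() < 1e-12

    def test_keller_segel_log_sensitivity(self, psi, tilted_fields):
        # chemotactic drift responds to grad S / S: S -> 2 S leaves it fixed
        d, fib, S = tilted_fields
        S2 = kx.ScalarCueField(d, "sampled", {}, values=2.0 * S.values)
        g = kx.SensingKernel("heaviside", 0.3)
        c1 = caseii_coeffs("independent", fib, S, (g, g), psi)
        c2 = caseii_coeffs("independent", fib, S2, (g, g), psi)
        assert np.abs(c1.drift - c2.drift).max() < 1e-11

    def test_tensor_divergence_manufactured(self):
        d = kx.Domain2D(nx=64, ny=64)
        X, Y = d.mesh()
        Dten = np.zeros((64, 64, 2, 2))
        Dten[..., 0, 0] = X**2
        Dten[..., 0, 1] = Dten[..., 1, 0] = X * Y
        Dten[..., 1, 1] = Y**2
        div = tensor_divergence(Dten, d)
        # rows: (d/dx x^2 + d/dy xy, d/dx xy + d/dy y^2) = (3x, 3y)
        inner = interior(d, 0.2)
        assert np.allclose(div[..., 0][inner], 3 * X[inner], rtol=1e-10)
        assert np.allclose(div[..., 1][inner], 3 * Y[inner], rtol=1e-10)


class TestDriftCases:
    def test_casei_equals_transition_mean_velocity(self, psi, tilted_fields):
        d, fib, S = tilted_fields
        dirs = kx.DirectionGrid(16)
        g = kx.SensingKernel("heaviside", 0.4)
        co = casei_drift("independent", fib, S, (g, g), psi, dirs)
        T = kx.transition_independent(fib, S, g, g, dirs)
        U = kx.transition_mean_velocity(T, psi)
        assert np.abs(co.drift - U).max() < 1e-12
        cod = casei_drift("dependent", fib, S, g, psi, dirs)
        Td = kx.transition_dependent(fib, S, g, dirs)
        assert np.abs(cod.drift - kx.transition_mean_velocity(Td, psi)).max() \
            < 1e-12

    def test_casei_homogeneous_cues_zero_drift_interior(self, psi):
        d = kx.Domain2D(nx=32, ny=32)
        S = kx.constant_chemoattractant(d, 1.0)
        fib = kx.uniform_fibers(d, 10.0, 0.7)
        dirs = kx.DirectionGrid(16)
        g = kx.SensingKernel("heaviside", 0.3)
        co = casei_drift("independent", fib, S, (g, g), psi, dirs)
        inner = interior(d, 0.35)
        assert np.abs(co.drift[inner]).max() < 1e-12

    @pytest.mark.parametrize("case_fn", [caseiii_drift, caseiv_drift])
    def test_dirac_kernels_make_models_coincide(self, psi, tilted_fields,
                                                case_fn):
        d, fib, S = tilted_fields
        dirs = kx.DirectionGrid(16)
        kern = kx.SensingKernel("dirac_at_R", 0.2)
        ci = case_fn("independent", fib, S, (kern, kern), psi, dirs)
        cd = case_fn("dependent", fib, S, kern, psi, dirs)
        scale = max(1.0, float(np.abs(ci.drift).max()))
        assert np.abs(ci.drift - cd.drift).max() / scale < 1e-12

    def test_caseiii_local_fiber_sensing_gives_parabolic_remark_form(self, psi):
        # q~ = q (symmetric): drift proportional to D_q grad S, diffusion kept
        d = kx.Domain2D(nx=24, ny=24)
        S = kx.linear_chemoattractant(d, 10.0)
        fib = kx.uniform_fibers(d, 5.0, np.pi / 2)
        dirs = kx.DirectionGrid(64)
        co = caseiii_drift("independent", fib, S,
                           (kx.SensingKernel("dirac_at_0", 0.2),
                            kx.SensingKernel("dirac_at_R", 0.2)), psi, dirs)
        assert co.diffusion is not None
        Dq = kx.fiber_diffusion_tensor(fib, 2.5, 2.5)
        gS = np.array([0.0, 10.0])
        expected = psi.Ubar * 0.2 * (Dq @ gS) / S.values[12, 12]
        assert np.allclose(co.drift[12, 12], expected, rtol=1e-4)

    def test_caseiii_homogeneous_fibers_only_gradS_term(self, psi):
        d = kx.Domain2D(nx=24, ny=24)
        S = kx.gaussian_chemoattractant(d, 10.0, 1.0, (4.0, 4.0))
        fib = kx.uniform_fibers(d, 8.0, np.pi / 4)
        dirs = kx.DirectionGrid(64)
        g = kx.SensingKernel("dirac_at_0", 0.2)
        co = caseiii_drift("independent", fib, S,
                           (g, kx.SensingKernel("heaviside", 0.2)), psi, dirs)
        # E_q~ = 0 so the drift is a pure projection of grad S
        gx, gy = S.gradient_grid()
        Dq = kx.fiber_diffusion_tensor(fib, 2.5, 2.5)
        g12 = np.array([gx[12, 12], gy[12, 12]])
        drift_dir = co.drift[12, 12] / np.linalg.norm(co.drift[12, 12])
        exp_dir = (Dq @ g12) / np.linalg.norm(Dq @ g12)
        assert np.allclose(drift_dir, exp_dir, atol=1e-6)

    def test_caseiv_local_chemo_homogeneous_fibers_zero_drift(self, psi):
        # reduces to a fully anisotropic diffusive equation: no drift
        d = kx.Domain2D(nx=24, ny=24)
        S = kx.gaussian_chemoattractant(d, 10.0, 0.3, (4.0, 4.0))
        fib = kx.uniform_fibers(d, 20.0, np.pi / 3)
        dirs = kx.DirectionGrid(32)
        co = caseiv_drift("independent", fib, S,
                          (kx.SensingKernel("heaviside", 0.2),
                           kx.SensingKernel("dirac_at_0", 0.2)), psi, dirs)
        assert np.abs(co.drift).max() < 1e-10

    def test_casei_chemoattractant_pull_direction(self, psi):
        # chemoattractant in the upper-right corner: drift points there
        d = kx.Domain2D(nx=32, ny=32)
        S = kx.gaussian_chemoattractant(d, 10.0, 0.05, (4.5, 4.5))
        fib = kx.gaussian_alignment_map(d, 100.0, 0.15, (2.5, 2.5),
                                        3 * np.pi / 4)
        dirs = kx.DirectionGrid(32)
        g = kx.SensingKernel("heaviside", 0.7)
        co = casei_drift("independent", fib, S, (g, g), psi, dirs)
        i = np.argmin(np.abs(d.x_nodes - 1.5))
        drift = co.drift[i, i]
        assert drift[0] > 0 and drift[1] > 0


class TestLimitSolvers:
    def test_heat_equation_variance_growth(self, psi):
        d = kx.Domain2D(nx=64, ny=64)
        S = kx.constant_chemoattractant(d, 1.0)
        fib = kx.uniform_fibers(d, 0.0)
        g = kx.SensingKernel("dirac_at_0", 0.1)
        mu = 1.0
        co = caseii_coeffs("independent", fib, S, (g, g), psi, mu=mu)
        X, Y = d.mesh()
        rho0 = np.exp(-((X - 2.5) ** 2 + (Y - 2.5) ** 2) / 0.1)
        dt = 0.2 * d.dx**2 / (psi.D * 0.5 / mu)
        states = drift_diffusion_solve(co, rho0, dt, 2.0)
        def var_x(r):
            m = r.sum()
            mx = (r * X).sum() / m
            return ((X - mx) ** 2 * r).sum() / m
        growth = (var_x(states[-1].rho) - var_x(states[0].rho)) / 2.0
        # analytic isotropic diffusion: dVar_x/dt = 2 D_c = D / mu
        assert growth == pytest.approx(psi.D / mu, rel=0.02)

    def test_drift_diffusion_mass_conserved(self, psi, tilted_fields):
        d, fib, S = tilted_fields
        g = kx.SensingKernel("heaviside", 0.1)
        co = caseii_coeffs("independent", fib, S, (g, g), psi)
        X, Y = d.mesh()
        rho0 = np.exp(-((X - 2.5) ** 2 + (Y - 2.5) ** 2) / 0.3)
        dt = 0.1 * d.dx**2 / np.abs(co.diffusion).max()
        states = drift_diffusion_solve(co, rho0, dt, 0.5)
        assert states[-1].total_mass() == pytest.approx(
            states[0].total_mass(), rel=1e-12)

    def test_double_divergence_not_fickian(self, psi):
        """The diffusion operator must act on the tensor inside both
        derivatives: for constant rho the right-hand side is the double
        divergence of D Dq itself, whereas the Fickian form would vanish."""
        d = kx.Domain2D(nx=48, ny=48)
        S = kx.constant_chemoattractant(d, 1.0)
        X, Y = d.mesh()
        # smoothly varying concentration map -> spatially varying Dq
        fib = kx.FiberField(d, 3.0 + np.sin(2 * np.pi * X / 5), 0.0)
        g = kx.SensingKernel("dirac_at_0", 0.1)
        co = caseii_coeffs("independent", fib, S, (g, g), psi, mu=1.0)
        rho0 = np.ones((48, 48))
        dt = 0.05 * d.dx**2 / np.abs(co.diffusion).max()
        states = drift_diffusion_solve(co, rho0, dt, dt)
        rhs = (states[-1].rho - rho0) / dt + 0.0
        # Fickian mis-implementation would give rhs = 0 for constant rho;
        # the double divergence gives d2/dx2 of (D Dq_xx) (up to drift part)
        from kinetaxis.macrolimits import tensor_divergence, _advective_fluxes
        G = co.diffusion / 1.0  # D Dq, rho = 1
        F = tensor_divergence(G, d)
        expected = (np.gradient(F[..., 0], d.dx, axis=0)
                    + np.gradient(F[..., 1], d.dy, axis=1))
        # drift term for constant rho: -div(U rho) = -div U
        U = co.drift
        expected -= (np.gradient(U[..., 0], d.dx, axis=0)
                     + np.gradient(U[..., 1], d.dy, axis=1))
        inner = interior(d, 0.3)
        assert np.abs(expected[inner]).max() > 1e-3  # genuinely non-zero
        assert np.allclose(rhs[inner], expected[inner],
                           atol=0.05 * np.abs(expected[inner]).max())

    def test_advection_zero_drift_keeps_rho(self, psi, tilted_fields):
        d, fib, S = tilted_fields
        co = casei_drift("independent", fib, S,
                         (kx.SensingKernel("heaviside", 0.3),) * 2, psi,
                         kx.DirectionGrid(16))
        co.drift[:] = 0.0
        X, Y = d.mesh()
        rho0 = np.exp(-((X - 2.5) ** 2 + (Y - 2.5) ** 2) / 0.3)
        states = advection_solve(co, rho0, 0.01, 0.2)
        assert np.array_equal(states[-1].rho, rho0)

    def test_periodic_translation_against_analytic(self, psi):
        d = kx.Domain2D(nx=128, ny=16)
        co = kx.MacroCoefficients(case="i", model="independent", domain=d,
                                  drift=np.tile(np.array([0.5, 0.0]),
                                                (128, 16, 1)))
        X, Y = d.mesh()
        rho0 = 1.0 + np.cos(2 * np.pi * (X - 2.5) / 5)
        dt = 0.5 * d.dx / 0.5
        states = advection_solve(co, rho0, dt, 2.0, periodic=True)
        shift = 0.5 * states[-1].t
        expected = 1.0 + np.cos(2 * np.pi * (X - shift - 2.5) / 5)
        err = np.abs(states[-1].rho - expected).max() / 2.0
        assert err < 0.15  # first-order upwind on a smooth profile

    def test_advection_mass_conserved_with_walls(self, psi, tilted_fields):
        d, fib, S = tilted_fields
        dirs = kx.DirectionGrid(16)
        g = kx.SensingKernel("heaviside", 0.3)
        co = casei_drift("independent", fib, S, (g, g), psi, dirs)
        X, Y = d.mesh()
        rho0 = np.exp(-((X - 2.5) ** 2 + (Y - 2.5) ** 2) / 0.3)
        umax = np.abs(co.drift).max()
        states = advection_solve(co, rho0, 0.4 * d.dx / umax, 3.0)
        assert states[-1].total_mass() == pytest.approx(
            states[0].total_mass(), rel=1e-12)
        assert states[-1].rho.min() >= 0

    def test_stationary_state_peaks_at_chemoattractant(self, psi):
        # drift balancing diffusion concentrates mass at the S maximum
        d = kx.Domain2D(nx=32, ny=32)
        S = kx.gaussian_chemoattractant(d, 10.0, 0.8, (2.5, 2.5))
        fib = kx.uniform_fibers(d, 0.0)
        g = kx.SensingKernel("heaviside", 0.3)
        co = caseii_coeffs("independent", fib, S, (g, g), psi, mu=8.0)
        X, Y = d.mesh()
        rho0 = np.full((32, 32), 0.1)
        dt = 0.2 * d.dx**2 / (np.abs(co.diffusion).max() / 8.0)
        states = drift_diffusion_solve(co, rho0, dt, 60.0)
        i, j = np.unravel_index(np.argmax(states[-1].rho), (32, 32))
        peak = np.array([d.x_nodes[i], d.y_nodes[j]])
        assert np.linalg.norm(peak - np.array([2.5, 2.5])) < 3 * d.dx

    def test_diffusive_cfl_guard(self, psi, tilted_fields):
        d, fib, S = tilted_fields
        g = kx.SensingKernel("heaviside", 0.1)
        co = caseii_coeffs("independent", fib, S, (g, g), psi)
        with pytest.raises(ConfigurationError):
            drift_diffusion_solve(co, np.ones((24, 24)), 10.0, 20.0)
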