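from types import SimpleNamespace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import plaqstab as p
from plaqstab.discretization import (
    _boundary_divergence,
    _grad_tau,
    linear_operator,
)
from plaqstab.errors import ConfigurationError
from plaqstab.geometry import area_weights
from plaqstab.model import homogeneous_rhs
from plaqstab.sampling import sample_model
from plaqstab.stability import reaction_matrix


def pure_diffusion_params(D=1.0):
    """Duck-typed zero-rate parameter object for conservation checks.

    ModelParameters itself requires strictly positive rates, so the pure
    diffusion limit is exercised through an equivalent lightweight object.
    """

    class _ZeroResponse:
        def __call__(self, L):
            z = np.zeros_like(np.asarray(L, dtype=float))
            return z, z

    return SimpleNamespace(D_L=D, D_M=D, mu=0.0, k_L=0.0, k_M=0.0, k_N=0.0,
                           L0=0.0, response=_ZeroResponse())


class TestLaplacian:
    def test_annihilates_constants(self, grid24):
        lap = p.laplacian(np.full(grid24.shape, 3.7), grid24)
        assert np.abs(lap[1:-1]).max() < 1e-12

    def test_exact_on_tau_squared(self, grid24):
        f = np.broadcast_to(grid24.tau_values[:, None] ** 2, grid24.shape).copy()
        lap = p.laplacian(f, grid24)
        expected = 2.0 / grid24.h**2
        np.testing.assert_allclose(lap[1:-1], expected[1:-1], rtol=1e-11)

    def test_cos_sigma_stencil_identity(self, grid24):
        f = np.broadcast_to(np.cos(grid24.sigma_values)[None, :], grid24.shape).copy()
        lap = p.laplacian(f, grid24)
        factor = (2 * np.cos(grid24.dsigma) - 2) / (grid24.dsigma**2 * grid24.h**2)
        np.testing.assert_allclose(lap[1:-1], (f * factor)[1:-1], rtol=1e-10, atol=1e-12)

    def test_shape_mismatch(self, grid24):
        with pytest.raises(ConfigurationError):
            p.laplacian(np.zeros((3, 3)), grid24)

    def test_second_order_convergence(self):
        def max_err(mn):
            g = p.make_grid(1.0, 2.0, mn, mn, 1.0)
            f = np.sin(g.tau_values)[:, None] * np.cos(g.sigma_values)[None, :]
            exact = -2.0 * f / g.h**2
            return np.abs(p.laplacian(f, g) - exact)[1:-1].max()

        e1, e2 = max_err(32), max_err(64)
        order = np.log2(e1 / e2)
        assert 1.8 <= order <= 2.2


class TestGradientDot:
    def test_constant_second_field(self, grid24):
        A = np.random.default_rng(0).standard_normal(grid24.shape)
        out = p.gradient_dot(A, np.full(grid24.shape, 2.0), grid24)
        assert np.abs(out).max() == 0.0

    def test_self_product_nonnegative(self, grid24):
        A = np.random.default_rng(1).standard_normal(grid24.shape)
        out = p.gradient_dot(A, A, grid24)
        assert np.all(out[1:-1] >= 0)

    def test_tau_field(self, grid24):
        f = np.broadcast_to(grid24.tau_values[:, None], grid24.shape).copy()
        out = p.gradient_dot(f, f, grid24)
        np.testing.assert_allclose(out[1:-1], 1.0 / grid24.h[1:-1] ** 2, rtol=1e-12)


class TestRhsNonlinear:
    def test_equilibrium_stationary(self, grid24, logistic_model):
        eq = p.compute_equilibrium(logistic_model)
        st = p.StateField.uniform(grid24, (eq.L_e, eq.M_e, eq.N_e), "nonlinear")
        d = p.rhs_nonlinear(st, logistic_model)
        assert max(np.abs(d.L).max(), np.abs(d.M).max(), np.abs(d.N).max()) < 1e-10

    def test_homogeneous_reduction(self, grid24, logistic_model):
        eq = p.compute_equilibrium(logistic_model)
        st = p.StateField.uniform(grid24, (2 * eq.L_e, eq.M_e, eq.N_e), "nonlinear")
        d = p.rhs_nonlinear(st, logistic_model)
        expected = homogeneous_rhs(logistic_model, 2 * eq.L_e, eq.M_e, eq.N_e)
        for arr, val in zip((d.L, d.M, d.N), expected):
            assert np.abs(arr - val).max() < 1e-10  # identical across grid points

    def test_pure_diffusion_mass_conservation(self):
        g = p.make_grid(1.0, 2.0, 64, 64, 1.0)
        s = g.tau_values - 1.0
        bump = 1.0 + 0.3 * np.cos(np.pi * s)[:, None] * np.ones(g.n)[None, :]
        st = p.StateField(grid=g, mode="nonlinear", L=bump, M=bump.copy(),
                          N=np.ones(g.shape))
        d = p.rhs_nonlinear(st, pure_diffusion_params())
        w = area_weights(g)
        drift = abs(np.sum(d.L * w))
        assert drift < 1e-6 * np.sum(st.L * w)

    def test_mode_check(self, grid24, logistic_model):
        st = p.StateField.uniform(grid24, (0, 0, 0), "linearized")
        with pytest.raises(ConfigurationError):
            p.rhs_nonlinear(st, logistic_model)


class TestRhsLinearized:
    def test_uniform_reduces_to_reaction_matrix(self, grid24, logistic_eq_lc):
        _, lc = logistic_eq_lc
        v = np.array([0.3, -0.2, 0.5])
        st = p.StateField.uniform(grid24, v, "linearized")
        d = p.rhs_linearized(st, lc)
        expected = reaction_matrix(lc) @ v
        for arr, val in zip((d.a, d.b, d.c), expected):
            np.testing.assert_allclose(arr, val, rtol=1e-12, atol=1e-13)

    def test_zero_a_decouples_b(self, grid24, logistic_eq_lc):
        _, lc = logistic_eq_lc
        rngf = np.random.default_rng(4)
        b = rngf.standard_normal(grid24.shape)
        st = p.StateField(grid=grid24, mode="linearized",
                          L=np.zeros(grid24.shape), M=b, N=np.zeros(grid24.shape))
        d = p.rhs_linearized(st, lc)
        # with a == 0 the b-equation keeps only diffusion and -k4 b
        from plaqstab.discretization import _apply_diffusion
        expected = lc.D_b * _apply_diffusion(b, grid24, "faithful") - lc.k4 * b
        np.testing.assert_allclose(d.b, expected, rtol=1e-12, atol=1e-13)

    @pytest.mark.parametrize("mn", [10, 16, 24])
    def test_frechet_derivative_oracle(self, mn, rng):
        params = sample_model(rng)
        eq = p.compute_equilibrium(params)
        lc = p.linearize(params, eq)
        g = p.make_grid(1.0, 2.0, mn, mn, 1.0)
        pert = p.make_perturbation(
            p.PerturbationSpec(amplitude=1.0, pattern="random", seed=5), g
        )
        lin = p.rhs_linearized(pert, lc)
        errs = []
        for eps in (1e-4, 1e-5):
            st = p.StateField(grid=g, mode="nonlinear",
                              L=eq.L_e + eps * pert.a, M=eq.M_e + eps * pert.b,
                              N=eq.N_e + eps * pert.c)
            dn = p.rhs_nonlinear(st, params)
            errs.append(max(
                np.abs(dn.L / eps - lin.a).max(),
                np.abs(dn.M / eps - lin.b).max(),
                np.abs(dn.N / eps - lin.c).max(),
            ))
        assert errs[0] < 1.0  # O(eps) at eps = 1e-4 for O(1) coefficients
        assert errs[1] < 0.2 * errs[0]  # first-order reduction in eps


class TestBoundary:
    def test_no_flux_rows_identically_zero(self, grid24):
        f = np.random.default_rng(2).standard_normal(grid24.shape)
        F = _grad_tau(f, grid24)
        assert np.all(F[0] == 0.0) and np.all(F[-1] == 0.0)

    def test_boundary_rhs_zero_at_equilibrium(self, grid24, logistic_model):
        eq = p.compute_equilibrium(logistic_model)
        st = p.StateField.uniform(grid24, (eq.L_e, eq.M_e, eq.N_e), "nonlinear")
        rows_L, rows_M, rows_N = p.boundary_rhs(st, logistic_model)
        for rows in (rows_L, rows_M, rows_N):
            assert np.abs(rows).max() < 1e-10

    def test_one_sided_stencil_exact_on_quadratic_flux(self, grid_small):
        g = grid_small
        t = g.tau_values
        F = ((t - 1.0) * (2.0 - t))[:, None] * np.ones(g.n)[None, :]
        G = np.zeros(g.shape)
        r0, rm = _boundary_divergence(F, G, g, "faithful")
        # d/dtau [(t-1)(2-t)] = 3 - 2t: slope 1 at tau=1 and -1 at tau=2
        np.testing.assert_allclose(r0, 1.0 / g.h[0], rtol=1e-12)
        np.testing.assert_allclose(rm, -1.0 / g.h[-1], rtol=1e-12)

    def test_boundary_mass_drift_shrinks_under_refinement(self):
        drifts = []
        for mn in (32, 64):
            g = p.make_grid(1.0, 2.0, mn, mn, 1.0)
            bump = 1.0 + 0.3 * np.cos(np.pi * (g.tau_values - 1.0))[:, None] \
                * np.ones(g.n)[None, :]
            st = p.StateField(grid=g, mode="nonlinear", L=bump, M=bump.copy(),
                              N=np.ones(g.shape))
            d = p.rhs_nonlinear(st, pure_diffusion_params())
            drifts.append(abs(np.sum(d.L * area_weights(g))))
        assert drifts[1] < drifts[0]

    def test_curvilinear_mode_exactly_conservative(self):
        g = p.make_grid(1.0, 2.0, 32, 32, 1.0)
        bump = 1.0 + 0.3 * np.cos(np.pi * (g.tau_values - 1.0))[:, None] \
            * np.ones(g.n)[None, :]
        st = p.StateField(grid=g, mode="nonlinear", L=bump, M=bump.copy(),
                          N=np.ones(g.shape))
        d = p.rhs_nonlinear(st, pure_diffusion_params(), divergence="curvilinear")
        drift = abs(np.sum(d.L * area_weights(g)))
        assert drift < 1e-12 * np.sum(st.L * area_weights(g))


class TestLinearOperator:
    @pytest.mark.parametrize("divergence", ["faithful", "curvilinear"])
    def test_matches_rhs_linearized(self, grid_small, logistic_eq_lc, divergence):
        _, lc = logistic_eq_lc
        A = linear_operator(lc, grid_small, divergence)
        st = p.make_perturbation(
            p.PerturbationSpec(amplitude=1.0, pattern="random", seed=9), grid_small
        )
        direct = p.rhs_linearized(st, lc, divergence).to_vector()
        np.testing.assert_allclose(A @ st.to_vector(), direct, rtol=1e-12, atol=1e-13)


class TestIntegrate:
    def test_homogeneous_ode_oracle(self, logistic_model):
        g = p.make_grid(1.0, 2.0, 12, 12, 1.0)
        eq = p.compute_equilibrium(logistic_model)
        y0 = (1.3 * eq.L_e, 0.8 * eq.M_e, 1.1 * eq.N_e)
        st = p.StateField.uniform(g, y0, "nonlinear")
        times = np.linspace(0.0, 5.0, 6)
        traj = p.integrate(st, logistic_model, 5.0, times)
        ode = solve_ivp(
            lambda t, y: homogeneous_rhs(logistic_model, *y), (0, 5.0), y0,
            t_eval=times, rtol=1e-10, atol=1e-12,
        )
        for k in range(len(times)):
            pde = np.array([traj[k].L.mean(), traj[k].M.mean(), traj[k].N.mean()])
            np.testing.assert_allclose(pde, ode.y[:, k], atol=1e-6)

    def test_zero_initial_linearized_stays_zero(self, grid_small, logistic_eq_lc):
        _, lc = logistic_eq_lc
        st = p.StateField.uniform(grid_small, (0, 0, 0), "linearized")
        traj = p.integrate(st, lc, 1.0, np.linspace(0, 1, 3))
        for s in traj.states:
            assert np.abs(s.to_vector()).max() == 0.0

    def test_discrete_dispersion_relation(self):
        # near-constant scale factor (large tau) so a sigma Fourier mode is
        # close to an eigenfunction of the discrete operator
        g = p.make_grid(5.0, 5.05, 8, 24, 1.0)
        lc = p.LinearCoefficients(k1=0.7, k2=0.0, k3=0.0, k4=1.0, k5=1.0, k6=0.0,
                                  chi_a=0.0, D_a=1.0, D_b=1.0, fprime_at_Le=1.0)
        k = 3
        spec = p.PerturbationSpec(amplitude=1e-3, pattern="fourier", k_tau=0,
                                  k_sigma=k, species_mask=(True, False, False))
        pert = p.make_perturbation(spec, g)
        hbar = g.h.mean()
        k2_disc = (2 - 2 * np.cos(k * g.dsigma)) / (g.dsigma**2 * hbar**2)
        rate_pred = lc.k1 + lc.D_a * k2_disc
        t_end = 1.0 / rate_pred
        traj = p.integrate(pert, lc, t_end, np.linspace(0, t_end, 5),
                           rtol=1e-8, atol=1e-14)
        I = [p.energy_integral(s, None, g) for s in traj.states]
        rate_obs = -0.5 * np.log(I[-1] / I[0]) / t_end
        assert rate_obs == pytest.approx(rate_pred, rel=0.1)

    def test_deterministic(self, grid_small, logistic_eq_lc):
        _, lc = logistic_eq_lc
        spec = p.PerturbationSpec(amplitude=0.01, pattern="random", seed=11)
        st = p.make_perturbation(spec, grid_small)
        t1 = p.integrate(st, lc, 2.0, np.linspace(0, 2, 5))
        t2 = p.integrate(st, lc, 2.0, np.linspace(0, 2, 5))
        for s1, s2 in zip(t1.states, t2.states):
            np.testing.assert_array_equal(s1.to_vector(), s2.to_vector())

    def test_expm_matches_bdf_on_tiny_grid(self, logistic_eq_lc):
        _, lc = logistic_eq_lc
        g = p.make_grid(1.0, 2.0, 5, 6, 1.0)
        st = p.make_perturbation(
            p.PerturbationSpec(amplitude=0.01, pattern="fourier", k_sigma=1), g
        )
        times = np.linspace(0, 1.0, 3)
        tb = p.integrate(st, lc, 1.0, times, rtol=1e-10, atol=1e-13)
        te = p.integrate(st, lc, 1.0, times, method="expm")
        for sb, se in zip(tb.states, te.states):
            np.testing.assert_allclose(sb.to_vector(), se.to_vector(), atol=1e-8)

    def test_invalid_inputs(self, grid_small, logistic_model, logistic_eq_lc):
        _, lc = logistic_eq_lc
        st = p.StateField.uniform(grid_small, (1, 1, 1), "nonlinear")
        with pytest.raises(ConfigurationError):
            p.integrate(st, logistic_model, -1.0)
        with pytest.raises(ConfigurationError):
            p.integrate(st, logistic_model, 1.0, [0.0, 2.0])  # beyond t_end
        neg = p.StateField.uniform(grid_small, (-1, 1, 1), "nonlinear")
        with pytest.raises(ConfigurationError):
            p.integrate(neg, logistic_model, 1.0)
        lin = p.StateField.uniform(grid_small, (0, 0, 0), "nonlinear")
        with pytest.raises(ConfigurationError):
            p.integrate(lin, logistic_model, 1.0, method="expm")
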