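"""Semi-implicit time integration: fixed points, conservation, bounds,
porous-medium benchmark, and parameter continuity."""

import numpy as np
import pytest

import qsbiofilm as qb
from qsbiofilm.params import ModelParameters
from qsbiofilm.stepping import PreconCache, StepFluxes

from conftest import quick_settings


def _diffusion_only_params(**kw):
    """All reactions off; only transport remains."""
    base = dict(mu=0.0, k4=0.0, eta1=0.0, alpha=0.0, beta=0.0, C_inf=0.0)
    base.update(kw)
    return ModelParameters(**base)


class TestFixedPointsAndConservation:
    def test_sterile_state_is_a_fixed_point(self, params, small_grid):
        state = qb.StateFields.uniform(small_grid, C=params.C_inf)
        s = quick_settings(t_end=0.005)
        res = qb.run(state, small_grid, params, s)
        f = res.final_state
        assert np.all(f.M == 0) and np.all(f.N == 0) and np.all(f.A == 0)
        assert np.allclose(f.C, params.C_inf, rtol=1e-12)

    def test_pure_biomass_diffusion_conserves_mass(self, small_grid):
        p = _diffusion_only_params(delta=1e-9)
        rng = np.random.default_rng(3)
        M = rng.uniform(0.0, 0.6, small_grid.shape)
        state = qb.StateFields(t=0.0, M=M, N=np.zeros(small_grid.shape),
                               C=np.zeros(small_grid.shape), A=np.zeros(small_grid.shape))
        s = quick_settings(t_end=0.01, solver_tol=1e-12)
        res = qb.run(state, small_grid, p, s)
        m0 = small_grid.integrate(M)
        m1 = small_grid.integrate(res.final_state.M)
        assert m1 == pytest.approx(m0, rel=1e-10)

    def test_t_end_zero_gives_single_initial_record(self, params, small_grid, seeded_state):
        s = quick_settings(t_end=0.0)
        res = qb.run(seeded_state, small_grid, params, s)
        assert len(res.timeseries) == 1
        assert res.timeseries["t"][0] == 0.0

    def test_target_size_terminates_run_early(self, small_grid):
        p = qb.default_parameters(alpha=0.0, beta=0.0)  # uninhibited growth
        state = qb.generate_inoculum(qb.InoculumSpec(n_colonies=3, seed=2),
                                     small_grid, p)
        s = quick_settings(t_end=5.0, target_size=0.05, output_every=0.01)
        res = qb.run(state, small_grid, p, s)
        assert res.terminated_by == "target_size"
        assert res.final_state.t < 5.0
        assert res.timeseries["omega"][-1] >= 0.05

    def test_global_balance_closes_over_a_reacting_run(self, small_grid):
        p = qb.default_parameters(tau=10.0, eta1=3.6)
        spec = qb.InoculumSpec(n_colonies=2, seed=5)
        state = qb.generate_inoculum(spec, small_grid, p)
        s = quick_settings(t_end=0.5, output_every=0.1)
        res = qb.run(state, small_grid, p, s)
        assert qb.mass_balance_residual(res.timeseries) < 1e-8


class TestBoundsPreservation:
    def test_bounds_hold_every_step(self, small_grid):
        p = qb.default_parameters(tau=5.0, eta1=3.6)  # low threshold: dispersal active
        state = qb.generate_inoculum(qb.InoculumSpec(n_colonies=3, seed=2),
                                     small_grid, p)
        s = quick_settings()
        cache = PreconCache()
        for _ in range(60):
            state, _, _ = qb.step(state, small_grid, p, s, cache=cache)
            assert state.M.min() >= 0.0 and state.M.max() < 1.0
            assert state.N.min() >= 0.0
            assert state.A.min() >= 0.0
            assert state.C.min() >= 0.0 and state.C.max() <= p.C_inf + 1e-12

    def test_no_qs_control_keeps_A_zero_and_grows_monotonically(self, small_grid):
        p = qb.default_parameters(alpha=0.0, beta=0.0, eta1=3.6)
        state = qb.generate_inoculum(qb.InoculumSpec(n_colonies=3, seed=2),
                                     small_grid, p)
        s = quick_settings(t_end=0.3, output_every=0.05)
        res = qb.run(state, small_grid, p, s)
        assert np.all(res.final_state.A == 0)
        M_tot = res.timeseries["M_tot"]
        assert np.all(np.diff(M_tot) > 0)  # growth exceeds lysis, no dispersal


class TestParameterContinuity:
    def test_eta1_to_zero_recovers_no_dispersal_run(self, small_grid):
        spec = qb.InoculumSpec(n_colonies=2, seed=9)
        s = quick_settings(t_end=0.05)
        finals = []
        for eta1 in (0.0, 1e-7):
            p = qb.default_parameters(tau=10.0, eta1=eta1)
            state = qb.generate_inoculum(spec, small_grid, p)
            finals.append(qb.run(state, small_grid, p, s).final_state)
        for name in ("M", "N", "C", "A"):
            a, b = getattr(finals[0], name), getattr(finals[1], name)
            assert np.allclose(a, b, rtol=1e-5, atol=1e-10), name

    def test_dt_refinement_consistency(self, small_grid):
        spec = qb.InoculumSpec(n_colonies=2, seed=9)
        p = qb.default_parameters(tau=10.0, eta1=3.6)
        M_tots = []
        for dt in (2e-3, 1e-3):
            state = qb.generate_inoculum(spec, small_grid, p)
            s = quick_settings(t_end=0.2, dt=dt, output_every=0.2)
            res = qb.run(state, small_grid, p, s)
            M_tots.append(res.timeseries["M_tot"][-1])
        assert M_tots[0] == pytest.approx(M_tots[1], rel=2e-2)


def barenblatt(x, s, m, total_scale_C):
    """Source solution of du/ds = d2(u^m)/dx2 in 1D:
    u = s^(-alpha) (C - k xi^2)_+^(1/(m-1)), xi = x s^(-alpha), alpha = 1/(m+1)."""
    alpha = 1.0 / (m + 1)
    k = (m - 1) / (2.0 * m * (m + 1))
    xi = x * s ** (-alpha)
    core = np.maximum(total_scale_C - k * xi**2, 0.0)
    return s ** (-alpha) * core ** (1.0 / (m - 1))


class TestPorousMediumBenchmark:
    """Degenerate-diffusion-only biomass equation against the self-similar
    closed form of the porous medium equation."""

    def test_barenblatt_interface_and_profile(self):
        a, delta = 4.0, 1.0
        m = a + 1.0                      # d u/dt = (delta/m) d2(u^m)/dx2
        A0, r0, x0 = 0.6, 0.15, 0.5      # initial amplitude, radius, center
        k = (m - 1) / (2 * m * (m + 1))
        s0 = k * r0**2 / A0**4           # Barenblatt time of that profile
        Cb = A0**4 * s0 ** (2.0 / (m + 1))
        lam = 4.0
        s1 = lam * s0
        t_phys = m * (s1 - s0) / delta   # physical horizon in solver time

        nx, ny = 256, 8
        p = _diffusion_only_params(delta=delta, a=a, b=0.0, L=1.0, H=0.1)
        grid = qb.Grid(nx=nx, ny=ny, L=p.L, H=p.H)
        u0 = barenblatt(grid.xc - x0, s0, m, Cb)
        M = np.tile(u0, (ny, 1))
        state = qb.StateFields(t=0.0, M=M, N=np.zeros(grid.shape),
                               C=np.zeros(grid.shape), A=np.zeros(grid.shape))
        n_steps = 200
        s = quick_settings(nx=nx, ny=ny, dt=t_phys / n_steps, t_end=t_phys,
                           output_every=t_phys, solver_tol=1e-12)
        res = qb.run(state, grid, p, s)
        u = res.final_state.M[0, :]
        exact = barenblatt(grid.xc - x0, s1, m, Cb)

        # interface: u^(m-1) is asymptotically linear at the front; extrapolate
        v = u ** (m - 1)
        idx = np.nonzero(u > 1e-4 * A0)[0]
        i = idx[-1]
        x_front = grid.xc[i] + grid.hx * v[i] / (v[i - 1] - v[i])
        r_exact = np.sqrt(Cb / k) * s1 ** (1.0 / (m + 1))
        assert abs((x_front - x0) - r_exact) / r_exact < 0.02

        # profile in L1, relative to total mass
        l1 = np.abs(u - exact).sum() / exact.sum()
        assert l1 < 0.02

        # mass conservation along the way
        assert grid.integrate(res.final_state.M) == pytest.approx(
            grid.integrate(M), rel=1e-10)


class TestStepFluxes:
    def test_accumulation(self):
        a = StepFluxes(production_M=1.0, growth_MN=2.0)
        a += StepFluxes(production_M=0.5, lysis_MN=0.25)
        assert a.production_M == 1.5 and a.growth_MN == 2.0 and a.lysis_MN == 0.25
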