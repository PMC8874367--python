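"""Mixture-flow solver: constitutive laws, benchmarks and conservation."""

import numpy as np
import pytest

from tests.conftest import duct_grid

from ngc_elute.geometry import GeometrySpec, ReleaseSystemSpec, build_relay_ngc, place_release_system
from ngc_elute.mixture_solver import (
    GDNF,
    INTERSTITIAL_FLUID,
    MixtureSolver,
    MixtureState,
    SolverConfig,
    SolverError,
    advect_alpha,
    drift_velocity,
    mixture_density,
    mixture_viscosity,
    run_case,
)
from ngc_elute.release_model import ReleaseSchedule, modified_profile, schedule_constant_time


class TestMixtureProperties:
    @pytest.mark.parametrize(
        "alpha,rho,mu",
        [(0.0, 1000.0, 0.0035), (1.0, 1370.0, 0.0015), (0.5, 1185.0, 0.0025)],
    )
    def test_weighted_laws(self, alpha, rho, mu):
        a = np.full((3, 3), alpha)
        assert mixture_density(a)[0, 0] == pytest.approx(rho)
        assert mixture_viscosity(a)[0, 0] == pytest.approx(mu)

    def test_out_of_range_alpha_rejected(self):
        with pytest.raises(SolverError):
            mixture_density(np.array([[1.2]]))
        with pytest.raises(SolverError):
            mixture_viscosity(np.array([[-0.1]]))


class TestDriftVelocity:
    def _state(self):
        u = np.full((4, 6), 1e-6)
        v = np.zeros((5, 5))
        return MixtureState(u=u, v=v, p=np.zeros((4, 5)), alpha=np.zeros((4, 5)))

    def test_zero_slip_closure(self):
        udr, vdr = drift_velocity(self._state(), config=SolverConfig(drift_closure="zero_slip"))
        assert not udr.any() and not vdr.any()

    def test_equal_densities_no_slip(self):
        phases = (INTERSTITIAL_FLUID, type(GDNF)("matched", 1000.0, 0.0015))
        cfg = SolverConfig(drift_closure="algebraic_slip", gravity=(0.0, -9.81))
        udr, vdr = drift_velocity(self._state(), phases, cfg)
        assert np.allclose(udr, 0) and np.allclose(vdr, 0)

    def test_magnitude_bounded_by_closure(self):
        cfg = SolverConfig(drift_closure="algebraic_slip", gravity=(0.0, -9.81))
        udr, vdr = drift_velocity(self._state(), (INTERSTITIAL_FLUID, GDNF), cfg)
        tau = GDNF.density * cfg.drift_particle_diameter**2 / (18 * INTERSTITIAL_FLUID.viscosity)
        bound = tau * (GDNF.density - 1000.0) / GDNF.density * 9.81
        assert np.abs(vdr).max() <= bound * (1 + 1e-12)


def _quiet_schedule(total=25.0):
    return ReleaseSchedule(burst_time=5.0, continuous_time=total - 5.0, burst_speed=0.0, continuous_speed=0.0)


class TestAdvance:
    def test_zero_inflow_stays_at_rest(self, duct):
        cfg = SolverConfig(inlet1_speed=0.0)
        solver = MixtureSolver(duct, config=cfg)
        st = MixtureState.quiescent(duct)
        for _ in range(3):
            st = solver.advance(st, _quiet_schedule())
        assert np.abs(st.u).max() == 0.0
        assert np.abs(st.v).max() == 0.0
        assert st.alpha.max() == 0.0

    def test_step_beyond_schedule_rejected(self, duct):
        solver = MixtureSolver(duct, config=SolverConfig())
        st = MixtureState.quiescent(duct)
        st.t = 24.8
        with pytest.raises(ValueError):
            solver.advance(st, _quiet_schedule(25.0))

    def test_poiseuille_profile(self):
        """Developed duct flow matches the plane-Poiseuille parabola to 2 %."""
        grid = duct_grid(n_across=20, n_along=60, h=0.02)
        u0 = 1e-6
        solver = MixtureSolver(grid, config=SolverConfig(inlet1_speed=u0, quasi_steady=False))
        st = MixtureState.quiescent(grid)
        for _ in range(6):
            st = solver.advance(st, _quiet_schedule())
        H = 20 * grid.h * 1e-3
        y = (np.arange(20) + 0.5) * grid.h * 1e-3
        exact = 6.0 * u0 * y * (H - y) / H**2
        numeric = 0.5 * (st.u[2:22, 48] + st.u[2:22, 49])
        assert np.abs(numeric - exact).max() / exact.max() < 0.02

    def test_divergence_free_after_step(self, duct):
        cfg = SolverConfig(inlet1_speed=1e-6)
        solver = MixtureSolver(duct, config=cfg)
        st = MixtureState.quiescent(duct)
        for _ in range(3):
            st = solver.advance(st, _quiet_schedule())
        h = duct.h * 1e-3
        div = (st.u[:, 1:] - st.u[:, :-1] + st.v[1:, :] - st.v[:-1, :]) / h
        assert np.abs(div[duct.fluid]).max() < cfg.pressure_tolerance


class TestAlphaTransport:
    def test_constant_field_preserved_in_interior(self):
        # uniform alpha and uniform velocity: conservative advection leaves the
        # interior unchanged (only the inflow boundary sees the ambient value)
        alpha = np.full((10, 30), 0.4)
        u = np.full((10, 31), 1e-6)
        v = np.zeros((11, 30))
        dt, h = 0.5, 2e-5
        a_new, _, _ = advect_alpha(alpha, u, v, dt, h)
        assert np.allclose(a_new[:, 1:], 0.4)

    @pytest.mark.parametrize("scheme", ["first_order_upwind", "van_leer"])
    def test_square_patch_translates_at_flow_speed(self, scheme):
        """Center of mass of an advected patch tracks the prescribed velocity."""
        ny, nx, h = 20, 200, 2e-5
        dt = 0.5
        speed = 2e-5 * 0.5 / dt  # CFL = 0.5
        alpha = np.zeros((ny, nx))
        alpha[8:12, 10:20] = 1.0
        u = np.full((ny, nx + 1), speed)
        v = np.zeros((ny + 1, nx))
        x = np.arange(nx)
        com0 = (alpha.sum(axis=0) * x).sum() / alpha.sum()
        a = alpha
        for _ in range(100):
            a, _, _ = advect_alpha(a, u, v, dt, h, scheme=scheme)
        com = (a.sum(axis=0) * x).sum() / a.sum()
        expected = com0 + 100 * speed * dt / h
        assert abs(com - expected) <= 1.0  # within one cell
        assert a.min() >= -1e-12 and a.max() <= 1.0 + 1e-12

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            advect_alpha(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((3, 2)), 0.5, 1e-5, scheme="qck")


@pytest.fixture(scope="module")
def short_run():
    """Default single-layer system at h = 0.04 mm, 60 s of release."""
    grid = place_release_system(build_relay_ngc(GeometrySpec(), 0.04), ReleaseSystemSpec.single_layer())
    sched = schedule_constant_time(modified_profile())
    sched = ReleaseSchedule(
        burst_time=9.0,
        continuous_time=51.0,
        burst_speed=sched.burst_speed,
        continuous_speed=sched.continuous_speed,
    )
    return grid, run_case(grid, sched)


class TestRunCase:
    def test_alpha_bounded(self, short_run):
        _, run = short_run
        assert run.state.alpha.min() >= 0.0
        assert run.state.alpha.max() <= 1.0

    def test_gdnf_ledger_closes(self, short_run):
        # emitted - exited - stored vanishes to round-off (conservative fluxes)
        _, run = short_run
        assert run.conservation_error < 1e-10

    def test_emission_matches_schedule(self, short_run):
        grid, run = short_run
        led = run.ledger.iloc[-1]
        assert led.emitted > 0
        # burst phase (first 9 s) emits much faster than the continuous tail
        early = run.ledger.iloc[17].emitted / 9.0
        late = (led.emitted - run.ledger.iloc[17].emitted) / 51.0
        assert early > 10 * late

    def test_zero_release_stays_clean(self, duct):
        run = run_case(duct, _quiet_schedule(10.0))
        assert run.state.alpha.max() == 0.0
        assert run.ledger["emitted"].iloc[-1] == 0.0

    def test_quasi_steady_freeze_reduces_solves(self, short_run):
        _, run = short_run
        assert run.n_full_solves < len(run.ledger)  # velocity frozen mid-phase
        assert run.cfl_max < 1.0

    def test_mean_alpha_grid_convergence(self):
        """Domain-mean alpha moves < 10 % between h and h/2 on the default case."""
        from ngc_elute.study import build_manifest, run_single_case

        case = next(c for c in build_manifest("constant_time") if c.case_id == "a_single_default")
        coarse, _, _ = run_single_case(case, h=0.04)
        fine, _, _ = run_single_case(case, h=0.02)
        assert abs(coarse.mean_alpha - fine.mean_alpha) / fine.mean_alpha < 0.10
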