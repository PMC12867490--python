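import numpy as np
import pytest

import pwspdt as pw
import pwspdt.geometry as geometry
from pwspdt.reaction_transport import (
    MOL_PHOTONS_PER_JOULE,
    StateFields,
    TransportSolver,
    photon_molar_flux,
)


def closed_box_solver(model, params=None, **kwargs):
    """Solver with no Dirichlet boundaries, no flow, no infusion, no light."""
    params = params or pw.PhotochemParams(gamma1=0.0)
    boundary = pw.OxygenBoundary(surface_pO2=None)
    return TransportSolver(model, params, boundary, irradiance=0.0, **kwargs)


def box_model(n=8, h=10.0):
    cfg = pw.GeometryConfig(
        domain_size=(n * h, n * h, n * h), voxel_size=h, count=0, coarse_wall=True,
        layer_thicknesses=(10.0, 100.0, 100.0) if n * h > 210 else (10.0, 100.0, 100.0),
    )
    cfg2 = pw.GeometryConfig(
        domain_size=(n * h, n * h, max(n * h, 220.0)), voxel_size=h, count=0, coarse_wall=True
    )
    model = pw.build_tissue_model(cfg2)
    model.labels[:] = geometry.REGION_CODES["reticular_dermis"]
    return model


class TestHenryConversion:
    @pytest.mark.parametrize(
        "po2, expected", [(159.0, 0.232), (100.0, 0.146), (0.0, 0.0)]
    )
    def test_boundary_conversions(self, po2, expected):
        assert pw.henry_concentration(po2) == pytest.approx(expected, abs=5e-4)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            pw.henry_concentration(-1.0)


class TestRateLaws:
    params = pw.PhotochemParams(kappa=1.0)

    def test_dark_rate_is_zero(self):
        assert pw.ros_generation_rate(0.05, 0.1, 0.0, self.params) == 0.0

    def test_oxygen_saturation_limit(self):
        """Co ≫ β: the oxygen factor approaches one."""
        rate = pw.ros_generation_rate(0.05, 1e9, 100.0, self.params)
        full = 2.303 * self.params.epsilon_si * self.params.phi * 0.05 * photon_molar_flux(100.0)
        assert rate == pytest.approx(full, rel=1e-6)

    def test_low_oxygen_linear_slope(self):
        """Co ≪ β: rate is linear in Co with slope (full rate)/β."""
        co = 1e-6
        rate = pw.ros_generation_rate(0.05, co, 100.0, self.params)
        slope = rate / co
        expected = (
            2.303 * self.params.epsilon_si * self.params.phi * 0.05
            * photon_molar_flux(100.0) / self.params.beta
        )
        assert slope == pytest.approx(expected, rel=1e-3)

    def test_bleaching_zero_without_sensitizer(self):
        assert pw.photobleaching_rate(0.0, 0.1, 100.0, self.params) == 0.0

    def test_bleaching_quadratic_in_concentration(self):
        r1 = pw.photobleaching_rate(0.02, 0.1, 100.0, self.params)
        r2 = pw.photobleaching_rate(0.04, 0.1, 100.0, self.params)
        assert r2 == pytest.approx(4 * r1, rel=1e-12)
        assert r1 <= 0

    def test_photon_flux_conversion_constant(self):
        # 1 W of 532 nm light carries λ/(N_A h c) mol photons per second
        assert MOL_PHOTONS_PER_JOULE == pytest.approx(4.447e-6, rel=1e-3)


class TestZeroDimensionalBleachingOracle:
    def test_second_order_decay_closed_form(self):
        """Well-mixed photobleaching follows Cm(t) = Cm0/(1 + k·Cm0·t) within 0.1%."""
        params = pw.PhotochemParams(kappa=1.0, beta=2.5)
        co, psi = 0.5, 100.0
        k = params.Km * (co / (co + params.beta)) * photon_molar_flux(psi)
        cm0, dt, T = 0.05, 0.01, 50.0
        cm = cm0
        t = 0.0
        while t < T - 1e-9:
            # midpoint integration of dCm/dt = -k Cm^2 at fixed Co, psi
            half = cm + 0.5 * dt * pw.photobleaching_rate(cm, co, psi, params)
            cm = cm + dt * pw.photobleaching_rate(half, co, psi, params)
            t += dt
        analytic = cm0 / (1 + k * cm0 * T)
        assert cm == pytest.approx(analytic, rel=1e-3)


class TestTransportStep:
    def test_uniform_field_equilibrium(self):
        """No light, no metabolism, closed boundaries: nothing changes."""
        model = box_model()
        solver = closed_box_solver(model)
        Co = np.full(model.shape, 0.1)
        Cm = np.full(model.shape, 0.02)
        state = StateFields(Co.copy(), Cm.copy(), np.zeros(model.shape), np.zeros(model.shape))
        for _ in range(5):
            state = solver.step(state, 2.5)
        assert np.allclose(state.Co, 0.1, rtol=0, atol=1e-14)
        assert np.allclose(state.Cm, 0.02, rtol=0, atol=1e-14)

    def test_mass_conservation_closed_box(self):
        """Total photosensitizer mass conserved to 1e-8 over 1000 steps."""
        model = box_model()
        solver = closed_box_solver(model)
        rng = np.random.default_rng(0)
        Cm = rng.random(model.shape)
        state = StateFields(np.full(model.shape, 0.1), Cm.copy(), np.zeros(model.shape), np.zeros(model.shape))
        m0 = state.Cm.sum()
        for _ in range(1000):
            state = solver.step(state, 2.5)
        assert abs(state.Cm.sum() - m0) / m0 <= 1e-8

    def test_oxygen_steady_profile_analytic(self):
        """Surface-fed column with uniform sink relaxes to the parabolic profile.

        Steady diffusion with a zero-order sink, surface Dirichlet Cs and
        a no-flux bottom has C(z) = Cs − (Γ1/D)(L·z − z²/2).
        """
        h, L = 10.0, 400.0
        cfg = pw.GeometryConfig(domain_size=(2 * h, 2 * h, L), voxel_size=h, count=0)
        model = pw.build_tissue_model(cfg)
        model.labels[:] = geometry.REGION_CODES["reticular_dermis"]
        gamma1 = 5e-4
        params = pw.PhotochemParams(gamma1=gamma1, oxygen_cutoff=1e-12)
        boundary = pw.OxygenBoundary(surface_pO2=159.0)
        solver = TransportSolver(model, params, boundary, irradiance=0.0)
        state = solver.initial_state(t_relax=2000.0, dt_relax=5.0)
        z = model.cell_centers(2)
        cs = boundary.surface_concentration
        analytic = cs - gamma1 / params.Do * (L * z - z**2 / 2)
        assert np.allclose(state.Co[0, 0, :], analytic, rtol=0.01)

    def test_nonnegative_and_monotone_cumulative(self, small_vessel_model):
        """Concentrations stay nonnegative; cumulative ROS never decreases."""
        solver = TransportSolver(
            small_vessel_model,
            pw.PhotochemParams(),
            pw.OxygenBoundary.preset("normoxia"),
            flow=pw.FlowConfig(),
            infusion=pw.InfusionProfile(),
            irradiance=100.0,
        )
        state = solver.initial_state(t_relax=500.0)
        prev_cum = state.ros_cum.copy()
        for _ in range(40):
            state = solver.step(state, 2.5)
            assert state.Co.min() >= 0 and state.Cm.min() >= 0
            assert np.all(state.ros_cum >= prev_cum - 1e-15)
            prev_cum = state.ros_cum.copy()

    def test_functional_step_matches_solver_step(self, small_vessel_model):
        """The free-function single-step interface mirrors the solver's."""
        import pwspdt.reaction_transport as rt

        model = small_vessel_model
        params = pw.PhotochemParams()
        boundary = pw.OxygenBoundary.preset("normoxia")
        flow = pw.FlowConfig()
        fluence = pw.solve_fluence(model, 100.0)
        velocity = pw.build_velocity_field(model, flow)
        solver = TransportSolver(
            model, params, boundary, flow=flow, infusion=pw.InfusionProfile(),
            irradiance=100.0, fluence=fluence,
        )
        state = solver.initial_state(t_relax=200.0)
        a = solver.step(state, 2.5)
        b = rt.step(
            state, model, velocity, fluence, params, boundary, 2.5,
            flow=flow, infusion=pw.InfusionProfile(),
        )
        assert np.allclose(a.Co, b.Co, rtol=0, atol=1e-15)
        assert np.allclose(a.Cm, b.Cm, rtol=0, atol=1e-15)

    def test_nonpositive_dt_rejected(self, small_vessel_model):
        with pytest.raises(ValueError):
            TransportSolver(
                small_vessel_model,
                pw.PhotochemParams(),
                pw.OxygenBoundary.preset("normoxia"),
                dt=0.0,
            )
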