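"""Bioheat solver: analytic conduction/Pennes oracles, conservation, protocols."""

import numpy as np
import pytest

import rfasim as rf
from rfasim.bioheat import (
    ProtocolPhase,
    SolverOptions,
    ThermoState,
    control_power,
    gaussian_power,
    run_protocol,
    step_temperature,
)
from rfasim.errors import ConfigError, PowerError, StabilityError
from rfasim.needle import SourcePoints
from rfasim.phantom import Grid, Mask, TissueProperties, build_phantom

from conftest import grid_center, uniform_phantom


def point_source(phantom, offset=(0.0, 0.0, 0.0)):
    c = grid_center(phantom) + np.asarray(offset)
    return SourcePoints(np.array([c]), np.array([1.0]))


class TestGaussianPower:
    def test_zero_power_gives_zero_field(self, small_phantom):
        pf = gaussian_power(small_phantom.grid, point_source(small_phantom), 0.0, 3.0,
                            small_phantom.liver_roi)
        assert np.all(pf.q == 0.0)

    def test_total_power_is_exact_after_renormalization(self, small_phantom):
        pf = gaussian_power(small_phantom.grid, point_source(small_phantom), 37.0, 3.0,
                            small_phantom.liver_roi)
        assert np.isclose(pf.total_W, 37.0, rtol=1e-12)

    def test_field_peaks_at_source_and_is_radially_symmetric(self):
        ph = uniform_phantom(17, 2.0)
        pf = gaussian_power(ph.grid, point_source(ph), 10.0, 4.0, ph.liver_roi)
        peak = np.unravel_index(np.argmax(pf.q), ph.grid.shape)
        assert peak == (8, 8, 8)
        # symmetry: mirrored probe voxels carry equal density
        assert np.isclose(pf.q[8 + 3, 8, 8], pf.q[8 - 3, 8, 8])
        assert np.isclose(pf.q[8, 8 + 3, 8], pf.q[8, 8, 8 - 3])

    def test_two_sources_match_brute_force_kernel_sum(self):
        ph = uniform_phantom(16, 2.0)
        c = grid_center(ph)
        pts = np.array([c + [-4, 0, 0], c + [4, 0, 0]])
        sources = SourcePoints(pts, np.array([0.5, 0.5]))
        sigma, P = 3.0, 20.0
        pf = gaussian_power(ph.grid, sources, P, sigma, ph.liver_roi)
        # independent oracle: direct kernel sum at random probe voxels,
        # renormalized by the brute-force total over the ROI
        rng = np.random.default_rng(0)
        kern = np.zeros(ph.grid.shape)
        for idx in np.ndindex(ph.grid.shape):
            p = np.asarray(ph.grid.origin) + np.asarray(idx) * np.asarray(ph.grid.spacing)
            for s, w in zip(pts, [0.5, 0.5]):
                kern[idx] += w * np.exp(-np.sum((p - s) ** 2) / (2 * sigma**2))
        kern[~ph.liver_roi.values] = 0.0
        vol = ph.grid.voxel_volume_mm3 * 1e-9
        oracle = P * kern / (kern.sum() * vol)
        for _ in range(10):
            ix = tuple(rng.integers(0, 16, 3))
            assert np.isclose(pf.q[ix], oracle[ix], rtol=1e-9)

    def test_sources_outside_roi_rejected(self, small_phantom):
        far = SourcePoints(np.array([[1e4, 1e4, 1e4]]), np.array([1.0]))
        with pytest.raises(PowerError):
            gaussian_power(small_phantom.grid, far, 10.0, 3.0, small_phantom.liver_roi)


class TestStepTemperature:
    def test_baseline_is_equilibrium_fixed_point(self):
        ph = uniform_phantom(12, 3.0, perfusion=2.0)
        zero = rf.PowerField(ph.grid, np.zeros(ph.grid.shape))
        state = ThermoState.initial(ph)
        for method in ("implicit", "explicit"):
            s = state
            for _ in range(5):
                s = step_temperature(s, 1.0, ph, zero, method=method)
            np.testing.assert_allclose(s.T, 37.0, atol=1e-9)

    def test_1d_steady_conduction_is_linear(self):
        # chain of voxels, ends held at 37 and 47 degC, no perfusion/source:
        # steady state is the linear profile, midpoint exactly 42
        n = 33
        grid = Grid((n, 1, 1), (2.0, 2.0, 2.0))
        roi = np.zeros(grid.shape, dtype=bool)
        roi[1:-1] = True
        props = TissueProperties(1060, 3600, 0.512, 0.0)
        tumor = Mask(grid, np.zeros(grid.shape, dtype=bool))
        ph = build_phantom(grid, tumor, liver_roi=Mask(grid, roi),
                           healthy=props, tumor_props=props, vessel_props=props,
                           crop_radius=None)
        state = ThermoState.initial(ph)
        T = state.T.copy()
        T[0] = 37.0
        T[-1] = 47.0
        state = ThermoState(0.0, T, state.A, state.V, state.D)
        zero = rf.PowerField(grid, np.zeros(grid.shape))
        for _ in range(3):
            state = step_temperature(state, 1e9, ph, zero)
        expected = np.linspace(37.0, 47.0, n)
        np.testing.assert_allclose(state.T[:, 0, 0], expected, atol=1e-6)
        assert np.isclose(state.T[n // 2, 0, 0], 42.0, atol=1e-6)

    def test_point_source_far_field_matches_pennes_green_function(self):
        # steady screened-Poisson solution: T - T_b = P/(4 pi k r) exp(-r/delta)
        ph = uniform_phantom(64, 1.5, perfusion=2.0, crop_radius=45.0)
        c = grid_center(ph)
        P, sigma = 1.0, 1.5
        pf = gaussian_power(ph.grid, point_source(ph), P, sigma, ph.liver_roi)
        state = step_temperature(ThermoState.initial(ph), 1e8, ph, pf)
        k = 0.512
        delta = np.sqrt(k / (2.0 * 3600.0))  # m
        X, Y, Z = ph.grid.coords()
        r_mm = np.broadcast_to(
            np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2), ph.grid.shape
        )
        sel = (r_mm > 12.0) & (r_mm < 24.0) & ph.liver_roi.values  # kernel negligible here
        r_m = r_mm[sel] * 1e-3
        analytic = P / (4 * np.pi * k * r_m) * np.exp(-r_m / delta)
        rel = np.abs((state.T[sel] - 37.0) - analytic) / analytic
        assert rel.max() < 0.05

    @pytest.mark.parametrize("method", ["implicit", "explicit"])
    def test_energy_balance_insulated_no_perfusion(self, method):
        # no Dirichlet voxels, no perfusion: the heat content must grow by
        # exactly the deposited energy each step
        ph = uniform_phantom(14, 3.0, perfusion=0.0)
        rng = np.random.default_rng(4)
        q = rng.uniform(0, 5e5, ph.grid.shape)
        pf = rf.PowerField(ph.grid, q)
        state = ThermoState.initial(ph)
        vol = ph.grid.voxel_volume_mm3 * 1e-9
        rho_c = ph.properties.density * ph.properties.heat_capacity
        dt = 2.0
        for _ in range(3):
            new = step_temperature(state, dt, ph, pf, method=method)
            dE = np.sum(rho_c * (new.T - state.T)) * vol
            deposited = q.sum() * vol * dt
            assert abs(dE - deposited) / deposited < 1e-6
            state = new

    def test_discrete_maximum_principle(self, small_phantom):
        rng = np.random.default_rng(8)
        q = rng.uniform(0, 1e6, small_phantom.grid.shape)
        q[~small_phantom.liver_roi.values] = 0.0
        pf = rf.PowerField(small_phantom.grid, q)
        state = ThermoState.initial(small_phantom)
        for _ in range(10):
            state = step_temperature(state, 2.0, small_phantom, pf)
            assert np.all(state.T >= 37.0 - 1e-12)

    def test_vessel_voxels_pinned_at_blood_temperature(self, small_phantom, simple_needle):
        proto = rf.Protocol((ProtocolPhase(60.0, "constant_power", 30.0),), gaussian_sigma_mm=4.0)
        res = run_protocol(small_phantom, simple_needle, proto, options=SolverOptions(dt=2.0))
        assert np.all(res.state.T[small_phantom.vessels.values] == 37.0)

    def test_explicit_unstable_dt_names_the_bound(self):
        ph = uniform_phantom(10, 1.0)  # 1 mm grid -> tight bound
        zero = rf.PowerField(ph.grid, np.zeros(ph.grid.shape))
        with pytest.raises(StabilityError, match="stability bound"):
            step_temperature(ThermoState.initial(ph), 10.0, ph, zero, method="explicit")

    def test_grid_refinement_converges(self):
        # halving the spacing moves the final peak temperature by < 2%
        def peak(n, h):
            ph = uniform_phantom(n, h, perfusion=2.0)
            pf = gaussian_power(ph.grid, point_source(ph), 15.0, 8.0, ph.liver_roi)
            st = ThermoState.initial(ph)
            for _ in range(30):
                st = step_temperature(st, 2.0, ph, pf)
            return st.T.max()

        coarse, fine = peak(24, 3.0), peak(48, 1.5)
        assert abs(coarse - fine) / fine < 0.02


class TestControlPower:
    phase = ProtocolPhase(60.0, "temperature_controlled", 40.0, 90.0)

    def test_cooldown_is_always_off(self):
        p = ProtocolPhase(30.0, "cooldown", 0.0)
        for t in (20.0, 37.0, 150.0):
            assert control_power(p, t) == 0.0

    def test_far_below_target_saturates_at_max(self):
        assert control_power(self.phase, 37.0, band=5.0) == 40.0

    def test_at_target_plus_band_power_is_zero(self):
        assert control_power(self.phase, 95.0, band=5.0) == 0.0

    def test_proportional_midpoint(self):
        assert np.isclose(control_power(self.phase, 92.5, band=5.0), 20.0)

    def test_constant_power_ignores_probe_temperature(self):
        p = ProtocolPhase(30.0, "constant_power", 25.0)
        assert control_power(p, 200.0) == 25.0


class TestRunProtocol:
    def test_total_time_is_sum_of_phase_durations(self, small_phantom, simple_needle):
        proto = rf.Protocol(
            (ProtocolPhase(60.0, "constant_power", 10.0), ProtocolPhase(30.0, "cooldown", 0.0)),
            gaussian_sigma_mm=3.0,
        )
        res = run_protocol(small_phantom, simple_needle, proto, options=SolverOptions(dt=2.0))
        assert np.isclose(res.state.time, 90.0)

    def test_zero_power_protocol_leaves_tissue_untouched(self, small_phantom, simple_needle):
        proto = rf.Protocol((ProtocolPhase(60.0, "cooldown", 0.0),), gaussian_sigma_mm=3.0)
        res = run_protocol(small_phantom, simple_needle, proto, options=SolverOptions(dt=2.0))
        assert res.lesion.count == 0
        np.testing.assert_allclose(res.state.T, 37.0, atol=1e-9)

    def test_chained_cycles_equal_concatenated_protocol(self, small_phantom, simple_needle):
        opts = SolverOptions(dt=2.0)
        pa = ProtocolPhase(30.0, "constant_power", 20.0)
        pb = ProtocolPhase(20.0, "cooldown", 0.0)
        sigma = 3.0
        full = run_protocol(small_phantom, simple_needle,
                            rf.Protocol((pa, pb), gaussian_sigma_mm=sigma), options=opts)
        first = run_protocol(small_phantom, simple_needle,
                             rf.Protocol((pa,), gaussian_sigma_mm=sigma), options=opts)
        second = run_protocol(small_phantom, simple_needle,
                              rf.Protocol((pb,), gaussian_sigma_mm=sigma), options=opts,
                              initial=first)
        np.testing.assert_allclose(second.state.T, full.state.T, atol=1e-9)
        np.testing.assert_allclose(second.state.D, full.state.D, atol=1e-9)
        assert np.isclose(second.state.time, full.state.time)

    def test_lesion_volume_consistent_between_dt_and_half_dt(self, simple_needle):
        # operator-splitting refinement: lesion volume stable within 2%
        ph = rf.make_default_phantom(shape=(24, 24, 24), spacing=(3.0, 3.0, 3.0),
                                     tumor_radius=7.0, vessel_offset=12.0)
        c = ph.tumor.centroid()
        nd = rf.make_simple_needle(c, c + np.array([0.0, 0.0, 30.0]))
        proto = rf.Protocol((ProtocolPhase(120.0, "constant_power", 18.0),), gaussian_sigma_mm=4.0)
        v1 = run_protocol(ph, nd, proto, options=SolverOptions(dt=2.0)).lesion.volume_ml
        v2 = run_protocol(ph, nd, proto, options=SolverOptions(dt=1.0)).lesion.volume_ml
        assert v1 > 0
        assert abs(v1 - v2) / v2 < 0.02

    def test_history_records_monotone_lesion_growth(self, small_phantom, simple_needle, fast_protocol):
        res = run_protocol(small_phantom, simple_needle, fast_protocol,
                           options=SolverOptions(dt=2.0, record_every=5))
        vols = res.history["lesion_volume_ml"].to_numpy()
        assert np.all(np.diff(vols) >= 0)

    def test_invalid_phase_configurations_rejected(self):
        with pytest.raises(ConfigError):
            ProtocolPhase(-5.0, "constant_power", 10.0)
        with pytest.raises(ConfigError):
            ProtocolPhase(10.0, "cooldown", 5.0)
        with pytest.raises(ConfigError):
            ProtocolPhase(10.0, "temperature_controlled", 5.0)  # no target
        with pytest.raises(ConfigError):
            rf.Protocol((), gaussian_sigma_mm=2.0)
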