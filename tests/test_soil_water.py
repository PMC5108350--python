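"""Soil water and heat transport: conservation, oracles, limits."""

import math
from datetime import date

import numpy as np
import pytest

from grassflux.soil_water import (
    PotentialET, SoilColumnState, SoilLayerPhysical, actual_et,
    fourier_heat_step, hydraulic_conductivity, potential_evapotranspiration,
    potential_from_theta, richards_step, theta_from_potential,
)


class _Day:
    def __init__(self, tmax, tmin, rad, wind, rh, d=date(2001, 7, 1)):
        self.tmax_c, self.tmin_c = tmax, tmin
        self.radiation_mj_m2, self.wind_m_s, self.rh_pct = rad, wind, rh
        self.date = d


class TestRetentionFunctions:
    def test_theta_potential_round_trip(self, clay_layers):
        theta = np.array([0.25, 0.3, 0.35, 0.42])
        h = potential_from_theta(theta, clay_layers)
        np.testing.assert_allclose(theta_from_potential(h, clay_layers), theta, rtol=1e-9)

    def test_saturation_at_zero_potential(self, clay_layers):
        theta = theta_from_potential(np.zeros(4), clay_layers)
        np.testing.assert_allclose(theta, [l.theta_s for l in clay_layers])

    def test_conductivity_monotone_in_theta(self, clay_layers):
        thetas = np.linspace(0.15, 0.47, 20)
        for l in clay_layers:
            k = [hydraulic_conductivity(np.array([t]), [l])[0] for t in thetas]
            assert all(k2 >= k1 for k1, k2 in zip(k, k[1:]))


class TestRichardsStep:
    def test_mass_closure_every_step(self, clay_layers, column_at_fc):
        state = column_at_fc
        rng = np.random.default_rng(0)
        for _ in range(60):
            inp = float(rng.choice([0.0, 2.0, 8.0, 20.0]))
            et = rng.uniform(0, 1, 4)
            state, fx = richards_step(state, clay_layers, inp, et)
            assert abs(fx.closure_residual_mm()) <= 1e-3

    def test_theta_bounds_never_violated(self, clay_layers, column_at_fc):
        state = column_at_fc
        rng = np.random.default_rng(1)
        for _ in range(80):
            state, _ = richards_step(
                state, clay_layers, float(rng.choice([0, 0, 30.0])), rng.uniform(0, 2, 4)
            )
            for j, l in enumerate(clay_layers):
                assert l.theta_wp / 2 - 1e-9 <= state.theta[j] <= l.theta_s + 1e-9

    def test_dry_equilibrium_no_fluxes(self, clay_layers):
        # near-residual column: conductivity vanishes, nothing moves
        theta = np.array([l.theta_wp / 2 + 1e-4 for l in clay_layers])
        state = SoilColumnState(theta, np.full(4, 10.0))
        state2, fx = richards_step(state, clay_layers, 0.0, np.zeros(4))
        assert fx.runoff_mm == 0.0
        assert fx.drainage_mm == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(state2.theta, theta, atol=1e-6)

    def test_saturation_excess_runoff(self, clay_layers):
        sat = SoilColumnState(
            np.array([l.theta_s - 1e-6 for l in clay_layers]), np.full(4, 10.0)
        )
        _, fx = richards_step(sat, clay_layers, 1000.0, np.zeros(4))
        assert fx.runoff_mm >= 0.9 * 1000.0
        assert abs(fx.delta_storage_mm) < 1.0

    def test_runoff_nondecreasing_in_input(self, clay_layers):
        theta0 = np.array([l.theta_fc + 0.05 for l in clay_layers])
        runoffs = []
        for inp in (0.0, 20.0, 60.0, 150.0, 400.0):
            st = SoilColumnState(theta0.copy(), np.full(4, 10.0))
            _, fx = richards_step(st, clay_layers, inp, np.zeros(4))
            runoffs.append(fx.runoff_mm)
        assert all(b >= a - 1e-9 for a, b in zip(runoffs, runoffs[1:]))

    def test_against_fine_timestep_explicit_oracle(self, three_layer_column):
        """Implicit daily step vs explicit sub-minute forward integration."""
        layers, state = three_layer_column
        dz = np.array([l.thickness_m for l in layers])
        pulse = 12.0  # mm over the day

        new, _ = richards_step(state, layers, pulse, np.zeros(3), dt_days=1.0)

        # oracle: same physics integrated explicitly at dt = 2e-5 d (~1.7 s)
        theta = state.theta.copy()
        n_steps = 50_000
        dt = 1.0 / n_steps
        q_supply = pulse / 1000.0
        dz_int = 0.5 * (dz[:-1] + dz[1:])
        ks0 = layers[0].k_sat_m_d
        for _ in range(n_steps):
            h = potential_from_theta(theta, layers)
            k = hydraulic_conductivity(theta, layers)
            k_int = 0.5 * (k[:-1] + k[1:])
            q_cap = max(0.0, ks0 * (-h[0] / (dz[0] / 2) + 1.0))
            q_top = min(q_supply, q_cap)
            q_internal = k_int * ((h[:-1] - h[1:]) / dz_int + 1.0)
            q_bot = k[-1]
            q_in = np.concatenate([[q_top], q_internal])
            q_out = np.concatenate([q_internal, [q_bot]])
            theta = theta + (q_in - q_out) / dz * dt
        np.testing.assert_allclose(new.theta, theta, rtol=0.01)


class TestPotentialET:
    def test_no_driving_force_zero(self):
        day = _Day(10, 10, 0.0, 0.0, 100.0, date(2001, 1, 15))
        assert potential_evapotranspiration(day, 0.0).total_mm == pytest.approx(0.0, abs=1e-6)

    def test_partition_limits(self):
        day = _Day(22, 12, 22, 2.5, 65)
        bare = potential_evapotranspiration(day, 0.0)
        dense = potential_evapotranspiration(day, 5.0)
        assert bare.transpiration_mm == pytest.approx(0.0)
        assert dense.transpiration_mm / dense.total_mm > 0.9
        assert bare.total_mm == pytest.approx(dense.total_mm, rel=1e-9)

    def test_against_independent_penman_monteith(self):
        """Independent FAO-56 implementation written directly from the
        reference equations."""
        day = _Day(24.0, 13.0, 23.5, 2.2, 60.0, date(2001, 6, 21))
        lat, z = 50.77, 180.0
        t = 18.5
        e0 = lambda T: 0.6108 * math.exp(17.27 * T / (T + 237.3))
        delta = 4098 * e0(t) / (t + 237.3) ** 2
        P = 101.3 * ((293 - 0.0065 * z) / 293) ** 5.26
        gamma = 0.000665 * P
        es = (e0(24.0) + e0(13.0)) / 2
        ea = 0.6 * es
        doy = 172
        dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
        dec = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
        phi = math.radians(lat)
        ws = math.acos(-math.tan(phi) * math.tan(dec))
        Ra = 24 * 60 / math.pi * 0.082 * dr * (
            ws * math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.sin(ws)
        )
        Rso = (0.75 + 2e-5 * z) * Ra
        Rns = 0.77 * 23.5
        Rnl = 4.903e-9 * ((24 + 273.16) ** 4 + (13 + 273.16) ** 4) / 2 \
            * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * min(1, 23.5 / Rso) - 0.35)
        Rn = Rns - Rnl
        expected = (0.408 * delta * Rn + gamma * 900 / (t + 273) * 2.2 * (es - ea)) \
            / (delta + gamma * (1 + 0.34 * 2.2))
        got = potential_evapotranspiration(day, 0.0).total_mm
        assert got == pytest.approx(expected, abs=0.05)


class TestActualET:
    def test_wilting_profile_no_extraction(self, clay_layers):
        theta = np.array([l.theta_wp for l in clay_layers])
        state = SoilColumnState(theta, np.full(4, 10.0))
        et = actual_et(PotentialET(4.0, 1.0, 3.0), state, clay_layers, np.full(4, 0.25))
        assert np.all(et == 0)

    def test_ample_water_meets_demand(self, clay_layers):
        theta = np.array([l.theta_fc for l in clay_layers])
        state = SoilColumnState(theta, np.full(4, 10.0))
        pet = PotentialET(4.0, 1.0, 3.0)
        et = actual_et(pet, state, clay_layers, np.array([0.5, 0.3, 0.15, 0.05]))
        assert et.sum() == pytest.approx(pet.total_mm, rel=1e-9)

    def test_total_never_exceeds_pet(self, clay_layers, column_at_fc):
        pet = PotentialET(5.0, 2.0, 3.0)
        et = actual_et(pet, column_at_fc, clay_layers, np.full(4, 0.25))
        assert et.sum() <= pet.total_mm + 1e-12

    def test_deep_roots_extract_more_from_wet_subsoil(self, clay_layers):
        theta = np.array([
            clay_layers[0].theta_wp + 0.005, clay_layers[1].theta_wp + 0.005,
            clay_layers[2].theta_fc, clay_layers[3].theta_fc,
        ])
        state = SoilColumnState(theta, np.full(4, 10.0))
        pet = PotentialET(4.0, 0.5, 3.5)
        shallow = actual_et(pet, state, clay_layers, np.array([0.7, 0.3, 0.0, 0.0]))
        deep = actual_et(pet, state, clay_layers, np.array([0.3, 0.2, 0.3, 0.2]))
        assert deep.sum() > shallow.sum()


class TestHeatStep:
    def test_isothermal_unchanged(self, clay_layers, column_at_fc):
        out = fourier_heat_step(column_at_fc, clay_layers, 10.0)
        np.testing.assert_allclose(out.temperature_c, 10.0, atol=1e-9)

    def test_step_response_monotone_damped_with_depth(self, clay_layers, column_at_fc):
        state = column_at_fc
        for _ in range(3):
            state = fourier_heat_step(state, clay_layers, 20.0)
        dt = state.temperature_c - 10.0
        assert np.all(dt > 0)
        assert np.all(np.diff(dt) < 0)  # response decays with depth

    def test_annual_sinusoid_amplitude_matches_analytic_damping(self):
        layers = [SoilLayerPhysical(0.05, 0.48, 0.38, 0.20, 0.1) for _ in range(60)]  # 3 m
        n = len(layers)
        state = SoilColumnState(np.full(n, 0.3), np.full(n, 10.0))
        lam = 1.2 * 86400.0
        kappa = lam / 2.5e6
        omega = 2 * math.pi / 365.0
        damping_depth = math.sqrt(2 * kappa / omega)
        amp, mean = 8.0, 10.0
        rec = []
        for t in range(3 * 365):
            ts = mean + amp * math.sin(omega * t)
            state = fourier_heat_step(state, layers, ts, substeps=2)
            if t >= 2 * 365:
                rec.append(state.temperature_c.copy())
        rec = np.array(rec)
        centers = np.cumsum([l.thickness_m for l in layers]) - 0.025
        for z_query in (0.2, 0.5, 1.0):
            i = int(np.argmin(np.abs(centers - z_query)))
            a_num = (rec[:, i].max() - rec[:, i].min()) / 2
            a_true = amp * math.exp(-centers[i] / damping_depth)
            assert a_num == pytest.approx(a_true, rel=0.05)


def test_layer_validation():
    with pytest.raises(ValueError):
        SoilLayerPhysical(0.1, 0.4, 0.45, 0.2, 0.1)  # fc > sat
    with pytest.raises(ValueError):
        SoilLayerPhysical(0.1, 0.45, 0.4, 0.2, -0.1)
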