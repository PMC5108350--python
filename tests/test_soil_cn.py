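"""Soil C/N pool dynamics: decay law, MM kinetics, conservation, inputs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grassflux.livestock import StockingPeriod, excreta_returns, load_default_specs
from grassflux.soil_cn import (
    CNParams, EnvModifiers, LayerCNPools, apply_deposition, apply_excreta,
    apply_fertilizer, apply_fym, decompose, denitrify, moisture_response,
    nitrify, temperature_response, transport_solutes,
)

MODS1 = EnvModifiers(f_t=1.0, f_w=1.0, wfps=0.5)


def all_pools(p: LayerCNPools) -> list[float]:
    return [p.fom_c, p.fom_n, p.litter_c, p.litter_n, p.humus_c, p.humus_n,
            p.doc, p.don, p.nh4, p.no3]


class TestDecompose:
    def test_zero_pools_zero_fluxes(self):
        out, fx = decompose(LayerCNPools(), MODS1)
        assert fx.het_co2_c == 0 and fx.gross_mineralization == 0
        assert all(v == 0 for v in all_pools(out))

    def test_isolated_pool_first_order_decay_closed_form(self):
        params = CNParams()
        c0 = 1000.0
        p = LayerCNPools(humus_c=c0, humus_n=c0 / params.humus_cn, nh4=50.0)
        out, fx = decompose(p, MODS1, dt=1.0, params=params)
        expected_loss = c0 * (1 - math.exp(-params.k_humus))
        assert c0 - out.humus_c == pytest.approx(expected_loss, abs=1e-10)

    def test_high_cn_litter_immobilizes_without_negative_nh4(self):
        p = LayerCNPools(litter_c=4000.0, litter_n=50.0, nh4=0.5)  # C:N 80
        out, fx = decompose(p, MODS1)
        assert fx.immobilization > fx.gross_mineralization  # net immobilization
        assert out.nh4 >= 0 and out.no3 >= 0

    def test_n_mass_conserved(self):
        p = LayerCNPools(fom_c=500, fom_n=25, litter_c=800, litter_n=10,
                         humus_c=30000, humus_n=3000, doc=50, don=5, nh4=20, no3=30)
        n0 = p.total_n()
        out, fx = decompose(p, MODS1)
        assert out.total_n() == pytest.approx(n0, abs=1e-9)

    def test_c_loss_equals_co2(self):
        p = LayerCNPools(fom_c=500, fom_n=25, humus_c=30000, humus_n=3000, nh4=20)
        c0 = p.total_c()
        out, fx = decompose(p, MODS1)
        assert c0 - out.total_c() == pytest.approx(fx.het_co2_c, abs=1e-9)

    def test_rates_scale_with_modifiers(self):
        p = LayerCNPools(litter_c=1000, litter_n=50, nh4=100)
        _, fx_full = decompose(p, EnvModifiers(1.0, 1.0, 0.5))
        _, fx_half = decompose(p, EnvModifiers(0.5, 1.0, 0.5))
        assert fx_half.het_co2_c < fx_full.het_co2_c


class TestNitrify:
    def test_no_ammonium_no_nitrification(self):
        out, fx = nitrify(LayerCNPools(no3=10.0), MODS1)
        assert fx.nitrification == 0

    def test_half_saturation_identity(self):
        # Vmax/2 below the pool so the availability cap does not bind
        params = CNParams(nitrif_vmax=4.0, nitrif_km=5.0)
        p = LayerCNPools(nh4=params.nitrif_km)
        _, fx = nitrify(p, EnvModifiers(1.0, 1.0, 0.5), params=params)
        assert fx.nitrification == pytest.approx(params.nitrif_vmax / 2, abs=1e-10)

    def test_saturation_limit(self):
        params = CNParams()
        p = LayerCNPools(nh4=1e6)
        _, fx = nitrify(p, EnvModifiers(1.0, 1.0, 0.5), params=params)
        assert fx.nitrification == pytest.approx(params.nitrif_vmax, rel=1e-4)

    def test_fixed_n2o_fraction_and_routing(self):
        params = CNParams()
        p = LayerCNPools(nh4=40.0)
        out, fx = nitrify(p, MODS1, params=params)
        assert fx.n2o == pytest.approx(params.nitrif_n2o_fraction * fx.nitrification)
        assert out.no3 == pytest.approx(fx.nitrification - fx.n2o)
        assert p.nh4 - out.nh4 == pytest.approx(fx.nitrification)

    def test_aeration_declines_above_optimum(self):
        p = LayerCNPools(nh4=40.0)
        _, fx_opt = nitrify(p, EnvModifiers(1.0, 1.0, 0.6))
        _, fx_wet = nitrify(p, EnvModifiers(1.0, 1.0, 0.9))
        assert fx_wet.nitrification < fx_opt.nitrification


class TestDenitrify:
    def test_below_threshold_inactive(self):
        out, fx = denitrify(LayerCNPools(no3=100.0), EnvModifiers(1.0, 1.0, 0.5),
                            het_co2_c=50.0)
        assert fx.denitrification == 0

    def test_products_sum_to_consumed_no3(self):
        p = LayerCNPools(no3=80.0)
        out, fx = denitrify(p, EnvModifiers(1.0, 0.2, 0.9), het_co2_c=20.0)
        assert fx.n2o + fx.n2 == pytest.approx(fx.denitrification, abs=1e-10)
        assert p.no3 - out.no3 == pytest.approx(fx.denitrification, abs=1e-10)

    def test_n2_dominates_at_saturation(self):
        p = LayerCNPools(no3=200.0)
        _, fx = denitrify(p, EnvModifiers(1.0, 0.2, 1.0), het_co2_c=100.0)
        assert fx.denitrification > 0
        assert fx.n2 > fx.n2o

    def test_requires_carbon(self):
        p = LayerCNPools(no3=100.0)
        _, fx = denitrify(p, EnvModifiers(1.0, 0.2, 0.95), het_co2_c=0.0)
        assert fx.denitrification == 0


class TestTransport:
    def test_zero_flow_zero_transport(self):
        pools = [LayerCNPools(no3=50, doc=20, don=5, nh4=10)]
        out, fx = transport_solutes(pools, [100.0], np.zeros(0), 0.0, 0.0, [0.1])
        assert fx.n_leached == 0 and fx.n_runoff == 0
        assert out[0].no3 == 50

    def test_half_water_leaches_half_nitrate_single_layer(self):
        pools = [LayerCNPools(no3=40.0)]
        out, fx = transport_solutes(pools, [100.0], np.zeros(0), 50.0, 0.0, [0.1])
        assert fx.no3_leached == pytest.approx(20.0, abs=1e-12)
        assert out[0].no3 == pytest.approx(20.0)

    def test_total_mass_conserved(self):
        pools = [LayerCNPools(no3=40, nh4=10, doc=25, don=6),
                 LayerCNPools(no3=5, nh4=3, doc=2, don=1)]
        n0 = sum(p.total_n() for p in pools)
        out, fx = transport_solutes(pools, [60.0, 90.0], np.array([20.0]), 15.0, 5.0, [0.1, 0.2])
        n1 = sum(p.total_n() for p in out)
        assert n1 + fx.n_leached + fx.n_runoff == pytest.approx(n0, abs=1e-9)

    def test_nh4_less_mobile_than_no3(self):
        pools = [LayerCNPools(no3=40.0, nh4=40.0)]
        _, fx = transport_solutes(pools, [100.0], np.zeros(0), 50.0, 0.0, [0.1])
        assert fx.nh4_leached < fx.no3_leached


class TestInputs:
    def test_ammonium_nitrate_split_even(self):
        out, vol = apply_fertilizer(LayerCNPools(), 100.0, "ammonium_nitrate")
        reaching = 100.0 - vol
        assert out.nh4 == pytest.approx(reaching / 2)
        assert out.no3 == pytest.approx(reaching / 2)
        assert vol == pytest.approx(2.0)  # 2% NH3 loss at spreading

    def test_unknown_product_rejected(self):
        with pytest.raises(KeyError):
            apply_fertilizer(LayerCNPools(), 50.0, "mystery_blend")

    def test_fym_available_fraction_routing(self):
        out = apply_fym(LayerCNPools(), 10_000.0, 100.0, available_n_fraction=0.25)
        assert out.nh4 == pytest.approx(25.0)
        assert out.fom_n == pytest.approx(75.0)

    def test_zero_amount_event_no_change(self):
        p = LayerCNPools(nh4=5.0)
        out = apply_fym(p, 0.0, 0.0)
        assert all_pools(out) == all_pools(p)

    def test_excreta_routing_matches_return(self):
        spec = load_default_specs()["beef"]
        from datetime import date
        sp = StockingPeriod(date(2001, 6, 1), date(2001, 6, 30), 10, 5.0, "beef")
        ret = excreta_returns(spec, sp)
        out = apply_excreta(LayerCNPools(), ret)
        assert out.total_n() == pytest.approx(ret.total_soil_n, abs=1e-12)
        assert out.fom_c == pytest.approx(ret.dung_c)

    def test_deposition_daily_rate(self):
        params = CNParams()
        out, dep = apply_deposition(LayerCNPools(), 1.0, params)
        assert dep == pytest.approx(params.deposition_kg_n_ha_yr / 365)
        assert out.nh4 + out.no3 == pytest.approx(dep)


class TestModifiers:
    def test_q10_reference(self):
        assert temperature_response(20.0) == pytest.approx(1.0)
        assert temperature_response(30.0) == pytest.approx(2.0)
        assert temperature_response(10.0) == pytest.approx(0.5)

    def test_moisture_optimum(self):
        assert moisture_response(0.6) == pytest.approx(1.0)
        assert moisture_response(0.0) == 0.0
        assert moisture_response(1.0) == pytest.approx(0.2)


pool_values = st.floats(min_value=0.0, max_value=1e5, allow_nan=False)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    fom_c=pool_values, fom_n=pool_values, litter_c=pool_values, litter_n=pool_values,
    humus_c=pool_values, humus_n=pool_values, doc=pool_values, don=pool_values,
    nh4=pool_values, no3=pool_values,
    f_t=st.floats(0.0, 3.0), wfps=st.floats(0.0, 1.0),
)
def test_pools_stay_non_negative_and_n_closes_under_adversarial_states(
    fom_c, fom_n, litter_c, litter_n, humus_c, humus_n, doc, don, nh4, no3, f_t, wfps
):
    """Pipeline of all transformations keeps pools >= 0 and conserves N."""
    p = LayerCNPools(fom_c=fom_c, fom_n=fom_n, litter_c=litter_c, litter_n=litter_n,
                     humus_c=humus_c, humus_n=humus_n, doc=doc, don=don, nh4=nh4, no3=no3)
    mods = EnvModifiers(f_t=f_t, f_w=moisture_response(wfps), wfps=wfps)
    n0 = p.total_n()
    p, fx1 = decompose(p, mods)
    p, fx2 = nitrify(p, mods)
    p, fx3 = denitrify(p, mods, het_co2_c=fx1.het_co2_c)
    assert all(v >= 0 for v in all_pools(p))
    exports = fx1.n2o + fx2.n2o + fx3.n2o + fx3.n2
    assert p.total_n() + exports == pytest.approx(n0, abs=max(1e-9, n0 * 1e-12))
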