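"""Sward growth: development index, assimilation, partitioning, roots, cuts."""

from datetime import date

import numpy as np
import pytest

from grassflux.plants import (
    C_FRACTION_DM, SPECIES_REGISTRY, PlantState, SpeciesParams, assimilate,
    cut, graze, grow_roots, litterfall, n_demand, new_sward, respire_and_partition,
    root_fractions, update_development, uptake_and_fix,
)


class _Day:
    def __init__(self, tmax, tmin, rad=15.0):
        self.tmax_c, self.tmin_c, self.radiation_mj_m2 = tmax, tmin, rad
        self.wind_m_s, self.rh_pct, self.date = 3.0, 80.0, date(2001, 6, 1)


RYE = SPECIES_REGISTRY["ryegrass"]
CLOVER = SPECIES_REGISTRY["white_clover"]
FESTU = SPECIES_REGISTRY["festulolium"]


class TestDevelopment:
    def test_cold_day_no_advance(self):
        s = new_sward(RYE, 4)
        s2 = update_development(s, _Day(RYE.base_temperature_c, RYE.base_temperature_c - 2), RYE)
        assert s2.di == s.di

    def test_thermal_time_arithmetic(self):
        params = SpeciesParams(name="x", base_temperature_c=0.0, thermal_time_norm_cd=1000.0)
        s = new_sward(params, 4)
        s2 = update_development(s, _Day(12.0, 8.0), params)  # Tmean 10
        assert s2.di - s.di == pytest.approx(0.01)

    def test_cut_resets_di(self):
        s = new_sward(RYE, 4, seedling_dm=6000.0)
        s.di = 1.3
        s2, removed = cut(s, RYE)
        assert removed > 0
        assert s2.di == 0.0


class TestAssimilate:
    def test_no_leaves_no_gpp(self):
        s = PlantState()
        assert assimilate(s, _Day(20, 12), 1.0, 1.0, RYE) == 0.0

    def test_full_stress_no_gpp(self):
        s = new_sward(RYE, 4, seedling_dm=2000.0)
        assert assimilate(s, _Day(20, 12), 0.0, 1.0, RYE) == 0.0

    def test_full_interception_limit(self):
        s = new_sward(RYE, 4, seedling_dm=1e7)  # LAI -> inf
        day = _Day(21.0, 21.0, rad=20.0)  # in the temperature optimum
        gpp = assimilate(s, day, 1.0, 1.0, RYE)
        assert gpp == pytest.approx(RYE.rue_g_c_mj * 20.0 * 10.0, rel=1e-4)

    def test_co2_response_unity_at_reference(self):
        s = new_sward(RYE, 4, seedling_dm=2000.0)
        day = _Day(20, 12)
        assert assimilate(s, day, 1.0, 1.0, RYE, co2_mg_m3=695.0) == pytest.approx(
            assimilate(s, day, 1.0, 1.0, RYE)
        )


class TestRespirationPartitioning:
    def test_zero_gpp_zero_plant_zero_fluxes(self):
        s = PlantState()
        s2, fx = respire_and_partition(s, 0.0, 15.0, RYE)
        assert fx.respiration == 0 and fx.gpp == 0

    def test_partition_fraction_arithmetic(self):
        params = SpeciesParams(
            name="x", partition_breakpoints=((0.0, (0.5, 0.2, 0.3)),),
            maintenance_resp_per_day=0.0, growth_resp_fraction=0.0,
        )
        s = PlantState()
        s2, fx = respire_and_partition(s, 10.0, 20.0, params)
        assert (fx.growth_leaf_c, fx.growth_stem_c, fx.growth_root_c) == \
            pytest.approx((5.0, 2.0, 3.0))

    def test_c_balance_identity(self):
        s = new_sward(RYE, 4, seedling_dm=2000.0)
        c0 = s.plant_c
        s2, fx = respire_and_partition(s, 50.0, 18.0, RYE)
        assert s2.plant_c - c0 == pytest.approx(fx.gpp - fx.respiration, abs=1e-9)

    def test_partition_fractions_always_sum_to_one(self):
        for di in np.linspace(0, 3, 30):
            assert RYE.partition_at(di).sum() == pytest.approx(1.0, abs=1e-12)


class TestUptakeFixation:
    def test_non_legume_no_mineral_no_uptake(self):
        s = new_sward(RYE, 2)
        s2, fx = uptake_and_fix(s, np.zeros(2), 2.0, RYE)
        assert fx.n_uptake == 0 and fx.n_fixation == 0

    def test_legume_deficit_rule(self):
        s = new_sward(CLOVER, 2)
        s2, fx = uptake_and_fix(s, np.zeros(2), 2.0, CLOVER)
        assert fx.n_fixation == pytest.approx(2.0)

    def test_fixation_capped_at_max_rate(self):
        s = new_sward(CLOVER, 2)
        s2, fx = uptake_and_fix(s, np.zeros(2), 100.0, CLOVER)
        assert fx.n_fixation == pytest.approx(CLOVER.max_fixation_kg_n_ha_d)

    def test_fixation_non_increasing_in_mineral_n(self):
        prev = np.inf
        for mineral in (0.0, 2.0, 5.0, 20.0, 100.0):
            s = new_sward(CLOVER, 1)
            _, fx = uptake_and_fix(s, np.array([mineral]), 2.5, CLOVER)
            assert fx.n_fixation <= prev + 1e-12
            prev = fx.n_fixation

    def test_fixation_zero_when_uptake_meets_demand(self):
        s = new_sward(CLOVER, 1)
        _, fx = uptake_and_fix(s, np.array([1000.0]), 2.0, CLOVER)
        assert fx.n_uptake == pytest.approx(2.0)
        assert fx.n_fixation == 0.0

    def test_uptake_capped_by_demand(self):
        s = new_sward(RYE, 2)
        _, fx = uptake_and_fix(s, np.array([50.0, 50.0]), 1.5, RYE)
        assert fx.n_uptake == pytest.approx(1.5)

    def test_n_balance_identity(self):
        s = new_sward(RYE, 2)
        n0 = s.plant_n
        s2, fx = uptake_and_fix(s, np.array([10.0, 5.0]), 3.0, RYE)
        assert s2.plant_n - n0 == pytest.approx(fx.n_uptake + fx.n_fixation, abs=1e-12)


class TestRoots:
    def test_fractions_sum_to_one(self):
        dz = [0.1, 0.2, 0.25, 0.3]
        for depth in (0.02, 0.1, 0.35, 0.85, 2.0):
            assert root_fractions(depth, dz, 3.0).sum() == pytest.approx(1.0)

    def test_at_max_depth_unchanged(self):
        s = new_sward(RYE, 4)
        s.root_depth_m = RYE.max_root_depth_m
        s2 = grow_roots(s, _Day(20, 10), RYE, [0.1, 0.2, 0.25, 0.3])
        assert s2.root_depth_m == RYE.max_root_depth_m

    def test_deep_rooting_species_outgrows_ryegrass(self):
        dz = [0.1, 0.2, 0.25, 0.3]
        rye, festu = new_sward(RYE, 4), new_sward(FESTU, 4)
        for _ in range(400):
            rye = grow_roots(rye, _Day(18, 10), RYE, dz)
            festu = grow_roots(festu, _Day(18, 10), FESTU, dz)
        assert festu.root_depth_m > rye.root_depth_m
        assert festu.root_depth_m == pytest.approx(FESTU.max_root_depth_m)


class TestCutAndGraze:
    def test_below_stubble_no_removal(self):
        s = new_sward(RYE, 4, seedling_dm=500.0)
        s2, removed = cut(s, RYE)
        assert removed == 0.0

    def test_removal_arithmetic(self):
        s = PlantState(leaf_c=3000 * 0.45 * 0.6, stem_c=3000 * 0.45 * 0.4,
                       leaf_n=30, stem_n=10)
        s2, removed = cut(s, RYE)  # above-ground DM 3000, stubble 1000
        assert removed == pytest.approx(2000.0)
        assert s2.aboveground_dm == pytest.approx(RYE.stubble_kg_dm_ha)

    def test_roots_untouched_by_cut(self):
        s = new_sward(RYE, 4, seedling_dm=8000.0)
        root_before = s.root_c
        s2, _ = cut(s, RYE)
        assert s2.root_c == root_before

    def test_graze_capped_at_stubble(self):
        s = new_sward(RYE, 4, seedling_dm=4000.0)
        s2, removed = graze(s, 1e6, RYE)
        assert s2.aboveground_dm == pytest.approx(RYE.stubble_kg_dm_ha)
        assert removed == pytest.approx(s.aboveground_dm - RYE.stubble_kg_dm_ha)


class TestLitterfall:
    def test_turnover_conserves_mass(self):
        s = new_sward(RYE, 4, seedling_dm=3000.0)
        c0, n0 = s.plant_c, s.plant_n
        s2, fx = litterfall(s, RYE)
        assert c0 - s2.plant_c == pytest.approx(fx.litter_c + fx.root_litter_c, abs=1e-12)
        assert n0 - s2.plant_n == pytest.approx(fx.litter_n + fx.root_litter_n, abs=1e-12)


def test_species_params_validation():
    with pytest.raises(ValueError):
        SpeciesParams(name="bad", partition_breakpoints=((0.0, (0.6, 0.2, 0.3)),))
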