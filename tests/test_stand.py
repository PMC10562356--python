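"""Surrogate stand model: initialization, GPP, growth, conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forcarb_uq as f
from forcarb_uq.params import GrowthParams, ParameterSet, PhotosynthesisParams
from forcarb_uq.stand import HarvestApplication

from conftest import make_stand_state


def segment_frame(ba=20.0, dbh=22.0, height=18.0, age=60.0,
                  species=(1.0, 0.0, 0.0), site_type=3,
                  soil_class="mineral", land_class="productive"):
    return pd.DataFrame([{
        "segment_id": "s0", "area_ha": 1.0, "basal_area": ba, "mean_dbh": dbh,
        "mean_height": height, "mean_age": age, "prop_pine": species[0],
        "prop_spruce": species[1], "prop_birch": species[2],
        "site_type": site_type, "soil_class": soil_class,
        "land_class": land_class}])


def weather_year(rad=10.0, temp=15.0, vpd=0.5, precip=2.0, co2=400.0):
    return {"radiation": np.full(365, rad), "temperature": np.full(365, temp),
            "vpd": np.full(365, vpd), "precipitation": np.full(365, precip),
            "co2": co2}


class TestInitializeStand:
    def test_crown_height_factor_is_multiplicative(self, default_params):
        seg = segment_frame()
        s1 = f.initialize_stand(seg, 1.0, default_params)
        s2 = f.initialize_stand(seg, 1.2, default_params)
        np.testing.assert_allclose(s2.crown_height, 1.2 * s1.crown_height)

    def test_zero_basal_area_gives_zero_stocks(self, default_params):
        seg = segment_frame(ba=0.0, dbh=0.0, height=0.0, age=0.0)
        state = f.initialize_stand(seg, 1.0, default_params)
        assert state.volume[0] == 0.0
        assert state.tree_c[0] == 0.0

    def test_toy_volume_matches_hand_arithmetic(self, default_params):
        # pure pine, BA 20 m2/ha, height 18 m, dbh 22 cm, default coefficients
        state = f.initialize_stand(segment_frame(), 1.0, default_params)
        crown = 0.45 * 18.0 + 0.05 * 22.0 + 0.5          # = 9.7 m
        crown_ratio = 1.0 - crown / 18.0
        form = 0.45 * (1.0 - 0.25 * (1.0 - crown_ratio))
        volume = 20.0 * 18.0 * form
        assert state.crown_height[0] == pytest.approx(crown)
        assert state.volume[0] == pytest.approx(volume)
        assert state.tree_c[0] == pytest.approx(volume * 400.0 * 0.5 * 1.55)

    def test_nonpositive_factor_rejected(self, default_params):
        with pytest.raises(ValueError, match="crown_height_factor"):
            f.initialize_stand(segment_frame(), 0.0, default_params)


class TestAnnualGpp:
    def test_zero_radiation_gives_zero_gpp(self, default_params):
        state = make_stand_state(5)
        gpp = f.annual_gpp(state, weather_year(rad=0.0), default_params)
        np.testing.assert_array_equal(gpp, 0.0)

    def test_linear_in_lue(self, default_params):
        state = make_stand_state(5)
        wy = weather_year()
        gpp1 = f.annual_gpp(state, wy, default_params)
        doubled = ParameterSet(photosynthesis=PhotosynthesisParams(
            lue=2 * default_params.photosynthesis.lue))
        gpp2 = f.annual_gpp(state, wy, doubled)
        np.testing.assert_allclose(gpp2, 2.0 * gpp1, rtol=1e-12)

    def test_monotone_in_co2(self, default_params):
        state = make_stand_state(3)
        lo = f.annual_gpp(state, weather_year(co2=400.0), default_params)
        hi = f.annual_gpp(state, weather_year(co2=600.0), default_params)
        assert (hi > lo).all()

    def test_incomplete_weather_year_rejected(self, default_params):
        state = make_stand_state(2)
        wy = weather_year()
        wy["radiation"] = wy["radiation"][:100]
        with pytest.raises(ValueError, match="365"):
            f.annual_gpp(state, wy, default_params)


class TestGrowStand:
    def test_exact_carbon_conservation_many_random_states(self, default_params):
        """delta(tree+gv) = npp - litter - mortality - harvest, elementwise,
        over 10^4 random states with random consistent harvests."""
        rng = np.random.default_rng(42)
        n = 10_000
        state = make_stand_state(n, rng)
        frac = rng.uniform(0.0, 1.0, n) * (rng.random(n) < 0.3)
        removed = frac * state.tree_c
        app = HarvestApplication(
            removal_frac=frac, clearcut=frac == 1.0,
            harvested_c=0.6 * removed, residue_litter_c=0.4 * removed)
        gpp = rng.uniform(0.0, 15_000.0, n)
        before = state.tree_c + state.gv_c
        new, flux = f.grow_stand(state, gpp, default_params, harvest=app)
        lhs = (new.tree_c + new.gv_c) - before
        rhs = flux.npp - flux.litter - flux.mortality_litter - flux.harvested_c
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-6)
        assert (new.tree_c >= 0).all() and (new.gv_c >= 0).all()

    def test_zero_gpp_zero_mortality_flux_identity(self):
        params = ParameterSet(growth=GrowthParams(mort_rate=0.0))
        state = make_stand_state(50, np.random.default_rng(1),
                                 stems=np.full(50, 100.0))
        before = state.tree_c + state.gv_c
        new, flux = f.grow_stand(state, np.zeros(50), params)
        np.testing.assert_allclose(
            (new.tree_c + new.gv_c) - before,
            -flux.litter - flux.mortality_litter, rtol=1e-9, atol=1e-9)

    def test_no_crowding_mortality_below_reineke_threshold(self, default_params):
        g = default_params.growth
        state = make_stand_state(20, np.random.default_rng(2),
                                 dbh=np.full(20, 25.0),
                                 stems=np.full(20, 0.5 * g.reineke_k))
        _, flux = f.grow_stand(state, np.zeros(20), default_params)
        # only the random-mortality fraction applies
        np.testing.assert_allclose(flux.mortality_litter,
                                   g.mort_rate * state.tree_c, rtol=1e-12)

    def test_crowding_activates_above_threshold(self, default_params):
        g = default_params.growth
        state = make_stand_state(5, np.random.default_rng(3),
                                 dbh=np.full(5, 25.0),
                                 stems=np.full(5, 2.0 * g.reineke_k))
        _, flux = f.grow_stand(state, np.zeros(5), default_params)
        assert (flux.mortality_litter > g.mort_rate * state.tree_c).all()

    def test_negative_gpp_rejected(self, default_params):
        state = make_stand_state(2)
        with pytest.raises(ValueError, match="non-negative"):
            f.grow_stand(state, np.array([-1.0, 0.0]), default_params)

    def test_age_increments_and_clearcut_resets(self, default_params):
        state = make_stand_state(4, np.random.default_rng(4))
        app = HarvestApplication.none(4)
        app.removal_frac[0] = 1.0
        app.clearcut[0] = True
        removed = state.tree_c[0]
        app.harvested_c[0] = 0.7 * removed
        app.residue_litter_c[0] = 0.3 * removed
        ages = state.age.copy()
        new, _ = f.grow_stand(state, np.zeros(4), default_params, harvest=app)
        assert new.age[0] == 0.0
        np.testing.assert_allclose(new.age[1:], ages[1:] + 1.0)

    def test_thirty_year_trajectory_matches_scalar_recurrence(self, default_params):
        """Integration of a single toy pixel against an independently coded
        scalar recurrence of the documented update order."""
        g = default_params.growth
        seg = segment_frame(ba=15.0, dbh=20.0, height=16.0, age=40.0)
        state = f.initialize_stand(seg, 1.0, default_params)
        gpp_const = 8000.0  # kgC/ha/yr

        # --- independent scalar recurrence
        tree = state.tree_c[0]
        gv = state.gv_c[0]
        stems = state.stems[0]
        ba = state.basal_area[0]
        expected = []
        rho = 400.0  # pure pine
        for _ in range(30):
            ra = g.resp_frac * gpp_const
            npp = gpp_const - ra
            m = g.mort_rate  # density kept below the crowding threshold
            t2 = tree * (1.0 - m)
            litter = g.tree_turnover * t2
            t3 = t2 - litter
            ba_post = ba * (1.0 - m)
            light = np.exp(-g.light_k * ba_post)
            gv_target = g.gv_base[2] * (g.gv_min_frac + (1 - g.gv_min_frac) * light)
            gv_litter = g.gv_turnover * gv
            npp_gv = min(max(gv_target - gv + gv_litter, 0.0), g.gv_frac_cap * npp)
            gv = gv + npp_gv - gv_litter
            tree = t3 + (npp - npp_gv)
            vol = tree / (g.bef * rho * g.carbon_frac)
            stems = stems * (1.0 - m)
            c_geom = g.form_base * (np.pi / 40000.0) * g.h_a
            dbh = (vol / (c_geom * stems)) ** (1.0 / (2.0 + g.h_b))
            ba = stems * np.pi * (dbh / 200.0) ** 2
            expected.append(tree)

        # --- model integration
        actual = []
        for _ in range(30):
            state, _ = f.grow_stand(state, np.array([gpp_const]), default_params)
            actual.append(state.tree_c[0])
        np.testing.assert_allclose(actual, expected, rtol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(tree=st.floats(0, 1e5), gv=st.floats(0, 3000),
           gpp=st.floats(0, 2e4), frac=st.floats(0, 1))
    def test_conservation_property(self, tree, gv, gpp, frac):
        params = f.ParameterSet()
        state = make_stand_state(1, np.random.default_rng(0),
                                 tree_c=np.array([tree]), gv_c=np.array([gv]))
        removed = frac * tree
        app = HarvestApplication(
            removal_frac=np.array([frac]), clearcut=np.array([frac == 1.0]),
            harvested_c=np.array([0.55 * removed]),
            residue_litter_c=np.array([0.45 * removed]))
        before = state.tree_c[0] + state.gv_c[0]
        new, flux = f.grow_stand(state, np.array([gpp]), params, harvest=app)
        lhs = new.tree_c[0] + new.gv_c[0] - before
        rhs = (flux.npp - flux.litter - flux.mortality_litter - flux.harvested_c)[0]
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6)


class TestGroundVegetation:
    def test_zero_light_gives_configured_minimum(self):
        g = GrowthParams()
        b = f.ground_vegetation_biomass(3, 0.0, g)
        assert b == pytest.approx(g.gv_base[2] * g.gv_min_frac)

    def test_monotone_in_light(self):
        assert f.ground_vegetation_biomass(2, 1.0) >= f.ground_vegetation_biomass(2, 0.5)

    def test_fertile_sites_support_more_biomass(self):
        assert f.ground_vegetation_biomass(1, 0.8) >= f.ground_vegetation_biomass(5, 0.8)

    def test_light_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="light"):
            f.ground_vegetation_biomass(3, 1.5)
        with pytest.raises(ValueError, match="site_type"):
            f.ground_vegetation_biomass(7, 0.5)
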