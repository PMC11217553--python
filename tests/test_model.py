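"""Unit and property tests of the mass-balance ecosystem model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import carbonflux as cf
from carbonflux.model import (
    CompiledConfig,
    ForcingSeries,
    HetParams,
    ModelConfig,
    PhytoParams,
    dormancy_update,
    het_rates,
    limitation_factors_phyto,
    new_state,
    phyto_rates,
    pom_dissolution,
    remineralization,
    simulate,
    step,
)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

class TestLimitationFactors:
    def test_reference_temperature_gives_unit_factor(self):
        p = PhytoParams(q10=2.0, t_ref=15.0)
        f = limitation_factors_phyto(p, 15.0, 100.0, 12.0, 5.0, 0.5)
        assert f["f_T"] == pytest.approx(1.0)

    def test_half_saturation_nitrogen(self):
        p = PhytoParams(k_din=1.0)
        f = limitation_factors_phyto(p, 15.0, 100.0, 12.0, din=1.0, po4=0.5)
        assert f["f_N"] == pytest.approx(0.5)

    def test_saturating_light_limited_by_photoperiod(self):
        p = PhytoParams(k_light=30.0)
        f = limitation_factors_phyto(p, 15.0, 1e12, 12.0, 5.0, 0.5)
        assert f["f_I"] == pytest.approx(0.5, rel=1e-6)

    def test_cold_water_reduces_growth(self):
        p = PhytoParams(q10=2.0, t_ref=15.0)
        f = limitation_factors_phyto(p, 5.0, 100.0, 12.0, 5.0, 0.5)
        assert f["f_T"] == pytest.approx(0.5)

    def test_non_silicifier_reports_unit_silicate_factor(self):
        f = limitation_factors_phyto(PhytoParams(), 15.0, 100.0, 12.0,
                                     5.0, 0.5, si=0.0)
        assert f["f_Si"] == 1.0


class TestPhytoRates:
    def test_exudation_combines_basal_and_photosynthesis_fraction(self):
        p = PhytoParams(mu_max=2.0, ke=0.05, fe=0.1, kr=0.0, fr=0.0, kd=0.0)
        ones = {k: 1.0 for k in ("f_T", "f_I", "f_N", "f_P", "f_Si")}
        r = phyto_rates(p, 1.0, ones)
        assert r["photosynthesis"] == pytest.approx(2.0)
        assert r["exudation"] == pytest.approx(0.25)

    def test_zero_biomass_zero_rates(self):
        ones = {k: 1.0 for k in ("f_T", "f_I", "f_N", "f_P", "f_Si")}
        r = phyto_rates(PhytoParams(), 0.0, ones)
        assert all(v == 0.0 for v in r.values())

    def test_death_split_between_dom_and_pom(self):
        p = PhytoParams(mu_max=0.0, kd=0.1, f_dom=0.5, ke=0.0, kr=0.0)
        ones = {k: 1.0 for k in ("f_T", "f_I", "f_N", "f_P", "f_Si")}
        r = phyto_rates(p, 2.0, ones)
        assert r["death_dom"] == pytest.approx(0.1)
        assert r["death_pom"] == pytest.approx(0.1)


class TestHetRates:
    def test_saturating_substrate_reaches_vmax(self):
        h = HetParams(v_max=2.0, affinity={"d": 1.0}, t_ref=15.0)
        r = het_rates(h, 1.0, {"d": 1e9}, 15.0)
        assert sum(r["uptake"].values()) == pytest.approx(2.0, rel=1e-6)

    def test_half_saturation_substrate(self):
        h = HetParams(v_max=2.0, affinity={"d": 1.5}, t_ref=15.0)
        r = het_rates(h, 1.0, {"d": 1.5}, 15.0)
        assert sum(r["uptake"].values()) == pytest.approx(1.0)

    def test_growth_efficiency_splits_uptake(self):
        h = HetParams(v_max=1.0, affinity={"d": 1.0}, yield_=0.3, t_ref=15.0)
        r = het_rates(h, 1.0, {"d": 1e12}, 15.0)
        assert r["growth"] == pytest.approx(0.3, rel=1e-6)
        assert r["respiration"] == pytest.approx(0.7, rel=1e-6)

    def test_equal_weights_over_usable_species(self):
        h = HetParams(v_max=2.0, affinity={"a": 1.0, "b": 1.0}, t_ref=15.0)
        r = het_rates(h, 1.0, {"a": 1e9, "b": 1e9}, 15.0)
        assert r["uptake"]["a"] == pytest.approx(1.0, rel=1e-6)
        assert r["uptake"]["b"] == pytest.approx(1.0, rel=1e-6)


class TestRemineralization:
    def test_redfield_release_on_30pct_yield(self):
        rel = remineralization(1.0, 0.3, 16 / 106, 16 / 106)
        assert rel == pytest.approx(0.7 * 16 / 106)

    def test_zero_uptake_zero_release(self):
        assert remineralization(0.0, 0.0, 16 / 106, 16 / 106) == 0.0

    def test_nutrient_poor_substrate_creates_demand(self):
        assert remineralization(1.0, 0.3, 0.0, 16 / 106) < 0.0


class TestPomDissolution:
    @pytest.mark.parametrize("pom, k, alloc, expected", [
        (0.0, 0.05, {"d": 1.0}, {"d": 0.0}),
        (2.0, 0.05, {"d": 1.0}, {"d": 0.1}),
        (2.0, 0.05, {"a": 0.6, "b": 0.4}, {"a": 0.06, "b": 0.04}),
    ])
    def test_flux_distribution(self, pom, k, alloc, expected):
        out = pom_dissolution(pom, k, alloc)
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)


class TestDormancy:
    def test_growing_with_empty_dormant_pool_is_identity(self):
        h = HetParams(affinity={"d": 1.0}, dorm_out=0.3)
        assert dormancy_update(1.0, 0.0, h, +0.1, 1.0) == (1.0, 0.0)

    def test_shrinking_population_retreats(self):
        h = HetParams(affinity={"d": 1.0}, dorm_in=0.2)
        active, dormant = dormancy_update(1.0, 0.0, h, -0.1, 1.0)
        assert active == pytest.approx(0.8)
        assert dormant == pytest.approx(0.2)

    @given(st.floats(0.0, 10.0), st.floats(0.0, 10.0),
           st.floats(-1.0, 1.0), st.floats(0.01, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_transfer_conserves_total(self, active, dormant, mu, dt):
        h = HetParams(affinity={"d": 1.0}, dorm_in=0.4, dorm_out=0.4)
        a2, d2 = dormancy_update(active, dormant, h, mu, dt)
        assert a2 >= 0 and d2 >= 0
        assert a2 + d2 == pytest.approx(active + dormant, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# the Euler step
# ---------------------------------------------------------------------------

def _forcing_const(days=10.0, temp=15.0, par=40.0, dl=12.0):
    n = int(days) + 1
    d = np.linspace(0, days, n)
    return ForcingSeries(days=d, temperature=np.full(n, temp),
                         par=np.full(n, par), daylength=np.full(n, dl))


class TestStep:
    def test_pure_decay_matches_hand_euler(self):
        cfg = ModelConfig(
            phyto={"p": PhytoParams(mu_max=0.0, ke=0.0, kr=0.0, kd=0.3)},
            het={"h": HetParams(affinity={"d": 1e9}, v_max=0.0, kd=0.0)},
            dom_ids=["d"], k_dis=0.0, dt=0.1)
        state = new_state(cfg, {"p": 2.0}, {"h": 0.0}, dom_total=0.0,
                          pom_total=0.0)
        new, _ = step(state, CompiledConfig(cfg), 15.0, 40.0, 12.0, dt=0.1)
        assert new.bp[0] == pytest.approx(2.0 * (1 - 0.3 * 0.1))

    def test_overdraft_scales_outflows_to_empty_pool_exactly(self):
        # death demand alone is 2x the stock in one step
        cfg = ModelConfig(
            phyto={"p": PhytoParams(mu_max=0.0, ke=0.0, kr=0.0, kd=20.0,
                                    f_dom=0.5)},
            het={"h": HetParams(affinity={"d": 1e9}, v_max=0.0, kd=0.0)},
            dom_ids=["d"], k_dis=0.0, dt=0.1)
        state = new_state(cfg, {"p": 1.0}, {"h": 0.0}, dom_total=0.0,
                          pom_total=0.0)
        new, fl = step(state, CompiledConfig(cfg), 15.0, 40.0, 12.0, dt=0.1)
        assert new.bp[0] == pytest.approx(0.0, abs=1e-12)
        assert new.dom_src.sum() + new.pom_src.sum() == pytest.approx(1.0)
        assert (fl.death_dom_p[0] + fl.death_pom_p[0]) * 0.1 == pytest.approx(1.0)

    def test_closed_system_conserves_organic_carbon(self):
        # no phytoplankton, no respiration: yield 1, heterotrophs just cycle C
        cfg = ModelConfig(
            phyto={}, het={"h": HetParams(v_max=2.0, affinity={"d0": 0.5},
                                          yield_=1.0, kd=0.3, f_dom=0.6)},
            dom_ids=["d0", "d1"], k_dis=0.1, dt=0.05)
        state = new_state(cfg, {}, {"h": 1.0}, dom_total=3.0, pom_total=1.0,
                          no3=5.0, nh4=1.0, po4=0.5, si=0.0)
        comp = CompiledConfig(cfg)
        total0 = state.total_organic_c()
        cur = state
        for _ in range(1000):
            cur, _ = step(cur, comp, 18.0, 40.0, 12.0, dt=0.05)
        assert cur.total_organic_c() == pytest.approx(total0, rel=1e-9)

    def test_ledger_always_sums_to_pool(self, tiny_config, constant_forcing):
        state = new_state(tiny_config, {"p1": 1.0}, {"h1": 0.5})
        traj = simulate(tiny_config, constant_forcing, state, t1=50.0)
        assert np.allclose(traj.ledger_dom.sum(axis=2), traj.dom,
                           rtol=1e-12, atol=1e-12)
        assert np.allclose(traj.ledger_pom.sum(axis=1), traj.pom,
                           rtol=1e-12, atol=1e-12)

    def test_all_pools_stay_nonnegative(self, tiny_config, constant_forcing):
        state = new_state(tiny_config, {"p1": 5.0}, {"h1": 2.0},
                          no3=0.2, nh4=0.05, po4=0.02, si=0.1)
        traj = simulate(tiny_config, constant_forcing, state, t1=200.0)
        for arr in (traj.bp, traj.ba, traj.bd, traj.dom, traj.pom,
                    traj.nutrients):
            assert np.all(arr >= 0)

    @given(st.floats(0.0, 20.0), st.floats(0.0, 20.0), st.floats(0.0, 20.0),
           st.floats(0.0, 10.0))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_step_conserves_carbon_from_random_states(self, b_p, b_h, dom,
                                                      pom):
        cfg = ModelConfig(
            phyto={"p": PhytoParams()},
            het={"h": HetParams(affinity={"d0": 1.0})},
            dom_ids=["d0", "d1"], k_dis=0.08, dt=0.1)
        state = new_state(cfg, {"p": b_p}, {"h": b_h}, dom_total=dom,
                          pom_total=pom, no3=3.0, nh4=0.5, po4=0.3, si=1.0)
        comp = CompiledConfig(cfg)
        before = state.total_organic_c() + state.exported_c
        new, fl = step(state, comp, 14.0, 30.0, 12.0, dt=0.1)
        after = new.total_organic_c() + new.exported_c
        supplied = fl.photosynthesis.sum() * 0.1
        assert after - before == pytest.approx(supplied, rel=1e-9, abs=1e-12)
        assert np.all(new.bp >= 0) and np.all(new.dom_src >= 0)

    def test_nutrient_conservation_with_loadings(self, tiny_config):
        n = 101
        days = np.linspace(0, 100.0, n)
        forcing = ForcingSeries(days=days, temperature=np.full(n, 12.0),
                                par=np.full(n, 30.0), daylength=np.full(n, 12.0),
                                load_no3=np.full(n, 0.05),
                                load_po4=np.full(n, 0.004))
        state = new_state(tiny_config, {"p1": 1.0}, {"h1": 0.5})
        n0 = state.total_n(tiny_config)
        p0 = state.total_p(tiny_config)
        comp = CompiledConfig(tiny_config)
        cur = state
        for i in range(1000):
            cur, _ = step(cur, comp, 12.0, 30.0, 12.0, dt=0.1,
                          load_no3=0.05, load_po4=0.004)
        assert cur.total_n(tiny_config) - cur.loaded_n == pytest.approx(
            n0, rel=1e-9)
        assert cur.total_p(tiny_config) - cur.loaded_p == pytest.approx(
            p0, rel=1e-9)


class TestSimulate:
    def test_determinism_bitwise(self, tiny_config, constant_forcing):
        state = new_state(tiny_config, {"p1": 1.0}, {"h1": 0.5})
        t1 = simulate(tiny_config, constant_forcing, state, t1=60.0)
        t2 = simulate(tiny_config, constant_forcing, state, t1=60.0)
        assert np.array_equal(t1.bp, t2.bp)
        assert np.array_equal(t1.ledger_dom, t2.ledger_dom)
        assert np.array_equal(t1.flux["uptake"], t2.flux["uptake"])

    def test_halving_dt_reduces_error(self):
        from carbonflux.experiments import exponential_growth_error

        coarse = exponential_growth_error(dt=0.2)
        fine = exponential_growth_error(dt=0.1)
        assert fine < coarse

    def test_missing_forcing_span_raises(self, tiny_config, constant_forcing):
        state = new_state(tiny_config, {"p1": 1.0}, {"h1": 0.5})
        with pytest.raises(ValueError, match="forcing"):
            simulate(tiny_config, constant_forcing, state, t1=1e4)

    def test_flux_records_table_shape(self, tiny_config, constant_forcing):
        state = new_state(tiny_config, {"p1": 1.0}, {"h1": 0.5})
        traj = simulate(tiny_config, constant_forcing, state, t1=10.0)
        records = traj.flux_records()
        assert set(records["process"]) <= {
            "photosynthesis", "exudation", "death_dom", "death_pom",
            "dissolution", "sinking", "uptake", "respiration",
            "remineralization", "loading"}
        assert (records.loc[~records["nutrient"], "value"] >= 0).all()


class TestValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fe"):
            PhytoParams(fe=1.5).validate()

    def test_empty_affinity_rejected(self):
        with pytest.raises(ValueError, match="affinity"):
            HetParams(affinity={}).validate()

    def test_unknown_dom_species_rejected(self):
        cfg = ModelConfig(phyto={}, het={"h": HetParams(affinity={"x": 1.0})},
                          dom_ids=["d0"])
        with pytest.raises(ValueError, match="unknown DOM"):
            cfg.validate()

    def test_dom_quota_above_biomass_rejected(self):
        cfg = ModelConfig(phyto={}, het={"h": HetParams(affinity={"d0": 1.0})},
                          dom_ids=["d0"], q_n_dom={"d0": 0.5})
        with pytest.raises(ValueError, match="quota"):
            cfg.validate()

    def test_config_roundtrip_through_dict(self, tiny_config):
        clone = ModelConfig.from_dict(tiny_config.to_dict())
        assert clone.to_dict() == tiny_config.to_dict()
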