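"""Tests of bloom detection, flux attribution and derived metrics."""

import numpy as np
import pandas as pd
import pytest

import carbonflux as cf
from carbonflux import fluxes as fx
from carbonflux.model import (
    CompiledConfig,
    ForcingSeries,
    HetParams,
    ModelConfig,
    PhytoParams,
    new_state,
    simulate,
)


def _series(values, start="2012-01-01", freq="7D"):
    idx = pd.date_range(start, periods=len(values), freq=freq)
    return pd.Series(values, index=idx)


# ---------------------------------------------------------------------------
# bloom detection
# ---------------------------------------------------------------------------

class TestDetectBlooms:
    def test_default_duration_when_concentration_stays_high(self):
        # ramp into a mid-March peak, then a slow decline that never falls
        # below the start concentration within 28 days
        vals = [1.0, 1.2, 1.1, 2.0, 4.0, 8.0, 12.0, 11.0, 10.0, 9.5, 9.0, 9.0]
        s = _series(vals, start="2012-02-01")
        w = fx.detect_blooms(s, "phyto_spring", 2012)
        assert w.duration == 28
        assert str(w.peak_date)[:10] == "2012-03-14"

    def test_ends_early_when_below_start_concentration(self):
        idx = pd.date_range("2012-02-01", periods=40, freq="D")
        vals = np.concatenate([
            np.linspace(2.0, 2.0, 5),       # flat lead-in
            np.linspace(2.0, 10.0, 8),      # bloom build-up
            np.linspace(10.0, 0.5, 9),      # crash below start at some day
            np.full(18, 0.4)])
        s = pd.Series(vals, index=idx)
        w = fx.detect_blooms(s, "phyto_spring", 2012)
        assert w.duration < 28
        assert float(s.loc[pd.Timestamp(str(w.end_date)[:10])]) < \
            float(s.loc[pd.Timestamp(str(w.start_date)[:10])])

    def test_flat_series_warns_and_uses_prepeak_minimum(self):
        s = _series(np.linspace(5.0, 6.0, 20), start="2012-01-01")
        with pytest.warns(UserWarning, match="no local minimum"):
            w = fx.detect_blooms(s, "phyto_spring", 2012)
        assert w.start_date <= w.peak_date <= w.end_date

    def test_no_data_in_window_returns_none(self):
        s = _series([1.0, 2.0], start="2012-10-01")
        assert fx.detect_blooms(s, "phyto_summer", 2012) is None

    def test_duration_override(self):
        vals = [1.0, 1.2, 1.1, 2.0, 4.0, 8.0, 12.0, 11.0, 10.0, 9.5, 9.0, 9.0]
        s = _series(vals, start="2012-02-01")
        w = fx.detect_blooms(s, "phyto_spring", 2012, duration_override=42)
        assert w.duration == 42

    def test_invariant_duration_never_exceeds_default(self, truth_run):
        _, traj, _, blooms = truth_run
        assert all(b.duration <= fx.DEFAULT_BLOOM_DURATION for b in blooms)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="bloom type"):
            fx.detect_blooms(_series([1.0, 2.0]), "autumn", 2012)


# ---------------------------------------------------------------------------
# pairwise attribution
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_producer_run():
    """One phytoplankton feeding dom0, heterotroph death feeding dom1."""
    cfg = ModelConfig(
        phyto={"p": PhytoParams(mu_max=1.2, k_din=0.5, ke=0.05, fe=0.1,
                                kd=0.1, f_dom=0.6, dom_alloc={"d0": 1.0})},
        het={"h1": HetParams(v_max=2.0, affinity={"d0": 1.0, "d1": 1.0},
                             yield_=0.3, kd=0.3, f_dom=0.6,
                             dom_alloc={"d1": 1.0}),
             "h2": HetParams(v_max=1.5, affinity={"d1": 0.5}, yield_=0.3,
                             kd=0.2, f_dom=0.5, dom_alloc={"d1": 1.0})},
        dom_ids=["d0", "d1"], k_dis=0.05,
        pom_alloc={"d0": 0.5, "d1": 0.5}, dt=0.05)
    n = 121
    days = np.linspace(0, 120.0, n)
    forcing = ForcingSeries(days=days, temperature=np.full(n, 16.0),
                            par=np.full(n, 40.0), daylength=np.full(n, 14.0))
    state = new_state(cfg, {"p": 2.0}, {"h1": 0.5, "h2": 0.3},
                      dom_total=1.0, pom_total=0.2, no3=8.0, nh4=0.5,
                      po4=0.6, si=2.0)
    traj = simulate(cfg, forcing, state, t1=120.0,
                    start_date="2012-01-01")
    return traj


class TestPairwiseFluxes:
    def test_attribution_conserves_total_uptake(self, two_producer_run):
        traj = two_producer_run
        pairwise = fx.pairwise_fluxes(traj)
        per_time = pairwise.groupby(["time", "consumer"])["flux"].sum()
        mids = traj.bin_mid_times()
        for i, h in enumerate(traj.het_ids):
            total = traj.flux["uptake"][:, i, :].sum(axis=1)
            got = per_time.reindex(
                [(t, h) for t in mids], fill_value=0.0).to_numpy()
            assert np.allclose(got, total, rtol=1e-9, atol=1e-12)

    def test_single_source_pool_fully_attributed(self):
        # only the phytoplankton feeds dom0 and only h eats it
        cfg = ModelConfig(
            phyto={"p": PhytoParams(mu_max=1.0, ke=0.1, fe=0.1, kd=0.0,
                                    dom_alloc={"d0": 1.0})},
            het={"h": HetParams(v_max=1.0, affinity={"d0": 0.5}, yield_=0.3,
                                kd=0.0, dom_alloc={"d0": 1.0})},
            dom_ids=["d0"], k_dis=0.0, dt=0.05)
        n = 31
        forcing = ForcingSeries(days=np.linspace(0, 30, n),
                                temperature=np.full(n, 15.0),
                                par=np.full(n, 40.0),
                                daylength=np.full(n, 12.0))
        state = new_state(cfg, {"p": 1.0}, {"h": 0.5}, dom_total=0.0,
                          pom_total=0.0, no3=20.0, nh4=0.0, po4=2.0)
        traj = simulate(cfg, forcing, state, t1=30.0, start_date="2012-01-01")
        pairwise = fx.pairwise_fluxes(traj)
        late = pairwise[pairwise["time"] > 5.0]
        assert set(late.loc[late["flux"] > 0, "producer"]) == {"p"}

    def test_mixed_pool_split_by_ledger_fractions(self, two_producer_run):
        pairwise = fx.pairwise_fluxes(two_producer_run)
        by_class = pairwise.groupby("producer_class")["flux"].sum()
        assert by_class.get("phytoplankton", 0.0) > 0
        assert by_class.get("heterotroph", 0.0) > 0

    def test_tampered_ledger_raises_integrity_error(self, two_producer_run):
        import copy

        broken = copy.copy(two_producer_run)
        broken.ledger_dom = two_producer_run.ledger_dom * 1.5
        with pytest.raises(fx.FluxIntegrityError):
            fx.pairwise_fluxes(broken)


# ---------------------------------------------------------------------------
# aggregation and metrics
# ---------------------------------------------------------------------------

def _pairwise_frame(times, p2h, h2h):
    rows = [pd.DataFrame({"time": times, "producer": "p", "consumer": "h",
                          "producer_class": "phytoplankton", "flux": p2h}),
            pd.DataFrame({"time": times, "producer": "h2", "consumer": "h",
                          "producer_class": "heterotroph", "flux": h2h})]
    return pd.concat(rows, ignore_index=True)


class TestAggregateBloomFluxes:
    def test_constant_flux_mean(self):
        times = np.arange(28) + 0.5
        agg = fx.aggregate_bloom_fluxes(
            _pairwise_frame(times, np.full(28, 0.2), np.zeros(28)), (0, 28))
        assert agg["phyto_to_het"] == pytest.approx(0.2)

    def test_linear_ramp_mean(self):
        times = np.arange(28) + 0.5
        ramp = 0.28 * times / 28.0
        agg = fx.aggregate_bloom_fluxes(
            _pairwise_frame(times, ramp, np.zeros(28)), (0, 28))
        assert agg["phyto_to_het"] == pytest.approx(0.14, rel=0.01)

    def test_weekly_bins_partition_window(self):
        times = np.arange(28) + 0.5
        rng = np.random.default_rng(0)
        p2h = rng.uniform(0.0, 1.0, 28)
        agg = fx.aggregate_bloom_fluxes(
            _pairwise_frame(times, p2h, np.zeros(28)), (0, 28))
        assert agg["week_start_day"] == [0, 7, 14, 21]
        assert np.mean(agg["weekly_phyto_to_het"]) == pytest.approx(
            agg["phyto_to_het"])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fx.aggregate_bloom_fluxes(
                _pairwise_frame(np.array([1.0]), [0.1], [0.1]), (5.0, 5.0))


class TestProductionMetrics:
    def test_zero_biomass_zero_metrics(self, tiny_config, constant_forcing):
        state = new_state(tiny_config, {"p1": 0.0}, {"h1": 0.0},
                          dom_total=0.0, pom_total=0.0)
        traj = simulate(tiny_config, constant_forcing, state, t1=20.0)
        met = fx.production_metrics(traj)
        assert met["gpp"] == 0.0 and met["gross_het_prod"] == 0.0

    def test_areal_conversion(self, two_producer_run):
        met = fx.production_metrics(two_producer_run, depth_m=50.0)
        assert met["gpp_areal"] == pytest.approx(met["gpp"] * 50.0)

    def test_npp_never_exceeds_gpp(self, two_producer_run):
        met = fx.production_metrics(two_producer_run)
        assert met["npp"] <= met["gpp"]

    def test_bad_depth_rejected(self, two_producer_run):
        with pytest.raises(ValueError):
            fx.production_metrics(two_producer_run, depth_m=0.0)


class TestNormalizedHeterotrophy:
    def test_hand_value(self):
        assert fx.normalized_heterotrophy(0.1, 0.5, 10.0) == pytest.approx(0.02)

    def test_zero_uptake(self):
        assert fx.normalized_heterotrophy(0.0, 0.5, 10.0) == 0.0

    def test_doubling_doc_halves_rate(self):
        one = fx.normalized_heterotrophy(0.1, 0.5, 10.0)
        two = fx.normalized_heterotrophy(0.1, 0.5, 20.0)
        assert two == pytest.approx(one / 2)

    def test_zero_denominator_flagged(self):
        with pytest.raises(ValueError):
            fx.normalized_heterotrophy(0.1, 0.0, 10.0)


def _ratio_run(f_dom: float):
    cfg = ModelConfig(
        phyto={"p": PhytoParams(mu_max=1.0, kd=0.05)},
        het={"h": HetParams(v_max=2.0, affinity={"d0": 1.0}, kd=0.3,
                            f_dom=f_dom)},
        dom_ids=["d0"], dt=0.05)
    n = 61
    forcing = ForcingSeries(days=np.linspace(0, 60, n),
                            temperature=np.full(n, 16.0),
                            par=np.full(n, 40.0), daylength=np.full(n, 12.0))
    state = new_state(cfg, {"p": 1.0}, {"h": 1.0}, no3=5.0, po4=0.5)
    return simulate(cfg, forcing, state, t1=60.0)


class TestDomPomReleaseRatio:
    @pytest.mark.parametrize("f_dom, expected, lysis", [
        (0.5, 1.0, False),
        (0.3, 3.0 / 7.0, False),
        (0.533, 0.533 / 0.467, True),
    ])
    def test_ratio_reflects_death_split(self, f_dom, expected, lysis):
        out = fx.dom_pom_release_ratio(_ratio_run(f_dom))
        assert out["ratio"] == pytest.approx(expected, rel=1e-6)
        assert out["lysis_dominated"] is lysis

    def test_ratio_above_one_iff_mean_fdom_above_half(self, truth_run):
        _, traj, _, _ = truth_run
        out = fx.dom_pom_release_ratio(traj)
        f_doms = [h.f_dom for h in traj.config.het.values()]
        assert out["lysis_dominated"] == (np.mean(f_doms) > 0.5)

    def test_no_pom_release_undefined(self):
        out = fx.dom_pom_release_ratio(_ratio_run(1.0))
        assert not out["defined"]


class TestLimitationTimeseries:
    def test_recomputed_factors_match_recorded(self, two_producer_run):
        traj = two_producer_run
        table = fx.limitation_timeseries(traj, taxa=["p"])
        rec = traj.phyto_factors[:, 0, :]
        got = table[["f_T", "f_I", "f_N", "f_P", "f_Si"]].to_numpy()
        assert np.allclose(got, rec, rtol=1e-9, atol=1e-12)

    def test_replete_conditions_unlimited(self):
        p = PhytoParams(q10=2.0, t_ref=15.0, k_light=10.0)
        f = cf.limitation_factors_phyto(p, 15.0, 1e12, 24.0, 1e12, 1e12)
        assert all(f[k] == pytest.approx(1.0) for k in
                   ("f_T", "f_I", "f_N", "f_P", "f_Si"))

    def test_most_limiting_identified(self):
        p = PhytoParams(k_din=1.0, q10=2.0, t_ref=15.0, k_light=10.0)
        f = cf.limitation_factors_phyto(p, 15.0, 1e12, 24.0, 1.0, 1e12)
        considered = {k: f[k] for k in ("f_T", "f_I", "f_N", "f_P")}
        assert min(considered, key=considered.get) == "f_N"
        assert f["f_N"] == pytest.approx(0.5)

    def test_default_selection_topk(self, truth_run):
        _, traj, _, _ = truth_run
        table = fx.limitation_timeseries(traj, top_k=2)
        assert table["taxon"].nunique() == 4      # 2 phyto + 2 het


class TestNetworkSnapshot:
    def test_snapshot_nodes_and_flux_balance(self, two_producer_run):
        g = fx.network_snapshot(two_producer_run, day=60.0)
        classes = {d["node_class"] for _, d in g.nodes(data=True)}
        assert {"phytoplankton", "heterotroph", "DOM", "POM"} <= classes
        assert all(d["flux"] >= 0 for *_, d in g.edges(data=True))
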