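"""Flux-network analyses on simulated trajectories.

Turns a :class:`~carbonflux.model.Trajectory` into the quantities the study
design is after: producer-attributed pairwise carbon fluxes (who fed whom,
via the DOM source ledgers), typed bloom windows on concentration series,
bloom-averaged and weekly flux aggregates, primary/heterotrophic production
metrics, DOC-normalized heterotrophy rates, the DOM/POM death-release ratio
(a viral-lysis indicator), and per-taxon limitation-factor time series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    FluxIntegrityError,
    Trajectory,
    limitation_factors_phyto,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BloomWindow",
    "pairwise_fluxes",
    "detect_blooms",
    "window_days",
    "aggregate_bloom_fluxes",
    "production_metrics",
    "normalized_heterotrophy",
    "normalized_heterotrophy_series",
    "dom_pom_release_ratio",
    "limitation_timeseries",
    "network_snapshot",
]

BLOOM_SEARCH_WINDOWS = {
    "phyto_spring": (2, 5),      # February–May, chlorophyll
    "phyto_summer": (7, 8),      # July–August, chlorophyll
    "bacteria_summer": (6, 8),   # June–August, heterotroph concentration
}
DEFAULT_BLOOM_DURATION = 28      # days


@dataclass(frozen=True)
class BloomWindow:
    """A typed bloom interval around a seasonal concentration maximum."""

    bloom_type: str
    peak_date: np.datetime64
    start_date: np.datetime64
    end_date: np.datetime64

    @property
    def duration(self) -> int:
        return int((self.end_date - self.start_date) / np.timedelta64(1, "D"))

    def __post_init__(self):
        if not (self.start_date <= self.peak_date <= self.end_date):
            raise ValueError("bloom window requires start <= peak <= end")


# ---------------------------------------------------------------------------
# Producer-attributed pairwise fluxes
# ---------------------------------------------------------------------------

def pairwise_fluxes(traj: Trajectory, ledger_tol: float = 1e-6) -> pd.DataFrame:
    """Attribute every unit of heterotrophic DOM uptake to its producer.

    For consumer ``h`` taking up DOM species ``j`` during an output bin, the
    flux credited to producer ``p`` is the uptake times the ledger fraction of
    ``p`` in pool ``j`` (averaged over the bin endpoints).  Returns a tidy
    table (time, producer, consumer, producer_class, flux µmol C L⁻¹ d⁻¹);
    producer classes are phytoplankton, heterotroph, or external for the
    initial background DOM.
    """
    # integrity: ledger must sum to the pool it describes
    led_tot = traj.ledger_dom.sum(axis=2)
    mism = np.abs(led_tot - traj.dom)
    scale = np.maximum(traj.dom, 1.0)
    if np.any(mism > ledger_tol * scale):
        raise FluxIntegrityError("DOM source ledger does not sum to pool mass")

    led_mean = 0.5 * (traj.ledger_dom[:-1] + traj.ledger_dom[1:])  # (B, n_dom, n_src)
    tot = led_mean.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tot > 0, led_mean / np.maximum(tot, 1e-300), 0.0)
    uptake = traj.flux["uptake"]                    # (B, n_h, n_dom)
    attributed = np.einsum("bhj,bjs->bsh", uptake, frac)  # (B, n_src, n_h)

    mids = traj.bin_mid_times()
    n_p = len(traj.phyto_ids)
    classes = (["phytoplankton"] * n_p
               + ["heterotroph"] * len(traj.het_ids) + ["external"])
    rows = []
    for s, sid in enumerate(traj.source_ids):
        for h, hid in enumerate(traj.het_ids):
            col = attributed[:, s, h]
            if not np.any(col > 0):
                continue
            rows.append(pd.DataFrame({
                "time": mids, "producer": sid, "consumer": hid,
                "producer_class": classes[s], "flux": col,
            }))
    if not rows:
        return pd.DataFrame(columns=["time", "producer", "consumer",
                                     "producer_class", "flux"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Bloom detection
# ---------------------------------------------------------------------------

def detect_blooms(series: pd.Series, bloom_type: str, year: int,
                  max_duration: int = DEFAULT_BLOOM_DURATION,
                  start_override: "np.datetime64 | str | None" = None,
                  duration_override: int | None = None) -> BloomWindow | None:
    """Locate one typed bloom in a concentration series (DatetimeIndex).

    The peak is the maximum inside the type's seasonal search window; the
    start is the latest local minimum before the peak (override supported, as
    starts are operationally assigned); the bloom ends ``max_duration`` days
    after the start unless the concentration falls back below the starting
    concentration first.  Returns None when the search window holds no data
    (some years have no pronounced summer bloom).
    """
    if bloom_type not in BLOOM_SEARCH_WINDOWS:
        raise ValueError(f"unknown bloom type {bloom_type!r}")
    series = series.dropna().sort_index()
    m0, m1 = BLOOM_SEARCH_WINDOWS[bloom_type]
    in_win = series[(series.index.year == year)
                    & (series.index.month >= m0) & (series.index.month <= m1)]
    if in_win.empty:
        logger.info("no data for %s in %d: no bloom assigned", bloom_type, year)
        return None
    peak_date = in_win.idxmax()

    if start_override is not None:
        start_date = pd.Timestamp(start_override)
        if start_date > peak_date:
            raise ValueError("start override lies after the detected peak")
    else:
        # latest local minimum in the max_duration days leading up to the peak
        # (so the default-duration window still contains the peak)
        duration = duration_override if duration_override is not None \
            else max_duration
        lo = peak_date - pd.Timedelta(days=duration)
        before = series[(series.index >= lo) & (series.index < peak_date)]
        start_date = None
        vals, idx = before.to_numpy(), before.index
        for i in range(len(vals) - 1, 0, -1):
            right = vals[i + 1] if i + 1 < len(vals) else series.loc[peak_date]
            if vals[i] <= vals[i - 1] and vals[i] <= right:
                start_date = idx[i]
                break
        if start_date is None:
            if len(before):
                start_date = before.idxmin()
            else:
                start_date = peak_date
            warnings.warn(
                f"no local minimum before {bloom_type} peak in {year}; "
                "using the pre-peak minimum", stacklevel=2)

    duration = duration_override if duration_override is not None else max_duration
    end_date = start_date + pd.Timedelta(days=duration)
    start_value = float(series.asof(start_date))
    after_peak = series[(series.index > peak_date) & (series.index <= end_date)]
    below = after_peak[after_peak < start_value]
    if not below.empty:
        end_date = below.index[0]
    return BloomWindow(bloom_type=bloom_type,
                       peak_date=np.datetime64(peak_date, "s"),
                       start_date=np.datetime64(pd.Timestamp(start_date), "s"),
                       end_date=np.datetime64(pd.Timestamp(end_date), "s"))


def window_days(window: BloomWindow, start_date: np.datetime64
                ) -> tuple[float, float]:
    """Convert a bloom window to (start, end) in days since ``start_date``."""
    day = np.timedelta64(1, "D")
    return (float((window.start_date - np.datetime64(start_date, "s")) / day),
            float((window.end_date - np.datetime64(start_date, "s")) / day))


# ---------------------------------------------------------------------------
# Bloom-aggregated fluxes
# ---------------------------------------------------------------------------

def aggregate_bloom_fluxes(pairwise: pd.DataFrame,
                           span: tuple[float, float]) -> dict:
    """Bloom-mean and weekly producer-class fluxes inside ``span`` (days).

    Returns bloom means of phytoplankton→heterotroph and
    heterotroph→heterotroph flux (µmol C L⁻¹ d⁻¹) plus weekly means over
    7-day bins anchored at the bloom start (the bins partition the window, so
    their duration-weighted mean equals the bloom mean).
    """
    t0, t1 = span
    if not t1 > t0:
        raise ValueError("empty bloom window")
    sel = pairwise[(pairwise["time"] >= t0) & (pairwise["time"] < t1)]
    if sel.empty:
        raise ValueError("bloom window contains no flux records")

    def class_rate(df: pd.DataFrame, cls: str) -> pd.Series:
        sub = df[df["producer_class"] == cls]
        return sub.groupby("time")["flux"].sum()

    times = np.sort(sel["time"].unique())
    p2h = class_rate(sel, "phytoplankton").reindex(times, fill_value=0.0)
    h2h = class_rate(sel, "heterotroph").reindex(times, fill_value=0.0)
    week = np.floor((times - t0) / 7.0).astype(int)
    weekly_p2h, weekly_h2h, week_start = [], [], []
    for w in np.unique(week):
        mask = week == w
        weekly_p2h.append(float(p2h.to_numpy()[mask].mean()))
        weekly_h2h.append(float(h2h.to_numpy()[mask].mean()))
        week_start.append(int(7 * w))
    return {
        "phyto_to_het": float(p2h.mean()),
        "het_to_het": float(h2h.mean()),
        "week_start_day": week_start,
        "weekly_phyto_to_het": weekly_p2h,
        "weekly_het_to_het": weekly_h2h,
        "n_times": len(times),
    }


# ---------------------------------------------------------------------------
# Production metrics and rate normalizations
# ---------------------------------------------------------------------------

def production_metrics(traj: Trajectory, depth_m: float = 50.0,
                       span: tuple[float, float] | None = None) -> dict:
    """Gross/net primary and heterotrophic production over a time span.

    Volumetric rates are time means in µmol C L⁻¹ d⁻¹; areal rates multiply by
    the integration depth (1 µmol L⁻¹ d⁻¹ ≡ 1 mmol m⁻³ d⁻¹, so areal =
    volumetric × depth in mmol C m⁻² d⁻¹).
    """
    if depth_m <= 0:
        raise ValueError("depth_m must be positive")
    mids = traj.bin_mid_times()
    mask = np.ones_like(mids, dtype=bool) if span is None else \
        (mids >= span[0]) & (mids < span[1])
    if not mask.any():
        raise ValueError("span contains no output bins")
    gpp = float(traj.flux["photosynthesis"][mask].sum(axis=1).mean())
    resp_p = float(traj.flux["resp_p"][mask].sum(axis=1).mean())
    ghp = float(traj.flux["growth"][mask].sum(axis=1).mean())
    death_h = float((traj.flux["death_dom_h"][mask]
                     + traj.flux["death_pom_h"][mask]).sum(axis=1).mean())
    out = {
        "gpp": gpp,
        "npp": gpp - resp_p,
        "gross_het_prod": ghp,
        "net_het_prod": ghp - death_h,
    }
    out.update({f"{k}_areal": v * depth_m for k, v in list(out.items())})
    return out


def normalized_heterotrophy(uptake: float, het_c: float, doc: float) -> float:
    """DOC-concentration-normalized heterotrophy rate, L mol⁻¹ d⁻¹.

    ``uptake`` in mol C L⁻¹ d⁻¹ divided by heterotroph carbon and DOC
    concentration (both mol C L⁻¹).
    """
    if uptake == 0:
        return 0.0
    if het_c <= 0 or doc <= 0:
        raise ValueError("het_c and doc must be positive for a nonzero uptake")
    return uptake / (het_c * doc)


def normalized_heterotrophy_series(traj: Trajectory) -> pd.Series:
    """Per-bin normalized heterotrophy of the whole community, L mol⁻¹ d⁻¹."""
    uptake = traj.flux["uptake"].sum(axis=(1, 2)) * 1e-6          # mol C L⁻¹ d⁻¹
    het = 0.5 * (traj.total_het_c()[:-1] + traj.total_het_c()[1:]) * 1e-6
    doc = 0.5 * (traj.doc()[:-1] + traj.doc()[1:]) * 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where((het > 0) & (doc > 0), uptake / (het * doc), np.nan)
    return pd.Series(rate, index=traj.bin_mid_times(), name="normalized_heterotrophy")


def dom_pom_release_ratio(traj: Trajectory, taxa: list[str] | None = None,
                          span: tuple[float, float] | None = None) -> dict:
    """Ratio of death-released DOM to death-released POM for heterotroph taxa.

    A ratio above 1 indicates DOM-dominated release, consistent with viral
    lysis as the predominant death mechanism (protist grazing would route
    carbon mainly to POM).
    """
    mids = traj.bin_mid_times()
    mask = np.ones_like(mids, dtype=bool) if span is None else \
        (mids >= span[0]) & (mids < span[1])
    idx = [traj.het_ids.index(t) for t in taxa] if taxa is not None \
        else list(range(len(traj.het_ids)))
    dom_rel = float(traj.flux["death_dom_h"][mask][:, idx].sum())
    pom_rel = float(traj.flux["death_pom_h"][mask][:, idx].sum())
    if pom_rel == 0:
        return {"ratio": np.nan, "lysis_dominated": None, "defined": False}
    ratio = dom_rel / pom_rel
    return {"ratio": ratio, "lysis_dominated": bool(ratio > 1), "defined": True}


# ---------------------------------------------------------------------------
# Limitation analyses
# ---------------------------------------------------------------------------

def limitation_timeseries(traj: Trajectory, top_k: int = 5,
                          taxa: list[str] | None = None) -> pd.DataFrame:
    """Recompute per-taxon limitation factors from the stored trajectory.

    Phytoplankton get temperature, light, nitrogen, phosphorus (and silicate
    for silicifiers) factors recomputed from the stored forcing and nutrient
    states; heterotrophs get the temperature factor and the aggregate
    substrate (DOM Monod) factor.  The most limiting factor per date is
    flagged.  Defaults to the ``top_k`` taxa of each class by mean carbon.
    """
    cfg = traj.config
    if taxa is None:
        p_rank = np.argsort(-traj.bp.mean(axis=0))[:top_k]
        h_rank = np.argsort(-(traj.ba + traj.bd).mean(axis=0))[:top_k]
        taxa = [traj.phyto_ids[i] for i in p_rank] + [traj.het_ids[i] for i in h_rank]
    rows = []
    for tid in taxa:
        if tid in traj.phyto_ids:
            params = cfg.phyto[tid]
            for k, t in enumerate(traj.times):
                temp, par, dl = traj.forcing[k]
                no3, nh4, po4, si = traj.nutrients[k]
                f = limitation_factors_phyto(params, temp, par, dl,
                                             no3 + nh4, po4, si)
                considered = {"f_T": f["f_T"], "f_I": f["f_I"],
                              "f_N": f["f_N"], "f_P": f["f_P"]}
                if params.silicifier:
                    considered["f_Si"] = f["f_Si"]
                most = min(considered, key=considered.get)
                rows.append({"time": float(t), "taxon": tid, "taxon_class":
                             "phytoplankton", **f, "most_limiting": most})
        elif tid in traj.het_ids:
            i = traj.het_ids.index(tid)
            params = cfg.het[tid]
            for k, t in enumerate(traj.times):
                temp = traj.forcing[k, 0]
                f_t = min(1.0, params.q10 ** ((temp - params.t_ref) / 10.0))
                dom = {d: traj.ledger_dom[k, j].sum()
                       for j, d in enumerate(traj.dom_ids)}
                f_s = sum((dom[j] / (dom[j] + kj) if dom[j] > 0 else 0.0)
                          for j, kj in params.affinity.items()) / len(params.affinity)
                most = "f_T" if f_t <= f_s else "f_substrate"
                rows.append({"time": float(t), "taxon": tid,
                             "taxon_class": "heterotroph", "f_T": f_t,
                             "f_substrate": f_s, "most_limiting": most})
        else:
            raise KeyError(f"unknown taxon {tid!r}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Network snapshots
# ---------------------------------------------------------------------------

def network_snapshot(traj: Trajectory, day: float):
    """Flux network for the output bin containing ``day`` (a networkx DiGraph).

    Nodes carry the class and the size convention used for display: carbon
    outflow for phytoplankton, inflow for heterotrophs, throughflow (mean of
    inflow and outflow) for DOM and POM.  Edges carry the bin-mean flux.
    """
    import networkx as nx

    mids = traj.bin_mid_times()
    k = int(np.clip(np.searchsorted(mids, day), 0, len(mids) - 1))
    fl = traj.flux
    g = nx.DiGraph(day=float(mids[k]))
    for i, p in enumerate(traj.phyto_ids):
        outflow = float(fl["exudation"][k, i] + fl["death_dom_p"][k, i]
                        + fl["death_pom_p"][k, i])
        g.add_node(p, node_class="phytoplankton", size=outflow)
    from .model import CompiledConfig

    comp = CompiledConfig(traj.config)
    dom_in = np.zeros(len(traj.dom_ids))
    for i, p in enumerate(traj.phyto_ids):
        rel = float(fl["exudation"][k, i] + fl["death_dom_p"][k, i])
        for j, d in enumerate(traj.dom_ids):
            v = rel * comp.A_p[i, j]
            if v > 0:
                g.add_edge(p, d, flux=v)
                dom_in[j] += v
        v = float(fl["death_pom_p"][k, i])
        if v > 0:
            g.add_edge(p, "POM", flux=v)
    for i, h in enumerate(traj.het_ids):
        rel = float(fl["death_dom_h"][k, i])
        for j, d in enumerate(traj.dom_ids):
            v = rel * comp.A_h[i, j]
            if v > 0:
                g.add_edge(h, d, flux=v)
                dom_in[j] += v
        v = float(fl["death_pom_h"][k, i])
        if v > 0:
            g.add_edge(h, "POM", flux=v)
    dis = float(fl["dissolution"][k].sum())
    if dis > 0:
        for j, d in enumerate(traj.dom_ids):
            v = dis * comp.pom_alloc[j]
            if v > 0:
                g.add_edge("POM", d, flux=v)
                dom_in[j] += v
    dom_out = traj.flux["uptake"][k].sum(axis=0)
    for j, d in enumerate(traj.dom_ids):
        g.add_node(d, node_class="DOM", size=0.5 * (dom_in[j] + float(dom_out[j])))
        for i, h in enumerate(traj.het_ids):
            v = float(traj.flux["uptake"][k, i, j])
            if v > 0:
                g.add_edge(d, h, flux=v)
    pom_in = float(fl["death_pom_p"][k].sum() + fl["death_pom_h"][k].sum())
    g.add_node("POM", node_class="POM", size=0.5 * (pom_in + dis))
    for i, h in enumerate(traj.het_ids):
        g.add_node(h, node_class="heterotroph",
                   size=float(traj.flux["uptake"][k, i].sum()))
    return g
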