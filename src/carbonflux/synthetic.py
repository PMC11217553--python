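"""Synthetic observation generator emulating a temperate coastal time series.

Produces seasonal forcing (temperature, PAR, daylength, winter nutrient
loading), a ground-truth model run whose parameters are chosen to reproduce
the qualitative bloom regime of temperate coastal waters — a spring
chlorophyll peak, a heterotroph (bacterial) peak in summer, and a late-summer
chlorophyll peak — and weekly noisy observations with the structure of real
monitoring data: chlorophyll with lognormal measurement noise, 18S/16S
amplicon read tables drawn Dirichlet-multinomially around the true carbon
fractions (including heterotrophic/unassigned 18S and chloroplast/cyanobacterial
16S decoy ASVs that the ingest filters must remove), flow-cytometric cell
counts, and nutrient concentrations.

Everything is deterministic given the scenario seed.  The generator writes
the same CSV/TSV dialects the ingest module reads, so the full pipeline can be
exercised end-to-end without any external data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fluxes as fx
from .model import (
    ForcingSeries,
    HetParams,
    ModelConfig,
    ModelState,
    PhytoParams,
    Trajectory,
    new_state,
    simulate,
)

__all__ = [
    "SyntheticScenario",
    "default_true_config",
    "generate_forcing",
    "initial_state",
    "generate_ground_truth",
    "sample_observations",
    "write_observation_csvs",
    "CHL_TO_C_G_PER_G",
    "SYN_CELL_QUOTA_UMOL",
    "HET_CELL_QUOTA_UMOL",
]

# unit constants shared with the ingest conversions
CHL_TO_C_G_PER_G = 40.0          # g phytoplankton C per g chlorophyll
CARBON_MOLAR_MASS = 12.011       # g mol⁻¹
SYN_CELL_QUOTA_UMOL = 1.4e-8     # µmol C per Synechococcus cell (1.4e-14 mol)
HET_CELL_QUOTA_UMOL = 2.0e-9     # µmol C per heterotroph cell (2.0e-15 mol)

SYN_ID = "Synechococcus"


@dataclass
class SyntheticScenario:
    """All knobs of one synthetic study; the defaults are the study conditions."""

    seed: int = 0
    years: int = 2
    n_phyto: int = 5             # eukaryotic phytoplankton OTUs (Syn is extra)
    n_het: int = 8
    n_dom: int = 6
    # forcing: annual sinusoids, temperate-coastal scale
    temp_mean: float = 12.25     # °C
    temp_amp: float = 4.25       # °C (≈8–16.5 °C range)
    temp_phase_day: float = 136.0     # max around late August
    par_mean: float = 25.0
    par_amp: float = 20.0
    daylength_min: float = 8.0   # h
    daylength_max: float = 16.5  # h
    winter_no3_load: float = 0.08     # µmol N L⁻¹ d⁻¹ October–February
    winter_po4_load: float = 0.005
    winter_si_load: float = 0.015
    # observation noise
    sigma_bulk: float = 0.15     # lognormal sigma for bulk measurements
    read_depth: int = 50_000     # reads per sample and marker gene
    overdispersion: float = 500.0     # Dirichlet concentration (larger = tighter)
    asvs_per_otu: int = 2        # 18S ASVs lumped into each OTU
    sample_every: int = 7        # days between observations

    def __post_init__(self):
        if min(self.years, self.n_phyto, self.n_het, self.n_dom) < 1:
            raise ValueError("all counts must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Ground-truth configuration
# ---------------------------------------------------------------------------

def default_true_config(scenario: SyntheticScenario) -> ModelConfig:
    """The generator's true model configuration.

    Taxon parameters span the trait axes that create the seasonal succession:
    cold-adapted fast-growing diatoms and picoeukaryotes drive the spring
    bloom, warm-adapted dinoflagellate-like taxa and Synechococcus the
    late-summer bloom, and warm-adapted heterotrophs with diverse DOM
    affinities the bacterial summer bloom.  Phytoplankton release DOM mostly
    into the first species; heterotroph death releases DOM mostly into the
    last species, so phytoplankton-derived and heterotroph-derived carbon stay
    distinguishable for the source-attribution analyses.
    """
    n_dom = scenario.n_dom
    dom_ids = [f"dom{j}" for j in range(n_dom)]

    def alloc(center: float, width: float = 1.2) -> dict[str, float]:
        # smooth allocation profile over the DOM axis, normalized to 1
        x = np.arange(n_dom, dtype=float)
        w = np.exp(-0.5 * ((x - center) / width) ** 2)
        w /= w.sum()
        return {d: float(v) for d, v in zip(dom_ids, w)}

    rng = np.random.default_rng(12345)   # fixed trait jitter, part of the truth
    phyto: dict[str, PhytoParams] = {}
    # (mu_max, t_ref, q10, k_light, k_din, silicifier) per eukaryote archetype
    archetypes = [
        # (name, mu_max, t_ref, q10, k_light, k_din, k_po4, silicifier)
        ("diatom", 1.7, 8.0, 1.6, 18.0, 1.5, 0.04, True),
        ("picoeuk", 1.3, 10.0, 1.8, 14.0, 1.0, 0.13, False),
        ("phaeo", 1.25, 11.0, 1.9, 20.0, 0.8, 0.02, False),
        ("dino", 1.0, 18.0, 3.0, 30.0, 0.4, 0.03, False),
        ("flagellate", 0.95, 16.0, 2.4, 24.0, 0.6, 0.10, False),
    ]
    for i in range(scenario.n_phyto):
        name, mu, tref, q10, kl, kn, kp, sil = archetypes[i % len(archetypes)]
        jit = float(rng.lognormal(0.0, 0.05))
        phyto[f"{name}_{i}" if i >= len(archetypes) else name] = PhytoParams(
            mu_max=mu * jit, k_light=kl, k_din=kn, k_po4=kp, k_si=1.0,
            silicifier=sil, q10=q10, t_ref=tref,
            ke=0.02, fe=0.10, kr=0.03, fr=0.10,
            kd=0.09, f_dom=0.5,
            dom_alloc=alloc(center=0.8 + 0.4 * (i % 3)),
        )
    phyto[SYN_ID] = PhytoParams(
        mu_max=1.2, k_light=12.0, k_din=0.12, k_po4=0.09, silicifier=False,
        q10=2.6, t_ref=17.0, ke=0.02, fe=0.08, kr=0.03, fr=0.08,
        kd=0.10, f_dom=0.6, dom_alloc=alloc(center=1.2),
    )

    het: dict[str, HetParams] = {}
    for i in range(scenario.n_het):
        # alternate specialists along the DOM axis; later taxa prefer the
        # heterotroph-derived (high-index) species
        center = (i / max(1, scenario.n_het - 1)) * (n_dom - 1)
        prof = alloc(center, width=1.0)
        usable = {d: 4.0 / (v * n_dom + 0.2) for d, v in prof.items() if v > 0.02}
        het[f"het{i}"] = HetParams(
            v_max=float(2.2 + 0.8 * np.sin(2.0 * i)), affinity=usable,
            yield_=0.30, q10=3.2, t_ref=15.5 + (i % 3),
            kd=0.30, f_dom=0.533, dom_alloc=alloc(n_dom - 1.2, width=1.0),
            dorm_in=0.5, dorm_out=0.5,
        )

    cfg = ModelConfig(
        phyto=phyto, het=het, dom_ids=dom_ids,
        k_dis=0.06, k_sink=0.12, seed_floor=0.005,
        dormant_death_mult=0.05,
        pom_alloc=None, dt=0.05, output_every=1.0,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Forcing and ground truth
# ---------------------------------------------------------------------------

def generate_forcing(scenario: SyntheticScenario) -> ForcingSeries:
    """Daily seasonal forcing over the scenario span (365-day years):
    exactly 365 records per simulated year."""
    days = np.arange(scenario.years * 365, dtype=float)
    ang_t = 2 * np.pi * (days - scenario.temp_phase_day) / 365.0
    temp = scenario.temp_mean + scenario.temp_amp * np.sin(ang_t)
    ang_s = 2 * np.pi * (days - 81.0) / 365.0     # solar: peak at day ~172
    par = np.maximum(0.0, scenario.par_mean + scenario.par_amp * np.sin(ang_s))
    half_range = 0.5 * (scenario.daylength_max - scenario.daylength_min)
    daylength = (scenario.daylength_min + half_range) + half_range * np.sin(ang_s)
    doy = days % 365
    winter = (doy >= 274) | (doy < 60)            # October–February
    return ForcingSeries(
        days=days, temperature=temp, par=par, daylength=daylength,
        load_no3=np.where(winter, scenario.winter_no3_load, 0.0),
        load_po4=np.where(winter, scenario.winter_po4_load, 0.0),
        load_si=np.where(winter, scenario.winter_si_load, 0.0),
    )


def initial_state(config: ModelConfig, scenario: SyntheticScenario) -> ModelState:
    """January-1st initial state: low winter biomass, replete nutrients."""
    phyto0 = {p: 0.6 / len(config.phyto) for p in config.phyto}
    het0 = {h: 0.5 / len(config.het) for h in config.het}
    return new_state(config, phyto0, het0, dom_total=2.0, pom_total=0.5,
                     no3=6.0, nh4=0.5, po4=0.5, si=4.0, dormant_fraction=0.3)


def generate_ground_truth(scenario: SyntheticScenario,
                          config: ModelConfig | None = None,
                          ) -> tuple[Trajectory, pd.DataFrame, list[fx.BloomWindow]]:
    """Run the true model; return trajectory, true pairwise fluxes, blooms.

    The true pairwise table uses the per-step in-simulation attribution (the
    exact discrete fluxes), which serves as ground truth for the analysis
    pipeline's ledger-based estimates.  Blooms are detected per simulated
    year on the model's chlorophyll-equivalent and total-heterotroph series.
    A scenario whose run produces no bloom of some type triggers a warning.
    """
    import warnings

    config = default_true_config(scenario) if config is None else config
    forcing = generate_forcing(scenario)
    state = initial_state(config, scenario)
    start = np.datetime64("2012-01-01")
    traj = simulate(config, forcing, state, start_date=start)

    # exact per-step attribution accumulated by the simulator
    mids = traj.bin_mid_times()
    n_p = len(traj.phyto_ids)
    classes = (["phytoplankton"] * n_p
               + ["heterotroph"] * len(traj.het_ids) + ["external"])
    rows = []
    pw = traj.flux["pairwise"]              # (B, n_src, n_h)
    for s, sid in enumerate(traj.source_ids):
        for h, hid in enumerate(traj.het_ids):
            col = pw[:, s, h]
            if np.any(col > 0):
                rows.append(pd.DataFrame({
                    "time": mids, "producer": sid, "consumer": hid,
                    "producer_class": classes[s], "flux": col}))
    true_pairwise = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["time", "producer", "consumer", "producer_class", "flux"])

    chl_series = pd.Series(
        traj.total_phyto_c() - traj.bp[:, traj.phyto_ids.index(SYN_ID)]
        if SYN_ID in traj.phyto_ids else traj.total_phyto_c(),
        index=pd.DatetimeIndex(traj.dates))
    het_series = pd.Series(traj.total_het_c(), index=pd.DatetimeIndex(traj.dates))
    blooms: list[fx.BloomWindow] = []
    year0 = pd.Timestamp(start).year
    for y in range(year0, year0 + scenario.years):
        for btype, series in (("phyto_spring", chl_series),
                              ("bacteria_summer", het_series),
                              ("phyto_summer", chl_series)):
            w = fx.detect_blooms(series, btype, y)
            if w is None:
                warnings.warn(f"scenario produced no {btype} bloom in {y}",
                              stacklevel=2)
            else:
                blooms.append(w)
    return traj, true_pairwise, blooms


# ---------------------------------------------------------------------------
# Weekly noisy observations
# ---------------------------------------------------------------------------

def _dirichlet_multinomial(rng: np.random.Generator, fractions: np.ndarray,
                           depth: int, concentration: float) -> np.ndarray:
    """Read counts around true fractions with compositional overdispersion."""
    alpha = np.maximum(fractions * concentration, 1e-8)
    p = rng.dirichlet(alpha)
    return rng.multinomial(depth, p)


def sample_observations(traj: Trajectory, scenario: SyntheticScenario
                        ) -> "ObservationBundle":
    """Subsample the trajectory weekly and add observation noise.

    Chlorophyll is back-converted from eukaryotic phytoplankton carbon with
    the fixed 40 gC/gChl factor; Synechococcus is excluded from chlorophyll
    and instead observed as cytometric cell counts, mirroring how prokaryotic
    phytoplankton are measured.  Read tables include decoy ASVs (heterotrophic
    and unassigned 18S; chloroplast, cyanobacterial and ammonia-oxidizing
    archaeal 16S) that downstream filtering must remove.
    """
    rng = np.random.default_rng(scenario.seed)
    # full sampling weeks only: one simulated year yields 52 sample dates
    idx = np.arange(0, len(traj.times) - 1, scenario.sample_every)
    dates = pd.DatetimeIndex(traj.dates[idx])
    noise = lambda n: np.exp(rng.normal(0.0, scenario.sigma_bulk, n)) \
        if scenario.sigma_bulk > 0 else np.ones(n)

    syn_i = traj.phyto_ids.index(SYN_ID) if SYN_ID in traj.phyto_ids else None
    euk_ids = [p for p in traj.phyto_ids if p != SYN_ID]
    euk_cols = [traj.phyto_ids.index(p) for p in euk_ids]
    euk_c = traj.bp[idx][:, euk_cols]                      # (S, n_euk)
    euk_total = euk_c.sum(axis=1)
    syn_c = traj.bp[idx, syn_i] if syn_i is not None else np.zeros(len(idx))
    het_c = (traj.ba + traj.bd)[idx]
    het_total = het_c.sum(axis=1)

    chl = euk_total * CARBON_MOLAR_MASS / CHL_TO_C_G_PER_G * noise(len(idx))
    syn_cells = syn_c / SYN_CELL_QUOTA_UMOL * noise(len(idx))
    het_cells = het_total / HET_CELL_QUOTA_UMOL * noise(len(idx))

    # --- 18S table: each OTU split into member ASVs + decoys -------------
    asv18_ids, asv18_tax, otu_of_asv, within = [], [], [], []
    for i, otu in enumerate(euk_ids):
        w = np.linspace(1.0, 0.4, scenario.asvs_per_otu)
        w /= w.sum()
        for a in range(scenario.asvs_per_otu):
            asv18_ids.append(f"asv18_{otu}_{a}")
            asv18_tax.append((f"Eukaryota;Archaeplastida;{otu}", "phototrophic"))
            otu_of_asv.append(i)
            within.append(w[a])
    decoys18 = [("asv18_het_cilia", "Eukaryota;Ciliophora;Strombidium",
                 "heterotrophic", 0.06),
                ("asv18_het_cerco", "Eukaryota;Cercozoa;Cryothecomonas",
                 "heterotrophic", 0.04),
                ("asv18_unk", "Eukaryota;uncultured", "unassigned", 0.03)]
    reads18 = np.zeros((len(asv18_ids) + len(decoys18), len(idx)), dtype=int)
    for s in range(len(idx)):
        tot = euk_total[s]
        frac_otu = euk_c[s] / tot if tot > 0 else np.full(len(euk_ids),
                                                          1.0 / len(euk_ids))
        decoy_frac = np.array([d[3] for d in decoys18])
        member = frac_otu[otu_of_asv] * np.array(within)
        fr = np.concatenate([member * (1 - decoy_frac.sum()), decoy_frac])
        reads18[:, s] = _dirichlet_multinomial(rng, fr, scenario.read_depth,
                                               scenario.overdispersion)
    tax18 = pd.DataFrame(
        [(a, lin, tro) for a, (lin, tro) in zip(asv18_ids, asv18_tax)]
        + [(d[0], d[1], d[2]) for d in decoys18],
        columns=["asv_id", "lineage", "trophy"]).set_index("asv_id")
    asv18 = pd.DataFrame(reads18, index=tax18.index, columns=dates)

    # --- 16S table: heterotroph ASVs + decoys ----------------------------
    decoys16 = [("asv16_chloro", "Bacteria;Cyanobacteria;Chloroplast", None),
                ("asv16_syn", "Bacteria;Cyanobacteria;Synechococcus", None),
                ("asv16_aoa", "Archaea;Thaumarchaeota;Nitrosopumilus", None),
                ("asv16_unk", "unassigned", None)]
    het_ids = traj.het_ids
    reads16 = np.zeros((len(het_ids) + len(decoys16), len(idx)), dtype=int)
    for s in range(len(idx)):
        tot = het_total[s]
        frac = het_c[s] / tot if tot > 0 else np.full(len(het_ids),
                                                      1.0 / len(het_ids))
        # decoy abundance scales with its real counterpart where one exists
        chl_frac = min(0.25, 0.04 * euk_total[s] / max(tot, 1e-12))
        syn_frac = min(0.25, 0.5 * syn_c[s] / max(tot, 1e-12))
        dec = np.array([chl_frac, syn_frac, 0.02, 0.02])
        fr = np.concatenate([frac * (1 - dec.sum()), dec])
        reads16[:, s] = _dirichlet_multinomial(rng, fr, scenario.read_depth,
                                               scenario.overdispersion)
    ids16 = [f"asv16_{h}" for h in het_ids] + [d[0] for d in decoys16]
    lin16 = ([f"Bacteria;Proteobacteria;{h}" for h in het_ids]
             + [d[1] for d in decoys16])
    tax16 = pd.DataFrame({"asv_id": ids16, "lineage": lin16,
                          "trophy": ""}).set_index("asv_id")
    asv16 = pd.DataFrame(reads16, index=tax16.index, columns=dates)

    nut = pd.DataFrame({
        "no3no2": traj.nutrients[idx, 0] * noise(len(idx)),
        "nh4": traj.nutrients[idx, 1] * noise(len(idx)),
        "po4": traj.nutrients[idx, 2] * noise(len(idx)),
        "si": traj.nutrients[idx, 3] * noise(len(idx)),
    }, index=dates)
    poc = (traj.pom[idx] + traj.total_phyto_c()[idx]
           + traj.total_het_c()[idx]) * noise(len(idx))

    from .ingest import ObservationSet     # deferred: avoid import cycle

    obs = ObservationSet(
        dates=dates,
        chlorophyll=pd.Series(chl, index=dates),
        asv18s=asv18, tax18s=tax18,
        asv16s=asv16, tax16s=tax16,
        syn_counts=pd.Series(syn_cells, index=dates),
        het_counts=pd.Series(het_cells, index=dates),
        nutrients=nut,
        temperature=pd.Series(traj.forcing[idx, 0], index=dates),
        par=pd.Series(traj.forcing[idx, 1], index=dates),
        daylength=pd.Series(traj.forcing[idx, 2], index=dates),
        poc=pd.Series(poc, index=dates),
    )
    obs.validate()
    return obs


def write_observation_csvs(obs, outdir: str | Path) -> dict[str, Path]:
    """Write an observation set in the CSV/TSV dialects the ingest reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bulk = pd.DataFrame({
        "date": obs.dates.strftime("%Y-%m-%d"),
        "chlorophyll": obs.chlorophyll.to_numpy(),
        "syn_cells": obs.syn_counts.to_numpy(),
        "het_cells": (obs.het_counts.to_numpy()
                      if obs.het_counts is not None else np.nan),
        "temperature": obs.temperature.to_numpy(),
        "par": obs.par.to_numpy(),
        "daylength": obs.daylength.to_numpy(),
        "no3no2": obs.nutrients["no3no2"].to_numpy(),
        "nh4": obs.nutrients["nh4"].to_numpy(),
        "po4": obs.nutrients["po4"].to_numpy(),
        "si": obs.nutrients["si"].to_numpy(),
        "poc": obs.poc.to_numpy() if obs.poc is not None else np.nan,
    })
    paths["bulk"] = outdir / "bulk.csv"
    bulk.to_csv(paths["bulk"], index=False)

    for name, table, tax in (("asv18s", obs.asv18s, obs.tax18s),
                             ("asv16s", obs.asv16s, obs.tax16s)):
        wide = table.copy()
        wide.columns = [pd.Timestamp(c).strftime("%Y-%m-%d") for c in wide.columns]
        wide.index.name = "asv_id"
        paths[name] = outdir / f"{name}.csv"
        wide.to_csv(paths[name])
        tx = tax.copy()
        tx.index.name = "asv_id"
        paths[f"tax_{name}"] = outdir / f"taxonomy_{name}.tsv"
        tx.to_csv(paths[f"tax_{name}"], sep="\t")
    return paths
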