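"""Pipeline orchestration: staged runs, manifests, caching, reports.

Ties the stages (synthetic data → ingest → calibration → flux analyses →
report) into one reproducible run driven by a single YAML configuration and
one root seed.  Every stage writes a manifest entry (config hash, input
checksums, seed, version, timing, outputs); a stage is re-used from cache
when its manifest hash is unchanged and its outputs still exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import calibrate as cal
from . import fluxes as fx
from . import ingest as ing
from . import synthetic as syn
from .model import ForcingSeries, ModelConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_report"]

STAGES = ("synth", "ingest", "calibrate", "fluxes", "report")


class PipelineError(RuntimeError):
    pass


def apply_overrides(data: Mapping[str, Any],
                    overrides: Mapping[str, Any] | None) -> dict:
    """Apply dotted-key overrides (``calibrate.iterations=200``) to a config."""
    data = {k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in data.items()}
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return data


@dataclass
class PipelineConfig:
    """Validated single-file configuration for a pipeline run."""

    seed: int = 0
    outdir: Path = Path("runs/run0")
    synth: dict = field(default_factory=dict)
    ingest: dict = field(default_factory=dict)
    calibrate: dict = field(default_factory=dict)
    fluxes: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path,
                  overrides: Mapping[str, Any] | None = None) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(apply_overrides(data, overrides))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {"seed", "outdir", *STAGES}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(
            seed=int(data.get("seed", 0)),
            outdir=Path(data.get("outdir", "runs/run0")),
            synth=dict(data.get("synth") or {}),
            ingest=dict(data.get("ingest") or {}),
            calibrate=dict(data.get("calibrate") or {}),
            fluxes=dict(data.get("fluxes") or {}),
            report=dict(data.get("report") or {}),
        )
        dt = cfg.calibrate.get("dt")
        if dt is not None and dt <= 0:
            raise PipelineError("calibrate.dt must be positive")
        depth = cfg.fluxes.get("depth_m")
        if depth is not None and depth <= 0:
            raise PipelineError("fluxes.depth_m must be positive")
        return cfg

    def stage_dict(self, stage: str) -> dict:
        return {"seed": self.seed, stage: getattr(self, stage)}


def _hash_obj(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage provenance: hashes, seeds, version, timings, outputs."""

    path: Path
    entries: dict = field(default_factory=dict)

    @classmethod
    def load(cls, outdir: Path) -> "RunManifest":
        path = outdir / "manifest.json"
        entries = json.loads(path.read_text()) if path.exists() else {}
        return cls(path=path, entries=entries)

    def is_cached(self, stage: str, key: str) -> bool:
        ent = self.entries.get(stage)
        return bool(ent and ent.get("hash") == key
                    and all(Path(p).exists() for p in ent.get("outputs", [])))

    def record(self, stage: str, key: str, outputs: list[Path],
               seconds: float) -> None:
        self.entries[stage] = {
            "hash": key,
            "outputs": [str(p) for p in outputs],
            "checksums": {str(p): _checksum(Path(p)) for p in outputs
                          if Path(p).is_file()},
            "seconds": round(seconds, 3),
            "version": _pkg_version,
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.entries, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_synth(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    scenario = syn.SyntheticScenario(seed=cfg.seed,
                                     **cfg.synth.get("scenario", {}))
    traj, true_pairwise, blooms = syn.generate_ground_truth(scenario)
    obs = syn.sample_observations(traj, scenario)
    d = outdir / "synth"
    paths = syn.write_observation_csvs(obs, d)
    scenario.to_yaml(d / "scenario.yaml")
    (d / "true_config.yaml").write_text(
        yaml.safe_dump(syn.default_true_config(scenario).to_dict(),
                       sort_keys=False))
    true_pairwise.to_csv(d / "true_pairwise_fluxes.csv", index=False)
    _blooms_frame(blooms).to_csv(d / "true_blooms.csv", index=False)
    return [*paths.values(), d / "scenario.yaml", d / "true_config.yaml",
            d / "true_pairwise_fluxes.csv", d / "true_blooms.csv"]


def _stage_ingest(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    d = outdir / "synth"
    if not (d / "bulk.csv").exists():
        raise PipelineError("ingest needs the synth stage outputs "
                            f"(missing {d / 'bulk.csv'})")
    obs = ing.read_observations({
        "bulk": d / "bulk.csv", "asv18s": d / "asv18s.csv",
        "asv16s": d / "asv16s.csv",
        "tax_asv18s": d / "taxonomy_asv18s.tsv",
        "tax_asv16s": d / "taxonomy_asv16s.tsv",
    })
    options = ing.IngestOptions(**cfg.ingest)
    carbon = ing.observations_to_carbon(obs, options)
    out = outdir / "ingest"
    out.mkdir(parents=True, exist_ok=True)
    ing.write_carbon_csv(carbon, out / "carbon_observations.csv")
    loadings = ing.derive_nutrient_loadings(
        obs.nutrients["no3no2"] + obs.nutrients["nh4"])
    loadings.to_csv(out / "din_loadings.csv", index=False)
    return [out / "carbon_observations.csv", out / "din_loadings.csv"]


def _rebuild_inputs(cfg: PipelineConfig, outdir: Path):
    """Reload scenario/observations shared by calibrate and fluxes stages."""
    d = outdir / "synth"
    scenario = syn.SyntheticScenario.from_yaml(d / "scenario.yaml")
    true_config = ModelConfig.from_dict(
        yaml.safe_load((d / "true_config.yaml").read_text()))
    forcing = syn.generate_forcing(scenario)
    obs = ing.read_observations({
        "bulk": d / "bulk.csv", "asv18s": d / "asv18s.csv",
        "asv16s": d / "asv16s.csv",
        "tax_asv18s": d / "taxonomy_asv18s.tsv",
        "tax_asv16s": d / "taxonomy_asv16s.tsv",
    })
    carbon = ing.observations_to_carbon(obs, ing.IngestOptions(**cfg.ingest))
    return scenario, true_config, forcing, carbon


def _stage_calibrate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    scenario, true_config, forcing, carbon = _rebuild_inputs(cfg, outdir)
    spec = cfg.calibrate
    free = [cal.FreeParameter(*fp) for fp in spec.get(
        "free_parameters",
        [["phyto", "picoeuk", "mu_max"], ["het", "het0", "v_max"]])]
    start = true_config.copy()
    rng = np.random.default_rng(cfg.seed + 1)
    jitter = float(spec.get("start_jitter", 0.5))
    bounds = cal.default_bounds()
    for fp in free:      # start away from the truth: calibration must work
        fp.set(start, bounds.clip(fp, fp.get(start)
                                  * float(rng.lognormal(0.0, jitter))))
    state = syn.initial_state(true_config, scenario)
    fit = cal.calibrate_year(
        start, carbon, forcing, state, free, bounds,
        iterations=int(spec.get("iterations", 100)),
        seed=cfg.seed, sigma=float(spec.get("sigma", 0.2)),
        t0=0.0, t1=float(spec.get("t1", 365.0)),
        dt=float(spec.get("dt", 0.1)),
        start_date=np.datetime64("2012-01-01"))
    out = outdir / "calibrate"
    fit.save(out)
    return [out / "fit_result.json", out / "best_config.yaml",
            out / "acceptance_trace.csv"]


def _blooms_frame(blooms: list[fx.BloomWindow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "bloom_type": b.bloom_type, "start": str(b.start_date)[:10],
        "peak": str(b.peak_date)[:10], "end": str(b.end_date)[:10],
        "duration_days": b.duration} for b in blooms])


def _stage_fluxes(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    scenario, true_config, forcing, carbon = _rebuild_inputs(cfg, outdir)
    best_path = outdir / "calibrate" / "best_config.yaml"
    config = ModelConfig.from_dict(yaml.safe_load(best_path.read_text())) \
        if best_path.exists() else true_config
    state = syn.initial_state(true_config, scenario)
    start = np.datetime64("2012-01-01")
    traj = simulate(config, forcing, state, start_date=start)

    out = outdir / "fluxes"
    out.mkdir(parents=True, exist_ok=True)
    pairwise = fx.pairwise_fluxes(traj)
    pairwise.to_csv(out / "pairwise_fluxes.csv", index=False)
    traj.flux_records().to_csv(out / "flux_records.csv", index=False)
    traj.states_frame().to_csv(out / "state_series.csv", index=False)

    syn_id = syn.SYN_ID
    chl = pd.Series(traj.total_phyto_c()
                    - (traj.bp[:, traj.phyto_ids.index(syn_id)]
                       if syn_id in traj.phyto_ids else 0.0),
                    index=pd.DatetimeIndex(traj.dates))
    het = pd.Series(traj.total_het_c(), index=pd.DatetimeIndex(traj.dates))
    blooms = []
    for year in sorted({d.year for d in pd.DatetimeIndex(traj.dates)}):
        for btype, series in (("phyto_spring", chl), ("bacteria_summer", het),
                              ("phyto_summer", chl)):
            w = fx.detect_blooms(series, btype, year)
            if w is not None:
                blooms.append(w)
    _blooms_frame(blooms).to_csv(out / "blooms.csv", index=False)

    depth = float(cfg.fluxes.get("depth_m", 50.0))
    rows = []
    for b in blooms:
        span = fx.window_days(b, start)
        agg = fx.aggregate_bloom_fluxes(pairwise, span)
        met = fx.production_metrics(traj, depth_m=depth, span=span)
        ratio = fx.dom_pom_release_ratio(traj, span=span)
        rows.append({"bloom_type": b.bloom_type, "peak": str(b.peak_date)[:10],
                     "phyto_to_het": agg["phyto_to_het"],
                     "het_to_het": agg["het_to_het"],
                     "dom_pom_ratio": ratio["ratio"], **met})
    pd.DataFrame(rows).to_csv(out / "bloom_fluxes.csv", index=False)
    met_all = fx.production_metrics(traj, depth_m=depth)
    pd.DataFrame([met_all]).to_csv(out / "production_metrics.csv", index=False)
    fx.limitation_timeseries(traj, top_k=3).to_csv(
        out / "limitation_timeseries.csv", index=False)

    # network snapshot for the median day of each bloom window
    import networkx as nx

    for b in blooms:
        t0, t1 = fx.window_days(b, start)
        g = fx.network_snapshot(traj, 0.5 * (t0 + t1))
        nx.write_graphml(g, out / f"network_{b.bloom_type}_{str(b.peak_date)[:10]}.graphml")
    return [out / "pairwise_fluxes.csv", out / "flux_records.csv",
            out / "state_series.csv", out / "blooms.csv",
            out / "bloom_fluxes.csv", out / "production_metrics.csv",
            out / "limitation_timeseries.csv"]


def write_report(results_dir: str | Path) -> list[Path]:
    """Summary tables + plain-text digest from the fluxes stage outputs."""
    results_dir = Path(results_dir)
    fdir = results_dir / "fluxes"
    if not (fdir / "bloom_fluxes.csv").exists():
        raise PipelineError("report needs the fluxes stage outputs")
    bloom_fluxes = pd.read_csv(fdir / "bloom_fluxes.csv")
    out = results_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    lines = ["carbonflux run summary", "======================", ""]
    if bloom_fluxes.empty:
        lines.append("no blooms detected")
    else:
        summary = bloom_fluxes.groupby("bloom_type")[
            ["phyto_to_het", "het_to_het", "gpp", "npp", "gross_het_prod",
             "net_het_prod", "dom_pom_ratio"]].mean()
        summary.to_csv(out / "bloom_summary.csv")
        outputs.append(out / "bloom_summary.csv")
        lines.append(summary.round(4).to_string())
        lines.append("")
        lines.append("fluxes in µmol C L⁻¹ d⁻¹; production also in "
                     "bloom means; dom_pom_ratio dimensionless")
    met = pd.read_csv(fdir / "production_metrics.csv")
    lines.append("")
    lines.append("whole-run production (volumetric µmol C L⁻¹ d⁻¹ / "
                 "areal mmol C m⁻² d⁻¹):")
    lines.append(met.round(4).to_string(index=False))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    outputs.append(out / "summary.txt")
    return outputs


def _stage_report(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    return write_report(outdir)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "ingest": _stage_ingest,
    "calibrate": _stage_calibrate,
    "fluxes": _stage_fluxes,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None,
                 force: bool = False) -> RunManifest:
    """Execute the requested stages in dependency order with caching.

    A stage re-runs only when its section of the configuration (plus the root
    seed) changed or its outputs are missing; otherwise the cached results are
    reused and the manifest entry kept.
    """
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.load(outdir)
    for stage in stages:
        key = _hash_obj(config.stage_dict(stage))
        if not force and manifest.is_cached(stage, key):
            logger.info("stage %s cached; reusing outputs", stage)
            continue
        logger.info("running stage %s", stage)
        t0 = time.time()
        outputs = _STAGE_FUNCS[stage](config, outdir)
        manifest.record(stage, key, outputs, time.time() - t0)
    return manifest
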