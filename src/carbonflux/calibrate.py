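"""Stochastic calibration of the ecosystem model to carbon observations.

The optimizer is a greedy stochastic hill climb tailored to this model class:
each iteration perturbs a small random subset of free parameters
multiplicatively (lognormal steps, clipped to literature-derived bounds),
simulates, scores the trajectory against the carbon-converted observations
with a log-scale least-squares objective, and accepts the proposal only when
the score improves.  An optional simulated-annealing acceptance schedule is
available but off by default.  Years are calibrated separately; gradual
delumping expands lumped taxa into their members, children inheriting the
parent's fitted parameters with multiplicative jitter and the parent's
initial carbon split by the observed member fractions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ingest import CarbonObservations
from .model import ForcingSeries, ModelConfig, ModelState, Trajectory, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "FreeParameter",
    "ParameterBounds",
    "FitResult",
    "default_bounds",
    "objective_score",
    "propose_perturbation",
    "calibrate_year",
    "delump_taxa",
]

OBJECTIVE_EPS = 1e-4     # µmol C L⁻¹ floor inside the log residuals


@dataclass(frozen=True)
class FreeParameter:
    """One calibrated parameter: group ('phyto'|'het'|'model'), taxon, name."""

    group: str
    taxon: str | None
    name: str

    def get(self, config: ModelConfig) -> float:
        return float(getattr(self._owner(config), self.name))

    def set(self, config: ModelConfig, value: float) -> None:
        setattr(self._owner(config), self.name, float(value))

    def _owner(self, config: ModelConfig):
        if self.group == "phyto":
            return config.phyto[self.taxon]
        if self.group == "het":
            return config.het[self.taxon]
        if self.group == "model":
            return config
        raise ValueError(f"unknown parameter group {self.group!r}")


@dataclass
class ParameterBounds:
    """Per-parameter-class {lower, upper} bounds with per-taxon overrides."""

    by_name: dict[str, tuple[float, float]]
    overrides: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.by_name.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def of(self, fp: FreeParameter) -> tuple[float, float]:
        if fp.taxon is not None and (fp.taxon, fp.name) in self.overrides:
            return self.overrides[(fp.taxon, fp.name)]
        if fp.name not in self.by_name:
            raise KeyError(f"no bounds configured for parameter {fp.name!r}")
        return self.by_name[fp.name]

    def clip(self, fp: FreeParameter, value: float) -> float:
        lo, hi = self.of(fp)
        return min(max(value, lo), hi)

    def to_yaml(self, path: str | Path) -> None:
        data = {"by_name": {k: list(v) for k, v in self.by_name.items()},
                "overrides": {f"{t}:{n}": list(v)
                              for (t, n), v in self.overrides.items()}}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterBounds":
        data = yaml.safe_load(Path(path).read_text())
        overrides = {}
        for key, v in (data.get("overrides") or {}).items():
            taxon, name = key.split(":", 1)
            overrides[(taxon, name)] = tuple(v)
        return cls(by_name={k: tuple(v) for k, v in data["by_name"].items()},
                   overrides=overrides)


def default_bounds() -> ParameterBounds:
    """Literature-scale bounds for the calibrated rate parameters."""
    return ParameterBounds(by_name={
        "mu_max": (0.2, 4.0),        # d⁻¹
        "k_light": (2.0, 100.0),
        "k_din": (0.05, 5.0),        # µmol N L⁻¹
        "k_po4": (0.005, 0.5),
        "k_si": (0.1, 5.0),
        "q10": (1.2, 4.0),
        "t_ref": (2.0, 28.0),
        "ke": (0.0, 0.2),            # d⁻¹
        "fe": (0.0, 0.5),
        "kr": (0.0, 0.2),
        "fr": (0.0, 0.5),
        "kd": (0.005, 1.0),
        "f_dom": (0.05, 0.95),
        "v_max": (0.2, 8.0),         # d⁻¹
        "yield_": (0.05, 0.6),
        "dorm_in": (0.0, 2.0),
        "dorm_out": (0.0, 2.0),
        "k_dis": (0.005, 0.5),
    })


@dataclass
class FitResult:
    """Outcome of one calibration run (per calendar year)."""

    best_config: ModelConfig
    objective_value: float
    acceptance_trace: list[tuple[int, float]]
    year: int
    rng_seed: int

    def __post_init__(self):
        vals = [v for _, v in self.acceptance_trace]
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("acceptance trace must be non-increasing")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "fit_result.json").write_text(json.dumps({
            "objective_value": self.objective_value,
            "year": self.year, "rng_seed": self.rng_seed,
            "iterations": len(self.acceptance_trace)}, indent=2))
        (d / "best_config.yaml").write_text(
            yaml.safe_dump(self.best_config.to_dict(), sort_keys=False))
        pd.DataFrame(self.acceptance_trace,
                     columns=["iteration", "objective"]).to_csv(
            d / "acceptance_trace.csv", index=False)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _model_series(traj: Trajectory, carbon_obs: CarbonObservations
                  ) -> list[tuple[str, np.ndarray, np.ndarray, float]]:
    """(name, model values at obs dates, obs values, weight) per series.

    Total-pool series are weighted by their member-taxon counts so totals and
    composition contribute comparably to the objective.
    """
    if traj.start_date is None:
        raise ValueError("trajectory needs a calendar start date for scoring")
    day = np.timedelta64(1, "D")
    obs_days = ((carbon_obs.dates.values - traj.start_date) / day).astype(float)
    in_span = (obs_days >= traj.times[0] - 1e-9) & (obs_days <= traj.times[-1] + 1e-9)
    if not in_span.any():
        raise ValueError("no observation dates overlap the trajectory")
    obs_days = obs_days[in_span]

    def interp(col: np.ndarray) -> np.ndarray:
        return np.interp(obs_days, traj.times, col)

    out: list[tuple[str, np.ndarray, np.ndarray, float]] = []
    syn_like = {"Synechococcus"}
    matched_p: list[int] = []
    for otu in carbon_obs.phyto_otu_c.index:
        if otu in traj.phyto_ids:
            i = traj.phyto_ids.index(otu)
            matched_p.append(i)
            out.append((f"otu:{otu}", interp(traj.bp[:, i]),
                        carbon_obs.phyto_otu_c.loc[otu].to_numpy()[in_span], 1.0))
        else:
            logger.debug("observed OTU %s has no model taxon; skipped", otu)
    if matched_p:
        total_model = interp(traj.bp[:, matched_p].sum(axis=1))
        out.append(("total_phyto", total_model,
                    carbon_obs.total_phyto_c.to_numpy()[in_span],
                    float(len(matched_p))))
    for syn in syn_like & set(traj.phyto_ids):
        i = traj.phyto_ids.index(syn)
        out.append((f"syn:{syn}", interp(traj.bp[:, i]),
                    carbon_obs.syn_c.to_numpy()[in_span], 1.0))
    het_tot = traj.ba + traj.bd
    matched_h: list[int] = []
    for asv in carbon_obs.het_asv_c.index:
        taxon = carbon_obs.het_taxon_of_asv.get(asv, asv)
        if taxon in traj.het_ids:
            i = traj.het_ids.index(taxon)
            matched_h.append(i)
            out.append((f"asv:{asv}", interp(het_tot[:, i]),
                        carbon_obs.het_asv_c.loc[asv].to_numpy()[in_span], 1.0))
    if matched_h:
        out.append(("total_het", interp(het_tot[:, matched_h].sum(axis=1)),
                    carbon_obs.total_het_c.to_numpy()[in_span],
                    float(len(matched_h))))
    return out


def objective_score(traj: Trajectory, carbon_obs: CarbonObservations,
                    weights: Mapping[str, float] | None = None,
                    eps: float = OBJECTIVE_EPS) -> float:
    """Log-scale weighted least squares between model and observed carbon.

    score = Σ_series w · Σ_dates (log10(model+ε) − log10(obs+ε))² with
    ε = 1e-4 µmol C L⁻¹; missing observations are skipped.  A model matching
    the observations exactly scores 0, and inflating any single residual
    strictly increases the score.
    """
    total = 0.0
    for name, model, obs, w in _model_series(traj, carbon_obs):
        if weights is not None:
            w = weights.get(name, w)
        ok = np.isfinite(obs)
        if not ok.any():
            continue
        resid = np.log10(model[ok] + eps) - np.log10(obs[ok] + eps)
        total += w * float((resid ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# Proposals and the hill climb
# ---------------------------------------------------------------------------

def propose_perturbation(config: ModelConfig, free: Sequence[FreeParameter],
                         bounds: ParameterBounds, rng: np.random.Generator,
                         sigma: float = 0.2,
                         n_params: tuple[int, int] = (1, 3)) -> ModelConfig:
    """Perturb a random subset of free parameters by lognormal factors.

    Deterministic given the generator state; every output parameter is
    clipped to its bounds.  ``sigma = 0`` returns an identical configuration.
    """
    new = config.copy()
    k = int(rng.integers(n_params[0], min(n_params[1], len(free)) + 1))
    picks = rng.choice(len(free), size=k, replace=False)
    for i in picks:
        fp = free[i]
        value = fp.get(new) * float(rng.lognormal(0.0, sigma))
        fp.set(new, bounds.clip(fp, value))
    return new


def calibrate_year(config: ModelConfig, carbon_obs: CarbonObservations,
                   forcing: ForcingSeries, initial_state: ModelState,
                   free: Sequence[FreeParameter],
                   bounds: ParameterBounds | None = None,
                   iterations: int = 500, seed: int = 0,
                   sigma: float = 0.2, year: int | None = None,
                   t0: float = 0.0, t1: float | None = None,
                   dt: float | None = None,
                   start_date=None,
                   anneal_temperature: float = 0.0,
                   anneal_cooling: float = 0.995,
                   weights: Mapping[str, float] | None = None) -> FitResult:
    """Greedy stochastic hill climb over the free parameters of one year.

    Accepts a proposal iff its objective decreases (or, with a positive
    ``anneal_temperature``, with the Metropolis probability of a cooling
    simulated-annealing schedule).  Failed simulations reject the proposal.
    Reproducible given the seed; the acceptance trace is non-increasing.
    """
    bounds = bounds or default_bounds()
    rng = np.random.default_rng(seed)
    if start_date is None and carbon_obs.dates is not None:
        start_date = np.datetime64(carbon_obs.dates[0], "D")
    if year is None:
        year = int(pd.Timestamp(start_date).year)

    def run(cfg: ModelConfig) -> float:
        traj = simulate(cfg, forcing, initial_state, t0=t0, t1=t1, dt=dt,
                        start_date=start_date)
        return objective_score(traj, carbon_obs, weights=weights)

    best = config.copy()
    best_score = run(best)
    current, current_score = best, best_score
    temperature = anneal_temperature
    trace = [(0, best_score)]
    for it in range(1, iterations + 1):
        proposal = propose_perturbation(current, free, bounds, rng, sigma=sigma)
        try:
            score = run(proposal)
        except Exception as exc:                      # noqa: BLE001
            logger.warning("proposal %d failed (%s); rejected", it, exc)
            trace.append((it, best_score))
            continue
        accept = score < current_score
        if not accept and temperature > 0:
            accept = rng.random() < math.exp((current_score - score)
                                             / temperature)
            temperature *= anneal_cooling
        if accept:
            current, current_score = proposal, score
            if score < best_score:
                best, best_score = proposal, score
        trace.append((it, best_score))
    return FitResult(best_config=best, objective_value=best_score,
                     acceptance_trace=trace, year=year, rng_seed=seed)


# ---------------------------------------------------------------------------
# Delumping
# ---------------------------------------------------------------------------

def delump_taxa(config: ModelConfig, members: Mapping[str, Sequence[str]],
                parent_carbon: Mapping[str, float],
                member_fracs: Mapping[str, Mapping[str, float]] | None = None,
                jitter_sigma: float = 0.0,
                rng: np.random.Generator | None = None,
                group: str = "phyto") -> tuple[ModelConfig, dict[str, float]]:
    """Replace lumped taxa by their members (gradual diversification stage).

    Children inherit the parent's parameters with multiplicative lognormal
    jitter; their initial carbon splits the parent's by the observed member
    fractions at the stage start (equal split, with a warning, when no
    fractions are available).  Total initial carbon is conserved per parent.
    """
    import warnings

    rng = rng or np.random.default_rng(0)
    new = config.copy()
    pool = new.phyto if group == "phyto" else new.het
    carbon: dict[str, float] = {k: v for k, v in parent_carbon.items()
                                if k not in members}
    jitter_fields = ("mu_max", "ke", "fe", "kr", "fr", "kd") if group == "phyto" \
        else ("v_max", "yield_", "kd")
    for parent, children in members.items():
        if parent not in pool:
            raise KeyError(f"lumped taxon {parent!r} not in configuration")
        params = pool.pop(parent)
        fracs = dict(member_fracs.get(parent, {})) if member_fracs else {}
        if not fracs or sum(fracs.values()) <= 0:
            warnings.warn(f"no member fractions for {parent!r}; equal split",
                          stacklevel=2)
            fracs = {c: 1.0 / len(children) for c in children}
        norm = sum(fracs.get(c, 0.0) for c in children)
        for child in children:
            child_params = type(params)(**{
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in vars(params).items()})
            if jitter_sigma > 0:
                for name in jitter_fields:
                    setattr(child_params, name,
                            getattr(child_params, name)
                            * float(rng.lognormal(0.0, jitter_sigma)))
            pool[child] = child_params
            carbon[child] = parent_carbon.get(parent, 0.0) \
                * fracs.get(child, 0.0) / norm
    new.validate()
    return new, carbon
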