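"""Mass-balance carbon/nutrient ecosystem model for plankton microbial communities.

The model simulates organic carbon held in phytoplankton taxa, heterotrophic
prokaryote taxa (with an active and a dormant sub-pool each), a set of
hypothetical dissolved organic matter (DOM) species, and a single particulate
organic matter (POM) pool, together with inorganic nutrients (NO3, NH4, PO4,
silicate).  Phytoplankton fix carbon as a function of light, temperature and
inorganic nutrients (Q10 temperature response, Monod light and nutrient terms,
Liebig minimum over nutrients).  They release DOM by exudation (a basal rate
``ke`` plus a fraction ``fe`` of photosynthesis) and by death; death is split
between DOM and POM, and POM dissolves back into DOM.  Heterotrophic
prokaryotes grow by consuming DOM species with taxon-specific affinities,
respire a fixed fraction of uptake (growth efficiency ``yield``), die into
DOM/POM, and never exude DOM.  Dormancy shelters heterotrophs from extinction:
when net growth is negative, biomass transfers to a dormant pool that takes up
nothing and dies slowly.

Every DOM species and the POM pool carry a *source ledger*: the mass currently
in the pool broken down by the taxon that produced it.  Consumption removes
ledger mass proportionally to the current source fractions, which is what lets
downstream analyses attribute each unit of heterotrophic uptake to the
phytoplankton or heterotroph that originally released the carbon.

Integration is fixed-step explicit Euler with proportional outflow capping
(all outflows of a pool are scaled down together whenever one step's demand
exceeds the stock), so no pool ever goes negative and every recorded flux is
an exact term of the discrete mass balance.  Carbon, nitrogen and phosphorus
are conserved to machine precision by construction: respiration exports carbon
to a cumulative sink while its nutrient content is remineralized to NH4/PO4,
and quota differences between biomass and DOM are balanced against NH4/PO4 at
the moment of each transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "REDFIELD_N_C",
    "REDFIELD_P_C",
    "DEFAULT_SI_C",
    "PhytoParams",
    "HetParams",
    "ModelConfig",
    "ForcingSeries",
    "ModelState",
    "SourceLedger",
    "FluxRecord",
    "Trajectory",
    "limitation_factors_phyto",
    "phyto_rates",
    "het_rates",
    "remineralization",
    "pom_dissolution",
    "dormancy_update",
    "step",
    "simulate",
]

# Redfield stoichiometric quotas (mol N or P per mol C of biomass).
REDFIELD_N_C = 16.0 / 106.0
REDFIELD_P_C = 1.0 / 106.0
# Si quota applied to silicifying phytoplankton (diatom-like), mol Si per mol C.
DEFAULT_SI_C = 15.0 / 106.0

BACKGROUND_SOURCE = "background"  # ledger id for pre-existing (seed) organic mass

_TINY = 1e-300


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class PhytoParams:
    """Parameters of one phytoplankton taxon.

    Rates are per day; half-saturations are in the units of the corresponding
    forcing/nutrient series (PAR units for ``k_light``, µmol L⁻¹ otherwise).
    """

    mu_max: float = 1.2          # maximum growth rate, d⁻¹
    k_light: float = 30.0        # PAR half-saturation
    k_din: float = 1.0           # DIN (NO3+NH4) half-saturation, µmol N L⁻¹
    k_po4: float = 0.06          # PO4 half-saturation, µmol P L⁻¹
    k_si: float = 1.0            # silicate half-saturation (silicifiers only)
    silicifier: bool = False
    q10: float = 1.9             # temperature coefficient
    t_ref: float = 15.0          # reference temperature, °C
    ke: float = 0.02             # basal exudation rate, d⁻¹
    fe: float = 0.10             # exuded fraction of photosynthesis
    kr: float = 0.03             # basal respiration rate, d⁻¹
    fr: float = 0.10             # respired fraction of photosynthesis
    kd: float = 0.08             # death rate, d⁻¹
    f_dom: float = 0.5           # fraction of death flux routed to DOM (rest POM)
    dom_alloc: Mapping[str, float] | None = None  # DOM species allocation; None = uniform

    def validate(self) -> None:
        for name in ("mu_max", "k_light", "k_din", "k_po4", "k_si", "ke", "kr", "kd"):
            _check_nonneg(name, getattr(self, name))
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")
        for name in ("fe", "fr", "f_dom"):
            _check_fraction(name, getattr(self, name))
        if self.dom_alloc is not None:
            total = sum(self.dom_alloc.values())
            if any(v < 0 for v in self.dom_alloc.values()):
                raise ValueError("dom_alloc fractions must be >= 0")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"dom_alloc must sum to 1, got {total}")


@dataclass
class HetParams:
    """Parameters of one heterotrophic prokaryote taxon.

    ``affinity`` maps DOM species id to its Monod half-saturation (µmol C L⁻¹);
    species absent from the map cannot be consumed by this taxon.
    """

    v_max: float = 2.5           # maximum specific uptake, d⁻¹
    affinity: Mapping[str, float] = field(default_factory=dict)
    yield_: float = 0.3          # growth efficiency (G/U)
    q10: float = 2.5
    t_ref: float = 18.0
    kd: float = 0.12             # death rate, d⁻¹
    f_dom: float = 0.533         # death DOM fraction
    dom_alloc: Mapping[str, float] | None = None
    dorm_in: float = 0.3         # active→dormant rate when shrinking, d⁻¹
    dorm_out: float = 0.3        # dormant→active rate when growing, d⁻¹

    def validate(self) -> None:
        for name in ("v_max", "kd", "dorm_in", "dorm_out"):
            _check_nonneg(name, getattr(self, name))
        if not self.affinity:
            raise ValueError("affinity map must be non-empty")
        if any(k <= 0 for k in self.affinity.values()):
            raise ValueError("affinity half-saturations must be positive")
        if not 0.0 < self.yield_ <= 1.0:
            raise ValueError(f"yield must be in (0, 1], got {self.yield_}")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")
        _check_fraction("f_dom", self.f_dom)
        if self.dom_alloc is not None:
            total = sum(self.dom_alloc.values())
            if any(v < 0 for v in self.dom_alloc.values()):
                raise ValueError("dom_alloc fractions must be >= 0")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"dom_alloc must sum to 1, got {total}")


@dataclass
class ModelConfig:
    """Full model configuration: taxa, pools, stoichiometry and numerics."""

    phyto: dict[str, PhytoParams]
    het: dict[str, HetParams]
    dom_ids: list[str]
    k_dis: float = 0.05                      # POM dissolution rate, d⁻¹
    k_sink: float = 0.0                      # POM sinking-export rate, d⁻¹
    seed_floor: float = 0.0                  # µmol C L⁻¹ refuge below which
                                             # biomass losses shut off
    pom_alloc: Mapping[str, float] | None = None   # DOM allocation of dissolved POM
    q_n_bio: float = REDFIELD_N_C
    q_p_bio: float = REDFIELD_P_C
    q_si: float = DEFAULT_SI_C
    q_n_dom: Mapping[str, float] | None = None     # per-DOM N:C; None = biomass quota
    q_p_dom: Mapping[str, float] | None = None
    dormant_death_mult: float = 0.1
    dt: float = 0.05                         # Euler step, days
    output_every: float = 1.0                # output cadence, days

    def validate(self) -> None:
        if not self.dom_ids:
            raise ValueError("at least one DOM species required")
        if len(set(self.dom_ids)) != len(self.dom_ids):
            raise ValueError("dom_ids must be unique")
        for pid, p in self.phyto.items():
            try:
                p.validate()
                if p.dom_alloc is not None and set(p.dom_alloc) - set(self.dom_ids):
                    raise ValueError("dom_alloc refers to unknown DOM species")
            except ValueError as exc:
                raise ValueError(f"phytoplankton {pid!r}: {exc}") from exc
        for hid, h in self.het.items():
            try:
                h.validate()
                if set(h.affinity) - set(self.dom_ids):
                    raise ValueError("affinity refers to unknown DOM species")
                if h.dom_alloc is not None and set(h.dom_alloc) - set(self.dom_ids):
                    raise ValueError("dom_alloc refers to unknown DOM species")
            except ValueError as exc:
                raise ValueError(f"heterotroph {hid!r}: {exc}") from exc
        _check_nonneg("k_dis", self.k_dis)
        _check_nonneg("k_sink", self.k_sink)
        _check_nonneg("seed_floor", self.seed_floor)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.output_every < self.dt:
            raise ValueError("output_every must be >= dt")
        qn = dict(self.q_n_dom or {})
        qp = dict(self.q_p_dom or {})
        for d in self.dom_ids:
            if qn.get(d, self.q_n_bio) > self.q_n_bio + 1e-12:
                raise ValueError(f"DOM N quota of {d!r} exceeds biomass quota")
            if qp.get(d, self.q_p_bio) > self.q_p_bio + 1e-12:
                raise ValueError(f"DOM P quota of {d!r} exceeds biomass quota")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def params_dict(p) -> dict:
            d = {k: v for k, v in vars(p).items()}
            for key in ("dom_alloc", "affinity"):
                if key in d and d[key] is not None:
                    d[key] = dict(d[key])
            return d

        return {
            "phyto": {k: params_dict(v) for k, v in self.phyto.items()},
            "het": {k: params_dict(v) for k, v in self.het.items()},
            "dom_ids": list(self.dom_ids),
            "k_dis": self.k_dis,
            "k_sink": self.k_sink,
            "seed_floor": self.seed_floor,
            "pom_alloc": dict(self.pom_alloc) if self.pom_alloc else None,
            "q_n_bio": self.q_n_bio,
            "q_p_bio": self.q_p_bio,
            "q_si": self.q_si,
            "q_n_dom": dict(self.q_n_dom) if self.q_n_dom else None,
            "q_p_dom": dict(self.q_p_dom) if self.q_p_dom else None,
            "dormant_death_mult": self.dormant_death_mult,
            "dt": self.dt,
            "output_every": self.output_every,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        phyto = {k: PhytoParams(**v) for k, v in d["phyto"].items()}
        het = {k: HetParams(**v) for k, v in d["het"].items()}
        rest = {k: v for k, v in d.items() if k not in ("phyto", "het")}
        cfg = cls(phyto=phyto, het=het, **rest)
        cfg.validate()
        return cfg

    def copy(self) -> "ModelConfig":
        return ModelConfig.from_dict(self.to_dict())


@dataclass
class ForcingSeries:
    """Environmental forcing on a daily (or finer) time grid.

    ``days`` are days since simulation start.  Temperature/PAR/daylength are
    linearly interpolated between grid points; nutrient loading rates
    (µmol L⁻¹ d⁻¹, distributed sources from water-mass intrusions) are
    piecewise-constant from each grid point to the next.
    """

    days: np.ndarray
    temperature: np.ndarray
    par: np.ndarray
    daylength: np.ndarray
    load_no3: np.ndarray | None = None
    load_po4: np.ndarray | None = None
    load_si: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        for name in ("temperature", "par", "daylength"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.days.shape:
                raise ValueError(f"forcing series {name} misaligned with days")
            setattr(self, name, arr)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("forcing days must be strictly increasing")
        if np.any((self.daylength < 0) | (self.daylength > 24)):
            raise ValueError("daylength must lie in [0, 24] hours")

    def span(self) -> tuple[float, float]:
        return float(self.days[0]), float(self.days[-1])


# ---------------------------------------------------------------------------
# State, ledger, flux records
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Model state vector: taxon carbon, source-resolved DOM/POM, nutrients.

    The DOM pools are stored *as* their source ledger: ``dom_src[j, s]`` is the
    carbon in DOM species ``j`` produced by source ``s`` (phytoplankton taxa,
    then heterotroph taxa, then a "background" seed source), so ledger
    consistency (sources summing to the pool) holds identically.
    """

    phyto_ids: list[str]
    het_ids: list[str]
    dom_ids: list[str]
    bp: np.ndarray            # (n_p,) phytoplankton carbon, µmol C L⁻¹
    ba: np.ndarray            # (n_h,) active heterotroph carbon
    bd: np.ndarray            # (n_h,) dormant heterotroph carbon
    dom_src: np.ndarray       # (n_dom, n_src) DOM carbon by producing source
    pom_src: np.ndarray       # (n_src,) POM carbon by producing source
    no3: float = 0.0
    nh4: float = 0.0
    po4: float = 0.0
    si: float = 0.0
    exported_c: float = 0.0   # cumulative respired carbon
    sunk_c: float = 0.0       # cumulative POM carbon lost to sinking export
    sunk_n: float = 0.0       # N/P/Si carried out by sinking particles (audit)
    sunk_p: float = 0.0
    sunk_si: float = 0.0
    loaded_n: float = 0.0     # cumulative external N loading (audit)
    loaded_p: float = 0.0
    loaded_si: float = 0.0

    @property
    def source_ids(self) -> list[str]:
        return self.phyto_ids + self.het_ids + [BACKGROUND_SOURCE]

    @property
    def dom_c(self) -> np.ndarray:
        return self.dom_src.sum(axis=1)

    @property
    def pom_c(self) -> float:
        return float(self.pom_src.sum())

    @property
    def ledger(self) -> "SourceLedger":
        return SourceLedger(
            dom_sources={
                d: {s: float(self.dom_src[j, k]) for k, s in enumerate(self.source_ids)
                    if self.dom_src[j, k] > 0}
                for j, d in enumerate(self.dom_ids)
            },
            pom_sources={s: float(self.pom_src[k]) for k, s in enumerate(self.source_ids)
                         if self.pom_src[k] > 0},
        )

    def total_organic_c(self) -> float:
        return float(self.bp.sum() + self.ba.sum() + self.bd.sum()
                     + self.dom_src.sum() + self.pom_src.sum())

    def total_n(self, config: ModelConfig) -> float:
        """All nitrogen ever in the system: organic at quota, dissolved
        inorganic, and N exported with sinking particles."""
        qn_dom = _dom_quota(config, "n")
        organic = config.q_n_bio * (self.bp.sum() + self.ba.sum() + self.bd.sum()
                                    + self.pom_src.sum())
        organic += float(self.dom_c @ qn_dom)
        return float(organic + self.no3 + self.nh4 + self.sunk_n)

    def total_p(self, config: ModelConfig) -> float:
        qp_dom = _dom_quota(config, "p")
        organic = config.q_p_bio * (self.bp.sum() + self.ba.sum() + self.bd.sum()
                                    + self.pom_src.sum())
        organic += float(self.dom_c @ qp_dom)
        return float(organic + self.po4 + self.sunk_p)

    def validate(self) -> None:
        arrays = (self.bp, self.ba, self.bd, self.dom_src, self.pom_src)
        if any(np.any(~np.isfinite(a)) for a in arrays):
            raise FluxIntegrityError("non-finite value in model state")
        if any(np.any(a < 0) for a in arrays):
            raise FluxIntegrityError("negative pool in model state")
        for name in ("no3", "nh4", "po4", "si"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < -1e-12:
                raise FluxIntegrityError(f"invalid nutrient {name}={v}")

    def copy(self) -> "ModelState":
        return replace(
            self,
            bp=self.bp.copy(), ba=self.ba.copy(), bd=self.bd.copy(),
            dom_src=self.dom_src.copy(), pom_src=self.pom_src.copy(),
        )


@dataclass
class SourceLedger:
    """Per-pool decomposition of DOM/POM mass by producing taxon (a view)."""

    dom_sources: dict[str, dict[str, float]]
    pom_sources: dict[str, float]


@dataclass(frozen=True)
class FluxRecord:
    """One timestamped carbon (or nutrient) flux between two compartments."""

    time: float
    source_id: str
    sink_id: str
    process: str
    value: float          # µmol C L⁻¹ d⁻¹ (µmol N/P L⁻¹ d⁻¹ when nutrient flag set)
    nutrient: bool = False


class FluxIntegrityError(RuntimeError):
    """Raised when the numerical mass balance is violated (should be unreachable)."""


def new_state(config: ModelConfig,
              phyto_c: Mapping[str, float],
              het_c: Mapping[str, float],
              dom_total: float = 1.0,
              pom_total: float = 0.5,
              no3: float = 6.0, nh4: float = 0.5,
              po4: float = 0.5, si: float = 4.0,
              dormant_fraction: float = 0.0) -> ModelState:
    """Build an initial state; seed DOM/POM mass is attributed to "background"."""
    phyto_ids = list(config.phyto)
    het_ids = list(config.het)
    n_dom, n_src = len(config.dom_ids), len(phyto_ids) + len(het_ids) + 1
    bp = np.array([max(0.0, phyto_c.get(p, 0.0)) for p in phyto_ids])
    btot = np.array([max(0.0, het_c.get(h, 0.0)) for h in het_ids])
    dom_src = np.zeros((n_dom, n_src))
    dom_src[:, -1] = dom_total / n_dom
    pom_src = np.zeros(n_src)
    pom_src[-1] = pom_total
    return ModelState(
        phyto_ids=phyto_ids, het_ids=het_ids, dom_ids=list(config.dom_ids),
        bp=bp, ba=btot * (1 - dormant_fraction), bd=btot * dormant_fraction,
        dom_src=dom_src, pom_src=pom_src,
        no3=no3, nh4=nh4, po4=po4, si=si,
    )


# ---------------------------------------------------------------------------
# Rate operations (per-taxon forms; `step` applies the same math vectorized)
# ---------------------------------------------------------------------------

def limitation_factors_phyto(params: PhytoParams, temperature: float, par: float,
                             daylength: float, din: float, po4: float,
                             si: float = 0.0) -> dict[str, float]:
    """Growth limitation factors of one phytoplankton taxon, each in [0, 1].

    Temperature follows a Q10 response capped at 1; light is a Monod term in
    PAR scaled by the photoperiod fraction; nutrients are Monod terms combined
    downstream by a Liebig minimum (``f_si`` is reported as 1 for
    non-silicifiers so the minimum ignores it).
    """
    f_t = min(1.0, params.q10 ** ((temperature - params.t_ref) / 10.0))
    f_i = par / (par + params.k_light) * (daylength / 24.0) if par > 0 else 0.0
    f_n = din / (din + params.k_din) if din > 0 else 0.0
    f_p = po4 / (po4 + params.k_po4) if po4 > 0 else 0.0
    f_si = (si / (si + params.k_si) if si > 0 else 0.0) if params.silicifier else 1.0
    return {"f_T": f_t, "f_I": f_i, "f_N": f_n, "f_P": f_p, "f_Si": f_si}


def growth_rate_phyto(params: PhytoParams, factors: Mapping[str, float]) -> float:
    """µ = mu_max · f_T · f_I · min(f_N, f_P[, f_Si]) (Liebig minimum)."""
    nut = min(factors["f_N"], factors["f_P"], factors["f_Si"])
    return params.mu_max * factors["f_T"] * factors["f_I"] * nut


def phyto_rates(params: PhytoParams, biomass: float,
                factors: Mapping[str, float]) -> dict[str, float]:
    """Carbon process rates of one phytoplankton taxon (µmol C L⁻¹ d⁻¹)."""
    if biomass < 0:
        raise ValueError("biomass must be >= 0")
    mu = growth_rate_phyto(params, factors)
    photo = mu * biomass
    exud = params.ke * biomass + params.fe * photo
    resp = params.kr * biomass + params.fr * photo
    death = params.kd * biomass
    return {
        "photosynthesis": photo,
        "exudation": exud,
        "respiration": resp,
        "death_dom": params.f_dom * death,
        "death_pom": (1.0 - params.f_dom) * death,
    }


def het_rates(params: HetParams, b_active: float, dom: Mapping[str, float],
              temperature: float) -> dict[str, object]:
    """Uptake/growth/respiration/death rates of one heterotroph taxon.

    Uptake of DOM species j: v_max · f_T · B · w_j · D_j/(D_j + K_j) with equal
    weights w over the species the taxon can use (Σw = 1).
    """
    if b_active < 0:
        raise ValueError("active biomass must be >= 0")
    f_t = min(1.0, params.q10 ** ((temperature - params.t_ref) / 10.0))
    usable = list(params.affinity)
    w = 1.0 / len(usable)
    uptake = {}
    for j in usable:
        d = max(0.0, dom.get(j, 0.0))
        uptake[j] = params.v_max * f_t * b_active * w * (d / (d + params.affinity[j])
                                                         if d > 0 else 0.0)
    total = sum(uptake.values())
    growth = params.yield_ * total
    death = params.kd * b_active
    return {
        "uptake": uptake,
        "growth": growth,
        "respiration": total - growth,
        "death_dom": params.f_dom * death,
        "death_pom": (1.0 - params.f_dom) * death,
        "f_T": f_t,
    }


def remineralization(uptake: float, growth: float, q_dom: float,
                     q_bio: float) -> float:
    """Net inorganic nutrient flux from heterotrophic consumption.

    ``uptake × q_dom`` enters with the consumed DOM; ``growth × q_bio`` is
    retained in new biomass; the difference is released to (positive) or drawn
    from (negative) the dissolved inorganic pool.
    """
    if not uptake >= growth >= 0:
        raise ValueError("need uptake >= growth >= 0")
    return uptake * q_dom - growth * q_bio


def pom_dissolution(pom: float, k_dis: float,
                    dom_alloc: Mapping[str, float]) -> dict[str, float]:
    """POM→DOM dissolution flux, distributed over DOM species."""
    if pom < 0:
        raise ValueError("pom must be >= 0")
    total = k_dis * pom
    return {j: total * a for j, a in dom_alloc.items()}


def dormancy_update(active: float, dormant: float, params: HetParams,
                    mu_net: float, dt: float) -> tuple[float, float]:
    """One Euler transfer between active and dormant pools (mass-conserving).

    Shrinking populations (µ_net < 0) retreat into dormancy at ``dorm_in``;
    growing ones (µ_net > 0) reactivate at ``dorm_out``.
    """
    if active < 0 or dormant < 0:
        raise ValueError("pools must be >= 0")
    if mu_net < 0:
        moved = min(active, params.dorm_in * active * dt)
        return active - moved, dormant + moved
    if mu_net > 0:
        moved = min(dormant, params.dorm_out * dormant * dt)
        return active + moved, dormant - moved
    return active, dormant


# ---------------------------------------------------------------------------
# Compiled configuration (array form) and the Euler step
# ---------------------------------------------------------------------------

def _dom_quota(config: ModelConfig, which: str) -> np.ndarray:
    base = config.q_n_bio if which == "n" else config.q_p_bio
    over = (config.q_n_dom if which == "n" else config.q_p_dom) or {}
    return np.array([over.get(d, base) for d in config.dom_ids])


def _alloc_row(alloc: Mapping[str, float] | None, dom_ids: Sequence[str]) -> np.ndarray:
    if alloc is None:
        return np.full(len(dom_ids), 1.0 / len(dom_ids))
    return np.array([alloc.get(d, 0.0) for d in dom_ids])


class CompiledConfig:
    """Array view of a ModelConfig used by the inner simulation loop."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.phyto_ids = list(config.phyto)
        self.het_ids = list(config.het)
        self.dom_ids = list(config.dom_ids)
        self.n_p, self.n_h, self.n_dom = (len(self.phyto_ids), len(self.het_ids),
                                          len(self.dom_ids))
        self.n_src = self.n_p + self.n_h + 1

        P = list(config.phyto.values())
        get = lambda attr: np.array([getattr(p, attr) for p in P], dtype=float)
        self.mu_max, self.k_light = get("mu_max"), get("k_light")
        self.k_din, self.k_po4, self.k_si = get("k_din"), get("k_po4"), get("k_si")
        self.q10_p, self.tref_p = get("q10"), get("t_ref")
        self.ke, self.fe, self.kr, self.fr = get("ke"), get("fe"), get("kr"), get("fr")
        self.kd_p, self.fdom_p = get("kd"), get("f_dom")
        self.silic = np.array([p.silicifier for p in P], dtype=bool)
        self.A_p = np.vstack([_alloc_row(p.dom_alloc, self.dom_ids) for p in P]) \
            if P else np.zeros((0, self.n_dom))

        H = list(config.het.values())
        geth = lambda attr: np.array([getattr(h, attr) for h in H], dtype=float)
        self.v_max, self.yields = geth("v_max"), geth("yield_")
        self.q10_h, self.tref_h = geth("q10"), geth("t_ref")
        self.kd_h, self.fdom_h = geth("kd"), geth("f_dom")
        self.dorm_in, self.dorm_out = geth("dorm_in"), geth("dorm_out")
        self.K = np.full((self.n_h, self.n_dom), np.inf)
        self.W = np.zeros((self.n_h, self.n_dom))
        for i, h in enumerate(H):
            usable = [self.dom_ids.index(j) for j in h.affinity]
            w = 1.0 / len(usable)
            for j_id, k in h.affinity.items():
                j = self.dom_ids.index(j_id)
                self.K[i, j] = k
                self.W[i, j] = w
        self.A_h = np.vstack([_alloc_row(h.dom_alloc, self.dom_ids) for h in H]) \
            if H else np.zeros((0, self.n_dom))

        self.pom_alloc = _alloc_row(config.pom_alloc, self.dom_ids)
        if abs(self.pom_alloc.sum() - 1.0) > 1e-9:
            raise ValueError("pom_alloc must sum to 1")
        self.qn_dom = _dom_quota(config, "n")
        self.qp_dom = _dom_quota(config, "p")
        self.qn, self.qp, self.qsi = config.q_n_bio, config.q_p_bio, config.q_si
        self.k_dis = config.k_dis
        self.k_sink = config.k_sink
        self.floor = config.seed_floor
        self.dorm_mult = config.dormant_death_mult


@dataclass
class StepFluxes:
    """All per-step flux terms (rates, µmol L⁻¹ d⁻¹) produced by :func:`step`."""

    photosynthesis: np.ndarray     # (n_p,)
    exudation: np.ndarray          # (n_p,)
    resp_p: np.ndarray             # (n_p,)
    death_dom_p: np.ndarray        # (n_p,)
    death_pom_p: np.ndarray        # (n_p,)
    uptake: np.ndarray             # (n_h, n_dom)
    growth: np.ndarray             # (n_h,)
    resp_h: np.ndarray             # (n_h,)
    death_dom_h: np.ndarray        # (n_h,)
    death_pom_h: np.ndarray        # (n_h,)
    dissolution: np.ndarray        # (n_src,) POM→DOM by original producer
    sinking: np.ndarray            # (n_src,) POM export by original producer
    remin_n: np.ndarray            # (n_h,) net NH4 release
    pairwise: np.ndarray           # (n_src, n_h) uptake attributed to producers
    load_n: float
    load_p: float
    load_si: float


def step(state: ModelState, comp: CompiledConfig, temperature: float, par: float,
         daylength: float, dt: float,
         load_no3: float = 0.0, load_po4: float = 0.0, load_si: float = 0.0,
         ) -> tuple[ModelState, StepFluxes]:
    """One explicit-Euler step; returns the new state and all flux terms.

    Outflows of any pool are proportionally rescaled whenever one step's demand
    would overdraw the stock, so no pool goes negative.  The DOM/POM source
    ledgers are updated in the same step: production adds mass under the
    producing taxon; consumption and dissolution remove mass proportionally to
    the current source fractions.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bp, ba, bd = state.bp, state.ba, state.bd
    D, pom = state.dom_src, state.pom_src
    no3, nh4, po4, si = state.no3, state.nh4, state.po4, state.si
    n_p, n_h = comp.n_p, comp.n_h

    # --- phytoplankton --------------------------------------------------
    f_t = np.minimum(1.0, comp.q10_p ** ((temperature - comp.tref_p) / 10.0))
    f_i = (par / (par + comp.k_light) if par > 0 else np.zeros(n_p)) * (daylength / 24.0)
    din = no3 + nh4
    f_n = din / (din + comp.k_din) if din > 0 else np.zeros(n_p)
    f_p = po4 / (po4 + comp.k_po4) if po4 > 0 else np.zeros(n_p)
    f_si = np.where(comp.silic, (si / (si + comp.k_si) if si > 0 else 0.0), 1.0)
    mu = comp.mu_max * f_t * f_i * np.minimum(f_n, np.minimum(f_p, f_si))
    photo = mu * bp

    # nutrient-supply caps on photosynthesis (proportional per pool)
    dem_n = photo.sum() * comp.qn * dt
    dem_p = photo.sum() * comp.qp * dt
    dem_si = float((photo * comp.silic).sum()) * comp.qsi * dt
    s_n = min(1.0, din / dem_n) if dem_n > din else 1.0
    s_p = min(1.0, po4 / dem_p) if dem_p > po4 else 1.0
    s_si = min(1.0, si / dem_si) if dem_si > si else 1.0
    scale = np.full(n_p, min(s_n, s_p))
    scale[comp.silic] = np.minimum(scale[comp.silic], min(s_n, s_p, s_si))
    photo = photo * scale

    exud = comp.ke * bp + comp.fe * photo
    resp_p = comp.kr * bp + comp.fr * photo
    death_p = comp.kd_p * bp
    if comp.floor > 0:
        # refuge: losses fade out as a taxon approaches the seed floor, so
        # populations can re-bloom after a seasonal collapse
        refuge = np.clip(1.0 - comp.floor / np.maximum(bp, _TINY), 0.0, 1.0)
        exud, resp_p, death_p = exud * refuge, resp_p * refuge, death_p * refuge
    out_p = exud + resp_p + death_p
    with np.errstate(divide="ignore", invalid="ignore"):
        cap = np.where(out_p * dt > bp, bp / np.maximum(out_p * dt, _TINY), 1.0)
    exud, resp_p, death_p = exud * cap, resp_p * cap, death_p * cap
    ddom_p = comp.fdom_p * death_p
    dpom_p = death_p - ddom_p

    # --- heterotrophs ---------------------------------------------------
    f_th = np.minimum(1.0, comp.q10_h ** ((temperature - comp.tref_h) / 10.0))
    Dtot = D.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(Dtot[None, :] > 0, Dtot[None, :] / (Dtot[None, :] + comp.K), 0.0)
    u = (comp.v_max * f_th * ba)[:, None] * comp.W * M
    dem_d = u.sum(axis=0) * dt
    s_d = np.where(dem_d > Dtot, Dtot / np.maximum(dem_d, _TINY), 1.0)
    u = u * s_d[None, :]
    U = u.sum(axis=1)
    growth = comp.yields * U

    # nutrient balance of heterotrophy (NH4/PO4 release or capped draw)
    n_in = u @ comp.qn_dom
    p_in = u @ comp.qp_dom
    def_n = np.maximum(0.0, growth * comp.qn - n_in)     # NH4 demand, rate
    def_p = np.maximum(0.0, growth * comp.qp - p_in)
    # availability after phytoplankton draws (NH4 consumed before NO3)
    n_draw_phyto = photo.sum() * comp.qn * dt
    draw_nh4_phyto = min(nh4, n_draw_phyto)
    draw_no3_phyto = n_draw_phyto - draw_nh4_phyto
    p_draw_phyto = photo.sum() * comp.qp * dt
    nh4_avail = nh4 - draw_nh4_phyto
    po4_avail = po4 - p_draw_phyto
    tot_def_n, tot_def_p = def_n.sum() * dt, def_p.sum() * dt
    s_dn = min(1.0, nh4_avail / tot_def_n) if tot_def_n > nh4_avail else 1.0
    s_dp = min(1.0, po4_avail / tot_def_p) if tot_def_p > po4_avail else 1.0
    if s_dn < 1.0 or s_dp < 1.0:
        # insufficient inorganic nutrients: reduce growth to what N and P
        # supply supports; surplus carbon is respired instead
        g_n = np.where(comp.qn > 0, (n_in + def_n * s_dn) / comp.qn, growth)
        g_p = np.where(comp.qp > 0, (p_in + def_p * s_dp) / comp.qp, growth)
        growth = np.minimum(growth, np.minimum(g_n, g_p))
        def_n = np.maximum(0.0, growth * comp.qn - n_in)
        def_p = np.maximum(0.0, growth * comp.qp - p_in)
    resp_h = U - growth
    remin_n = n_in - growth * comp.qn         # net NH4 flux (may be negative)
    remin_p = p_in - growth * comp.qp

    # dormancy and death
    mu_net = comp.yields * comp.v_max * f_th * (comp.W * M).sum(axis=1) - comp.kd_h
    to_dorm = np.where(mu_net < 0, comp.dorm_in * ba, 0.0)
    to_act = np.where(mu_net > 0, comp.dorm_out * bd, 0.0)
    death_a = comp.kd_h * ba
    if comp.floor > 0:
        tot_h = ba + bd
        refuge_h = np.clip(1.0 - comp.floor / np.maximum(tot_h, _TINY), 0.0, 1.0)
        death_a = death_a * refuge_h
    out_a = death_a + to_dorm
    with np.errstate(divide="ignore", invalid="ignore"):
        cap_a = np.where(out_a * dt > ba, ba / np.maximum(out_a * dt, _TINY), 1.0)
    death_a, to_dorm = death_a * cap_a, to_dorm * cap_a
    death_d = comp.kd_h * comp.dorm_mult * bd
    if comp.floor > 0:
        death_d = death_d * refuge_h
    out_d = death_d + to_act
    with np.errstate(divide="ignore", invalid="ignore"):
        cap_d = np.where(out_d * dt > bd, bd / np.maximum(out_d * dt, _TINY), 1.0)
    death_d, to_act = death_d * cap_d, to_act * cap_d
    death_h = death_a + death_d
    ddom_h = comp.fdom_h * death_h
    dpom_h = death_h - ddom_h

    # --- POM dissolution and sinking export -----------------------------
    k_tot = comp.k_dis + comp.k_sink
    s_pom = min(1.0, 1.0 / (k_tot * dt)) if k_tot * dt > 1.0 else 1.0
    dis_src = comp.k_dis * s_pom * pom        # (n_src,)
    sink_src = comp.k_sink * s_pom * pom      # (n_src,)

    # --- assemble new state --------------------------------------------
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(Dtot[:, None] > 0, D / np.maximum(Dtot[:, None], _TINY), 0.0)
    removal = u.sum(axis=0) * dt              # (n_dom,)
    D_new = D - removal[:, None] * frac
    D_new[:, :n_p] += (comp.A_p * ((exud + ddom_p) * dt)[:, None]).T
    D_new[:, n_p:n_p + n_h] += (comp.A_h * (ddom_h * dt)[:, None]).T
    D_new += comp.pom_alloc[:, None] * (dis_src * dt)[None, :]
    np.maximum(D_new, 0.0, out=D_new)         # clip float dust from exact emptying

    pom_new = pom - (dis_src + sink_src) * dt
    pom_new[:n_p] += dpom_p * dt
    pom_new[n_p:n_p + n_h] += dpom_h * dt
    np.maximum(pom_new, 0.0, out=pom_new)

    bp_new = np.maximum(bp + dt * (photo - exud - resp_p - death_p), 0.0)
    ba_new = np.maximum(ba + dt * (growth - death_a - to_dorm + to_act), 0.0)
    bd_new = np.maximum(bd + dt * (to_dorm - to_act - death_d), 0.0)

    # nutrient updates: quota-difference releases on every organic→DOM transfer
    dq_n = comp.qn - comp.qn_dom              # (n_dom,) ≥ 0 by validation
    dq_p = comp.qp - comp.qp_dom
    rel_n = (float((exud + ddom_p) @ (comp.A_p @ dq_n)) if n_p else 0.0) \
        + (float(ddom_h @ (comp.A_h @ dq_n)) if n_h else 0.0) \
        + float(dis_src.sum()) * float(comp.pom_alloc @ dq_n) \
        + resp_p.sum() * comp.qn + remin_n.sum()
    rel_p = (float((exud + ddom_p) @ (comp.A_p @ dq_p)) if n_p else 0.0) \
        + (float(ddom_h @ (comp.A_h @ dq_p)) if n_h else 0.0) \
        + float(dis_src.sum()) * float(comp.pom_alloc @ dq_p) \
        + resp_p.sum() * comp.qp + remin_p.sum()

    nh4_new = nh4 - draw_nh4_phyto + rel_n * dt
    no3_new = no3 - draw_no3_phyto + load_no3 * dt
    po4_new = po4 - p_draw_phyto + rel_p * dt + load_po4 * dt
    # silica: taken up by silicifier photosynthesis; returned by exudation,
    # respiration and DOM-routed death; opal in dead particles sinks out
    si_out = comp.qsi * float((photo * comp.silic).sum()) * dt
    si_back = comp.qsi * float(((exud + resp_p + ddom_p) * comp.silic).sum()) * dt
    si_sunk = comp.qsi * float((dpom_p * comp.silic).sum()) * dt
    si_new = si - si_out + si_back + load_si * dt
    # numerical floor: proportional capping keeps these non-negative up to
    # rounding; clip the dust
    nh4_new, no3_new = max(nh4_new, 0.0), max(no3_new, 0.0)
    po4_new, si_new = max(po4_new, 0.0), max(si_new, 0.0)

    exported_new = state.exported_c + dt * (resp_p.sum() + resp_h.sum())
    sink_total = float(sink_src.sum()) * dt

    # pairwise producer attribution of this step's uptake
    pairwise = frac.T @ (u.T * dt)            # (n_src, n_h), carbon amounts
    pairwise /= dt                            # back to rates

    new = ModelState(
        phyto_ids=state.phyto_ids, het_ids=state.het_ids, dom_ids=state.dom_ids,
        bp=bp_new, ba=ba_new, bd=bd_new, dom_src=D_new, pom_src=pom_new,
        no3=no3_new, nh4=nh4_new, po4=po4_new, si=si_new,
        exported_c=exported_new,
        sunk_c=state.sunk_c + sink_total,
        sunk_n=state.sunk_n + comp.qn * sink_total,
        sunk_p=state.sunk_p + comp.qp * sink_total,
        sunk_si=state.sunk_si + si_sunk,
        loaded_n=state.loaded_n + load_no3 * dt,
        loaded_p=state.loaded_p + load_po4 * dt,
        loaded_si=state.loaded_si + load_si * dt,
    )
    fluxes = StepFluxes(
        photosynthesis=photo, exudation=exud, resp_p=resp_p,
        death_dom_p=ddom_p, death_pom_p=dpom_p,
        uptake=u, growth=growth, resp_h=resp_h,
        death_dom_h=ddom_h, death_pom_h=dpom_h,
        dissolution=dis_src, sinking=sink_src, remin_n=remin_n, pairwise=pairwise,
        load_n=load_no3, load_p=load_po4, load_si=load_si,
    )
    if not (math.isfinite(new.exported_c) and np.all(np.isfinite(bp_new))
            and np.all(np.isfinite(D_new))):
        raise FluxIntegrityError("non-finite value after Euler step")
    return new, fluxes


# ---------------------------------------------------------------------------
# Trajectory container and the driver loop
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Simulation output at the configured cadence.

    State arrays are snapshots at ``times``; flux arrays are means over the
    output bin *ending* at each time (index k covers ``times[k]..times[k+1]``,
    so flux arrays have ``len(times) - 1`` rows).
    """

    times: np.ndarray                   # (T,) days since start
    start_date: np.datetime64 | None
    phyto_ids: list[str]
    het_ids: list[str]
    dom_ids: list[str]
    source_ids: list[str]
    bp: np.ndarray                      # (T, n_p)
    ba: np.ndarray                      # (T, n_h)
    bd: np.ndarray                      # (T, n_h)
    dom: np.ndarray                     # (T, n_dom)
    pom: np.ndarray                     # (T,)
    nutrients: np.ndarray               # (T, 4): no3, nh4, po4, si
    exported: np.ndarray                # (T,)
    ledger_dom: np.ndarray              # (T, n_dom, n_src)
    ledger_pom: np.ndarray              # (T, n_src)
    forcing: np.ndarray                 # (T, 3): temperature, par, daylength
    phyto_factors: np.ndarray           # (T, n_p, 5): f_T, f_I, f_N, f_P, f_Si
    het_factors: np.ndarray             # (T, n_h, 2): f_T, substrate factor
    flux: dict[str, np.ndarray]         # bin-mean flux arrays, keys as StepFluxes
    config: ModelConfig

    @property
    def n_bins(self) -> int:
        return len(self.times) - 1

    @property
    def dates(self) -> np.ndarray:
        if self.start_date is None:
            raise ValueError("trajectory has no calendar start date")
        return self.start_date + np.round(self.times * 24 * 3600).astype(
            "timedelta64[s]")

    def bin_mid_times(self) -> np.ndarray:
        return 0.5 * (self.times[:-1] + self.times[1:])

    def total_phyto_c(self) -> np.ndarray:
        return self.bp.sum(axis=1)

    def total_het_c(self) -> np.ndarray:
        return self.ba.sum(axis=1) + self.bd.sum(axis=1)

    def doc(self) -> np.ndarray:
        """Total model DOC (sum over DOM species), µmol C L⁻¹."""
        return self.dom.sum(axis=1)

    def flux_records(self) -> "pd.DataFrame":
        """Tidy table of all recorded fluxes (one row per FluxRecord)."""
        import pandas as pd

        rows: list[tuple] = []
        mids = self.bin_mid_times()
        fl = self.flux
        for k, t in enumerate(mids):
            t = float(t)
            for i, p in enumerate(self.phyto_ids):
                if fl["photosynthesis"][k, i] > 0:
                    rows.append((t, "DIC", p, "photosynthesis",
                                 fl["photosynthesis"][k, i], False))
                if fl["exudation"][k, i] > 0:
                    rows.append((t, p, "DOM", "exudation", fl["exudation"][k, i], False))
                if fl["resp_p"][k, i] > 0:
                    rows.append((t, p, "DIC", "respiration", fl["resp_p"][k, i], False))
                if fl["death_dom_p"][k, i] > 0:
                    rows.append((t, p, "DOM", "death_dom", fl["death_dom_p"][k, i], False))
                if fl["death_pom_p"][k, i] > 0:
                    rows.append((t, p, "POM", "death_pom", fl["death_pom_p"][k, i], False))
            for i, h in enumerate(self.het_ids):
                for j, d in enumerate(self.dom_ids):
                    v = fl["uptake"][k, i, j]
                    if v > 0:
                        rows.append((t, d, h, "uptake", v, False))
                if fl["resp_h"][k, i] > 0:
                    rows.append((t, h, "DIC", "respiration", fl["resp_h"][k, i], False))
                if fl["death_dom_h"][k, i] > 0:
                    rows.append((t, h, "DOM", "death_dom", fl["death_dom_h"][k, i], False))
                if fl["death_pom_h"][k, i] > 0:
                    rows.append((t, h, "POM", "death_pom", fl["death_pom_h"][k, i], False))
                if fl["remin_n"][k, i] != 0:
                    rows.append((t, h, "NH4", "remineralization",
                                 fl["remin_n"][k, i], True))
            dis = fl["dissolution"][k].sum()
            if dis > 0:
                rows.append((t, "POM", "DOM", "dissolution", dis, False))
            snk = fl["sinking"][k].sum()
            if snk > 0:
                rows.append((t, "POM", "EXPORT", "sinking", snk, False))
            if fl["load_n"][k] > 0:
                rows.append((t, "EXTERNAL", "NO3", "loading", fl["load_n"][k], True))
            if fl["load_p"][k] > 0:
                rows.append((t, "EXTERNAL", "PO4", "loading", fl["load_p"][k], True))
            if fl["load_si"][k] > 0:
                rows.append((t, "EXTERNAL", "Si", "loading", fl["load_si"][k], True))
        return pd.DataFrame(rows, columns=["time", "source_id", "sink_id",
                                           "process", "value", "nutrient"])

    def states_frame(self) -> "pd.DataFrame":
        """Tidy (time, compartment_id, value) table of all state series."""
        import pandas as pd

        frames = []
        for ids, arr in (
            (self.phyto_ids, self.bp),
            (self.het_ids, self.ba + self.bd),
            (self.dom_ids, self.dom),
        ):
            for i, cid in enumerate(ids):
                frames.append(pd.DataFrame(
                    {"time": self.times, "compartment_id": cid, "value": arr[:, i]}))
        frames.append(pd.DataFrame(
            {"time": self.times, "compartment_id": "POM", "value": self.pom}))
        for i, name in enumerate(["NO3", "NH4", "PO4", "Si"]):
            frames.append(pd.DataFrame(
                {"time": self.times, "compartment_id": name,
                 "value": self.nutrients[:, i]}))
        return pd.concat(frames, ignore_index=True)


def _interp_forcing(forcing: ForcingSeries, t: np.ndarray
                    ) -> tuple[np.ndarray, ...]:
    temp = np.interp(t, forcing.days, forcing.temperature)
    par = np.interp(t, forcing.days, forcing.par)
    dl = np.interp(t, forcing.days, forcing.daylength)
    loads = []
    idx = np.clip(np.searchsorted(forcing.days, t, side="right") - 1,
                  0, len(forcing.days) - 1)
    for arr in (forcing.load_no3, forcing.load_po4, forcing.load_si):
        loads.append(np.asarray(arr, dtype=float)[idx] if arr is not None
                     else np.zeros_like(t))
    return temp, par, dl, loads[0], loads[1], loads[2]


def simulate(config: ModelConfig, forcing: ForcingSeries, state: ModelState,
             t0: float = 0.0, t1: float | None = None,
             dt: float | None = None, output_every: float | None = None,
             start_date: np.datetime64 | str | None = None,
             check_balance: bool = False) -> Trajectory:
    """Run the model from ``t0`` to ``t1`` and record states and fluxes.

    Deterministic given config, forcing and initial state.  With
    ``check_balance`` the carbon balance is audited every step (Δ(organic C +
    exported) must equal the photosynthesis input to 1e-9 relative).
    """
    comp = CompiledConfig(config)
    dt = config.dt if dt is None else dt
    output_every = config.output_every if output_every is None else output_every
    lo, hi = forcing.span()
    if t1 is None:
        t1 = hi
    if not t1 > t0:
        raise ValueError("t1 must exceed t0")
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise ValueError("forcing does not cover the simulation span")
    if start_date is not None:
        start_date = np.datetime64(start_date)

    n_steps = int(round((t1 - t0) / dt))
    steps_per_bin = max(1, int(round(output_every / dt)))
    n_bins = math.ceil(n_steps / steps_per_bin)
    t_grid = t0 + dt * np.arange(n_steps + 1)
    temp, par, dl, l_n, l_p, l_si = _interp_forcing(forcing, t_grid[:-1])

    n_p, n_h, n_dom, n_src = comp.n_p, comp.n_h, comp.n_dom, comp.n_src
    T = n_bins + 1
    out = Trajectory(
        times=np.empty(T), start_date=start_date,
        phyto_ids=comp.phyto_ids, het_ids=comp.het_ids, dom_ids=comp.dom_ids,
        source_ids=comp.phyto_ids + comp.het_ids + [BACKGROUND_SOURCE],
        bp=np.empty((T, n_p)), ba=np.empty((T, n_h)), bd=np.empty((T, n_h)),
        dom=np.empty((T, n_dom)), pom=np.empty(T), nutrients=np.empty((T, 4)),
        exported=np.empty(T), ledger_dom=np.empty((T, n_dom, n_src)),
        ledger_pom=np.empty((T, n_src)), forcing=np.empty((T, 3)),
        phyto_factors=np.empty((T, n_p, 5)), het_factors=np.empty((T, n_h, 2)),
        flux={}, config=config,
    )
    acc = {
        "photosynthesis": np.zeros((n_bins, n_p)), "exudation": np.zeros((n_bins, n_p)),
        "resp_p": np.zeros((n_bins, n_p)), "death_dom_p": np.zeros((n_bins, n_p)),
        "death_pom_p": np.zeros((n_bins, n_p)),
        "uptake": np.zeros((n_bins, n_h, n_dom)), "growth": np.zeros((n_bins, n_h)),
        "resp_h": np.zeros((n_bins, n_h)), "death_dom_h": np.zeros((n_bins, n_h)),
        "death_pom_h": np.zeros((n_bins, n_h)), "dissolution": np.zeros((n_bins, n_src)),
        "sinking": np.zeros((n_bins, n_src)),
        "remin_n": np.zeros((n_bins, n_h)), "pairwise": np.zeros((n_bins, n_src, n_h)),
        "load_n": np.zeros(n_bins), "load_p": np.zeros(n_bins),
        "load_si": np.zeros(n_bins),
    }

    def snapshot(k: int, t: float, s: ModelState, tc: float, pc: float, dlc: float):
        out.times[k] = t
        out.bp[k], out.ba[k], out.bd[k] = s.bp, s.ba, s.bd
        out.dom[k] = s.dom_src.sum(axis=1)
        out.pom[k] = s.pom_src.sum()
        out.nutrients[k] = (s.no3, s.nh4, s.po4, s.si)
        out.exported[k] = s.exported_c
        out.ledger_dom[k] = s.dom_src
        out.ledger_pom[k] = s.pom_src
        out.forcing[k] = (tc, pc, dlc)
        # instantaneous limitation factors at the snapshot
        f_t = np.minimum(1.0, comp.q10_p ** ((tc - comp.tref_p) / 10.0))
        f_i = (pc / (pc + comp.k_light) if pc > 0 else np.zeros(n_p)) * (dlc / 24.0)
        din = s.no3 + s.nh4
        f_n = din / (din + comp.k_din) if din > 0 else np.zeros(n_p)
        f_pp = s.po4 / (s.po4 + comp.k_po4) if s.po4 > 0 else np.zeros(n_p)
        f_s = np.where(comp.silic, (s.si / (s.si + comp.k_si) if s.si > 0 else 0.0), 1.0)
        out.phyto_factors[k] = np.stack([f_t, f_i, f_n, f_pp, f_s], axis=1)
        f_th = np.minimum(1.0, comp.q10_h ** ((tc - comp.tref_h) / 10.0))
        Dtot = s.dom_src.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            M = np.where(Dtot[None, :] > 0,
                         Dtot[None, :] / (Dtot[None, :] + comp.K), 0.0)
        out.het_factors[k] = np.stack([f_th, (comp.W * M).sum(axis=1)], axis=1)

    cur = state.copy()
    tc0, pc0, dlc0, *_ = _interp_forcing(forcing, np.array([t0]))
    snapshot(0, t0, cur, float(tc0[0]), float(pc0[0]), float(dlc0[0]))

    for i in range(n_steps):
        if check_balance:
            before = cur.total_organic_c() + cur.exported_c + cur.sunk_c
        cur, fl = step(cur, comp, float(temp[i]), float(par[i]), float(dl[i]), dt,
                       float(l_n[i]), float(l_p[i]), float(l_si[i]))
        k = i // steps_per_bin
        for key in ("photosynthesis", "exudation", "resp_p", "death_dom_p",
                    "death_pom_p", "growth", "resp_h", "death_dom_h",
                    "death_pom_h", "dissolution", "sinking", "remin_n"):
            acc[key][k] += getattr(fl, key) * dt
        acc["uptake"][k] += fl.uptake * dt
        acc["pairwise"][k] += fl.pairwise * dt
        acc["load_n"][k] += fl.load_n * dt
        acc["load_p"][k] += fl.load_p * dt
        acc["load_si"][k] += fl.load_si * dt
        if check_balance:
            after = cur.total_organic_c() + cur.exported_c + cur.sunk_c
            supplied = fl.photosynthesis.sum() * dt
            scale_ref = max(abs(before) + supplied, 1.0)
            if abs(after - before - supplied) > 1e-9 * scale_ref:
                raise FluxIntegrityError(
                    f"carbon balance violated at step {i}: "
                    f"Δ={after - before:.3e} vs P={supplied:.3e}")
        if (i + 1) % steps_per_bin == 0 or i == n_steps - 1:
            t = t0 + (i + 1) * dt
            tcv, pcv, dlcv, *_ = _interp_forcing(forcing, np.array([t]))
            snapshot(i // steps_per_bin + 1, t, cur,
                     float(tcv[0]), float(pcv[0]), float(dlcv[0]))
    cur.validate()

    # convert accumulated amounts to bin-mean rates
    bin_len = np.diff(out.times)
    for key, arr in acc.items():
        shape = (n_bins,) + (1,) * (arr.ndim - 1)
        out.flux[key] = arr / bin_len.reshape(shape)
    return out
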