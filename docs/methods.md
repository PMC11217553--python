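# Methods

## The inference problem

Amplicon surveys and bulk measurements describe *who is there*, not *who
feeds whom*.  `carbonflux` closes that gap with mechanistic inference: a
mass-balance ecosystem model whose state variables correspond to the observed
quantities (per-taxon carbon, nutrients) is calibrated to a weekly time
series, and the calibrated model's explicitly simulated carbon fluxes are
then read off as estimates of the unobservable interactions — in particular
the flux of dissolved organic carbon (DOC) from phytoplankton to
heterotrophic prokaryotes, and the "internal recycling" flux from
heterotrophic prokaryotes to other heterotrophic prokaryotes via DOC released
on death.

## Model structure

State variables (all carbon in µmol C L⁻¹, nutrients in µmol L⁻¹):

* phytoplankton taxa (eukaryotic OTUs plus *Synechococcus* as an ordinary
  phytoplankton taxon with its own parameters);
* heterotrophic prokaryote taxa, each split into an active and a dormant
  sub-pool;
* a configurable number of hypothetical DOM species — distinct substrate
  classes with taxon-specific production allocations and uptake affinities;
* one POM pool;
* NO₃, NH₄, PO₄ and silicate;
* bookkeeping sinks: cumulative respired carbon and cumulative carbon (and
  nutrients) exported by particle sinking.

Process rates:

* **Phytoplankton growth** µ = µ_max · f_T · f_I · min(f_N, f_P[, f_Si]) with
  a Q10 temperature factor capped at 1 (f_T = min(1, Q10^((T−T_ref)/10))), a
  Monod light term scaled by the photoperiod fraction
  (f_I = I/(I+k_I) · daylength/24), Monod nutrient terms and a Liebig
  minimum.  The silicate term applies only to taxa flagged as silicifiers.
* **Exudation** E = k_e·B + f_e·P: a basal leak plus a fixed fraction of
  photosynthesis.  **Respiration** has the same form (k_r, f_r).
* **Death** at rate k_d, split f_dom : (1−f_dom) between DOM and POM.  Death
  is a lumped closure for viral lysis and grazing; the DOM/POM split is what
  distinguishes them diagnostically (lysis releases mostly dissolved
  material), which is why the death-release DOM/POM ratio is reported as a
  lysis indicator.
* **Heterotrophic uptake** of DOM species j:
  u_j = v_max · f_T · B · w_j · D_j/(D_j+K_j), with equal weights w_j over
  the species a taxon can use.  Growth is yield·ΣU; the rest is respired.
  Heterotrophs do not exude DOM, so every heterotroph→heterotroph flux is
  death-mediated.
* **Remineralization**: nitrogen enters with consumed DOM at its quota and
  is retained in biomass at the Redfield quota; the difference is released
  to NH₄ (or drawn from it when the substrate is nutrient-poor — in that
  case the draw is capped by availability and growth is reduced, the excess
  carbon being respired).  Phosphorus is handled identically.
* **POM** dissolves into DOM at k_dis and sinks out at k_sink.  Sinking is
  the system's only organic export; without it, winter nutrient loadings
  accumulate year over year and no recurring seasonal regime exists.
* **Dormancy**: when a heterotroph's net specific growth is negative, active
  biomass retreats to a dormant pool (rate dorm_in); when positive, dormant
  biomass reactivates (dorm_out).  Dormant cells take up nothing and die at
  a reduced rate (configurable multiplier).  This prevents extinctions and
  supports coexistence through the seasonal cycle.
* **Seed-floor refuge** (default off): all loss terms of a taxon fade to
  zero as its biomass approaches a small configured floor.  This plays the
  role dormancy plays for heterotrophs, but for phytoplankton: a taxon can
  collapse seasonally yet re-bloom the next year.  No mass is ever injected,
  so conservation is unaffected.
* **Nutrient loadings**: non-negative increments of measured nutrient totals
  are applied as distributed external sources over their observation
  interval, representing water-mass intrusions.

## Source ledgers and flux attribution

Every DOM species and the POM pool is stored *as* its source ledger: a
vector of masses indexed by the taxon that produced the carbon (plus a
"background" entry for initial mass).  Production adds mass under the
producer; consumption and dissolution remove mass proportionally to the
current source fractions.  Because the pool total is defined as the ledger
sum, attribution consistency is exact by construction.

Pairwise producer→consumer fluxes are obtained by multiplying each
consumer's uptake of DOM species j by the ledger fractions of j (averaged
over the output-bin endpoints).  The simulator additionally accumulates the
exact per-Euler-step attribution, which the synthetic-data generator exposes
as ground truth; the analysis-side estimate and the exact attribution agree
closely at the default daily output cadence, and the analysis invariant
Σ_producers flux(p→h) = total uptake of h holds exactly.

## Numerics

Fixed-step explicit Euler (default dt = 0.05 d) with **proportional outflow
capping**: whenever one step's total outflow demand of a pool exceeds its
stock, all outflows of that pool are scaled by the factor that empties it
exactly.  No pool ever goes negative, every recorded flux is an exact term
of the discrete balance, and carbon closure Δ(organic C + respired + sunk) =
photosynthesis input holds to machine precision each step (the simulator can
audit this every step; the acceptance suite requires < 1e-9 relative).
Euler was chosen over an adaptive integrator because the flux records are
then exact sums of the mass balance rather than quadrature approximations.
Accuracy: the global error against the closed-form single-species
exponential is first order in dt (≈ r²·t·dt/2), about 0.5% at dt = 0.01 d
for r ≈ 0.22 d⁻¹ over 20 days; halving dt halves the error.

Stoichiometry is fixed Redfield (N:C = 16/106, P:C = 1/106) for all biomass
and, by default, for DOM; DOM quotas may be lowered per species (never
raised above the biomass quota, which validation enforces so organic→DOM
transfers always release rather than draw inorganic nutrients).  Silicate is
taken up by silicifier photosynthesis at 15/106 and returned on dissolved
loss paths; the opal of dead particulate cells is exported with sinking.

## Observation model (ingest)

* Chlorophyll → carbon with a fixed 40 gC/gChl ratio (divided by
  12.011 g mol⁻¹; 1 mg chl m⁻³ ↔ 3.3303 µmol C L⁻¹).
* *Synechococcus* cytometric counts → carbon at 1.4·10⁻¹⁴ mol C cell⁻¹.
* 18S tables: the 10 000 most abundant ASVs are kept (ties broken by
  ascending ASV id), heterotrophic and unassigned ASVs dropped, the rest
  lumped into OTUs by the finest assigned taxonomic name, and OTU read
  fractions (renormalized over retained OTUs) multiplied by the
  chlorophyll-derived total — so OTU carbon sums exactly to the total.
* 16S tables: chloroplast, unassigned, cyanobacterial and ammonia-oxidizing
  archaeal lineages are removed by configurable regex filters; the retained
  ASVs' read fractions are multiplied by total heterotroph carbon, obtained
  from cytometric counts at 2.0·10⁻¹⁵ mol C cell⁻¹ (a configurable quota; a
  fixed total can be supplied when counts are absent).
* Observations are never interpolated; only physical forcing (temperature,
  PAR, daylength) is interpolated inside the simulator.

## Calibration

The objective is Σ_series w · Σ_dates (log10(model+ε) − log10(obs+ε))² with
ε = 10⁻⁴ µmol C L⁻¹, over per-taxon carbon series plus the total
phytoplankton and total heterotroph series, the totals weighted by their
member counts so composition and bulk fit contribute comparably.  The log
scale makes a ten-fold error cost the same for rare and abundant taxa.

The optimizer is a greedy stochastic hill climb: each iteration multiplies a
random subset of 1–3 free parameters by lognormal noise (σ = 0.2 by
default), clips to literature-scale bounds, simulates, and accepts only
improvements.  It is deterministic given the seed, and the best-objective
trace is non-increasing by construction.  A simulated-annealing acceptance
schedule exists but is off by default — on the synthetic problems the greedy
rule recovers parameters well and is easier to reason about.  Years are
calibrated separately (initial state = observed carbon at the year's first
sample); delumping proceeds in two stages (lumped groups → members), with
children inheriting jittered parent parameters and the parent's carbon split
by observed member fractions.

Calibration runs use a coarsened Euler step (dt = 0.2 d) for speed; the
fitted configuration is re-simulated at the fine step for all flux analyses.
The coarse-step bias is small relative to the recovery tolerances (recovery
experiments come in near 2% error against a 20% criterion).

## Bloom definitions and derived quantities

Blooms are typed seasonal maxima: spring phytoplankton (February–May,
chlorophyll), summer phytoplankton (July–August, chlorophyll), bacterial
summer (June–August, total heterotroph concentration).  The start is the
latest local minimum within the 28 days before the peak (bloom starts are
operationally assigned in field practice, so explicit overrides are
first-class); the bloom ends 28 days after the start unless the
concentration falls below its starting value first, and the duration cap can
be overridden (longer windows are legitimate when concentrations stay high).
Restricting the start search to the 28 pre-peak days is what guarantees
start ≤ peak ≤ end.

Derived quantities: bloom-mean and weekly (7-day bins anchored at the start)
phytoplankton→heterotroph and heterotroph→heterotroph fluxes; GPP, NPP
(= GPP − phytoplankton respiration), gross (= yield·uptake) and net
(= gross − death) heterotrophic production, volumetric and areal (× depth;
default 50 m, configurable — reported areal values scale linearly with this
choice); DOC-normalized heterotrophy rates uptake/(B_het·DOC) in L mol⁻¹ d⁻¹
with DOC = Σ model DOM pools (the model carries no recalcitrant background
DOC); the heterotroph death DOM/POM release ratio with its lysis flag
(ratio > 1 exactly when the carbon-weighted mean f_dom exceeds ½); per-taxon
limitation-factor series recomputed from stored states (they equal the
factors recorded during simulation); and a flux-network snapshot for the
median day of each bloom window, with node sizes following the
outflow/inflow/throughflow convention.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions: 2 simulated years (365-day
years), 5 eukaryotic OTUs + *Synechococcus* + 8 heterotroph ASVs + 6 DOM
species; sinusoidal temperate-coastal forcing (8–16.5 °C, daylength
8–16.5 h, PAR peaking at the solstice) and winter (October–February)
nutrient loadings; weekly sampling (52 dates per year); lognormal
measurement noise (σ = 0.15) on bulk quantities; Dirichlet-multinomial read
sampling (depth 50 000, concentration 500) around true carbon fractions,
each OTU split over two member ASVs; and decoy ASVs (heterotrophic and
unassigned 18S; chloroplast, *Synechococcus*, ammonia-oxidizing archaeon and
unassigned 16S) that the ingest filters must remove.  Chlorophyll represents
the eukaryotic phytoplankton only — *Synechococcus* is observed through
cytometry, exactly as its carbon is derived in the ingest — which keeps the
OTU-carbon-sums-to-total invariant exact.

The true configuration was tuned once, at design time, until the
deterministic truth run exhibits the intended qualitative regime in both
years: a spring diatom/picoeukaryote bloom (~April), a bacterial bloom in
June/early July gated by the heterotrophs' steep temperature response on the
DOC accumulated in spring, a summer phytoplankton peak after the bacterial
peak fed by remineralized NH₄, an HP→HP share of attributed uptake that is
near zero in spring blooms, reaches ~0.2–0.3 in bacterial blooms and rises
from the first to the last bloom week, and a death DOM/POM ratio of ≈1.14
(f_dom = 0.533 for heterotrophs).

What passing tests on these data do **not** show about real observations:
the generator and the inference share the same process model (no structural
mismatch), read fractions are unbiased proxies of carbon fractions
(no copy-number, extraction or primer bias), conversion factors are exactly
the ones the ingest assumes, forcing is noise-free, and there is no
allochthonous DOM.  Recovery results here are therefore upper bounds on what
field data would support.

## Problem sizes and tolerances

The validation experiments (tests and the acceptance script) use: 2000 Euler
steps for the conservation audit (tolerance 1e-9 relative; measured at
machine precision); dt = 0.01 d over 20 days for the exponential check
(tolerance 1%); five observation-noise seeds, one calibration year at
dt = 0.2 and 60 hill-climb iterations for the two-parameter recovery
(tolerance 20% median error) and the flux-share recovery (tolerance ±0.15
median absolute error, five jittered parameters).  These sizes keep a full
validation run in a few minutes on one CPU while leaving the tolerances
far from binding.

## Known limitations

* No grazers, viruses or oxygen as state variables; death is lumped.
* Q10 temperature response has no supra-optimal decline, so cold-adapted
  taxa are never heat-limited; summer succession must come from nutrient
  and substrate competition.
* Fixed stoichiometry (no luxury uptake or variable quotas).
* Single well-mixed box; sinking is a one-way loss with no resuspension.
* The hill climb finds good fits on the synthetic problems but is a local
  method; the multi-seed spread is the only uncertainty measure provided.
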