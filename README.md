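# carbonflux

Mechanistic inference of carbon fluxes in plankton microbial communities
from time-series observations.

Molecular surveys (16S/18S amplicon tables, flow cytometry, chlorophyll)
measure the *composition* of a microbial community but not the *fluxes*
between its members — who produced the dissolved organic carbon (DOC) a
given bacterium is eating cannot be observed directly.  `carbonflux` closes
that gap for whoever needs flux estimates from monitoring data (microbial
ecologists, biogeochemical modellers): it converts the observations into a
common carbon currency, calibrates a mass-balance ecosystem model to them,
and reads the fluxes off the calibrated model, with every unit of consumed
DOC attributed to the taxon that originally released it.

## The model in brief

State variables: phytoplankton taxa B_p, heterotrophic prokaryote taxa B_h
(active + dormant), many hypothetical DOM species D_j, one POM pool, and
inorganic nutrients (NO₃, NH₄, PO₄, Si), all as differential mass balances.
Phytoplankton grow at

&nbsp;&nbsp;µ = µ_max · min(1, Q10^((T−T_ref)/10)) · I/(I+k_I) · (daylength/24) · min(f_N, f_P[, f_Si]),

exude DOM at k_e·B + f_e·P (basal rate plus a fraction of photosynthesis),
respire, and die at k_d with the death flux split f_dom : 1−f_dom between
DOM and POM (POM dissolves back into DOM and partly sinks out).
Heterotrophs take up DOM species j at v_max · f_T · B · w_j · D_j/(D_j+K_j)
with taxon-specific affinities K_j, grow with a fixed efficiency (the rest
is respired, remineralizing N and P at Redfield stoichiometry), die into
DOM/POM, and never exude — so every heterotroph→heterotroph carbon flux is
death-mediated ("internal recycling", the viral-shunt pathway).  Each DOM
pool carries a **source ledger** (mass by producing taxon); consumption
removes mass proportionally to the source fractions, which is what turns a
simulation into a producer-attributed flux network.

Integration is explicit Euler with proportional outflow capping, so pools
never go negative and carbon/nitrogen/phosphorus are conserved to machine
precision — the test suite enforces 1e-9.  Calibration is a seeded,
reproducible stochastic hill climb on a log-scale least-squares objective,
run per year, with gradual delumping of lumped taxa.  Bloom windows (spring
phytoplankton, bacterial summer, summer phytoplankton) are detected as
seasonal concentration maxima with a default 28-day duration.  A
synthetic-data generator emulates the whole observation structure (weekly
cadence, Dirichlet-multinomial read tables with decoy ASVs, cytometric
counts, seasonal forcing) so the entire pipeline is testable end to end.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

Generate one synthetic year, ingest it, compute the flux network and the
report (the `calibrate` stage is skipped here, so the fluxes come from the
generator's true configuration):

```sh
carbonflux run --seed 5 --outdir runs/demo \
    --stages synth,ingest,fluxes,report \
    --override synth.scenario.years=1
```

`runs/demo/report/summary.txt` then contains (exact output):

```
                 phyto_to_het  het_to_het     gpp     npp  gross_het_prod  net_het_prod  dom_pom_ratio
bloom_type
bacteria_summer        1.9060      0.7129  2.7490  1.9502          0.7918        0.0146         1.1413
phyto_spring           0.0000      0.0000  3.0185  2.4396          0.0000       -0.0016         1.1413
phyto_summer           2.4592      0.6563  3.5245  2.6531          0.9467        0.0671         1.1413
```

Reading it: in the **spring bloom** heterotrophs are still cold-limited —
phytoplankton production (NPP 2.44 µmol C L⁻¹ d⁻¹) runs ahead of
consumption and the phyto→heterotroph flux is negligible; DOC accumulates.
In the **bacterial summer bloom** heterotrophs consume that stock: the
phyto→het flux (1.91 µmol C L⁻¹ d⁻¹) now rivals NPP (1.95), and the
het→het flux (0.71) — carbon released by heterotroph death and re-consumed
by other heterotrophs — is a substantial fraction of the total, rising
through the bloom as phytoplankton-derived DOC is exhausted.  The DOM/POM
death-release ratio of 1.14 (> 1) indicates the dissolved-dominated release
expected from viral lysis rather than protist grazing.  Whole-run GPP in
this scenario is 0.80 µmol C L⁻¹ d⁻¹, i.e. 40 mmol C m⁻² d⁻¹ over the
default 50 m integration depth.

The same run leaves tidy CSVs under `runs/demo/fluxes/` (pairwise
producer→consumer fluxes, bloom table, per-bloom fluxes and production,
limitation-factor series) and a GraphML flux-network snapshot for the
median day of each bloom.

The library surface mirrors the pipeline: `generate_ground_truth` /
`sample_observations` (synthetic data), `read_observations` /
`observations_to_carbon` (ingest), `simulate` (model), `calibrate_year`
(fitting), `pairwise_fluxes` / `detect_blooms` / `production_metrics`
(analysis).

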