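"""Observation ingest: reading time-series tables and converting to carbon.

Reads weekly monitoring tables (chlorophyll, 18S/16S amplicon read counts
with taxonomy, flow-cytometric cell counts, nutrients, physical forcing) and
converts everything onto a common currency of µmol C L⁻¹: chlorophyll via a
fixed 40 gC/gChl factor, Synechococcus cell counts via a per-cell carbon
quota, 18S read fractions (after dropping heterotrophic/unassigned ASVs and
lumping the remainder into OTUs) via the chlorophyll-derived total, and 16S
read fractions (after dropping chloroplast/unassigned/cyanobacterial/
ammonia-oxidizing-archaeal ASVs) via a cytometry-derived total heterotroph
carbon.  Missing weeks are never interpolated in observations; only physical
forcing is interpolated downstream.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationSet",
    "CarbonObservations",
    "IngestOptions",
    "read_observations",
    "chl_to_carbon",
    "cells_to_carbon",
    "prefilter_top_n",
    "classify_and_lump_18s",
    "filter_16s",
    "reads_to_carbon",
    "derive_nutrient_loadings",
    "observations_to_carbon",
    "write_carbon_csv",
]

CHL_TO_C_G_PER_G = 40.0         # g phytoplankton carbon per g chlorophyll
CARBON_MOLAR_MASS = 12.011      # g mol⁻¹
SYN_CELL_QUOTA_MOL = 1.4e-14    # mol C per Synechococcus cell
HET_CELL_QUOTA_MOL = 2.0e-15    # mol C per heterotrophic prokaryote cell

# lineage patterns removed from 16S tables (case-insensitive regex)
DEFAULT_16S_EXCLUDE = ("chloroplast", "unassigned", "cyanobacteria",
                       "nitroso(pumilus|sphaera)|ammonia.oxidizing")

NUTRIENT_COLS = ["no3no2", "nh4", "po4", "si"]


@dataclass
class ObservationSet:
    """All measured series on one common (weekly, possibly gappy) date axis.

    Missing values are NaN, never zero-filled.  Read tables are wide
    (rows = ASV, columns = dates); taxonomy frames are indexed by asv_id with
    ``lineage`` (semicolon-separated) and ``trophy`` columns.
    """

    dates: pd.DatetimeIndex
    chlorophyll: pd.Series              # mg m⁻³
    asv18s: pd.DataFrame                # reads
    tax18s: pd.DataFrame
    asv16s: pd.DataFrame
    tax16s: pd.DataFrame
    syn_counts: pd.Series               # cells L⁻¹
    nutrients: pd.DataFrame             # µmol L⁻¹, columns no3no2/nh4/po4/si
    temperature: pd.Series              # °C
    par: pd.Series
    daylength: pd.Series                # h
    het_counts: pd.Series | None = None  # cells L⁻¹ (cytometric heterotrophs)
    poc: pd.Series | None = None        # µmol C L⁻¹

    def validate(self) -> None:
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing and unique")
        for name in ("chlorophyll", "syn_counts", "temperature", "par",
                     "daylength"):
            s = getattr(self, name)
            if not s.index.equals(self.dates):
                raise ValueError(f"series {name} not aligned with date axis")
        for name, s in (("chlorophyll", self.chlorophyll),
                        ("syn_counts", self.syn_counts),
                        ("het_counts", self.het_counts)):
            if s is not None and (s.dropna() < 0).any():
                raise ValueError(f"negative values in {name}")
        if (self.nutrients.stack().dropna() < 0).any():
            raise ValueError("negative nutrient concentrations")
        for name, t in (("asv18s", self.asv18s), ("asv16s", self.asv16s)):
            vals = t.to_numpy()
            finite = vals[np.isfinite(vals)]
            if (finite < 0).any():
                raise ValueError(f"negative read counts in {name}")
            if not np.allclose(finite, np.round(finite)):
                raise ValueError(f"non-integer read counts in {name}")
        dl = self.daylength.dropna()
        if ((dl < 0) | (dl > 24)).any():
            raise ValueError("daylength must lie in [0, 24] hours")


@dataclass
class CarbonObservations:
    """All observations expressed as carbon concentrations (µmol C L⁻¹)."""

    dates: pd.DatetimeIndex
    total_phyto_c: pd.Series
    phyto_otu_c: pd.DataFrame           # rows = OTU, columns = dates
    syn_c: pd.Series
    het_asv_c: pd.DataFrame             # rows = ASV, columns = dates
    total_het_c: pd.Series
    nutrients: pd.DataFrame
    het_taxon_of_asv: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        tot = self.phyto_otu_c.sum(axis=0)
        obs = self.total_phyto_c
        both = tot.notna() & obs.notna() & (obs > 0)
        if both.any():
            rel = np.abs(tot[both] - obs[both]) / obs[both]
            if (rel > 1e-9).any():
                raise ValueError("OTU carbon does not sum to total phytoplankton "
                                 "carbon")
        for frame in (self.phyto_otu_c, self.het_asv_c):
            vals = frame.to_numpy()
            if (vals[np.isfinite(vals)] < 0).any():
                raise ValueError("negative carbon concentration")


# ---------------------------------------------------------------------------
# File reading
# ---------------------------------------------------------------------------

@dataclass
class TableSchema:
    """Column-name configuration for :func:`read_observations`."""

    date: str = "date"
    chlorophyll: str = "chlorophyll"
    syn_cells: str = "syn_cells"
    het_cells: str = "het_cells"
    temperature: str = "temperature"
    par: str = "par"
    daylength: str = "daylength"
    poc: str = "poc"
    nutrients: Mapping[str, str] = field(default_factory=lambda: {
        "no3no2": "no3no2", "nh4": "nh4", "po4": "po4", "si": "si"})
    asv_layout: str = "wide"            # "wide" or "long"
    long_cols: tuple[str, str, str] = ("asv_id", "date", "count")


def _parse_dates(values: Sequence[str], context: str) -> pd.DatetimeIndex:
    try:
        return pd.DatetimeIndex(pd.to_datetime(values, format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable ISO-8601 date in {context}: {exc}") from exc


def _read_asv_table(path: Path, schema: TableSchema) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)
    if schema.asv_layout == "long":
        a, d, c = schema.long_cols
        dates = _parse_dates(raw[d], str(path))
        raw = raw.assign(**{d: dates})
        table = raw.pivot_table(index=a, columns=d, values=c, aggfunc="sum")
    else:
        table = raw.set_index(raw.columns[0])
        table.columns = _parse_dates(table.columns, str(path))
    if (table.fillna(0).to_numpy() < 0).any():
        raise ValueError(f"negative read counts in {path}")
    return table


def _read_taxonomy(path: Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "asv_id" not in tax.columns or "lineage" not in tax.columns:
        raise ValueError(f"taxonomy file {path} needs asv_id and lineage columns")
    if "trophy" not in tax.columns:
        tax["trophy"] = ""
    return tax.set_index("asv_id")


def read_observations(paths: Mapping[str, str | Path],
                      schema: TableSchema | None = None) -> ObservationSet:
    """Read observation tables and align them on the union of their dates.

    ``paths`` must provide ``bulk`` (scalar series incl. nutrients), the read
    tables ``asv18s``/``asv16s`` and their taxonomies ``tax_asv18s``/
    ``tax_asv16s``.  A date present in only one file appears in the common
    axis with the other series marked missing.
    """
    schema = schema or TableSchema()
    bulk = pd.read_csv(Path(paths["bulk"]))
    bdates = _parse_dates(bulk[schema.date], "bulk table")
    bulk = bulk.set_index(bdates)
    if (bulk[schema.chlorophyll].dropna() < 0).any():
        raise ValueError("negative chlorophyll in bulk table")

    asv18 = _read_asv_table(Path(paths["asv18s"]), schema)
    asv16 = _read_asv_table(Path(paths["asv16s"]), schema)
    tax18 = _read_taxonomy(Path(paths["tax_asv18s"]))
    tax16 = _read_taxonomy(Path(paths["tax_asv16s"]))

    dates = bdates.union(asv18.columns).union(asv16.columns)

    def series(col: str) -> pd.Series:
        if col in bulk.columns:
            return bulk[col].reindex(dates).astype(float)
        return pd.Series(np.nan, index=dates)

    nutrients = pd.DataFrame(
        {key: series(col) for key, col in schema.nutrients.items()})
    obs = ObservationSet(
        dates=dates,
        chlorophyll=series(schema.chlorophyll),
        asv18s=asv18.reindex(columns=dates), tax18s=tax18,
        asv16s=asv16.reindex(columns=dates), tax16s=tax16,
        syn_counts=series(schema.syn_cells),
        het_counts=series(schema.het_cells),
        nutrients=nutrients,
        temperature=series(schema.temperature),
        par=series(schema.par),
        daylength=series(schema.daylength),
        poc=series(schema.poc),
    )
    obs.validate()
    return obs


# ---------------------------------------------------------------------------
# Unit conversions (all linear and homogeneous)
# ---------------------------------------------------------------------------

def chl_to_carbon(chl):
    """Chlorophyll (mg m⁻³) → phytoplankton carbon (µmol C L⁻¹).

    Fixed conversion of 40 g carbon per g chlorophyll; mg C m⁻³ equals
    µg C L⁻¹, divided by 12.011 g mol⁻¹.
    """
    arr = np.asarray(chl, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("chlorophyll must be >= 0")
    out = arr * CHL_TO_C_G_PER_G / CARBON_MOLAR_MASS
    return float(out) if np.isscalar(chl) else out


def cells_to_carbon(count, quota_mol: float = SYN_CELL_QUOTA_MOL):
    """Cell counts (cells L⁻¹) → carbon (µmol C L⁻¹) at a per-cell quota."""
    arr = np.asarray(count, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("cell count must be >= 0")
    out = arr * quota_mol * 1e6
    return float(out) if np.isscalar(count) else out


# ---------------------------------------------------------------------------
# ASV filtering and lumping
# ---------------------------------------------------------------------------

def prefilter_top_n(asv_table: pd.DataFrame, n: int = 10_000) -> pd.DataFrame:
    """Keep the ``n`` ASVs with the highest total reads over all dates.

    Ties at the cutoff break by ascending asv_id, so the result is
    deterministic; tables with at most ``n`` ASVs pass unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(asv_table) <= n:
        return asv_table.copy()
    totals = asv_table.fillna(0).sum(axis=1)
    order = sorted(asv_table.index, key=lambda a: (-totals[a], str(a)))
    keep = order[:n]
    return asv_table.loc[[a for a in asv_table.index if a in set(keep)]]


def finest_taxon(lineage: str) -> str:
    """Finest non-empty name of a semicolon-separated lineage string."""
    parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
    return parts[-1] if parts else "unclassified"


def classify_and_lump_18s(asv_table: pd.DataFrame, taxonomy: pd.DataFrame,
                          lump_key=finest_taxon) -> pd.DataFrame:
    """Drop heterotrophic/unassigned 18S ASVs and lump the rest into OTUs.

    ASVs sharing a lumping key (by default the finest assigned taxonomic
    name) are summed into one OTU per date.  ASVs without a taxonomy record
    are treated as unassigned and logged.
    """
    keys = {}
    for asv in asv_table.index:
        if asv not in taxonomy.index:
            logger.warning("18S ASV %s lacks a taxonomy record; treated as "
                           "unassigned", asv)
            continue
        rec = taxonomy.loc[asv]
        if str(rec.get("trophy", "")).lower() != "phototrophic":
            continue
        keys[asv] = lump_key(rec["lineage"])
    if not keys:
        warnings.warn("no phototrophic 18S ASVs retained; OTU table is empty",
                      stacklevel=2)
        return asv_table.iloc[0:0]
    sub = asv_table.loc[list(keys)]
    return sub.groupby([keys[a] for a in sub.index]).sum(min_count=1)


def filter_16s(asv_table: pd.DataFrame, taxonomy: pd.DataFrame,
               exclude: Sequence[str] = DEFAULT_16S_EXCLUDE) -> pd.DataFrame:
    """Remove chloroplast/unassigned/cyanobacterial/AOA 16S ASVs."""
    patterns = [re.compile(p, re.IGNORECASE) for p in exclude]
    keep = []
    for asv in asv_table.index:
        lineage = str(taxonomy.loc[asv, "lineage"]) if asv in taxonomy.index \
            else "unassigned"
        if not any(p.search(lineage) for p in patterns):
            keep.append(asv)
    if not keep:
        warnings.warn("all 16S ASVs excluded by lineage filters", stacklevel=2)
    return asv_table.loc[keep]


def reads_to_carbon(read_fractions: pd.DataFrame,
                    pool_carbon: pd.Series) -> pd.DataFrame:
    """Per-taxon carbon = read fraction × pool carbon (µmol C L⁻¹).

    Fractions must be non-negative and sum to at most 1 per date; when they
    sum to 1 the per-taxon carbon sums exactly to the pool.
    """
    vals = read_fractions.to_numpy(dtype=float)
    if (vals[np.isfinite(vals)] < 0).any():
        raise ValueError("read fractions must be >= 0")
    sums = read_fractions.sum(axis=0, skipna=True)
    if (sums > 1 + 1e-9).any():
        raise ValueError("read fractions sum to more than 1")
    return read_fractions.mul(pool_carbon.reindex(read_fractions.columns), axis=1)


def derive_nutrient_loadings(series: pd.Series) -> pd.DataFrame:
    """Non-negative increments of a measured nutrient total, per interval.

    Increases of the measured total beyond what the model can produce
    internally are balanced by external loadings (water-mass intrusions):
    for each observation interval, loading = max(0, increase), reported both
    as an amount (µmol L⁻¹) and as a rate distributed over the interval.
    """
    s = series.dropna().sort_index()
    if len(s) < 2:
        return pd.DataFrame(columns=["start", "end", "amount", "rate"])
    starts, ends = s.index[:-1], s.index[1:]
    amounts = np.maximum(0.0, np.diff(s.to_numpy()))
    days = (ends - starts) / pd.Timedelta(days=1)
    return pd.DataFrame({"start": starts, "end": ends, "amount": amounts,
                         "rate": amounts / days.to_numpy()})


# ---------------------------------------------------------------------------
# Full conversion pipeline
# ---------------------------------------------------------------------------

@dataclass
class IngestOptions:
    top_n_18s: int = 10_000
    het_cell_quota_mol: float = HET_CELL_QUOTA_MOL
    fixed_total_het_c: float | None = None   # µmol C L⁻¹, used without counts
    exclude_16s: Sequence[str] = DEFAULT_16S_EXCLUDE


def observations_to_carbon(obs: ObservationSet,
                           options: IngestOptions | None = None
                           ) -> CarbonObservations:
    """Convert an ObservationSet to carbon units with the standard filters.

    18S: top-N prefilter → drop heterotrophic/unassigned → lump to OTUs →
    read fractions (renormalized over retained OTUs) × chlorophyll-derived
    total phytoplankton carbon.  16S: lineage exclusion filters → read
    fractions × total heterotroph carbon from cytometric counts and a
    per-cell quota (or a configured fixed total when counts are missing).
    """
    opt = options or IngestOptions()
    total_phyto = pd.Series(chl_to_carbon(obs.chlorophyll.to_numpy()),
                            index=obs.dates)
    syn_c = pd.Series(cells_to_carbon(obs.syn_counts.to_numpy()),
                      index=obs.dates)

    table18 = prefilter_top_n(obs.asv18s.fillna(0).astype(float), opt.top_n_18s)
    otus = classify_and_lump_18s(table18, obs.tax18s)
    reads_total = otus.sum(axis=0)
    frac18 = otus.div(reads_total.where(reads_total > 0), axis=1)
    otu_c = reads_to_carbon(frac18, total_phyto)

    table16 = filter_16s(obs.asv16s.fillna(0).astype(float), obs.tax16s,
                         opt.exclude_16s)
    if obs.het_counts is not None and obs.het_counts.notna().any():
        total_het = pd.Series(
            cells_to_carbon(obs.het_counts.to_numpy(), opt.het_cell_quota_mol),
            index=obs.dates)
    elif opt.fixed_total_het_c is not None:
        total_het = pd.Series(opt.fixed_total_het_c, index=obs.dates)
    else:
        raise ValueError("no heterotroph counts and no fixed total configured")
    reads16_total = table16.sum(axis=0)
    frac16 = table16.div(reads16_total.where(reads16_total > 0), axis=1)
    het_c = reads_to_carbon(frac16, total_het)

    het_map = {asv: finest_taxon(obs.tax16s.loc[asv, "lineage"])
               for asv in table16.index if asv in obs.tax16s.index}
    carbon = CarbonObservations(
        dates=obs.dates, total_phyto_c=total_phyto, phyto_otu_c=otu_c,
        syn_c=syn_c, het_asv_c=het_c, total_het_c=total_het,
        nutrients=obs.nutrients.copy(), het_taxon_of_asv=het_map,
    )
    carbon.validate()
    return carbon


def write_carbon_csv(carbon: CarbonObservations, path: str | Path) -> Path:
    """Write carbon observations as tidy CSV (taxon_id, date, carbon)."""
    rows = []
    for frame, prefix in ((carbon.phyto_otu_c, ""), (carbon.het_asv_c, "")):
        for taxon in frame.index:
            for date, val in frame.loc[taxon].items():
                rows.append((taxon, pd.Timestamp(date).strftime("%Y-%m-%d"), val))
    for name, series in (("total_phytoplankton", carbon.total_phyto_c),
                         ("Synechococcus", carbon.syn_c),
                         ("total_heterotrophs", carbon.total_het_c)):
        for date, val in series.items():
            rows.append((name, pd.Timestamp(date).strftime("%Y-%m-%d"), val))
    df = pd.DataFrame(rows, columns=["taxon_id", "date", "carbon_umol_per_L"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
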