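"""Per-year, per-region indicator-kriging orchestration.

For every modelled year the global reef raster is split into four ocean
regions (Caribbean, Indian, Pacific, East Pacific by default).  Within a
region-year:

1. presence = reef cells holding at least one report of severity > 1;
2. pseudo-absence = reef cells whose annual maximum DHW stayed below the
   chosen threshold (0.5 degC-weeks by default) — heat-driven bleaching is
   implausible without thermal stress, and true absence reports are too
   scarce to use alone;
3. if the region-year holds enough of both classes, an empirical indicator
   variogram is fitted automatically and ordinary kriging predicts the
   probability of bleaching at every reef cell in the region;
4. otherwise the region-year falls back to the degenerate assignment:
   probability 1.0 at presence cells, 0.0 everywhere else.

Per-region fragments are then combined into one global probability map per
year, with per-region provenance (kriged / fallback / no-data) recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .grid import CellIndex, ReefMask, cell_center
from .report_db import BleachingReport, parse_reports, presence_cells, snap_reports
from .thermal_stress import annual_max_dhw_grid, mmm_grid
from .variogram import ALL_FAMILIES, EmpiricalVariogram, VariogramModel, autofit_variogram, empirical_variogram
from .kriging import IndicatorObservation, krige_grid

PSEUDO_ABSENCE_THRESHOLDS = (0.0, 0.25, 0.5, 1.0)

PROVENANCE_KRIGED = "kriged"
PROVENANCE_FALLBACK = "fallback"
PROVENANCE_NO_DATA = "no-data"


@dataclass
class RegionSpec:
    """A named ocean region as a union of lon/lat rectangles.

    Rectangles are (lon_min, lon_max, lat_min, lat_max), half-open on the
    upper edges.  Reef cells are assigned to the first region whose box
    contains their center; a region flagged ``catch_all`` collects the
    remainder so that the regions always partition the mask.
    """

    name: str
    boxes: list[tuple[float, float, float, float]] = field(default_factory=list)
    catch_all: bool = False

    def contains(self, lat: float, lon: float) -> bool:
        return any(lo <= lon < hi and la <= lat < ha for lo, hi, la, ha in self.boxes)


def default_regions() -> list[RegionSpec]:
    """Rectangles approximating the four published kriging basins."""
    return [
        RegionSpec("Caribbean", [(-100.0, -55.0, 5.0, 40.0)]),
        RegionSpec("EastPacific", [(-120.0, -65.0, -35.0, 5.0)]),
        RegionSpec("Indian", [(20.0, 100.0, -45.0, 35.0)]),
        RegionSpec("Pacific", [(100.0, 180.0, -50.0, 50.0), (-180.0, -120.0, -50.0, 50.0)], catch_all=True),
    ]


def assign_regions(mask: ReefMask, regions: Sequence[RegionSpec]) -> dict[str, list[CellIndex]]:
    """Partition the reef mask over the regions (first-match, then catch-all)."""
    catch = next((r.name for r in regions if r.catch_all), regions[-1].name)
    out: dict[str, list[CellIndex]] = {r.name: [] for r in regions}
    for cell in mask:
        lat, lon = cell_center(cell)
        for region in regions:
            if region.contains(lat, lon):
                out[region.name].append(cell)
                break
        else:
            out[catch].append(cell)
    return out


@dataclass
class PipelineConfig:
    """Tunable knobs of the interpolation pipeline (YAML-serializable)."""

    pseudo_absence_threshold: float = 0.5   # degC-weeks; strict <, 0 means "zero all year"
    presence_precedence: bool = True        # presence wins when a cell qualifies as both
    min_presence_cells: int = 5             # sufficiency rule: all three must hold
    min_absence_cells: int = 5
    min_lag_bins: int = 3
    n_max_neighbors: int = 100
    n_lags: int = 15
    cutoff_km: Optional[float] = None       # default: max pair distance / 3
    families: list[str] = field(default_factory=lambda: list(ALL_FAMILIES))
    variogram_weights: str = "npairs_over_h2"
    manual_initials: Optional[tuple[float, float, float]] = None  # retry pathway
    max_snap_km: float = 50.0
    climatology_years: Optional[tuple[int, int]] = None  # default: first 10 full years
    years: tuple[int, int] = (1985, 2017)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if cfg.climatology_years is not None:
            cfg.climatology_years = tuple(cfg.climatology_years)
        if cfg.manual_initials is not None:
            cfg.manual_initials = tuple(cfg.manual_initials)
        cfg.years = tuple(cfg.years)
        return cfg


@dataclass
class ProbabilityMap:
    """Annual global bleaching-probability surface on the reef raster."""

    year: int
    probabilities: dict[CellIndex, float]          # NaN = no-data
    provenance: dict[str, str]                     # region -> kriged | fallback | no-data
    models: dict[str, Optional[VariogramModel]] = field(default_factory=dict)

    def to_frame(self, region_of: Optional[dict[CellIndex, str]] = None) -> pd.DataFrame:
        rows = []
        for cell in sorted(self.probabilities, key=lambda c: (c.j, c.i)):
            lat, lon = cell_center(cell)
            region = region_of.get(cell) if region_of else None
            prov = self.provenance.get(region, "") if region else ""
            rows.append({
                "year": self.year, "i": cell.i, "j": cell.j, "lat": lat, "lon": lon,
                "probability": self.probabilities[cell], "region": region, "provenance": prov,
            })
        return pd.DataFrame(rows)


# -- observation assembly ---------------------------------------------------

def generate_pseudo_absences(
    annual_max: dict[CellIndex, float],
    region_cells: Sequence[CellIndex],
    threshold: float,
    presence: set[CellIndex],
    presence_precedence: bool = True,
) -> list[IndicatorObservation]:
    """Value-0 observations at thermally quiet reef cells.

    For a positive threshold a cell qualifies when its annual maximum DHW
    is strictly below it; the zero threshold keeps only cells whose DHW
    was zero all year.  Presence cells are excluded when presence
    precedence is on (the default; the published text is ambiguous when a
    cell holds severe reports but no thermal stress).
    """
    out = []
    for cell in region_cells:
        if cell not in annual_max:
            raise KeyError(f"annual-max DHW missing for region cell ({cell.i}, {cell.j})")
        if presence_precedence and cell in presence:
            continue
        amax = annual_max[cell]
        quiet = (amax == 0.0) if threshold == 0.0 else (amax < threshold)
        if quiet:
            lat, lon = cell_center(cell)
            out.append(IndicatorObservation(lat=lat, lon=lon, value=0, cell=cell))
    return out


def assemble_indicator_data(
    presence: set[CellIndex],
    absences: Sequence[IndicatorObservation],
    region_cells: Optional[Sequence[CellIndex]] = None,
) -> list[IndicatorObservation]:
    """One observation per cell: 1 at presence cells, 0 at pseudo-absences.

    A cell appearing in both inputs collapses to a single value-1
    observation (presence precedence).  Cells in neither set are
    prediction-only.
    """
    region_set = set(region_cells) if region_cells is not None else None
    obs: dict[CellIndex, IndicatorObservation] = {}
    for cell in sorted(presence, key=lambda c: (c.j, c.i)):
        if region_set is not None and cell not in region_set:
            continue
        lat, lon = cell_center(cell)
        obs[cell] = IndicatorObservation(lat=lat, lon=lon, value=1, cell=cell)
    for ab in absences:
        if ab.cell in obs:
            continue  # presence wins
        obs[ab.cell] = ab
    return list(obs.values())


# -- region-year interpolation ----------------------------------------------

@dataclass
class RegionYearOutcome:
    region: str
    year: int
    provenance: str
    n_presence: int
    n_absence: int
    model: Optional[VariogramModel] = None
    n_lag_bins: int = 0
    n_failed_cells: int = 0
    note: str = ""


def interpolate_year_region(
    presence: set[CellIndex],
    annual_max: dict[CellIndex, float],
    region_cells: Sequence[CellIndex],
    region_name: str,
    year: int,
    config: PipelineConfig,
) -> tuple[dict[CellIndex, float], RegionYearOutcome]:
    """Probability surface for one region-year: kriged when data suffice.

    The sufficiency rule requires at least ``min_presence_cells`` presence
    cells, ``min_absence_cells`` pseudo-absence cells, and
    ``min_lag_bins`` non-empty variogram lag bins; anything less falls
    back to 1.0 at presence cells and 0.0 elsewhere, as does a variogram
    that fails to converge even after a retry from manual initials.
    """
    region_presence = {c for c in presence if c in set(region_cells)}
    absences = generate_pseudo_absences(
        annual_max, region_cells, config.pseudo_absence_threshold,
        region_presence, config.presence_precedence,
    )
    obs = assemble_indicator_data(region_presence, absences, region_cells)
    outcome = RegionYearOutcome(
        region=region_name, year=year, provenance=PROVENANCE_FALLBACK,
        n_presence=len(region_presence), n_absence=len(absences),
    )

    def fallback(note: str) -> tuple[dict[CellIndex, float], RegionYearOutcome]:
        outcome.provenance = PROVENANCE_FALLBACK
        outcome.note = note
        probs = {c: (1.0 if c in region_presence else 0.0) for c in region_cells}
        return probs, outcome

    if len(region_presence) < config.min_presence_cells or len(absences) < config.min_absence_cells:
        return fallback("insufficient presence/absence data")

    lats = np.array([o.lat for o in obs])
    lons = np.array([o.lon for o in obs])
    vals = np.array([o.value for o in obs], dtype=float)
    try:
        emp = empirical_variogram(lats, lons, vals, n_lags=config.n_lags, cutoff=config.cutoff_km)
    except ValueError as exc:
        return fallback(f"variogram estimation failed: {exc}")
    outcome.n_lag_bins = emp.n_nonempty
    if emp.n_nonempty < config.min_lag_bins:
        return fallback("too few non-empty variogram lag bins")

    try:
        model = autofit_variogram(emp, config.families, weights=config.variogram_weights)
    except (RuntimeError, ValueError):
        if config.manual_initials is None:
            return fallback("variogram fitting failed")
        try:
            model = autofit_variogram(
                emp, config.families, initial=config.manual_initials,
                weights=config.variogram_weights,
            )
        except (RuntimeError, ValueError):
            return fallback("variogram fitting failed even with manual initials")

    centers = [cell_center(c) for c in region_cells]
    results, errors = krige_grid(
        obs, model,
        [la for la, _ in centers], [lo for _, lo in centers],
        n_max=config.n_max_neighbors,
    )
    probs: dict[CellIndex, float] = {}
    for cell, res in zip(region_cells, results):
        probs[cell] = res.estimate if res is not None else math.nan
    outcome.provenance = PROVENANCE_KRIGED
    outcome.model = model
    outcome.n_failed_cells = len(errors)
    return probs, outcome


def combine_regions(
    fragments: dict[str, dict[CellIndex, float]],
    region_assignment: dict[str, list[CellIndex]],
    outcomes: dict[str, RegionYearOutcome],
    year: int,
) -> ProbabilityMap:
    """Union of per-region fragments into one global map.

    Regions without a fragment are flagged no-data (NaN probabilities),
    never silently zeroed.  Values are carried over bit-exactly.
    """
    probs: dict[CellIndex, float] = {}
    provenance: dict[str, str] = {}
    models: dict[str, Optional[VariogramModel]] = {}
    for region, cells in region_assignment.items():
        frag = fragments.get(region)
        if frag is None:
            provenance[region] = PROVENANCE_NO_DATA
            models[region] = None
            for cell in cells:
                probs[cell] = math.nan
            continue
        provenance[region] = outcomes[region].provenance
        models[region] = outcomes[region].model
        for cell in cells:
            if cell in probs:
                raise ValueError(f"cell ({cell.i}, {cell.j}) assigned by more than one region")
            probs[cell] = frag[cell]
    return ProbabilityMap(year=year, probabilities=probs, provenance=provenance, models=models)


# -- full pipeline ----------------------------------------------------------

@dataclass
class SSTGrid:
    """Daily SST for every reef cell, time-major, aligned with mask order."""

    dates: pd.DatetimeIndex
    values: np.ndarray          # (T, n_cells)
    mask: ReefMask

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, mask: ReefMask) -> "SSTGrid":
        """Build from a long table with columns date, i, j, sst."""
        df = df.copy()
        df.columns = [c.lower() for c in df.columns]
        df["date"] = pd.to_datetime(df["date"])
        pivot = df.pivot_table(index="date", columns=["i", "j"], values="sst")
        dates = pd.DatetimeIndex(pivot.index)
        cols = [(c.i, c.j) for c in mask.cells]
        missing = [c for c in cols if c not in pivot.columns]
        if missing:
            raise ValueError(f"SST table missing {len(missing)} reef cells, e.g. {missing[0]}")
        values = pivot[cols].to_numpy()
        if np.isnan(values).any():
            raise ValueError("SST table has gaps; fill or trim before running the pipeline")
        return cls(dates=dates, values=values, mask=mask)

    @classmethod
    def from_csv(cls, path, mask: ReefMask) -> "SSTGrid":
        return cls.from_long_frame(pd.read_csv(path), mask)

    def to_long_frame(self) -> pd.DataFrame:
        cells = self.mask.cells
        n_t, n_c = self.values.shape
        return pd.DataFrame({
            "date": np.repeat(self.dates.strftime("%Y-%m-%d"), n_c),
            "i": np.tile([c.i for c in cells], n_t),
            "j": np.tile([c.j for c in cells], n_t),
            "sst": self.values.ravel(),
        })


@dataclass
class PipelineResult:
    maps: list[ProbabilityMap]
    run_report: pd.DataFrame            # one row per region-year
    annual_max: pd.DataFrame            # year x cell-position annual max DHW
    region_assignment: dict[str, list[CellIndex]]
    qc_log: list = field(default_factory=list)

    def region_of(self) -> dict[CellIndex, str]:
        return {c: r for r, cells in self.region_assignment.items() for c in cells}

    def maps_frame(self) -> pd.DataFrame:
        region_of = self.region_of()
        return pd.concat([m.to_frame(region_of) for m in self.maps], ignore_index=True)


def compute_annual_max_dhw(sst: SSTGrid, config: PipelineConfig, years: Sequence[int]) -> pd.DataFrame:
    clim_years = config.climatology_years
    if clim_years is None:
        counts = pd.Series(1, index=sst.dates).groupby(sst.dates.year).sum()
        full = [int(y) for y, n in counts.items() if n >= 365]
        if not full:
            raise ValueError("SST series contains no complete calendar year for the climatology")
        clim_years = (full[0], full[:10][-1])
    mmm = mmm_grid(sst.dates, sst.values, clim_years)
    return annual_max_dhw_grid(sst.dates, sst.values, mmm, years=list(years))


def _annual_max_by_cell(annual_max: pd.DataFrame, mask: ReefMask, year: int) -> dict[CellIndex, float]:
    row = annual_max.loc[year]
    return {cell: float(row.iloc[k]) for k, cell in enumerate(mask.cells)}


def run_pipeline(
    reports,
    sst: SSTGrid,
    mask: ReefMask,
    regions: Optional[Sequence[RegionSpec]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """End-to-end annual interpolation.

    Parameters
    ----------
    reports : path | DataFrame | list of BleachingReport
        The observational report table (CSV schema of `report_db`).
    sst, mask : the daily SST grid and reef raster.
    regions : kriging regions (default: the four-basin layout).
    config : pipeline knobs (default: PipelineConfig()).
    """
    config = config or PipelineConfig()
    regions = list(regions) if regions is not None else default_regions()
    years = list(range(config.years[0], config.years[1] + 1))

    if isinstance(reports, (list, tuple)) and (not reports or isinstance(reports[0], BleachingReport)):
        parsed = list(reports)
        qc_log = []
    else:
        res = parse_reports(reports, last_year=config.years[1])
        parsed, qc_log = res.reports, res.log
    located, snap_log = snap_reports(parsed, mask, max_snap_km=config.max_snap_km)
    qc_log = list(qc_log) + snap_log

    annual_max = compute_annual_max_dhw(sst, config, years)
    region_assignment = assign_regions(mask, regions)

    maps: list[ProbabilityMap] = []
    report_rows = []
    for year in years:
        presence = presence_cells(located, year)
        amax = _annual_max_by_cell(annual_max, mask, year)
        fragments: dict[str, dict[CellIndex, float]] = {}
        outcomes: dict[str, RegionYearOutcome] = {}
        for region in regions:
            cells = region_assignment[region.name]
            if not cells:
                continue
            probs, outcome = interpolate_year_region(
                presence, amax, cells, region.name, year, config
            )
            fragments[region.name] = probs
            outcomes[region.name] = outcome
            report_rows.append({
                "year": year, "region": region.name, "provenance": outcome.provenance,
                "n_presence": outcome.n_presence, "n_absence": outcome.n_absence,
                "family": outcome.model.family if outcome.model else "",
                "nugget": outcome.model.nugget if outcome.model else np.nan,
                "partial_sill": outcome.model.partial_sill if outcome.model else np.nan,
                "range_km": outcome.model.range_km if outcome.model else np.nan,
                "rss": outcome.model.rss if outcome.model else np.nan,
                "n_lag_bins": outcome.n_lag_bins,
                "n_failed_cells": outcome.n_failed_cells,
                "note": outcome.note,
            })
        maps.append(combine_regions(fragments, region_assignment, outcomes, year))
    run_report = pd.DataFrame(report_rows)
    return PipelineResult(maps=maps, run_report=run_report, annual_max=annual_max,
                          region_assignment=region_assignment, qc_log=qc_log)


def threshold_sensitivity(
    reports,
    sst: SSTGrid,
    mask: ReefMask,
    region: RegionSpec,
    year: int,
    thresholds: Sequence[float] = PSEUDO_ABSENCE_THRESHOLDS,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Probability at report cells under alternative pseudo-absence thresholds.

    For each candidate threshold the region-year is re-interpolated and the
    mean/median probability over cells with observed presence reported —
    the harness behind choosing the operational 0.5 degC-week cutoff.
    Thresholds for which kriging is impossible are flagged, not dropped.
    """
    base = config or PipelineConfig()
    # scope to the region: subset the reef mask (and SST columns) to cells
    # whose centers fall inside the region's boxes
    keep_idx = [k for k, c in enumerate(mask.cells) if region.contains(*cell_center(c))]
    if not keep_idx:
        raise ValueError(f"region {region.name} contains no reef cells")
    sub_mask = ReefMask([mask.cells[k] for k in keep_idx])
    order = {(c.i, c.j): k for k, c in zip(keep_idx, [mask.cells[k] for k in keep_idx])}
    cols = [order[(c.i, c.j)] for c in sub_mask.cells]
    sub_sst = SSTGrid(dates=sst.dates, values=sst.values[:, cols], mask=sub_mask)

    rows = []
    for thr in thresholds:
        cfg = PipelineConfig(**{**asdict(base), "pseudo_absence_threshold": thr})
        cfg.families = list(base.families)
        cfg.years = (year, year)
        result = run_pipeline(
            reports, sub_sst, sub_mask,
            regions=[RegionSpec(region.name, list(region.boxes), catch_all=True)],
            config=cfg,
        )
        pmap = result.maps[0]
        located, _ = snap_reports(
            parse_reports(reports).reports if not isinstance(reports, list) else reports,
            sub_mask, max_snap_km=cfg.max_snap_km,
        )
        pres = {c for c in presence_cells(located, year) if c in pmap.probabilities}
        probs = [pmap.probabilities[c] for c in pres]
        outcome = result.run_report.iloc[0]
        rows.append({
            "threshold": thr,
            "provenance": outcome["provenance"],
            "n_presence": int(outcome["n_presence"]),
            "n_absence": int(outcome["n_absence"]),
            "mean_presence_prob": float(np.nanmean(probs)) if probs else np.nan,
            "median_presence_prob": float(np.nanmedian(probs)) if probs else np.nan,
        })
    return pd.DataFrame(rows)
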