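"""Seeded synthetic worlds with known ground truth.

Real inputs to the reconstruction — a curated bleaching-report database
and a satellite SST product — cannot ship with the package, so every
stage is exercised against generated worlds that mimic their statistical
structure: reefs clustered inside four ocean basins, daily SST with a
latitude-dependent seasonal cycle, a linear warming trend, AR(1) weather
noise and discrete Gaussian heatwave events, a logistic link from annual
maximum DHW to true bleaching, and a biased observation process
(region-dependent survey effort, occasional false and unknown-severity
reports, coordinate errors that push reports off the reef raster).

Everything derives deterministically from (seed, parameters): the same
pair always yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .grid import CellIndex, ReefMask, cell_center, haversine_km, latlon_to_cell
from .pipeline import RegionSpec, SSTGrid, assign_regions, default_regions
from .thermal_stress import annual_max_dhw_grid, mmm_grid


@dataclass
class WorldParams:
    """Generator knobs; defaults define the standard study conditions."""

    n_clusters: int = 4                   # one reef cluster per region
    cells_per_cluster: int = 50
    cluster_sigma_deg: float = 1.2        # spatial spread of each cluster

    start_year: int = 1998
    n_baseline_years: int = 3             # event-free years for the MMM climatology
    n_model_years: int = 5                # modelled (interpolated) years

    base_sst_c: float = 29.0              # tropical mean minus latitude decay
    lat_decay_c_per_deg: float = 0.08
    seasonal_amplitude_c: float = 1.5
    warming_trend_c_per_decade: float = 0.2
    ar1_rho: float = 0.8                  # daily weather noise
    ar1_sigma_c: float = 0.3

    event_prob: float = 0.7               # per region per model year
    event_peak_range_c: tuple[float, float] = (1.5, 3.5)
    event_duration_range_days: tuple[int, int] = (40, 90)
    event_radius_range_km: tuple[float, float] = (100.0, 250.0)

    beta0: float = -4.0                   # logistic link: p = expit(beta0 + beta1 * annual max DHW)
    beta1: float = 1.0
    effort: dict = field(default_factory=lambda: {
        "Caribbean": 0.5, "Indian": 0.3, "Pacific": 0.3, "EastPacific": 0.2,
    })
    false_report_rate: float = 0.02
    unknown_severity_rate: float = 0.05
    coord_error_rate: float = 0.10
    coord_error_deg: tuple[float, float] = (0.08, 0.30)

    @property
    def model_years(self) -> list[int]:
        first = self.start_year + self.n_baseline_years
        return list(range(first, first + self.n_model_years))

    @property
    def all_years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_baseline_years + self.n_model_years))

    @property
    def climatology_years(self) -> tuple[int, int]:
        return (self.start_year, self.start_year + self.n_baseline_years - 1)


@dataclass
class HeatwaveEvent:
    year: int
    region: str
    center_lat: float
    center_lon: float
    radius_km: float
    peak_c: float
    duration_days: int
    peak_doy: int


@dataclass
class SyntheticWorld:
    seed: int
    params: WorldParams
    mask: ReefMask
    regions: list[RegionSpec]
    region_assignment: dict[str, list[CellIndex]]
    sst: SSTGrid
    events: list[HeatwaveEvent]
    truth: pd.DataFrame            # year, i, j, annual_max_dhw, p_bleach, bleached
    reports: pd.DataFrame          # report_db CSV schema

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "params": asdict(self.params),
            "n_reef_cells": len(self.mask),
            "model_years": self.params.model_years,
            "events": [asdict(e) for e in self.events],
        }


def make_reef_mask(
    seed: int,
    n_clusters: int = 4,
    cells_per_cluster: int = 50,
    regions: Optional[Sequence[RegionSpec]] = None,
    cluster_sigma_deg: float = 1.2,
) -> tuple[ReefMask, list[RegionSpec], dict[str, list[CellIndex]]]:
    """Clustered reef cells, one cluster per region (cycled if more)."""
    if n_clusters <= 0 or cells_per_cluster <= 0:
        raise ValueError("cluster counts must be positive")
    regions = list(regions) if regions is not None else default_regions()
    rng = np.random.default_rng([seed, 0x5EEF])
    cells: set[CellIndex] = set()
    for k in range(n_clusters):
        region = regions[k % len(regions)]
        lo, hi, la, ha = region.boxes[0]
        margin = 4.0 * cluster_sigma_deg
        c_lon = rng.uniform(lo + margin, hi - margin)
        c_lat = rng.uniform(max(la, -30.0) + margin, min(ha, 30.0) - margin)
        added = 0
        while added < cells_per_cluster:
            lat = c_lat + rng.normal(0.0, cluster_sigma_deg)
            lon = c_lon + rng.normal(0.0, cluster_sigma_deg)
            if not (-89.9 < lat < 89.9 and -180.0 <= lon < 180.0):
                continue
            if not region.contains(lat, lon):
                continue
            cell = latlon_to_cell(lat, lon)
            if cell not in cells:
                cells.add(cell)
                added += 1
    mask = ReefMask(cells)
    assignment = assign_regions(mask, regions)
    return mask, regions, assignment


def _schedule_events(
    rng: np.random.Generator,
    params: WorldParams,
    region_assignment: dict[str, list[CellIndex]],
) -> list[HeatwaveEvent]:
    events = []
    for year in params.model_years:
        for region, cells in sorted(region_assignment.items()):
            if not cells or rng.random() >= params.event_prob:
                continue
            center = cells[rng.integers(len(cells))]
            lat, lon = cell_center(center)
            # peak in the local warm season
            peak_doy = int(rng.integers(200, 260)) if lat >= 0 else int(rng.integers(30, 90))
            events.append(HeatwaveEvent(
                year=year, region=region, center_lat=lat, center_lon=lon,
                radius_km=float(rng.uniform(*params.event_radius_range_km)),
                peak_c=float(rng.uniform(*params.event_peak_range_c)),
                duration_days=int(rng.integers(params.event_duration_range_days[0],
                                               params.event_duration_range_days[1] + 1)),
                peak_doy=peak_doy,
            ))
    return events


def simulate_sst(
    seed: int,
    params: WorldParams,
    mask: ReefMask,
    region_assignment: dict[str, list[CellIndex]],
    events: Optional[list[HeatwaveEvent]] = None,
) -> tuple[SSTGrid, list[HeatwaveEvent]]:
    """Daily SST per reef cell over baseline plus model years.

    SST = latitude-dependent mean + seasonal sinusoid (hemisphere phase)
    + linear warming trend + AR(1) noise + Gaussian-in-space-and-time
    heatwave anomalies.  Deterministic per (seed, params).
    """
    rng = np.random.default_rng([seed, 0x557])
    if events is None:
        events = _schedule_events(np.random.default_rng([seed, 0xEE]), params, region_assignment)

    dates = pd.date_range(f"{params.all_years[0]}-01-01", f"{params.all_years[-1]}-12-31", freq="D")
    t = np.arange(len(dates), dtype=float)
    doy = dates.dayofyear.to_numpy(dtype=float)
    lats, lons = mask.centers()
    n_cells = len(mask)

    mean_c = params.base_sst_c - params.lat_decay_c_per_deg * np.abs(lats)
    # warm-season peak: early August north, early February south
    phase_doy = np.where(lats >= 0.0, 215.0, 35.0)
    seasonal = params.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (doy[:, None] - phase_doy[None, :]) / 365.25
    )
    trend = (params.warming_trend_c_per_decade / 3652.5) * t[:, None]

    eps = rng.normal(0.0, params.ar1_sigma_c, size=(len(dates), n_cells))
    noise = signal.lfilter([1.0], [1.0, -params.ar1_rho], eps, axis=0)

    sst = mean_c[None, :] + seasonal + trend + noise
    for ev in events:
        d_km = haversine_km(ev.center_lat, ev.center_lon, lats, lons)
        space = np.exp(-0.5 * (d_km / ev.radius_km) ** 2)
        peak_idx = (pd.Timestamp(f"{ev.year}-01-01") - dates[0]).days + ev.peak_doy - 1
        sigma_t = ev.duration_days / 4.0
        time_shape = np.exp(-0.5 * ((t - peak_idx) / sigma_t) ** 2)
        sst += ev.peak_c * time_shape[:, None] * space[None, :]
    return SSTGrid(dates=pd.DatetimeIndex(dates), values=sst, mask=mask), events


def simulate_truth_and_reports(
    seed: int,
    params: WorldParams,
    mask: ReefMask,
    region_assignment: dict[str, list[CellIndex]],
    sst: SSTGrid,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the true bleaching field and the biased report table.

    True bleaching per cell-year is Bernoulli with
    p = expit(beta0 + beta1 * annual max DHW).  Surveys sample cells with
    region-dependent effort; surveyed cells yield one report whose percent
    bleached reflects the truth (with a small false-report rate), mapped
    through the ordinal severity scale.  A fraction of reports receives a
    coordinate error, and another a severity code of -1 (unknown).
    """
    rng = np.random.default_rng([seed, 0x7247])
    mmm = mmm_grid(sst.dates, sst.values, params.climatology_years)
    amax = annual_max_dhw_grid(sst.dates, sst.values, mmm, years=params.model_years)
    cells = mask.cells
    region_of = {c: r for r, cs in region_assignment.items() for c in cs}

    truth_rows = []
    report_rows = []
    for year in params.model_years:
        dhw_row = amax.loc[year].to_numpy()
        p = 1.0 / (1.0 + np.exp(-(params.beta0 + params.beta1 * dhw_row)))
        bleached = rng.random(len(cells)) < p
        surveyed = rng.random(len(cells)) < np.array(
            [params.effort.get(region_of[c], 0.3) for c in cells]
        )
        for k, cell in enumerate(cells):
            truth_rows.append({
                "year": year, "i": cell.i, "j": cell.j,
                "annual_max_dhw": float(dhw_row[k]),
                "p_bleach": float(p[k]), "bleached": int(bleached[k]),
            })
            if not surveyed[k]:
                continue
            if bleached[k]:
                percent = float(rng.uniform(15.0, 95.0))
            elif rng.random() < params.false_report_rate:
                percent = float(rng.uniform(15.0, 60.0))
            else:
                percent = float(rng.uniform(1.0, 9.0)) if rng.random() < 0.2 else float(rng.uniform(0.0, 0.9))
            severity = 0 if percent < 1.0 else (1 if percent <= 10.0 else (2 if percent <= 50.0 else 3))
            lat, lon = cell_center(cell)
            if rng.random() < params.coord_error_rate:
                mag = rng.uniform(*params.coord_error_deg)
                angle = rng.uniform(0.0, 2.0 * np.pi)
                lat = float(np.clip(lat + mag * np.sin(angle), -89.9, 89.9))
                lon = float(((lon + mag * np.cos(angle)) + 180.0) % 360.0 - 180.0)
            if rng.random() < params.unknown_severity_rate:
                severity, percent = -1, None
            report_rows.append({
                "SOURCE": "synthetic-survey", "COUNTRY": region_of[cell], "SITE": f"cell-{cell.i}-{cell.j}",
                "LAT": round(lat, 5), "LON": round(lon, 5), "YEAR": year,
                "MONTH": 8 if lat >= 0 else 2,
                "PERCENT_BLEACHED": None if percent is None else round(percent, 2),
                "SEVERITY": severity,
                "PERCENT_MORTALITY": None, "MORTALITY_CODE": None,
                "DEPTH_M": None, "METHOD": "synthetic",
            })
    truth = pd.DataFrame(truth_rows)
    reports = pd.DataFrame(report_rows)
    return truth, reports


def make_world(seed: int, params: Optional[WorldParams] = None) -> SyntheticWorld:
    """Generate a complete synthetic world from one seed."""
    params = params or WorldParams()
    mask, regions, assignment = make_reef_mask(
        seed, params.n_clusters, params.cells_per_cluster,
        cluster_sigma_deg=params.cluster_sigma_deg,
    )
    sst, events = simulate_sst(seed, params, mask, assignment)
    truth, reports = simulate_truth_and_reports(seed, params, mask, assignment, sst)
    return SyntheticWorld(
        seed=seed, params=params, mask=mask, regions=regions,
        region_assignment=assignment, sst=sst, events=events,
        truth=truth, reports=reports,
    )
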