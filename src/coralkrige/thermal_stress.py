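"""Maximum Monthly Mean climatology, HotSpots and Degree Heating Weeks.

Degree Heating Weeks (DHW) is the standard satellite thermal-stress metric
for coral bleaching.  Its operational definition, fixed here:

* the climatological baseline is the Maximum Monthly Mean (MMM) SST — the
  warmest of the twelve climatological monthly-mean temperatures;
* a HotSpot is the positive anomaly ``max(0, SST - MMM)`` in degrees C;
* only HotSpots of at least 1 degree C accumulate;
* DHW(t) is the sum of qualifying HotSpots over the trailing 84 days
  (12 weeks), divided by 7 to express the result in degC-weeks.

Bleaching Alert Level 1 corresponds to DHW = 4 and Level 2 to DHW = 8
degC-weeks.  Annual maxima are taken over calendar years, with no
hemisphere-season adjustment (a documented limitation for austral-summer
events spanning New Year).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .grid import CellIndex

DHW_WINDOW_DAYS = 84
HOTSPOT_CUTOFF_C = 1.0

_SST_PLAUSIBLE = (-5.0, 45.0)


@dataclass
class SSTSeries:
    """Daily SST at one grid cell."""

    cell: Optional[CellIndex]
    dates: pd.DatetimeIndex
    sst: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.sst = np.asarray(self.sst, dtype=float)
        if len(self.dates) != len(self.sst):
            raise ValueError("dates and sst lengths differ")
        if len(self.dates) == 0:
            raise ValueError("empty SST series")
        deltas = np.diff(self.dates.to_numpy()).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError("SST series must be daily and gap-free; fill or trim gaps first")
        if not np.all(np.isfinite(self.sst)):
            raise ValueError("SST contains non-finite values")
        lo, hi = _SST_PLAUSIBLE
        if self.sst.min() <= lo or self.sst.max() >= hi:
            raise ValueError(f"SST outside plausible range {_SST_PLAUSIBLE}")


@dataclass
class Climatology:
    cell: Optional[CellIndex]
    monthly_means: np.ndarray  # 12 values, Jan..Dec, degC

    @property
    def mmm(self) -> float:
        return float(np.max(self.monthly_means))


@dataclass
class DHWField:
    """Daily DHW series and its calendar-year maxima at one cell."""

    cell: Optional[CellIndex]
    dates: pd.DatetimeIndex
    dhw: np.ndarray  # degC-weeks per day

    @property
    def annual_max(self) -> dict[int, float]:
        years = self.dates.year.to_numpy()
        return {int(y): float(self.dhw[years == y].max()) for y in np.unique(years)}


def compute_mmm(series: SSTSeries, climatology_years: tuple[int, int] | None = None) -> Climatology:
    """Monthly-mean climatology and MMM over a baseline year range.

    ``climatology_years`` is an inclusive (first, last) range; the default
    takes the first ten complete calendar years of the series (or all
    complete years if fewer are available).
    """
    years = series.dates.year.to_numpy()
    if climatology_years is None:
        complete = _complete_years(series.dates)
        if not complete:
            raise ValueError("series contains no complete calendar year for the climatology baseline")
        climatology_years = (complete[0], complete[: 10][-1])
    y0, y1 = climatology_years
    in_range = (years >= y0) & (years <= y1)
    if not in_range.any():
        raise ValueError(f"series does not cover climatology years {y0}-{y1}")
    months = series.dates.month.to_numpy()[in_range]
    sst = series.sst[in_range]
    means = np.empty(12)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            raise ValueError(f"no SST days in month {m} within climatology years {y0}-{y1}")
        means[m - 1] = sst[sel].mean()
    return Climatology(cell=series.cell, monthly_means=means)


def _complete_years(dates: pd.DatetimeIndex) -> list[int]:
    counts = pd.Series(1, index=dates).groupby(dates.year).sum()
    return [int(y) for y, n in counts.items() if n >= 365]


def hotspot(sst, mmm):
    """Positive SST anomaly above the MMM baseline, degC (array-safe)."""
    return np.maximum(0.0, np.asarray(sst, dtype=float) - mmm)


def dhw_from_hotspots(hotspots: np.ndarray, axis: int = 0) -> np.ndarray:
    """Trailing-window DHW from a daily HotSpot array.

    Only HotSpots >= 1 degC accumulate; the window is the trailing 84 days
    and the sum is divided by 7.  Leading partial windows are evaluated
    over the available days.  Works on 1-D (time,) or 2-D (time, cell)
    arrays along ``axis`` 0.
    """
    hs = np.asarray(hotspots, dtype=float)
    qualifying = np.where(hs >= HOTSPOT_CUTOFF_C, hs, 0.0)
    csum = np.cumsum(qualifying, axis=axis)
    shifted = np.roll(csum, DHW_WINDOW_DAYS, axis=axis)
    # the first `window` entries have no predecessor: trailing sum = cumsum
    if axis != 0:
        raise ValueError("axis must be 0 (time-major)")
    shifted[:DHW_WINDOW_DAYS] = 0.0
    return (csum - shifted) / 7.0


def dhw_series(series: SSTSeries, clim: Climatology, mask_partial: bool = False) -> DHWField:
    """Daily DHW for one cell.

    ``mask_partial=True`` sets the first 83 days (incomplete trailing
    windows) to NaN instead of evaluating them over the partial window.
    """
    dhw = dhw_from_hotspots(hotspot(series.sst, clim.mmm))
    if mask_partial:
        dhw = dhw.copy()
        dhw[: DHW_WINDOW_DAYS - 1] = np.nan
    return DHWField(cell=series.cell, dates=series.dates, dhw=dhw)


def annual_max_dhw(field: DHWField, year: int) -> float:
    """Maximum daily DHW within one calendar year."""
    sel = field.dates.year == year
    if not sel.any():
        raise ValueError(f"DHW field does not cover year {year}")
    return float(np.nanmax(field.dhw[sel]))


# -- grid-level helpers -----------------------------------------------------

def annual_max_dhw_grid(
    dates: pd.DatetimeIndex,
    sst: np.ndarray,
    mmm: np.ndarray,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Annual maximum DHW for many cells at once.

    Parameters
    ----------
    dates : daily, gap-free time axis of length T
    sst : (T, n_cells) daily SST
    mmm : (n_cells,) per-cell MMM baseline
    years : calendar years to report (default: all present)

    Returns
    -------
    DataFrame indexed by year with one column per cell position.
    """
    sst = np.asarray(sst, dtype=float)
    mmm = np.asarray(mmm, dtype=float)
    dhw = dhw_from_hotspots(np.maximum(0.0, sst - mmm[None, :]))
    year_arr = pd.DatetimeIndex(dates).year.to_numpy()
    if years is None:
        years = [int(y) for y in np.unique(year_arr)]
    out = np.empty((len(years), sst.shape[1]))
    for k, y in enumerate(years):
        sel = year_arr == y
        if not sel.any():
            raise ValueError(f"SST does not cover year {y}")
        out[k] = dhw[sel].max(axis=0)
    return pd.DataFrame(out, index=pd.Index(years, name="year"))


def mmm_grid(dates: pd.DatetimeIndex, sst: np.ndarray, climatology_years: tuple[int, int]) -> np.ndarray:
    """Per-cell MMM over a baseline range for a (T, n_cells) SST array."""
    dates = pd.DatetimeIndex(dates)
    years = dates.year.to_numpy()
    y0, y1 = climatology_years
    in_range = (years >= y0) & (years <= y1)
    if not in_range.any():
        raise ValueError(f"SST does not cover climatology years {y0}-{y1}")
    months = dates.month.to_numpy()[in_range]
    sst_base = np.asarray(sst, dtype=float)[in_range]
    monthly = np.empty((12, sst_base.shape[1]))
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            raise ValueError(f"no SST days in month {m} within climatology years {y0}-{y1}")
        monthly[m - 1] = sst_base[sel].mean(axis=0)
    return monthly.max(axis=0)
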