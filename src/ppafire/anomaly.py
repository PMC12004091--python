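"""Daily climatologies, anomalies, smoothing, latitude correction and the
seasonally varying magnitude threshold.

The persistent-anomaly detector consumes 500 hPa geopotential-height (Z500)
anomalies that have been (1) referenced to a per-calendar-day cross-year
climatology, (2) smoothed with a centered 5-day moving mean, and (3) scaled
by ``sin(45°)/sin(lat)`` so that a given anomaly magnitude represents a
comparable departure of the circulation at all latitudes (atmospheric energy
dispersion scales with the Coriolis parameter).  The magnitude threshold is
the per-calendar-day domain-mean standard deviation of the *unsmoothed*
latitude-corrected anomalies in a four-week moving window, pooled across
years, so that summer cells are not held to winter variance and the
smoothing step does not deflate the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid, GriddedField

STAGE_RAW = "raw"
STAGE_SMOOTHED = "smoothed"
STAGE_LAT_CORRECTED = "latitude_corrected"

_STAGE_ORDER = [STAGE_RAW, STAGE_SMOOTHED, STAGE_LAT_CORRECTED]


@dataclass
class ClimatologyField:
    """Cross-year mean per calendar day per cell.

    ``calendar_keys`` holds ``100*month + day`` integers; ``mean_values`` is
    ``(n_calendar_days, nlat, nlon)``.
    """

    grid: Grid
    calendar_keys: np.ndarray
    mean_values: np.ndarray

    def lookup(self, keys: np.ndarray) -> np.ndarray:
        """Climatological means for a sequence of calendar keys."""
        pos = {int(k): i for i, k in enumerate(self.calendar_keys)}
        try:
            idx = np.array([pos[int(k)] for k in keys])
        except KeyError as exc:
            raise ValueError(f"calendar day {exc} missing from climatology") from exc
        return self.mean_values[idx]


class AnomalyField(GriddedField):
    """A :class:`GriddedField` of anomalies carrying a processing-stage flag."""

    def __init__(self, *args, stage: str = STAGE_RAW, **kwargs):
        super().__init__(*args, **kwargs)
        if stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}")
        self.stage = stage

    def _advance(self, values: np.ndarray, stage: str) -> "AnomalyField":
        if _STAGE_ORDER.index(stage) <= _STAGE_ORDER.index(self.stage):
            raise ValueError(f"stage may only advance ({self.stage} -> {stage})")
        return AnomalyField(
            grid=self.grid, dates=self.dates, values=values,
            name=self.name, units=self.units, stage=stage,
        )


@dataclass
class ThresholdSeries:
    """Seasonally varying magnitude threshold, one scalar per calendar day.

    ``per_cell`` optionally carries the per-cell variant
    ``(n_calendar_days, nlat, nlon)`` for the cell-wise criterion.
    """

    calendar_keys: np.ndarray
    threshold: np.ndarray
    multiplier: float = 1.0
    per_cell: np.ndarray | None = None

    def lookup(self, keys: np.ndarray) -> np.ndarray:
        pos = {int(k): i for i, k in enumerate(self.calendar_keys)}
        idx = np.array([pos[int(k)] for k in keys])
        return self.threshold[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.calendar_keys // 100,
                "day": self.calendar_keys % 100,
                "threshold": self.threshold,
            }
        )


def daily_climatology(field: GriddedField) -> ClimatologyField:
    """Mean across years for each calendar day and cell.

    Requires at least two distinct years; a single year would make every
    anomaly identically zero.
    """
    if field.dates.year.nunique() < 2:
        raise ValueError("climatology requires at least two years of data")
    keys = field.calendar_keys()
    uniq = np.unique(keys)
    means = np.empty((uniq.size,) + field.grid.shape)
    for i, k in enumerate(uniq):
        with np.errstate(invalid="ignore"):
            means[i] = np.nanmean(field.values[keys == k], axis=0)
    return ClimatologyField(grid=field.grid, calendar_keys=uniq, mean_values=means)


def compute_anomaly(field: GriddedField, clim: ClimatologyField) -> AnomalyField:
    """Subtract the climatological mean for each day's calendar date."""
    anom = field.values - clim.lookup(field.calendar_keys())
    return AnomalyField(
        grid=field.grid, dates=field.dates, values=anom,
        name=f"{field.name}_anom", units=field.units, stage=STAGE_RAW,
    )


def smooth_time(anom: AnomalyField, window_days: int = 5) -> AnomalyField:
    """Centered moving mean per cell along time.

    The window must be odd.  At season edges (gaps in the date index) the
    window shrinks to the available days; it never crosses a season boundary.
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    out = np.empty_like(anom.values)
    for seg in anom.season_segments():
        vals = anom.values[seg]
        n = vals.shape[0]
        flat = pd.DataFrame(vals.reshape(n, -1))
        # rolling(center=True, min_periods=1) implements the shrink-at-edges rule
        sm = flat.rolling(window_days, center=True, min_periods=1).mean()
        out[seg] = sm.to_numpy().reshape(vals.shape)
    return anom._advance(out, STAGE_SMOOTHED)


def latitude_correction(anom: AnomalyField, ref_lat: float = 45.0) -> AnomalyField:
    """Scale each anomaly by ``sin(ref_lat)/sin(lat)``.

    Standard convention of the persistent-anomaly literature: the amplitude
    of quasi-stationary height anomalies scales with the sine of latitude, so
    this correction makes one magnitude threshold meaningful across the
    domain.  Requires a northern-hemisphere grid.
    """
    if np.any(anom.grid.lat <= 0):
        raise ValueError("latitude correction requires all latitudes > 0")
    factor = np.sin(np.deg2rad(ref_lat)) / np.sin(np.deg2rad(anom.grid.lat))
    return anom._advance(anom.values * factor[None, :, None], STAGE_LAT_CORRECTED)


def seasonal_threshold(
    anom: AnomalyField,
    window_days: int = 28,
    multiplier: float = 1.0,
    per_cell: bool = False,
) -> ThresholdSeries:
    """Seasonally varying magnitude threshold.

    For each calendar day the anomalies of all years whose day-of-season
    index falls in a ``window_days`` window centered on it are pooled per
    cell; the per-cell standard deviations are then averaged over the domain
    to give one scalar per calendar day ("mean standard deviation").  With
    ``per_cell=True`` the per-cell standard deviations are additionally kept
    as a cell-wise threshold variant.

    The window is indexed by day-of-season, so it never mixes days across
    the season boundary; at the edges it shrinks.
    """
    if anom.stage != STAGE_LAT_CORRECTED:
        raise ValueError("threshold is computed from latitude-corrected anomalies")
    if anom.dates.year.nunique() < 2:
        raise ValueError("threshold requires at least two years")
    keys = anom.calendar_keys()
    uniq = np.unique(keys)
    n_season_days = uniq.size
    if window_days > n_season_days:
        raise ValueError("threshold window longer than the season")
    # day-of-season index for every date
    key_to_doy = {int(k): i for i, k in enumerate(uniq)}
    doy = np.array([key_to_doy[int(k)] for k in keys])

    lo_off = window_days // 2
    hi_off = window_days - lo_off - 1
    thr = np.empty(n_season_days)
    cellwise = np.empty((n_season_days,) + anom.grid.shape) if per_cell else None
    for d in range(n_season_days):
        sel = (doy >= d - lo_off) & (doy <= d + hi_off)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(anom.values[sel], axis=0, ddof=1)
            thr[d] = np.nanmean(sd)
        if cellwise is not None:
            cellwise[d] = sd
    return ThresholdSeries(
        calendar_keys=uniq, threshold=thr, multiplier=multiplier, per_cell=cellwise
    )


def surface_anomalies(fields: dict[str, GriddedField]) -> dict[str, AnomalyField]:
    """Raw anomalies of surface variables (no smoothing, no latitude
    correction): value minus the per-calendar-day cross-year mean."""
    return {
        name: compute_anomaly(f, daily_climatology(f)) for name, f in fields.items()
    }
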