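"""Synthetic gridded-weather worlds with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real reanalysis/burned-area data, with every quantity of interest known by
construction:

* a Z500 field = smooth seasonal mean + spatiotemporally autocorrelated
  background noise (AR(1) in time over spatially smoothed Gaussian noise),
  with persistent blocking-like events injected as Gaussian bumps of
  configurable amplitude (expressed as a multiple of the realized seasonal
  detection threshold), radius, duration and drift;
* surface weather coupled to event presence (warmer, drier, calmer, less
  rain on event cell-days);
* fire occurrences whose daily odds are elevated by a configurable factor
  ``or_true`` on exposed cell-days (event day or the preceding ``lag_days``
  days), with log-normal burned areas.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import anomaly as anomaly_mod
from .association import lagged_exposure
from .grid import Grid, GriddedField


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults give a modest 24°×36° mid-latitude domain at 1° resolution,
    three March–October seasons, background anomalies with day-to-day
    autocorrelation 0.8 and marginal standard deviation 80 gpm (typical of
    summer mid-latitude Z500 variability), two injected events per season,
    and surface/fire couplings of the sign and rough size the pipeline is
    meant to detect.
    """

    # grid / calendar
    lat_start: float = 36.0
    lon_start: float = -10.0
    nlat: int = 24
    nlon: int = 36
    resolution: float = 1.0
    first_year: int = 2001
    n_years: int = 3
    season_months: tuple[int, int] = (3, 10)

    # background field
    rho: float = 0.8                 # AR(1) day-to-day autocorrelation
    spatial_smoothing: float = 2.0   # Gaussian kernel length scale, cells
    sigma_z: float = 80.0            # marginal anomaly s.d., gpm

    # injected events
    events_per_season: int = 2
    amplitude_range: tuple[float, float] = (1.5, 3.0)  # × seasonal threshold
    radius_range: tuple[int, int] = (3, 5)             # cells
    duration_range: tuple[int, int] = (8, 15)          # days
    drift_cells_per_day: float = 0.0

    # surface coupling on event cell-days
    delta_temp: float = 4.0          # °C added
    delta_rh: float = 15.0           # % subtracted
    wind_factor: float = 0.7         # multiplicative
    precip_suppression: float = 0.3  # wet-day probability multiplier
    precip_lag_days: int = 3         # suppression persists after the event

    # fire model
    p0: float = 0.01                 # baseline daily fire probability
    or_true: float = 3.0             # exposure odds multiplier
    fire_lag_days: int = 7           # exposure carry-over for fires
    fire_area_median_ha: float = 100.0
    fire_area_sigma: float = 1.0     # log-normal log-s.d.

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        if self.or_true <= 0:
            raise ValueError("or_true must be positive")
        if self.n_years < 2:
            raise ValueError("need at least two years (climatology requires it)")
        if self.events_per_season > 0:
            # placement needs room for the truncated footprint (~1.5 radius)
            margin = 1.5 * max(self.radius_range) + 2
            if 2 * margin + 1 >= min(self.nlat, self.nlon):
                raise ValueError("event radius too large for the domain")

    def grid(self) -> Grid:
        return Grid(
            lat=self.lat_start + self.resolution * np.arange(self.nlat),
            lon=self.lon_start + self.resolution * np.arange(self.nlon),
        )

    def dates(self) -> pd.DatetimeIndex:
        parts = []
        m0, m1 = self.season_months
        for y in range(self.first_year, self.first_year + self.n_years):
            last_day = pd.Timestamp(y, m1, 1) + pd.offsets.MonthEnd(0)
            parts.append(pd.date_range(pd.Timestamp(y, m0, 1), last_day, freq="D"))
        return parts[0].append(parts[1:])


@dataclass
class InjectedEvent:
    """Ground-truth record of one injected blocking-like event."""

    event_id: int
    t_start: int          # index into the date axis
    duration: int
    center: tuple[float, float]   # fractional (ilat, ilon) at t_start
    radius: float                 # cells
    amplitude_mult: float         # × seasonal threshold, post-correction peak
    drift: tuple[float, float]    # cells/day in (ilat, ilon)

    def center_at(self, t: int) -> tuple[float, float]:
        dt = t - self.t_start
        return (self.center[0] + self.drift[0] * dt, self.center[1] + self.drift[1] * dt)


@dataclass
class SyntheticTruth:
    """Injected-event catalog, true exposure mask and true odds ratio."""

    config: SyntheticConfig
    events: list[InjectedEvent]
    truth_mask: np.ndarray        # bool (time, nlat, nlon): injected anomaly >= 1× threshold
    coupling: np.ndarray          # intensity arc (0..1) on truth cell-days
    or_true: float
    threshold_gpm: float | None = None   # realized mean seasonal threshold (if calibrated)
    fire_labels: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# background field
# ---------------------------------------------------------------------------


def _background_anomalies(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """AR(1)-in-time field of spatially smoothed noise, marginal s.d. σ_z.

    The innovation s.d. after spatial smoothing is normalized empirically so
    the marginal process s.d. matches σ_z regardless of the kernel width.
    """
    nt = len(cfg.dates())
    shape = (nt, cfg.nlat, cfg.nlon)
    innov = rng.standard_normal(shape)
    if cfg.spatial_smoothing > 0:
        # periodic smoothing keeps the marginal variance identical at every
        # cell (edge padding would inflate it near the boundary)
        for t in range(nt):
            innov[t] = gaussian_filter(innov[t], cfg.spatial_smoothing, mode="wrap")
    innov *= 1.0 / innov.std()
    out = np.empty(shape)
    # restart the AR chain at each season boundary
    dates = cfg.dates()
    gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D")) + 1
    starts = np.concatenate(([0], gaps, [nt]))
    a = cfg.rho
    b = np.sqrt(1 - a * a)
    for s, e in zip(starts[:-1], starts[1:]):
        out[s] = innov[s]
        for t in range(s + 1, e):
            out[t] = a * out[t - 1] + b * innov[t]
    return cfg.sigma_z * out


def _seasonal_mean(cfg: SyntheticConfig) -> np.ndarray:
    """Smooth climatological Z500 surface: poleward decrease plus a seasonal
    cycle peaking in mid-summer."""
    dates = cfg.dates()
    doy = dates.dayofyear.to_numpy()
    seasonal = 60.0 * np.sin(np.pi * (doy - 60) / 245.0)
    lat = cfg.grid().lat
    base = 5700.0 - 4.0 * (lat - 30.0)
    return base[None, :, None] + seasonal[:, None, None] + np.zeros((1, 1, cfg.nlon))


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def _draw_events(cfg: SyntheticConfig, rng: np.random.Generator) -> list[InjectedEvent]:
    """Place events at random, separated in space, away from domain edges."""
    dates = cfg.dates()
    gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D")) + 1
    starts = np.concatenate(([0], gaps, [len(dates)]))
    events = []
    eid = 0
    # (cal_start, cal_end, cy, cx, radius) of every placed event; events in
    # different years that overlap in calendar time must also be spatially
    # separated, or the cross-year climatology would absorb their amplitude
    placed: list[tuple[int, int, float, float, float]] = []
    for s, e in zip(starts[:-1], starts[1:]):
        for _ in range(cfg.events_per_season):
            radius = rng.uniform(*cfg.radius_range)
            duration = int(rng.integers(cfg.duration_range[0], cfg.duration_range[1] + 1))
            # footprints extend to ~1.5 radius (threshold-contour truncation)
            margin = 1.5 * radius + 2
            for _attempt in range(100):
                cy = rng.uniform(margin, cfg.nlat - 1 - margin)
                cx = rng.uniform(margin, cfg.nlon - 1 - margin)
                t_start = int(rng.integers(s + 10, max(e - duration - 10, s + 11)))
                c0, c1 = t_start - s, t_start - s + duration
                ok = True
                for o0, o1, oy, ox, orad in placed:
                    time_clash = c0 - 10 <= o1 and o0 <= c1 + 10
                    space_clash = np.hypot(cy - oy, cx - ox) <= 1.5 * (radius + orad) + 3.0
                    if time_clash and space_clash:
                        ok = False
                        break
                if ok:
                    break
            placed.append((t_start - s, t_start - s + duration, cy, cx, radius))
            amp = rng.uniform(*cfg.amplitude_range)
            if cfg.drift_cells_per_day > 0:
                ang = rng.uniform(0, 2 * np.pi)
                drift = (
                    cfg.drift_cells_per_day * np.sin(ang),
                    cfg.drift_cells_per_day * np.cos(ang),
                )
            else:
                drift = (0.0, 0.0)
            events.append(
                InjectedEvent(
                    event_id=eid,
                    t_start=t_start,
                    duration=duration,
                    center=(cy, cx),
                    radius=radius,
                    amplitude_mult=amp,
                    drift=drift,
                )
            )
            eid += 1
    return events


def _spatial_profile(ev: InjectedEvent, t: int, shape: tuple[int, int]) -> np.ndarray:
    """Gaussian spatial profile of an event on day t (0 outside lifetime).

    The profile is truncated at the contour where the injected anomaly
    equals 1× the seasonal threshold (``amplitude_mult × profile = 1``):
    cells that could never satisfy the magnitude criterion receive no
    injection, so the bump has no sub-threshold skirt of marginal cells.
    """
    if not (ev.t_start <= t < ev.t_start + ev.duration):
        return np.zeros(shape)
    cy, cx = ev.center_at(t)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    prof = np.exp(-d2 / (2.0 * ev.radius**2))
    prof[ev.amplitude_mult * prof < 1.0] = 0.0
    return prof


def _temporal_factor(ev: InjectedEvent, t: int) -> float:
    """Intensity arc over the event's lifetime.

    Blocks build, peak mid-life and decay: a gentle sine arc (0.8 → 1.0 →
    0.8) with half amplitude on the first and last day.  The arc makes the
    maximum-strength day well defined and lets surface couplings peak with
    block intensity; the half-amplitude edges make the 5-day-smoothed
    signal cross the threshold at the true event boundaries.
    """
    if not (ev.t_start <= t < ev.t_start + ev.duration):
        return 0.0
    frac = (t - ev.t_start + 0.5) / ev.duration
    arc = 0.8 + 0.2 * np.sin(np.pi * frac)
    if t == ev.t_start or t == ev.t_start + ev.duration - 1:
        arc *= 0.5
    return float(arc)


def _event_profile(ev: InjectedEvent, t: int, shape: tuple[int, int]) -> np.ndarray:
    """Full (spatial × temporal) injected profile of an event on day t."""
    return _temporal_factor(ev, t) * _spatial_profile(ev, t, shape)


def _truth_masks(
    events: list[InjectedEvent], nt: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Truth exposure mask and coupling intensity.

    ``mask``: cell-days where the injected (post-correction) anomaly is at
    least 1× the seasonal threshold.  ``coupling``: the temporal intensity
    arc on those cell-days (what the surface couplings scale with).
    """
    mask = np.zeros((nt,) + shape, dtype=bool)
    coupling = np.zeros((nt,) + shape)
    for ev in events:
        for t in range(ev.t_start, ev.t_start + ev.duration):
            if 0 <= t < nt:
                arc = _temporal_factor(ev, t)
                cells = ev.amplitude_mult * arc * _spatial_profile(ev, t, shape) >= 1.0
                mask[t] |= cells
                coupling[t] = np.where(cells, np.maximum(coupling[t], arc), coupling[t])
    return mask, coupling


def gen_truth(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Injected-event catalog and exposure mask without the gridded fields.

    Sufficient for the fire model and association-recovery experiments,
    which depend only on where and when the events are, not on the height
    field itself.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    events = _draw_events(cfg, rng)
    mask, coupling = _truth_masks(events, len(cfg.dates()), (cfg.nlat, cfg.nlon))
    return SyntheticTruth(
        config=cfg, events=events, truth_mask=mask, coupling=coupling, or_true=cfg.or_true
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_z500(cfg: SyntheticConfig) -> tuple[GriddedField, SyntheticTruth]:
    """Generate the Z500 field with injected events and return the truth.

    Event amplitudes are specified relative to the *realized* seasonal
    threshold: the detection threshold is first computed on the
    background-only field, and each bump's raw peak is scaled by the inverse
    latitude-correction factor at its cells, so that after correction the
    peak equals ``amplitude_mult`` × threshold irrespective of the
    background parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    dates = cfg.dates()
    mu = _seasonal_mean(cfg)
    bg = _background_anomalies(cfg, rng)
    base = GriddedField(grid=grid, dates=dates, values=mu + bg, name="z500", units="gpm")

    # realized threshold of the background-only world (unsmoothed anomaly
    # s.d., matching the detection chain's threshold semantics)
    clim = anomaly_mod.daily_climatology(base)
    raw = anomaly_mod.compute_anomaly(base, clim)
    thr = anomaly_mod.seasonal_threshold(anomaly_mod.latitude_correction(raw))
    thr_by_day = thr.lookup(base.calendar_keys())

    events = _draw_events(cfg, rng)
    lat_factor = np.sin(np.deg2rad(45.0)) / np.sin(np.deg2rad(grid.lat))
    values = mu + bg
    for ev in events:
        for t in range(ev.t_start, ev.t_start + ev.duration):
            prof = _event_profile(ev, t, grid.shape)
            # divide out the latitude correction so the corrected peak is clean
            values[t] += (
                ev.amplitude_mult * thr_by_day[t] * prof / lat_factor[:, None]
            )
    field = GriddedField(grid=grid, dates=dates, values=values, name="z500", units="gpm")
    mask, coupling = _truth_masks(events, len(dates), grid.shape)
    truth = SyntheticTruth(
        config=cfg,
        events=events,
        truth_mask=mask,
        coupling=coupling,
        or_true=cfg.or_true,
        threshold_gpm=float(thr.threshold.mean()),
    )
    return field, truth


def gen_surface(
    truth: SyntheticTruth, cfg: SyntheticConfig | None = None
) -> dict[str, GriddedField]:
    """Surface weather coupled to event presence.

    On event cell-days the couplings scale with the event's intensity arc
    c ∈ (0, 1]: temperature shifted by +ΔT·c, relative humidity by −ΔRH·c
    (clipped to [0, 100]), wind multiplied by 1 − (1 − wind_factor)·c; the
    wet-day probability is suppressed on event days and for
    ``precip_lag_days`` days afterwards.  Elsewhere weather is seasonal
    mean plus independent noise.  Also returns a second near-surface level
    of wind for the hot–dry–windy index.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    grid = cfg.grid()
    dates = cfg.dates()
    nt = len(dates)
    shape = (nt, cfg.nlat, cfg.nlon)
    on = truth.truth_mask
    c = truth.coupling

    doy = dates.dayofyear.to_numpy()
    seasonal = np.sin(np.pi * (doy - 60) / 245.0)
    temp = (
        8.0
        + 14.0 * seasonal[:, None, None]
        - 0.4 * (grid.lat - grid.lat[0])[None, :, None]
        + rng.normal(0, 2.0, shape)
    )
    temp += cfg.delta_temp * c

    rh = 68.0 - 12.0 * seasonal[:, None, None] + rng.normal(0, 8.0, shape)
    rh -= cfg.delta_rh * c
    rh = np.clip(rh, 0.0, 100.0)

    wind = rng.lognormal(mean=np.log(12.0), sigma=0.4, size=shape)  # km/h
    wind *= 1.0 - (1.0 - cfg.wind_factor) * c

    # rain stays suppressed for a few days after the block decays: subsidence
    # and dried fuels outlast the height anomaly itself
    dry = lagged_exposure(on, dates, cfg.precip_lag_days)
    wet_p = np.full(shape, 0.35)
    wet_p[dry] *= cfg.precip_suppression
    wet = rng.random(shape) < wet_p
    rain = np.where(wet, rng.gamma(1.2, 4.0, shape), 0.0)

    mk = lambda v, name, units: GriddedField(
        grid=grid, dates=dates, values=v, name=name, units=units
    )
    return {
        "temp": mk(temp, "temp", "degC"),
        "rh": mk(rh, "rh", "%"),
        "wind": mk(wind, "wind", "km/h"),
        "rain": mk(rain, "rain", "mm"),
        # second near-surface level: slightly stronger winds aloft (m/s)
        "wind_level2": mk(wind / 3.6 * 1.2, "wind_level2", "m/s"),
    }


def gen_fires(
    truth: SyntheticTruth,
    cfg: SyntheticConfig | None = None,
    lag_days: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fire records with a known exposure odds ratio.

    Exposure follows the lag rule applied to the truth mask.  The daily
    fire probability p satisfies odds(p) = odds(p₀) × OR_true on exposed
    cell-days and p = p₀ otherwise; burned areas are log-normal.  Returns
    ``(records, labels)`` where ``labels`` lists every cell-day's exposure
    and fire outcome (the simulation's own classification ground truth).
    """
    cfg = cfg or truth.config
    lag = cfg.fire_lag_days if lag_days is None else lag_days
    rng = np.random.default_rng(cfg.seed + 2)
    grid = cfg.grid()
    dates = cfg.dates()
    exposure = lagged_exposure(truth.truth_mask, dates, lag)

    odds0 = cfg.p0 / (1.0 - cfg.p0)
    odds1 = odds0 * cfg.or_true
    p1 = odds1 / (1.0 + odds1)
    if p1 >= 1.0:
        raise ValueError("exposed fire probability reaches 1; reduce p0 or or_true")
    p = np.where(exposure, p1, cfg.p0)
    fire = rng.random(p.shape) < p

    t_idx, iy, ix = np.nonzero(fire)
    areas = rng.lognormal(np.log(cfg.fire_area_median_ha), cfg.fire_area_sigma, t_idx.size)
    records = pd.DataFrame(
        {
            "date": dates[t_idx],
            "lat": grid.lat[iy],
            "lon": grid.lon[ix],
            "area_ha": areas,
        }
    )
    labels = pd.DataFrame(
        {
            "exposed_cell_days": [int(exposure.sum())],
            "unexposed_cell_days": [int((~exposure).sum())],
            "exposed_fires": [int(fire[exposure].sum())],
            "unexposed_fires": [int(fire[~exposure].sum())],
        }
    )
    return records, labels


def evaluate_detection(truth: SyntheticTruth, detected) -> pd.DataFrame:
    """Match detected events to the injected catalog.

    Each truth event is matched to the detected event sharing the largest
    fraction of its truth cell-days.  Returns one row per truth event with
    the overlap fraction, the matched duration and the duration error
    (detected − truth); unmatched events have zero overlap.
    """
    nt = truth.truth_mask.shape[0]
    shape = truth.truth_mask.shape[1:]
    rows = []
    det_sets = []
    for ev in detected:
        s = set()
        for t, cells in zip(ev.time_idx, ev.cells_by_day):
            s.update((t, int(c[0]), int(c[1])) for c in cells)
        det_sets.append(s)
    for te in truth.events:
        tset = set()
        for t in range(te.t_start, min(te.t_start + te.duration, nt)):
            prof = _event_profile(te, t, shape)
            for iy, ix in np.argwhere(te.amplitude_mult * prof >= 1.0):
                tset.add((t, int(iy), int(ix)))
        best_overlap, best_idx = 0.0, -1
        for i, ds in enumerate(det_sets):
            ov = len(tset & ds) / max(len(tset), 1)
            if ov > best_overlap:
                best_overlap, best_idx = ov, i
        rows.append(
            {
                "truth_event_id": te.event_id,
                "truth_duration": te.duration,
                "overlap_fraction": best_overlap,
                "matched_event_id": detected[best_idx].event_id if best_idx >= 0 else -1,
                "matched_duration": detected[best_idx].duration_days if best_idx >= 0 else 0,
                "duration_error": (
                    detected[best_idx].duration_days - te.duration if best_idx >= 0 else np.nan
                ),
                "qualifying_duration_error": (
                    detected[best_idx].qualifying_days - te.duration if best_idx >= 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_world(cfg: SyntheticConfig):
    """Full synthetic world: Z500, surface weather, fires and truth."""
    z500, truth = gen_z500(cfg)
    surface = gen_surface(truth, cfg)
    fires, labels = gen_fires(truth, cfg)
    truth.fire_labels = labels
    return z500, surface, fires, truth
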