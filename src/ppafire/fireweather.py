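"""Surface fire-weather indices: VPD, the Canadian Fire Weather Index
System (CFWIS) and the hot–dry–windy index (HDWI).

The CFWIS chains three moisture codes with increasing memory — FFMC (fine
litter, ~16 h lag), DMC (upper duff, ~15 d), DC (deep organic layer,
~52 d) — advanced once per day from noon weather (temperature °C, relative
humidity %, 10 m wind km/h, 24 h rain mm), and three behaviour indices
computed from the same-day codes: ISI (spread rate from FFMC and wind), BUI
(fuel availability from DMC and DC) and FWI (overall intensity).  The
update equations are the standard published system equations with the
conventional start-up codes FFMC = 85, DMC = 6, DC = 15 at each season
start and no overwintering of DC.

All update functions are vectorized over cells: state and weather may be
scalars or same-shape arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GriddedField

# DMC effective day-length hours and DC day-length factors per month
# (standard 46°N reference tables).
DMC_DAY_LENGTH = np.array([6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0])
DC_DAY_FACTOR = np.array([-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6])

DEFAULT_START = {"ffmc": 85.0, "dmc": 6.0, "dc": 15.0}


def saturation_vapour_pressure(temp_c):
    """Magnus-type saturation vapour pressure, hPa.

    e_s(T) = 6.112 · exp(17.67 T / (T + 243.5)).
    """
    t = np.asarray(temp_c, dtype=float)
    return 6.112 * np.exp(17.67 * t / (t + 243.5))


def vpd(temp_c, rh):
    """Vapour pressure deficit in hPa: e_s(T) · (1 − RH/100)."""
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    return saturation_vapour_pressure(temp_c) * (1.0 - rh / 100.0)


def hdwi(vpd_levels, wind_levels):
    """Hot–dry–windy index: max VPD × max wind over the near-surface levels.

    ``vpd_levels`` (hPa) and ``wind_levels`` (m/s) are stacked along axis 0
    (one slice per pressure level in the lowest ~50 hPa); the maxima may come
    from different levels.
    """
    v = np.asarray(vpd_levels, dtype=float)
    w = np.asarray(wind_levels, dtype=float)
    if v.shape[0] == 0 or w.shape[0] == 0:
        raise ValueError("HDWI needs at least one level")
    return np.max(v, axis=0) * np.max(w, axis=0)


@dataclass
class FwiState:
    """Carry-over moisture codes advanced daily."""

    ffmc: np.ndarray | float = 85.0
    dmc: np.ndarray | float = 6.0
    dc: np.ndarray | float = 15.0


# --- individual code updates (standard system equations) -------------------


def _ffmc_update(ffmc0, temp, rh, wind, rain):
    mo = 147.2 * (101.0 - ffmc0) / (59.5 + ffmc0)
    # rain phase (effective rain beyond the 0.5 mm canopy trap)
    rf = np.maximum(rain - 0.5, 0.0)
    raining = rain > 0.5
    mr = mo + 42.5 * rf * np.exp(-100.0 / (251.0 - mo)) * (1.0 - np.exp(-6.93 / np.where(rf > 0, rf, 1.0)))
    mr = mr + np.where(
        mo > 150.0, 0.0015 * (mo - 150.0) ** 2 * np.sqrt(rf), 0.0
    )
    mo = np.where(raining, np.minimum(mr, 250.0), mo)

    ed = (
        0.942 * rh**0.679
        + 11.0 * np.exp((rh - 100.0) / 10.0)
        + 0.18 * (21.1 - temp) * (1.0 - np.exp(-0.115 * rh))
    )
    ew = (
        0.618 * rh**0.753
        + 10.0 * np.exp((rh - 100.0) / 10.0)
        + 0.18 * (21.1 - temp) * (1.0 - np.exp(-0.115 * rh))
    )
    # drying toward ed
    ko = 0.424 * (1.0 - (rh / 100.0) ** 1.7) + 0.0694 * np.sqrt(wind) * (
        1.0 - (rh / 100.0) ** 8
    )
    kd = ko * 0.581 * np.exp(0.0365 * temp)
    m_dry = ed + (mo - ed) * 10.0 ** (-kd)
    # wetting toward ew
    kl = 0.424 * (1.0 - ((100.0 - rh) / 100.0) ** 1.7) + 0.0694 * np.sqrt(wind) * (
        1.0 - ((100.0 - rh) / 100.0) ** 8
    )
    kw = kl * 0.581 * np.exp(0.0365 * temp)
    m_wet = ew - (ew - mo) * 10.0 ** (-kw)

    m = np.where(mo > ed, m_dry, np.where(mo < ew, m_wet, mo))
    ffmc = 59.5 * (250.0 - m) / (147.2 + m)
    return np.clip(ffmc, 0.0, 101.0)


def _dmc_update(dmc0, temp, rh, rain, month):
    t = np.maximum(temp, -1.1)
    el = DMC_DAY_LENGTH[np.asarray(month) - 1]
    rk = 1.894 * (t + 1.1) * (100.0 - rh) * el * 1e-4

    raining = rain > 1.5
    rw = 0.92 * rain - 1.27
    wmi = 20.0 + 280.0 / np.exp(0.023 * dmc0)
    b = np.where(
        dmc0 <= 33.0,
        100.0 / (0.5 + 0.3 * dmc0),
        np.where(
            dmc0 <= 65.0,
            14.0 - 1.3 * np.log(np.maximum(dmc0, 1e-12)),
            6.2 * np.log(np.maximum(dmc0, 1e-12)) - 17.2,
        ),
    )
    wmr = wmi + 1000.0 * rw / (48.77 + b * rw)
    pr = np.maximum(43.43 * (5.6348 - np.log(np.maximum(wmr - 20.0, 1e-12))), 0.0)
    base = np.where(raining, pr, dmc0)
    return np.maximum(base + rk, 0.0)


def _dc_update(dc0, temp, rain, month):
    t = np.maximum(temp, -2.8)
    fl = DC_DAY_FACTOR[np.asarray(month) - 1]
    pe = np.maximum((0.36 * (t + 2.8) + fl) / 2.0, 0.0)

    raining = rain > 2.8
    rw = 0.83 * rain - 1.27
    smi = 800.0 * np.exp(-dc0 / 400.0)
    dr = dc0 - 400.0 * np.log(1.0 + 3.937 * np.maximum(rw, 0.0) / smi)
    base = np.where(raining, np.maximum(dr, 0.0), dc0)
    return np.maximum(base + pe, 0.0)


def _isi(ffmc, wind):
    m = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    ff = 91.9 * np.exp(-0.1386 * m) * (1.0 + m**5.31 / 4.93e7)
    return 0.208 * np.exp(0.05039 * wind) * ff


def _bui(dmc, dc):
    denom = dmc + 0.4 * dc
    low = np.where(denom > 0, 0.8 * dmc * dc / np.where(denom > 0, denom, 1.0), 0.0)
    high = dmc - (1.0 - 0.8 * dc / np.where(denom > 0, denom, 1.0)) * (
        0.92 + (0.0114 * dmc) ** 1.7
    )
    return np.maximum(np.where(dmc <= 0.4 * dc, low, high), 0.0)


def _fwi(isi, bui):
    fd = np.where(
        bui > 80.0,
        1000.0 / (25.0 + 108.64 * np.exp(-0.023 * bui)),
        0.626 * bui**0.809 + 2.0,
    )
    bb = 0.1 * isi * fd
    with np.errstate(divide="ignore", invalid="ignore"):
        high = np.exp(2.72 * (0.434 * np.log(np.maximum(bb, 1e-12))) ** 0.647)
    return np.where(bb <= 1.0, bb, high)


def cfwis_step(state: FwiState, temp, rh, wind, rain, month):
    """Advance the moisture codes one day and compute the behaviour indices.

    Parameters are noon weather: ``temp`` °C, ``rh`` % (0–100), ``wind``
    km/h, ``rain`` mm accumulated over 24 h, ``month`` 1–12 (selects the
    day-length tables).  Returns ``(new_state, isi, bui, fwi)``.
    """
    temp = np.asarray(temp, dtype=float)
    rh = np.clip(np.asarray(rh, dtype=float), 0.0, 100.0)
    wind = np.asarray(wind, dtype=float)
    rain = np.asarray(rain, dtype=float)
    ffmc = _ffmc_update(state.ffmc, temp, rh, wind, rain)
    dmc = _dmc_update(state.dmc, temp, rh, rain, month)
    dc = _dc_update(state.dc, temp, rain, month)
    isi = _isi(ffmc, wind)
    bui = _bui(dmc, dc)
    fwi = _fwi(isi, bui)
    return FwiState(ffmc=ffmc, dmc=dmc, dc=dc), isi, bui, fwi


@dataclass
class FwiSeries:
    """Daily fire-weather index fields, each ``(time, nlat, nlon)``."""

    dates: pd.DatetimeIndex
    ffmc: np.ndarray
    dmc: np.ndarray
    dc: np.ndarray
    isi: np.ndarray
    bui: np.ndarray
    fwi: np.ndarray


def cfwis_run(
    temp: GriddedField,
    rh: GriddedField,
    wind: GriddedField,
    rain: GriddedField,
    init: FwiState | None = None,
) -> FwiSeries:
    """Fold the daily CFWIS update over each season.

    The moisture codes reset to the start-up state at each season start
    (gap in the date index); there is no overwintering.  All four inputs
    must share grid and dates.
    """
    dates = temp.dates
    for other in (rh, wind, rain):
        if not dates.equals(other.dates):
            raise ValueError("weather fields must share the same dates")
    if init is None:
        init = FwiState(**DEFAULT_START)
    shape = temp.values.shape
    out = {k: np.empty(shape) for k in ("ffmc", "dmc", "dc", "isi", "bui", "fwi")}
    months = dates.month.to_numpy()
    for seg in temp.season_segments():
        state = FwiState(
            ffmc=np.full(shape[1:], init.ffmc),
            dmc=np.full(shape[1:], init.dmc),
            dc=np.full(shape[1:], init.dc),
        )
        for t in range(seg.start, seg.stop):
            state, isi, bui, fwi = cfwis_step(
                state,
                temp.values[t],
                rh.values[t],
                wind.values[t],
                rain.values[t],
                int(months[t]),
            )
            out["ffmc"][t] = state.ffmc
            out["dmc"][t] = state.dmc
            out["dc"][t] = state.dc
            out["isi"][t] = isi
            out["bui"][t] = bui
            out["fwi"][t] = fwi
    return FwiSeries(dates=dates, **out)


@dataclass
class ExtremeFlags:
    """Per-cell-month 95th-percentile FWI thresholds and daily exceedance."""

    thresholds: dict[int, np.ndarray]  # month -> (nlat, nlon), NaN = no data
    fwix: np.ndarray                   # bool, (time, nlat, nlon)


def extreme_flags(
    fwi_values: np.ndarray,
    dates: pd.DatetimeIndex,
    q: float = 95.0,
    min_pool: int = 20,
) -> ExtremeFlags:
    """Flag extreme-fire-weather days (FWIx).

    The threshold is the ``q``-th percentile (linear interpolation between
    order statistics) of a cell's FWI values pooled by calendar month across
    all years; a day is flagged iff its FWI is strictly greater.  Pools
    smaller than ``min_pool`` still yield a threshold but are unreliable.
    """
    dates = pd.DatetimeIndex(dates)
    fwix = np.zeros(fwi_values.shape, dtype=bool)
    thresholds: dict[int, np.ndarray] = {}
    for m in sorted(set(dates.month)):
        sel = np.asarray(dates.month == m)
        pool = fwi_values[sel]
        if pool.shape[0] == 0:
            continue
        if pool.shape[0] < min_pool:
            warnings.warn(
                f"month {m}: only {pool.shape[0]} pooled days for the "
                f"{q}th percentile (< {min_pool}); thresholds are unreliable",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            thr = np.nanpercentile(pool, q, axis=0)
        thresholds[m] = thr
        fwix[sel] = pool > thr[None]
    return ExtremeFlags(thresholds=thresholds, fwix=fwix)
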