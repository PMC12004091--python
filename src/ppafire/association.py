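"""Exposure×outcome classification, odds ratios and burned-area attribution.

Every analysed cell-day is categorized into a 2×2 table: exposed (a PPA
covered the cell that day or within the preceding ``lag_days`` days of the
same season) × outcome (a fire ignition, or an extreme-fire-weather day).
The per-cell-month tables give odds ratios with a partial Haldane
correction (+2 added to all four cells), which keeps the estimate finite
when a cell is zero and reduces small-sample bias.  Cell-level odds ratios
are then summarized per region and month, and burned area is attributed to
exposure by summing hectares over exposed cell-days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid, RegionMap


def lagged_exposure(
    mask: np.ndarray, dates: pd.DatetimeIndex, lag_days: int
) -> np.ndarray:
    """Exposure with carry-over: True iff the mask was True on the day or any
    of the preceding ``lag_days`` days within the same season segment."""
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    dates = pd.DatetimeIndex(dates)
    out = np.zeros_like(mask, dtype=bool)
    gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D")) + 1
    starts = np.concatenate(([0], gaps, [len(dates)]))
    for s, e in zip(starts[:-1], starts[1:]):
        seg = mask[s:e]
        acc = seg.copy()
        for k in range(1, lag_days + 1):
            acc[k:] |= seg[:-k]
        out[s:e] = acc
    return out


@dataclass
class ContingencyTable:
    """2×2 counts: a = exposed+outcome, b = exposed only, c = outcome only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def classify_days(
    exposure: np.ndarray,
    outcome: np.ndarray,
    dates: pd.DatetimeIndex,
    grid: Grid,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Accumulate 2×2 counts per cell per calendar month across years.

    ``exposure`` and ``outcome`` are boolean ``(time, nlat, nlon)`` arrays;
    ``valid`` optionally masks out cells excluded from the analysis.
    Returns one row per (ilat, ilon, month) with columns a, b, c, d; every
    analysed day falls in exactly one of the four counts.
    """
    dates = pd.DatetimeIndex(dates)
    if exposure.shape != outcome.shape:
        raise ValueError("exposure and outcome must have the same shape")
    ny, nx = grid.shape
    rows = []
    for m in sorted(set(dates.month)):
        sel = np.asarray(dates.month == m)
        e = exposure[sel]
        o = outcome[sel]
        a = (e & o).sum(axis=0)
        b = (e & ~o).sum(axis=0)
        c = (~e & o).sum(axis=0)
        d = (~e & ~o).sum(axis=0)
        iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        keep = np.ones((ny, nx), dtype=bool) if valid is None else valid
        rows.append(
            pd.DataFrame(
                {
                    "ilat": iy[keep],
                    "ilon": ix[keep],
                    "lat": grid.lat[iy[keep]],
                    "lon": grid.lon[ix[keep]],
                    "month": m,
                    "a": a[keep],
                    "b": b[keep],
                    "c": c[keep],
                    "d": d[keep],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def classify_fire_days(
    ppa_mask: np.ndarray,
    fire_day: np.ndarray,
    dates: pd.DatetimeIndex,
    grid: Grid,
    lag_days: int = 7,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """PPA–fire classification: exposed = PPA during or up to ``lag_days``
    days before the day; outcome = fire ignition recorded that day."""
    exposure = lagged_exposure(ppa_mask, dates, lag_days)
    return classify_days(exposure, fire_day, dates, grid, valid=valid)


def classify_fwix_days(
    ppa_mask: np.ndarray,
    fwix: np.ndarray,
    dates: pd.DatetimeIndex,
    grid: Grid,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """PPA–FWIx classification: zero lag, outcome = extreme fire weather."""
    return classify_days(ppa_mask, fwix, dates, grid, valid=valid)


def odds_ratio(a, b, c, d, correction: float = 2.0):
    """Corrected odds ratio (a+k)(d+k) / ((b+k)(c+k)).

    With the partial Haldane correction k added to all four cells the ratio
    is always finite; k = 0 gives the classical cross-product ratio.
    """
    k = correction
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    return (a + k) * (d + k) / ((b + k) * (c + k))


def add_odds_ratios(tables: pd.DataFrame, correction: float = 2.0) -> pd.DataFrame:
    """Attach OR and the insufficient-data flag to a classification table.

    A cell-month is flagged insufficient when it has no outcome days at all
    (a + c = 0); flagged rows carry no odds ratio.
    """
    out = tables.copy()
    out["insufficient_data"] = (out["a"] + out["c"]) == 0
    out["odds_ratio"] = odds_ratio(out["a"], out["b"], out["c"], out["d"], correction)
    out.loc[out["insufficient_data"], "odds_ratio"] = np.nan
    return out


def regional_summary(
    results: pd.DataFrame, regions: RegionMap
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Summarize cell-level odds ratios by region.

    Returns ``(per_region_month, per_region, overall)``:

    * per region × month: mean, median, quartiles and share of cells with
      OR > 1 over the valid cell-level ORs;
    * per region: the same statistics pooled over that region's cell-months;
    * overall: the mean of the regional pooled means (the headline figure).

    Excluded cells and insufficient-data cell-months never contribute.
    """
    df = results.copy()
    df["region"] = [
        regions.labels[iy, ix] for iy, ix in zip(df["ilat"], df["ilon"])
    ]
    df["excluded"] = [
        bool(regions.excluded[iy, ix]) for iy, ix in zip(df["ilat"], df["ilon"])
    ]
    df = df[(df["region"] != "") & ~df["excluded"] & df["odds_ratio"].notna()]

    def _stats(g: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n_cells": len(g),
                "mean_or": g.mean(),
                "median_or": g.median(),
                "q25_or": g.quantile(0.25),
                "q75_or": g.quantile(0.75),
                "share_or_gt1": (g > 1).mean(),
            }
        )

    by_month = (
        df.groupby(["region", "month"])["odds_ratio"].apply(_stats).unstack()
        if len(df)
        else pd.DataFrame()
    )
    by_region = (
        df.groupby("region")["odds_ratio"].apply(_stats).unstack()
        if len(df)
        else pd.DataFrame()
    )
    overall = float(by_region["mean_or"].mean()) if len(by_region) else float("nan")
    return by_month.reset_index(), by_region.reset_index(), overall


@dataclass
class AttributionSummary:
    """Burned area on exposed cell-days as a share of all burned area."""

    region: str
    ppa_burned_ha: float
    total_burned_ha: float

    @property
    def percent(self) -> float:
        if self.total_burned_ha == 0:
            return float("nan")
        return 100.0 * self.ppa_burned_ha / self.total_burned_ha


def burned_area_attribution(
    burned_area: np.ndarray,
    ppa_mask: np.ndarray,
    dates: pd.DatetimeIndex,
    grid: Grid,
    regions: RegionMap,
    lag_days: int = 7,
) -> tuple[list[AttributionSummary], pd.DataFrame]:
    """Percent of burned area on PPA-exposed cell-days, per region and pooled.

    Also returns a per-lag histogram: hectares burned k days after the most
    recent PPA day covering the cell (k = 0 means during the PPA; k > lag
    or never-exposed hectares are binned as ``unexposed``).
    """
    exposure = lagged_exposure(ppa_mask, dates, lag_days)
    summaries = []
    region_mask = {
        r: (regions.labels == r) & ~regions.excluded for r in regions.regions
    }
    pooled_sel = ~regions.excluded & (regions.labels != "")
    for r, rm in region_mask.items():
        tot = float(burned_area[:, rm].sum())
        ppa = float(burned_area[:, rm][exposure[:, rm]].sum())
        summaries.append(AttributionSummary(region=r, ppa_burned_ha=ppa, total_burned_ha=tot))
    summaries.append(
        AttributionSummary(
            region="all",
            ppa_burned_ha=float(burned_area[:, pooled_sel][exposure[:, pooled_sel]].sum()),
            total_burned_ha=float(burned_area[:, pooled_sel].sum()),
        )
    )

    # lag histogram: days since most recent PPA day, within the lag window
    dates = pd.DatetimeIndex(dates)
    since = np.full(ppa_mask.shape, np.iinfo(np.int32).max, dtype=np.int32)
    gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D")) + 1
    starts = np.concatenate(([0], gaps, [len(dates)]))
    for s, e in zip(starts[:-1], starts[1:]):
        run = np.full(ppa_mask.shape[1:], np.iinfo(np.int32).max, dtype=np.int64)
        for t in range(s, e):
            run = np.where(ppa_mask[t], 0, np.minimum(run + 1, np.iinfo(np.int32).max))
            since[t] = run
    rows = []
    for k in range(lag_days + 1):
        sel = (since == k) & pooled_sel[None]
        rows.append({"days_since_ppa": k, "burned_ha": float(burned_area[sel].sum())})
    sel = (since > lag_days) & pooled_sel[None]
    rows.append({"days_since_ppa": -1, "burned_ha": float(burned_area[sel].sum())})
    return summaries, pd.DataFrame(rows)
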