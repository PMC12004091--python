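"""Event-relative diagnostics: lead–lag composites of surface anomalies and
burned area around the day of maximum PPA strength, and per-cell-month
t-statistics for the PPA effect on surface weather.

The composite freezes each event's footprint at its maximum-strength day
and averages the surface anomaly over that footprint at day offsets
−window…+window; offsets outside the season are dropped for that event and
the number of contributing events per lag is reported.  The per-cell
PPA-effect statistic is the t-statistic of the slope from an ordinary
least-squares regression of the daily anomaly on a PPA/non-PPA indicator —
algebraically identical to the pooled two-sample t — so values are
comparable across cells regardless of anomaly scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .anomaly import AnomalyField
from .detect import PPAEvent


def max_strength_day(event: PPAEvent) -> pd.Timestamp:
    """Date of maximal strength; ties broken by the earliest day."""
    return event.max_strength_date


@dataclass
class LeadLagComposite:
    """Mean anomaly and burned-area totals per day offset from max strength."""

    lags: np.ndarray
    mean_anomaly: dict[str, np.ndarray]   # variable -> per-lag composite mean
    burned_ha: np.ndarray                 # summed over events per lag
    n_events: np.ndarray                  # contributing events per lag

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lag": self.lags, "n_events": self.n_events, "burned_ha": self.burned_ha})
        for var, vals in self.mean_anomaly.items():
            df[f"mean_{var}"] = vals
        return df


def leadlag_composite(
    events: list[PPAEvent],
    anomalies: dict[str, AnomalyField],
    burned_area: np.ndarray | None = None,
    window: int = 15,
) -> LeadLagComposite:
    """Composite surface anomalies around each event's maximum-strength day.

    For each event the footprint (member cells on the max-strength day) is
    fixed; for each lag in ``[-window, +window]`` every anomaly variable is
    spatially averaged over the footprint on that day, and the composite is
    the unweighted mean across events.  Burned area is summed over event
    footprints per lag.  Lags falling outside the season (or data range)
    are dropped for that event.
    """
    if not events:
        raise ValueError("composite requires at least one event")
    some = next(iter(anomalies.values()))
    dates = some.dates
    gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D")) + 1
    starts = np.concatenate(([0], gaps, [len(dates)]))
    seg_of = np.zeros(len(dates), dtype=int)
    for i, (s, e) in enumerate(zip(starts[:-1], starts[1:])):
        seg_of[s:e] = i

    lags = np.arange(-window, window + 1)
    sums = {v: np.zeros(lags.size) for v in anomalies}
    counts = np.zeros(lags.size, dtype=int)
    burned = np.zeros(lags.size)
    for ev in events:
        i0 = ev.max_strength_day_index
        t0 = ev.time_idx[i0]
        cells = ev.cells_by_day[i0]
        for j, lag in enumerate(lags):
            t = t0 + lag
            if t < 0 or t >= len(dates) or seg_of[t] != seg_of[t0]:
                continue
            counts[j] += 1
            for v, an in anomalies.items():
                sums[v][j] += float(np.nanmean(an.values[t, cells[:, 0], cells[:, 1]]))
            if burned_area is not None:
                burned[j] += float(burned_area[t, cells[:, 0], cells[:, 1]].sum())
    means = {
        v: np.where(counts > 0, s / np.maximum(counts, 1), np.nan)
        for v, s in sums.items()
    }
    return LeadLagComposite(lags=lags, mean_anomaly=means, burned_ha=burned, n_events=counts)


def ppa_effect_tstat(
    anomalies: dict[str, AnomalyField],
    ppa_mask: np.ndarray,
    months: list[int] | None = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Per-cell-month t-statistic of the PPA effect on each surface variable.

    Fits anomaly ~ 1 + is_ppa_day by OLS per (cell, month) pool (days of
    that calendar month across all years) and reports the slope t-statistic
    (positive when PPA days have larger anomalies).  Cell-months with fewer
    than ``min_group`` days in either group, or with zero residual variance,
    are flagged and carry no t value.
    """
    some = next(iter(anomalies.values()))
    dates = some.dates
    ny, nx = some.grid.shape
    use_months = months or sorted(set(dates.month))
    rows = []
    for m in use_months:
        sel = np.asarray(dates.month == m)
        expo = ppa_mask[sel]
        for var, an in anomalies.items():
            vals = an.values[sel]
            for iy in range(ny):
                for ix in range(nx):
                    y = vals[:, iy, ix]
                    x = expo[:, iy, ix].astype(float)
                    ok = ~np.isnan(y)
                    y, x = y[ok], x[ok]
                    n1 = int(x.sum())
                    n0 = int(len(x) - n1)
                    t_val = np.nan
                    if n1 >= min_group and n0 >= min_group:
                        res = sm.OLS(y, sm.add_constant(x)).fit()
                        if res.bse[1] > 0 and np.isfinite(res.bse[1]):
                            t_val = float(res.tvalues[1])
                    rows.append(
                        {
                            "ilat": iy,
                            "ilon": ix,
                            "month": m,
                            "variable": var,
                            "t_stat": t_val,
                            "n_ppa_days": n1,
                            "n_non_ppa_days": n0,
                        }
                    )
    return pd.DataFrame(rows)


def seasonal_mean_tstat(tstats: pd.DataFrame, months: list[int]) -> pd.DataFrame:
    """Average the monthly t surfaces over a set of months (e.g. Jun–Aug)."""
    sub = tstats[tstats["month"].isin(months)]
    return (
        sub.groupby(["ilat", "ilon", "variable"])["t_stat"].mean().reset_index()
    )


def residual_normality_screen(
    anomalies: dict[str, AnomalyField], ppa_mask: np.ndarray, max_cells: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Shapiro–Wilk screen of regression residuals on a random cell sample.

    Logged diagnostics only — normality is assessed, never enforced.
    """
    rng = np.random.default_rng(seed)
    some = next(iter(anomalies.values()))
    ny, nx = some.grid.shape
    cells = [(iy, ix) for iy in range(ny) for ix in range(nx)]
    if len(cells) > max_cells:
        cells = [cells[i] for i in rng.choice(len(cells), max_cells, replace=False)]
    rows = []
    for var, an in anomalies.items():
        for iy, ix in cells:
            y = an.values[:, iy, ix]
            x = ppa_mask[:, iy, ix].astype(float)
            ok = ~np.isnan(y)
            y, x = y[ok], x[ok]
            if len(y) < 8 or x.sum() == 0 or x.sum() == len(x):
                continue
            resid = y - y[x == 0].mean() - x * (y[x == 1].mean() - y[x == 0].mean())
            w, p = stats.shapiro(resid[: min(len(resid), 500)])
            rows.append({"variable": var, "ilat": iy, "ilon": ix, "shapiro_w": w, "p_value": p})
    return pd.DataFrame(rows)
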