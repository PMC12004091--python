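"""Persistent-positive-anomaly (PPA) detection and tracking.

A PPA cell-day is a grid cell whose latitude-corrected, 5-day-smoothed Z500
anomaly stays at or above the seasonally varying magnitude threshold for at
least ``min_duration`` consecutive days.  Flagged cells are clustered
spatially each day (8-connectivity by default), clusters are linked through
time by cell overlap, and a track whose area ever reaches
``min_event_area`` km² is labelled a PPA event.  Event strength on a day is
the anomaly integrated over the member cells (gpm·km²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label

from .anomaly import AnomalyField, STAGE_LAT_CORRECTED, ThresholdSeries
from .grid import Grid


def flag_cells(
    anom: AnomalyField,
    thresholds: ThresholdSeries,
    min_duration: int = 5,
    use_per_cell: bool = False,
) -> np.ndarray:
    """Boolean mask of PPA cell-days.

    A cell-day is flagged iff it belongs to a run of at least
    ``min_duration`` consecutive in-season days on which the anomaly is
    >= multiplier × threshold(day).  Runs never span season boundaries.
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    if anom.stage != STAGE_LAT_CORRECTED:
        raise ValueError("flagging requires latitude-corrected anomalies")
    keys = anom.calendar_keys()
    if use_per_cell:
        if thresholds.per_cell is None:
            raise ValueError("per-cell thresholds were not computed")
        pos = {int(k): i for i, k in enumerate(thresholds.calendar_keys)}
        idx = np.array([pos[int(k)] for k in keys])
        thr = thresholds.per_cell[idx]
    else:
        thr = thresholds.lookup(keys)[:, None, None]
    exceed = anom.values >= thresholds.multiplier * thr

    mask = np.zeros_like(exceed)
    for seg in anom.season_segments():
        mask[seg] = _runs_at_least(exceed[seg], min_duration)
    return mask


def _runs_at_least(exceed: np.ndarray, min_len: int) -> np.ndarray:
    """Mark members of consecutive-True runs of length >= min_len (axis 0)."""
    n = exceed.shape[0]
    run = np.zeros(exceed.shape[1:], dtype=np.int32)
    fwd = np.empty_like(exceed, dtype=np.int32)
    for t in range(n):
        run = np.where(exceed[t], run + 1, 0)
        fwd[t] = run
    out = np.zeros_like(exceed)
    best = np.zeros(exceed.shape[1:], dtype=np.int32)
    for t in range(n - 1, -1, -1):
        best = np.where(exceed[t], np.maximum(best, fwd[t]), 0)
        out[t] = best >= min_len
    return out


def cluster_daily(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label spatially contiguous flagged cells per day.

    ``connectivity`` 8 joins cells sharing an edge or a corner, 4 only an
    edge.  Returns an int array of per-day labels, 0 = background.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    labels = np.zeros(mask.shape, dtype=np.int32)
    for t in range(mask.shape[0]):
        labels[t] = sk_label(mask[t], connectivity=conn)
    return labels


@dataclass
class Track:
    """A chain of day-to-day linked clusters.

    ``cells_by_day[i]`` is an ``(n_i, 2)`` array of (ilat, ilon) member
    indices for consecutive time index ``time_idx[i]``.
    """

    track_id: int
    time_idx: list[int] = field(default_factory=list)
    cells_by_day: list[np.ndarray] = field(default_factory=list)
    parent_id: int | None = None  # track this one split from / merged into

    @property
    def duration(self) -> int:
        return len(self.time_idx)


def track_clusters(labels: np.ndarray, dates: pd.DatetimeIndex) -> list[Track]:
    """Link daily clusters into tracks by >= 1-cell overlap on consecutive days.

    When several clusters merge, the largest-area parent's identity
    continues and the other parents terminate with a link; when a cluster
    splits, the largest child keeps the identity and the other children
    start new tracks linked to the parent.  A day without overlap ends the
    track (no gap-bridging: persistence is already enforced per cell).
    Season boundaries (gaps in ``dates``) always break links.
    """
    dates = pd.DatetimeIndex(dates)
    tracks: list[Track] = []
    # active: cluster label on previous day -> track index
    active: dict[int, int] = {}
    prev_labels = None
    next_id = 0

    for t in range(labels.shape[0]):
        day = labels[t]
        day_cluster_ids = [int(c) for c in np.unique(day) if c != 0]
        contiguous = (
            t > 0 and (dates[t] - dates[t - 1]) == pd.Timedelta(days=1)
        )
        new_active: dict[int, int] = {}
        if contiguous and prev_labels is not None and active:
            # overlap matrix between yesterday's and today's clusters
            overlaps: dict[int, list[int]] = {c: [] for c in day_cluster_ids}
            parents_children: dict[int, list[int]] = {}
            both = (prev_labels != 0) & (day != 0)
            pairs = set(zip(prev_labels[both].tolist(), day[both].tolist()))
            for p, c in pairs:
                overlaps[c].append(p)
                parents_children.setdefault(p, []).append(c)
            sizes_today = {c: int((day == c).sum()) for c in day_cluster_ids}
            sizes_prev = {p: int((prev_labels == p).sum()) for p in parents_children}

            for c in day_cluster_ids:
                cells = np.argwhere(day == c)
                parents = overlaps[c]
                if parents:
                    # merge rule: continue the largest-area parent
                    p_star = max(parents, key=lambda p: (sizes_prev[p], -p))
                    # split rule: only the largest child continues p_star
                    siblings = parents_children[p_star]
                    c_star = max(siblings, key=lambda s: (sizes_today[s], -s))
                    parent_track = active[p_star]
                    if c == c_star:
                        tracks[parent_track].time_idx.append(t)
                        tracks[parent_track].cells_by_day.append(cells)
                        new_active[c] = parent_track
                        continue
                    # smaller split fragment: new track with a parent link
                    tr = Track(track_id=next_id, parent_id=tracks[parent_track].track_id)
                    next_id += 1
                    tr.time_idx.append(t)
                    tr.cells_by_day.append(cells)
                    tracks.append(tr)
                    new_active[c] = len(tracks) - 1
                else:
                    tr = Track(track_id=next_id)
                    next_id += 1
                    tr.time_idx.append(t)
                    tr.cells_by_day.append(cells)
                    tracks.append(tr)
                    new_active[c] = len(tracks) - 1
        else:
            for c in day_cluster_ids:
                tr = Track(track_id=next_id)
                next_id += 1
                tr.time_idx.append(t)
                tr.cells_by_day.append(np.argwhere(day == c))
                tracks.append(tr)
                new_active[c] = len(tracks) - 1
        active = new_active
        prev_labels = day
    return tracks


@dataclass
class PPAEvent:
    """A labelled PPA event: a track that reached the minimum size."""

    event_id: int
    start: pd.Timestamp
    end: pd.Timestamp
    duration_days: int
    max_area_km2: float
    max_strength: float
    max_strength_date: pd.Timestamp
    time_idx: list[int]
    cells_by_day: list[np.ndarray]
    areas_km2: np.ndarray          # per day
    strengths: np.ndarray          # per day, gpm·km²
    centroids: np.ndarray          # per day, (lat, lon)
    qualifying_days: int = 0       # days on which area >= min_event_area

    @property
    def max_strength_day_index(self) -> int:
        return int(np.argmax(self.strengths))


def _track_diagnostics(
    track: Track, anom: AnomalyField, cell_areas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-day (area, strength, centroid) for a track."""
    nd = track.duration
    areas = np.empty(nd)
    strengths = np.empty(nd)
    centroids = np.empty((nd, 2))
    lat = anom.grid.lat
    lon = anom.grid.lon
    for i, (t, cells) in enumerate(zip(track.time_idx, track.cells_by_day)):
        a = cell_areas[cells[:, 0], cells[:, 1]]
        areas[i] = a.sum()
        strengths[i] = float(
            np.sum(anom.values[t, cells[:, 0], cells[:, 1]] * a)
        )
        w = a / a.sum()
        centroids[i] = (
            float(np.sum(lat[cells[:, 0]] * w)),
            float(np.sum(lon[cells[:, 1]] * w)),
        )
    return areas, strengths, centroids


def label_events(
    tracks: list[Track],
    anom: AnomalyField,
    min_event_area: float = 40_000.0,
    min_duration: int = 1,
) -> list[PPAEvent]:
    """Promote tracks that ever reach ``min_event_area`` km² to PPA events.

    Event duration is the full track lifespan, including days before the
    size criterion is first met; ``qualifying_days`` additionally counts the
    days on which the daily area meets the size criterion — a duration
    measure robust to one-cell fringe days at the track's ends.
    Identifiers are deterministic: events are ordered by start date, then
    west-to-east first-day centroid.
    """
    cell_areas = anom.grid.cell_areas()
    candidates = []
    for tr in tracks:
        if tr.duration < min_duration:
            continue
        areas, strengths, centroids = _track_diagnostics(tr, anom, cell_areas)
        if areas.max() < min_event_area:
            continue
        candidates.append((tr, areas, strengths, centroids))

    candidates.sort(
        key=lambda c: (c[0].time_idx[0], c[3][0, 1], c[3][0, 0])
    )
    events = []
    for eid, (tr, areas, strengths, centroids) in enumerate(candidates):
        imax = int(np.argmax(strengths))  # ties -> earliest day
        events.append(
            PPAEvent(
                event_id=eid,
                start=anom.dates[tr.time_idx[0]],
                end=anom.dates[tr.time_idx[-1]],
                duration_days=tr.duration,
                max_area_km2=float(areas.max()),
                max_strength=float(strengths[imax]),
                max_strength_date=anom.dates[tr.time_idx[imax]],
                time_idx=list(tr.time_idx),
                cells_by_day=list(tr.cells_by_day),
                areas_km2=areas,
                strengths=strengths,
                centroids=centroids,
                qualifying_days=int((areas >= min_event_area).sum()),
            )
        )
    return events


def ppa_day_mask(
    events: list[PPAEvent], grid: Grid, dates: pd.DatetimeIndex
) -> np.ndarray:
    """Boolean exposure mask: cell-day belongs to some labelled event."""
    mask = np.zeros((len(dates),) + grid.shape, dtype=bool)
    for ev in events:
        for t, cells in zip(ev.time_idx, ev.cells_by_day):
            mask[t, cells[:, 0], cells[:, 1]] = True
    return mask


def monthly_ppa_percentage(
    mask: np.ndarray, dates: pd.DatetimeIndex
) -> pd.DataFrame:
    """Average percentage of PPA days per cell per calendar month.

    For each calendar month, the share of that month's days (pooled across
    years) on which the cell lay inside a labelled event.
    """
    dates = pd.DatetimeIndex(dates)
    rows = []
    for m in sorted(set(dates.month)):
        sel = dates.month == m
        pct = 100.0 * mask[sel].mean(axis=0)
        rows.append(pct)
    months = sorted(set(dates.month))
    return pd.DataFrame(
        {
            "month": np.repeat(months, mask.shape[1] * mask.shape[2]),
            "ilat": np.tile(np.repeat(np.arange(mask.shape[1]), mask.shape[2]), len(months)),
            "ilon": np.tile(np.tile(np.arange(mask.shape[2]), mask.shape[1]), len(months)),
            "ppa_day_percent": np.concatenate([r.ravel() for r in rows]),
        }
    )


def detect_events(
    anom: AnomalyField,
    thresholds: ThresholdSeries,
    min_duration: int = 5,
    connectivity: int = 8,
    min_event_area: float = 40_000.0,
    use_per_cell: bool = False,
) -> tuple[list[PPAEvent], np.ndarray]:
    """Full detection chain: flag -> cluster -> track -> label.

    Returns the event list and the per-day exposure mask.
    """
    flags = flag_cells(anom, thresholds, min_duration=min_duration, use_per_cell=use_per_cell)
    labels = cluster_daily(flags, connectivity=connectivity)
    tracks = track_clusters(labels, anom.dates)
    events = label_events(tracks, anom, min_event_area=min_event_area)
    mask = ppa_day_mask(events, anom.grid, anom.dates)
    return events, mask


def events_to_frame(events: list[PPAEvent]) -> pd.DataFrame:
    """Event catalog as a flat table (one row per event)."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "duration_days": [e.duration_days for e in events],
            "max_area_km2": [e.max_area_km2 for e in events],
            "max_strength_gpm_km2": [e.max_strength for e in events],
            "max_strength_date": [e.max_strength_date for e in events],
            "centroid_lat": [e.centroids[e.max_strength_day_index, 0] for e in events],
            "centroid_lon": [e.centroids[e.max_strength_day_index, 1] for e in events],
        }
    )
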