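"""PPA cell flagging, daily clustering, tracking and event labelling.

Clustering is checked against a brute-force flood fill and tracking against
an independently coded overlap-chain tracker.
"""

import numpy as np
import pandas as pd
import pytest

from ppafire.anomaly import (
    ThresholdSeries,
    compute_anomaly,
    daily_climatology,
    latitude_correction,
    smooth_time,
)
from ppafire.detect import (
    _runs_at_least,
    cluster_daily,
    detect_events,
    flag_cells,
    label_events,
    monthly_ppa_percentage,
    ppa_day_mask,
    track_clusters,
)
from ppafire.grid import cell_area

from conftest import make_field, season_dates


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def flood_fill_oracle(mask, connectivity=8):
    """Label connected components by explicit stack-based flood fill."""
    ny, nx = mask.shape
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((ny, nx), dtype=int)
    nxt = 0
    for sy in range(ny):
        for sx in range(nx):
            if mask[sy, sx] and labels[sy, sx] == 0:
                nxt += 1
                stack = [(sy, sx)]
                labels[sy, sx] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in steps:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and labels[yy, xx] == 0:
                            labels[yy, xx] = nxt
                            stack.append((yy, xx))
    return labels


def run_scan_oracle(series, min_len):
    """Mark positions inside runs of >= min_len consecutive True values."""
    out = np.zeros(len(series), dtype=bool)
    i = 0
    while i < len(series):
        if series[i]:
            j = i
            while j < len(series) and series[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def chain_tracker_oracle(labels):
    """Independent overlap-chain tracker (set-based, quadratic).

    Implements the same linking contract: consecutive-day clusters link on
    >= 1 shared cell; merges continue the largest parent, splits continue
    the largest child; everything else starts a new track.
    Returns a list of tracks, each a list of (day, frozenset-of-cells).
    """
    days = []
    for t in range(labels.shape[0]):
        clusters = {}
        for lab in np.unique(labels[t]):
            if lab:
                clusters[lab] = frozenset(map(tuple, np.argwhere(labels[t] == lab)))
        days.append(clusters)
    tracks = []
    active = {}  # yesterday's label -> track index
    for t, clusters in enumerate(days):
        new_active = {}
        prev = days[t - 1] if t > 0 else {}
        for lab, cells in sorted(clusters.items()):
            parents = [pl for pl, pc in prev.items() if pc & cells]
            chosen = None
            if parents:
                p_star = max(parents, key=lambda p: (len(prev[p]), -p))
                children = [cl for cl, cc in clusters.items() if prev[p_star] & cc]
                c_star = max(children, key=lambda c: (len(clusters[c]), -c))
                if lab == c_star:
                    chosen = active[p_star]
            if chosen is None:
                tracks.append([])
                chosen = len(tracks) - 1
            tracks[chosen].append((t, cells))
            new_active[lab] = chosen
        active = new_active
    return tracks


def tracks_as_sets(tracks):
    return {frozenset((t, c) for t, cells in tr for c in map(tuple, cells)) for tr in tracks}


def pkg_tracks_as_sets(tracks):
    out = set()
    for tr in tracks:
        s = set()
        for t, cells in zip(tr.time_idx, tr.cells_by_day):
            s.update((t, (int(c[0]), int(c[1]))) for c in cells)
        out.add(frozenset(s))
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def _corrected_anomaly(values, lat0=40.0, ref_row=0, **kw):
    f = make_field(np.zeros(values.shape, dtype=float), lat0=lat0, **kw)
    an = compute_anomaly(f, daily_climatology(f)).copy_with(np.asarray(values, dtype=float))
    # identity scaling at row ref_row keeps hand-computed magnitudes exact there
    return latitude_correction(smooth_time(an, 1), ref_lat=lat0 + ref_row)


def _uniform_threshold(an, value):
    keys = np.unique(an.calendar_keys())
    return ThresholdSeries(calendar_keys=keys, threshold=np.full(keys.size, value))


class TestFlagCells:
    def _flags(self, series, min_duration=5):
        vals = np.zeros((490, 1, 1))
        vals[: len(series), 0, 0] = series
        an = _corrected_anomaly(vals, lat0=45.0)
        return flag_cells(an, _uniform_threshold(an, 1.0), min_duration)[:, 0, 0]

    def test_six_day_run_flagged(self):
        f = self._flags([0, 0, 0, 2, 2, 2, 2, 2, 2, 0])
        assert f[3:9].all() and not f[:3].any() and not f[9:].any()

    def test_four_day_run_not_flagged(self):
        assert not self._flags([0, 0, 0, 2, 2, 2, 2, 0]).any()

    def test_gap_splits_runs(self):
        pattern = [2] * 5 + [0] + [2] * 5
        f = self._flags(pattern)
        assert f[:5].all() and not f[5] and f[6:11].all()

    def test_min_duration_one(self):
        f = self._flags([0, 2, 0], min_duration=1)
        assert f[1] and not f[0] and not f[2]

    def test_invalid_duration(self):
        an = _corrected_anomaly(np.zeros((490, 1, 1)))
        with pytest.raises(ValueError):
            flag_cells(an, _uniform_threshold(an, 1.0), 0)

    def test_runs_never_cross_season_boundary(self):
        vals = np.zeros((490, 1, 1))
        vals[242:248] = 5.0  # 3 days end of season 1, 3 days start of season 2
        an = _corrected_anomaly(vals, lat0=45.0)
        assert not flag_cells(an, _uniform_threshold(an, 1.0), 5).any()

    def test_matches_run_scan_oracle(self, rng):
        exceed = rng.random((60, 4, 4)) < 0.45
        got = _runs_at_least(exceed, 5)
        for iy in range(4):
            for ix in range(4):
                assert (got[:, iy, ix] == run_scan_oracle(exceed[:, iy, ix], 5)).all()


class TestClusterDaily:
    def test_edge_neighbours_one_cluster(self):
        m = np.zeros((1, 3, 3), dtype=bool)
        m[0, 1, 0] = m[0, 1, 1] = True
        for conn in (4, 8):
            labs = cluster_daily(m, conn)[0]
            assert labs[1, 0] == labs[1, 1] > 0

    def test_corner_neighbours_depend_on_connectivity(self):
        m = np.zeros((1, 3, 3), dtype=bool)
        m[0, 0, 0] = m[0, 1, 1] = True
        assert cluster_daily(m, 8)[0][0, 0] == cluster_daily(m, 8)[0][1, 1]
        labs4 = cluster_daily(m, 4)[0]
        assert labs4[0, 0] != labs4[1, 1]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(30):
            m = (rng.random((1, 12, 12)) < 0.3)
            got = cluster_daily(m, connectivity)[0]
            want = flood_fill_oracle(m[0], connectivity)
            # same partition: label images agree up to renaming
            assert (got > 0).sum() == (want > 0).sum()
            for lab in np.unique(got):
                if lab:
                    cells = got == lab
                    assert len(np.unique(want[cells])) == 1
            assert len(np.unique(got)) == len(np.unique(want))


class TestTracking:
    def _dates(self, n):
        return season_dates([2001])[:n]

    def test_stationary_cluster_single_track(self):
        labels = np.zeros((6, 4, 4), dtype=int)
        labels[:, 1:3, 1:3] = 1
        tracks = track_clusters(labels, self._dates(6))
        assert len(tracks) == 1 and tracks[0].duration == 6

    def test_drifting_cluster_links_by_overlap(self):
        labels = np.zeros((5, 4, 10), dtype=int)
        for t in range(5):
            labels[t, 1:3, t : t + 3] = 1
        tracks = track_clusters(labels, self._dates(5))
        assert len(tracks) == 1 and tracks[0].duration == 5

    def test_disjoint_clusters_two_tracks(self):
        labels = np.zeros((4, 5, 10), dtype=int)
        labels[:2, 1, 1] = 1
        labels[2:, 3, 8] = 1
        tracks = track_clusters(labels, self._dates(4))
        assert len(tracks) == 2

    def test_season_gap_breaks_track(self):
        dates = season_dates([2001, 2002], months=(3, 3))
        labels = np.zeros((len(dates), 3, 3), dtype=int)
        labels[29:33, 1, 1] = 1  # spans the season boundary at index 31
        tracks = track_clusters(labels, dates)
        assert sorted(tr.duration for tr in tracks) == [2, 2]

    def test_matches_chain_oracle_on_random_scenarios(self, rng):
        for _ in range(25):
            mask = rng.random((6, 8, 8)) < 0.25
            labels = cluster_daily(mask, 8)
            got = pkg_tracks_as_sets(track_clusters(labels, self._dates(6)))
            want = tracks_as_sets(chain_tracker_oracle(labels))
            assert got == want


class TestLabelEvents:
    def _events(self, values, min_event_area=40_000.0, lat0=40.0):
        an = _corrected_anomaly(values, lat0=lat0)
        flags = flag_cells(an, _uniform_threshold(an, 1.0), 5)
        labels = cluster_daily(flags, 8)
        tracks = track_clusters(labels, an.dates)
        return label_events(tracks, an, min_event_area=min_event_area), an

    def test_small_track_not_labelled(self):
        vals = np.zeros((490, 4, 4))
        vals[10:20, 1, 1] = 5.0  # single cell ≈ 8500 km² < 40 000
        events, _ = self._events(vals)
        assert events == []

    def test_five_cell_block_at_forty_north(self):
        vals = np.zeros((490, 3, 8))
        vals[10:16, 1, 1:6] = 5.0  # 5 cells in the 41°N row for 6 days
        events, an = self._events(vals)
        area = 5 * cell_area(41.0, 1.0)
        assert area > 40_000
        assert len(events) == 1
        assert events[0].duration_days == 6
        assert events[0].max_area_km2 == pytest.approx(area)

    def test_strength_is_area_weighted_anomaly(self):
        vals = np.zeros((490, 3, 8))
        vals[10:16, 1, 1:7] = 100.0
        an = _corrected_anomaly(vals, lat0=45.0, ref_row=1)
        flags = flag_cells(an, _uniform_threshold(an, 1.0), 5)
        tracks = track_clusters(cluster_daily(flags, 8), an.dates)
        events = label_events(tracks, an, min_event_area=40_000.0)
        area = 6 * cell_area(46.0, 1.0)
        assert len(events) == 1
        assert events[0].strengths[2] == pytest.approx(100.0 * area, rel=1e-6)

    def test_event_count_monotone_in_thresholds(self, rng):
        vals = 60.0 * (rng.random((245, 10, 10)) < 0.5)  # dense noisy exceedances
        f = make_field(np.zeros((490, 10, 10)))
        an = compute_anomaly(f, daily_climatology(f)).copy_with(
            np.concatenate([vals, np.zeros((245, 10, 10))])
        )
        an = latitude_correction(smooth_time(an, 1), ref_lat=40.0)
        thr = _uniform_threshold(an, 30.0)
        counts_dur = []
        for dur in (2, 4, 6):
            flags = flag_cells(an, thr, dur)
            tracks = track_clusters(cluster_daily(flags), an.dates)
            counts_dur.append(len(label_events(tracks, an, min_event_area=20_000)))
        assert counts_dur == sorted(counts_dur, reverse=True)
        flags = flag_cells(an, thr, 2)
        tracks = track_clusters(cluster_daily(flags), an.dates)
        counts_area = [
            len(label_events(tracks, an, min_event_area=a)) for a in (10_000, 40_000, 80_000)
        ]
        assert counts_area == sorted(counts_area, reverse=True)


class TestExposureMask:
    def test_no_events_empty_mask(self, small_grid):
        dates = season_dates([2001])
        mask = ppa_day_mask([], small_grid, dates)
        assert not mask.any()
        pct = monthly_ppa_percentage(mask, dates)
        assert (pct["ppa_day_percent"] == 0).all()

    def test_month_percentage(self):
        vals = np.zeros((490, 3, 8))
        vals[61:70, 1, 1:7] = 100.0  # 9 days of May 2001 (May starts at index 61)
        an = _corrected_anomaly(vals)
        flags = flag_cells(an, _uniform_threshold(an, 1.0), 5)
        tracks = track_clusters(cluster_daily(flags), an.dates)
        events = label_events(tracks, an, min_event_area=40_000)
        mask = ppa_day_mask(events, an.grid, an.dates)
        pct = monthly_ppa_percentage(mask, an.dates)
        row = pct[(pct["month"] == 5) & (pct["ilat"] == 1) & (pct["ilon"] == 2)]
        # 9 of 31 May days in year one, 0 of 31 in year two
        assert row["ppa_day_percent"].iloc[0] == pytest.approx(100 * 9 / 62)

    def test_mask_equals_union_of_event_cells(self, rng):
        vals = 80.0 * (rng.random((245, 8, 8)) < 0.4)
        an = _corrected_anomaly(np.concatenate([vals, np.zeros((245, 8, 8))]))
        events, mask = detect_events(an, _uniform_threshold(an, 30.0), min_event_area=20_000)
        want = np.zeros_like(mask)
        for ev in events:
            for t, cells in zip(ev.time_idx, ev.cells_by_day):
                for c in cells:
                    want[t, c[0], c[1]] = True
        assert (mask == want).all()
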