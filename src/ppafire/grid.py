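"""Grid geometry, gridded fields, fire-record rasterization and region maps.

The analysis operates on a regular latitude/longitude grid (cell centers,
uniform spacing).  Gridded variables are held in :class:`GriddedField`, a thin
container around a ``(time, lat, lon)`` array with NaN as the explicit
missing-value sentinel.  Burned-area records are consumed as one
representative point per fire (date, lat, lon, hectares) and rasterized onto
the grid by half-open cell ownership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Grid:
    """Regular lat/lon grid defined by its cell centers.

    Parameters
    ----------
    lat : ndarray
        Cell-center latitudes, degrees north, strictly ascending, uniform.
    lon : ndarray
        Cell-center longitudes, degrees east, strictly ascending, uniform.
    """

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        for name, arr in (("lat", lat), ("lon", lon)):
            if arr.ndim != 1 or arr.size < 1:
                raise ValueError(f"{name} must be a 1-d array of centers")
            if arr.size > 1:
                steps = np.diff(arr)
                if not np.all(steps > 0):
                    raise ValueError(f"{name} centers must be ascending")
                if not np.allclose(steps, steps[0]):
                    raise ValueError(f"{name} spacing must be uniform")
        if np.any(np.abs(lat) >= 90):
            raise ValueError("latitude centers must satisfy |lat| < 90")

    @property
    def resolution(self) -> float:
        """Grid spacing in degrees (assumed equal in both axes)."""
        if self.lat.size > 1:
            return float(self.lat[1] - self.lat[0])
        if self.lon.size > 1:
            return float(self.lon[1] - self.lon[0])
        raise ValueError("resolution undefined for a single-cell grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    def cell_areas(self) -> np.ndarray:
        """Spherical area of every cell, km², shape ``(nlat, nlon)``."""
        res = self.resolution
        band = np.array([cell_area(la, res) for la in self.lat])
        return np.broadcast_to(band[:, None], self.shape).copy()

    def locate(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to cell indices under half-open ownership.

        A point belongs to the cell whose interval
        ``[center - res/2, center + res/2)`` contains it in both axes.
        Returns ``(ilat, ilon, inside)`` where ``inside`` is False for
        out-of-bounds points (their indices are undefined).
        """
        res = self.resolution
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        ilat = np.floor((lat - (self.lat[0] - res / 2)) / res).astype(int)
        ilon = np.floor((lon - (self.lon[0] - res / 2)) / res).astype(int)
        inside = (
            (ilat >= 0)
            & (ilat < self.lat.size)
            & (ilon >= 0)
            & (ilon < self.lon.size)
        )
        return ilat, ilon, inside


def cell_area(lat_center: float, resolution: float) -> float:
    """Area in km² of a grid cell centered at ``lat_center`` with width
    ``resolution`` degrees in both axes.

    Uses the exact spherical band formula
    ``R² Δλ (sin(φ+Δφ/2) − sin(φ−Δφ/2))`` with R = 6371 km.
    """
    if abs(lat_center) + resolution / 2 > 90 + 1e-12:
        raise ValueError("cell latitude band crosses a pole")
    dlam = np.deg2rad(resolution)
    phi_hi = np.deg2rad(lat_center + resolution / 2)
    phi_lo = np.deg2rad(lat_center - resolution / 2)
    return float(EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_hi) - np.sin(phi_lo)))


def _season_breaks(dates: pd.DatetimeIndex) -> np.ndarray:
    """Indices where a new contiguous season segment starts."""
    if len(dates) == 0:
        return np.array([], dtype=int)
    gaps = np.flatnonzero(np.diff(dates.values) != np.timedelta64(1, "D")) + 1
    return np.concatenate(([0], gaps))


@dataclass
class GriddedField:
    """One gridded variable: ``values[time, lat, lon]`` with NaN for missing.

    Dates are calendar days; within each year's season window they are
    contiguous, and gaps in the date index mark season boundaries (operations
    with moving windows never cross them).
    """

    grid: Grid
    dates: pd.DatetimeIndex
    values: np.ndarray
    name: str = "field"
    units: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.dates),) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match (time, lat, lon) {expected}"
            )

    # -- calendar helpers -------------------------------------------------
    def season_segments(self) -> list[slice]:
        """Slices of contiguous daily runs (one per season per year)."""
        starts = _season_breaks(self.dates)
        bounds = list(starts) + [len(self.dates)]
        return [slice(bounds[i], bounds[i + 1]) for i in range(len(starts))]

    def calendar_keys(self) -> np.ndarray:
        """Integer key ``100*month + day`` for every date (leap-safe within
        March–October)."""
        return (self.dates.month * 100 + self.dates.day).to_numpy()

    def copy_with(self, values: np.ndarray, **kw) -> "GriddedField":
        out = replace(self, values=np.asarray(values, dtype=float))
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    # -- I/O ---------------------------------------------------------------
    def to_xarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            coords={"time": self.dates, "latitude": self.grid.lat, "longitude": self.grid.lon},
            dims=("time", "latitude", "longitude"),
            name=self.name,
        )
        da.attrs["units"] = self.units
        return da

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_xarray(cls, da: xr.DataArray) -> "GriddedField":
        lat_name = "latitude" if "latitude" in da.dims else "lat"
        lon_name = "longitude" if "longitude" in da.dims else "lon"
        da = da.transpose("time", lat_name, lon_name)
        lat = da[lat_name].values
        if lat[0] > lat[-1]:  # stored north-to-south
            da = da.isel({lat_name: slice(None, None, -1)})
            lat = da[lat_name].values
        grid = Grid(lat=lat, lon=da[lon_name].values)
        return cls(
            grid=grid,
            dates=pd.DatetimeIndex(da["time"].values),
            values=da.values.astype(float),
            name=da.name or "field",
            units=str(da.attrs.get("units", "")),
        )

    @classmethod
    def from_netcdf(cls, path, variable: str | None = None) -> "GriddedField":
        ds = xr.open_dataset(path)
        if variable is None:
            data_vars = list(ds.data_vars)
            if len(data_vars) != 1:
                raise ValueError(f"specify variable; file has {data_vars}")
            variable = data_vars[0]
        return cls.from_xarray(ds[variable])


def regrid_mean(field: GriddedField, target_resolution: float) -> GriddedField:
    """Aggregate to a coarser grid by block-averaging.

    The target resolution must be an integer multiple of the source
    resolution; each coarse cell is the unweighted mean of its constituent
    fine cells, with missing fine cells excluded (an all-missing block stays
    missing).
    """
    src_res = field.grid.resolution
    factor = target_resolution / src_res
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target resolution {target_resolution} is not a multiple of {src_res}"
        )
    k = int(round(factor))
    ny, nx = field.grid.shape
    ny_c, nx_c = ny // k, nx // k
    vals = field.values[:, : ny_c * k, : nx_c * k]
    blocks = vals.reshape(len(field.dates), ny_c, k, nx_c, k)
    with np.errstate(invalid="ignore"):
        coarse = np.nanmean(blocks, axis=(2, 4))
    lat_c = field.grid.lat[: ny_c * k].reshape(ny_c, k).mean(axis=1)
    lon_c = field.grid.lon[: nx_c * k].reshape(nx_c, k).mean(axis=1)
    return GriddedField(
        grid=Grid(lat=lat_c, lon=lon_c),
        dates=field.dates,
        values=coarse,
        name=field.name,
        units=field.units,
    )


# ---------------------------------------------------------------------------
# Fire records
# ---------------------------------------------------------------------------

FIRE_COLUMNS = ["date", "lat", "lon", "area_ha"]


def read_fire_records(path) -> pd.DataFrame:
    """Read a delimited fire-record table with columns date, lat, lon, area_ha."""
    df = pd.read_csv(path)
    missing = set(FIRE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fire table missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df[FIRE_COLUMNS]


def clean_fire_records(
    records: pd.DataFrame, season_months: tuple[int, int] = (3, 10)
) -> pd.DataFrame:
    """Drop non-positive areas, undated records and out-of-season dates.

    Dropped counts are logged, never raised: the upstream databases contain
    records with undeterminable ignition dates and winter fires outside the
    analysis window.
    """
    n0 = len(records)
    out = records.dropna(subset=["date", "lat", "lon", "area_ha"])
    out = out[out["area_ha"] > 0]
    months = pd.DatetimeIndex(out["date"]).month
    out = out[(months >= season_months[0]) & (months <= season_months[1])]
    if len(out) < n0:
        logger.info("dropped %d of %d fire records (undated/out-of-season/non-positive)", n0 - len(out), n0)
    return out.reset_index(drop=True)


def rasterize_fires(
    records: pd.DataFrame, grid: Grid, dates: pd.DatetimeIndex
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sum burned hectares per (day, cell) and derive the fire-day indicator.

    Returns ``(burned_area, fire_day, n_dropped)`` where ``burned_area`` has
    shape ``(time, nlat, nlon)`` in hectares, ``fire_day = burned_area > 0``,
    and ``n_dropped`` counts out-of-bounds or off-calendar records.
    """
    dates = pd.DatetimeIndex(dates)
    burned = np.zeros((len(dates),) + grid.shape)
    if len(records) == 0:
        return burned, burned > 0, 0
    ilat, ilon, inside = grid.locate(records["lat"].to_numpy(), records["lon"].to_numpy())
    date_pos = dates.get_indexer(pd.DatetimeIndex(records["date"]).normalize())
    keep = inside & (date_pos >= 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d fire records outside grid/calendar", n_dropped)
    np.add.at(burned, (date_pos[keep], ilat[keep], ilon[keep]), records["area_ha"].to_numpy()[keep])
    return burned, burned > 0, n_dropped


# ---------------------------------------------------------------------------
# Region maps
# ---------------------------------------------------------------------------


@dataclass
class RegionMap:
    """Assignment of grid cells to named analysis regions.

    ``labels`` holds one string per cell ('' = unassigned); ``excluded``
    marks cells that never enter association statistics (e.g. cells in
    countries removed from the analysis).
    """

    grid: Grid
    labels: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape must match grid")
        if self.excluded is None:
            self.excluded = np.zeros(self.grid.shape, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)

    @property
    def regions(self) -> list[str]:
        return sorted({r for r in self.labels.ravel() if r})

    @classmethod
    def quadrants(
        cls,
        grid: Grid,
        lat_split: float = 52.0,
        lon_split: float = 15.0,
        names: tuple[str, str, str, str] = ("Northern", "Southern", "Eastern", "Western"),
    ) -> "RegionMap":
        """Built-in four-region split of the domain.

        Cells north of ``lat_split`` are Northern; below it, cells east of
        ``lon_split`` are Eastern, and the western side is split at its
        mid-latitude into Western (upper) and Southern (lower).  A schematic
        stand-in for country-based European regions, adequate for synthetic
        experiments; real analyses should supply a region table.
        """
        north, south, east, west = names
        lat2d = np.broadcast_to(grid.lat[:, None], grid.shape)
        lon2d = np.broadcast_to(grid.lon[None, :], grid.shape)
        mid = (lat_split + float(grid.lat[0])) / 2
        lab = np.empty(grid.shape, dtype=object)
        lab[:] = west
        lab[lat2d >= lat_split] = north
        lab[(lat2d < lat_split) & (lon2d >= lon_split)] = east
        lab[(lat2d < mid) & (lon2d < lon_split)] = south
        return cls(grid=grid, labels=lab)

    @classmethod
    def from_table(cls, path, grid: Grid) -> "RegionMap":
        """Load a delimited table with columns lat, lon, region."""
        df = pd.read_csv(path)
        lab = np.empty(grid.shape, dtype=object)
        lab[:] = ""
        ilat, ilon, inside = grid.locate(df["lat"].to_numpy(), df["lon"].to_numpy())
        for i, row in enumerate(df.itertuples(index=False)):
            if inside[i]:
                lab[ilat[i], ilon[i]] = row.region
        return cls(grid=grid, labels=lab)
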