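"""Gridded sea-temperature data model: climatology rasters, depth-resolved
monthly series, and the World Ocean Atlas standard depth bands.

Two product types are supported:

* :class:`TemperatureClimatology` — a pair of co-registered 2-D fields of
  long-term mean sea surface temperature (SST) and sea bottom temperature
  (SBT), in the style of the Bio-ORACLE marine layers.
* :class:`DepthResolvedSeries` — a 4-D (month-year, depth band, lat, lon)
  temperature product on WOA standard depth bands from 0 to 2,000 m, in the
  style of the IAP gridded ocean-temperature analysis.

Missing values (land, or no data at depth) are represented as NaN in memory
and as a ``_FillValue`` on disk.  All files are NetCDF with CF-style
coordinate variables, read and written through :mod:`xarray`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import xarray as xr

__all__ = [
    "DepthBandScheme",
    "WOA_SCHEME",
    "depth_band_index",
    "TemperatureClimatology",
    "DepthResolvedSeries",
    "load_climatology",
    "load_depth_series",
    "GridFormatError",
    "RegistrationError",
]

_NC_ENGINE = "scipy"  # NetCDF3 classic; portable, text-tool friendly
_FILL = -9999.0


class GridFormatError(ValueError):
    """A gridded input file does not have the expected structure."""


class RegistrationError(GridFormatError):
    """Two grids that must share a common geometry do not."""


# ---------------------------------------------------------------------------
# Depth bands
# ---------------------------------------------------------------------------

#: (upper bound in metres, band width in metres) runs defining the WOA-style
#: vertical discretisation: 10 m bands to 50 m, 25 m to 200 m, 50 m to 300 m,
#: 100 m to 1,500 m, 250 m to 2,000 m -> 27 bands in total.
_WOA_WIDTH_RUNS: tuple[tuple[float, float], ...] = (
    (50.0, 10.0),
    (200.0, 25.0),
    (300.0, 50.0),
    (1500.0, 100.0),
    (2000.0, 250.0),
)


def _woa_edges() -> np.ndarray:
    edges = [0.0]
    for upper, width in _WOA_WIDTH_RUNS:
        while edges[-1] < upper:
            edges.append(edges[-1] + width)
    return np.asarray(edges)


@dataclass(frozen=True)
class DepthBandScheme:
    """An ordered, contiguous set of depth bands ``[edge_i, edge_{i+1})``.

    Bands are half-open on the lower side; the single closure is at the
    scheme floor, so a depth exactly equal to the deepest edge maps to the
    deepest band.
    """

    band_edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.band_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise GridFormatError("band_edges must be a 1-D array of >= 2 depths")
        if not np.all(np.diff(edges) > 0):
            raise GridFormatError("band_edges must be strictly increasing")
        object.__setattr__(self, "band_edges", edges)

    @property
    def n_bands(self) -> int:
        return self.band_edges.size - 1

    @property
    def floor(self) -> float:
        return float(self.band_edges[-1])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.band_edges[:-1] + self.band_edges[1:])

    def band_indices(self, depths_m: np.ndarray) -> np.ndarray:
        """Vectorised band lookup; -1 marks depths below the scheme floor.

        Negative depths are a contract violation (they should have been
        normalised to 0 upstream) and raise.
        """
        d = np.asarray(depths_m, dtype=float)
        if np.any(d[np.isfinite(d)] < 0):
            raise ValueError("negative depth passed to band lookup; normalize first")
        idx = np.searchsorted(self.band_edges, d, side="right") - 1
        idx = np.where(d == self.floor, self.n_bands - 1, idx)  # closed floor
        idx = np.where(d > self.floor, -1, idx)
        idx = np.where(np.isnan(d), -1, idx)
        return idx.astype(np.int64)


#: The 27-band World Ocean Atlas scheme used by the depth-resolved product.
WOA_SCHEME = DepthBandScheme(_woa_edges())


def depth_band_index(depth_m: float, scheme: DepthBandScheme = WOA_SCHEME) -> int | None:
    """Return the band index containing ``depth_m``, or None below the floor.

    ``depth_m`` must be >= 0; the deepest edge (2,000 m for the WOA scheme)
    maps to the deepest band, anything deeper to None.
    """
    idx = int(scheme.band_indices(np.asarray([depth_m]))[0])
    return None if idx < 0 else idx


# ---------------------------------------------------------------------------
# Cell geometry helpers
# ---------------------------------------------------------------------------


def _cell_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open cell assignment [edge_i, edge_{i+1}); the final edge is
    closed.  Out-of-bounds values map to -1."""
    v = np.asarray(values, dtype=float)
    idx = np.searchsorted(edges, v, side="right") - 1
    idx = np.where(v == edges[-1], edges.size - 2, idx)
    out = (v < edges[0]) | (v > edges[-1]) | ~np.isfinite(v)
    return np.where(out, -1, idx).astype(np.int64)


def _edges_from_centers(centers: np.ndarray, what: str) -> np.ndarray:
    c = np.asarray(centers, dtype=float)
    if c.size < 2:
        raise GridFormatError(f"{what}: need at least 2 grid cells")
    step = np.diff(c)
    if not np.allclose(step, step[0], rtol=1e-6, atol=1e-9):
        raise GridFormatError(f"{what}: coordinate spacing is not uniform")
    half = step[0] / 2.0
    return np.concatenate([c - half, [c[-1] + half]])


# ---------------------------------------------------------------------------
# Climatology
# ---------------------------------------------------------------------------


@dataclass
class TemperatureClimatology:
    """Co-registered long-term mean SST and SBT fields (°C), NaN over land."""

    sst: np.ndarray
    sbt: np.ndarray
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sst = np.asarray(self.sst, dtype=float)
        self.sbt = np.asarray(self.sbt, dtype=float)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        if self.sst.shape != self.sbt.shape:
            raise RegistrationError("sst and sbt grids have different shapes")
        if self.sst.shape != (self.lat_edges.size - 1, self.lon_edges.size - 1):
            raise RegistrationError("grid shape inconsistent with cell edges")
        for name, e in (("lat_edges", self.lat_edges), ("lon_edges", self.lon_edges)):
            if not np.all(np.diff(e) > 0):
                raise GridFormatError(f"{name} must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sst.shape

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def cell_indices(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices for point coordinates; -1 when outside the grid."""
        return _cell_indices(lat, self.lat_edges), _cell_indices(lon, self.lon_edges)

    def to_netcdf(self, path: str | Path) -> None:
        ds = xr.Dataset(
            {
                "sst": (("lat", "lon"), np.where(np.isnan(self.sst), _FILL, self.sst)),
                "sbt": (("lat", "lon"), np.where(np.isnan(self.sbt), _FILL, self.sbt)),
            },
            coords={"lat": self.lat_centers, "lon": self.lon_centers},
            attrs={"Conventions": "CF-1.6", **self.attrs},
        )
        for v in ("sst", "sbt"):
            ds[v].attrs.update(units="degree_Celsius", _FillValue=_FILL)
        ds["lat"].attrs.update(units="degrees_north")
        ds["lon"].attrs.update(units="degrees_east")
        ds.to_netcdf(path, engine=_NC_ENGINE)


def load_climatology(
    paths: str | Path | Sequence[str | Path],
    sst_var: str = "sst",
    sbt_var: str = "sbt",
) -> TemperatureClimatology:
    """Read SST/SBT climatology layers from one NetCDF file (both variables)
    or a (sst_path, sbt_path) pair, checking co-registration."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    datasets = [xr.open_dataset(p, engine=_NC_ENGINE) for p in paths]
    try:
        if len(datasets) == 1:
            src_sst = src_sbt = datasets[0]
        elif len(datasets) == 2:
            src_sst, src_sbt = datasets
        else:
            raise GridFormatError("expected one combined file or an (sst, sbt) pair")
        for ds, var in ((src_sst, sst_var), (src_sbt, sbt_var)):
            if var not in ds:
                raise GridFormatError(f"variable {var!r} not found in {list(ds.data_vars)}")
        sst_da, sbt_da = src_sst[sst_var], src_sbt[sbt_var]
        if sst_da.shape != sbt_da.shape or not (
            np.allclose(src_sst["lat"], src_sbt["lat"])
            and np.allclose(src_sst["lon"], src_sbt["lon"])
        ):
            raise RegistrationError("sst and sbt layers are not co-registered")
        lat_edges = _edges_from_centers(src_sst["lat"].values, "lat")
        lon_edges = _edges_from_centers(src_sst["lon"].values, "lon")
        sst = _decode_fill(sst_da)
        sbt = _decode_fill(sbt_da)
    finally:
        for ds in datasets:
            ds.close()
    return TemperatureClimatology(sst, sbt, lat_edges, lon_edges)


def _decode_fill(da: xr.DataArray) -> np.ndarray:
    arr = np.asarray(da.values, dtype=float)
    fill = da.attrs.get("_FillValue", da.attrs.get("missing_value"))
    if fill is not None:
        arr = np.where(arr == float(fill), np.nan, arr)
    return arr


# ---------------------------------------------------------------------------
# Depth-resolved monthly series
# ---------------------------------------------------------------------------


@dataclass
class DepthResolvedSeries:
    """Monthly temperature at depth: ``temp[time, band, lat, lon]`` (°C).

    ``time`` runs in calendar order from January of ``year_start`` to
    December of ``year_end``.  ``deepest_wet_band[i, j]`` is the index of the
    deepest band with data at cell (i, j), or -1 for land columns; it is
    derived from (and kept consistent with) the NaN mask.
    """

    temp: np.ndarray
    year_start: int
    year_end: int
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    scheme: DepthBandScheme = WOA_SCHEME
    deepest_wet_band: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temp = np.asarray(self.temp, dtype=float)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        if self.temp.ndim != 4:
            raise GridFormatError("temp must be 4-D (time, band, lat, lon)")
        n_time, n_band, n_lat, n_lon = self.temp.shape
        if n_band != self.scheme.n_bands:
            raise GridFormatError(
                f"temp has {n_band} depth levels, scheme has {self.scheme.n_bands} bands"
            )
        if self.year_end < self.year_start:
            raise GridFormatError("year_end precedes year_start")
        if n_time != 12 * (self.year_end - self.year_start + 1):
            raise GridFormatError("time length inconsistent with year coverage")
        if (n_lat, n_lon) != (self.lat_edges.size - 1, self.lon_edges.size - 1):
            raise RegistrationError("grid shape inconsistent with cell edges")
        if self.deepest_wet_band is None:
            wet = np.isfinite(self.temp).any(axis=0)  # (band, lat, lon)
            any_wet = wet.any(axis=0)
            deepest = np.where(any_wet, wet.shape[0] - 1 - np.argmax(wet[::-1], axis=0), -1)
            self.deepest_wet_band = deepest.astype(np.int64)

    @property
    def n_months(self) -> int:
        return self.temp.shape[0]

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def time_indices(self, year: np.ndarray, month: np.ndarray) -> np.ndarray:
        """Flat month-year index into the time axis; -1 outside coverage or
        for missing dates (NaN)."""
        y = np.asarray(year, dtype=float)
        m = np.asarray(month, dtype=float)
        ok = np.isfinite(y) & np.isfinite(m) & (y >= self.year_start) & (y <= self.year_end)
        idx = np.where(ok, (y - self.year_start) * 12 + (m - 1), -1)
        return idx.astype(np.int64)

    def cell_indices(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return _cell_indices(lat, self.lat_edges), _cell_indices(lon, self.lon_edges)

    def to_netcdf(self, path: str | Path) -> None:
        n_years = self.year_end - self.year_start + 1
        years = np.repeat(np.arange(self.year_start, self.year_end + 1), 12)
        months = np.tile(np.arange(1, 13), n_years)
        ds = xr.Dataset(
            {
                "temp": (
                    ("time", "depth", "lat", "lon"),
                    np.where(np.isnan(self.temp), _FILL, self.temp),
                ),
                "year": ("time", years.astype(np.int32)),
                "month": ("time", months.astype(np.int32)),
            },
            coords={
                "time": years * 100 + months,  # YYYYMM
                "depth": self.scheme.midpoints,
                "lat": self.lat_centers,
                "lon": self.lon_centers,
            },
            attrs={"Conventions": "CF-1.6"},
        )
        ds["temp"].attrs.update(units="degree_Celsius", _FillValue=_FILL)
        ds["depth"].attrs.update(units="m", positive="down")
        ds.to_netcdf(path, engine=_NC_ENGINE)


def load_depth_series(
    path: str | Path,
    temp_var: str = "temp",
    scheme: DepthBandScheme = WOA_SCHEME,
) -> DepthResolvedSeries:
    """Read a (time, depth, lat, lon) NetCDF product onto a band scheme.

    The file's depth coordinate must equal the scheme's band midpoints; a
    mismatch is a format error rather than a silent reinterpretation.
    """
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        if temp_var not in ds:
            raise GridFormatError(f"variable {temp_var!r} not found in {list(ds.data_vars)}")
        da = ds[temp_var]
        if da.ndim != 4:
            raise GridFormatError("temperature variable must be 4-D (time, depth, lat, lon)")
        depth = np.asarray(ds["depth"].values, dtype=float)
        if depth.size != scheme.n_bands or not np.allclose(depth, scheme.midpoints):
            raise GridFormatError(
                "depth coordinate does not match the expected band scheme midpoints"
            )
        tcode = np.asarray(ds["time"].values).astype(np.int64)
        years, months = tcode // 100, tcode % 100
        temp = _decode_fill(da)
        lat_edges = _edges_from_centers(ds["lat"].values, "lat")
        lon_edges = _edges_from_centers(ds["lon"].values, "lon")
    return DepthResolvedSeries(
        temp=temp,
        year_start=int(years.min()),
        year_end=int(years.max()),
        lat_edges=lat_edges,
        lon_edges=lon_edges,
        scheme=scheme,
    )
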