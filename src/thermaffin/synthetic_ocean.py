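"""Synthetic oceans, species occurrences, and experimental thermal limits
with known ground truth.

The generator stands in for the three external data sources of the real
workflow — a global occurrence database (OBIS-style records with their
characteristic defects), a surface/bottom temperature climatology
(Bio-ORACLE style), and a depth- and month-resolved gridded product
(IAP style) — so that every stage of the pipeline can be tested offline
against known parameters.

The synthetic world is deliberately simple: sea surface temperature falls
linearly with absolute latitude plus cell-level noise, temperature decreases
by a fixed step per depth band, a sinusoidal seasonal cycle and interannual
(per-year, per-cell) noise drive the monthly series, and land is laid down
as contiguous rectangular blocks so that coarse-cell "mostly land" matching
failures occur just as they do against real coastlines.  Species place
occurrences preferentially in cells whose temperature is close to their
preferred temperature (Gaussian kernel weighting on the group's "best"
temperature measure), and record-level defects — missing or negative
depths, missing dates, years outside product coverage — are injected after
placement so that the spatial truth stays intact.

Every product is deterministic for a fixed seed, and the generated truth
(per-species realised affinity, thermal-limit generating coefficients) is
stored alongside the fixtures for parameter-recovery tests; the pipeline
itself never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid_data import (
    WOA_SCHEME,
    DepthBandScheme,
    DepthResolvedSeries,
    TemperatureClimatology,
)
from .grid_match import GROUP_KEYS, SBT_GROUPS

__all__ = [
    "WorldConfig",
    "SpeciesParams",
    "SyntheticWorld",
    "SyntheticWorldTruth",
    "make_world",
    "make_climatology",
    "make_depth_series",
    "sample_occurrences",
    "make_thermal_limits",
    "default_species_params",
    "truth_to_attributes",
    "write_fixtures",
    "WorldConfigError",
]


class WorldConfigError(ValueError):
    """Invalid synthetic-world configuration."""


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic ocean.

    Defaults emulate a coarse global ocean: SST of 28 °C at the equator
    falling by 0.45 °C per degree of latitude, ~0.8 °C cooling per depth
    band, a 3 °C seasonal half-amplitude, and 30% land cover.
    """

    lat_range: tuple[float, float] = (-80.0, 80.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    n_lat: int = 60
    n_lon: int = 60
    land_fraction: float = 0.3
    sst_gradient: float = -0.45  # °C per degree |latitude|
    sst_equator: float = 28.0
    depth_decay: float = 0.8  # °C per depth band, >= 0
    seasonal_amplitude: float = 3.0
    year_range: tuple[int, int] = (2000, 2009)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lat < 2 or self.n_lon < 2:
            raise WorldConfigError("n_lat and n_lon must both be >= 2")
        if not 0 <= self.land_fraction < 1:
            raise WorldConfigError("land_fraction must be in [0, 1)")
        if self.year_range[1] < self.year_range[0]:
            raise WorldConfigError("year_range is empty")
        if self.depth_decay < 0:
            raise WorldConfigError("depth_decay must be >= 0 (temperature cannot rise with depth)")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0:
            raise WorldConfigError("noise_sd and seasonal_amplitude must be >= 0")


@dataclass(frozen=True)
class SpeciesParams:
    """Occurrence-generating parameters for one synthetic species."""

    species_id: str
    n: int = 200
    preferred_temp: float = 15.0
    niche_sd: float = 2.0  # Gaussian kernel width in °C; 0 -> best cell only
    group_key: str = "fish:pelagic"
    depth_max: float = 0.0  # sampling depths uniform in [0, depth_max]
    missing_depth_rate: float = 0.45
    negative_depth_rate: float = 0.01
    missing_date_rate: float = 0.04
    out_of_range_date_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.group_key not in GROUP_KEYS:
            raise WorldConfigError(f"unknown group_key {self.group_key!r}")
        for r in (
            self.missing_depth_rate,
            self.negative_depth_rate,
            self.missing_date_rate,
            self.out_of_range_date_rate,
        ):
            if not 0 <= r <= 1:
                raise WorldConfigError("defect rates must be in [0, 1]")


@dataclass
class SyntheticWorldTruth:
    """Generator ground truth; consumed only by tests, never by the pipeline."""

    species: pd.DataFrame  # species_id, group_key, preferred_temp, niche_sd, true_affinity, n
    tmax_coeffs: tuple[float, float, float] | None = None
    tmax_noise_sd: float | None = None


@dataclass
class SyntheticWorld:
    """A co-registered synthetic climatology and depth-resolved series."""

    config: WorldConfig
    climatology: TemperatureClimatology
    depth_series: DepthResolvedSeries
    land_mask: np.ndarray  # True over land
    bathymetry: np.ndarray  # deepest wet band index, -1 over land


# ---------------------------------------------------------------------------
# Base fields (shared by both temperature products)
# ---------------------------------------------------------------------------


def _rng(config: WorldConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def _edges(config: WorldConfig) -> tuple[np.ndarray, np.ndarray]:
    lat = np.linspace(config.lat_range[0], config.lat_range[1], config.n_lat + 1)
    lon = np.linspace(config.lon_range[0], config.lon_range[1], config.n_lon + 1)
    return lat, lon


def _land_mask(config: WorldConfig) -> np.ndarray:
    """Contiguous rectangular land blocks covering ~land_fraction of cells."""
    mask = np.zeros((config.n_lat, config.n_lon), dtype=bool)
    if config.land_fraction == 0:
        return mask
    rng = _rng(config, 1)
    target = config.land_fraction * mask.size
    guard = 0
    while mask.sum() < target and guard < 10_000:
        h = rng.integers(1, max(2, config.n_lat // 3))
        w = rng.integers(1, max(2, config.n_lon // 3))
        i = rng.integers(0, config.n_lat - h + 1)
        j = rng.integers(0, config.n_lon - w + 1)
        mask[i : i + h, j : j + w] = True
        guard += 1
    return mask


def _bathymetry(config: WorldConfig, land: np.ndarray, scheme: DepthBandScheme) -> np.ndarray:
    """Deepest wet band per cell: half open ocean (deepest band), half a
    uniformly random shallower floor; -1 over land."""
    rng = _rng(config, 2)
    deep = scheme.n_bands - 1
    bathy = np.where(
        rng.random((config.n_lat, config.n_lon)) < 0.5,
        deep,
        rng.integers(0, scheme.n_bands, size=(config.n_lat, config.n_lon)),
    )
    return np.where(land, -1, bathy).astype(np.int64)


def _base_sst(config: WorldConfig) -> np.ndarray:
    lat_edges, _ = _edges(config)
    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    return (config.sst_equator + config.sst_gradient * np.abs(lat_c))[:, None] * np.ones(
        (1, config.n_lon)
    )


def make_climatology(
    config: WorldConfig, scheme: DepthBandScheme = WOA_SCHEME
) -> TemperatureClimatology:
    """Long-term mean SST/SBT fields: SST = sst_equator +
    sst_gradient * |lat| + Normal(0, noise_sd) per cell; SBT = SST minus
    depth_decay per band down to the cell floor, hence SBT <= SST by
    construction.  Land cells are missing in both layers."""
    lat_edges, lon_edges = _edges(config)
    land = _land_mask(config)
    bathy = _bathymetry(config, land, scheme)
    noise = _rng(config, 3).normal(0.0, config.noise_sd, size=(config.n_lat, config.n_lon))
    sst = _base_sst(config) + noise
    sbt = sst - config.depth_decay * np.maximum(bathy, 0)
    sst = np.where(land, np.nan, sst)
    sbt = np.where(land, np.nan, sbt)
    return TemperatureClimatology(sst, sbt, lat_edges, lon_edges)


def make_depth_series(
    config: WorldConfig, scheme: DepthBandScheme = WOA_SCHEME
) -> DepthResolvedSeries:
    """Monthly temperature at depth on the same world as the climatology.

    temp[month, band, cell] = base SST + seasonal cycle (cosine peaking in
    July, half-amplitude ``seasonal_amplitude``) + interannual noise (one
    Normal(0, noise_sd) draw per year and cell) - depth_decay * band.
    Temperature is therefore non-increasing with band at every wet cell,
    and months within a year are identical when the seasonal amplitude is
    zero.  Bands below the cell floor, and whole land columns, are missing.
    """
    lat_edges, lon_edges = _edges(config)
    land = _land_mask(config)
    bathy = _bathymetry(config, land, scheme)
    y0, y1 = config.year_range
    n_years = y1 - y0 + 1
    months = np.arange(1, 13)
    seasonal = config.seasonal_amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)
    annual_noise = _rng(config, 4).normal(
        0.0, config.noise_sd, size=(n_years, config.n_lat, config.n_lon)
    )
    base = _base_sst(config)

    surface = (
        base[None, None]
        + seasonal[None, :, None, None]
        + annual_noise[:, None]
    ).reshape(12 * n_years, config.n_lat, config.n_lon)
    bands = np.arange(scheme.n_bands)
    temp = surface[:, None] - config.depth_decay * bands[None, :, None, None]

    wet = bands[None, :, None, None] <= np.maximum(bathy, 0)[None, None]
    wet = wet & ~land[None, None]
    temp = np.where(wet, temp, np.nan)
    return DepthResolvedSeries(
        temp=temp,
        year_start=y0,
        year_end=y1,
        lat_edges=lat_edges,
        lon_edges=lon_edges,
        scheme=scheme,
    )


def make_world(config: WorldConfig, scheme: DepthBandScheme = WOA_SCHEME) -> SyntheticWorld:
    """Build the co-registered climatology + depth series pair."""
    land = _land_mask(config)
    return SyntheticWorld(
        config=config,
        climatology=make_climatology(config, scheme),
        depth_series=make_depth_series(config, scheme),
        land_mask=land,
        bathymetry=_bathymetry(config, land, scheme),
    )


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


def default_species_params(
    n_species: int,
    seed: int,
    n_per_species: int = 200,
    preferred_range: tuple[float, float] = (0.0, 28.0),
    niche_sd: float = 2.0,
    group_keys: tuple[str, ...] = ("fish:pelagic",),
    **rates,
) -> list[SpeciesParams]:
    """A convenience batch of species parameter sets with preferred
    temperatures uniform over ``preferred_range`` and groups cycling
    through ``group_keys``."""
    rng = np.random.default_rng([seed % (2**31), 10])
    prefs = rng.uniform(*preferred_range, size=n_species)
    return [
        SpeciesParams(
            species_id=f"sp{i:04d}",
            n=n_per_species,
            preferred_temp=float(prefs[i]),
            niche_sd=niche_sd,
            group_key=group_keys[i % len(group_keys)],
            **rates,
        )
        for i in range(n_species)
    ]


def sample_occurrences(
    world: SyntheticWorld,
    species_params: list[SpeciesParams],
    seed: int,
) -> tuple[pd.DataFrame, SyntheticWorldTruth]:
    """Place occurrence records in temperature-preferred wet cells, then
    inject record-level defects.

    Placement weight for a cell is a Gaussian kernel in the group's "best"
    climatology temperature around the species' preferred temperature; the
    species' *true affinity* recorded in the truth table is the
    weight-averaged temperature of its placement distribution — the
    expected value of a matched occurrence temperature — which is what the
    downstream affinity estimate converges to.

    Defects (missing depth, negative depth, missing date, out-of-coverage
    year) are applied after placement at the per-species configured rates.

    Returns an OBIS-style table (``species_id, decimalLatitude,
    decimalLongitude, depth_m, eventDate``; missing depth as NaN, missing
    date as an empty string) and the ground-truth table.
    """
    clim = world.climatology
    wet = ~np.isnan(clim.sst)
    if not wet.any():
        raise WorldConfigError("cannot place occurrences: the world is all land")
    wet_i, wet_j = np.nonzero(wet)
    lat_c, lon_c = clim.lat_centers, clim.lon_centers
    dlat = np.diff(clim.lat_edges)
    dlon = np.diff(clim.lon_edges)
    y0, y1 = world.config.year_range

    rng = np.random.default_rng([seed % (2**31), 20])
    frames = []
    truth_rows = []
    for sp in species_params:
        temps = (clim.sbt if sp.group_key in SBT_GROUPS else clim.sst)[wet_i, wet_j]
        usable = np.isfinite(temps)
        ti, tj, tv = wet_i[usable], wet_j[usable], temps[usable]
        if sp.niche_sd > 0:
            logw = -0.5 * ((tv - sp.preferred_temp) / sp.niche_sd) ** 2
            w = np.exp(logw - logw.max())
        else:  # degenerate niche: all mass on the best cell(s)
            d = np.abs(tv - sp.preferred_temp)
            w = (d == d.min()).astype(float)
        p = w / w.sum()
        true_affinity = float(np.sum(p * tv))
        pick = rng.choice(tv.size, size=sp.n, p=p)
        ci, cj = ti[pick], tj[pick]

        lat = lat_c[ci] + (rng.random(sp.n) - 0.5) * dlat[ci] * 0.999
        lon = lon_c[cj] + (rng.random(sp.n) - 0.5) * dlon[cj] * 0.999
        depth = (
            rng.uniform(0.0, sp.depth_max, size=sp.n)
            if sp.depth_max > 0
            else np.zeros(sp.n)
        )
        year = rng.integers(y0, y1 + 1, size=sp.n)
        month = rng.integers(1, 13, size=sp.n)

        # defect injection, after placement
        u = rng.random((4, sp.n))
        neg = u[0] < sp.negative_depth_rate
        depth = np.where(neg, np.where(depth > 0, -depth, -25.0), depth)
        depth = np.where(u[1] < sp.missing_depth_rate, np.nan, depth)
        year = np.where(
            u[2] < sp.out_of_range_date_rate,
            y0 - 1 - rng.integers(0, 30, size=sp.n),
            year,
        )
        dates = np.array(
            [f"{y:04d}-{m:02d}-15" for y, m in zip(year, month)], dtype=object
        )
        dates[u[3] < sp.missing_date_rate] = ""

        frames.append(
            pd.DataFrame(
                {
                    "species_id": sp.species_id,
                    "decimalLatitude": lat,
                    "decimalLongitude": lon,
                    "depth_m": depth,
                    "eventDate": dates,
                }
            )
        )
        truth_rows.append(
            {
                "species_id": sp.species_id,
                "group_key": sp.group_key,
                "preferred_temp": sp.preferred_temp,
                "niche_sd": sp.niche_sd,
                "true_affinity": true_affinity,
                "n_records": sp.n,
            }
        )
    occurrences = pd.concat(frames, ignore_index=True)
    truth = SyntheticWorldTruth(species=pd.DataFrame(truth_rows))
    return occurrences, truth


# ---------------------------------------------------------------------------
# Experimental thermal limits
# ---------------------------------------------------------------------------


def make_thermal_limits(
    truth: SyntheticWorldTruth,
    seed: int,
    coeffs: tuple[float, float, float] = (15.0, 1.2, -0.02),
    noise_sd: float = 1.0,
    max_estimates: int = 3,
    sd_range: tuple[float, float] = (0.5, 2.0),
    sd_missing_rate: float = 0.3,
    metric: str = "CTmax",
) -> pd.DataFrame:
    """Generate experimental upper-limit records from the truth table.

    Each species gets 1 to ``max_estimates`` estimates of
    ``Tmax = a + b*x + c*x**2 + Normal(0, noise_sd)`` with x its true
    affinity; each estimate carries an SD drawn from ``sd_range``, missing
    at ``sd_missing_rate``.  The generating coefficients are recorded on the
    truth object for recovery tests.
    """
    a, b, c = coeffs
    rng = np.random.default_rng([seed % (2**31), 30])
    rows = []
    for _, sp in truth.species.iterrows():
        x = sp["true_affinity"]
        expected = a + b * x + c * x * x
        k = int(rng.integers(1, max_estimates + 1)) if max_estimates > 1 else 1
        for _ in range(k):
            value = expected + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            sd = rng.uniform(*sd_range)
            if rng.random() < sd_missing_rate:
                sd = np.nan
            rows.append(
                {
                    "species_id": sp["species_id"],
                    "tmax_c": value,
                    "tmax_sd": sd,
                    "metric": metric,
                }
            )
    truth.tmax_coeffs = (a, b, c)
    truth.tmax_noise_sd = noise_sd
    return pd.DataFrame(rows)


def truth_to_attributes(truth: SyntheticWorldTruth) -> pd.DataFrame:
    """Species attribute table (group / habitat labels) from the truth,
    shaped like the functional-group input the pipeline expects."""
    rows = []
    for _, sp in truth.species.iterrows():
        key = sp["group_key"]
        if key.startswith("fish:"):
            rows.append(
                {"species_id": sp["species_id"], "group": "fish", "habitat": key.split(":", 1)[1]}
            )
        else:
            rows.append({"species_id": sp["species_id"], "group": key, "habitat": ""})
    return pd.DataFrame(rows)


def write_fixtures(
    world: SyntheticWorld,
    occurrences: pd.DataFrame,
    limits: pd.DataFrame,
    attributes: pd.DataFrame,
    truth: SyntheticWorldTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a complete fixture set to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "climatology": outdir / "climatology.nc",
        "depth_series": outdir / "depth_series.nc",
        "occurrences": outdir / "occurrences.csv",
        "limits": outdir / "limits.csv",
        "groups": outdir / "groups.csv",
        "truth": outdir / "truth.csv",
    }
    world.climatology.to_netcdf(paths["climatology"])
    world.depth_series.to_netcdf(paths["depth_series"])
    occurrences.to_csv(paths["occurrences"], index=False, float_format="%.10g")
    limits.to_csv(paths["limits"], index=False, float_format="%.10g")
    attributes.to_csv(paths["groups"], index=False)
    truth.species.to_csv(paths["truth"], index=False, float_format="%.10g")
    return paths
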