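"""Independent brute-force oracles used by the tests.

Everything here is written from the stated rules directly — linear scans,
explicit enumeration, textbook formulas — deliberately sharing no code with
the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_woa_edges() -> list[float]:
    """Depth-band edges from the stated widths: 10 m bands to 50 m, 25 m to
    200 m, 50 m to 300 m, 100 m to 1,500 m, 250 m to 2,000 m."""
    edges = [0.0]
    for stop, width in [(50, 10), (200, 25), (300, 50), (1500, 100), (2000, 250)]:
        while edges[-1] < stop:
            edges.append(edges[-1] + width)
    return edges


def band_index_scan(depth: float, edges: list[float]):
    """Linear scan for the half-open band [lo, hi) containing depth; the
    deepest edge is closed; below the floor -> None."""
    if depth == edges[-1]:
        return len(edges) - 2
    for i in range(len(edges) - 1):
        if edges[i] <= depth < edges[i + 1]:
            return i
    return None


def cell_scan(value: float, edges: np.ndarray):
    """Half-open cell lookup by linear scan; final edge closed; outside -> None."""
    if value == edges[-1]:
        return len(edges) - 2
    for i in range(len(edges) - 1):
        if edges[i] <= value < edges[i + 1]:
            return i
    return None


def climatology_match_scan(record, clim):
    """Brute-force climatology match for one record dict with keys lat/lon.

    Returns (sst, sbt, reason) with NaN for missing and '' for matched.
    """
    i = cell_scan(record["lat"], clim.lat_edges)
    j = cell_scan(record["lon"], clim.lon_edges)
    if i is None or j is None:
        return (math.nan, math.nan, "outside_grid")
    sst, sbt = float(clim.sst[i, j]), float(clim.sbt[i, j])
    if math.isnan(sst) and math.isnan(sbt):
        return (math.nan, math.nan, "land_cell")
    return (sst, sbt, "")


def depth_series_match_scan(record, series, edges):
    """Brute-force depth-series match for one record dict with keys
    lat/lon/depth_m/event_month/event_year.

    Returns (sst, sbt, t_at_depth, reason, tdepth_reason).
    """
    nan = math.nan
    month, year = record["event_month"], record["event_year"]
    if month is None or year is None:
        return (nan, nan, nan, "missing_date", "missing_date")
    if not (series.year_start <= year <= series.year_end):
        return (nan, nan, nan, "year_out_of_range", "year_out_of_range")
    i = cell_scan(record["lat"], series.lat_edges)
    j = cell_scan(record["lon"], series.lon_edges)
    if i is None or j is None:
        return (nan, nan, nan, "outside_grid", "outside_grid")
    t = (year - series.year_start) * 12 + (month - 1)
    # deepest wet band by scanning from the bottom
    deepest = None
    for k in range(len(edges) - 2, -1, -1):
        if np.isfinite(series.temp[:, k, i, j]).any():
            deepest = k
            break
    if deepest is None:
        return (nan, nan, nan, "land_cell", "land_cell")
    sst = float(series.temp[t, 0, i, j])
    sbt = float(series.temp[t, deepest, i, j])
    band = band_index_scan(record["depth_m"], edges)
    if band is None or band > deepest:
        return (sst, sbt, nan, "", "depth_below_cell_floor")
    return (sst, sbt, float(series.temp[t, band, i, j]), "", "")


def quantile_interpolated(values, q: float) -> float:
    """Sort-and-interpolate quantile: h = (n-1) q, linear between order
    statistics — the textbook 'type 7' rule, written out directly."""
    v = sorted(values)
    n = len(v)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def mad_scaled(values, scale: float = 1.4826) -> float:
    v = list(values)
    med = quantile_interpolated(v, 0.5)
    return scale * quantile_interpolated([abs(x - med) for x in v], 0.5)


def pearson_by_formula(x, y) -> float:
    """Covariance / (sd_x sd_y), written out directly."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / (n - 1))
    return cov / (sx * sy)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares by solving X'X beta = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)
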