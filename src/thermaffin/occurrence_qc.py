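"""Occurrence ingest and quality control.

Reads Darwin-Core-flavoured occurrence CSVs (species identifier, decimal
latitude/longitude, depth in metres, event date) and applies the record-level
normalisation rules used throughout the pipeline:

* coordinates — latitudes outside [-90, 90] are rejected (they cannot be
  wrapped); longitudes are wrapped into [-180, 180) by modular arithmetic;
* depth — negative and missing depths are set to 0 m (sea surface), because
  negative values in aggregated occurrence data can mean either a flipped
  sign convention, an intertidal record, or a missing value;
* dates — parsed into (month, year); missing or unparseable dates are kept
  as missing, leaving the record usable for climatology matching but not for
  month-year-resolved matching.

Every rejected row is logged with exactly one reason code, so that
``rows_in == records_out + rejected`` holds for every file.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COLUMNS",
    "read_occurrences",
    "normalize_depth",
    "normalize_longitude",
    "parse_event_date",
    "OccurrenceFormatError",
]

#: Default CSV header -> canonical field mapping (Darwin Core style).
DEFAULT_COLUMNS = {
    "species_id": "species_id",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
    "depth": "depth_m",
    "date": "eventDate",
}

#: Canonical columns of a normalized occurrence table.
RECORD_COLUMNS = ["species_id", "lat", "lon", "depth_m", "event_month", "event_year"]


class OccurrenceFormatError(ValueError):
    """The occurrence CSV is missing a required column."""


def normalize_depth(depth_raw):
    """Map raw depth to non-negative metres: negative or missing -> 0.

    Accepts scalars or arrays; NaN counts as missing.  Idempotent.
    """
    arr = np.asarray(depth_raw, dtype=float)
    out = np.where(np.isnan(arr) | (arr < 0), 0.0, arr)
    return float(out) if np.isscalar(depth_raw) or arr.ndim == 0 else out


def normalize_longitude(lon):
    """Wrap longitudes into [-180, 180)."""
    arr = np.asarray(lon, dtype=float)
    out = (arr + 180.0) % 360.0 - 180.0
    return float(out) if np.isscalar(lon) or arr.ndim == 0 else out


_DATE_RE = re.compile(
    r"^\s*(\d{4})(?:[-/](\d{1,2})(?:[-/](\d{1,2}))?)?(?:[T ].*)?\s*$"
)


def parse_event_date(raw_date) -> tuple[int | None, int | None]:
    """Parse an event date into ``(month, year)``.

    Accepts ISO-8601 full dates (``2003-07-15``), year-month (``2003-07``)
    and bare years (``2003``); a bare year yields ``(None, year)``.  Anything
    else — including an absent value — yields ``(None, None)``.  Missing is a
    value here, not an error: dateless records stay in the table and are
    simply ineligible for month-year-resolved temperature matching.
    """
    if raw_date is None or (isinstance(raw_date, float) and np.isnan(raw_date)):
        return (None, None)
    m = _DATE_RE.match(str(raw_date))
    if not m:
        return (None, None)
    year = int(m.group(1))
    month = int(m.group(2)) if m.group(2) else None
    if month is not None and not 1 <= month <= 12:
        return (None, None)
    if m.group(3) is not None and not 1 <= int(m.group(3)) <= 31:
        return (None, None)
    return (month, year)


def read_occurrences(
    path: str | Path,
    columns: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and normalise an occurrence CSV.

    Parameters
    ----------
    path
        CSV with at least the species, latitude and longitude columns.
    columns
        Optional override of the header mapping (keys as in
        :data:`DEFAULT_COLUMNS`); unmapped optional columns are treated as
        absent from the file.

    Returns
    -------
    (records, rejects)
        ``records`` has the canonical columns
        ``species_id, lat, lon, depth_m, event_month, event_year`` with
        depth already normalised; ``rejects`` has the original row index,
        the offending raw values and a single ``reason`` code per row
        (``missing_species_id``, ``lat_unparseable``, ``lat_out_of_range``,
        ``lon_unparseable``, ``depth_unparseable``).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("species_id", "lat", "lon"):
        if colmap[key] not in raw.columns:
            raise OccurrenceFormatError(
                f"required column {colmap[key]!r} (for {key}) not found in {path}"
            )

    species = raw[colmap["species_id"]].str.strip()
    lat = pd.to_numeric(raw[colmap["lat"]], errors="coerce")
    lon = pd.to_numeric(raw[colmap["lon"]], errors="coerce")
    has_depth = colmap["depth"] in raw.columns
    has_date = colmap["date"] in raw.columns
    depth_str = raw[colmap["depth"]].str.strip() if has_depth else pd.Series("", index=raw.index)
    depth_num = pd.to_numeric(depth_str.mask(depth_str == ""), errors="coerce")

    # one reason per row, first matching rule wins
    reason = pd.Series("", index=raw.index, dtype=object)
    reason[(reason == "") & (species == "")] = "missing_species_id"
    reason[(reason == "") & lat.isna()] = "lat_unparseable"
    reason[(reason == "") & (lat.abs() > 90)] = "lat_out_of_range"
    reason[(reason == "") & lon.isna()] = "lon_unparseable"
    # non-numeric, non-empty depth strings are data errors, not missing depths
    reason[(reason == "") & (depth_str != "") & depth_num.isna()] = "depth_unparseable"

    ok = reason == ""
    rejects = raw.loc[~ok].copy()
    rejects.insert(0, "row", rejects.index)
    rejects["reason"] = reason[~ok].values

    dates = raw[colmap["date"]] if has_date else pd.Series("", index=raw.index)
    parsed = [parse_event_date(d if str(d).strip() else None) for d in dates[ok]]
    months = [p[0] for p in parsed]
    years = [p[1] for p in parsed]

    records = pd.DataFrame(
        {
            "species_id": species[ok].values,
            "lat": lat[ok].values,
            "lon": normalize_longitude(lon[ok].values),
            "depth_m": normalize_depth(depth_num[ok].values),
            "event_month": pd.array(months, dtype="Int64"),
            "event_year": pd.array(years, dtype="Int64"),
        }
    )
    return records.reset_index(drop=True), rejects.reset_index(drop=True)
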