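"""Match occurrence records to gridded temperatures and account for every
exclusion.

Each record is matched against two products:

* the SST/SBT climatology, by latitude and longitude only;
* the depth-resolved monthly series, by latitude, longitude, month-year and
  sampling depth, yielding three values — SST (surface band), SBT (the
  deepest band with data in the cell, i.e. temperature at 2,000 m in deeper
  seas) and temperature at sampling depth.

A record excluded from one product remains eligible for the other; per-
measure matched counts therefore use different record subsets.  A "best"
temperature is then assigned per record from the species' functional group:
surface temperature for birds, mammals, and pelagic and reef-associated
fish; bottom temperature for benthos, macroalgae, and demersal and
benthopelagic fish.  Water-column nekton have no stated rule and default to
surface temperature (configurable).

Exclusion accounting is conservative by construction: for every temperature
measure, ``n_total == n_matched + sum over reasons of n_excluded``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid_data import DepthResolvedSeries, TemperatureClimatology

__all__ = [
    "SST_GROUPS",
    "SBT_GROUPS",
    "GROUP_KEYS",
    "MEASURES",
    "match_climatology",
    "match_depth_series",
    "assign_best_temperature",
    "match_report",
]

#: Functional groups whose experienced temperature is best represented by
#: sea surface temperature.  Nekton are unassigned in the source scheme and
#: default here to SST as water-column animals.
SST_GROUPS = frozenset(
    {"birds", "mammals", "fish:pelagic", "fish:reef-associated", "nekton"}
)
#: Groups best represented by sea bottom temperature.
SBT_GROUPS = frozenset({"benthos", "macroalgae", "fish:demersal", "fish:benthopelagic"})
GROUP_KEYS = SST_GROUPS | SBT_GROUPS

#: The seven per-record temperature measures produced by matching.
MEASURES = [
    "clim_sst",
    "clim_sbt",
    "clim_best",
    "grid_sst",
    "grid_sbt",
    "grid_t_at_depth",
    "grid_best",
]

#: Exclusion reason codes, in the order they are tested.
REASONS = [
    "missing_date",
    "year_out_of_range",
    "outside_grid",
    "land_cell",
    "depth_below_cell_floor",
    "no_temperature_value",
    "unknown_group",
]


def match_climatology(
    records: pd.DataFrame, clim: TemperatureClimatology
) -> pd.DataFrame:
    """Annotate records with ``clim_sst``/``clim_sbt`` and a reason code.

    Purely positional: the record's date plays no part.  A record on a cell
    masked in both layers is excluded with reason ``land_cell``; a cell
    masked in only one layer yields the other value with reason
    ``no_temperature_value`` attached to the missing measure.
    """
    out = records.copy()
    ii, jj = clim.cell_indices(out["lat"].to_numpy(), out["lon"].to_numpy())
    inside = (ii >= 0) & (jj >= 0)
    sst = np.full(len(out), np.nan)
    sbt = np.full(len(out), np.nan)
    sst[inside] = clim.sst[ii[inside], jj[inside]]
    sbt[inside] = clim.sbt[ii[inside], jj[inside]]

    reason = np.full(len(out), "", dtype=object)
    reason[~inside] = "outside_grid"
    both_masked = inside & np.isnan(sst) & np.isnan(sbt)
    reason[both_masked] = "land_cell"

    out["clim_sst"] = sst
    out["clim_sbt"] = sbt
    out["clim_reason"] = reason
    return out


def match_depth_series(
    records: pd.DataFrame, series: DepthResolvedSeries
) -> pd.DataFrame:
    """Annotate records with ``grid_sst``/``grid_sbt``/``grid_t_at_depth``.

    Exclusion cascade for the whole product: missing month or year ->
    ``missing_date``; year outside coverage -> ``year_out_of_range``; point
    off-grid -> ``outside_grid``; land column -> ``land_cell``.  A matched
    cell always yields SST (band 0) and SBT (deepest wet band); temperature
    at sampling depth is additionally missing, with reason
    ``depth_below_cell_floor``, when the sampling depth falls below the
    cell's deepest wet band or below the scheme floor.
    """
    out = records.copy()
    n = len(out)
    year = out["event_year"].to_numpy(dtype=float, na_value=np.nan)
    month = out["event_month"].to_numpy(dtype=float, na_value=np.nan)

    tt = series.time_indices(year, month)
    ii, jj = series.cell_indices(out["lat"].to_numpy(), out["lon"].to_numpy())
    dd = series.scheme.band_indices(out["depth_m"].to_numpy(dtype=float))

    reason = np.full(n, "", dtype=object)
    no_date = np.isnan(year) | np.isnan(month)
    reason[no_date] = "missing_date"
    bad_year = ~no_date & (tt < 0)
    reason[bad_year] = "year_out_of_range"
    off_grid = (reason == "") & ((ii < 0) | (jj < 0))
    reason[off_grid] = "outside_grid"
    cand = reason == ""
    deepest = np.full(n, -1, dtype=np.int64)
    deepest[cand] = series.deepest_wet_band[ii[cand], jj[cand]]
    land = cand & (deepest < 0)
    reason[land] = "land_cell"

    ok = reason == ""
    sst = np.full(n, np.nan)
    sbt = np.full(n, np.nan)
    tdep = np.full(n, np.nan)
    sst[ok] = series.temp[tt[ok], 0, ii[ok], jj[ok]]
    sbt[ok] = series.temp[tt[ok], deepest[ok], ii[ok], jj[ok]]

    tdepth_reason = np.full(n, "", dtype=object)
    tdepth_reason[~ok] = reason[~ok]
    depth_ok = ok & (dd >= 0) & (dd <= deepest)
    tdep[depth_ok] = series.temp[tt[depth_ok], dd[depth_ok], ii[depth_ok], jj[depth_ok]]
    tdepth_reason[ok & ~depth_ok] = "depth_below_cell_floor"

    out["grid_sst"] = sst
    out["grid_sbt"] = sbt
    out["grid_t_at_depth"] = tdep
    out["grid_reason"] = reason
    out["tdepth_reason"] = tdepth_reason
    return out


def assign_best_temperature(
    matched: pd.DataFrame,
    groups: pd.DataFrame | dict,
    nekton_best: str = "sst",
) -> pd.DataFrame:
    """Derive ``clim_best``/``grid_best`` from the species' functional group.

    ``groups`` maps species_id -> group key (one of :data:`GROUP_KEYS`),
    either as a dict or a DataFrame with ``species_id``/``group_key``
    columns.  Species with an unknown or missing group get no best value and
    the reason ``unknown_group``.
    """
    if isinstance(groups, pd.DataFrame):
        mapping = dict(zip(groups["species_id"], groups["group_key"]))
    else:
        mapping = dict(groups)
    if nekton_best not in ("sst", "sbt"):
        raise ValueError("nekton_best must be 'sst' or 'sbt'")

    out = matched.copy()
    key = out["species_id"].map(mapping)
    use_sst = key.isin(SST_GROUPS - {"nekton"}) | (
        (key == "nekton") & (nekton_best == "sst")
    )
    use_sbt = key.isin(SBT_GROUPS) | ((key == "nekton") & (nekton_best == "sbt"))
    known = (use_sst | use_sbt).to_numpy()

    out["group_key"] = key
    out["clim_best"] = np.where(use_sst, out["clim_sst"], np.where(use_sbt, out["clim_sbt"], np.nan))
    out["grid_best"] = np.where(use_sst, out["grid_sst"], np.where(use_sbt, out["grid_sbt"], np.nan))
    out["best_reason"] = np.where(known, "", "unknown_group")
    return out


def _measure_reason(matched: pd.DataFrame, measure: str) -> pd.Series:
    """Reason code series for one measure (empty string where matched)."""
    value = matched[measure]
    if measure.startswith("clim"):
        product_reason = matched.get("clim_reason", pd.Series("", index=matched.index))
    elif measure == "grid_t_at_depth":
        product_reason = matched.get("tdepth_reason", pd.Series("", index=matched.index))
    else:
        product_reason = matched.get("grid_reason", pd.Series("", index=matched.index))
    reason = pd.Series("", index=matched.index, dtype=object)
    missing = value.isna()
    reason[missing] = product_reason[missing]
    if measure.endswith("best"):
        best_reason = matched.get("best_reason", pd.Series("", index=matched.index))
        unk = missing & (best_reason == "unknown_group")
        reason[unk] = "unknown_group"
    # masked single layer, or best-source missing for a known group
    reason[missing & (reason == "")] = "no_temperature_value"
    return reason


def match_report(matched: pd.DataFrame, measures: list[str] | None = None) -> pd.DataFrame:
    """Per-measure match accounting (Table-1-style).

    One row per measure with ``n_total``, ``n_matched``, ``pct_matched``,
    per-reason exclusion counts (columns ``excluded_<reason>``), and the
    number and percentage of species matched at least once.
    """
    measures = [m for m in (measures or MEASURES) if m in matched.columns]
    n_total = len(matched)
    n_species = matched["species_id"].nunique()
    rows = []
    for measure in measures:
        present = matched[measure].notna()
        reason = _measure_reason(matched, measure)
        row = {
            "measure": measure,
            "n_total": n_total,
            "n_matched": int(present.sum()),
            "pct_matched": 100.0 * present.sum() / n_total if n_total else np.nan,
        }
        for r in REASONS:
            row[f"excluded_{r}"] = int((reason == r).sum())
        sp_matched = matched.loc[present, "species_id"].nunique()
        row["n_species"] = n_species
        row["n_species_matched"] = int(sp_matched)
        row["pct_species_matched"] = (
            100.0 * sp_matched / n_species if n_species else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
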