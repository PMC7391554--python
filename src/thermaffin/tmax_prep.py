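"""Aggregate experimental upper thermal limits into one Tmax per species.

Input records carry a species identifier, a limit value in °C, an optional
standard deviation, and the metric that produced it (CTmax, LT50, LT0,
LT100, or other).  The aggregation rules are:

* where a species reports both LT0 and LT100 (common for algal survival
  experiments), LT100 — the temperature at which all individuals die — is
  taken as the upper limit and LT0 records are dropped;
* a species with several estimates gets their mean, weighted by the inverse
  of each estimate's standard deviation where all SDs are available (giving
  more weight to more precise estimates); if any SD is missing the species
  falls back to the unweighted mean, so no estimate silently receives
  infinite or arbitrary weight.  A reported SD of zero is treated as
  missing, with a warning.

Functional groups arrive as a separate attribute table and are normalised
through the merge rules used for sparse habitat categories
(bathydemersal -> demersal; pelagic-neritic and pelagic-oceanic -> pelagic).
Targeted data corrections (e.g. replacing a limit shown to be a database
transcription error) are applied from an explicit edits list, never
hard-coded.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .grid_match import GROUP_KEYS

__all__ = [
    "select_upper_limit",
    "aggregate_tmax",
    "assign_functional_group",
    "apply_data_edits",
    "prepare_limits",
    "HABITAT_MERGES",
]

logger = logging.getLogger(__name__)

#: Raw habitat label -> merged fish habitat.
HABITAT_MERGES = {
    "bathydemersal": "demersal",
    "demersal": "demersal",
    "benthopelagic": "benthopelagic",
    "reef-associated": "reef-associated",
    "pelagic-neritic": "pelagic",
    "pelagic-oceanic": "pelagic",
    "pelagic": "pelagic",
}

#: Non-fish functional groups accepted as-is.
BASE_GROUPS = {"benthos", "birds", "fish", "macroalgae", "mammals", "nekton"}


def select_upper_limit(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the LT0/LT100 preference per species.

    For any species reporting both LT0 and LT100, LT0 rows are dropped
    (LT100 is the upper limit); all other metrics pass through.  Never
    removes a species' only record.
    """
    def keep(grp: pd.DataFrame) -> pd.DataFrame:
        metrics = set(grp["metric"])
        if "LT0" in metrics and "LT100" in metrics:
            return grp[grp["metric"] != "LT0"]
        return grp

    return (
        records.groupby("species_id", group_keys=False, sort=False)[records.columns]
        .apply(keep)
        .reset_index(drop=True)
    )


def _weighted_tmax(values: np.ndarray, sds: np.ndarray) -> float:
    """Inverse-SD weighted mean; unweighted fallback when any SD is missing.

    Note the weights are 1/SD as stated by the source protocol, not the
    inverse-variance 1/SD² convention.
    """
    if np.any(sds == 0):
        warnings.warn("thermal-limit SD of 0 treated as missing", stacklevel=3)
        sds = np.where(sds == 0, np.nan, sds)
    if values.size == 1:
        return float(values[0])
    if np.any(np.isnan(sds)):
        return float(np.mean(values))
    w = 1.0 / sds
    return float(np.sum(values * w) / np.sum(w))


def aggregate_tmax(records: pd.DataFrame, source: str | None = None) -> pd.DataFrame:
    """One Tmax per species: inverse-SD weighted mean of its estimates.

    Returns a frame with ``species_id, tmax, n_estimates`` (plus ``source``
    when given).  Apply :func:`select_upper_limit` first if LT0/LT100
    preference is wanted.
    """
    rows = []
    for species_id, grp in records.groupby("species_id", sort=True):
        values = grp["tmax_c"].to_numpy(dtype=float)
        sds = (
            grp["tmax_sd"].to_numpy(dtype=float)
            if "tmax_sd" in grp.columns
            else np.full(values.size, np.nan)
        )
        rows.append(
            {
                "species_id": species_id,
                "tmax": _weighted_tmax(values, sds),
                "n_estimates": int(values.size),
            }
        )
    out = pd.DataFrame(rows)
    if source is not None:
        out["source"] = source
    return out


def assign_functional_group(attributes: pd.DataFrame) -> pd.DataFrame:
    """Normalise a species attribute table into functional-group keys.

    ``attributes`` needs ``species_id`` and ``group`` columns, with an
    optional ``habitat`` column for fish.  Output adds ``group_key``
    (e.g. ``fish:demersal`` or ``benthos``) and a boolean ``grouped`` flag;
    unknown labels are flagged rather than dropped.
    """
    out = attributes.copy()
    keys = []
    grouped = []
    for _, row in out.iterrows():
        group = str(row.get("group", "")).strip().lower()
        habitat = str(row.get("habitat", "") or "").strip().lower()
        if group == "fish":
            merged = HABITAT_MERGES.get(habitat)
            key = f"fish:{merged}" if merged else None
        elif group in BASE_GROUPS:
            key = group
        else:
            key = None
        if key is not None and key not in GROUP_KEYS:
            key = None
        if key is None:
            logger.warning("species %s: unknown group/habitat (%r, %r)",
                           row.get("species_id"), group, habitat)
        keys.append(key)
        grouped.append(key is not None)
    out["group_key"] = keys
    out["grouped"] = grouped
    return out


def apply_data_edits(records: pd.DataFrame, edits: list[dict]) -> pd.DataFrame:
    """Apply targeted per-species value corrections.

    Each edit is ``{"species_id": ..., "field": ..., "value": ...,
    "note": ...}``.  Edits are applied in order (last wins) and each is
    logged; an edit naming an absent species is a warning, not a failure.
    """
    out = records.copy()
    for edit in edits or []:
        sid, fld, val = edit["species_id"], edit["field"], edit["value"]
        mask = out["species_id"] == sid
        if not mask.any():
            logger.warning("data edit skipped: species %r not present", sid)
            continue
        out.loc[mask, fld] = val
        logger.info("data edit: %s.%s := %r (%s)", sid, fld, val, edit.get("note", ""))
    return out


def prepare_limits(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    edits: list[dict] | None = None,
    source: str | None = None,
) -> pd.DataFrame:
    """Full limit preparation: LT rule -> aggregate -> edits -> groups.

    Returns one row per species with ``species_id, tmax, n_estimates,
    group_key`` (NaN group_key when ungrouped).
    """
    retained = select_upper_limit(records)
    agg = aggregate_tmax(retained, source=source)
    agg = apply_data_edits(agg, edits or [])
    groups = assign_functional_group(attributes)[["species_id", "group_key"]]
    return agg.merge(groups, on="species_id", how="left")
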