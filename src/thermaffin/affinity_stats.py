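"""Species-level thermal affinity: distributional summaries of the matched
temperatures of each species' occurrence records.

For each species and temperature measure the summary comprises the mean,
minimum, maximum, median, standard deviation (sample, n-1), median absolute
deviation (scaled by 1.4826 for normal consistency), and the 5th and 95th
quantiles (linear interpolation between order statistics), together with the
total and matched record counts.  Records without a temperature value for a
measure are excluded from that measure's statistics only.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid_match import MEASURES

__all__ = ["summarize_species", "summarize_affinities", "affinity_correlations", "MAD_SCALE"]

#: Normal-consistency constant for the median absolute deviation.
MAD_SCALE = 1.4826

_STAT_COLS = ["mean", "min", "max", "median", "sd", "mad", "q05", "q95"]


def _summary_row(values: np.ndarray, n_total: int) -> dict:
    v = values[np.isfinite(values)]
    row: dict = {"n_total": n_total, "n_matched": int(v.size)}
    if v.size == 0:
        row.update({c: np.nan for c in _STAT_COLS})
        return row
    row["mean"] = float(np.mean(v))
    row["min"] = float(np.min(v))
    row["max"] = float(np.max(v))
    row["median"] = float(np.median(v))
    row["sd"] = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
    row["mad"] = float(MAD_SCALE * np.median(np.abs(v - np.median(v))))
    row["q05"] = float(np.quantile(v, 0.05))  # linear interpolation default
    row["q95"] = float(np.quantile(v, 0.95))
    return row


def summarize_species(matched: pd.DataFrame, measure: str) -> dict:
    """Summary statistics of one measure over one species' matched records.

    ``matched`` must contain records of a single species; statistics are
    computed over present values only, with counts recorded.  With no
    matched value the summary carries counts only (statistics NaN).
    """
    if matched["species_id"].nunique() > 1:
        raise ValueError("summarize_species expects records of a single species")
    row = _summary_row(matched[measure].to_numpy(dtype=float), len(matched))
    row["species_id"] = matched["species_id"].iloc[0] if len(matched) else None
    row["measure"] = measure
    return row


def summarize_affinities(
    matched: pd.DataFrame, measures: list[str] | None = None
) -> pd.DataFrame:
    """Tidy per-species x per-measure affinity table.

    One row per (species_id, measure) with the statistics of
    :func:`summarize_species`.
    """
    measures = [m for m in (measures or MEASURES) if m in matched.columns]
    rows = []
    for species_id, grp in matched.groupby("species_id", sort=True):
        for measure in measures:
            row = _summary_row(grp[measure].to_numpy(dtype=float), len(grp))
            row["species_id"] = species_id
            row["measure"] = measure
            rows.append(row)
    cols = ["species_id", "measure", *_STAT_COLS, "n_total", "n_matched"]
    return pd.DataFrame(rows, columns=cols)


def affinity_correlations(
    affinities: pd.DataFrame,
    pairs: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between affinity variables across species.

    Each variable is a (measure, statistic) pair, e.g.
    ``("clim_best", "mean")``.  By default every unordered pair among
    {mean, q95} x available measures is compared.  Pairs with fewer than
    three complete species yield NaN with the pairwise n reported.
    """
    wide = affinities.pivot(index="species_id", columns="measure")
    if pairs is None:
        variables = [
            (m, s)
            for s in ("mean", "q95")
            for m in affinities["measure"].unique()
        ]
        pairs = list(combinations(variables, 2))
    rows = []
    for (m1, s1), (m2, s2) in pairs:
        x = wide[(s1, m1)] if (s1, m1) in wide.columns else pd.Series(dtype=float)
        y = wide[(s2, m2)] if (s2, m2) in wide.columns else pd.Series(dtype=float)
        xy = pd.concat([x, y], axis=1).dropna()
        n = len(xy)
        if n >= 3:
            r = float(sps.pearsonr(xy.iloc[:, 0], xy.iloc[:, 1]).statistic)
        else:
            r = np.nan
        rows.append(
            {
                "measure_1": m1,
                "stat_1": s1,
                "measure_2": m2,
                "stat_2": s2,
                "r": r,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
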