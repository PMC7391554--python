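"""Record-to-grid matching versus brute-force oracles, and exclusion accounting."""

import numpy as np
import pandas as pd
import pytest

from thermaffin.grid_match import (
    MEASURES,
    REASONS,
    assign_best_temperature,
    match_climatology,
    match_depth_series,
    match_report,
)

from _oracles import (
    climatology_match_scan,
    depth_series_match_scan,
    enumerate_woa_edges,
)


def random_records(world, n, seed, include_edge_cases=True):
    """Random records spanning the awkward cases: cell edges, land, missing
    and out-of-range dates, depths below the scheme floor."""
    rng = np.random.default_rng(seed)
    cfg = world.config
    lat = rng.uniform(*cfg.lat_range, n)
    lon = rng.uniform(*cfg.lon_range, n)
    depth = rng.choice([0.0, 5.0, 57.0, 180.0, 650.0, 1999.0, 2000.0, 2500.0], n)
    year = rng.choice(
        [cfg.year_range[0], cfg.year_range[1], cfg.year_range[0] - 5, 1939, 2050], n,
        p=[0.4, 0.4, 0.1, 0.05, 0.05],
    ).astype(float)
    month = rng.integers(1, 13, n).astype(float)
    missing = rng.random(n) < 0.1
    year[missing] = np.nan
    month[missing] = np.nan
    if include_edge_cases:  # pin some points exactly on interior cell edges
        k = min(n, world.climatology.lat_edges.size - 2)
        lat[:k] = world.climatology.lat_edges[1 : k + 1]
        lon[:k] = world.climatology.lon_edges[1 : k + 1]
    return pd.DataFrame(
        {
            "species_id": "sp",
            "lat": lat,
            "lon": lon,
            "depth_m": depth,
            "event_month": pd.array(month, dtype="Int64"),
            "event_year": pd.array(year, dtype="Int64"),
        }
    )


def assert_matches_oracle(world, records):
    edges = enumerate_woa_edges()
    matched = match_climatology(records, world.climatology)
    matched = match_depth_series(matched, world.depth_series)
    for idx, row in matched.iterrows():
        rec = {
            "lat": row["lat"],
            "lon": row["lon"],
            "depth_m": row["depth_m"],
            "event_month": None if pd.isna(row["event_month"]) else int(row["event_month"]),
            "event_year": None if pd.isna(row["event_year"]) else int(row["event_year"]),
        }
        sst, sbt, reason = climatology_match_scan(rec, world.climatology)
        np.testing.assert_equal(row["clim_sst"], sst, err_msg=f"row {idx} clim_sst")
        np.testing.assert_equal(row["clim_sbt"], sbt, err_msg=f"row {idx} clim_sbt")
        assert row["clim_reason"] == reason, f"row {idx} clim_reason"
        g_sst, g_sbt, g_td, g_reason, td_reason = depth_series_match_scan(
            rec, world.depth_series, edges
        )
        np.testing.assert_equal(row["grid_sst"], g_sst, err_msg=f"row {idx} grid_sst")
        np.testing.assert_equal(row["grid_sbt"], g_sbt, err_msg=f"row {idx} grid_sbt")
        np.testing.assert_equal(row["grid_t_at_depth"], g_td, err_msg=f"row {idx} t_at_depth")
        assert row["grid_reason"] == g_reason, f"row {idx} grid_reason"
        assert row["tdepth_reason"] == td_reason, f"row {idx} tdepth_reason"
    return matched


class TestOracleEquivalence:
    def test_matching_equals_brute_force_scan(self, small_world):
        records = random_records(small_world, 300, seed=21)
        assert_matches_oracle(small_world, records)


class TestDepthSeriesSemantics:
    def test_dateless_record_still_climatology_matchable(self, small_world):
        wet = np.nonzero(small_world.depth_series.deepest_wet_band >= 0)
        clim = small_world.climatology
        rec = pd.DataFrame(
            {
                "species_id": ["a"],
                "lat": [clim.lat_centers[wet[0][0]]],
                "lon": [clim.lon_centers[wet[1][0]]],
                "depth_m": [0.0],
                "event_month": pd.array([None], dtype="Int64"),
                "event_year": pd.array([None], dtype="Int64"),
            }
        )
        out = match_depth_series(match_climatology(rec, clim), small_world.depth_series)
        assert out.loc[0, "grid_reason"] == "missing_date"
        assert np.isnan(out.loc[0, "grid_sst"])
        assert np.isfinite(out.loc[0, "clim_sst"])

    def test_depth_below_cell_floor_keeps_sst_and_sbt(self, small_world):
        series = small_world.depth_series
        shallow = np.nonzero((series.deepest_wet_band >= 0) & (series.deepest_wet_band < 5))
        assert shallow[0].size, "fixture must contain a shallow shelf cell"
        i, j = shallow[0][0], shallow[1][0]
        rec = pd.DataFrame(
            {
                "species_id": ["a"],
                "lat": [series.lat_centers[i]],
                "lon": [series.lon_centers[j]],
                "depth_m": [500.0],
                "event_month": pd.array([6], dtype="Int64"),
                "event_year": pd.array([small_world.config.year_range[0]], dtype="Int64"),
            }
        )
        out = match_depth_series(rec, series)
        assert np.isfinite(out.loc[0, "grid_sst"]) and np.isfinite(out.loc[0, "grid_sbt"])
        assert np.isnan(out.loc[0, "grid_t_at_depth"])
        assert out.loc[0, "tdepth_reason"] == "depth_below_cell_floor"

    def test_sbt_at_full_depth_cell_is_deepest_band_value(self, small_world):
        series = small_world.depth_series
        deep = np.nonzero(series.deepest_wet_band == series.scheme.n_bands - 1)
        i, j = deep[0][0], deep[1][0]
        rec = pd.DataFrame(
            {
                "species_id": ["a"],
                "lat": [series.lat_centers[i]],
                "lon": [series.lon_centers[j]],
                "depth_m": [0.0],
                "event_month": pd.array([1], dtype="Int64"),
                "event_year": pd.array([small_world.config.year_range[0]], dtype="Int64"),
            }
        )
        out = match_depth_series(rec, series)
        assert out.loc[0, "grid_sbt"] == series.temp[0, 26, i, j]  # band [1750, 2000]

    def test_climatology_match_is_date_independent(self, small_world):
        records = random_records(small_world, 50, seed=22)
        a = match_climatology(records, small_world.climatology)
        shuffled = records.copy()
        shuffled["event_year"] = pd.array([2050] * len(records), dtype="Int64")
        b = match_climatology(shuffled, small_world.climatology)
        np.testing.assert_array_equal(a["clim_sst"], b["clim_sst"])


class TestBestTemperature:
    @pytest.mark.parametrize(
        "group,source",
        [
            ("birds", "sst"), ("mammals", "sst"), ("fish:pelagic", "sst"),
            ("fish:reef-associated", "sst"), ("benthos", "sbt"), ("macroalgae", "sbt"),
            ("fish:demersal", "sbt"), ("fish:benthopelagic", "sbt"),
        ],
    )
    def test_group_rule(self, group, source):
        df = pd.DataFrame(
            {
                "species_id": ["a"],
                "clim_sst": [10.0],
                "clim_sbt": [8.2],
                "grid_sst": [11.0],
                "grid_sbt": [7.5],
            }
        )
        out = assign_best_temperature(df, {"a": group})
        expected = df[f"clim_{source}"].iloc[0]
        assert out.loc[0, "clim_best"] == expected
        assert out.loc[0, "grid_best"] == df[f"grid_{source}"].iloc[0]

    def test_nekton_defaults_to_sst_with_override(self):
        df = pd.DataFrame(
            {"species_id": ["a"], "clim_sst": [10.0], "clim_sbt": [8.0],
             "grid_sst": [np.nan], "grid_sbt": [np.nan]}
        )
        assert assign_best_temperature(df, {"a": "nekton"}).loc[0, "clim_best"] == 10.0
        assert (
            assign_best_temperature(df, {"a": "nekton"}, nekton_best="sbt").loc[0, "clim_best"]
            == 8.0
        )

    def test_missing_component_propagates(self):
        df = pd.DataFrame(
            {"species_id": ["a"], "clim_sst": [10.0], "clim_sbt": [np.nan],
             "grid_sst": [np.nan], "grid_sbt": [np.nan]}
        )
        out = assign_best_temperature(df, {"a": "benthos"})
        assert np.isnan(out.loc[0, "clim_best"])

    def test_unknown_group_flagged_without_best_value(self):
        df = pd.DataFrame(
            {"species_id": ["a"], "clim_sst": [10.0], "clim_sbt": [8.0],
             "grid_sst": [1.0], "grid_sbt": [2.0]}
        )
        out = assign_best_temperature(df, {})
        assert np.isnan(out.loc[0, "clim_best"])
        assert out.loc[0, "best_reason"] == "unknown_group"


class TestMatchReport:
    def _matched(self, world, n=200, seed=30):
        records = random_records(world, n, seed)
        m = match_climatology(records, world.climatology)
        m = match_depth_series(m, world.depth_series)
        return assign_best_temperature(m, {"sp": "fish:pelagic"})

    def test_simple_percentage_arithmetic(self):
        # 10 records, 2 missing dates, all on wet cells -> 80% vs 100%
        df = pd.DataFrame(
            {
                "species_id": ["s"] * 10,
                "clim_sst": [10.0] * 10,
                "clim_sbt": [9.0] * 10,
                "clim_reason": [""] * 10,
                "grid_sst": [10.0] * 8 + [np.nan] * 2,
                "grid_reason": [""] * 8 + ["missing_date"] * 2,
            }
        )
        rep = match_report(df, measures=["clim_sst", "grid_sst"]).set_index("measure")
        assert rep.loc["clim_sst", "pct_matched"] == 100.0
        assert rep.loc["grid_sst", "pct_matched"] == 80.0
        assert rep.loc["grid_sst", "excluded_missing_date"] == 2

    def test_all_land_matches_nothing(self, small_world):
        clim = small_world.climatology
        land = np.nonzero(np.isnan(clim.sst))
        rec = pd.DataFrame(
            {
                "species_id": ["a", "a"],
                "lat": clim.lat_centers[land[0][:2]],
                "lon": clim.lon_centers[land[1][:2]],
                "depth_m": [0.0, 0.0],
                "event_month": pd.array([1, 1], dtype="Int64"),
                "event_year": pd.array([2000, 2000], dtype="Int64"),
            }
        )
        m = match_depth_series(match_climatology(rec, clim), small_world.depth_series)
        rep = match_report(m, measures=["clim_sst", "grid_sst"])
        assert (rep["n_matched"] == 0).all()
        assert (rep["pct_matched"] == 0.0).all()

    def test_exclusion_conservation_for_every_measure(self, small_world):
        matched = self._matched(small_world)
        rep = match_report(matched)
        excl_cols = [c for c in rep.columns if c.startswith("excluded_")]
        for _, row in rep.iterrows():
            assert row["n_total"] == row["n_matched"] + sum(row[c] for c in excl_cols)
            assert row["pct_matched"] == pytest.approx(
                100.0 * row["n_matched"] / row["n_total"]
            )

    def test_every_reason_code_is_known(self, small_world):
        matched = self._matched(small_world)
        for col in ("clim_reason", "grid_reason", "tdepth_reason"):
            assert set(matched[col].unique()) <= set(REASONS) | {""}
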