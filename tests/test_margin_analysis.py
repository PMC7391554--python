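"""Polynomial thermal-limit models, nested F tests, vertices and margins."""

import numpy as np
import pandas as pd
import pytest

from thermaffin.margin_analysis import (
    ModelComparison,
    ThermalLimitModel,
    assign_affinity_bin,
    bin_margin_table,
    compare_models,
    safety_margins,
)

from _oracles import ols_normal_equations


def quad_data(n=120, coeffs=(15.0, 1.2, -0.02), noise=0.0, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 30.0, n)
    a, b, c = coeffs
    y = a + b * x + c * x * x + (rng.normal(0, noise, n) if noise else 0.0)
    g = None
    if groups:
        g = np.asarray(groups)[rng.integers(0, len(groups), n)]
    return y, x, g


class TestFitting:
    def test_noiseless_pooled_recovery_is_exact(self):
        y, x, _ = quad_data()
        res = ThermalLimitModel(y, x, form="pooled").fit()
        np.testing.assert_allclose(res.params, [15.0, 1.2, -0.02], atol=1e-9)
        assert res.rsquared == pytest.approx(1.0)

    def test_constant_response_gives_flat_curve_and_zero_rsquared(self):
        x = np.linspace(0, 30, 50)
        res = ThermalLimitModel(np.full(50, 21.0), x, form="pooled").fit()
        np.testing.assert_allclose(res.params, [21.0, 0.0, 0.0], atol=1e-8)
        assert res.rsquared == 0.0

    @pytest.mark.parametrize("form", ["pooled", "additive", "interaction"])
    def test_coefficients_match_normal_equations_oracle(self, form):
        y, x, g = quad_data(n=200, noise=1.0, seed=3,
                            groups=("benthos", "macroalgae", "fish:pelagic"))
        res = ThermalLimitModel(y, x, group=g, form=form).fit()
        # raw-basis design built independently of the implementation
        if form == "pooled":
            X = np.column_stack([np.ones_like(x), x, x * x])
        elif form == "additive":
            dummies = np.column_stack([(g == k).astype(float) for k in sorted(set(g))])
            X = np.column_stack([dummies, x, x * x])
        else:
            cols = []
            for k in sorted(set(g)):
                d = (g == k).astype(float)
                cols += [d, d * x, d * x * x]
            X = np.column_stack(cols)
        expected = ols_normal_equations(X, y)
        np.testing.assert_allclose(res.params, expected, atol=1e-8)

    def test_interaction_equals_independent_per_group_fits(self):
        y, x, g = quad_data(n=150, noise=1.0, seed=4, groups=("benthos", "macroalgae"))
        res = ThermalLimitModel(y, x, group=g, form="interaction").fit()
        for k in ("benthos", "macroalgae"):
            sub = g == k
            solo = ThermalLimitModel(y[sub], x[sub], form="pooled").fit()
            np.testing.assert_allclose(res.coefficients(k), solo.params, atol=1e-8)

    def test_small_group_under_interaction_raises_naming_it(self):
        y, x, _ = quad_data(n=40)
        g = np.array(["benthos"] * 38 + ["macroalgae"] * 2)
        with pytest.raises(ValueError, match="macroalgae"):
            ThermalLimitModel(y, x, group=g, form="interaction")

    def test_too_few_species_raises(self):
        with pytest.raises(ValueError, match="at least"):
            ThermalLimitModel([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], form="pooled")

    def test_confidence_intervals_bracket_estimates(self):
        y, x, _ = quad_data(n=100, noise=1.0, seed=6)
        res = ThermalLimitModel(y, x, form="pooled").fit()
        ci = res.conf_int()
        assert np.all(ci[:, 0] < res.params) and np.all(res.params < ci[:, 1])

    def test_summary_mentions_fit_and_vertex(self):
        y, x, _ = quad_data(noise=0.5, seed=7)
        text = ThermalLimitModel(y, x, form="pooled").fit().summary()
        assert "R^2" in text and "vertex" in text


class TestModelComparison:
    def test_f_statistic_matches_hand_formula(self):
        y, x, g = quad_data(n=150, noise=1.0, seed=8, groups=("a", "b", "c"))
        f_add = ThermalLimitModel(y, x, group=g, form="additive").fit()
        f_int = ThermalLimitModel(y, x, group=g, form="interaction").fit()
        cmp_ = compare_models(f_add, f_int)
        dp = f_add.df_resid - f_int.df_resid
        expected = ((f_add.rss - f_int.rss) / dp) / (f_int.rss / f_int.df_resid)
        assert cmp_.f_statistic == pytest.approx(expected, rel=1e-12)
        assert (cmp_.df_num, cmp_.df_den) == (dp, f_int.df_resid)

    def test_identical_fits_give_zero_f(self):
        y, x, g = quad_data(n=80, noise=1.0, seed=9, groups=("a", "b"))
        f1 = ThermalLimitModel(y, x, group=g, form="additive").fit()
        f2 = ThermalLimitModel(y, x, group=g, form="additive").fit()
        cmp_ = compare_models(f1, f2)
        assert cmp_.f_statistic == 0.0 and cmp_.p_value == 1.0

    def test_reversed_nesting_rejected(self):
        y, x, g = quad_data(n=80, noise=1.0, seed=10, groups=("a", "b"))
        f_add = ThermalLimitModel(y, x, group=g, form="additive").fit()
        f_pool = ThermalLimitModel(y, x, form="pooled").fit()
        with pytest.raises(ValueError, match="not nested"):
            compare_models(f_add, f_pool)

    def test_different_responses_rejected(self):
        y1, x1, _ = quad_data(n=80, seed=11)
        y2, x2, _ = quad_data(n=80, seed=12, noise=1.0)
        f1 = ThermalLimitModel(y1, x1, form="pooled").fit()
        f2 = ThermalLimitModel(y2, x2, form="pooled").fit()
        with pytest.raises(ValueError, match="response"):
            compare_models(f1, f2)

    def test_null_interaction_f_is_calibrated_in_small_simulation(self):
        # no group effect in truth -> p-values roughly uniform
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(60):
            x = rng.uniform(0, 30, 120)
            g = np.asarray(("a", "b", "c"))[rng.integers(0, 3, 120)]
            y = 15 + 1.2 * x - 0.02 * x * x + rng.normal(0, 1, 120)
            f_add = ThermalLimitModel(y, x, group=g, form="additive").fit()
            f_int = ThermalLimitModel(y, x, group=g, form="interaction").fit()
            pvals.append(compare_models(f_add, f_int).p_value)
        assert np.mean(pvals) > 0.2
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2

    def test_interaction_never_decreases_rsquared(self):
        for seed in range(5):
            y, x, g = quad_data(n=90, noise=2.0, seed=seed, groups=("a", "b", "c"))
            r_pool = ThermalLimitModel(y, x, group=g, form="pooled").fit().rsquared
            r_add = ThermalLimitModel(y, x, group=g, form="additive").fit().rsquared
            r_int = ThermalLimitModel(y, x, group=g, form="interaction").fit().rsquared
            assert r_pool <= r_add + 1e-12 <= r_int + 2e-12


class TestVertex:
    def test_vertex_is_minus_b_over_2c(self):
        x = np.linspace(0, 40, 60)
        y = 10 + 2 * x - 0.03 * x * x
        v = ThermalLimitModel(y, x, form="pooled").fit().vertex()
        assert v["affinity_at_max"] == pytest.approx(-2 / (2 * -0.03), abs=1e-6)
        assert not v["extrapolated"]

    def test_convex_or_linear_fit_has_no_vertex(self):
        x = np.linspace(0, 30, 50)
        assert ThermalLimitModel(2 + 0.5 * x, x, form="pooled").fit().vertex() is None
        assert ThermalLimitModel(2 + 0.1 * x * x, x, form="pooled").fit().vertex() is None

    def test_vertex_outside_observed_range_flagged_extrapolated(self):
        x = np.linspace(0, 20, 50)  # optimum at 30, beyond the data
        y = 15 + 1.2 * x - 0.02 * x * x
        v = ThermalLimitModel(y, x, form="pooled").fit().vertex()
        assert v["extrapolated"] and v["affinity_at_max"] == pytest.approx(30.0, abs=1e-6)

    def test_noiseless_synthetic_fit_recovers_generating_optimum(self):
        y, x, _ = quad_data(n=200, coeffs=(15.0, 1.2, -0.02), seed=14)
        v = ThermalLimitModel(y, x, form="pooled").fit().vertex()
        assert v["affinity_at_max"] == pytest.approx(30.0, abs=1e-6)


class TestMargins:
    def _tables(self):
        limits = pd.DataFrame(
            {
                "species_id": ["a", "b", "c", "d"],
                "tmax": [30.0, 25.0, 40.0, 18.0],
                "group_key": ["benthos", "benthos", "fish:pelagic", "macroalgae"],
            }
        )
        affinities = pd.DataFrame(
            {
                "species_id": ["a", "b", "c", "e"],
                "measure": "grid_t_at_depth",
                "mean": [18.0, 10.0, 28.3, 5.0],
            }
        )
        return limits, affinities

    def test_margin_value_and_bin(self):
        limits, aff = self._tables()
        out = safety_margins(limits, aff).set_index("species_id")
        assert out.loc["a", "margin"] == 12.0
        assert out.loc["a", "affinity_bin"] == "moderate"

    def test_species_without_affinity_omitted(self):
        limits, aff = self._tables()
        out = safety_margins(limits, aff)
        assert set(out["species_id"]) == {"a", "b", "c"}

    @pytest.mark.parametrize(
        "affinity,expected",
        [(10.0, "cold"), (10.0001, "moderate"), (20.0, "moderate"), (20.0001, "warm"), (-2.0, "cold")],
    )
    def test_bin_edge_closures(self, affinity, expected):
        assert assign_affinity_bin(np.array([affinity]))[0] == expected

    def test_margin_plus_affinity_reproduces_tmax_bit_exactly(self):
        rng = np.random.default_rng(15)
        n = 5000
        limits = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(n)],
                "tmax": rng.uniform(2.0, 44.5, n),
                "group_key": "benthos",
            }
        )
        aff = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(n)],
                "measure": "grid_t_at_depth",
                "mean": rng.uniform(-2.0, 32.0, n),
            }
        )
        out = safety_margins(limits, aff)
        lhs = out["margin"].to_numpy() + out["affinity"].to_numpy()
        np.testing.assert_array_equal(lhs, out["tmax"].to_numpy())

    def test_bin_table_mean_sd_and_conservation(self):
        margins = pd.DataFrame(
            {
                "species_id": list("abcde"),
                "group_key": ["benthos"] * 4 + ["birds"],
                "tmax": 0.0,
                "affinity": [15, 16, 25, 26, 5],
                "margin": [12.0, 14.0, 9.0, 11.0, 20.0],
                "affinity_bin": ["moderate", "moderate", "warm", "warm", "cold"],
            }
        )
        table = bin_margin_table(margins)
        row = table.set_index(["group_key", "affinity_bin"]).loc[("benthos", "moderate")]
        assert row["mean_margin"] == 13.0
        assert row["sd_margin"] == pytest.approx(np.sqrt(2.0))
        # empty cells absent, sparse groups excluded, totals conserve
        assert ("benthos", "cold") not in table.set_index(["group_key", "affinity_bin"]).index
        assert "birds" not in set(table["group_key"])
        assert table["n"].sum() == 4
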