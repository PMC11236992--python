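"""Weighted community indices, demographic partition, jackknife, size classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from thermoshift.community_index import (
    basal_area,
    community_index,
    index_trajectory,
    jackknife_contributions,
    mean_annual_rate,
    partition_change,
    signed_sqrt,
    size_class_summary,
)

from conftest import build_series


class TestBasalArea:
    def test_unit_area_diameter(self):
        assert basal_area(2.0 / np.sqrt(np.pi)) == pytest.approx(1.0)

    def test_d10(self):
        assert basal_area(10.0) == pytest.approx(78.53981634, abs=1e-6)

    def test_doubling_diameter_quadruples(self):
        assert basal_area(24.0) == pytest.approx(4 * basal_area(12.0))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            basal_area(0.0)


def stems_frame(entries):
    """(species, diameter) tuples -> a one-census living-stems frame."""
    return pd.DataFrame(
        {
            "species": [e[0] for e in entries],
            "diameter_cm": [e[1] for e in entries],
            "alive": True,
        }
    )


class TestCommunityIndex:
    def test_monodominant(self, ab_optima):
        stems = stems_frame([("A", 15), ("A", 25), ("A", 40)])
        vals = pd.Series({"A": 14.2})
        for w in ("stem", "basal_area"):
            assert community_index(stems, vals, weighting=w).value == pytest.approx(14.2)

    def test_stem_weighting_three_to_one(self, ab_optima):
        stems = stems_frame([("A", 12), ("A", 30), ("A", 55), ("B", 20)])
        assert community_index(stems, ab_optima).value == pytest.approx(12.5)

    def test_basal_area_weighting_hand_example(self, ab_optima):
        """Weights proportional to D^2 (100 vs 900) give 19.0."""
        stems = stems_frame([("A", 10), ("B", 30)])
        idx = community_index(stems, ab_optima, weighting="basal_area")
        assert idx.value == pytest.approx(19.0)

    def test_uncovered_stems_renormalized_with_coverage(self, ab_optima):
        stems = stems_frame([("A", 12), ("B", 12), ("Indet sp1", 12), ("Indet sp1", 12)])
        idx = community_index(stems, ab_optima)
        assert idx.value == pytest.approx(15.0)
        assert idx.coverage == pytest.approx(0.5)

    def test_zero_coverage_warns_and_is_nan(self, ab_optima):
        stems = stems_frame([("Indet sp1", 12)])
        with pytest.warns(UserWarning):
            idx = community_index(stems, ab_optima)
        assert np.isnan(idx.value) and idx.coverage == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        diams=st_h.lists(st_h.floats(10.0, 120.0), min_size=2, max_size=20),
        opts=st_h.lists(st_h.floats(5.0, 25.0), min_size=2, max_size=2),
        data=st_h.data(),
    )
    def test_bounds_and_order_invariance(self, diams, opts, data):
        """The index lies within [min, max] attribute of covered species and
        ignores stem ordering."""
        vals = pd.Series({"A": opts[0], "B": opts[1]})
        species = [data.draw(st_h.sampled_from(["A", "B"])) for _ in diams]
        stems = stems_frame(list(zip(species, diams)))
        for w in ("stem", "basal_area"):
            v = community_index(stems, vals, weighting=w).value
            assert min(opts) - 1e-9 <= v <= max(opts) + 1e-9
            shuffled = stems.sample(frac=1, random_state=0)
            assert community_index(shuffled, vals, weighting=w).value == pytest.approx(v)

    def test_stem_equals_ba_when_diameters_equal(self, ab_optima):
        stems = stems_frame([("A", 17.0), ("B", 17.0), ("B", 17.0)])
        s = community_index(stems, ab_optima, weighting="stem").value
        b = community_index(stems, ab_optima, weighting="basal_area").value
        assert s == pytest.approx(b)

    def test_split_invariance(self, ab_optima):
        """Splitting a species' stems into groups does not move the index."""
        merged = stems_frame([("A", 20)] * 4 + [("B", 20)] * 2)
        split = stems_frame([("A", 20)] * 2 + [("B", 20)] * 2 + [("A", 20)] * 2)
        assert community_index(merged, ab_optima, weighting="basal_area").value == pytest.approx(
            community_index(split, ab_optima, weighting="basal_area").value
        )


class TestTrajectory:
    def test_identical_censuses_rate_zero(self, ab_optima):
        records = [(t, s, ci, d, True) for ci in (0, 1) for t, s, d in
                   [("x1", "A", 12), ("x2", "B", 20)]]
        series = build_series(records, [2010.0, 2015.0])
        tr = index_trajectory(series, ab_optima)
        assert tr.annual_rate == pytest.approx(0.0)

    def test_rate_is_change_over_interval(self, two_species_series, ab_optima):
        tr = index_trajectory(two_species_series, ab_optima)
        # 15.0 -> 17.5 over 10 years
        assert tr.annual_rate == pytest.approx(0.25)

    def test_middle_census_does_not_affect_rate(self, ab_optima):
        base = [("x1", "A", 0, 12, True), ("x2", "B", 0, 12, True),
                ("x1", "A", 2, 13, True), ("x2", "B", 2, 13, True)]
        mid_a = base + [("x1", "A", 1, 12.5, True), ("x2", "B", 1, 12.5, True)]
        mid_b = base + [("x1", "A", 1, 12.5, True)]  # very different middle
        dates = [2010.0, 2013.0, 2020.0]
        ra = index_trajectory(build_series(mid_a, dates), ab_optima).annual_rate
        rb = index_trajectory(build_series(mid_b, dates), ab_optima).annual_rate
        assert ra == pytest.approx(rb)


class TestPartition:
    def test_static_community_all_components_zero(self, ab_optima):
        records = [(t, s, ci, d, True) for ci in (0, 1) for t, s, d in
                   [("x1", "A", 12), ("x2", "B", 20)]]
        series = build_series(records, [2010.0, 2015.0])
        pr = partition_change(series, ab_optima)
        assert pr.mortality == pytest.approx(0.0)
        assert pr.recruitment == pytest.approx(0.0)

    def test_hand_computed_stem_partition(self, two_species_series, ab_optima):
        """{Ax2,Bx2} -> one A dies, one B recruits: survivors 16.667,
        mortality +1.667, recruitment +0.833, total +2.5."""
        pr = partition_change(two_species_series, ab_optima)
        assert pr.total == pytest.approx(2.5)
        assert pr.mortality == pytest.approx(5.0 / 3.0)
        assert pr.recruitment == pytest.approx(2.5 - 5.0 / 3.0)
        assert pr.growth == 0.0

    @staticmethod
    def random_census_pair(rng):
        n0 = rng.integers(4, 30)
        opts = pd.Series({f"S{k}": rng.uniform(8, 25) for k in range(5)})
        records = []
        survived = 0
        for i in range(n0):
            sp = f"S{rng.integers(0, 5)}"
            d0 = rng.uniform(10, 80)
            records.append((f"t{i}", sp, 0, d0, True))
            if rng.random() < 0.75:
                records.append((f"t{i}", sp, 1, d0 + rng.uniform(0, 5), True))
                survived += 1
            elif rng.random() < 0.5:
                records.append((f"t{i}", sp, 1, d0, False))
        for j in range(rng.integers(0, 6)):
            records.append((f"r{j}", f"S{rng.integers(0, 5)}", 1, rng.uniform(10, 15), True))
        return build_series(records, [2010.0, 2010.0 + rng.uniform(2, 12)]), opts, survived

    def test_additivity_on_random_census_pairs(self):
        """recruitment + mortality (+ growth) equals total to 1e-10 for both
        weightings on 500 random census pairs."""
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 500:
            series, opts, survived = self.random_census_pair(rng)
            if survived == 0:
                continue
            for w in ("stem", "basal_area"):
                pr = partition_change(series, opts, weighting=w)
                assert pr.recruitment + pr.mortality + pr.growth == pytest.approx(
                    pr.total, abs=1e-10
                )
            checked += 1

    def test_literal_two_term_variant_under_stem_weighting(self, ab_optima):
        """Under stem weighting the literal Survive_L - Alive_F / Alive_L -
        Survive_F formulas coincide with the chain decomposition."""
        series = build_series(
            [("x1", "A", 0, 12, True), ("x2", "B", 0, 14, True),
             ("x1", "A", 1, 13, True), ("r1", "B", 1, 11, True)],
            [2010.0, 2016.0],
        )
        lit = partition_change(series, ab_optima, literal_two_term=True)
        chain = partition_change(series, ab_optima)
        assert lit.mortality == pytest.approx(chain.mortality)
        assert lit.recruitment == pytest.approx(chain.recruitment)

    def test_no_survivors_warns(self, ab_optima):
        series = build_series(
            [("x1", "A", 0, 12, True), ("x1", "A", 1, 12, False),
             ("r1", "B", 1, 11, True)],
            [2010.0, 2016.0],
        )
        with pytest.warns(UserWarning, match="no survivors"):
            partition_change(series, ab_optima)


class TestJackknife:
    def plots_with_recruiting_warm_species(self):
        """Single plot where removing W exactly halves the trend."""
        series = build_series(
            [("c1", "C", 0, 12, True), ("c2", "C", 0, 12, True),
             ("c1", "C", 1, 13, True), ("c2", "C", 1, 13, True),
             ("w1", "W", 1, 11, True), ("x1", "X", 1, 11, True)],
            [2010.0, 2020.0],
        )
        vals = pd.Series({"C": 10.0, "W": 20.0, "X": 16.0})
        return [series], vals

    def test_halving_species_has_contribution_minus_half(self):
        plots, vals = self.plots_with_recruiting_warm_species()
        # all: 10 -> 14 over 10 y = 0.4; without W: 10 -> 12 = 0.2
        jk = jackknife_contributions(plots, vals, weighting="stem")
        assert jk.attrs["rate_all"] == pytest.approx(0.4)
        assert jk.loc["W", "contribution"] == pytest.approx(-0.5)
        assert jk.loc["W", "contribution_sqrt"] == pytest.approx(-np.sqrt(0.5))

    def test_absent_species_contributes_zero(self):
        plots, vals = self.plots_with_recruiting_warm_species()
        vals = pd.concat([vals, pd.Series({"Z": 30.0})])
        jk = jackknife_contributions(plots, vals, weighting="stem")
        assert jk.loc["Z", "contribution"] == 0.0
        assert jk.loc["Z", "rate_jackknife"] == pytest.approx(jk.attrs["rate_all"])

    def test_matches_pipeline_loop_oracle(self, bundle):
        """Jackknife deltas equal an independent per-species removal loop."""
        from thermoshift.thermal_affiliation import build_affiliation_table, included_values

        plots = bundle["plots"][:3]
        table = build_affiliation_table(bundle["occurrences"], bundle["grid_t"], bundle["grid_p"])
        vals = included_values(table, "t_opt")
        jk = jackknife_contributions(plots, vals, weighting="stem")
        base = jk.attrs["rate_all"]
        rng = np.random.default_rng(0)
        some = rng.choice(jk.index.to_numpy(), size=6, replace=False)
        for sp in some:
            rates = []
            for p in plots:
                stems = p.stems[p.stems["species"] != sp]
                sub = build_series([], p.censuses)
                sub.stems = stems
                r = mean_annual_rate([sub], vals, weighting="stem")
                rates.append(r)
            oracle = float(np.nanmean([r for r in rates if np.isfinite(r)]))
            assert jk.loc[sp, "rate_jackknife"] == pytest.approx(oracle, abs=1e-12)
            assert jk.loc[sp, "contribution"] == pytest.approx((oracle - base) / base, abs=1e-9)

    def test_zero_trend_raises(self, ab_optima):
        records = [(t, s, ci, d, True) for ci in (0, 1) for t, s, d in
                   [("x1", "A", 12), ("x2", "B", 20)]]
        series = build_series(records, [2010.0, 2015.0])
        with pytest.raises(ValueError, match="zero or undefined"):
            jackknife_contributions([series], ab_optima)


class TestSizeClasses:
    def test_boundary_stem_in_upper_class(self, ab_optima):
        series = build_series([("x1", "A", 0, 30.0, True)], [2010.0, 2015.0])
        out = size_class_summary(series, ab_optima)
        assert out.loc["30-50", "n_stems"] == 1
        assert out.loc["10-30", "n_stems"] == 0

    def test_monospecific_classes_share_mean(self, ab_optima):
        series = build_series(
            [("x1", "A", 0, 15, True), ("x2", "A", 0, 35, True), ("x3", "A", 0, 75, True)],
            [2010.0, 2015.0],
        )
        out = size_class_summary(series, ab_optima)
        filled = out[out["n_stems"] > 0]
        assert np.allclose(filled["mean"], 10.0)
        assert out.loc["50-70", "n_stems"] == 0

    def test_matches_groupby_oracle(self, bundle):
        from thermoshift.thermal_affiliation import build_affiliation_table, included_values

        p = bundle["plots"][0]
        table = build_affiliation_table(bundle["occurrences"], bundle["grid_t"], bundle["grid_p"])
        vals = included_values(table, "t_opt")
        out = size_class_summary(p, vals)
        stems = p.census(0).assign(opt=lambda d: d["species"].map(vals))
        bins = pd.cut(stems["diameter_cm"], [10, 30, 50, 70, np.inf], right=False)
        oracle = stems.groupby(bins, observed=False)["opt"].agg(["count", "mean", "std"])
        for (label, row), (_, orow) in zip(out.iterrows(), oracle.iterrows()):
            if row["n_with_attribute"] > 1:
                assert row["mean"] == pytest.approx(orow["mean"])
                assert row["sd"] == pytest.approx(orow["std"])


def test_signed_sqrt_sign_and_monotone():
    x = np.array([-4.0, -0.25, 0.0, 0.25, 4.0])
    out = signed_sqrt(x)
    np.testing.assert_allclose(out, [-2.0, -0.5, 0.0, 0.5, 2.0])
    assert (np.diff(out) > 0).all()
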