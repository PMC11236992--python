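"""Occurrence cleaning, per-species optima, niche breadth, threshold curve."""

import numpy as np
import pandas as pd
import pytest

from thermoshift.io_formats import ClimateGrid
from thermoshift.thermal_affiliation import (
    build_affiliation_table,
    clean_occurrences,
    dedupe_by_cell,
    niche_breadth,
    species_optimum,
    threshold_error_curve,
)


def occ_frame(lons, lats, species="Aa bb", years=None, flagged=None):
    n = len(lons)
    return pd.DataFrame(
        {
            "species": species if isinstance(species, list) else [species] * n,
            "lon": lons,
            "lat": lats,
            "year": years if years is not None else [2000] * n,
            "flagged": flagged if flagged is not None else [False] * n,
        }
    )


@pytest.fixture(scope="module")
def water_grid():
    """5x5 grid of MAT 15 with a nodata 'lake' at cell (2, 2)."""
    values = np.full((5, 5), 15.0)
    values[2, 2] = -9999.0
    return ClimateGrid(variable="MAT", origin_lon=0, origin_lat=0, cell_size=1.0, values=values)


class TestCleaning:
    def test_flagged_records_removed(self, water_grid):
        occ = occ_frame([0.5] * 10, [0.5] * 10, flagged=[True] * 2 + [False] * 8)
        assert len(clean_occurrences(occ, water_grid)) == 8

    def test_record_over_water_removed(self, water_grid):
        occ = occ_frame([2.5, 0.5], [2.5, 0.5])  # first falls in the lake cell
        out = clean_occurrences(occ, water_grid)
        assert len(out) == 1 and out["lon"].iloc[0] == 0.5

    def test_year_cutoff_matches_independent_filter(self, water_grid):
        rng = np.random.default_rng(3)
        years = rng.integers(1950, 2023, 60)
        occ = occ_frame(
            rng.uniform(0, 5, 60), rng.uniform(0, 2, 60), years=years
        )
        out = clean_occurrences(occ, water_grid, since=1980)
        assert len(out) == int((years >= 1980).sum())


class TestDedupe:
    def test_three_records_one_cell(self, water_grid):
        occ = occ_frame([0.2, 0.5, 0.8], [0.5, 0.5, 0.9])
        assert len(dedupe_by_cell(occ, water_grid)) == 1

    def test_edge_straddling_records_both_kept(self, water_grid):
        # lon 0.999 in column 0, lon 1.0 on the shared edge belongs to column 1
        occ = occ_frame([0.999, 1.0], [0.5, 0.5])
        assert len(dedupe_by_cell(occ, water_grid)) == 2

    def test_per_species_not_per_cell(self, water_grid):
        occ = occ_frame([0.5, 0.5], [0.5, 0.5], species=["Aa bb", "Cc dd"])
        assert len(dedupe_by_cell(occ, water_grid)) == 2

    def test_random_cloud_matches_set_count_oracle(self, ramp_grid):
        rng = np.random.default_rng(11)
        n = 500
        species = rng.choice(["S1", "S2", "S3"], n).tolist()
        occ = occ_frame(rng.uniform(0, 5, n), rng.uniform(0, 5, n), species=species)
        out = dedupe_by_cell(occ, ramp_grid)
        # brute-force distinct (species, cell) pairs
        pairs = {
            (sp, int(lat // 0.5), int(lon // 0.5))
            for sp, lon, lat in zip(occ["species"], occ["lon"], occ["lat"])
        }
        assert len(out) == len(pairs)

    def test_idempotent(self, ramp_grid):
        rng = np.random.default_rng(5)
        occ = occ_frame(rng.uniform(0, 5, 200), rng.uniform(0, 5, 200))
        once = dedupe_by_cell(occ, ramp_grid)
        twice = dedupe_by_cell(once, ramp_grid)
        pd.testing.assert_frame_equal(once, twice)


class TestOptimum:
    def test_single_record(self, const_grid):
        val, n = species_optimum(occ_frame([0.7], [0.7]), const_grid)
        assert val == pytest.approx(17.3) and n == 1

    def test_two_cells_mean(self, ramp_grid):
        # cells (0,0)=0 and (2,0)=20 -> mean 10
        val, n = species_optimum(occ_frame([0.1, 0.1], [0.1, 1.2]), ramp_grid)
        assert val == pytest.approx(10.0) and n == 2

    def test_matches_extraction_loop_oracle(self, ramp_grid):
        rng = np.random.default_rng(21)
        occ = occ_frame(rng.uniform(0, 5, 25), rng.uniform(0, 5, 25))
        val, n = species_optimum(occ, ramp_grid)
        manual = [ramp_grid.extract(lo, la) for lo, la in zip(occ["lon"], occ["lat"])]
        assert n == 25
        assert val == pytest.approx(np.mean(manual), abs=1e-12)

    def test_permutation_invariant(self, ramp_grid):
        rng = np.random.default_rng(22)
        occ = occ_frame(rng.uniform(0, 5, 30), rng.uniform(0, 5, 30))
        shuffled = occ.sample(frac=1, random_state=1).reset_index(drop=True)
        assert species_optimum(occ, ramp_grid)[0] == pytest.approx(
            species_optimum(shuffled, ramp_grid)[0]
        )

    def test_no_usable_records_gives_missing(self, water_grid):
        val, n = species_optimum(occ_frame([2.5], [2.5]), water_grid)  # lake only
        assert np.isnan(val) and n == 0


class TestNicheBreadth:
    def test_constant_records_zero(self, const_grid):
        occ = occ_frame([0.1, 0.7, 1.3], [0.1, 0.7, 1.3])
        assert niche_breadth(occ, const_grid) == pytest.approx(0.0)

    def test_eleven_evenly_spaced_values(self):
        """Values 10..20 give q95 - q5 = 9.0 under linear interpolation
        between order statistics (h = (n-1)p + 1 -> 19.5 - 10.5)."""
        grid = ClimateGrid(
            variable="MAT", origin_lon=0, origin_lat=0, cell_size=1.0,
            values=np.arange(10.0, 21.0).reshape(1, 11),
        )
        occ = occ_frame(np.arange(11) + 0.5, [0.5] * 11)
        assert niche_breadth(occ, grid) == pytest.approx(9.0)

    def test_bounded_by_range(self, ramp_grid):
        rng = np.random.default_rng(8)
        occ = occ_frame(rng.uniform(0, 5, 40), rng.uniform(0, 5, 40))
        b = niche_breadth(occ, ramp_grid)
        vals = ramp_grid.extract(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        assert 0.0 <= b <= vals.max() - vals.min()


class TestThresholdCurve:
    def test_zero_variance_species(self, const_grid):
        rng = np.random.default_rng(1)
        occ = occ_frame(rng.uniform(0, 5, 30), rng.uniform(0, 5, 30))
        curve = threshold_error_curve(occ, const_grid, [5, 10, 20], replicates=20, seed=0)
        np.testing.assert_allclose(curve.mean_abs_error, 0.0, atol=1e-12)

    def test_full_sample_error_zero(self, ramp_grid):
        rng = np.random.default_rng(2)
        occ = occ_frame(rng.uniform(0, 5, 20), rng.uniform(0, 5, 20))
        curve = threshold_error_curve(occ, ramp_grid, [20], replicates=5, seed=0)
        assert curve.mean_abs_error[0] == pytest.approx(0.0, abs=1e-12)

    def test_oversized_subsample_skipped_with_warning(self, ramp_grid):
        occ = occ_frame([0.1, 1.1, 2.1], [0.1, 1.1, 2.1])
        with pytest.warns(UserWarning, match="exceeds record count"):
            curve = threshold_error_curve(occ, ramp_grid, [2, 10], replicates=5, seed=0)
        assert curve.sizes.tolist() == [2]

    def test_matches_resampling_oracle_and_decreases(self):
        """For records drawn from a normal niche, the mean subsampling error
        tracks an independent resampling estimate of E|mean_n - mean_full|
        and is non-increasing in n (within 2 SE)."""
        rng = np.random.default_rng(77)
        vals = rng.normal(15.0, 3.0, 120)
        # one distinct cell per record so extraction returns vals verbatim
        grid = ClimateGrid(
            variable="MAT", origin_lon=0, origin_lat=0, cell_size=1.0,
            values=vals.reshape(1, -1).copy(),
        )
        occ = occ_frame(np.arange(120) + 0.5, [0.5] * 120)
        sizes = [5, 15, 60]
        curve = threshold_error_curve(occ, grid, sizes, replicates=400, seed=1)
        oracle_rng = np.random.default_rng(999)
        full = vals.mean()
        for i, n in enumerate(sizes):
            errs = np.array(
                [abs(oracle_rng.choice(vals, n, replace=False).mean() - full) for _ in range(1500)]
            )
            se = errs.std(ddof=1) * np.sqrt(1 / 1500 + 1 / 400)
            assert curve.mean_abs_error[i] == pytest.approx(errs.mean(), abs=3 * se)
        assert curve.mean_abs_error[0] > curve.mean_abs_error[1] > curve.mean_abs_error[2]


class TestAffiliationTable:
    def test_composition_matches_single_species_ops(self, bundle):
        occ, gt, gp = bundle["occurrences"], bundle["grid_t"], bundle["grid_p"]
        table = build_affiliation_table(occ, gt, gp, threshold=10)
        clean = dedupe_by_cell(clean_occurrences(occ, gt), gt)
        for sp in list(table.index)[:8]:
            grp = clean[clean["species"] == sp]
            t, n = species_optimum(grp, gt)
            assert table.loc[sp, "t_opt"] == pytest.approx(t)
            assert table.loc[sp, "n_records"] == n
            assert table.loc[sp, "included"] == (n >= 10)
            assert table.loc[sp, "niche_breadth_t"] == pytest.approx(niche_breadth(grp, gt))

    def test_threshold_monotonicity(self, bundle):
        occ, gt, gp = bundle["occurrences"], bundle["grid_t"], bundle["grid_p"]
        t0 = build_affiliation_table(occ, gt, gp, threshold="none")
        t10 = build_affiliation_table(occ, gt, gp, threshold=10)
        t30 = build_affiliation_table(occ, gt, gp, threshold="strict")
        inc0 = set(t0.index[t0["included"]])
        inc10 = set(t10.index[t10["included"]])
        inc30 = set(t30.index[t30["included"]])
        assert inc30 <= inc10 <= inc0
        assert inc0 == set(t0.index)

    def test_optimum_bounded_by_observed_range(self, bundle):
        """min observed MAT <= t_opt <= max observed MAT, per species."""
        occ, gt, gp = bundle["occurrences"], bundle["grid_t"], bundle["grid_p"]
        table = build_affiliation_table(occ, gt, gp)
        clean = dedupe_by_cell(clean_occurrences(occ, gt), gt)
        vals = gt.extract(clean["lon"].to_numpy(), clean["lat"].to_numpy())
        clean = clean.assign(mat=vals)
        by_sp = clean.groupby("species")["mat"]
        lo, hi = by_sp.min(), by_sp.max()
        assert (table["t_opt"] >= lo.reindex(table.index) - 1e-12).all()
        assert (table["t_opt"] <= hi.reindex(table.index) + 1e-12).all()


def test_optimum_error_shrinks_with_record_count():
    """Estimator consistency: |t_opt - mu| declines in log n (negative slope)."""
    from thermoshift.experiments import optimum_recovery

    df = optimum_recovery(sizes=(5, 20, 80), n_species=40, seed=3)
    slope = np.polyfit(np.log(df["n"]), df["mae"], 1)[0]
    assert slope < 0
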