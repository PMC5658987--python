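import itertools

import numpy as np
import pandas as pd
import pytest

from phylospat.grid_io import GridSpec, PresenceMatrix
from phylospat.range_model import (
    BinaryRange,
    RangeModelConfig,
    SuitabilitySurface,
    aggregate_to_coarse,
    auc,
    downsample_to_grid,
    fit_suitability,
    gaussian_distance_weight,
    hybrid_range,
    range_expansion_stats,
    sample_background,
    sss_threshold,
    threshold_range,
    union_otu_ranges,
)
from phylospat.synthdata import gen_climate, gen_sdm_truth

FINE = GridSpec(0.0, 0.0, 810.0)


def occ(names, xs, ys):
    return pd.DataFrame({"name": names, "x": xs, "y": ys})


class TestDownsample:
    def test_five_records_one_cell(self):
        df = downsample_to_grid(occ(["s"] * 5, [1, 2, 3, 4, 5], [1] * 5), FINE)
        assert len(df) == 1
        assert (df.loc[0, "x"], df.loc[0, "y"]) == (405.0, 405.0)

    def test_three_cells(self):
        df = downsample_to_grid(occ(["s"] * 3, [1, 1000, 2000], [1, 1, 1]), FINE)
        assert len(df) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = occ(
            rng.choice(["a", "b"], 50), rng.uniform(0, 5000, 50), rng.uniform(0, 5000, 50)
        )
        once = downsample_to_grid(df, FINE)
        twice = downsample_to_grid(once, FINE)
        assert len(once) == len(twice)
        assert np.allclose(
            once[["x", "y"]].to_numpy(), twice[["x", "y"]].to_numpy()
        )


class TestBackground:
    def test_draws_from_pool(self):
        pool = occ(["a", "b", "c"], [0.0, 900.0, 1800.0], [0.0, 0.0, 0.0])
        out = sample_background(pool, 10, seed=1)
        assert out.shape == (10, 2)
        assert {tuple(r) for r in out} <= {(0.0, 0.0), (900.0, 0.0), (1800.0, 0.0)}

    def test_deterministic(self):
        pool = occ(["a"] * 5, np.arange(5.0), np.zeros(5))
        assert np.array_equal(
            sample_background(pool, 20, seed=3), sample_background(pool, 20, seed=3)
        )

    def test_empty_pool(self):
        with pytest.raises(ValueError):
            sample_background(occ([], [], []), 5, seed=0)

    def test_uniformity_chisquare(self):
        from scipy.stats import chisquare

        pool = occ([f"s{i}" for i in range(20)], np.arange(20.0) * 900, np.zeros(20))
        out = sample_background(pool, 10_000, seed=7)
        counts = pd.Series([tuple(r) for r in out]).value_counts()
        stat, p = chisquare(counts.reindex(
            [(i * 900.0, 0.0) for i in range(20)], fill_value=0
        ))
        assert p > 1e-4  # uniform draws should not be wildly rejected


class TestAuc:
    def test_perfect(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_sets(self):
        assert auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_pair_counting_value(self):
        assert auc([0.9, 0.3], [0.6, 0.1]) == 0.75

    def test_matches_exhaustive_pairs(self):
        rng = np.random.default_rng(1)
        p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=30)
        b = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=40)
        wins = sum(
            1.0 if pi > bi else 0.5 if pi == bi else 0.0
            for pi, bi in itertools.product(p, b)
        )
        assert auc(p, b) == pytest.approx(wins / (len(p) * len(b)))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestSssThreshold:
    def test_worked_example(self):
        t = sss_threshold([0.9, 0.6, 0.4], [0.8, 0.3, 0.2, 0.1])
        assert t == 0.4

    def test_perfectly_separated_smallest_candidate(self):
        # any threshold in (0.4, 0.6] separates; smallest candidate wins
        t = sss_threshold([0.6, 0.7], [0.3, 0.4])
        assert t == 0.6

    def test_degenerate_all_equal(self):
        t = sss_threshold([0.5, 0.5], [0.5])
        assert t == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(25)
        b = rng.random(35)
        t = sss_threshold(p, b)
        best = max(
            np.unique(np.concatenate([p, b])),
            key=lambda c: ((p >= c).mean() + (b < c).mean(), -c),
        )
        assert t == pytest.approx(best)


class TestGaussianWeight:
    def test_zero_distance(self):
        w = gaussian_distance_weight([[0.0, 0.0]], [[0.0, 0.0]], sigma=50_000)
        assert w[0] == 1.0

    def test_one_sigma(self):
        w = gaussian_distance_weight([[50_000.0, 0.0]], [[0.0, 0.0]], sigma=50_000)
        assert w[0] == pytest.approx(np.exp(-0.5))

    def test_monotone_decay(self):
        centers = [[d, 0.0] for d in np.linspace(0, 200_000, 21)]
        w = gaussian_distance_weight(centers, [[0.0, 0.0]], sigma=50_000)
        assert (np.diff(w) < 0).all()

    def test_nearest_record_used(self):
        w = gaussian_distance_weight(
            [[0.0, 0.0]], [[1e6, 0.0], [0.0, 0.0]], sigma=50_000
        )
        assert w[0] == 1.0

    def test_no_records_errors(self):
        with pytest.raises(ValueError):
            gaussian_distance_weight([[0.0, 0.0]], np.empty((0, 2)), sigma=1.0)


def _toy_surface(values, n=10):
    cells = [(i, 0) for i in range(n)]
    return SuitabilitySurface(GridSpec(0, 0, 810.0), cells, values)


@pytest.fixture(scope="module")
def climate_grid():
    grid = GridSpec(0, 0, 810.0)
    clim = gen_climate(grid, (20, 20), seed=5, noise_sd=0.0)
    return grid, clim


class TestFitSuitability:
    def test_monotone_in_single_variable(self, climate_grid):
        grid, clim = climate_grid
        from phylospat.grid_io import parse_cell_id

        cells = [parse_cell_id(c) for c in clim.index]
        centers = grid.centers_of(cells)
        precip = clim["precip"].to_numpy()
        top = precip >= np.quantile(precip, 0.9)
        rng = np.random.default_rng(0)
        pres = centers[np.flatnonzero(top)[rng.integers(0, top.sum(), 40)]]
        back = centers[rng.integers(0, len(cells), 300)]
        surf = fit_suitability(pres, back, clim[["precip"]], grid)
        from scipy.stats import spearmanr

        # suitability should rise monotonically with precipitation
        rho, _ = spearmanr(precip, surf.values)
        assert rho > 0.95
        order = np.argsort(precip)
        fitted = surf.values[order]
        assert fitted[-10:].mean() > fitted[:10].mean()

    def test_null_discrimination_near_chance(self, climate_grid):
        grid, clim = climate_grid
        from phylospat.grid_io import parse_cell_id

        cells = [parse_cell_id(c) for c in clim.index]
        centers = grid.centers_of(cells)
        rng = np.random.default_rng(1)
        pres = centers[rng.integers(0, len(cells), 200)]
        back = centers[rng.integers(0, len(cells), 2000)]
        surf = fit_suitability(pres, back, clim, grid)
        a = auc(surf.score_at(pres), surf.score_at(back))
        assert 0.45 <= a <= 0.55

    def test_quadratic_peak_at_presence_climate(self, climate_grid):
        grid, clim = climate_grid
        from phylospat.grid_io import parse_cell_id

        cells = [parse_cell_id(c) for c in clim.index]
        centers = grid.centers_of(cells)
        precip = clim["precip"].to_numpy()
        mid = np.abs(precip - np.median(precip)) <= 30
        rng = np.random.default_rng(2)
        pres = centers[np.flatnonzero(mid)[rng.integers(0, mid.sum(), 50)]]
        back = centers[rng.integers(0, len(cells), 500)]
        surf = fit_suitability(pres, back, clim[["precip"]], grid)
        peak = precip[np.argmax(surf.values)]
        assert abs(peak - np.median(precip)) <= np.ptp(precip) * 0.2

    def test_too_few_presences(self, climate_grid):
        grid, clim = climate_grid
        with pytest.raises(ValueError, match="presences"):
            fit_suitability(
                np.zeros((2, 2)) + 405.0, np.zeros((10, 2)) + 405.0, clim, grid
            )

    def test_constant_variable_dropped(self, climate_grid):
        grid, clim = climate_grid
        clim2 = clim.copy()
        clim2["flat"] = 1.0
        from phylospat.grid_io import parse_cell_id

        cells = [parse_cell_id(c) for c in clim2.index]
        centers = grid.centers_of(cells)
        rng = np.random.default_rng(3)
        pres = centers[rng.integers(0, len(cells), 30)]
        back = centers[rng.integers(0, len(cells), 100)]
        surf = fit_suitability(pres, back, clim2, grid)  # warns, does not raise
        assert np.isfinite(surf.values).all()


class TestHybridRange:
    def test_sigma_infinity_equals_unconstrained(self):
        rng = np.random.default_rng(4)
        vals = rng.random(30)
        surf = _toy_surface(vals, n=30)
        pres = np.array([[405.0 + 810 * i, 405.0] for i in range(0, 10)])
        back = np.array([[405.0 + 810 * i, 405.0] for i in range(0, 30, 2)])
        w = gaussian_distance_weight(surf.centers(), pres, sigma=1e12)
        assert np.allclose(w, 1.0)
        hyb = hybrid_range(surf, w, pres, back)
        unc = threshold_range(surf, pres, back)
        assert hyb.cells == unc.cells

    def test_product_scores_monotone_in_sigma(self):
        surf = _toy_surface(np.linspace(0.2, 0.9, 30), n=30)
        pres = np.array([[405.0, 405.0]])
        w1 = gaussian_distance_weight(surf.centers(), pres, sigma=10_000)
        w2 = gaussian_distance_weight(surf.centers(), pres, sigma=40_000)
        assert (surf.values * w1 <= surf.values * w2 + 1e-15).all()

    def test_extent_shrinks_as_sigma_decreases(self):
        rng = np.random.default_rng(5)
        vals = np.clip(rng.random(40) * 0.8 + 0.1, 0, 1)
        surf = _toy_surface(vals, n=40)
        pres = np.array([[405.0 + 810 * i, 405.0] for i in range(5)])
        back = np.array([[405.0 + 810 * i, 405.0] for i in range(0, 40, 3)])
        unc = threshold_range(surf, pres, back)
        sizes = []
        for sigma in [1e9, 50_000, 10_000, 2_000]:
            w = gaussian_distance_weight(surf.centers(), pres, sigma)
            # fixed threshold from the unconstrained model for the nesting law
            t = sss_threshold(surf.score_at(pres), surf.score_at(back))
            cells = {
                c for c, v in zip(surf.cells, surf.values * w) if v >= t
            }
            sizes.append(len(cells))
        assert sizes[0] == len(unc.cells)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_distant_suitable_cell_excluded(self):
        # a highly suitable cell 5 sigma away drops out of the hybrid range
        vals = np.array([0.9] + [0.5] * 8 + [0.95])
        surf = _toy_surface(vals, n=10)
        sigma = 810.0
        pres = np.array([[405.0, 405.0], [405.0 + 810, 405.0]])
        back = np.array([[405.0 + 810 * i, 405.0] for i in range(10)])
        unc = threshold_range(surf, pres, back)
        assert (9, 0) in unc.cells
        w = gaussian_distance_weight(surf.centers(), pres, sigma)
        hyb = hybrid_range(surf, w, pres, back)
        assert (9, 0) not in hyb.cells

    def test_grid_mismatch(self):
        surf = _toy_surface(np.full(5, 0.5), n=5)
        with pytest.raises(ValueError):
            hybrid_range(surf, np.ones(4), np.zeros((1, 2)), np.zeros((1, 2)))


class TestUnionsAndAggregation:
    def test_union_disjoint(self):
        g = FINE
        r1 = BinaryRange("a", frozenset({(0, 0), (1, 0), (2, 0)}), g)
        r2 = BinaryRange("b", frozenset({(5, 5), (6, 5), (7, 5), (8, 5)}), g)
        out = union_otu_ranges({"a": r1, "b": r2}, {"a": "X", "b": "X"})
        assert out["X"].n_cells == 7

    def test_single_species_identity(self):
        g = FINE
        r1 = BinaryRange("a", frozenset({(0, 0)}), g)
        out = union_otu_ranges({"a": r1}, {"a": "X"})
        assert out["X"].cells == r1.cells

    def test_union_superset(self):
        g = FINE
        r1 = BinaryRange("a", frozenset({(0, 0), (1, 1)}), g)
        r2 = BinaryRange("b", frozenset({(1, 1), (2, 2)}), g)
        out = union_otu_ranges({"a": r1, "b": r2}, {"a": "X", "b": "X"})
        assert r1.cells <= out["X"].cells and r2.cells <= out["X"].cells

    def test_unmapped_errors(self):
        r1 = BinaryRange("a", frozenset({(0, 0)}), FINE)
        with pytest.raises(KeyError):
            union_otu_ranges({"a": r1}, {})

    def test_aggregate_single_cell(self):
        coarse = GridSpec(0, 0, 8100.0)
        r = BinaryRange("a", frozenset({(12, 3)}), FINE)
        out = aggregate_to_coarse(r, FINE, coarse)
        assert out.cells == frozenset({(1, 0)})

    def test_aggregate_full_grid(self):
        coarse = GridSpec(0, 0, 1620.0)
        r = BinaryRange("a", frozenset((i, j) for i in range(4) for j in range(4)), FINE)
        out = aggregate_to_coarse(r, FINE, coarse)
        assert out.cells == frozenset((i, j) for i in range(2) for j in range(2))

    def test_aggregate_monotone(self):
        coarse = GridSpec(0, 0, 1620.0)
        small = BinaryRange("a", frozenset({(0, 0)}), FINE)
        big = BinaryRange("a", frozenset({(0, 0), (3, 3)}), FINE)
        assert (
            aggregate_to_coarse(small, FINE, coarse).cells
            <= aggregate_to_coarse(big, FINE, coarse).cells
        )


class TestExpansionStats:
    def make_pair(self, obs_counts, mod_counts):
        taxa = [f"t{k}" for k in range(len(obs_counts))]
        g = GridSpec()

        def mat(counts):
            n = max(counts)
            X = np.zeros((n, len(taxa)), dtype=bool)
            for k, c in enumerate(counts):
                X[:c, k] = True
            return PresenceMatrix([(i, 0) for i in range(n)], taxa, X, g)

        return mat(obs_counts), mat(mod_counts)

    def test_ratio(self):
        obs, mod = self.make_pair([2], [10])
        stats = range_expansion_stats(obs, mod)
        assert stats["ratio"].iloc[0] == 5.0

    def test_identity(self):
        obs, mod = self.make_pair([4, 7], [4, 7])
        stats = range_expansion_stats(obs, mod)
        assert (stats["ratio"] == 1.0).all()

    def test_taxon_mismatch(self):
        obs, _ = self.make_pair([2], [3])
        mod, _ = self.make_pair([2, 3], [3, 4])
        with pytest.raises(ValueError):
            range_expansion_stats(obs, mod)


class TestEndToEndRecovery:
    def test_known_truth_jaccard(self):
        grid = GridSpec(0, 0, 810.0)
        clim = gen_climate(grid, (25, 25), seed=9, noise_sd=0.0)
        truth, occ_df = gen_sdm_truth(
            grid, clim, {"precip": 3.0, "cwd": -1.0}, n_presences=200, seed=9,
            intercept=-2.0,
        )
        pres = downsample_to_grid(occ_df, grid)[["x", "y"]].to_numpy()
        rng = np.random.default_rng(10)
        centers = truth.centers()
        back = centers[rng.integers(0, len(centers), 1000)]
        surf = fit_suitability(pres, back, clim, grid)
        modeled = threshold_range(surf, pres, back)
        true_cells = {
            c for c, v in zip(truth.cells, truth.values) if v >= 0.5
        }
        inter = len(modeled.cells & true_cells)
        union = len(modeled.cells | true_cells)
        assert union > 0
        assert inter / union >= 0.6
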