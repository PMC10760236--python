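import numpy as np
import pytest
from shapely.geometry import Polygon

from neurospot import (DendriteBranch, NeuronGeometry, SimulationError,
                       SpineSet, SpotTable, assign_spots, coexistence,
                       compare_to_null, nearest_distances,
                       null_mean_nearest_distance, simulate_null,
                       spine_occupancy)


def table(points):
    pts = np.asarray(points, dtype=float)
    return SpotTable(xyz=pts, intensity=np.full(len(pts), 100.0),
                     channel_label="mrna")


def manual_spines(points, bins):
    pts = np.asarray(points, dtype=float)
    return SpineSet(xyz=pts, branch=np.zeros(len(pts), dtype=int),
                    path_distance=np.zeros(len(pts)),
                    bin=np.asarray(bins, dtype=int))


def single_row_geometry():
    """Branch mask exactly one pixel wide (one row of pixel centers)."""
    soma = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
    branch = DendriteBranch(np.array([[1000.0, 550.0], [2000.0, 550.0]]),
                            half_width=30.0)
    return NeuronGeometry(soma=soma, branches=[branch], pixel_size_xy=100.0)


class TestObservedStatistics:
    def test_spine_radius_boundary_is_closed(self):
        spines = manual_spines([[0.0, 0.0, 0.0]], [0])
        near = spine_occupancy(np.array([[600.0, 0.0, 0.0]]), spines,
                               600.0, n_bins=1)
        far = spine_occupancy(np.array([[601.0, 0.0, 0.0]]), spines,
                              600.0, n_bins=1)
        assert near.loc[0, "freq_1"] == 1.0
        assert far.loc[0, "freq_0"] == 1.0

    def test_occupancy_uses_3d_distance(self):
        spines = manual_spines([[0.0, 0.0, 0.0]], [0])
        mrna = np.array([[500.0, 0.0, 500.0]])  # 707 nm in 3D, 500 in-plane
        assert spine_occupancy(mrna, spines, 600.0, 1,
                               mode="3d").loc[0, "freq_0"] == 1.0
        assert spine_occupancy(mrna, spines, 600.0, 1,
                               mode="2d").loc[0, "freq_1"] == 1.0

    def test_occupancy_matches_brute_force(self):
        rng = np.random.default_rng(3)
        mrna = np.column_stack([rng.uniform(0, 5000, 10),
                                rng.uniform(0, 5000, 10),
                                rng.uniform(0, 600, 10)])
        sp_xyz = np.column_stack([rng.uniform(0, 5000, 3),
                                  rng.uniform(0, 5000, 3),
                                  rng.uniform(0, 600, 3)])
        bins = [0, 1, 1]
        spines = manual_spines(sp_xyz, bins)
        r = 1500.0
        out = spine_occupancy(mrna, spines, r, n_bins=2)
        # exhaustive O(n*m) count
        counts = [(np.linalg.norm(mrna - s, axis=1) <= r).sum()
                  for s in sp_xyz]
        for k in range(2):
            ck = [c for c, b in zip(counts, bins) if b == k]
            assert out.loc[k, "freq_0"] == pytest.approx(
                np.mean([c == 0 for c in ck]))
            assert out.loc[k, "freq_1"] == pytest.approx(
                np.mean([c == 1 for c in ck]))
            assert out.loc[k, "freq_2plus"] == pytest.approx(
                np.mean([c >= 2 for c in ck]))

    def test_coexistence_boundary_and_zero_distance(self):
        ref = np.array([[0.0, 0.0, 0.0]])
        out = coexistence(ref, [0], np.array([[0.0, 0.0, 0.0]]), 700.0, 1)
        assert out.loc[0, "frac_coexisting"] == 1.0
        assert out.loc[0, "mean_nn_dist"] == 0.0
        out = coexistence(ref, [0], np.array([[700.0, 0.0, 0.0]]), 700.0, 1)
        assert out.loc[0, "frac_coexisting"] == 1.0
        out = coexistence(ref, [0], np.array([[700.5, 0.0, 0.0]]), 700.0, 1)
        assert out.loc[0, "frac_coexisting"] == 0.0

    def test_coexistence_matches_brute_force(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 3000, size=(5, 3))
        par = rng.uniform(0, 3000, size=(5, 3))
        bins = [0, 0, 1, 1, 1]
        out = coexistence(ref, bins, par, 700.0, 2)
        nn = [min(np.linalg.norm(par - r, axis=1)) for r in ref]
        for k in range(2):
            sel = [d for d, b in zip(nn, bins) if b == k]
            assert out.loc[k, "frac_coexisting"] == pytest.approx(
                np.mean([d <= 700.0 for d in sel]))
            assert out.loc[k, "mean_nn_dist"] == pytest.approx(np.mean(sel))

    def test_empty_partner_channel_flagged(self):
        out = coexistence(np.array([[0.0, 0.0, 0.0]]), [0],
                          np.empty((0, 3)), 700.0, 1)
        assert out.loc[0, "frac_coexisting"] == 0.0
        assert np.isnan(out.loc[0, "mean_nn_dist"])
        assert np.all(np.isinf(nearest_distances(np.zeros((2, 3)),
                                                 np.empty((0, 3)))))


class TestNullEnsemble:
    def test_counts_conserved_and_contained(self, square_geometry):
        rng = np.random.default_rng(7)
        attach = square_geometry.branches[0].skeleton[0]
        pts = np.column_stack([
            attach[0] + rng.uniform(0, 74_000, 30),
            attach[1] + rng.uniform(-400, 400, 30),
            rng.uniform(0, 600, 30)])
        spots = table(pts)
        assignment = assign_spots(spots, square_geometry)
        ens = simulate_null(assignment, spots, square_geometry, n_sim=20,
                            rng=np.random.default_rng(0))
        dend = assignment[assignment["compartment"] == "dendrite"]
        obs_counts = dend.groupby("bin").size()
        raster = square_geometry.raster
        ps = square_geometry.pixel_size_xy
        for pos in ens.positions:
            assert len(pos) == len(dend)
            for k, c in obs_counts.items():
                sel = ens.bin == k
                assert sel.sum() == c
                mask = raster.bin_mask(0, k, 25_000.0)
                keys = {tuple(q) for q in np.floor(
                    (mask - raster.origin) / ps).astype(int)}
                pix = np.floor((pos[sel][:, :2]
                                - raster.origin) / ps).astype(int)
                assert all(tuple(q) in keys for q in pix)

    def test_single_pixel_bin_is_degenerate(self):
        geom = single_row_geometry()
        spots = table([[1060.0, 552.0, 0.0]])
        assignment = assign_spots(spots, geom, bin_width=100.0)
        assert assignment.iloc[0]["bin"] == 0
        ens = simulate_null(assignment, spots, geom, n_sim=30,
                            rng=np.random.default_rng(1), bin_width=100.0,
                            n_bins=10, z_mode="zero")
        center = np.array([1050.0, 550.0])
        # every repeat lands in the same (only) pixel of the bin
        def stat(pos):
            d = np.linalg.norm(pos[:, :2] - center, axis=1)
            return np.array([(d <= 80.0).sum()] + [np.nan] * 9)
        values, mean, sd = ens.summarize(stat)
        assert mean[0] == 1.0 and sd[0] == 0.0

    def test_more_spots_than_pixels_raises(self):
        geom = single_row_geometry()
        spots = table([[1060.0, 552.0, 0.0], [1040.0, 548.0, 0.0]])
        assignment = assign_spots(spots, geom, bin_width=100.0)
        with pytest.raises(SimulationError):
            simulate_null(assignment, spots, geom, n_sim=2,
                          rng=np.random.default_rng(1), bin_width=100.0)

    def test_seed_determinism(self, square_geometry):
        rng = np.random.default_rng(5)
        attach = square_geometry.branches[0].skeleton[0]
        pts = np.column_stack([
            attach[0] + rng.uniform(0, 70_000, 15),
            attach[1] + rng.uniform(-400, 400, 15),
            np.zeros(15)])
        spots = table(pts)
        assignment = assign_spots(spots, square_geometry)
        e1 = simulate_null(assignment, spots, square_geometry, 5,
                           np.random.default_rng(123))
        e2 = simulate_null(assignment, spots, square_geometry, 5,
                           np.random.default_rng(123))
        for a, b in zip(e1.positions, e2.positions):
            np.testing.assert_array_equal(a, b)

    def test_simulated_z_is_group_median(self, square_geometry):
        attach = square_geometry.branches[0].skeleton[0]
        pts = np.array([[attach[0] + 1000.0, attach[1], 100.0],
                        [attach[0] + 2000.0, attach[1], 300.0],
                        [attach[0] + 3000.0, attach[1], 800.0]])
        spots = table(pts)
        assignment = assign_spots(spots, square_geometry)
        ens = simulate_null(assignment, spots, square_geometry, 3,
                            np.random.default_rng(0))
        for pos in ens.positions:
            assert np.all(pos[:, 2] == 300.0)


class TestNullComparison:
    def test_observed_equal_to_constant_null_gives_p_one(self):
        out = compare_to_null([3.0, 3.0], np.full(50, 3.0))
        assert out["p_emp"] == 1.0
        assert out["p_welch"] == 1.0

    def test_area_fraction_oracle(self, square_geometry):
        # single spine: MC probability that a uniformly re-drawn mRNA lies
        # within 600 nm must match exhaustive sub-pixel enumeration
        attach = square_geometry.branches[0].skeleton[0]
        hw = square_geometry.branches[0].half_width
        spine = np.array([attach[0] + 37_500.0, attach[1] + hw, 0.0])
        xs = attach[0] + np.array([30_000, 35_000, 40_000, 45_000, 48_000.0])
        spots = table(np.column_stack(
            [xs, np.full(5, attach[1]), np.zeros(5)]))
        assignment = assign_spots(spots, square_geometry)
        assert set(assignment["bin"]) == {1}
        ens = simulate_null(assignment, spots, square_geometry, n_sim=500,
                            rng=np.random.default_rng(11), z_mode="zero")
        allpos = np.concatenate(ens.positions)
        mc = float(np.mean(np.linalg.norm(
            allpos[:, :2] - spine[:2], axis=1) <= 600.0))

        mask = square_geometry.raster.bin_mask(0, 1, 25_000.0)
        ps = square_geometry.pixel_size_xy
        sub = (np.arange(10) + 0.5) / 10 - 0.5
        gx, gy = np.meshgrid(sub * ps, sub * ps)
        offsets = np.column_stack([gx.ravel(), gy.ravel()])
        inside = 0
        for px in mask:
            d = np.linalg.norm(px + offsets - spine[:2], axis=1)
            inside += (d <= 600.0).sum()
        oracle = inside / (len(mask) * len(offsets))

        se = np.sqrt(oracle * (1 - oracle) / len(allpos))
        assert abs(mc - oracle) <= 3 * se

    def test_null_nearest_distance_matches_quadrature(self, square_geometry):
        # one simulated partner per repeat in bin 1, one fixed reference on
        # the skeleton: E[nearest distance] by dense sub-pixel quadrature
        attach = square_geometry.branches[0].skeleton[0]
        ref = np.array([[attach[0] + 37_500.0, attach[1], 0.0]])
        spots = table([[attach[0] + 30_000.0, attach[1], 0.0]])
        assignment = assign_spots(spots, square_geometry)
        n_sim = 300
        ens = simulate_null(assignment, spots, square_geometry, n_sim,
                            np.random.default_rng(2), z_mode="zero")
        out = null_mean_nearest_distance(ens, ref, [1], 700.0, mode="2d")

        mask = square_geometry.raster.bin_mask(0, 1, 25_000.0)
        ps = square_geometry.pixel_size_xy
        sub = (np.arange(8) + 0.5) / 8 - 0.5
        gx, gy = np.meshgrid(sub * ps, sub * ps)
        offsets = np.column_stack([gx.ravel(), gy.ravel()])
        dists = np.concatenate([
            np.linalg.norm(px + offsets - ref[0, :2], axis=1) for px in mask])
        expected = dists.mean()
        se = dists.std() / np.sqrt(n_sim)
        assert abs(out.loc[1, "null_mean_nn_dist"] - expected) <= 3 * se

    def test_quadrupling_repeats_halves_standard_error(self, square_geometry):
        attach = square_geometry.branches[0].skeleton[0]
        ref = np.array([[attach[0] + 37_500.0, attach[1], 0.0]])
        spots = table([[attach[0] + 30_000.0, attach[1], 0.0]])
        assignment = assign_spots(spots, square_geometry)
        root = np.random.default_rng(42)

        def ensemble_mean(n_sim):
            ens = simulate_null(assignment, spots, square_geometry, n_sim,
                                root.spawn(1)[0], z_mode="zero")
            out = null_mean_nearest_distance(ens, ref, [1], 700.0, mode="2d")
            return out.loc[1, "null_mean_nn_dist"]

        small = np.std([ensemble_mean(50) for _ in range(60)])
        large = np.std([ensemble_mean(200) for _ in range(60)])
        assert small / large == pytest.approx(2.0, rel=0.2)
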