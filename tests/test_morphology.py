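"""Super-resolved morphometrics: filtering, drift, clustering, measurement."""

import numpy as np
import pandas as pd
import pytest

from aggrefinger import morphology as morph
from aggrefinger import synthetic as syn
from conftest import brute_force_dbscan


def loc_table(frames, precisions_nm, pixel_size_nm=107.0):
    n = len(frames)
    lp = np.asarray(precisions_nm) / pixel_size_nm
    return pd.DataFrame({
        "frame": frames, "x": np.zeros(n), "y": np.zeros(n),
        "photons": np.full(n, 1000.0), "sx": np.full(n, 1.3),
        "sy": np.full(n, 1.3), "bg": np.full(n, 50.0),
        "lpx": lp, "lpy": lp})


class TestFilter:
    def test_strict_precision_boundary(self):
        t = loc_table([500] * 4, [10, 29.9, 30, 35])
        out = morph.filter_localizations(t)
        np.testing.assert_allclose(out["lpx"] * 107.0, [10, 29.9])

    def test_early_frames_discarded(self):
        t = loc_table([0, 100, 299, 300, 301], [10] * 5)
        out = morph.filter_localizations(t)
        assert list(out["frame"]) == [300, 301]

    def test_all_early_frames_empty_result(self):
        t = loc_table([0, 1, 2], [10] * 3)
        assert morph.filter_localizations(t).empty

    def test_infinite_threshold_is_frame_filter_only(self):
        t = loc_table([100, 400], [10, 999])
        out = morph.filter_localizations(t, max_precision_nm=np.inf)
        assert list(out["frame"]) == [400]

    def test_idempotent(self):
        t = loc_table([500] * 10, np.linspace(5, 40, 10))
        once = morph.filter_localizations(t)
        twice = morph.filter_localizations(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDrift:
    def _dataset(self, drift, seed=3):
        aggs = [syn.GroundTruthAggregate(length_nm=L, n_localizations=400,
                                         center_nm=(cx * 107.0, cy * 107.0),
                                         orientation_rad=o)
                for L, cx, cy, o in [(200, 50, 50, 0.3), (150, 120, 80, 1.2),
                                     (300, 80, 130, 2.1), (100, 60, 110, 0.7)]]
        table, _ = syn.simulate_localization_table(
            aggs, background_rate_per_um2=0.05, drift_px_per_frame=drift,
            n_frames=5000, seed=seed)
        return table

    def test_zero_drift_trace_is_flat(self):
        table = self._dataset((0.0, 0.0))
        _, trace = morph.estimate_and_correct_drift(table, 10)
        rms = np.sqrt((trace[["dx_px", "dy_px"]] ** 2).to_numpy().mean())
        # render bin = 30 nm = 0.28 px; RMS well under 0.1 bins
        assert rms < 0.1 * 30.0 / 107.0

    def test_linear_drift_recovered(self):
        table = self._dataset((0.002, 0.001))
        corrected, trace = morph.estimate_and_correct_drift(table, 10)
        span = trace["frame"].iloc[-1] - trace["frame"].iloc[0]
        rate_x = (trace["dx_px"].iloc[-1] - trace["dx_px"].iloc[0]) / span
        rate_y = (trace["dy_px"].iloc[-1] - trace["dy_px"].iloc[0]) / span
        assert rate_x == pytest.approx(0.002, rel=0.10)
        assert rate_y == pytest.approx(0.001, rel=0.10)
        # corrected cloud is tighter than the drifted one
        assert corrected["x"].std() < table["x"].std()

    def test_single_block_rejected(self):
        table = self._dataset((0.0, 0.0))
        with pytest.raises(ValueError):
            morph.estimate_and_correct_drift(table, 1)


class TestClustering:
    def test_five_points_form_cluster(self):
        xy = np.zeros((5, 2)) + np.arange(5)[:, None] * 0.01
        t = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
        labels = morph.cluster_localizations(t)
        assert set(labels) == {0}

    def test_four_points_are_noise(self):
        t = pd.DataFrame({"x": [0.0] * 4, "y": [0.0] * 4})
        assert set(morph.cluster_localizations(t)) == {-1}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_density_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        xy = rng.uniform(0, 5, size=(n, 2))
        t = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
        got = morph.cluster_localizations(t, 0.5, 5)
        want = brute_force_dbscan(xy, 0.5, 5)
        from sklearn.metrics import adjusted_rand_score
        assert np.array_equal(got == -1, want == -1)
        if len(set(want)) > 1:
            assert adjusted_rand_score(got, want) == 1.0


class TestRegionize:
    def test_identity_when_radii_zero(self):
        xy = np.array([[10.0, 10.0], [10.05, 10.0], [10.1, 10.0]])
        mask, _ = morph.regionize_cluster(xy, render_px_nm=5.35,
                                          dilation_r=0, closing_r=0,
                                          erosion_r=0)
        assert mask.sum() == 3  # exactly the occupied bins

    def test_separate_clusters_give_disjoint_masks(self):
        a = np.array([[10.0, 10.0]])
        b = np.array([[10.0 + 500 / 107, 10.0]])  # 500 nm away
        ma, oa = morph.regionize_cluster(a)
        mb, ob = morph.regionize_cluster(b)
        assert abs(ob[0] - oa[0]) > 400  # origins far apart in nm

    def test_collinear_locs_single_connected_region(self):
        x = 10.0 + np.linspace(0, 200, 21) / 107.0  # 200 nm span, 10 nm steps
        xy = np.column_stack([x, np.full_like(x, 10.0)])
        mask, _ = morph.regionize_cluster(xy)
        from skimage.measure import label
        assert label(mask, connectivity=2).max() == 1

    def test_degenerate_identical_locs(self):
        xy = np.tile([[7.0, 7.0]], (10, 1))
        mask, _ = morph.regionize_cluster(xy)
        assert mask.any()


class TestMeasure:
    def test_filled_disc_geometry(self):
        from skimage.morphology import disk
        mask = disk(20).astype(bool)
        rec = morph.measure_aggregate(mask, np.zeros((50, 2)), render_px_nm=10.0)
        assert rec.eccentricity < 0.05
        assert rec.area_nm2 == pytest.approx(np.pi * 20 ** 2 * 100, rel=0.05)
        assert rec.skeleton_length_nm <= rec.perimeter_nm

    def test_density_is_count_over_area(self):
        mask = np.ones((10, 10), dtype=bool)
        rec = morph.measure_aggregate(mask, np.zeros((50, 2)), render_px_nm=10.0)
        assert rec.density_loc_per_nm2 == pytest.approx(50 / 10000.0)
        assert rec.density_loc_per_nm2 * rec.area_nm2 == pytest.approx(50)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            morph.measure_aggregate(np.zeros((5, 5), bool), np.zeros((1, 2)))

    def test_rod_recovery_150nm(self, rod_cloud):
        """A 150 nm rod at 12 nm precision: skeleton length within 20 percent,
        strongly elongated."""
        ratios, eccs = [], []
        for seed in range(10):
            table, agg = rod_cloud(150.0, seed=seed, orientation=seed * 0.37)
            xy = table[["x", "y"]].to_numpy()
            mask, _ = morph.regionize_cluster(xy)
            rec = morph.measure_aggregate(mask, xy)
            ratios.append(rec.skeleton_length_nm / 150.0)
            eccs.append(rec.eccentricity)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)
        assert np.mean(eccs) > 0.9

    def test_translation_invariance(self, rod_cloud):
        table, _ = rod_cloud(200.0, seed=1)
        xy = table[["x", "y"]].to_numpy()
        m1, _ = morph.regionize_cluster(xy)
        m2, _ = morph.regionize_cluster(xy + [37.0, -12.0])
        r1 = morph.measure_aggregate(m1, xy)
        r2 = morph.measure_aggregate(m2, xy)
        assert r1.area_nm2 == r2.area_nm2
        assert r1.skeleton_length_nm == r2.skeleton_length_nm

    def test_measure_all_pipeline(self, rod_cloud):
        table, _ = rod_cloud(200.0, seed=2)
        records = morph.measure_all(table)
        assert len(records) == 1
        assert records["skeleton_length_nm"].iloc[0] == pytest.approx(200, rel=0.3)
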