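"""Generator contracts: determinism, ground-truth export, noise models."""

import numpy as np
import pandas as pd
import pytest

from aggrefinger import synthetic as syn


class TestTirfStack:
    def test_noiseless_baseline_is_constant(self):
        spec = syn.TirfSimSpec(width_px=32, height_px=32, n_frames=3,
                               baseline=7.0, read_noise_sd=0.0,
                               shot_noise=False, spots=[])
        stack, truth = syn.simulate_tirf_stack(spec)
        assert stack.shape == (3, 32, 32)
        assert np.all(stack == 7.0)
        assert truth == []

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(0)
        spots = syn.random_spot_layout(5, 64, 64, 80.0, rng)
        spec = syn.TirfSimSpec(width_px=64, height_px=64, n_frames=4,
                               spots=spots, seed=9)
        s1, _ = syn.simulate_tirf_stack(spec)
        s2, _ = syn.simulate_tirf_stack(spec)
        np.testing.assert_array_equal(s1, s2)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            syn.TirfSimSpec(width_px=0)
        with pytest.raises(ValueError):
            syn.TirfSimSpec(n_frames=0)

    def test_spot_layout_respects_separation(self, rng):
        spots = syn.random_spot_layout(20, 256, 256, 50.0, rng,
                                       min_separation_px=12)
        xy = np.array([[s.x_px, s.y_px] for s in spots])
        from scipy.spatial.distance import pdist
        assert pdist(xy).min() >= 12


class TestLocalizationTable:
    def test_zero_precision_rod_lies_on_segment(self):
        agg = syn.GroundTruthAggregate(length_nm=200, sigma_nm=0.0,
                                       width_fwhm_nm=0.0, orientation_rad=0.0,
                                       center_nm=(1070.0, 1070.0),
                                       n_localizations=100)
        table, _ = syn.simulate_localization_table([agg], seed=1)
        y_nm = table["y"].to_numpy() * 107.0
        x_nm = table["x"].to_numpy() * 107.0
        np.testing.assert_allclose(y_nm, 1070.0, atol=1e-9)
        assert x_nm.min() >= 1070.0 - 100.0 - 1e-9
        assert x_nm.max() <= 1070.0 + 100.0 + 1e-9

    def test_precision_column_equals_jitter_sigma(self):
        agg = syn.GroundTruthAggregate(sigma_nm=12.0)
        table, _ = syn.simulate_localization_table([agg], seed=2)
        np.testing.assert_allclose(table["lpx"] * 107.0, 12.0)
        np.testing.assert_allclose(table["lpy"] * 107.0, 12.0)

    def test_background_poisson_rate(self):
        counts = [len(syn.simulate_localization_table(
            [], background_rate_per_um2=0.5, fov_px=(128, 128), seed=s)[0])
            for s in range(30)]
        area = 128 * 128 * 0.107 ** 2
        assert np.mean(counts) == pytest.approx(0.5 * area, rel=0.15)

    def test_negative_background_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_localization_table([], background_rate_per_um2=-1)

    def test_drift_shifts_late_frames(self):
        agg = syn.GroundTruthAggregate(sigma_nm=0.0, width_fwhm_nm=0.0,
                                       n_localizations=2000)
        table, truth = syn.simulate_localization_table(
            [agg], drift_px_per_frame=(0.01, 0.0), n_frames=1000, seed=3)
        early = table.loc[table.frame < 100, "x"].mean()
        late = table.loc[table.frame >= 900, "x"].mean()
        assert late - early == pytest.approx(0.01 * 850, rel=0.15)
        assert truth["drift_px_per_frame"] == (0.01, 0.0)


class TestCohort:
    def test_replicate_bookkeeping(self, small_cohort):
        agg = small_cohort["aggregates"]
        assert set(agg["cohort"]) == {"CRL", "MND_SOD", "MND_TDP"}
        assert set(agg["region"]) == {"cerebellum", "frontal_cortex"}
        assert agg["replicate"].nunique() == 3
        # 3 + 2 + 5 donors
        assert agg["donor"].nunique() == 10
        truth = small_cohort["truth"]
        assert len(truth) == 10 * 2  # donor x region rows

    def test_density_times_area_is_count(self, small_cohort):
        agg = small_cohort["aggregates"]
        np.testing.assert_allclose(
            agg["density_loc_per_nm2"] * agg["area_nm2"],
            agg["n_localizations"], rtol=1e-9)

    def test_determinism(self):
        a = syn.simulate_cohort(syn.SyntheticCohortSpec(seed=5))
        b = syn.simulate_cohort(syn.SyntheticCohortSpec(seed=5))
        pd.testing.assert_frame_equal(a["aggregates"], b["aggregates"])

    def test_length_effect_direction_recovered(self):
        """A TDP-vs-CRL donor-mean length shift is recovered with the right
        sign in nearly every simulation."""
        hits = 0
        for seed in range(10):
            out = syn.simulate_cohort(syn.SyntheticCohortSpec(seed=seed))
            means = out["aggregates"].groupby("cohort")["length_nm"].mean()
            hits += means["MND_TDP"] > means["CRL"]
        assert hits >= 9


class TestProteomicsSim:
    def test_contaminants_flagged(self, proteomics_tables):
        (total, agg, truth), _ = proteomics_tables
        assert total["contaminant"].sum() == len(truth["contaminants"]) > 0

    def test_equal_folds_give_unit_corrected_ratio(self):
        """A protein enriched identically in both fractions has expected
        corrected ratio 1 (the correction's purpose)."""
        enr = {"P00020": (3.0, 3.0)}
        logs = []
        for s in range(25):
            total, agg, _ = syn.simulate_proteomics(
                n_proteins=30, enriched=enr, cv=0.05, seed=s)
            i = total.index[total.accession == "P00020"][0]
            cases, ctrls = total.attrs["case_channels"], total.attrs["control_channels"]
            r_tot = total.loc[i, cases].mean() / total.loc[i, ctrls].mean()
            r_agg = agg.loc[i, cases].mean() / agg.loc[i, ctrls].mean()
            logs.append(np.log2(r_agg / r_tot))
        assert abs(np.mean(logs)) < 0.1

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_proteomics(enriched={"P00001": (0.0, 1.0)})

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_proteomics(n_controls=1)
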