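"""Tests of the synthetic cohort generator's planted statistical structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boldslope import cohort
from boldslope.cohort import (
    CohortSpec,
    assign_trajectories,
    generate_cohort_timeseries,
    generate_metabolic_maps,
    generate_parcel_geometry,
    generate_subject_table,
    generate_t2w_volumes,
    generate_timeseries,
    target_slope_matrix,
)
from boldslope.spectral import estimate_ss_matrix


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"n_frames": 32}, "n_frames"),
            ({"tr": 0.0}, "tr"),
            ({"age_range": (70.0, 30.0)}, "age_range"),
            ({"outlier_frac": 1.5}, "outlier_frac"),
            ({"censor_rate": -0.1}, "censor_rate"),
            ({"slope_effect_frac": 0.5}, "slope_effect_frac"),
            ({"noise_floor": -1.0}, "noise_floor"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            CohortSpec(**kwargs)


class TestSubjectTable:
    def test_zero_outlier_rate(self):
        t = generate_subject_table(CohortSpec(n_subjects=100, outlier_frac=0.0))
        assert not t["outlier"].any()

    def test_deterministic_given_seed(self):
        a = generate_subject_table(CohortSpec(seed=7))
        b = generate_subject_table(CohortSpec(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_outliers_only_above_45_within_binomial_bound(self):
        spec = CohortSpec(n_subjects=400, outlier_frac=0.1, seed=3)
        t = generate_subject_table(spec)
        assert (t.loc[t["outlier"], "age"] > 45).all()
        n_old = int((t["age"] > 45).sum())
        k = int(t["outlier"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_old, 0.1)
        assert lo <= k <= hi

    def test_covariates_independent_of_outlier_status(self):
        t = generate_subject_table(CohortSpec(n_subjects=2000, outlier_frac=0.5, seed=5))
        old = t[t["age"] > 45]
        p = stats.mannwhitneyu(
            old.loc[old["outlier"], "head_motion"],
            old.loc[~old["outlier"], "head_motion"],
        ).pvalue
        assert p > 0.001


class TestGeometry:
    def test_centroids_unit_norm_and_rsn_rows_sum_to_one(self, default_cohort):
        _, _, geom, _ = default_cohort
        xyz = geom[["x", "y", "z"]].to_numpy()
        np.testing.assert_allclose(np.linalg.norm(xyz, axis=1), 1.0, atol=1e-9)
        rsn = geom[[c for c in geom.columns if c.startswith("rsn_")]].to_numpy()
        np.testing.assert_allclose(rsn.sum(axis=1), 1.0, atol=1e-9)

    def test_quasi_uniform_spacing(self, default_cohort):
        _, _, geom, _ = default_cohort
        for h in ("L", "R"):
            xyz = geom.loc[geom["hemisphere"] == h, ["x", "y", "z"]].to_numpy()
            d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            nn = d.min(axis=1)
            assert nn.max() <= 3 * np.median(nn)

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ValueError, match="n_parcels"):
            generate_parcel_geometry(CohortSpec(n_parcels=5))


class TestTrajectories:
    def test_cluster_fractions_and_positivity(self, default_cohort):
        spec, _, geom, traj = default_cohort
        assert (traj["baseline_slope"] > 0).all()
        assert (traj["decline_rate"] >= 0).all()
        assert int((traj["cluster"] == 2).sum()) == round(
            spec.frac_cluster2 * spec.n_parcels
        )

    def test_outlier_permutation_preserves_marginals(self, default_cohort):
        spec, subjects, geom, traj = default_cohort
        slopes = target_slope_matrix(spec, subjects, traj, geom)
        nonmed = ~geom["medial_wall"].to_numpy()
        # rebuild the unpermuted matrix by disabling outliers
        clean_subjects = subjects.copy()
        clean_subjects["outlier"] = False
        ref = target_slope_matrix(spec, clean_subjects, traj, geom)
        for i in np.flatnonzero(subjects["outlier"].to_numpy()):
            np.testing.assert_allclose(
                np.sort(slopes[i, nonmed]), np.sort(ref[i, nonmed]), atol=1e-12
            )
            assert not np.allclose(slopes[i, nonmed], ref[i, nonmed])


class TestTimeseries:
    def test_no_censoring_gives_full_mask(self, default_cohort):
        spec, subjects, geom, traj = default_cohort
        spec0 = CohortSpec(seed=spec.seed, censor_rate=0.0)
        ts = generate_timeseries(subjects.iloc[0], geom.iloc[0], traj.iloc[0], spec0)
        assert ts.valid.all()
        assert ts.n_frames == spec0.n_frames

    def test_white_case_slope_near_zero(self, rng):
        spec = CohortSpec(n_frames=261, tr=1.97, seed=0)
        vals = cohort.synthesize_series(np.zeros(300), spec, rng, noise_floor=0.0)
        ss, _ = estimate_ss_matrix(vals, spec.tr)
        assert abs(ss.mean()) < 2 * ss.std() / np.sqrt(300)

    def test_target_slope_recovered_from_averaged_spectra(self, rng):
        spec = CohortSpec(n_frames=261, tr=1.97, seed=0)
        vals = cohort.synthesize_series(np.full(200, 10.0), spec, rng, noise_floor=0.0)
        ss, _ = estimate_ss_matrix(vals, spec.tr)
        assert ss.mean() == pytest.approx(10.0, abs=0.5)

    def test_negative_noise_floor_rejected(self, rng):
        spec = CohortSpec()
        with pytest.raises(ValueError, match="noise_floor"):
            cohort.synthesize_series(np.array([5.0]), spec, rng, noise_floor=-1.0)


class TestMetabolicMaps:
    def test_noise_free_map_is_rank_identical_to_baseline(self, default_cohort):
        spec, _, geom, traj = default_cohort
        maps = generate_metabolic_maps(
            geom, traj, spec, noise_sd={"cmrglc": 0.0, "cmro2": 0.0, "cbf": 0.0}
        )
        rho = stats.spearmanr(maps["cmrglc"], traj["baseline_slope"]).statistic
        assert rho == pytest.approx(1.0)

    def test_default_noise_correlation_in_range(self, default_cohort):
        spec, _, geom, traj = default_cohort
        maps = generate_metabolic_maps(geom, traj, spec)
        rho = stats.spearmanr(maps["cmrglc"], traj["baseline_slope"]).statistic
        assert 0.5 < rho < 0.9

    def test_noisier_modalities_correlate_less_on_average(self):
        diffs = []
        for seed in range(50):
            spec = CohortSpec(seed=seed, n_parcels=60)
            geom = generate_parcel_geometry(spec)
            traj = assign_trajectories(spec, geom)
            maps = generate_metabolic_maps(geom, traj, spec)
            s0 = traj["baseline_slope"]
            diffs.append(
                stats.spearmanr(maps["cmrglc"], s0).statistic
                - stats.spearmanr(maps["cbf"], s0).statistic
            )
        assert np.mean(diffs) > 0


class TestT2w:
    def test_zero_lesion_effect_equalizes_distributions(self):
        spec = CohortSpec(n_subjects=50, lesion_effect=0.0, seed=2)
        subs = generate_subject_table(spec)
        t2w = generate_t2w_volumes(subs, spec)
        inside = t2w.volumes[:, t2w.roi_mask].ravel()
        outside = t2w.volumes[:, ~t2w.roi_mask].ravel()[: inside.size]
        assert stats.ks_2samp(inside, outside).pvalue > 0.001

    def test_noise_free_roi_shift_equals_lesion_effect(self):
        spec = CohortSpec(n_subjects=60, lesion_effect=7.5, outlier_frac=0.5, seed=4)
        subs = generate_subject_table(spec)
        t2w = generate_t2w_volumes(subs, spec, noise_sd=0.0)
        out = subs["outlier"].to_numpy()
        assert out.any() and (~out).any()
        roi_means = t2w.volumes[:, t2w.roi_mask].mean(axis=1)
        delta = roi_means[out].mean() - roi_means[~out].mean()
        assert delta == pytest.approx(7.5, abs=1e-12)

    def test_default_settings_separate_groups(self):
        spec = CohortSpec(n_subjects=200, seed=6)
        subs = generate_subject_table(spec)
        t2w = generate_t2w_volumes(subs, spec)
        out = subs["outlier"].to_numpy()
        roi_means = t2w.volumes[:, t2w.roi_mask].mean(axis=1)
        p = stats.ttest_ind(roi_means[out], roi_means[~out]).pvalue
        assert p < 0.01

    def test_empty_roi_rejected(self):
        spec = CohortSpec(n_subjects=50, seed=2)
        subs = generate_subject_table(spec)
        with pytest.raises(ValueError, match="ROI"):
            generate_t2w_volumes(subs, spec, shape=(4, 4, 4))


class TestDeterminism:
    def test_timeseries_byte_identical_across_runs(self, default_cohort):
        spec, subjects, geom, traj = default_cohort
        small = subjects.head(3)
        a = generate_cohort_timeseries(spec, small, traj, geom)
        b = generate_cohort_timeseries(spec, small, traj, geom)
        for sid in a:
            np.testing.assert_array_equal(a[sid][0], b[sid][0])
            np.testing.assert_array_equal(a[sid][1], b[sid][1])
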