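import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stackenc.encoding import fit_stacked, preference_index
from stackenc.synthetic import (
    GroundTruth,
    SimulationConfig,
    simulate_bold,
    simulate_cohort,
    simulate_features,
    simulate_motion,
    simulate_study,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_grayordinates": 0},
            {"ar1_coef": 1.0},
            {"tr_seconds": 0.0},
            {"group_pref_shift": 1.5},
            {"n_parcels": 2, "n_designated_parcels": 3},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateFeatures:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(seed=9)
        a = simulate_features(cfg, "audio-low")
        b = simulate_features(cfg, "audio-low")
        np.testing.assert_array_equal(a.values, b.values)

    def test_spaces_have_configured_dimensionality(self):
        cfg = SimulationConfig()
        dims = {"audio-low": 6, "audio-high": 8, "visual-low": 2,
                "visual-high": 2}
        for space, p in dims.items():
            assert simulate_features(cfg, space).n_features == p

    def test_zero_sparsity_gives_all_zero_matrix(self):
        cfg = SimulationConfig()
        fm = simulate_features(cfg, "audio-high", sparsity=0.0)
        assert not fm.values.any()

    def test_high_level_features_binary_and_sparse(self):
        cfg = SimulationConfig(n_timepoints=2000)
        fm = simulate_features(cfg, "visual-high")
        assert set(np.unique(fm.values)) <= {0.0, 1.0}
        assert 0 < fm.values.mean() < 0.5

    def test_low_level_lag1_autocorrelation_matches_parameter(self):
        cfg = SimulationConfig(n_timepoints=10_000, ar1_coef=0.5)
        x = simulate_features(cfg, "visual-low").values[:, 0]
        rho = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert rho == pytest.approx(0.5, abs=0.03)

    def test_unknown_space_rejected_naming_valid_tags(self):
        with pytest.raises(ValueError, match="audio-low"):
            simulate_features(SimulationConfig(), "smell")


class TestSimulateBold:
    def test_noiseless_oracle_refit_r2_is_one(self):
        cfg = SimulationConfig(n_subjects_per_group=1, n_grayordinates=10,
                               n_parcels=2, n_timepoints=500, snr=np.inf,
                               seed=3)
        study = simulate_study(cfg)
        sid = study.phenotype["subject_id"].iloc[0]
        truth = study.truths[sid]
        y = study.bold[sid].values
        for gi in range(5):
            comps = []
            for k in study.designs:
                p = study.designs[k].values @ truth.coefs[k][gi]
                comps.append((p - p.mean()) / p.std())
            recon = np.column_stack(comps) @ truth.weights[gi] + truth.site_offset
            ss_res = np.sum((y[gi] - recon) ** 2)
            ss_tot = np.sum((y[gi] - y[gi].mean()) ** 2)
            assert 1 - ss_res / ss_tot == pytest.approx(1.0, abs=1e-10)

    def test_pure_single_space_mixture_uncorrelated_with_others(self, rng):
        cfg = SimulationConfig(n_grayordinates=1, n_parcels=1,
                               n_designated_parcels=0, n_timepoints=4000,
                               snr=np.inf, seed=4)
        designs = {s: simulate_features(cfg, s) for s in
                   ("audio-low", "audio-high", "visual-low", "visual-high")}
        coefs = {s: rng.standard_normal((1, d.n_features))
                 for s, d in designs.items()}
        truth = GroundTruth(
            weights=np.array([[1.0, 0.0, 0.0, 0.0]]), coefs=coefs,
            parcel_assignment=np.zeros(1, int), parcel_labels=np.array(["P0"]),
            designated_parcels=[], site="site0", group="nonASD", age=10.0,
            sex="M", ses=50.0, severity=45.0, site_offset=0.0,
        )
        bold = simulate_bold(cfg, designs, truth)
        y = bold.values[0]
        for other in ("audio-high", "visual-low", "visual-high"):
            pred = designs[other].values @ coefs[other][0]
            if pred.std() == 0:
                continue
            assert abs(np.corrcoef(y, pred)[0, 1]) < 0.1

    def test_variance_ratio_identity_at_unit_snr(self):
        """Mean stacked held-out R^2 approaches snr^2/(1+snr^2) = 0.5."""
        cfg = SimulationConfig(n_subjects_per_group=1, n_grayordinates=40,
                               n_parcels=8, n_timepoints=5000, snr=1.0,
                               seed=6)
        study = simulate_study(cfg)
        sid = study.phenotype["subject_id"].iloc[0]
        designs = {k: v.values for k, v in study.designs.items()}
        fit = fit_stacked(designs, study.bold[sid].values.T)
        assert np.nanmean(fit.stacked_r2) == pytest.approx(0.5, abs=0.05)

    def test_mismatched_time_axes_rejected(self, small_study):
        cfg = small_study.config
        designs = dict(small_study.designs)
        bad = simulate_features(
            SimulationConfig(n_timepoints=cfg.n_timepoints + 10), "audio-low"
        )
        designs["audio-low"] = bad
        sid = small_study.phenotype["subject_id"].iloc[0]
        with pytest.raises(ValueError, match="time axis"):
            simulate_bold(cfg, designs, small_study.truths[sid])


class TestSimulateCohort:
    def test_null_shift_gives_no_group_difference_anywhere(self):
        cfg = SimulationConfig(group_pref_shift=0.0, seed=2)
        pheno, truths = simulate_cohort(cfg)
        pref = {g: [] for g in ("ASD", "nonASD")}
        for sid, truth in truths.items():
            g = pheno.loc[pheno["subject_id"] == sid, "group"].iloc[0]
            pref[g].append(truth.weights[:, 3] - truth.weights[:, 2])
        diff = np.mean(pref["ASD"], axis=0) - np.mean(pref["nonASD"], axis=0)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_injected_shift_confined_to_designated_parcels(self):
        cfg = SimulationConfig(group_pref_shift=0.3, seed=2)
        pheno, truths = simulate_cohort(cfg)
        asd = [truths[s] for s in pheno[pheno.group == "ASD"]["subject_id"]]
        non = [truths[s] for s in pheno[pheno.group == "nonASD"]["subject_id"]]
        pref_asd = np.mean([t.weights[:, 3] - t.weights[:, 2] for t in asd], axis=0)
        pref_non = np.mean([t.weights[:, 3] - t.weights[:, 2] for t in non], axis=0)
        labels = asd[0].parcel_labels
        in_designated = np.isin(labels, asd[0].designated_parcels)
        diff = pref_non - pref_asd
        np.testing.assert_allclose(diff[in_designated], 0.3, atol=1e-10)
        np.testing.assert_allclose(diff[~in_designated], 0.0, atol=1e-12)

    def test_shift_magnitude_tracks_severity(self):
        cfg = SimulationConfig(group_pref_shift=0.3, seed=8)
        pheno, truths = simulate_cohort(cfg)
        asd = pheno[pheno.group == "ASD"]
        labels = next(iter(truths.values())).parcel_labels
        designated = next(iter(truths.values())).designated_parcels
        gi = int(np.flatnonzero(np.isin(labels, designated))[0])
        shifts = [0.5 - truths[s].weights[gi, 3] for s in asd["subject_id"]]
        rho = stats.spearmanr(shifts, asd["srs_total"]).statistic
        assert rho > 0.9

    def test_oversized_shift_reprojected_with_warning(self):
        cfg = SimulationConfig(group_pref_shift=1.0, seed=2,
                               n_subjects_per_group=4)
        with pytest.warns(UserWarning, match="simplex"):
            _, truths = simulate_cohort(cfg)
        for truth in truths.values():
            assert truth.weights.min() >= 0
            np.testing.assert_allclose(truth.weights.sum(axis=1), 1.0)

    def test_phenotype_schema_and_sss_identity(self):
        pheno, _ = simulate_cohort(SimulationConfig(seed=1))
        expected = {"subject_id", "consensus_label", "group", "adhd", "age",
                    "sex", "ses", "site", "srs_total", "srs_item20",
                    "srs_item42", "srs_item58", "scq_item14", "sss"}
        assert expected <= set(pheno.columns)
        recomputed = (pheno["srs_item20"] + pheno["srs_item42"]
                      + pheno["srs_item58"] + pheno["scq_item14"])
        pd.testing.assert_series_equal(pheno["sss"], recomputed,
                                       check_names=False)
        assert pheno["sss"].between(0, 12).all()

    def test_sites_assigned_round_robin(self):
        cfg = SimulationConfig(seed=1, site_count=3, n_subjects_per_group=6)
        pheno, _ = simulate_cohort(cfg)
        assert pheno["site"].value_counts().nunique() == 1


class TestSimulateMotion:
    def test_fd_always_nonnegative(self):
        cfg = SimulationConfig(seed=5)
        for fd in simulate_motion(cfg, np.array([6.0, 12.0, 18.0])):
            assert (fd >= 0).all()

    def test_zero_slope_leaves_no_age_trend(self):
        cfg = SimulationConfig(seed=5, motion_age_slope=0.0)
        ages = np.linspace(5, 21, 500)
        fracs = [np.mean(fd > 0.2) for fd in simulate_motion(cfg, ages, 200)]
        rho = stats.spearmanr(fracs, ages).statistic
        assert abs(rho) < 0.1

    def test_negative_slope_gives_negative_age_correlation(self):
        cfg = SimulationConfig(seed=5, motion_age_slope=-0.2)
        ages = np.linspace(5, 21, 300)
        fracs = [np.mean(fd > 0.2) for fd in simulate_motion(cfg, ages, 200)]
        assert stats.spearmanr(fracs, ages).statistic < -0.5

    def test_negative_ages_rejected(self):
        with pytest.raises(ValueError):
            simulate_motion(SimulationConfig(), np.array([-1.0]))


class TestDeterminism:
    def test_full_study_reproducible(self):
        cfg = SimulationConfig(n_subjects_per_group=2, n_grayordinates=8,
                               n_parcels=2, n_timepoints=100, seed=42)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        pd.testing.assert_frame_equal(a.phenotype, b.phenotype)
        for sid in a.bold:
            np.testing.assert_array_equal(a.bold[sid].values,
                                          b.bold[sid].values)
            np.testing.assert_array_equal(a.motion[sid], b.motion[sid])
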