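"""Synthetic cohort generator and image-level forward models."""

import numpy as np
import pytest

from renoximetry.cohort_synth import (
    CONDITIONS,
    DEFAULT_DEMOGRAPHY,
    DEFAULT_PHYSIOLOGY,
    INFRARENAL_IVC,
    LEFT_RENAL_VEIN,
    SITES,
    SUPRARENAL_IVC,
    AcquisitionGeometry,
    TruncatedNormal,
    default_geometry,
    generate_cohort,
    generate_condition_truth,
    generate_subject_schedule,
    render_t2prep_series,
    render_velocity_series,
    scale_demography,
    scale_physiology,
)
from renoximetry.flowquant import compute_bfr
from renoximetry.oximetry import DEFAULT_CALIBRATION, forward_t2
from renoximetry.relaxometry import fit_series


class TestTruncatedNormal:
    def test_bounds_excluding_mean_rejected(self):
        with pytest.raises(ValueError, match="exclude the mean"):
            TruncatedNormal(10.0, 1.0, 12.0, 20.0)
        with pytest.raises(ValueError):
            TruncatedNormal(10.0, -1.0)

    def test_degenerate_sd_returns_mean(self):
        rng = np.random.default_rng(0)
        assert TruncatedNormal(5.0, 0.0).sample(rng) == 5.0

    def test_samples_respect_bounds(self):
        rng = np.random.default_rng(0)
        spec = TruncatedNormal(0.0, 5.0, -1.0, 1.0)
        draws = spec.sample(rng, size=2000)
        assert draws.min() >= -1.0 and draws.max() <= 1.0


class TestCohort:
    def test_same_seed_identical_cohorts(self):
        assert generate_cohort(10, 42) == generate_cohort(10, 42)
        assert generate_cohort(10, 42) != generate_cohort(10, 43)

    def test_degenerate_cohort_sits_at_means(self):
        subject = generate_cohort(1, 0, scale_demography(DEFAULT_DEMOGRAPHY, 0.0))[0]
        assert subject.age == 30.0
        assert subject.left_kidney_mass == 172.0
        assert subject.right_kidney_mass == 159.0
        assert subject.hct == pytest.approx(0.42, abs=1e-12)

    def test_sample_mean_kidney_mass_near_population_mean(self):
        cohort = generate_cohort(10, 0)
        mean_mass = np.mean([s.left_kidney_mass for s in cohort])
        assert abs(mean_mass - 172.0) <= 3.0 * 29.0 / np.sqrt(10)

    def test_sex_split_and_hct_rule(self):
        cohort = generate_cohort(10, 1)
        assert sum(s.sex == "M" for s in cohort) == 5
        for s in cohort:
            assert s.hct == pytest.approx(s.hb / 0.34 / 100.0, abs=1e-12)

    def test_replicate_cohorts_recover_specified_means(self):
        # 200 replicate cohorts of n=10: empirical means within 4 SE.
        rng_seeds = range(200)
        values = {k: [] for k in DEFAULT_DEMOGRAPHY}
        for seed in rng_seeds:
            for s in generate_cohort(10, seed):
                values["age"].append(s.age)
                values["height"].append(s.height)
                values["weight"].append(s.weight)
                values["hb"].append(s.hb)
                values["left_kidney_mass"].append(s.left_kidney_mass)
                values["right_kidney_mass"].append(s.right_kidney_mass)
        for name, spec in DEFAULT_DEMOGRAPHY.items():
            arr = np.asarray(values[name])
            se = spec.sd / np.sqrt(len(arr))
            assert abs(arr.mean() - spec.mean) <= 4.0 * se, name


class TestConditionTruth:
    def test_degenerate_baseline_matches_reported_means(self):
        subject = generate_cohort(1, 0, scale_demography(DEFAULT_DEMOGRAPHY, 0.0))[0]
        physio = scale_physiology(DEFAULT_PHYSIOLOGY, 0.0)
        state = generate_condition_truth(subject, "baseline", 0, physio)
        assert state.sao2 == 0.99
        assert state.svo2_by_site[LEFT_RENAL_VEIN] == 0.92
        assert state.bfr_by_site[LEFT_RENAL_VEIN] == 410.0
        assert state.bfr_by_site[SUPRARENAL_IVC] == 2420.0  # infrarenal + outflow

    def test_degenerate_moderate_hypoxia(self):
        subject = generate_cohort(1, 0, scale_demography(DEFAULT_DEMOGRAPHY, 0.0))[0]
        physio = scale_physiology(DEFAULT_PHYSIOLOGY, 0.0)
        state = generate_condition_truth(subject, "moderate_hypoxia", 0, physio)
        assert state.sao2 == 0.84
        assert state.svo2_by_site[LEFT_RENAL_VEIN] == 0.76

    def test_venous_below_arterial_always(self):
        subject = generate_cohort(1, 0)[0]
        rng_seeds = np.random.SeedSequence(7).generate_state(2500)
        for i, seed in enumerate(rng_seeds):
            condition = CONDITIONS[i % 4]
            state = generate_condition_truth(subject, condition, int(seed))
            for site in SITES:
                assert state.svo2_by_site[site] < state.sao2
            assert state.bfr_by_site[SUPRARENAL_IVC] > state.bfr_by_site[INFRARENAL_IVC]

    def test_schedule_determinism_and_subject_effect(self):
        subject = generate_cohort(1, 0)[0]
        a = generate_subject_schedule(subject, 5)
        b = generate_subject_schedule(subject, 5)
        assert a == b
        # Subject-level effect induces positive correlation across conditions.
        base, rec = [], []
        for seed in range(400):
            sched = generate_subject_schedule(subject, seed, subject_effect_frac=0.5)
            base.append(sched["baseline"].svo2_by_site[LEFT_RENAL_VEIN])
            rec.append(sched["recovery"].svo2_by_site[LEFT_RENAL_VEIN])
        corr = np.corrcoef(base, rec)[0, 1]
        assert corr > 0.1
        # Marginal distribution preserved despite the shared effect.
        assert np.mean(base) == pytest.approx(0.92, abs=0.006)
        assert np.std(base) == pytest.approx(0.03, abs=0.006)

    def test_unknown_condition_rejected(self):
        subject = generate_cohort(1, 0)[0]
        with pytest.raises(ValueError):
            generate_condition_truth(subject, "apnea", 0)


class TestGeometry:
    def test_invalid_te_order_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            AcquisitionGeometry(effective_tes=(0.0, 80.0, 40.0, 160.0, 240.0))

    def test_vessel_must_fit_in_matrix(self):
        with pytest.raises(ValueError, match="inside"):
            AcquisitionGeometry(vessel_center=(2.0, 2.0), vessel_radii=(5.0, 5.0))

    def test_site_defaults(self):
        geom = default_geometry(SUPRARENAL_IVC)
        assert geom.venc == 100.0
        assert geom.ellipse_mask().sum() > 0


class TestT2PrepRendering:
    def test_noiseless_ratio_is_exact_exponential(self, baseline_state):
        geom = default_geometry(
            LEFT_RENAL_VEIN, noise_sigma=0.0, effective_tes=(0.0, 60.0, 120.0)
        )
        series = render_t2prep_series(
            baseline_state, geom, DEFAULT_CALIBRATION, 0.42, LEFT_RENAL_VEIN, 0
        )
        t2_blood = forward_t2(0.92, 0.42)
        mask = series.roi_mask
        ratio = series.images[1][mask].mean() / series.images[0][mask].mean()
        assert ratio == pytest.approx(np.exp(-60.0 / t2_blood), rel=1e-12)

    def test_background_is_suppressed(self, baseline_state):
        geom = default_geometry(LEFT_RENAL_VEIN, noise_sigma=0.0)
        series = render_t2prep_series(
            baseline_state, geom, DEFAULT_CALIBRATION, 0.42, LEFT_RENAL_VEIN, 0, s0=1000.0
        )
        background = series.images[0][~series.roi_mask]
        assert background.mean() <= 0.05 * 1000.0

    def test_closed_loop_fit_within_two_percent_at_snr_50(self, baseline_state):
        geom = default_geometry(LEFT_RENAL_VEIN, noise_sigma=20.0)
        series = render_t2prep_series(
            baseline_state, geom, DEFAULT_CALIBRATION, 0.42, LEFT_RENAL_VEIN, 11, s0=1000.0
        )
        t2_blood = forward_t2(0.92, 0.42)
        assert fit_series(series).t2 == pytest.approx(t2_blood, rel=0.02)

    def test_determinism(self, baseline_state):
        geom = default_geometry(LEFT_RENAL_VEIN)
        a = render_t2prep_series(baseline_state, geom, DEFAULT_CALIBRATION, 0.42,
                                 LEFT_RENAL_VEIN, 3)
        b = render_t2prep_series(baseline_state, geom, DEFAULT_CALIBRATION, 0.42,
                                 LEFT_RENAL_VEIN, 3)
        assert np.array_equal(a.images, b.images)


class TestVelocityRendering:
    def test_uniform_profile_arithmetic(self, baseline_state):
        # Plug flow at 10 cm/s through the ROI area gives area * 600 mL/min.
        geom = default_geometry(LEFT_RENAL_VEIN, velocity_noise_sigma=0.0)
        area = geom.roi_area_cm2()
        state = baseline_state
        target = 10.0 * area * 60.0
        state = type(state)(
            condition=state.condition,
            target_peto2=state.target_peto2,
            sao2=state.sao2,
            svo2_by_site=state.svo2_by_site,
            bfr_by_site={**state.bfr_by_site, LEFT_RENAL_VEIN: target},
        )
        series = render_velocity_series(state, geom, LEFT_RENAL_VEIN, 0, profile="uniform")
        vessel = series.velocity_maps[0][series.roi_mask]
        assert vessel == pytest.approx(10.0, rel=1e-12)
        assert compute_bfr(series).bfr == pytest.approx(target, rel=1e-12)

    def test_parabolic_mean_is_half_peak_on_fine_grid(self, baseline_state):
        # Analytic disc integral of v_max (1 - r^2/R^2) gives mean v_max / 2.
        geom = AcquisitionGeometry(
            matrix=(101, 101), vessel_center=(50.0, 50.0), vessel_radii=(35.0, 35.0),
            velocity_noise_sigma=0.0, venc=200.0,
        )
        series = render_velocity_series(baseline_state, geom, LEFT_RENAL_VEIN, 0)
        vessel = series.velocity_maps[0][series.roi_mask]
        assert vessel.mean() == pytest.approx(vessel.max() / 2.0, rel=0.02)

    def test_noiseless_flow_recovery_is_exact(self, baseline_state):
        geom = default_geometry(LEFT_RENAL_VEIN, velocity_noise_sigma=0.0)
        series = render_velocity_series(baseline_state, geom, LEFT_RENAL_VEIN, 0)
        assert compute_bfr(series).bfr == pytest.approx(410.0, abs=1e-9)

    def test_aliasing_guard(self, baseline_state):
        geom = default_geometry(LEFT_RENAL_VEIN)
        geom = AcquisitionGeometry(
            matrix=geom.matrix, vessel_center=geom.vessel_center,
            vessel_radii=geom.vessel_radii, venc=5.0,
        )
        with pytest.raises(ValueError, match="VENC"):
            render_velocity_series(baseline_state, geom, LEFT_RENAL_VEIN, 0)
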