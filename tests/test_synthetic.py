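"""Ground-truth generators: flow phantoms, dynamic speckle, motion, lesion
volumes, and NSS cohorts."""

import numpy as np
import pytest

from speckleflow import (
    EmptyIntervalError,
    ScenarioConfig,
    ScenarioOverflowError,
    UndersampledIntegrationError,
    k_squared,
    inject_motion,
    make_flow_phantom,
    make_lesion_volume,
    make_nss_cohort,
    render_sequence,
    render_speckle_frame,
)
from speckleflow.lesion import lesion_volume
from speckleflow.stats import NSS_CATEGORY_MAXIMA, nss_total


def small_config(**kw) -> ScenarioConfig:
    base = dict(
        image_shape=(96, 96), pixel_pitch_mm=0.08, target_area_15min_mm2=5.0, seed=1
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestFlowPhantom:
    def test_baseline_has_no_reduction(self):
        ph = make_flow_phantom(small_config(), 0.0)
        assert np.all(ph.relative_flow_map == 1.0)
        assert ph.true_reduction_area_mm2 == 0.0

    def test_planted_pixel_count_is_exact(self):
        # integer-arithmetic oracle: requested area / pitch² pixels
        cfg = ScenarioConfig(
            image_shape=(1024, 1024),
            pixel_pitch_mm=0.011,
            target_area_15min_mm2=12.4,
            seed=0,
        )
        ph = make_flow_phantom(cfg, 15.0)
        expected_px = round(12.4 / 0.011**2)
        assert int((ph.relative_flow_map < 0.5).sum()) == expected_px

    def test_territory_grows_to_target_at_15min(self):
        cfg = small_config()
        areas = [make_flow_phantom(cfg, t).true_reduction_area_mm2 for t in (0, 5, 10, 15, 20)]
        assert all(np.diff(areas) >= 0)
        assert areas[3] == pytest.approx(5.0, abs=2 * 0.08**2)
        assert areas[4] == areas[3]  # plateau after 15 min

    def test_flow_inversely_proportional_to_tau(self):
        ph = make_flow_phantom(small_config(), 15.0)
        np.testing.assert_allclose(ph.relative_flow_map * ph.tau_map, ph.tau_map.min())
        assert np.all(ph.tau_map > 0)
        inside = ph.relative_flow_map < 0.5
        assert np.all(ph.relative_flow_map[inside] < 0.5)
        assert np.all(ph.relative_flow_map[~inside] == 1.0)

    def test_overflowing_territory_raises(self):
        with pytest.raises(ScenarioOverflowError):
            ScenarioConfig(
                image_shape=(64, 64), pixel_pitch_mm=0.02, target_area_15min_mm2=50.0
            )
        cfg = small_config(target_area_15min_mm2=20.0)  # fits the hemisphere area
        with pytest.raises(ScenarioOverflowError):
            make_flow_phantom(cfg, 15.0)  # but the disc leaks past the midline


class TestSpeckleRendering:
    def test_frozen_speckle_contrast_near_unity(self):
        cfg = small_config(baseline_tau_s=10.0)
        frame = render_speckle_frame(make_flow_phantom(cfg, 0.0), cfg, seed=2)
        assert frame.std() / frame.mean() == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize("x", [1.0, 0.1])
    def test_uniform_tau_matches_closed_form(self, x):
        cfg = small_config(baseline_tau_s=x * 5e-3, n_substeps=96)
        ph = make_flow_phantom(cfg, 0.0)
        K = [
            (f.std() / f.mean())
            for f in (render_speckle_frame(ph, cfg, seed=(3, k)) for k in range(6))
        ]
        assert np.mean(K) == pytest.approx(np.sqrt(k_squared(x, T=1.0)), rel=0.05)

    def test_undersampled_exposure_rejected(self):
        cfg = small_config(baseline_tau_s=5e-3 / 20, n_substeps=64)  # T/tau = 20 > 16
        with pytest.raises(UndersampledIntegrationError):
            render_speckle_frame(make_flow_phantom(cfg, 0.0), cfg, seed=0)

    def test_seeded_determinism(self):
        cfg = small_config()
        ph = make_flow_phantom(cfg, 15.0)
        f1 = render_speckle_frame(ph, cfg, seed=9)
        f2 = render_speckle_frame(ph, cfg, seed=9)
        np.testing.assert_array_equal(f1, f2)


class TestRenderSequence:
    def test_one_second_at_50fps_gives_50_frames(self):
        cfg = small_config(target_area_15min_mm2=0.0)
        stack = render_sequence(cfg, 0.0, 1.0 / 60.0)
        assert len(stack) == 50
        assert stack.frame_rate_hz == 50.0

    def test_empty_interval_raises(self):
        cfg = small_config()
        with pytest.raises(EmptyIntervalError):
            render_sequence(cfg, 1.0, 1.0)

    def test_disjoint_renders_of_static_phantom_identical(self):
        cfg = small_config(target_area_15min_mm2=0.0)
        s1 = render_sequence(cfg, 16.0, 16.0 + 4 / 50 / 60)
        s2 = render_sequence(cfg, 20.0, 20.0 + 4 / 50 / 60)
        np.testing.assert_array_equal(s1.frames, s2.frames)


class TestInjectMotion:
    def test_zero_schedule_is_identity(self, stack_frozen):
        sched = np.zeros((len(stack_frozen), 2))
        out = inject_motion(stack_frozen, sched)
        np.testing.assert_array_equal(out.frames, stack_frozen.frames)

    def test_integer_shift_is_circular_roll(self, stack_frozen):
        sched = np.tile([3.0, -2.0], (len(stack_frozen), 1))
        out = inject_motion(stack_frozen, sched)
        expected = np.roll(stack_frozen.frames[0], (3, -2), axis=(0, 1))
        np.testing.assert_allclose(out.frames[0], expected, atol=1e-9)

    def test_round_trip_restores_original(self, stack_frozen):
        rng = np.random.default_rng(0)
        sched = rng.uniform(-4, 4, size=(len(stack_frozen), 2))
        back = inject_motion(inject_motion(stack_frozen, sched), -sched)
        span = stack_frozen.frames.max() - stack_frozen.frames.min()
        assert np.max(np.abs(back.frames - stack_frozen.frames)) < 0.01 * span

    def test_excessive_drift_rejected(self, stack_frozen):
        sched = np.full((len(stack_frozen), 2), 20.0)
        with pytest.raises(ValueError):
            inject_motion(stack_frozen, sched)


class TestLesionPhantom:
    def test_planted_voxel_volume_exact(self):
        vol = make_lesion_volume(63.7, n_slices=20, thickness_mm=1.0, in_plane_pitch_mm=0.1, seed=3)
        voxel = 0.1 * 0.1 * 1.0
        assert vol.truth_mask.sum() * voxel == pytest.approx(63.7, abs=voxel)
        assert vol.true_volume_mm3 == pytest.approx(63.7, abs=voxel)

    def test_zero_volume_gives_uniform_background(self):
        vol = make_lesion_volume(
            0.0, 8, 1.0, 0.1, background_intensity=0.0, noise_sd=0.0, seed=0
        )
        assert not vol.truth_mask.any()
        assert lesion_volume(vol).total_volume_mm3 == 0.0

    def test_ttc_analog_with_3mm_slices(self):
        vol = make_lesion_volume(32.0, 6, 3.0, 0.1, seed=4, modality="TTC-like")
        voxel = 0.1 * 0.1 * 3.0
        assert vol.truth_mask.sum() * voxel == pytest.approx(32.0, abs=voxel)
        assert vol.modality == "TTC-like"

    def test_preconditions_enforced(self):
        with pytest.raises(ValueError):  # background too bright for 75% threshold
            make_lesion_volume(10.0, 8, 1.0, 0.1, lesion_intensity=100, background_intensity=80)
        with pytest.raises(ValueError):  # noise too strong
            make_lesion_volume(10.0, 8, 1.0, 0.1, noise_sd=10.0)
        with pytest.raises(ValueError):  # does not fit the stack
            make_lesion_volume(1e5, 4, 1.0, 0.1)


class TestNSSCohort:
    def test_noise_free_cohort_sits_on_scoring_grid(self):
        recs = make_nss_cohort(5.9, 0.0, n_rats=3, examiner_sd=0.0, seed=0)
        by_rat = {r.rat_id for r in recs}
        for rat in by_rat:
            assert nss_total([r for r in recs if r.rat_id == rat]) == 6.0  # 5.9 rounded

    def test_zero_mean_gives_all_zero_categories(self):
        recs = make_nss_cohort(0.0, 0.0, n_rats=2, examiner_sd=0.0, seed=0)
        assert all(r.motor == r.sensory == r.beam == r.reflex == 0 for r in recs)

    def test_category_bounds_respected(self):
        recs = make_nss_cohort(17.0, 4.0, n_rats=20, examiner_sd=2.0, seed=1)
        for r in recs:
            for cat, mx in NSS_CATEGORY_MAXIMA.items():
                assert 0 <= getattr(r, cat) <= mx
            assert 0 <= r.total <= 18

    def test_cohort_mean_coverage(self):
        # ~95% of seeded cohorts should land within 2 SE of the group mean
        mean, sd, n = 5.9, 1.0, 11
        hits = 0
        for seed in range(100):
            recs = make_nss_cohort(mean, sd, n_rats=n, examiner_sd=0.3, seed=seed)
            totals = [
                nss_total([r for r in recs if r.rat_id == f"rat{i:02d}"]) for i in range(n)
            ]
            hits += abs(np.mean(totals) - mean) < 2 * sd / np.sqrt(n)
        assert hits >= 85
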