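"""Synthetic movie generator: determinism, forward model, ground truth."""
import numpy as np
import pytest
from scipy import stats

from furatrack import (
    DetectionParams,
    EventTable,
    OpticsParams,
    SceneParams,
    ValidationError,
    detect_events,
    fura2_forward,
    params_from_yaml,
    params_to_yaml,
    preset,
    score_detection,
    simulate_and_detect,
    simulate_scene,
)
from furatrack.simulate import GroundTruthEvents, TrueEvent, embryo_ellipse

SMALL = dict(frames=40, height=48, width=48)


class TestFura2Forward:
    def test_calcium_free_ratio_closed_form(self):
        optics = OpticsParams()
        f340, f380 = fura2_forward(np.zeros((4, 4)), optics)
        assert np.allclose(f340 / f380, optics.g340_free / optics.g380_free)

    def test_saturated_ratio_exceeds_free_ratio(self):
        optics = OpticsParams()
        lo = fura2_forward(np.zeros((2, 2)), optics)
        hi = fura2_forward(np.ones((2, 2)), optics)
        assert np.all(hi[0] / hi[1] > lo[0] / lo[1])
        assert np.allclose(hi[0] / hi[1], optics.g340_bound / optics.g380_bound)

    def test_half_saturation_forced_arithmetic(self):
        optics = OpticsParams(g340_free=1, g340_bound=3, g380_free=3, g380_bound=1, offset=0)
        f340, f380 = fura2_forward(np.full((2, 2), 0.5), optics)
        assert np.allclose(f340 / f380, 1.0)

    def test_ratio_strictly_increasing_in_c(self):
        optics = OpticsParams()
        c = np.linspace(0, 1, 21)
        f340, f380 = fura2_forward(c, optics)
        assert np.all(np.diff(f340 / f380) > 0)

    def test_c_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            fura2_forward(np.array([1.5]), OpticsParams())

    def test_wrong_spectral_ordering_rejected(self):
        with pytest.raises(ValidationError):
            OpticsParams(g340_free=3.0, g340_bound=0.5)


class TestSimulateScene:
    def test_rate_zero_noise_free_scene_is_static(self):
        scene = SceneParams(
            transient_rate_per_hour=0.0,
            noise=dict_noise(photon_scale=0.0, tau_bleach_s=np.inf),
            **SMALL,
        )
        stack, truth = simulate_scene(scene)
        assert truth.count == 0
        assert np.all(stack.f340 == stack.f340[0])
        assert np.all(stack.f380 == stack.f380[0])
        _, _, _, table = simulate_and_detect(scene)
        assert len(table) == 0

    def test_ground_truth_self_consistency(self):
        scene = SceneParams(transient_rate_per_hour=30.0, seed=7, **SMALL)
        _, truth = simulate_scene(scene)
        assert truth.count == len(truth.events)
        for ev in truth:
            assert 1 <= ev.onset_frame < scene.frames - 1
            assert 0 <= ev.center[0] < scene.height
            assert 0 <= ev.center[1] < scene.width

    def test_seeded_determinism_is_bit_exact(self):
        scene = preset("wildtype", seed=42, frames=60, height=64, width=64)
        s1, t1 = simulate_scene(scene)
        s2, t2 = simulate_scene(scene)
        assert np.array_equal(s1.f340, s2.f340)
        assert np.array_equal(s1.f380, s2.f380)
        assert [e.onset_frame for e in t1] == [e.onset_frame for e in t2]
        s3, _ = simulate_scene(preset("wildtype", seed=43, frames=60, height=64, width=64))
        assert not np.array_equal(s1.f340, s3.f340)

    def test_poisson_arrival_count_calibrated(self):
        """Empirical mean transient count over many seeds sits inside the
        95% interval for the mean of Poisson(rate x hours) draws."""
        rate, n_seeds = 20.0, 100
        scene_hours = SceneParams(transient_rate_per_hour=rate, **SMALL).session_hours
        lam = rate * scene_hours
        counts = [
            simulate_scene(SceneParams(transient_rate_per_hour=rate, seed=s, **SMALL))[1].count
            for s in range(n_seeds)
        ]
        se = np.sqrt(lam / n_seeds)
        assert abs(np.mean(counts) - lam) < 1.96 * se

    def test_morphant_events_larger_in_area_and_amplitude(self):
        """Morphant-mode scenes produce bigger, brighter release events
        than wild-type scenes, on the generator's own truth log."""
        wt_r, wt_a, mo_r, mo_a = [], [], [], []
        for seed in range(6):
            kw = dict(transient_rate_per_hour=40.0, seed=seed, **SMALL)
            _, wt = simulate_scene(SceneParams(**kw))
            _, mo = simulate_scene(SceneParams(morphant_mode=True, **kw))
            wt_r += [e.radius_px for e in wt]
            wt_a += [e.amplitude_c for e in wt]
            mo_r += [e.radius_px for e in mo]
            mo_a += [e.amplitude_c for e in mo]
        assert np.mean(mo_r) > np.mean(wt_r)
        assert np.mean(mo_a) > np.mean(wt_a)

    def test_morphant_detected_events_larger(self):
        """The enlargement survives the full pipeline: detected morphant
        footprints and amplitudes exceed wild-type ones."""
        kw = dict(frames=80, height=64, width=64, transient_rate_per_hour=40.0)
        _, _, _, wt = simulate_and_detect(SceneParams(seed=1, **kw))
        _, _, _, mo = simulate_and_detect(SceneParams(seed=1, morphant_mode=True, **kw))
        assert np.mean([e.area_px for e in mo.transients]) > \
            np.mean([e.area_px for e in wt.transients])
        assert np.mean([e.peak_delta_ratio for e in mo.transients]) > \
            np.mean([e.peak_delta_ratio for e in wt.transients])

    def test_detection_recall_precision_on_default_scene(self):
        scene = SceneParams(transient_rate_per_hour=25.0, seed=11, **SMALL)
        _, truth, _, table = simulate_and_detect(scene)
        precision, recall, f1 = score_detection(transients_only(table), truth)
        assert precision >= 0.9 and recall >= 0.9


class TestPresets:
    @pytest.mark.parametrize("name, rate", [
        ("wildtype", 5.3), ("rgs3_morphant", 21.7),
        ("wnt5b_morphant", 1.3), ("double_morphant", 1.8),
    ])
    def test_group_presets_carry_reported_rates(self, name, rate):
        assert preset(name).transient_rate_per_hour == rate

    def test_roi_preset_has_reference_and_suppression(self):
        scene = preset("roi_suppression", frames=40, height=48, width=48)
        assert scene.roi_suppression is not None
        stack, _ = simulate_scene(scene)
        assert stack.reference_540 is not None

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            preset("mutant_x")

    def test_yaml_round_trip(self):
        scene = preset("rgs3_morphant", seed=9, frames=50, height=40, width=40)
        back = params_from_yaml(params_to_yaml(scene))
        assert back == scene
        s1, _ = simulate_scene(scene)
        s2, _ = simulate_scene(back)
        assert np.array_equal(s1.f340, s2.f340)


class TestScoreDetection:
    def _truth(self, specs):
        return GroundTruthEvents(events=[
            TrueEvent(onset_frame=o, duration_frames=1, center=c, radius_px=2.0, amplitude_c=0.25)
            for o, c in specs
        ])

    def _detected(self, specs):
        from furatrack import TransientEvent
        events = [
            TransientEvent(id=i, onset_frame=o, offset_frame=o + 1, duration_s=30.0,
                           centroid=c, area_px=4, peak_delta_ratio=0.5, label="transient")
            for i, (o, c) in enumerate(specs)
        ]
        return EventTable(events=events, dt_s=15.0, n_frames=100, height=32, width=32)

    def test_exact_match_scores_one(self):
        specs = [(5, (10.0, 10.0)), (20, (20.0, 5.0))]
        p, r, f1 = score_detection(self._detected(specs), self._truth(specs))
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_empty_detection_scores_zero(self):
        p, r, f1 = score_detection(self._detected([]), self._truth([(5, (1.0, 1.0))]))
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_extra_detection_halves_precision(self):
        truth = self._truth([(5, (10.0, 10.0))])
        detected = self._detected([(5, (10.0, 10.0)), (50, (25.0, 25.0))])
        p, r, _ = score_detection(detected, truth)
        assert p == 0.5 and r == 1.0

    def test_one_to_one_matching_with_competing_detections(self):
        truth = self._truth([(10, (10.0, 10.0))])
        detected = self._detected([(10, (11.0, 10.0)), (11, (10.0, 10.0))])
        p, r, _ = score_detection(detected, truth, tol_frames=1)
        assert r == 1.0 and p == 0.5


def dict_noise(**kw):
    from furatrack import NoiseParams
    return NoiseParams(**kw)


def transients_only(table: EventTable) -> EventTable:
    return EventTable(
        events=table.transients, dt_s=table.dt_s, n_frames=table.n_frames,
        height=table.height, width=table.width, t0_s=table.t0_s,
    )


class TestEmbryoGeometry:
    def test_ellipse_covers_center_not_corners(self):
        e = embryo_ellipse((64, 64))
        assert e[32, 32]
        assert not e[0, 0] and not e[63, 63]
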