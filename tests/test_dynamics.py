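"""Phase segmentation and dynamic-instability parameter computation."""
import numpy as np
import pytest

from mtkymo.config import SimConfig
from mtkymo import simgen
from mtkymo.containers import GROWTH, SHRINK, PhaseAnnotation
from mtkymo.dynamics import (
    annotation_from_truth,
    compute_dynamics,
    segment_phases,
    weighted_mean,
)


class TestSegmentPhases:
    def test_sawtooth_vertices_recovered_exactly(self, sawtooth_trajectory):
        ann = segment_phases(sawtooth_trajectory, min_event_displacement=0.0)
        # corners at 300/330/630/660/960 s with positions 3000/0/3000/0/3000
        expected_t = [0.0, 300.0, 330.0, 630.0, 660.0, 960.0, 990.0]
        expected_x = [0.0, 3000.0, 0.0, 3000.0, 0.0, 3000.0, 0.0]
        np.testing.assert_allclose(ann.vertices[:, 0], expected_t, atol=1e-6)
        np.testing.assert_allclose(ann.vertices[:, 1], expected_x, atol=1e-6)
        assert ann.labels == [GROWTH, SHRINK] * 3

    def test_constant_velocity_single_growth_phase(self, linear_trajectory):
        ann = segment_phases(linear_trajectory)
        assert ann.labels == [GROWTH]
        summary = compute_dynamics([ann])
        assert summary.n_catastrophes == 0
        assert summary.growth_rate == pytest.approx(10.0)

    def test_short_trajectory_rejected(self):
        from mtkymo.containers import EndTrajectory

        with pytest.raises(ValueError):
            segment_phases(EndTrajectory(np.array([0.0, 5.0]), np.array([0.0, 1.0])))

    def test_noisy_transitions_matched_within_two_frames(self):
        # 40 nm position noise; only events whose flanking phases displace at
        # least the 480 nm calling threshold are resolvable by construction
        cfg = SimConfig(rng_seed=0, pos_noise_sd=40.0)
        trajs = simgen.simulate_dynamic_instability(cfg, duration=1800.0, n=60)
        matched = total = 0
        for tr in trajs:
            ann = segment_phases(tr, min_event_displacement=480.0, smooth_window=5)
            det = [
                ann.vertices[j + 1, 0]
                for j in range(len(ann.labels) - 1)
                if ann.labels[j] != ann.labels[j + 1]
            ]
            for j, ph in enumerate(tr.truth_phases[:-1]):
                nxt = tr.truth_phases[j + 1]
                v = {GROWTH: 7.6, SHRINK: 100.0}
                if (ph[1] - ph[0]) * v[ph[2]] < 480 or (nxt[1] - nxt[0]) * v[nxt[2]] < 480:
                    continue
                total += 1
                if det and min(abs(ph[1] - d) for d in det) <= 10.0:
                    matched += 1
        assert matched / total >= 0.90

    def test_truth_bypass_returns_exact_annotation(self):
        cfg = SimConfig(rng_seed=4)
        tr = simgen.simulate_dynamic_instability(cfg, duration=900.0, n=1)[0]
        ann = segment_phases(tr, use_truth=True)
        assert len(ann.labels) == len(tr.truth_phases)
        np.testing.assert_allclose(ann.vertices, tr.truth_vertices)


class TestComputeDynamics:
    def _one_mt_annotation(self):
        # growth 10 um in 500 s, one catastrophe, shrink 5 um in 50 s
        verts = np.array([[0.0, 0.0], [500.0, 10000.0], [550.0, 5000.0]])
        return PhaseAnnotation(
            vertices=verts, labels=[GROWTH, SHRINK], observation_time=550.0, n_marks=3
        )

    def test_quoted_formula_arithmetic(self):
        ann = self._one_mt_annotation()
        s = compute_dynamics([ann])
        assert s.catastrophe_freq == pytest.approx(1 / 500.0)
        # trailing shrink is censored: no rescue
        assert s.n_rescues == 0
        assert s.dynamicity == pytest.approx((10000 + 5000) / 550.0)

    def test_dynamicity_error_is_pixel_size_times_marks_over_time(self):
        ann = self._one_mt_annotation()
        s = compute_dynamics([ann], pixel_size=160.0)
        assert s.dynamicity_err == pytest.approx(160.0 * 3 / 550.0)

    def test_shrink_ending_above_seed_is_rescue(self):
        verts = np.array(
            [[0.0, 0.0], [500.0, 5000.0], [530.0, 2000.0], [600.0, 2532.0]]
        )
        ann = PhaseAnnotation(
            vertices=verts,
            labels=[GROWTH, SHRINK, GROWTH],
            observation_time=600.0,
        )
        s = compute_dynamics([ann])
        assert s.n_rescues == 1
        assert s.rescue_per_length == pytest.approx(1 / 3.0)

    def test_shrink_reaching_seed_not_a_rescue(self):
        verts = np.array([[0.0, 0.0], [500.0, 5000.0], [550.0, 0.0], [600.0, 380.0]])
        ann = PhaseAnnotation(
            vertices=verts,
            labels=[GROWTH, SHRINK, GROWTH],
            observation_time=600.0,
        )
        assert compute_dynamics([ann]).n_rescues == 0

    def test_catastrophe_freq_invariant_to_splitting_growth_phase(self):
        ann = self._one_mt_annotation()
        # same microtubule split into two contiguous annotations
        a1 = PhaseAnnotation(
            vertices=np.array([[0.0, 0.0], [250.0, 5000.0]]),
            labels=[GROWTH],
            observation_time=250.0,
        )
        a2 = PhaseAnnotation(
            vertices=np.array([[250.0, 5000.0], [500.0, 10000.0], [550.0, 5000.0]]),
            labels=[GROWTH, SHRINK],
            observation_time=300.0,
        )
        s_whole = compute_dynamics([ann])
        s_split = compute_dynamics([a1, a2])
        assert s_whole.catastrophe_freq == pytest.approx(s_split.catastrophe_freq)

    def test_pure_growth_dynamicity_equals_growth_rate(self, linear_trajectory):
        ann = segment_phases(linear_trajectory)
        s = compute_dynamics([ann])
        assert s.dynamicity == pytest.approx(s.growth_rate)

    def test_empty_annotation_list_rejected(self):
        with pytest.raises(ValueError):
            compute_dynamics([])

    def test_truth_annotations_recover_generating_parameters(self):
        cfg = SimConfig(rng_seed=0)
        trajs = simgen.simulate_dynamic_instability(cfg, duration=1800.0, n=300)
        s = compute_dynamics([annotation_from_truth(t) for t in trajs])
        assert s.growth_rate == pytest.approx(7.6, rel=1e-9)
        assert s.shrink_rate == pytest.approx(100.0, rel=1e-9)
        assert abs(s.catastrophe_freq - 0.004) < 2 * s.catastrophe_freq_err
        assert abs(s.rescue_per_length - 0.2) < 2 * s.rescue_per_length_err


class TestWeightedMean:
    def test_equal_weights(self):
        m, se = weighted_mean([10.0, 20.0], [1.0, 1.0])
        assert m == pytest.approx(15.0)
        assert se == pytest.approx(1 / np.sqrt(2))

    def test_unequal_weights(self):
        m, se = weighted_mean([10.0, 20.0], [1.0, 2.0])
        assert m == pytest.approx(12.0)
        assert se == pytest.approx(1 / np.sqrt(1.25))

    def test_single_replicate_identity(self):
        assert weighted_mean([3.0], [0.5]) == (pytest.approx(3.0), pytest.approx(0.5))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([1.0, 2.0], [1.0, 0.0])
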