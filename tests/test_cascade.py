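"""Unit and property tests for the hierarchical association cascade."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pentrack as pt
from pentrack.cascade import (
    ReservedDetection,
    Tracker,
    appearance_similarity,
    first_match,
    predict_center,
    second_match,
    third_match,
    track_sequence,
)
from pentrack.core import Detection, Track, TrackerConfig, normalize_embedding
from pentrack.errors import SequenceOrderError, SimilarityUnavailableError


def make_track(tid, centers, frames=None, score=1.0, embedding=None,
               status="active", displacement=None):
    track = Track(track_id=tid)
    frames = frames if frames is not None else list(range(len(centers)))
    for f, c in zip(frames, centers):
        track.add_observation(Detection(f, tuple(c), (20.0, 20.0), score,
                                        embedding=embedding))
    track.status = status
    track.displacement = displacement
    return track


def det(frame, center, size=(20.0, 20.0), score=0.9, emb=None, disp=None):
    return Detection(frame, center, size, score, embedding=emb, displacement=disp)


class TestPredictCenter:
    def test_single_record_predicts_in_place(self):
        assert predict_center(make_track(1, [(10, 10)])) == (10, 10)

    def test_constant_velocity_extrapolation(self):
        assert predict_center(make_track(1, [(10, 10), (12, 13)])) == (14, 16)

    def test_supplied_displacement_overrides_finite_difference(self):
        track = make_track(1, [(40, 40), (50, 40)], displacement=(-2.0, 0.0))
        assert predict_center(track) == (48, 40)


class TestFirstMatch:
    def test_unambiguous_pair_matches(self):
        tracks = [make_track(1, [(10, 10)])]
        res = first_match(tracks, [det(1, (11.0, 10.0))], TrackerConfig())
        assert res.matches == [(0, 0)]

    def test_gate_violation_leaves_both_unmatched(self):
        tracks = [make_track(1, [(10, 10)])]
        far = det(1, (10.0 + 3 * 20.0, 10.0))  # 3 * sqrt(w*h) away
        res = first_match(tracks, [far], TrackerConfig())
        assert res.matches == []
        assert res.unmatched_detections == [0]
        assert res.unmatched_tracks == [0]

    def test_empty_inputs_are_valid(self):
        res = first_match([], [det(1, (0.0, 0.0))], TrackerConfig())
        assert res.unmatched_detections == [0]
        res = first_match([make_track(1, [(0, 0)])], [], TrackerConfig())
        assert res.unmatched_tracks == [0]

    def test_crossing_configuration_matches_nearest_first_oracle(self):
        # documented oracle: claim candidate-detection pairs in ascending
        # distance order
        tracks = [make_track(i + 1, [c]) for i, c in
                  enumerate([(0.0, 0.0), (30.0, 0.0), (60.0, 0.0)])]
        dets = [det(1, (29.0, 0.0)), det(1, (2.0, 0.0)), det(1, (58.0, 0.0))]
        res = first_match(tracks, dets, TrackerConfig())
        assert sorted(res.matches) == [(0, 1), (1, 0), (2, 2)]

    def test_well_separated_equals_min_total_distance_assignment(self, rng):
        for _ in range(20):
            centers = rng.uniform(0, 1000, size=(3, 2))
            if np.min(
                [np.linalg.norm(a - b) for a, b in itertools.combinations(centers, 2)]
            ) < 100:
                continue
            tracks = [make_track(i + 1, [tuple(c)]) for i, c in enumerate(centers)]
            dets = [det(1, tuple(c + rng.normal(0, 2, 2))) for c in centers[::-1]]
            res = first_match(tracks, dets, TrackerConfig())
            best = min(
                itertools.permutations(range(3)),
                key=lambda p: sum(
                    np.linalg.norm(centers[i] - np.array(dets[p[i]].center))
                    for i in range(3)
                ),
            )
            assert sorted(res.matches) == sorted((i, best[i]) for i in range(3))

    @given(st.integers(0, 10_000))
    def test_shrinking_gate_never_increases_matches(self, seed):
        r = np.random.default_rng(seed)
        tracks = [make_track(i + 1, [tuple(c)])
                  for i, c in enumerate(r.uniform(0, 200, size=(4, 2)))]
        dets = [det(5, tuple(c)) for c in r.uniform(0, 200, size=(4, 2))]
        counts = [
            len(first_match(tracks, dets, TrackerConfig(gate_factor=g)).matches)
            for g in (2.0, 1.0, 0.5, 0.25)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestAppearanceSimilarity:
    def setup_method(self):
        self.cfg = TrackerConfig()
        self.e1 = normalize_embedding(np.array([1.0, 0.0]))
        self.e2 = normalize_embedding(np.array([0.0, 1.0]))

    def _track(self, emb, last_frame, score):
        track = make_track(1, [(0, 0)], frames=[last_frame], score=score,
                           embedding=emb)
        return track

    def test_identical_embeddings_fresh_track(self):
        track = self._track(self.e1, 0, 1.0)
        d = det(1, (0.0, 0.0), emb=self.e1)
        assert appearance_similarity(track, d, 1, self.cfg) == pytest.approx(1.0)

    def test_orthogonal_embeddings_zero(self):
        track = self._track(self.e1, 0, 0.7)
        d = det(3, (0.0, 0.0), emb=self.e2)
        assert appearance_similarity(track, d, 3, self.cfg) == pytest.approx(0.0)

    def test_hand_arithmetic_inverse_decay(self):
        # cosine 0.8, alpha = 4, beta = 0.5, g = 1/alpha -> 0.8 * 0.5 / 4
        emb_a = normalize_embedding(np.array([1.0, 0.0]))
        emb_b = normalize_embedding(np.array([0.8, 0.6]))
        track = self._track(emb_a, 0, 0.5)
        d = det(4, (0.0, 0.0), emb=emb_b)
        assert appearance_similarity(track, d, 4, self.cfg) == pytest.approx(0.1)

    def test_exponential_decay_option(self):
        cfg = TrackerConfig(time_decay="exponential", time_decay_rate=0.5)
        track = self._track(self.e1, 0, 1.0)
        d = det(2, (0.0, 0.0), emb=self.e1)
        assert appearance_similarity(track, d, 2, cfg) == pytest.approx(
            math.exp(-1.0)
        )

    def test_missing_embedding_signals_unavailable(self):
        track = self._track(None, 0, 1.0)
        with pytest.raises(SimilarityUnavailableError):
            appearance_similarity(track, det(1, (0.0, 0.0), emb=self.e1), 1, self.cfg)


def _orthogonal_embedding_pairs(matrix):
    """Unit vectors whose inner products reproduce ``matrix`` exactly."""
    nt, nd = matrix.shape
    dim = nt + nd
    det_vecs = [np.eye(dim)[j] for j in range(nd)]
    track_vecs = []
    for i in range(nt):
        v = np.zeros(dim)
        v[:nd] = matrix[i]
        v[nd + i] = math.sqrt(max(0.0, 1.0 - np.sum(matrix[i] ** 2)))
        track_vecs.append(v)
    return track_vecs, det_vecs


class TestSecondMatch:
    def _pair(self, matrix, floor=-10.0):
        """Tracks/detections engineered so similarity equals ``matrix``."""
        matrix = np.asarray(matrix, dtype=float)
        cfg = TrackerConfig(similarity_floor=floor)
        track_vecs, det_vecs = _orthogonal_embedding_pairs(matrix)
        tracks = [
            make_track(i + 1, [(0, 0)], frames=[0], score=1.0,
                       embedding=normalize_embedding(v), status="lost")
            for i, v in enumerate(track_vecs)
        ]
        dets = [det(1, (0.0, 0.0), emb=normalize_embedding(v)) for v in det_vecs]
        return tracks, dets, cfg

    def test_single_pair_with_identical_embedding_matches(self):
        e = normalize_embedding(np.array([0.3, 0.4, 0.5]))
        track = make_track(7, [(0, 0)], frames=[0], score=1.0, embedding=e,
                           status="lost")
        res = second_match([track], [det(2, (0.0, 0.0), emb=e)], 2, TrackerConfig())
        assert res.matches == [(0, 0)]

    def test_dominant_diagonal_assignment(self):
        tracks, dets, cfg = self._pair([[0.25, 0.05], [0.1, 0.2]])
        res = second_match(tracks, dets, 1, cfg)
        assert sorted(res.matches) == [(0, 0), (1, 1)]

    def test_equals_brute_force_on_random_matrices(self, rng):
        # scaled so the similarity matrix is exactly embeddable
        for trial in range(100):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            matrix = rng.uniform(-0.3, 0.3, size=(n, m))
            tracks, dets, cfg = self._pair(matrix)
            res = second_match(tracks, dets, 1, cfg)
            total = sum(matrix[t, d] for t, d in res.matches)
            k = min(n, m)
            best = max(
                sum(matrix[list(rows), list(perm)])
                for rows in itertools.combinations(range(n), k)
                for perm in itertools.permutations(range(m), k)
            )
            assert total == pytest.approx(best, abs=1e-9)

    def test_similarity_floor_drops_negative_assignments(self):
        tracks, dets, cfg = self._pair([[-0.2]], floor=0.0)
        res = second_match(tracks, dets, 1, cfg)
        assert res.matches == []

    def test_all_unavailable_returns_inputs_unmatched(self):
        track = make_track(1, [(0, 0)], frames=[0], status="lost")
        res = second_match([track], [det(1, (0.0, 0.0))], 1, TrackerConfig())
        assert res.matches == []
        assert res.unmatched_tracks == [0]
        assert res.unmatched_detections == [0]


class TestThirdMatch:
    def test_high_score_leftover_spawns_new_track(self):
        new, low = third_match([det(0, (0.0, 0.0), score=0.7)], TrackerConfig())
        assert new == [0] and low == []

    def test_low_score_leftover_is_reserved(self):
        new, low = third_match([det(0, (0.0, 0.0), score=0.3)], TrackerConfig())
        assert new == [] and low == [0]

    def test_reserved_detection_expires_after_reserve_frames(self):
        tracker = Tracker(TrackerConfig(reserve_frames=3))
        tracker.step(0, [det(0, (500.0, 500.0), score=0.3)])
        assert len(tracker.reserved_pool) == 1
        for f in range(1, 5):
            tracker.step(f, [])
        assert tracker.reserved_pool == []

    def test_reserved_detection_confirmed_by_nearby_later_detection(self):
        tracker = Tracker()
        tracker.step(0, [det(0, (500.0, 500.0), score=0.3)])
        res = tracker.step(1, [det(1, (502.0, 500.0), score=0.9)])
        assert len(res.matches) == 1
        assert tracker.reserved_pool == []
        (traj,) = tracker.trajectories()
        assert list(traj.frames) == [0, 1]  # seeded from the reserved box


class TestStep:
    def test_first_frame_confident_detections_spawn_tracks(self):
        tracker = Tracker()
        dets = [det(0, (100.0 * i, 100.0), score=0.9) for i in range(3)]
        res = tracker.step(0, dets)
        assert sorted(res.new_track_ids) == [1, 2, 3]
        assert res.matches == []

    def test_perfect_continuation_resolves_in_stage_one(self):
        tracker = Tracker()
        tracker.step(0, [det(0, (100.0 * i, 100.0), score=0.9) for i in range(3)])
        res = tracker.step(1, [det(1, (100.0 * i, 100.0), score=0.9) for i in range(3)])
        assert len(res.matches) == 3
        assert res.new_track_ids == [] and res.reserved == []

    def test_low_score_admission_filter_discards(self):
        tracker = Tracker()
        res = tracker.step(0, [det(0, (0.0, 0.0), score=0.1)])
        assert res.discarded == [0]

    def test_reappearance_after_two_frame_gap_keeps_identity(self):
        # hand-traced cascade: spawn, match, vanish for 2 frames, reappear
        # with the preserved embedding -> second matching revives the track
        e = normalize_embedding(np.arange(1.0, 9.0))
        far = normalize_embedding(-np.arange(1.0, 9.0)[::-1])
        tracker = Tracker()
        tracker.step(0, [det(0, (100.0, 100.0), score=0.9, emb=e),
                         det(0, (600.0, 600.0), score=0.9, emb=far)])
        tracker.step(1, [det(1, (101.0, 100.0), score=0.9, emb=e),
                         det(1, (600.0, 601.0), score=0.9, emb=far)])
        tracker.step(2, [det(2, (600.0, 602.0), score=0.9, emb=far)])
        tracker.step(3, [det(3, (600.0, 603.0), score=0.9, emb=far)])
        res = tracker.step(4, [det(4, (140.0, 100.0), score=0.9, emb=e),
                               det(4, (600.0, 604.0), score=0.9, emb=far)])
        assert (1, 0) in res.matches  # original id 1 revived
        assert res.new_track_ids == []

    def test_out_of_order_frame_rejected(self):
        tracker = Tracker()
        tracker.step(5, [])
        with pytest.raises(SequenceOrderError):
            tracker.step(5, [])

    @given(st.integers(0, 10_000))
    def test_partition_invariant_on_random_streams(self, seed):
        r = np.random.default_rng(seed)
        tracker = Tracker()
        for f in range(8):
            dets = [
                det(f, tuple(r.uniform(0, 400, 2)), score=float(r.uniform(0, 1)),
                    emb=normalize_embedding(r.normal(size=8)))
                for _ in range(int(r.integers(0, 6)))
            ]
            res = tracker.step(f, dets)
            claimed = (
                [d for _, d in res.matches]
                + list(res.new_track_detections.values())
                + res.reserved
                + res.discarded
            )
            assert sorted(claimed) == list(range(len(dets)))


class TestTrackSequence:
    def test_noiseless_scene_reproduces_ground_truth(self):
        scene = pt.generate_scene(
            pt.SceneConfig(n_piglets=12, n_frames=30, noise=pt.NoiseConfig.zero())
        )
        trajs = track_sequence(scene.detections)
        assert len(trajs) == 13  # 12 piglets + sow
        gt_by_class = {(t.class_label, tuple(t.centers[0])) for t in
                       scene.gt_trajectories}
        hyp_by_class = {(t.class_label, tuple(t.centers[0])) for t in trajs}
        assert gt_by_class == hyp_by_class
        for traj in trajs:
            assert len(traj) == 30

    def test_scripted_occlusion_preserves_identity_count(self):
        scene = pt.generate_scene(
            pt.SceneConfig(
                n_piglets=6,
                n_frames=40,
                occlusion_script=((3, 15, 5, 0.25),),
                noise=pt.NoiseConfig(0.5, 0.3, 0.05, 0.0, 0.0),
                seed=3,
            )
        )
        trajs = track_sequence(scene.detections)
        assert len(trajs) == len(scene.gt_trajectories)

    def test_deterministic_given_identical_input(self):
        scene = pt.generate_scene(pt.SceneConfig(n_piglets=5, n_frames=25, seed=9))
        a = track_sequence(scene.detections)
        b = track_sequence(scene.detections)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            assert ta.track_id == tb.track_id
            np.testing.assert_array_equal(ta.frames, tb.frames)
            np.testing.assert_array_equal(ta.centers, tb.centers)

    def test_empty_stream_yields_no_trajectories(self):
        assert track_sequence([]) == []
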