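import itertools

import numpy as np
import pytest

from cnswave import wave_detection as wd
from cnswave.errors import SchemaError
from cnswave.volume_io import VolumeSeries


def synthetic_wave_traces(
    T=600, dt=0.2, events=((40.0, "forward"), (70.0, "backward")), noise=0.0, seed=0
):
    """16 hemisegment traces with staggered Gaussian bumps per wave."""
    rng = np.random.default_rng(seed)
    t = np.arange(T) * dt
    data = np.zeros((16, T))
    labels = list(wd.HEMISEGMENT_LABELS)
    for time, direction in events:
        for i, label in enumerate(labels):
            seg = int(label[1]) - 1  # 0..7 for A1..A8
            frac = (7 - seg) / 7 if direction == "forward" else seg / 7
            centre = time + (frac - 0.5) * 6.0
            data[i] += np.exp(-0.5 * ((t - centre) / 0.8) ** 2)
    data += noise * rng.standard_normal(data.shape)
    return wd.TraceMatrix(data, labels, dt)


class TestRoiTraces:
    def test_single_voxel_roi_reproduces_voxel_series(self):
        data = np.random.default_rng(0).random((4, 4, 2, 6))
        dff = VolumeSeries(data)
        rois = wd.RoiSet({"v": np.array([[1, 2, 0]])})
        tm = wd.extract_roi_traces(dff, rois)
        np.testing.assert_allclose(tm.trace("v"), data[1, 2, 0, :])

    def test_two_voxel_roi_averages(self):
        data = np.zeros((2, 2, 1, 4))
        data[0, 0, 0] = 0.0
        data[1, 0, 0] = 2.0
        rois = wd.RoiSet({"pair": np.array([[0, 0, 0], [1, 0, 0]])})
        tm = wd.extract_roi_traces(VolumeSeries(data), rois)
        np.testing.assert_allclose(tm.trace("pair"), 1.0)

    def test_out_of_bounds_roi_names_the_roi(self):
        dff = VolumeSeries(np.zeros((2, 2, 2, 2)))
        rois = wd.RoiSet({"bad": np.array([[5, 0, 0]])})
        with pytest.raises(IndexError, match="bad"):
            wd.extract_roi_traces(dff, rois)

    def test_chunked_extraction_matches_direct(self):
        data = np.random.default_rng(1).random((6, 5, 4, 50))
        dff = VolumeSeries(data)
        rois = wd.RoiSet({"r": np.array([[0, 0, 0], [3, 2, 1], [5, 4, 3]])})
        a = wd.extract_roi_traces(dff, rois, chunk_frames=7)
        b = wd.extract_roi_traces(dff, rois, chunk_frames=1000)
        np.testing.assert_allclose(a.data, b.data)


class TestPreprocessTraces:
    def test_constant_traces_become_all_zero(self):
        tm = wd.TraceMatrix(
            np.full((16, 100), 3.0), list(wd.HEMISEGMENT_LABELS), 0.2
        )
        pre = wd.preprocess_traces(tm, skip=2.0)
        assert not pre.X.any()

    def test_left_right_symmetric_input_equals_single_side(self):
        tm = synthetic_wave_traces()
        pre = wd.preprocess_traces(tm, skip=0.0)
        # rows already identical L/R by construction: averaging is a no-op
        left = tm.data[0::2]
        z = np.array([wd._zscore(r) for r in left])
        z = z - np.array([wd._zscore(r) for r in tm.data]).mean(axis=0)
        np.testing.assert_allclose(pre.X, z, atol=1e-10)

    def test_zscore_rows_have_unit_moments(self, rng):
        data = rng.random((16, 400)) * 5 + 1
        tm = wd.TraceMatrix(data, list(wd.HEMISEGMENT_LABELS), 0.2)
        n_skip = int(round(10.0 / 0.2))
        z = np.array([wd._zscore(r[n_skip:]) for r in data])
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-12)

    def test_missing_hemisegment_label_rejected(self):
        tm = wd.TraceMatrix(np.zeros((2, 50)), ["A1L", "A1R"], 0.2)
        with pytest.raises(SchemaError):
            wd.preprocess_traces(tm)

    def test_skip_longer_than_recording_rejected(self):
        tm = wd.TraceMatrix(
            np.zeros((16, 50)), list(wd.HEMISEGMENT_LABELS), 0.2
        )
        with pytest.raises(ValueError):
            wd.preprocess_traces(tm, skip=100.0)


class TestEmbedding:
    def test_zero_matrix_embeds_to_zero_amplitude(self):
        pre = wd.PreprocessedTraces(np.zeros((8, 100)), 0.2, 0.0)
        emb = wd.embed(pre)
        assert not emb.amplitude.any()
        assert not wd.detect_waves(emb)

    def test_quadrature_rows_give_circular_trajectory(self):
        # staggered cosines span a 2D rotation: amplitude nearly constant,
        # unwrapped phase advances nearly linearly
        T = 400
        t = np.arange(T)
        X = np.array(
            [np.cos(2 * np.pi * t / 100 + 2 * np.pi * k / 8) for k in range(8)]
        )
        pre = wd.PreprocessedTraces(X, 0.2, 0.0)
        emb = wd.embed(pre)
        r = emb.amplitude
        assert r.std() / r.mean() < 0.05
        slopes = np.diff(emb.phase)
        assert np.abs(slopes - slopes.mean()).max() < 0.05 * abs(slopes.mean())

    def test_time_reversal_flips_phase_slope(self):
        tm = synthetic_wave_traces(events=((40.0, "forward"),))
        pre = wd.preprocess_traces(tm, skip=0.0)
        emb = wd.embed(pre)
        rev = wd.PreprocessedTraces(pre.X[:, ::-1].copy(), pre.frame_interval, 0.0)
        emb_rev = wd.embed(rev)
        np.testing.assert_allclose(
            emb.amplitude, emb_rev.amplitude[::-1], atol=1e-8
        )
        peak = np.argmax(emb.amplitude)
        hw = int(round(1.0 / 0.2))
        s1 = wd._phase_slope(emb.phase, peak, hw, 0.2)
        s2 = wd._phase_slope(
            emb_rev.phase, len(emb_rev.phase) - 1 - peak, hw, 0.2
        )
        assert np.sign(s1) == -np.sign(s2)


class TestDetectWaves:
    def _embedding_from(self, amplitude, phase, dt=0.2):
        return wd.Embedding(
            v1=amplitude * np.cos(phase),
            v2=amplitude * np.sin(phase),
            singular_values=np.ones(2),
            amplitude=amplitude,
            phase=phase,
            frame_interval=dt,
            t_start=0.0,
        )

    def test_single_bump_with_phase_ramp_gives_one_event(self):
        t = np.arange(0, 100, 0.2)
        amp = 0.1 * np.exp(-0.5 * ((t - 50) / 2.0) ** 2)
        phase = 0.3 * t
        events = wd.detect_waves(self._embedding_from(amp, phase))
        assert len(events) == 1
        assert events[0].time == pytest.approx(50.0, abs=0.4)
        assert events[0].phase_slope == pytest.approx(0.3, rel=0.05)

    def test_subthreshold_amplitude_gives_no_events(self):
        t = np.arange(0, 100, 0.2)
        amp = 0.03 * np.exp(-0.5 * ((t - 50) / 2.0) ** 2)
        events = wd.detect_waves(self._embedding_from(amp, 0.3 * t))
        assert events == []

    def test_subthreshold_phase_slope_discarded(self):
        t = np.arange(0, 100, 0.2)
        amp = 0.1 * np.exp(-0.5 * ((t - 50) / 2.0) ** 2)
        events = wd.detect_waves(self._embedding_from(amp, 0.05 * t))
        assert events == []

    def test_close_peaks_resolved_to_larger(self):
        t = np.arange(0, 100, 0.2)
        amp = 0.10 * np.exp(-0.5 * ((t - 50) / 0.4) ** 2) + 0.08 * np.exp(
            -0.5 * ((t - 51) / 0.4) ** 2
        )
        events = wd.detect_waves(self._embedding_from(amp, 0.3 * t))
        assert len(events) == 1
        assert events[0].time == pytest.approx(50.0, abs=0.3)

    def test_raising_threshold_never_adds_events(self):
        tm = synthetic_wave_traces(
            events=((40.0, "forward"), (70.0, "backward"), (100.0, "forward")),
            noise=0.02,
            T=700,
        )
        pre = wd.preprocess_traces(tm, skip=0.0)
        emb = wd.embed(pre)
        counts = [
            len(wd.detect_waves(emb, amp_thresh=th))
            for th in (0.01, 0.04, 0.08, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_greedy_separation_is_lexicographically_optimal(self, rng):
        # on small instances the greedy rule (descending amplitude) yields
        # the subset whose sorted amplitude sequence is lexicographically
        # maximal among all min-separation-feasible subsets
        for _ in range(30):
            n = rng.integers(3, 12)
            cand = np.sort(rng.choice(np.arange(200), size=n, replace=False))
            amps = rng.random(n)
            sep = float(rng.integers(5, 40))
            kept = wd._greedy_separate(cand, amps, sep)
            amp_of = dict(zip(cand, amps))
            best = None
            for mask in itertools.product([0, 1], repeat=n):
                subset = [cand[i] for i in range(n) if mask[i]]
                if any(
                    abs(a - b) < sep
                    for a, b in itertools.combinations(subset, 2)
                ):
                    continue
                key = sorted((amp_of[i] for i in subset), reverse=True)
                if best is None or key > best[0]:
                    best = (key, sorted(subset))
            assert sorted(kept) == best[1]

    def test_direction_calibration_from_segment_order(self):
        tm = synthetic_wave_traces(
            events=((40.0, "forward"), (75.0, "backward"), (110.0, "forward")),
            T=800,
        )
        events = wd.detect_fictive_waves(tm, skip=0.0)
        assert [e.direction for e in sorted(events, key=lambda e: e.time)] == [
            "forward",
            "backward",
            "forward",
        ]

    def test_detection_invariant_to_embedding_sign_flip(self):
        tm = synthetic_wave_traces(
            events=((40.0, "forward"), (75.0, "backward")), T=700
        )
        pre = wd.preprocess_traces(tm, skip=0.0)
        emb = wd.embed(pre)
        segs = tm.segment_traces()
        ev1 = wd.detect_waves(emb, segment_traces=segs)
        flipped = wd.Embedding(
            -emb.v1,
            -emb.v2,
            emb.singular_values,
            emb.amplitude,
            np.unwrap(np.arctan2(-emb.v2, -emb.v1)),
            emb.frame_interval,
            emb.t_start,
        )
        ev2 = wd.detect_waves(flipped, segment_traces=segs)
        assert [(round(e.time, 1), e.direction) for e in ev1] == [
            (round(e.time, 1), e.direction) for e in ev2
        ]


class TestEvaluateDetection:
    def _ev(self, time, direction):
        return wd.WaveEvent(time, direction, 0.1, 0.3)

    def test_perfect_detection_scores_perfectly(self):
        det = [self._ev(10, "forward"), self._ev(30, "backward")]
        ann = [(10.0, "forward"), (30.0, "backward")]
        assert wd.evaluate_detection(det, ann) == (1.0, 0.0)

    def test_partial_matching_oracle_case(self):
        det = [self._ev(101, "forward"), self._ev(205, "forward"), self._ev(400, "forward")]
        ann = [(100.0, "forward"), (200.0, "forward"), (300.0, "forward")]
        hit, fa = wd.evaluate_detection(det, ann, match_tol=6.0)
        assert hit == pytest.approx(2 / 3)
        assert fa == pytest.approx(1 / 3)
        # at a 3 s tolerance the 205 s detection can no longer match 200 s
        hit3, fa3 = wd.evaluate_detection(det, ann, match_tol=3.0)
        assert hit3 == pytest.approx(1 / 3)
        assert fa3 == pytest.approx(2 / 3)

    def test_direction_flip_fails_all_matches(self):
        det = [self._ev(10, "backward"), self._ev(30, "forward")]
        ann = [(10.0, "forward"), (30.0, "backward")]
        assert wd.evaluate_detection(det, ann) == (0.0, 1.0)

    def test_empty_annotations_undefined_hit_rate(self):
        hit, fa = wd.evaluate_detection([self._ev(1, "forward")], [])
        assert np.isnan(hit)

    def test_one_to_one_matching_no_double_credit(self):
        det = [self._ev(10.0, "forward"), self._ev(10.5, "forward")]
        ann = [(10.0, "forward")]
        hit, fa = wd.evaluate_detection(det, ann)
        assert hit == 1.0
        assert fa == pytest.approx(0.5)


class TestWaveStatistics:
    def test_frequency_is_count_over_duration(self):
        events = [wd.WaveEvent(100.0 * i, "forward", 0.1, 0.3) for i in range(10)]
        tm = synthetic_wave_traces(T=5000, events=())
        stats = wd.wave_statistics(events, tm, analysed_duration_s=1000.0)
        assert stats["forward"]["frequency_mhz"] == pytest.approx(10.0)
        assert stats["backward"]["count"] == 0

    def test_duration_from_terminal_segment_peaks(self):
        tm = synthetic_wave_traces(events=((60.0, "forward"),), T=600)
        events = [wd.WaveEvent(60.0, "forward", 0.1, 0.3)]
        stats = wd.wave_statistics(events, tm)
        # bumps staggered 6 s A8->A1 by construction
        assert stats["forward"]["duration_mean_s"] == pytest.approx(6.0, abs=0.21)
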