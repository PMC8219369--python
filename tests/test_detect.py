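"""Interval features, sigmoid bounding, library matching, event assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from szloop import detect, synthgen

FS = 512.0

finite_intervals = hnp.arrays(
    dtype=np.float64,
    shape=st.integers(64, 256),
    elements=st.floats(-100, 100, allow_nan=False),
)
gains = st.floats(0.1, 10.0)


class TestCoastline:
    def test_hand_example(self):
        assert detect.coastline([0, 1, -1, 2]) == 6.0

    def test_constant_is_zero(self):
        assert detect.coastline(np.full(100, 4.2)) == 0.0

    def test_unit_sine_coastline(self):
        # one second of A*sin(2*pi*f*t) sums to ~4*A*f of absolute change
        t = np.arange(int(FS)) / FS
        assert detect.coastline(np.sin(2 * np.pi * 10 * t)) == pytest.approx(40.0, rel=0.01)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect.coastline([1.0])

    @settings(deadline=None, max_examples=50)
    @given(v=finite_intervals, a=gains)
    def test_scale_equivariance(self, v, a):
        assert detect.coastline(a * v) == pytest.approx(a * detect.coastline(v), rel=1e-9)


class TestIntermittency:
    def test_one_dominant_step(self):
        v = np.cumsum([0.0] + [1.0] * 9 + [11.0])
        assert detect.intermittency(v) == pytest.approx(11 / 20)

    def test_equal_steps(self):
        v = np.arange(11.0)  # 10 equal steps, m = ceil(1) = 1
        assert detect.intermittency(v) == pytest.approx(0.1)

    def test_flat_degenerate(self):
        assert detect.intermittency(np.zeros(50)) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(v=finite_intervals, a=gains)
    def test_scale_invariance(self, v, a):
        base = detect.intermittency(v)
        assert detect.intermittency(a * v) == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestSpikiness:
    def test_one_large_bin(self, rng):
        # 51 bins of 10 samples at 512 Hz; one bin of range 10, others range 1
        v = np.tile([0.0, 1.0], 256)[:512] * 1.0
        v[100:110] = np.linspace(0, 10, 10)
        assert detect.spikiness(v, FS) == pytest.approx(10.0, rel=0.01)

    def test_constant_degenerate(self):
        assert detect.spikiness(np.ones(512), FS) == 1.0

    def test_bin_width_is_ten_samples_at_512(self):
        assert detect._bin_samples(FS, 0.0196) == 10

    def test_spike_on_noise_exceeds_pure_noise(self, rng):
        noise = rng.standard_normal(512)
        spiked = noise.copy()
        spiked[250:260] += 30 * np.hanning(10)
        assert detect.spikiness(spiked, FS) > 2 * detect.spikiness(noise, FS)

    @settings(deadline=None, max_examples=50)
    @given(v=finite_intervals, a=gains)
    def test_scale_invariance(self, v, a):
        if v.size < 2 * detect._bin_samples(FS, 0.0196):
            return
        base = detect.spikiness(v, FS)
        assert detect.spikiness(a * v, FS) == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestCoherence:
    def test_few_cycle_sine_near_one(self):
        t = np.arange(512) / FS
        assert detect.coherence_metric(np.sin(2 * np.pi * 5 * t)) >= 0.95

    def test_sixty_hz_sine_near_ten_sixtieths(self):
        t = np.arange(512) / FS
        val = detect.coherence_metric(np.sin(2 * np.pi * 60 * t))
        assert val == pytest.approx(10 / 60, abs=0.01)

    def test_monotone_ramp_is_one(self):
        assert detect.coherence_metric(np.linspace(0, 1, 256)) == pytest.approx(1.0)

    def test_flat_degenerate(self):
        assert detect.coherence_metric(np.zeros(64)) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(v=finite_intervals, a=gains)
    def test_scale_invariance(self, v, a):
        base = detect.coherence_metric(v)
        assert detect.coherence_metric(a * v) == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestSigmoid:
    CAL = detect.SigmoidCalibration(centres=[10, 0.5, 2, 0.3], scales=[2, 0.1, 0.5, 0.05])

    def test_centre_maps_to_half(self):
        out = detect.sigmoid_bound(np.array([10, 0.5, 2, 0.3]), self.CAL)
        np.testing.assert_allclose(out, 0.5)

    def test_asymptotes(self):
        hi = detect.sigmoid_bound(np.full(4, 1e9), self.CAL)
        lo = detect.sigmoid_bound(np.full(4, -1e9), self.CAL)
        np.testing.assert_allclose(hi, 1.0)
        np.testing.assert_allclose(lo, 0.0)

    def test_strictly_increasing(self, rng):
        x1 = rng.normal(size=4)
        x2 = x1 + 0.5
        assert np.all(
            detect.sigmoid_bound(x2, self.CAL) > detect.sigmoid_bound(x1, self.CAL)
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            detect.SigmoidCalibration(centres=[0, 0, 0, 0], scales=[1, 1, 0, 1])


class TestCalibrateSigmoid:
    def test_centre_is_midpoint_of_medians(self, rng):
        base = rng.normal(10, 1, size=(200, 4))
        seiz = rng.normal(30, 1, size=(200, 4))
        cal = detect.calibrate_sigmoid(base, seiz)
        np.testing.assert_allclose(cal.centres, 0.5 * (np.median(base, 0) + np.median(seiz, 0)))

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            detect.calibrate_sigmoid(np.ones((10, 4)), np.full((10, 4), 2.0))

    def test_identical_distributions_warn(self, rng):
        x = rng.normal(size=(50, 4))
        with pytest.warns(UserWarning, match="separate"):
            detect.calibrate_sigmoid(x, x.copy())

    def test_seizure_intervals_separate_after_calibration(
        self, training_recording, library, detector_config
    ):
        """>=90% of true-seizure intervals score >0.5 on >=3 of 4 features."""
        rec, truth = training_recording
        raw = detect.interval_features(rec.samples[0], rec.fs, detector_config)
        starts = np.arange(raw.shape[0]) * 1.0
        inside = np.zeros(raw.shape[0], dtype=bool)
        for a, b in truth.seizure_intervals:
            inside |= (starts >= a) & (starts + 1 <= b)
        sig = detect.sigmoid_bound(raw[inside], library.calibration)
        assert np.mean((sig > 0.5).sum(axis=1) >= 3) >= 0.90


class TestClassify:
    LIB = detect.SeizureLibrary(
        entries=np.array([[0.9, 0.8, 0.7, 0.6], [0.5, 0.5, 0.5, 0.5]]),
        calibration=detect.SigmoidCalibration(np.zeros(4), np.ones(4)),
    )

    def test_exact_match(self):
        hit, d = detect.classify_interval(np.array([0.9, 0.8, 0.7, 0.6]), self.LIB)
        assert hit and d == 0.0

    def test_uniform_gap_rejected(self):
        hit, d = detect.classify_interval(np.array([0.7, 0.7, 0.7, 0.7]), self.LIB)
        assert not hit and d == pytest.approx(0.2)

    def test_boundary_inclusive(self):
        hit, d = detect.classify_interval(np.array([0.6, 0.6, 0.6, 0.6]), self.LIB)
        assert hit and d == pytest.approx(0.1)

    def test_matrix_agrees_with_scalar(self, rng):
        V = rng.uniform(0, 1, size=(100, 4))
        flags, best = detect.classify_matrix(V, self.LIB)
        for v, f, b in zip(V, flags, best):
            fs, bs = detect.classify_interval(v, self.LIB)
            assert fs == f and bs == pytest.approx(b)

    def test_empty_library_rejected(self):
        lib = detect.SeizureLibrary(
            entries=np.empty((0, 4)),
            calibration=detect.SigmoidCalibration(np.zeros(4), np.ones(4)),
        )
        with pytest.raises(ValueError):
            detect.classify_interval(np.zeros(4), lib)


class TestAssembleEvents:
    def test_three_consecutive_make_one_event(self):
        events = detect.assemble_events([False, True, True, True, False])
        assert len(events) == 1
        ev = events[0]
        assert ev.onset == 1.0 and ev.duration == 3.0 and ev.timestamp_interval == 3

    def test_interrupted_run_makes_no_event(self):
        assert detect.assemble_events([True, True, False, True, True]) == []

    def test_gap_tolerance_bridges_single_gap(self):
        cfg = detect.DetectorConfig(gap_tolerance_intervals=1)
        events = detect.assemble_events(
            [True, True, True, False, True, False, False, False], cfg
        )
        assert len(events) == 1 and events[0].duration == 5.0

    def test_gap_beyond_tolerance_splits(self):
        cfg = detect.DetectorConfig(gap_tolerance_intervals=0)
        flags = [True] * 3 + [False] + [True] * 3
        events = detect.assemble_events(flags, cfg)
        assert len(events) == 2

    def test_empty_input(self):
        assert detect.assemble_events([]) == []

    def test_event_validation(self):
        with pytest.raises(ValueError):
            detect.SeizureEvent(onset=5.0, offset=5.0, timestamp_interval=0)
        with pytest.raises(ValueError):
            detect.SeizureEvent(onset=0.0, offset=1.0, timestamp_interval=0, severity=7)


class TestIntervalFeatures:
    def test_matches_scalar_functions(self, rng):
        x = rng.standard_normal(int(5 * FS))
        cfg = detect.DetectorConfig()
        feats = detect.interval_features(x, FS, cfg)
        assert feats.shape == (5, 4)
        for i in range(5):
            seg = x[int(i * FS) : int((i + 1) * FS)]
            assert feats[i, 0] == pytest.approx(detect.coastline(seg), rel=1e-12)
            assert feats[i, 1] == pytest.approx(detect.intermittency(seg), rel=1e-12)
            assert feats[i, 2] == pytest.approx(detect.spikiness(seg, FS), rel=1e-12)
            assert feats[i, 3] == pytest.approx(detect.coherence_metric(seg), rel=1e-12)

    def test_trailing_partial_interval_dropped(self, rng):
        x = rng.standard_normal(int(2.5 * FS))
        assert detect.interval_features(x, FS).shape[0] == 2
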