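"""Generator contracts: determinism, spectral structure, event statistics."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as sst

from szloop import detect, synthgen

FS = 512.0


class TestBackground:
    def test_deterministic_in_seed(self, background_model):
        a = synthgen.generate_background(10.0, FS, background_model, seed=7)
        b = synthgen.generate_background(10.0, FS, background_model, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = synthgen.generate_background(10.0, FS, background_model, seed=8)
        assert not np.array_equal(a.samples, c.samples)

    def test_zero_amplitude_gives_zero_trace(self):
        model = synthgen.BackgroundModel(theta_power=0.0, amplitude_sd=0.0)
        rec = synthgen.generate_background(5.0, FS, model, seed=0)
        np.testing.assert_array_equal(rec.samples, 0.0)

    def test_invalid_duration_rejected(self, background_model):
        with pytest.raises(ValueError):
            synthgen.generate_background(0.0, FS, background_model, seed=0)
        with pytest.raises(ValueError):
            synthgen.generate_background(10.0, -1.0, background_model, seed=0)

    def test_theta_peak_at_theta_freq(self):
        model = synthgen.BackgroundModel(theta_power=0.5, theta_freq=7.0)
        rec = synthgen.generate_background(60.0, FS, model, seed=3)
        f, p = sps.periodogram(rec.samples[0], fs=FS)
        band = (f >= 1) & (f <= 30)
        assert abs(f[band][np.argmax(p[band])] - 7.0) <= 0.5

    def test_psd_slope_matches_noise_exponent(self):
        """Log-log periodogram slope over 1-100 Hz recovers the 1/f exponent."""
        model = synthgen.BackgroundModel(noise_exponent=1.5, theta_power=0.0)
        acc = None
        n_rep = 200
        for seed in range(n_rep):
            rec = synthgen.generate_background(30.0, FS, model, seed=seed)
            f, p = sps.periodogram(rec.samples[0], fs=FS)
            acc = p if acc is None else acc + p
        acc /= n_rep
        band = (f >= 1.0) & (f <= 100.0)
        slope = np.polyfit(np.log(f[band]), np.log(acc[band]), 1)[0]
        assert abs(slope + 1.5) < 0.1

    def test_variance_matches_amplitude(self):
        model = synthgen.BackgroundModel(amplitude_sd=50.0)
        rec = synthgen.generate_background(120.0, FS, model, seed=5)
        assert rec.samples[0].std() == pytest.approx(50.0, rel=0.1)


class TestLEDChannel:
    def test_default_protocol_pulse_counts(self):
        proto = synthgen.StimProtocol(n_epochs=2)
        rec, onsets = synthgen.generate_led_channel(proto, FS)
        # 30 s x 10 Hz -> 300 pulses of round(0.010*512)=5 high samples each
        first = rec.samples[0][int(onsets[0] * FS) : int((onsets[0] + 30) * FS)]
        n_high = int(first.sum())
        assert n_high == 300 * 5
        edges = np.diff(np.concatenate([[0.0], first])) > 0
        assert int(edges.sum()) == 300

    def test_session_length_arithmetic(self):
        proto = synthgen.StimProtocol()
        assert proto.session_duration == 120 * (30 + 90)
        rec, onsets = synthgen.generate_led_channel(synthgen.StimProtocol(n_epochs=3), FS)
        assert rec.n_samples == int(3 * 120 * FS)
        assert len(onsets) == 3

    def test_led_zero_between_epochs(self):
        proto = synthgen.StimProtocol(n_epochs=2)
        rec, onsets = synthgen.generate_led_channel(proto, FS)
        gap = rec.samples[0][: int((onsets[0] - 0.1) * FS)]
        assert not gap.any()

    def test_unrepresentable_pulse_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_led_channel(synthgen.StimProtocol(), fs=50.0)

    def test_protocol_invariants(self):
        with pytest.raises(ValueError):
            synthgen.StimProtocol(pulse_width=0.2)
        with pytest.raises(ValueError):
            synthgen.StimProtocol(n_epochs=0)


class TestLockedSession:
    @staticmethod
    def _epoch_lags(kappa, seed, n_epochs=30):
        proto = synthgen.StimProtocol(n_epochs=n_epochs, inter_epoch_interval=30.0)
        model = synthgen.BackgroundModel(locking_strength=kappa)
        rec, truth = synthgen.generate_locked_session(proto, model, FS, seed)
        _, onsets = synthgen.generate_led_channel(proto, FS)
        lfp = rec.channel("lfp")
        t = np.arange(rec.n_samples) / FS
        ref = np.exp(-2j * np.pi * 10.0 * t)  # LED-fundamental reference phasor
        lags = []
        for t0 in onsets:
            i0, i1 = int(t0 * FS), int((t0 + proto.epoch_duration) * FS)
            lags.append(np.angle(np.sum(lfp[i0:i1] * ref[i0:i1])))
        return np.asarray(lags)

    def test_circular_variance_decreases_with_kappa(self):
        """Per-epoch LFP-vs-LED phase lags cluster more tightly as κ grows."""
        cv = []
        for kappa in (0.5, 2.0, 100.0):
            lags = np.concatenate([self._epoch_lags(kappa, seed) for seed in (21, 22)])
            cv.append(1.0 - np.abs(np.exp(1j * lags).mean()))
        assert cv[0] > cv[1] > cv[2]

    def test_kappa_zero_has_no_locked_component(self):
        assert synthgen.locked_amplitude_gain(0.0) == 0.0
        proto = synthgen.StimProtocol(n_epochs=2, inter_epoch_interval=30.0)
        model = synthgen.BackgroundModel(locking_strength=0.0)
        rec, truth = synthgen.generate_locked_session(proto, model, FS, seed=5)
        bg = synthgen.generate_background(rec.duration, FS, model, seed=5)
        np.testing.assert_array_equal(rec.channel("lfp"), bg.samples[0])

    def test_ground_truth_carries_kappa_and_seed(self):
        proto = synthgen.StimProtocol(n_epochs=1)
        model = synthgen.BackgroundModel(locking_strength=2.5)
        _, truth = synthgen.generate_locked_session(proto, model, FS, seed=9)
        assert truth.locking_strength == 2.5 and truth.seed == 9
        assert truth.seizure_intervals == []


class TestEpilepticRecording:
    def test_zero_rate_gives_zero_events(self, background_model):
        model = synthgen.SeizureModel(event_rate=1e-12)
        _, truth = synthgen.generate_epileptic_recording(
            3600.0, FS, background_model, model, seed=1
        )
        assert truth.seizure_intervals == []

    def test_zero_amplitude_equals_background(self, background_model):
        model = synthgen.SeizureModel(spike_amplitude=0.0)
        rec, _ = synthgen.generate_epileptic_recording(
            600.0, FS, background_model, model, seed=2
        )
        bg = synthgen.generate_background(600.0, FS, background_model, seed=2)
        np.testing.assert_array_equal(rec.samples, bg.samples)

    def test_event_count_within_poisson_interval(self, background_model):
        model = synthgen.SeizureModel(event_rate=6.0)
        _, truth = synthgen.generate_epileptic_recording(
            2 * 3600.0, FS, background_model, model, seed=1
        )
        lo, hi = sst.poisson.interval(0.99, 12)
        assert lo <= len(truth.seizure_intervals) <= hi

    def test_intervals_sorted_nonoverlapping(self, background_model, seizure_model):
        _, truth = synthgen.generate_epileptic_recording(
            3600.0, FS, background_model, seizure_model, seed=17
        )
        iv = truth.seizure_intervals
        assert all(b > a for a, b in iv)
        assert all(iv[i + 1][0] >= iv[i][1] for i in range(len(iv) - 1))

    def test_within_seizure_coastline_exceeds_background(self, background_model):
        """Rhythmic discharges at >=3 SD raise the coastline in >=95% of 1-s bins."""
        model = synthgen.SeizureModel(spike_amplitude=3.0, event_rate=20.0)
        rec, truth = synthgen.generate_epileptic_recording(
            1800.0, FS, background_model, model, seed=4
        )
        feats = detect.interval_features(rec.samples[0], FS)
        starts = np.arange(feats.shape[0]) * 1.0
        inside = np.zeros(feats.shape[0], dtype=bool)
        for a, b in truth.seizure_intervals:
            inside |= (starts >= a + model.onset_ramp) & (starts + 1 <= b - model.onset_ramp)
        bg_coast = np.median(feats[~inside, 0])
        assert np.mean(feats[inside, 0] > bg_coast) >= 0.95

    def test_saturation_warns(self, background_model):
        model = synthgen.SeizureModel(event_rate=600.0, duration_median=30.0)
        with pytest.warns(UserWarning, match="half"):
            synthgen.generate_epileptic_recording(600.0, FS, background_model, model, seed=3)

    def test_seizure_model_validation(self):
        with pytest.raises(ValueError):
            synthgen.SeizureModel(duration_median=2.0)
        with pytest.raises(ValueError):
            synthgen.SeizureModel(event_rate=-1.0)


class TestBuildLibrary:
    def test_single_seizure_interval_count(self, background_model, detector_config):
        rec = synthgen.generate_background(60.0, FS, background_model, seed=6)
        truth = synthgen.GroundTruth(seizure_intervals=[(20.0, 30.0)], seed=6)
        lib = synthgen.build_library(rec, truth, detector_config, curate=False)
        assert len(lib) in (9, 10)

    def test_curation_drops_baseline_like_edge_entries(
        self, training_recording, detector_config
    ):
        rec, truth = training_recording
        full = synthgen.build_library(rec, truth, detector_config, curate=False)
        curated = synthgen.build_library(rec, truth, detector_config)
        assert 0 < len(curated) <= len(full)
        assert np.all((curated.entries > 0.5).sum(axis=1) >= 3)

    def test_deterministic(self, training_recording, detector_config):
        rec, truth = training_recording
        a = synthgen.build_library(rec, truth, detector_config)
        b = synthgen.build_library(rec, truth, detector_config)
        np.testing.assert_array_equal(a.entries, b.entries)

    def test_empty_truth_rejected(self, background_model, detector_config):
        rec = synthgen.generate_background(30.0, FS, background_model, seed=1)
        with pytest.raises(ValueError):
            synthgen.build_library(rec, synthgen.GroundTruth(), detector_config)

    def test_entries_inside_unit_cube(self, library):
        assert np.all(library.entries > 0) and np.all(library.entries < 1)
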