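"""Seeded synthetic hippocampal LFP with ground truth.

The generators in this module stand in for chronic in-vivo recordings: a
1/f-like broadband background with a theta oscillation, a 10 Hz square-pulse
LED channel, a stimulation-locked oscillatory component with tunable locking
strength, and spontaneous electrographic seizures rendered as high-amplitude
rhythmic spike trains.  Every generator is a pure function of its parameters
and an integer seed, and returns the ground truth the downstream analyses are
tested against.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import special

__all__ = [
    "StimProtocol",
    "SeizureModel",
    "BackgroundModel",
    "Recording",
    "GroundTruth",
    "generate_background",
    "generate_led_channel",
    "generate_locked_session",
    "generate_epileptic_recording",
    "build_library",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StimProtocol:
    """Optical stimulation protocol: trains of square pulses.

    Defaults are the in-vivo protocol: 120 epochs of 10 ms pulses at 10 Hz
    applied for 30 s, with 90 s between epochs.
    """

    pulse_rate: float = 10.0        # Hz
    pulse_width: float = 0.010      # s
    epoch_duration: float = 30.0    # s
    inter_epoch_interval: float = 90.0  # s
    n_epochs: int = 120

    def __post_init__(self) -> None:
        if self.pulse_width >= 1.0 / self.pulse_rate:
            raise ValueError("pulse_width must be shorter than a pulse period")
        if self.epoch_duration < 1.0 / self.pulse_rate:
            raise ValueError("epoch_duration must hold at least one pulse")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    @property
    def session_duration(self) -> float:
        """Total session length: one inter-epoch gap before every epoch."""
        return self.n_epochs * (self.epoch_duration + self.inter_epoch_interval)


@dataclass
class SeizureModel:
    """Spontaneous electrographic seizures as rhythmic discharge trains.

    Durations are log-normal (heavy-tailed, as in chronic epilepsy models),
    parameterised by the median in seconds and the log-scale dispersion.
    Spike amplitude is expressed in multiples of the background SD so the
    discharges scale with whatever background they ride on.
    """

    event_rate: float = 12.0        # events / hour
    duration_median: float = 25.0   # s
    duration_sigma: float = 0.45    # log-scale SD
    spike_rate: float = 8.0         # Hz within a seizure
    spike_amplitude: float = 5.0    # × background SD
    onset_ramp: float = 1.5         # s, linear amplitude ramp at both ends

    def __post_init__(self) -> None:
        for name in ("event_rate", "duration_median", "duration_sigma", "spike_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.duration_median <= 3.0:
            raise ValueError(
                "duration_median must exceed 3 s (a seizure must span at "
                "least three 1-s detector intervals)"
            )
        if self.spike_amplitude < 0:
            raise ValueError("spike_amplitude must be >= 0")


@dataclass
class BackgroundModel:
    """Background LFP: 1/f^a broadband noise plus a theta oscillation.

    ``locking_strength`` is the von Mises concentration κ of the per-epoch
    phase lag of the stimulation-locked component relative to the LED
    fundamental: κ = 0 leaves the LFP phase independent of the LED, κ → ∞
    approaches a deterministic lag.  The locked component's amplitude is
    scaled by the mean resultant R(κ) = I1(κ)/I0(κ) — the mean-field
    amplitude of a population of partially entrained oscillators — so both
    phase locking and 10 Hz power grow with κ.
    """

    noise_exponent: float = 1.0     # PSD slope (power ∝ f^-exponent)
    theta_freq: float = 7.0         # Hz
    theta_power: float = 0.3        # fraction of total variance
    locking_strength: float = 0.0   # κ ≥ 0
    amplitude_sd: float = 50.0      # overall background SD, µV
    locked_amplitude_sd: float = 4.0  # fully locked component amplitude, × SD
    theta_phase_diffusion: float = 0.3  # rad²/s; theta decorrelates across epochs

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_power < 1.0:
            raise ValueError("theta_power must be in [0, 1)")
        if self.locking_strength < 0:
            raise ValueError("locking_strength (kappa) must be >= 0")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be >= 0")


LED_ROLE = "LED"


@dataclass
class Recording:
    """Multi-channel time series in µV with per-channel roles.

    ``samples`` is channels × time; the LED channel, when present, is binary
    0/1 and dimensionless.
    """

    samples: np.ndarray
    fs: float
    channel_roles: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_roles):
            raise ValueError("one role per channel required")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        led = self.led_index()
        if led is not None:
            vals = np.unique(self.samples[led])
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("LED channel must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def led_index(self) -> int | None:
        for i, role in enumerate(self.channel_roles):
            if role.upper() == LED_ROLE:
                return i
        return None

    def channel(self, role: str) -> np.ndarray:
        """Return the first channel whose role matches (case-insensitive)."""
        for i, r in enumerate(self.channel_roles):
            if r.lower() == role.lower():
                return self.samples[i]
        raise KeyError(f"no channel with role {role!r}")

    def lfp_channels(self) -> np.ndarray:
        idx = [i for i, r in enumerate(self.channel_roles) if r.upper() != LED_ROLE]
        return self.samples[idx]


@dataclass
class GroundTruth:
    """Generator-side truth used by recovery tests."""

    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    locking_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        iv = sorted((float(a), float(b)) for a, b in self.seizure_intervals)
        for (a0, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("seizure intervals must be non-overlapping")
        for a, b in iv:
            if b <= a:
                raise ValueError("seizure offset must follow onset")
        self.seizure_intervals = iv

    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.seizure_intervals])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seizure_intervals": self.seizure_intervals,
                    "locking_strength": self.locking_strength,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seizure_intervals=[tuple(x) for x in d["seizure_intervals"]],
            locking_strength=d["locking_strength"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one master seed into independent per-component generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _colored_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ∝ f^-exponent, unit SD."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_background(
    duration: float, fs: float, model: BackgroundModel, seed: int
) -> Recording:
    """One channel of background LFP: shaped noise plus a theta sinusoid.

    Total variance is ``amplitude_sd**2``, split between the broadband noise
    and the theta component according to ``theta_power``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if fs <= 2 * model.theta_freq:
        raise ValueError("fs must exceed twice theta_freq")
    n = int(round(duration * fs))
    rng_noise, rng_theta = _rngs(seed, 2)
    t = np.arange(n) / fs
    sd = model.amplitude_sd
    noise = _colored_noise(n, fs, model.noise_exponent, rng_noise)
    noise *= sd * np.sqrt(1.0 - model.theta_power)
    theta_amp = sd * np.sqrt(2.0 * model.theta_power)
    # narrowband stochastic oscillation: Brownian phase drift makes theta
    # decorrelate between epochs, as a biological rhythm does
    phase0 = rng_theta.uniform(0, 2 * np.pi)
    if model.theta_phase_diffusion > 0 and theta_amp > 0:
        dphi = rng_theta.normal(0.0, np.sqrt(model.theta_phase_diffusion / fs), size=n)
        drift = np.cumsum(dphi)
    else:
        drift = 0.0
    theta = theta_amp * np.sin(2 * np.pi * model.theta_freq * t + phase0 + drift)
    return Recording(samples=noise + theta, fs=fs, channel_roles=["lfp"])


def generate_led_channel(
    protocol: StimProtocol, fs: float
) -> tuple[Recording, np.ndarray]:
    """Binary LED channel for a whole session, plus epoch onset times.

    Each epoch is preceded by one inter-epoch gap, so a full-length baseline
    window exists before every stimulation train.  Pulses are high for
    ``round(pulse_width * fs)`` samples.
    """
    width = int(round(protocol.pulse_width * fs))
    if width < 1:
        raise ValueError("pulse unrepresentable: pulse_width * fs < 1")
    if fs < 2.0 / protocol.pulse_width:
        warnings.warn("fs below 2/pulse_width: pulse edges are coarsely sampled")
    n = int(round(protocol.session_duration * fs))
    led = np.zeros(n)
    period = protocol.epoch_duration + protocol.inter_epoch_interval
    onsets = protocol.inter_epoch_interval + period * np.arange(protocol.n_epochs)
    pulses_per_epoch = int(np.floor(protocol.epoch_duration * protocol.pulse_rate))
    for t0 in onsets:
        for j in range(pulses_per_epoch):
            start = int(round((t0 + j / protocol.pulse_rate) * fs))
            led[start : start + width] = 1.0
    rec = Recording(samples=led, fs=fs, channel_roles=[LED_ROLE])
    return rec, onsets


def locked_amplitude_gain(kappa: float) -> float:
    """Mean resultant length R(κ) = I1(κ)/I0(κ) of a von Mises law."""
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def generate_locked_session(
    protocol: StimProtocol,
    background: BackgroundModel,
    fs: float,
    seed: int,
) -> tuple[Recording, GroundTruth]:
    """Background + LED session with a stimulation-locked 10 Hz component.

    During each stimulation epoch a sinusoid at the pulse rate is added whose
    phase lag to the LED fundamental is drawn once per epoch from a von Mises
    law with concentration κ (= ``background.locking_strength``).  Its
    amplitude is ``locked_amplitude_sd × amplitude_sd × R(κ)``; at κ = 0 the
    LFP is independent of the LED by construction.
    """
    led_rec, onsets = generate_led_channel(protocol, fs)
    n = led_rec.n_samples
    rng_bg_seed, rng_phase = np.random.SeedSequence(seed).spawn(2)
    bg = generate_background(n / fs, fs, background, seed)
    lfp = bg.samples[0].copy()

    kappa = background.locking_strength
    amp = background.locked_amplitude_sd * background.amplitude_sd * locked_amplitude_gain(kappa)
    rng = np.random.default_rng(rng_phase)
    t = np.arange(n) / fs
    for t0 in onsets:
        if kappa == 0:
            lag = rng.uniform(-np.pi, np.pi)
        else:
            lag = rng.vonmises(0.0, kappa)
        i0 = int(round(t0 * fs))
        i1 = min(n, int(round((t0 + protocol.epoch_duration) * fs)))
        if amp > 0:
            lfp[i0:i1] += amp * np.cos(
                2 * np.pi * protocol.pulse_rate * (t[i0:i1] - t0) - lag
            )
    rec = Recording(
        samples=np.vstack([lfp, led_rec.samples[0]]),
        fs=fs,
        channel_roles=["lfp", LED_ROLE],
    )
    truth = GroundTruth(seizure_intervals=[], locking_strength=kappa, seed=seed)
    return rec, truth


def _spike_kernel(fs: float, width_s: float = 0.040) -> np.ndarray:
    """Raised-cosine (Hann) deflection of unit peak amplitude."""
    w = max(3, int(round(width_s * fs)))
    return np.hanning(w)


def generate_epileptic_recording(
    duration: float,
    fs: float,
    background: BackgroundModel,
    seizures: SeizureModel,
    seed: int,
) -> tuple[Recording, GroundTruth]:
    """Background LFP with superimposed electrographic seizures.

    Event onsets follow a Poisson process at ``event_rate`` per hour;
    durations are log-normal.  Each seizure is a train of alternating-sign
    raised-cosine spikes at ``spike_rate`` with peak amplitude
    ``spike_amplitude × background SD``, with a linear amplitude ramp of
    ``onset_ramp`` seconds at onset and offset.  Overlapping drawn events are
    merged.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    bg = generate_background(duration, fs, background, seed)
    lfp = bg.samples[0].copy()
    n = lfp.size

    _, _, rng_ev_seed, rng_dur_seed = np.random.SeedSequence(seed).spawn(4)
    rng_ev = np.random.default_rng(rng_ev_seed)
    rng_dur = np.random.default_rng(rng_dur_seed)

    # Poisson onsets via exponential gaps
    rate_per_s = seizures.event_rate / 3600.0
    onsets = []
    t = rng_ev.exponential(1.0 / rate_per_s) if rate_per_s > 0 else np.inf
    while t < duration:
        onsets.append(t)
        t += rng_ev.exponential(1.0 / rate_per_s)

    mu = np.log(seizures.duration_median)
    intervals: list[tuple[float, float]] = []
    for on in onsets:
        dur = float(rng_dur.lognormal(mu, seizures.duration_sigma))
        off = min(on + dur, duration)
        if off - on < 1.0 / seizures.spike_rate:
            continue
        if intervals and on <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], off))
        else:
            intervals.append((on, off))

    covered = sum(b - a for a, b in intervals)
    if covered > 0.5 * duration:
        warnings.warn("seizure events cover more than half of the recording")

    kernel = _spike_kernel(fs)
    half = kernel.size // 2
    amp = seizures.spike_amplitude * background.amplitude_sd
    if amp > 0:
        for a, b in intervals:
            n_spikes = int(np.floor((b - a) * seizures.spike_rate))
            for j in range(n_spikes):
                ts = a + j / seizures.spike_rate
                ramp = min(
                    1.0,
                    (ts - a) / seizures.onset_ramp if seizures.onset_ramp > 0 else 1.0,
                    (b - ts) / seizures.onset_ramp if seizures.onset_ramp > 0 else 1.0,
                )
                ramp = max(ramp, 0.0)
                sign = 1.0 if j % 2 == 0 else -1.0
                i0 = int(round(ts * fs)) - half
                k0, k1 = max(0, -i0), min(kernel.size, n - i0)
                if k1 > k0:
                    lfp[i0 + k0 : i0 + k1] += sign * ramp * amp * kernel[k0:k1]

    rec = Recording(samples=lfp, fs=fs, channel_roles=["lfp"])
    truth = GroundTruth(seizure_intervals=intervals, locking_strength=0.0, seed=seed)
    return rec, truth


def build_library(
    recording: Recording,
    ground_truth: GroundTruth,
    detector_config,
    curate: bool = True,
):
    """Build a seizure library from a recording with known seizure intervals.

    Computes the four interval features for every 1-s interval, calibrates the
    sigmoid bounding on baseline-vs-seizure feature distributions, and stores
    the sigmoid-bounded vectors of all intervals lying fully inside true
    seizures.  Deterministic: the same input always yields the same library.

    With ``curate=True`` (default) entries that are not separable from
    baseline activity — fewer than 3 of their 4 sigmoid features above 0.5 —
    are dropped.  The first and last second of a seizure, where the discharge
    is still ramping, otherwise enter the library as baseline-like templates
    and make the nearest-entry similarity rule match ordinary background;
    curation mirrors the practice of building the library from reviewed,
    unambiguous seizure activity.
    """
    from . import detect  # deferred: detect imports nothing from here at import time

    if not ground_truth.seizure_intervals:
        raise ValueError("ground truth contains no seizures; cannot build a library")
    lfp = recording.lfp_channels()[0]
    raw = detect.interval_features(lfp, recording.fs, detector_config)
    L = detector_config.interval_length
    starts = np.arange(raw.shape[0]) * L
    in_seizure = np.zeros(raw.shape[0], dtype=bool)
    near_seizure = np.zeros(raw.shape[0], dtype=bool)
    margin = 2.0  # s kept out of the baseline pool around each event
    for a, b in ground_truth.seizure_intervals:
        in_seizure |= (starts >= a) & (starts + L <= b)
        near_seizure |= (starts + L > a - margin) & (starts < b + margin)
    if not in_seizure.any():
        raise ValueError("no 1-s interval lies fully inside a true seizure")
    calibration = detect.calibrate_sigmoid(raw[~near_seizure], raw[in_seizure])
    entries = detect.sigmoid_bound(raw[in_seizure], calibration)
    ids = np.flatnonzero(in_seizure)
    n_raw = entries.shape[0]
    if curate:
        keep = (entries > 0.5).sum(axis=1) >= 3
        if not keep.any():
            raise ValueError("curation removed every library entry")
        entries, ids = entries[keep], ids[keep]
    provenance = {
        "n_source_intervals": int(raw.shape[0]),
        "n_uncurated_entries": int(n_raw),
        "interval_ids": ids.tolist(),
        "seed": ground_truth.seed,
    }
    return detect.SeizureLibrary(entries=entries, calibration=calibration, provenance=provenance)
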