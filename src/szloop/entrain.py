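"""Phase-locking and spectral entrainment of the LFP to optical stimulation.

Two complementary metrics quantify how strongly rhythmic stimulation
entrains the hippocampal LFP:

* the **phase-locking value** (PLV): instantaneous phases of the LED and LFP
  channels are extracted with the Hilbert transform, and at each epoch
  timepoint the modulus of the trial-averaged unit phasor of the phase
  difference is computed — 1 for perfect locking, 0 for independence;
* the **entrainment power ratio**: the fraction of theta-band (3–13 Hz)
  periodogram power concentrated within ±1 Hz of the stimulation frequency.

Both are computed per epoch and referenced to the immediately preceding
equal-length baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "PLVResult",
    "EntrainConfig",
    "EntrainmentResult",
    "extract_phase",
    "epoch_session",
    "plv_timecourse",
    "baseline_subtracted_plv",
    "psd_periodogram",
    "entrainment_ratio",
    "entrainment_efficiency",
    "session_entrainment",
]


@dataclass
class EpochSet:
    """Trial-aligned phase and voltage matrices for one condition."""

    phase_led: np.ndarray       # trials × timepoints, radians in (-pi, pi]
    phase_lfp: np.ndarray
    voltage_lfp: np.ndarray
    condition: str              # "baseline" | "stimulation"
    fs: float

    def __post_init__(self) -> None:
        for name in ("phase_led", "phase_lfp", "voltage_lfp"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))
        if not (self.phase_led.shape == self.phase_lfp.shape == self.voltage_lfp.shape):
            raise ValueError("phase/voltage matrices must share one shape")

    @property
    def n_trials(self) -> int:
        return self.phase_led.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.phase_led.shape[1]


@dataclass
class PLVResult:
    plv_timecourse: np.ndarray
    mean_plv: float
    baseline_mean_plv: float
    baseline_subtracted_mean: float


@dataclass
class EntrainConfig:
    stim_freq: float = 10.0
    narrow_halfwidth: float = 1.0
    band_low: float = 3.0
    band_high: float = 13.0
    psd_window: str = "boxcar"

    def __post_init__(self) -> None:
        if not (
            self.band_low <= self.stim_freq - self.narrow_halfwidth
            and self.stim_freq + self.narrow_halfwidth <= self.band_high
        ):
            raise ValueError("narrow band must lie inside the wide band")


@dataclass
class EntrainmentResult:
    ratio_stim: np.ndarray
    ratio_baseline: np.ndarray
    efficiency: float           # median over epochs of (stim - baseline)
    pairs: np.ndarray = field(default=None)  # per-epoch (stim, baseline)


def extract_phase(signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase via the analytic signal, radians in (-pi, pi].

    The mean is removed before the Hilbert transform (a DC offset would
    otherwise bias the phase).  Constant input has no defined phase.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have at least two samples")
    x = x - x.mean()
    if np.all(x == 0):
        raise ValueError("phase undefined for a constant signal")
    return np.angle(sps.hilbert(x))


def epoch_session(
    recording,
    epoch_onsets: np.ndarray,
    epoch_duration: float,
    baseline_offset: float = 0.0,
    lfp_role: str = "lfp",
) -> tuple[EpochSet, EpochSet]:
    """Slice a continuous recording into baseline/stimulation epoch sets.

    Phase is extracted on the whole continuous trace and then sliced, which
    keeps Hilbert edge artefacts out of the epochs.  The baseline for each
    epoch is the equal-length window ending ``baseline_offset`` seconds
    before its onset (default: immediately preceding).  Epochs whose baseline
    or stimulation window falls outside the recording are dropped with a
    logged warning.
    """
    fs = recording.fs
    led_idx = recording.led_index()
    if led_idx is None:
        raise ValueError("recording has no LED channel")
    led = recording.samples[led_idx]
    lfp = recording.channel(lfp_role)
    ph_led = extract_phase(led)
    ph_lfp = extract_phase(lfp)

    L = int(round(epoch_duration * fs))
    n = lfp.size
    stim_rows, base_rows = [], []
    for t0 in np.asarray(epoch_onsets, dtype=float):
        i_stim = int(round(t0 * fs))
        i_base = int(round((t0 - baseline_offset) * fs)) - L
        if i_base < 0 or i_stim + L > n:
            logger.warning("epoch at t=%.1f s out of range; trial dropped", t0)
            continue
        if not led[i_stim : i_stim + L].any():
            logger.warning("LED silent during claimed epoch at t=%.1f s", t0)
        stim_rows.append((i_stim, i_stim + L))
        base_rows.append((i_base, i_base + L))

    def build(rows, condition):
        return EpochSet(
            phase_led=np.array([ph_led[a:b] for a, b in rows]),
            phase_lfp=np.array([ph_lfp[a:b] for a, b in rows]),
            voltage_lfp=np.array([lfp[a:b] for a, b in rows]),
            condition=condition,
            fs=fs,
        )

    return build(base_rows, "baseline"), build(stim_rows, "stimulation")


def plv_timecourse(phase_led: np.ndarray, phase_lfp: np.ndarray) -> np.ndarray:
    """Per-timepoint PLV across trials.

    PLV(τ) = | mean over trials of exp(i·(φ_LED(trial, τ) − φ_LFP(trial, τ))) |.
    """
    a = np.atleast_2d(np.asarray(phase_led, dtype=float))
    b = np.atleast_2d(np.asarray(phase_lfp, dtype=float))
    if a.shape != b.shape:
        raise ValueError("phase matrices must share one shape")
    if a.shape[0] < 2:
        raise ValueError("PLV needs at least two trials (degenerate at 1)")
    return np.abs(np.exp(1j * (a - b)).mean(axis=0))


def baseline_subtracted_plv(stim: EpochSet, base: EpochSet) -> PLVResult:
    """Mean PLV of the stimulation epochs referenced to baseline epochs."""
    if stim.phase_led.shape != base.phase_led.shape:
        raise ValueError("stimulation and baseline epoch sets must match in shape")
    tc_stim = plv_timecourse(stim.phase_led, stim.phase_lfp)
    tc_base = plv_timecourse(base.phase_led, base.phase_lfp)
    mean_stim = float(tc_stim.mean())
    mean_base = float(tc_base.mean())
    return PLVResult(
        plv_timecourse=tc_stim,
        mean_plv=mean_stim,
        baseline_mean_plv=mean_base,
        baseline_subtracted_mean=mean_stim - mean_base,
    )


def psd_periodogram(
    segment: np.ndarray, fs: float, window: str = "boxcar"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram (rectangular window, mean removed).

    Frequency resolution is fs/len(segment); integrated density equals the
    signal variance (Parseval).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < fs:
        raise ValueError("segment must be at least 1 s long")
    return sps.periodogram(x, fs=fs, window=window, detrend="constant")


def entrainment_ratio(
    freqs: np.ndarray, psd: np.ndarray, config: EntrainConfig | None = None
) -> float:
    """Narrow-band over wide-band cumulative PSD ratio, in [0, 1].

    Power in [stim_freq − halfwidth, stim_freq + halfwidth] divided by power
    in [band_low, band_high]; band endpoints inclusive, bins assigned by bin
    centre.
    """
    config = config or EntrainConfig()
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(psd, dtype=float)
    if f.max() < config.band_high:
        raise ValueError("frequency grid does not cover the wide band")
    wide = (f >= config.band_low) & (f <= config.band_high)
    narrow = (f >= config.stim_freq - config.narrow_halfwidth) & (
        f <= config.stim_freq + config.narrow_halfwidth
    )
    denom = p[wide].sum()
    if denom == 0:
        import warnings

        warnings.warn("zero wide-band power; entrainment ratio defined as 0")
        return 0.0
    return float(p[narrow].sum() / denom)


def entrainment_efficiency(
    stim_ratios: np.ndarray, base_ratios: np.ndarray
) -> EntrainmentResult:
    """Median per-epoch difference between stimulation and baseline ratios."""
    s = np.asarray(stim_ratios, dtype=float)
    b = np.asarray(base_ratios, dtype=float)
    if s.shape != b.shape:
        raise ValueError("stimulation and baseline ratio lists must pair up")
    return EntrainmentResult(
        ratio_stim=s,
        ratio_baseline=b,
        efficiency=float(np.median(s - b)),
        pairs=np.column_stack([s, b]),
    )


def session_entrainment(
    stim: EpochSet, base: EpochSet, config: EntrainConfig | None = None
) -> EntrainmentResult:
    """Per-epoch entrainment power ratios for a paired epoch-set session."""
    config = config or EntrainConfig()

    def ratios(es: EpochSet) -> np.ndarray:
        out = np.empty(es.n_trials)
        for i in range(es.n_trials):
            f, p = psd_periodogram(es.voltage_lfp[i], es.fs, config.psd_window)
            out[i] = entrainment_ratio(f, p, config)
        return out

    return entrainment_efficiency(ratios(stim), ratios(base))
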