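"""Closed-loop stimulation controller.

Replays the in-vivo control logic over a recording: the detector runs on
streaming 1-s intervals, a seizure timestamp is raised at the third
consecutive seizure-classified interval, and each timestamp triggers a 30-s
optical pulse train with probability 0.5 (seeded Bernoulli stream, consumed
in detection order).  Every interval's classification uses only that
interval's samples, so the decision process is strictly causal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import detect as _detect
from .synthgen import GroundTruth, StimProtocol

__all__ = [
    "ControllerConfig",
    "Detection",
    "EventLog",
    "run_controller",
    "decide",
    "detection_latency",
    "apply_stim_effect",
]


@dataclass
class ControllerConfig:
    stim_probability: float = 0.5
    train_duration: float = 30.0        # s, one train per trigger
    refractory: float | None = None     # s between train starts; default = train length
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stim_probability <= 1.0:
            raise ValueError("stim_probability must be in [0, 1]")

    @property
    def effective_refractory(self) -> float:
        return self.train_duration if self.refractory is None else self.refractory

    def protocol(self) -> StimProtocol:
        """The emitted train as a single-epoch stimulation protocol."""
        return StimProtocol(epoch_duration=self.train_duration, n_epochs=1)


@dataclass
class Detection:
    timestamp: float            # s, end of the triggering interval
    stimulated: bool
    latency_intervals: int      # online detection resolution


@dataclass
class EventLog:
    detections: list[Detection] = field(default_factory=list)
    stim_trains: list[tuple[float, float]] = field(default_factory=list)

    def stimulated_fraction(self) -> float:
        if not self.detections:
            return float("nan")
        return float(np.mean([d.stimulated for d in self.detections]))


def decide(
    classifications,
    config: ControllerConfig,
    detector_config: _detect.DetectorConfig | None = None,
) -> EventLog:
    """Run the trigger/randomization logic over per-interval seizure flags.

    Seizures are randomized once each: after a timestamp, further timestamps
    are locked out for one refractory period (default: the train length), so
    a long discharge that re-satisfies the three-interval rule after a brief
    classification gap does not draw a second Bernoulli variate.  Without the
    lockout, longer seizures would accumulate extra draws and be stimulated
    with probability above the configured one, confounding any
    duration-dependent endpoint.  One Bernoulli(stim_probability) variate is
    consumed per emitted timestamp, in detection order, from the seeded
    stream; trains are therefore also non-overlapping.
    """
    detector_config = detector_config or _detect.DetectorConfig()
    flags = np.asarray(classifications, dtype=bool)
    rng = np.random.default_rng(config.rng_seed)
    dt = detector_config.interval_length
    req = detector_config.consecutive_required
    refr = config.effective_refractory
    log = EventLog()
    run = 0
    last_ts = -np.inf
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run == req:
            ts = (i + 1) * dt
            if ts - last_ts < refr:
                continue
            last_ts = ts
            stim = bool(rng.random() < config.stim_probability)
            if stim:
                log.stim_trains.append((ts, ts + config.train_duration))
            log.detections.append(Detection(timestamp=ts, stimulated=stim, latency_intervals=req))
    return log


def run_controller(
    recording,
    library: _detect.SeizureLibrary,
    config: ControllerConfig,
    detector_config: _detect.DetectorConfig | None = None,
) -> tuple[EventLog, list[_detect.SeizureEvent]]:
    """Stream a recording through the detector and closed-loop logic.

    Returns the event log and the offline-assembled seizure events with
    their ``stimulated`` flags set from the matching detections.
    """
    detector_config = detector_config or _detect.DetectorConfig()
    lfp = recording.lfp_channels()[0]
    raw = _detect.interval_features(lfp, recording.fs, detector_config)
    if raw.shape[0] < detector_config.consecutive_required:
        return EventLog(), []
    sig = _detect.sigmoid_bound(raw, library.calibration)
    flags, _ = _detect.classify_matrix(sig, library, detector_config.similarity_threshold)
    log = decide(flags, config, detector_config)
    events = _detect.assemble_events(flags, detector_config)
    for ev in events:
        for det in log.detections:
            if ev.onset <= det.timestamp <= ev.offset:
                ev.stimulated = ev.stimulated or det.stimulated
    return log, events


def _match_truth(timestamp: float, truth: GroundTruth, slack: float) -> int | None:
    for k, (a, b) in enumerate(truth.seizure_intervals):
        if a <= timestamp <= b + slack:
            return k
    return None


def detection_latency(
    log: EventLog, ground_truth: GroundTruth, slack: float = 2.0
) -> tuple[np.ndarray, int]:
    """Per-event latency: first detection timestamp minus the true onset.

    A seizure detected more than once (the run counter restarts after a gap
    of unclassified intervals) contributes the latency of its *first*
    timestamp.  Detections not falling inside any true seizure (within
    ``slack`` seconds past its offset) are excluded and counted.
    Returns (latencies, n_unmatched).
    """
    first: dict[int, float] = {}
    unmatched = 0
    for det in log.detections:
        k = _match_truth(det.timestamp, ground_truth, slack)
        if k is None:
            unmatched += 1
        elif k not in first:
            first[k] = det.timestamp - ground_truth.seizure_intervals[k][0]
    return np.asarray(list(first.values())), unmatched


def apply_stim_effect(
    ground_truth: GroundTruth, log: EventLog, multiplier: float
) -> GroundTruth:
    """Truncate stimulated seizures: the biological effect under test.

    For each emitted stimulation train, the true seizure containing its start
    is shortened so that the remaining duration after train onset is
    ``multiplier`` times what it would have been.  ``multiplier = 1`` is the
    null (no effect); unstimulated seizures are untouched.
    """
    if not 0.0 < multiplier <= 1.0:
        raise ValueError("multiplier must be in (0, 1]")
    intervals = list(ground_truth.seizure_intervals)
    for start, _ in log.stim_trains:
        k = _match_truth(start, ground_truth, slack=0.0)
        if k is None:
            continue
        a, b = intervals[k]
        if b > start:
            intervals[k] = (a, start + multiplier * (b - start))
    return GroundTruth(
        seizure_intervals=intervals,
        locking_strength=ground_truth.locking_strength,
        seed=ground_truth.seed,
    )
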