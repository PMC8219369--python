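"""Cohort-level simulation: many animals through the closed-loop pipeline.

Two routes produce per-animal event tables for the endpoint statistics:

* :func:`run_animal_pipeline` — the full signal-level route: synthesise an
  epileptic recording, detect seizures online, randomize stimulation, apply
  the duration-truncation effect, and read the observed durations off the
  modified ground truth (the stand-in for offline blinded duration review);
* :func:`simulate_animal_events` — the event-level route: draw the same
  event process (Poisson onsets, log-normal durations, Bernoulli stimulation,
  truncation after the detection latency) without rendering any signal.
  Distributionally equivalent for the endpoint statistics and cheap enough
  for large calibration sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import control, detect, synthgen

__all__ = [
    "AnimalEvents",
    "simulate_animal_events",
    "run_animal_pipeline",
    "events_to_frame",
]

EVENT_COLUMNS = ["onset", "offset", "duration", "stimulated", "severity"]


@dataclass
class AnimalEvents:
    animal_id: str
    events: pd.DataFrame        # columns: onset, offset, duration, stimulated, severity
    n_detections: int = 0
    ground_truth: synthgen.GroundTruth | None = field(default=None, repr=False)

    def durations(self, stimulated: bool) -> np.ndarray:
        df = self.events
        return df.loc[df["stimulated"] == stimulated, "duration"].to_numpy()


def _severity(rng: np.random.Generator, n: int, shift: float = 0.0) -> np.ndarray:
    """Racine scores 1..6 drawn around a mid-scale mode, optionally shifted."""
    base = rng.normal(3.5 + shift, 1.0, size=n)
    return np.clip(np.rint(base), 1, 6).astype(int)


def simulate_animal_events(
    animal_id: str,
    model: synthgen.SeizureModel,
    hours: float,
    stim_probability: float = 0.5,
    multiplier: float = 1.0,
    latency_s: float = 3.0,
    severity_shift_on: float = 0.0,
    seed: int = 0,
) -> AnimalEvents:
    """Draw one animal's event table directly from the seizure model.

    Stimulated events are truncated to ``latency_s + multiplier × (d −
    latency_s)``, mirroring a train that starts one detection latency after
    onset; ``multiplier = 1`` is the exact null.
    """
    rng = np.random.default_rng(seed)
    rate_per_s = model.event_rate / 3600.0
    horizon = hours * 3600.0
    onsets, t = [], 0.0
    while True:
        t += rng.exponential(1.0 / rate_per_s)
        if t >= horizon:
            break
        onsets.append(t)
    n = len(onsets)
    durations = rng.lognormal(np.log(model.duration_median), model.duration_sigma, size=n)
    stim = rng.random(n) < stim_probability
    observed = durations.copy()
    trunc = stim & (durations > latency_s)
    observed[trunc] = latency_s + multiplier * (durations[trunc] - latency_s)
    sev = _severity(rng, n)
    sev[stim] = _severity(rng, int(stim.sum()), severity_shift_on)
    df = pd.DataFrame(
        {
            "onset": onsets,
            "offset": np.asarray(onsets) + observed,
            "duration": observed,
            "stimulated": stim,
            "severity": sev,
        }
    )
    return AnimalEvents(animal_id=animal_id, events=df, n_detections=n)


def run_animal_pipeline(
    animal_id: str,
    duration_hours: float,
    library: detect.SeizureLibrary,
    multiplier: float,
    seed: int,
    background: synthgen.BackgroundModel | None = None,
    seizures: synthgen.SeizureModel | None = None,
    fs: float = 512.0,
    detector_config: detect.DetectorConfig | None = None,
    controller_config: control.ControllerConfig | None = None,
) -> AnimalEvents:
    """Full signal-level closed-loop run for one synthetic animal.

    The controller's decisions are made online on the un-truncated recording
    (the stimulation effect unfolds after the train starts, which the 3-s
    detection latency precedes); observed durations are then read from the
    effect-modified ground truth, standing in for offline blinded review.
    """
    background = background or synthgen.BackgroundModel()
    seizures = seizures or synthgen.SeizureModel()
    detector_config = detector_config or detect.DetectorConfig()
    ctrl_seed, sev_seed = [
        int(s.generate_state(1, dtype=np.uint64)[0] >> 33)
        for s in np.random.SeedSequence(seed).spawn(2)
    ]
    controller_config = controller_config or control.ControllerConfig(rng_seed=ctrl_seed)

    rec, truth = synthgen.generate_epileptic_recording(
        duration_hours * 3600.0, fs, background, seizures, seed
    )
    log, _ = control.run_controller(rec, library, controller_config, detector_config)
    modified = control.apply_stim_effect(truth, log, multiplier)

    stim_by_event: dict[int, bool] = {}
    for det in log.detections:
        k = control._match_truth(det.timestamp, truth, slack=2.0)
        if k is not None:
            stim_by_event[k] = stim_by_event.get(k, False) or det.stimulated

    rng = np.random.default_rng(sev_seed)
    rows = []
    for k, (a, b) in enumerate(modified.seizure_intervals):
        if k not in stim_by_event:
            continue  # undetected seizures never enter the in-vivo event log
        stim = stim_by_event[k]
        rows.append((a, b, b - a, stim, int(_severity(rng, 1)[0])))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return AnimalEvents(
        animal_id=animal_id,
        events=df,
        n_detections=len(log.detections),
        ground_truth=modified,
    )


def events_to_frame(animals: list[AnimalEvents]) -> pd.DataFrame:
    frames = []
    for an in animals:
        df = an.events.copy()
        df.insert(0, "animal_id", an.animal_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
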