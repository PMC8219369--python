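"""Online electrographic seizure identification.

The detector analyses the LFP in non-overlapping 1-s intervals.  For each
interval four features are computed:

* **coastline** — sum of absolute sample-to-sample voltage changes (µV);
* **intermittency** — fraction of the coastline generated by the 10% largest
  steps;
* **spikiness** — ratio of the maximum voltage range across 19.6-ms bins to
  the median bin range;
* **coherence** — fraction of the voltage area under the (mean-referenced)
  curve occupied by the 10 largest peak-and-trough pairs.

Raw features are mapped through per-feature logistic sigmoids into (0, 1) and
compared against a library of known-seizure feature vectors; an interval is
classified as seizure if every feature lies within a similarity threshold of
some library entry.  Three consecutive seizure intervals produce a seizure
timestamp.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorConfig",
    "IntervalFeatures",
    "SigmoidCalibration",
    "SeizureLibrary",
    "SeizureEvent",
    "coastline",
    "intermittency",
    "spikiness",
    "coherence_metric",
    "sigmoid_bound",
    "calibrate_sigmoid",
    "classify_interval",
    "classify_matrix",
    "interval_features",
    "assemble_events",
    "detect_recording",
]

FEATURE_NAMES = ("coastline", "intermittency", "spikiness", "coherence")


@dataclass
class DetectorConfig:
    interval_length: float = 1.0            # s
    spikiness_bin_width: float = 0.0196     # s
    intermittency_top_fraction: float = 0.10
    coherence_n_pairs: int = 10
    similarity_threshold: float = 0.1
    consecutive_required: int = 3
    gap_tolerance_intervals: int = 2        # offline offset extension only

    def __post_init__(self) -> None:
        if not 0.0 < self.intermittency_top_fraction < 1.0:
            raise ValueError("intermittency_top_fraction must be in (0, 1)")
        if self.consecutive_required < 1:
            raise ValueError("consecutive_required must be >= 1")
        if self.similarity_threshold <= 0:
            raise ValueError("similarity_threshold must be > 0")


@dataclass
class SigmoidCalibration:
    """Per-feature logistic parameters: x -> 1/(1+exp(-(x-centre)/scale))."""

    centres: np.ndarray
    scales: np.ndarray

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("sigmoid scales must be > 0")


@dataclass
class IntervalFeatures:
    interval_start: float
    coastline: float
    intermittency: float
    spikiness: float
    coherence: float
    sigmoid: np.ndarray | None = None

    def raw_vector(self) -> np.ndarray:
        return np.array(
            [self.coastline, self.intermittency, self.spikiness, self.coherence]
        )


@dataclass
class SeizureLibrary:
    """Reference set of sigmoid-bounded seizure feature vectors."""

    entries: np.ndarray                     # (n, 4) in (0,1)^4
    calibration: SigmoidCalibration
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if self.entries.shape[1] != 4:
            raise ValueError("library entries must be 4-vectors")

    def __len__(self) -> int:
        return self.entries.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "entries": self.entries.tolist(),
                    "calibration": {
                        "centres": self.calibration.centres.tolist(),
                        "scales": self.calibration.scales.tolist(),
                    },
                    "provenance": self.provenance,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SeizureLibrary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            entries=np.array(d["entries"]),
            calibration=SigmoidCalibration(
                d["calibration"]["centres"], d["calibration"]["scales"]
            ),
            provenance=d.get("provenance", {}),
        )


@dataclass
class SeizureEvent:
    onset: float                    # s
    offset: float                   # s
    timestamp_interval: int         # index of the 3rd consecutive positive interval
    stimulated: bool = False
    severity: int | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")
        if self.severity is not None and self.severity not in range(1, 7):
            raise ValueError("severity must be a Racine score in 1..6")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# interval features
# ---------------------------------------------------------------------------

def coastline(interval: np.ndarray) -> float:
    """Sum of absolute voltage changes, µV.  Scale-equivariant."""
    v = np.asarray(interval, dtype=float)
    if v.size < 2:
        raise ValueError("coastline needs at least two samples")
    return float(np.abs(np.diff(v)).sum())


def intermittency(interval: np.ndarray, top_fraction: float = 0.10) -> float:
    """Fraction of the coastline generated by the ``top_fraction`` largest steps.

    The number of steps counted is ``ceil(top_fraction * n_steps)``, so at
    least one step always contributes.  A flat interval (zero coastline)
    returns 0.
    """
    v = np.asarray(interval, dtype=float)
    if v.size < 2:
        raise ValueError("intermittency needs at least two samples")
    steps = np.abs(np.diff(v))
    total = steps.sum()
    if total == 0:
        return 0.0
    m = math.ceil(top_fraction * steps.size)
    top = np.partition(steps, steps.size - m)[steps.size - m :]
    return float(top.sum() / total)


def _bin_samples(fs: float, bin_width: float) -> int:
    return int(math.floor(bin_width * fs))


def spikiness(interval: np.ndarray, fs: float, bin_width: float = 0.0196) -> float:
    """Max over per-bin voltage ranges divided by the median bin range.

    Bins are ``floor(bin_width * fs)`` samples (10 at 512 Hz); the trailing
    remainder is dropped.  Degenerate intervals (zero median range) return 1.
    """
    v = np.asarray(interval, dtype=float)
    b = _bin_samples(fs, bin_width)
    if b < 1 or v.size < 2 * b:
        raise ValueError("interval must span at least two full bins")
    nb = v.size // b
    bins = v[: nb * b].reshape(nb, b)
    ranges = bins.max(axis=1) - bins.min(axis=1)
    med = float(np.median(ranges))
    if med == 0:
        return 1.0
    return float(ranges.max() / med)


def _coherence_core(v: np.ndarray, n_pairs: int) -> float:
    v = v - v.mean()
    a = np.abs(v)
    total = a.sum()
    if total == 0:
        return 0.0
    d = np.diff(v)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return 0.0
    if nz.size != s.size:
        # forward-fill plateau signs so each plateau joins its rising/falling flank
        idx = np.where(s != 0, np.arange(s.size), -1)
        np.maximum.accumulate(idx, out=idx)
        idx[idx < 0] = nz[0]
        s = s[idx]
    ext = np.flatnonzero(s[1:] != s[:-1]) + 1
    if ext.size < 2:
        # monotone (or single-extremum) interval: the global max/min are the pair
        lo_i, hi_i = int(np.argmax(v)), int(np.argmin(v))
        if lo_i == hi_i:
            return 0.0
        ext = np.array(sorted((lo_i, hi_i)))
    npair = ext.size // 2
    pairs = ext[: 2 * npair].reshape(npair, 2)
    amp = np.abs(v[pairs[:, 0]] - v[pairs[:, 1]])
    # each pair's span reaches to the midpoints toward its neighbouring
    # extrema (signal edges for the first/last pair), so an isolated cycle
    # owns the full area around its peak and trough
    prev_ext = np.full(npair, -1, dtype=int)
    if npair > 1:
        prev_ext[1:] = ext[1 : 2 * npair - 1 : 2]
    next_ext = np.full(npair, -1, dtype=int)
    cand = 2 * np.arange(npair) + 2
    mask = cand < ext.size
    next_ext[mask] = ext[cand[mask]]
    lo = np.where(prev_ext >= 0, (prev_ext + pairs[:, 0] + 1) // 2, 0)
    hi = np.where(next_ext >= 0, (pairs[:, 1] + next_ext) // 2, v.size - 1)
    csum = np.concatenate([[0.0], np.cumsum(a)])
    areas = csum[hi + 1] - csum[lo]
    top = np.argsort(amp, kind="stable")[::-1][:n_pairs]
    return float(min(1.0, areas[top].sum() / total))


def coherence_metric(interval: np.ndarray, n_pairs: int = 10) -> float:
    """Fraction of the voltage area occupied by the largest peak-trough pairs.

    The interval is mean-referenced; local extrema are paired in temporal
    order (peak with its adjacent trough), ranked by peak-to-trough amplitude,
    and the area |v - mean| spanned by the top ``n_pairs`` pairs is divided by
    the total area.  Capped at 1.
    """
    v = np.asarray(interval, dtype=float)
    if v.size < 3:
        raise ValueError("coherence needs at least three samples")
    return _coherence_core(v, n_pairs)


def interval_features(
    signal: np.ndarray, fs: float, config: DetectorConfig | None = None
) -> np.ndarray:
    """All four features for every non-overlapping interval of a trace.

    Returns an ``(n_intervals, 4)`` array ordered (coastline, intermittency,
    spikiness, coherence).  Intervals are aligned to the start of the trace;
    a trailing partial interval is dropped.  Vectorised across intervals.
    """
    config = config or DetectorConfig()
    x = np.asarray(signal, dtype=float)
    L = int(round(config.interval_length * fs))
    n = x.size // L
    if n == 0:
        return np.empty((0, 4))
    X = x[: n * L].reshape(n, L)

    steps = np.abs(np.diff(X, axis=1))
    coast = steps.sum(axis=1)
    m = math.ceil(config.intermittency_top_fraction * steps.shape[1])
    top = np.partition(steps, steps.shape[1] - m, axis=1)[:, steps.shape[1] - m :]
    safe = np.where(coast > 0, coast, 1.0)
    interm = np.where(coast > 0, top.sum(axis=1) / safe, 0.0)

    b = _bin_samples(fs, config.spikiness_bin_width)
    nb = L // b
    bins = X[:, : nb * b].reshape(n, nb, b)
    ranges = bins.max(axis=2) - bins.min(axis=2)
    med = np.median(ranges, axis=1)
    spik = np.where(med > 0, ranges.max(axis=1) / np.where(med > 0, med, 1.0), 1.0)

    coh = np.fromiter(
        (_coherence_core(row, config.coherence_n_pairs) for row in X),
        dtype=float,
        count=n,
    )
    return np.column_stack([coast, interm, spik, coh])


# ---------------------------------------------------------------------------
# sigmoid bounding and library matching
# ---------------------------------------------------------------------------

def sigmoid_bound(features: np.ndarray, calibration: SigmoidCalibration) -> np.ndarray:
    """Map raw feature vectors into (0, 1) with per-feature logistics."""
    x = np.asarray(features, dtype=float)
    return 1.0 / (1.0 + np.exp(-(x - calibration.centres) / calibration.scales))


def calibrate_sigmoid(
    baseline_features: np.ndarray, seizure_features: np.ndarray
) -> SigmoidCalibration:
    """Fit sigmoid centres/scales from baseline vs seizure feature samples.

    Centre = midpoint of the two class medians; scale = half the pooled
    interquartile spread.  Baseline intervals then map mostly below 0.5 and
    seizure intervals mostly above.
    """
    base = np.atleast_2d(np.asarray(baseline_features, dtype=float))
    seiz = np.atleast_2d(np.asarray(seizure_features, dtype=float))
    if base.size == 0 or seiz.size == 0:
        raise ValueError("both feature sets must be non-empty")
    med_b = np.median(base, axis=0)
    med_s = np.median(seiz, axis=0)
    iqr_b = np.subtract(*np.percentile(base, [75, 25], axis=0))
    iqr_s = np.subtract(*np.percentile(seiz, [75, 25], axis=0))
    centres = 0.5 * (med_b + med_s)
    scales = 0.5 * (0.5 * (iqr_b + iqr_s))
    if np.any(scales <= 0):
        raise ValueError("degenerate zero-spread feature distribution")
    for j in np.flatnonzero(med_b == med_s):
        warnings.warn(f"feature {FEATURE_NAMES[j]!r} does not separate the classes")
    return SigmoidCalibration(centres=centres, scales=scales)


def classify_interval(
    sigmoid_vec: np.ndarray, library: SeizureLibrary, threshold: float | None = None
) -> tuple[bool, float]:
    """Match one sigmoid-bounded vector against the library.

    An interval is a seizure iff some library entry is within ``threshold``
    of it on *every* feature (per-metric Chebyshev rule, boundary inclusive).
    Also returns the best (smallest max-over-features) distance.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    thr = 0.1 if threshold is None else threshold
    d = np.max(np.abs(library.entries - np.asarray(sigmoid_vec)), axis=1)
    best = float(d.min())
    return best <= thr, best


def classify_matrix(
    sigmoid_vecs: np.ndarray,
    library: SeizureLibrary,
    threshold: float | None = None,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised classify_interval over many intervals (chunked)."""
    if len(library) == 0:
        raise ValueError("library is empty")
    thr = 0.1 if threshold is None else threshold
    V = np.atleast_2d(np.asarray(sigmoid_vecs, dtype=float))
    best = np.empty(V.shape[0])
    for i in range(0, V.shape[0], chunk):
        block = V[i : i + chunk]
        d = np.abs(block[:, None, :] - library.entries[None, :, :]).max(axis=2)
        best[i : i + chunk] = d.min(axis=1)
    return best <= thr, best


# ---------------------------------------------------------------------------
# event assembly
# ---------------------------------------------------------------------------

def assemble_events(
    classifications, config: DetectorConfig | None = None
) -> list[SeizureEvent]:
    """Turn per-interval seizure flags into seizure events.

    A timestamp is emitted at the third (``consecutive_required``-th)
    consecutive positive interval; the event onset is the start of the first
    of those intervals.  Offline, the offset extends to the end of the last
    positive interval before a run of more than ``gap_tolerance_intervals``
    negatives, bridging short gaps within one discharge.
    """
    config = config or DetectorConfig()
    flags = np.asarray(classifications, dtype=bool)
    dt = config.interval_length
    req = config.consecutive_required
    tol = config.gap_tolerance_intervals
    events: list[SeizureEvent] = []
    n = flags.size
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < n and flags[j]:
            j += 1
        if j - i < req:
            i = j + 1
            continue
        onset_idx = i
        ts_idx = i + req - 1
        last_pos = j - 1
        gap = 0
        k = j
        while k < n:
            if flags[k]:
                last_pos = k
                gap = 0
            else:
                gap += 1
                if gap > tol:
                    break
            k += 1
        events.append(
            SeizureEvent(
                onset=onset_idx * dt,
                offset=(last_pos + 1) * dt,
                timestamp_interval=ts_idx,
            )
        )
        i = last_pos + 1 + tol + 1
    return events


def detect_recording(
    recording,
    library: SeizureLibrary,
    config: DetectorConfig | None = None,
):
    """Full offline detection pass over a recording.

    Returns ``(raw_features, sigmoid_features, flags, events)``.
    """
    config = config or DetectorConfig()
    lfp = recording.lfp_channels()[0]
    raw = interval_features(lfp, recording.fs, config)
    sig = sigmoid_bound(raw, library.calibration)
    flags, _ = classify_matrix(sig, library, config.similarity_threshold)
    events = assemble_events(flags, config)
    return raw, sig, flags, events
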