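"""File formats and run configuration.

EDF is the canonical signal container (16-bit, one signal per channel,
physical dimension µV; the LED channel is written as a dimensionless 0/1
signal).  A minimal EDF writer/reader pair is implemented here; recordings
round-trip within the 16-bit quantization step.  CSV is retained for
inspectability, and ground truth / libraries / summaries travel as JSON.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control, detect, entrain, synthgen
from .synthgen import LED_ROLE, Recording

__all__ = [
    "write_edf",
    "read_edf",
    "write_csv",
    "read_csv",
    "read_recording",
    "write_recording",
    "write_events_csv",
    "read_events_csv",
    "write_group_summary",
    "PipelineConfig",
    "write_run_log",
]

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path) -> None:
    """Write a recording to EDF with 1-s data records.

    The final partial record, if any, is zero-padded; the true sample count
    is stored in the header's reserved field and honoured by
    :func:`read_edf`.
    """
    fs = recording.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    data = recording.samples
    ns, n = data.shape
    n_rec = int(np.ceil(n / spr))

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min == 0
    phys_max[flat] += 1.0  # avoid zero gain for constant channels

    gains = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.empty((ns, n_rec * spr), dtype="<i2")
    for c in range(ns):
        d = np.round((data[c] - phys_min[c]) / gains[c]) + _EDF_DIG_MIN
        padded = np.zeros(n_rec * spr)
        padded[:n] = np.clip(d, _EDF_DIG_MIN, _EDF_DIG_MAX)
        digital[c] = padded.astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad(f"NSAMP={n}", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    dims = ["" if r.upper() == LED_ROLE else "uV" for r in recording.channel_roles]
    sig_header = b"".join(
        [_pad(r, 16) for r in recording.channel_roles]
        + [_pad("", 80)] * ns
        + [_pad(d, 8) for d in dims]
        + [_pad(f"{v:.8g}"[:8], 8) for v in phys_min]
        + [_pad(f"{v:.8g}"[:8], 8) for v in phys_max]
        + [_pad(str(_EDF_DIG_MIN), 8)] * ns
        + [_pad(str(_EDF_DIG_MAX), 8)] * ns
        + [_pad("", 80)] * ns
        + [_pad(str(spr), 8)] * ns
        + [_pad("", 32)] * ns
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for c in range(ns):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (or any 1-s-record EDF)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        reserved = head[192:236].decode().strip()
        sig = fh.read(256 * ns)

        def fields(off, width):
            base = off * ns
            return [
                sig[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(ns)
            ]

        # cumulative byte offsets of the signal-header fields:
        # label 0, transducer 16, dim 96, phys min 104, phys max 112,
        # dig min 120, dig max 128, prefilter 136, samples/record 216
        labels = fields(0, 16)
        phys_min = np.array([float(v) for v in fields(104, 8)])
        phys_max = np.array([float(v) for v in fields(112, 8)])
        dig_min = np.array([float(v) for v in fields(120, 8)])
        dig_max = np.array([float(v) for v in fields(128, 8)])
        spr = [int(v) for v in fields(216, 8)]
        if len(set(spr)) != 1:
            raise ValueError("channels with mismatched samples-per-record")
        spr = spr[0]
        raw = np.frombuffer(fh.read(2 * n_rec * ns * spr), dtype="<i2")

    raw = raw.reshape(n_rec, ns, spr).transpose(1, 0, 2).reshape(ns, n_rec * spr)
    gains = (phys_max - phys_min) / (dig_max - dig_min)
    data = (raw - dig_min[:, None]) * gains[:, None] + phys_min[:, None]
    if reserved.startswith("NSAMP="):
        data = data[:, : int(reserved[6:])]
    fs = spr / rec_dur
    led = [i for i, lab in enumerate(labels) if lab.upper() == LED_ROLE]
    for i in led:
        data[i] = np.round(data[i])
    return Recording(samples=data, fs=fs, channel_roles=labels)


def write_csv(recording: Recording, path) -> None:
    """Recording to (optionally gzipped) CSV: time plus one column per role."""
    df = pd.DataFrame({"time": recording.times})
    for role, ch in zip(recording.channel_roles, recording.samples):
        df[role] = ch
    df.to_csv(path, index=False)


def read_csv(path) -> Recording:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("CSV must have a 'time' column")
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    roles = [c for c in df.columns if c != "time"]
    samples = df[roles].to_numpy().T
    led = [i for i, r in enumerate(roles) if r.upper() == LED_ROLE]
    for i in led:
        samples[i] = np.round(samples[i])
    return Recording(samples=samples, fs=float(round(fs)), channel_roles=roles, start_time=float(t[0]))


def read_recording(path, fmt: str | None = None) -> Recording:
    """Read EDF or CSV by extension (or explicit ``fmt``)."""
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return read_edf(path)
    if fmt == "csv":
        return read_csv(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(recording: Recording, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        write_edf(recording, path)
    elif fmt == "csv":
        write_csv(recording, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


EVENT_CSV_COLUMNS = ["onset_s", "offset_s", "duration_s", "stimulated", "severity"]


def write_events_csv(events, path) -> None:
    """Seizure events to CSV with a fixed column order (header always written)."""
    rows = [
        {
            "onset_s": ev.onset,
            "offset_s": ev.offset,
            "duration_s": ev.duration,
            "stimulated": ev.stimulated,
            "severity": ev.severity if ev.severity is not None else "",
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_group_summary(group, results, path) -> None:
    """Group-level endpoint summary as JSON."""
    payload = {
        "per_animal": [
            {
                "animal_id": r.animal_id,
                "n_on": int(r.durations_on.size),
                "n_off": int(r.durations_off.size),
                "median_on_s": r.median_on,
                "median_off_s": r.median_off,
                "ks_statistic": r.ks_statistic,
                "ks_p": r.ks_p,
                "normalized_change": r.normalized_change,
            }
            for r in results
        ],
        "group": {
            "wilcoxon_W": group.wilcoxon_W,
            "wilcoxon_p": group.wilcoxon_p,
            "t_statistic": group.t_statistic,
            "t_p": group.t_p,
            "interseizure_W": group.interseizure_W,
            "interseizure_p": group.interseizure_p,
            "severity_T": group.severity_T,
            "severity_p": group.severity_p,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of a full run; round-trips through YAML."""

    fs: float = 512.0
    master_seed: int = 0
    background: synthgen.BackgroundModel = dataclasses.field(default_factory=synthgen.BackgroundModel)
    seizures: synthgen.SeizureModel = dataclasses.field(default_factory=synthgen.SeizureModel)
    protocol: synthgen.StimProtocol = dataclasses.field(default_factory=synthgen.StimProtocol)
    detector: detect.DetectorConfig = dataclasses.field(default_factory=detect.DetectorConfig)
    entrain: entrain.EntrainConfig = dataclasses.field(default_factory=entrain.EntrainConfig)
    controller: control.ControllerConfig = dataclasses.field(default_factory=control.ControllerConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            fs=d["fs"],
            master_seed=d["master_seed"],
            background=synthgen.BackgroundModel(**d["background"]),
            seizures=synthgen.SeizureModel(**d["seizures"]),
            protocol=synthgen.StimProtocol(**d["protocol"]),
            detector=detect.DetectorConfig(**d["detector"]),
            entrain=entrain.EntrainConfig(**d["entrain"]),
            controller=control.ControllerConfig(**d["controller"]),
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_run_log(path, config: PipelineConfig, extra: dict | None = None) -> None:
    """Append a run record: seed, config hash, package version."""
    from . import __version__

    record = {
        "seed": config.master_seed,
        "config_sha256_16": config.digest(),
        "szloop_version": __version__,
    }
    record.update(extra or {})
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")
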