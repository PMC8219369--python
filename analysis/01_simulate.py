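"""Simulate the two kinds of synthetic session the pipeline consumes.

Writes a 1-h epileptic LFP recording and a 30-epoch stimulation session
with a phase-locked 10 Hz response.  Signal files (EDF) go to scratch/;
ground truth (JSON) goes to results/.
"""

from pathlib import Path

import numpy as np
from _common import RESULTS, default_config, write_provenance

from szloop import io, synthgen

SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    cfg = default_config()
    write_provenance(cfg, "simulate")
    SCRATCH.mkdir(exist_ok=True)

    rec, truth = synthgen.generate_epileptic_recording(
        3600.0, cfg.fs, cfg.background, cfg.seizures, seed=cfg.master_seed
    )
    io.write_edf(rec, SCRATCH / "epileptic_1h.edf")
    truth.to_json(RESULTS / "epileptic_1h_truth.json")
    durs = truth.durations()
    print(
        f"epileptic_1h.edf: {rec.duration:.0f} s at {cfg.fs:.0f} Hz, "
        f"{len(truth.seizure_intervals)} seizures, "
        f"median duration {np.median(durs):.1f} s"
    )

    proto = synthgen.StimProtocol(n_epochs=30)
    locked_bg = synthgen.BackgroundModel(locking_strength=5.0)
    session, struth = synthgen.generate_locked_session(
        proto, locked_bg, cfg.fs, cfg.master_seed
    )
    io.write_edf(session, SCRATCH / "locked_session.edf")
    print(
        f"locked_session.edf: {session.duration:.0f} s, {proto.n_epochs} stimulation "
        f"epochs at {proto.pulse_rate:.0f} Hz, locking kappa={struth.locking_strength}"
    )


if __name__ == "__main__":
    main()
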