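"""Build the seizure library from a synthetic training cohort recording.

Two hours of epileptic LFP stand in for the pilot-cohort recordings from
which the reference seizure intervals were taken; the library stores the
sigmoid-bounded 4-feature vectors of curated in-seizure intervals plus the
fitted sigmoid calibration.
"""

import numpy as np
from _common import RESULTS, default_config, get_library, write_provenance


def main() -> None:
    cfg = default_config()
    write_provenance(cfg, "build-library")
    (RESULTS / "library.json").unlink(missing_ok=True)  # force a fresh build
    lib = get_library(cfg)
    print(f"library.json: {len(lib)} entries "
          f"({lib.provenance['n_uncurated_entries']} before curation) "
          f"from {lib.provenance['n_source_intervals']} source intervals")
    print("sigmoid centres :", np.array2string(lib.calibration.centres, precision=3))
    print("sigmoid scales  :", np.array2string(lib.calibration.scales, precision=3))


if __name__ == "__main__":
    main()
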