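"""Shared plumbing for the analysis scripts: paths, config, library cache."""

from pathlib import Path

from szloop import detect, io, synthgen

RESULTS = Path(__file__).resolve().parent.parent / "results"
TRAIN_SEED = 100
TRAIN_HOURS = 2.0


def default_config(master_seed: int = 1) -> io.PipelineConfig:
    return io.PipelineConfig(master_seed=master_seed)


def write_provenance(cfg: io.PipelineConfig, stage: str) -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg.to_yaml(RESULTS / "config.yaml")
    io.write_run_log(RESULTS / "run.log", cfg, extra={"stage": stage})


def get_library(cfg: io.PipelineConfig) -> detect.SeizureLibrary:
    """Load the seizure library if already built, else build and cache it."""
    path = RESULTS / "library.json"
    if path.exists():
        return detect.SeizureLibrary.from_json(path)
    rec, truth = synthgen.generate_epileptic_recording(
        TRAIN_HOURS * 3600.0, cfg.fs, cfg.background, cfg.seizures, seed=TRAIN_SEED
    )
    lib = synthgen.build_library(rec, truth, cfg.detector)
    RESULTS.mkdir(exist_ok=True)
    lib.to_json(path)
    return lib
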