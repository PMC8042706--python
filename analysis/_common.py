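"""Shared driver plumbing for the numbered analysis scripts.

Each script re-runs the deterministic pipeline through its own stage
into ``results/run`` (earlier stages are cheap and reproduce
bit-identically from the seed), then reports what it found.
"""

from pathlib import Path

import yaml

from ohnoshift.pipeline import ALL_STAGES, PipelineConfig, run_pipeline
from ohnoshift.synthetic import SimConfig

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"
CONFIG_PATH = HERE / "config.yaml"


def load_config() -> PipelineConfig:
    if CONFIG_PATH.exists():
        cfg = PipelineConfig.from_yaml(CONFIG_PATH)
    else:
        cfg = PipelineConfig(sim=SimConfig(seed=1))
    cfg.outdir = str(RESULTS / "run")
    return cfg


def run_through(stage: str) -> Path:
    cfg = load_config()
    k = ALL_STAGES.index(stage) + 1
    cfg.stages = ALL_STAGES[:k]
    cfg.force = True
    return run_pipeline(cfg)
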