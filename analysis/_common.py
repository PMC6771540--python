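"""Shared settings for the numbered analysis scripts.

Every script drives the library on the same synthetic scenario (seed 1,
the default 3-species x 2-condition x 4-timepoint x 3-replicate design
with 5000 ortholog families) and writes its tables under results/.
Stages are cheap to recompute, so each script simply runs the pipeline up
to the stage it narrates.
"""

from pathlib import Path

from droughtcross.pipeline import PipelineConfig, run_pipeline

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
WORKDIR = RESULTS / "pipeline"


def run_stages(*stages: str) -> dict:
    cfg = PipelineConfig(seed=SEED, workdir=str(WORKDIR), stages=list(stages))
    return run_pipeline(cfg)
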