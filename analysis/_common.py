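"""Shared plumbing for the numbered analysis drivers.

Each driver replays the deterministic pipeline from the start through its own
stage into ``results/run`` (cheap: the full workflow takes well under a
minute), prints what it found, and leaves every stage table under the run
directory.
"""

import argparse
from pathlib import Path

from caflineage import pipeline
from caflineage.config import PipelineConfig


def run_through(stage: str, description: str) -> pipeline.RunState:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    cfg = PipelineConfig(seed=args.seed)
    cfg.synthetic.seed = args.seed
    stages = pipeline.STAGES[: pipeline.STAGES.index(stage) + 1]
    return pipeline.run_pipeline(cfg, args.out / "run", stages=stages, force=True)
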