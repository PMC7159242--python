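"""Shared configuration for the numbered analysis drivers.

Every driver operates on the same run directory (results/analysis) and the
same seed, so they can be executed in order (01 .. 06) and each stage picks
up the artifacts the previous one wrote.
"""

from pathlib import Path

from saltmir.pipeline import PipelineConfig

RUN_DIR = Path("results/analysis")
SEED = 1


def config() -> PipelineConfig:
    return PipelineConfig(seed=SEED, out_dir=RUN_DIR)
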