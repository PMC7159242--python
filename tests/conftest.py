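import pytest

from saltmir import synthetic
from saltmir.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def small_genome():
    """Compact genome with five planted hairpins for unit-scale checks."""
    genome, truth = synthetic.generate_genome(
        n_chrom=1, chrom_len=20_000, gc=0.43, n_hairpins=5, seed=11
    )
    return genome, truth


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One end-to-end run at the study conditions: 1 chromosome x 50 kb,
    GC 0.43, 10 planted hairpins, 1e5 reads per library, seed 1."""
    out = tmp_path_factory.mktemp("full_run")
    cfg = PipelineConfig(seed=1, out_dir=out)
    results = run_all(cfg)
    return cfg, results
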