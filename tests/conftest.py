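import pytest

from ligandlink import (
    PipelineConfig,
    SyntheticConfig,
    generate_bundle,
    run_pipeline,
    write_bundle,
)
from ligandlink.io import read_pairs


def run_on_bundle(bundle, tmp_dir):
    """Write a synthetic bundle and run the full pipeline on its files."""
    paths = write_bundle(bundle, tmp_dir / "bundle")
    cfg = PipelineConfig(activities="unused").for_bundle(paths, tmp_dir / "out")
    summary = run_pipeline(cfg)
    pairs = read_pairs(tmp_dir / "out" / "pairs_new.tsv")
    return summary, pairs


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory):
    """Clean-signal study: 8 families x 6 targets, 5 planted pairs."""
    bundle = generate_bundle(SyntheticConfig.noise_free(seed=11))
    summary, pairs = run_on_bundle(bundle, tmp_path_factory.mktemp("clean"))
    return bundle, summary, pairs


@pytest.fixture(scope="session")
def nuisance_run(tmp_path_factory):
    """Default study conditions: planted pairs plus every nuisance class."""
    bundle = generate_bundle(SyntheticConfig(seed=23))
    summary, pairs = run_on_bundle(bundle, tmp_path_factory.mktemp("noisy"))
    return bundle, summary, pairs
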