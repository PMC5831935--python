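import numpy as np
import pytest

from premirseq.pipeline import run_pipeline, score_against_manifest
from premirseq.synthetic_data import write_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One small end-to-end pipeline run on synthetic data, shared across
    tests that only read its outputs."""
    root = tmp_path_factory.mktemp("smallds")
    cfg, manifest = write_dataset(
        5, root, n_good=8, n_loop_decoys=2, n_mismatch_decoys=2,
        n_bulge_decoys=2, n_contaminant_decoys=2,
    )
    result = run_pipeline(cfg)
    scores = score_against_manifest(result, manifest)
    return cfg, manifest, result, scores
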