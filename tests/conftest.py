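import logging

import numpy as np
import pytest

import sscryo as s
from sscryo import qc
from sscryo.pipeline import PipelineConfig, run_pipeline

logging.getLogger("sscryo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_experiment():
    """A compact three-arm null experiment used by several unit tests."""
    cfg = s.preset(
        "null", seed=123, cells_per_replicate=150, n_genes_per_species=450
    )
    counts, truth = s.simulate_experiment(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def small_normalized(small_experiment):
    _, counts, truth = small_experiment
    return qc.normalize_cpm_log(counts.rat), counts.rat_genes, truth


@pytest.fixture(scope="session")
def transplanted_report():
    """Full pipeline run on the transplanted preset (shared across tests)."""
    return run_pipeline(PipelineConfig(preset_name="transplanted_unselected", seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
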