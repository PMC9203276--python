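import warnings

import pytest

from minquant.demux import BarcodeLayout, generate_barcodes
from minquant.pipeline import PipelineConfig, run_pipeline
from minquant.simdata import SimulationConfig, simulate_landscape, simulate_pool

SESSION_SEED = 101


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def model(default_config):
    return simulate_landscape(default_config)


@pytest.fixture(scope="session")
def small_pools():
    """Small pooled libraries with a clean tag channel (no errors, no dups)."""
    cfg = SimulationConfig(seed=7, depth=4_000, dup_rate=0.0, tag_error_rate=0.0)
    model = simulate_landscape(cfg)
    layout = BarcodeLayout(generate_barcodes(len(cfg.sample_ids), seed=7),
                           cfg.sample_ids)
    pools, truth = simulate_pool(model, cfg, layout)
    return cfg, model, layout, pools, truth


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One full default-scale pipeline run shared by the slower tests."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        sim=SimulationConfig(seed=SESSION_SEED), write_tracks=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg, outdir)
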