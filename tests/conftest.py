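import numpy as np
import pytest

from minidials.model import Experiment
from minidials.pipeline import PipelineConfig, run_pipeline
from minidials.simulate import SimConfig, simulate_dataset

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    """The standard study conditions: P222 crystal, 180 x 1 deg images."""
    cfg = SimConfig(space_group="P222")
    truth, expt, stack, _ = simulate_dataset(cfg, seed=DEFAULT_SEED)
    return cfg, truth, expt, stack


@pytest.fixture(scope="session")
def crystal_free_experiment(default_sim):
    _, _, expt, _ = default_sim
    return Experiment(
        beam=expt.beam, goniometer=expt.goniometer, detector=expt.detector,
        scan=expt.scan, crystal=None,
    )


@pytest.fixture(scope="session")
def pipeline_result(default_sim, crystal_free_experiment):
    """Full end-to-end processing of the default simulation (shared)."""
    _, _, _, stack = default_sim
    return run_pipeline(
        crystal_free_experiment, stack, PipelineConfig(seed=DEFAULT_SEED)
    )


@pytest.fixture(scope="session")
def strong_spots(default_sim, crystal_free_experiment):
    from minidials.spotfind import SpotFindParams, filter_spots, find_spots

    _, _, _, stack = default_sim
    table = find_spots(crystal_free_experiment, stack, SpotFindParams())
    return filter_spots(table, min_spot_size=3)
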