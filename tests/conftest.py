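import dataclasses
import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import benthicmap as bm
from benthicmap.raster import Raster


@pytest.fixture(scope="session")
def small_config() -> bm.PipelineConfig:
    """Fast study conditions: small grid, few simulations/trees."""
    cfg = bm.PipelineConfig(seed=7)
    cfg.synth = dataclasses.replace(cfg.synth, grid_shape=(180, 180))
    cfg.mc = dataclasses.replace(cfg.mc, n_sim=8)
    cfg.rf = dataclasses.replace(cfg.rf, ntree=60)
    return cfg


@pytest.fixture(scope="session")
def small_run(small_config) -> bm.PipelineResult:
    """One shared end-to-end pipeline run on the small study area."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bm.run_pipeline(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_depth(seed: int, shape=(8, 8), cell=2.0) -> Raster:
    g = np.random.default_rng(seed)
    values = 20 + 5 * g.standard_normal(shape)
    return Raster(values, cell)
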