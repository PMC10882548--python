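import numpy as np
import pytest

from dualburden.preprocess import build_model_frame
from dualburden.simulate import GeneratorConfig, generate, grid_region_graph


@pytest.fixture(scope="session")
def graph15():
    return grid_region_graph()


@pytest.fixture(scope="session")
def small_survey():
    """A small default-conditions survey with its truth sidecar."""
    cfg = GeneratorConfig(n=900, seed=11)
    df, truth = generate(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def small_frame(small_survey):
    """Fixed-effects model frame over the small survey."""
    cfg, df, _ = small_survey
    return build_model_frame(
        df, ["sex", "location", "wealth_quintile"], ["sex"], cfg.graph,
        theta_terms=[],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
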