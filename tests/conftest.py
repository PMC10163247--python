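import numpy as np
import pandas as pd
import pytest

from treecloud import WINTER, gen_pixel_samples
from treecloud.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240929)


@pytest.fixture(scope="session")
def winter_samples() -> pd.DataFrame:
    """2,000 labeled winter-preset pixels (1,000 per species)."""
    return gen_pixel_samples(WINTER, 1000, seed=7)


@pytest.fixture(scope="session")
def preset_results() -> dict:
    """Full pipeline runs for both phenological presets, one shared seed.

    Session-scoped: the heavier acceptance-style checks all read from the
    same pair of runs.
    """
    return {
        name: run_pipeline(
            PipelineConfig(
                preset=name, n_per_class=1000, raster_shape=(96, 96), seed=7
            )
        )
        for name in ("autumn", "winter")
    }
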