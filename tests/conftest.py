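import numpy as np
import pytest

from fuzzypima import (
    FitConfig,
    SimSpec,
    SplitSpec,
    fit_pipeline,
    simulate,
)


@pytest.fixture(scope="session")
def two_cluster_table():
    """A well-separated (5 sigma) two-cluster dataset with the study class balance."""
    return simulate(SimSpec(seed=11))


@pytest.fixture(scope="session")
def fitted_auto(two_cluster_table):
    """Auto-mode fit on the two-cluster data, half of each class held out."""
    return fit_pipeline(
        two_cluster_table,
        split=SplitSpec(250, 134),
        config=FitConfig(threshold_mode="auto"),
    )


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(20260925))


def write_csv(path, text):
    path.write_text(text)
    return path
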