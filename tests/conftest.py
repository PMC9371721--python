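import numpy as np
import pytest

import gradientforge as gf


@pytest.fixture(scope="session")
def pt_kin():
    return gf.load_catalyst("pt")


@pytest.fixture(scope="session")
def au_kin():
    return gf.load_catalyst("au")


@pytest.fixture(scope="session")
def coarse_settings():
    """Coarse but physically faithful discretization for fast batch work."""
    return gf.SolverSettings(spacing_um=2.0)


@pytest.fixture(scope="session")
def small_pt_dataset(coarse_settings):
    """250 simulated Pt conditions; shared across surrogate/design tests."""
    samples = gf.sample_conditions(250, seed=101)
    return gf.generate_dataset(samples, "pt", coarse_settings)["O2"]


@pytest.fixture(scope="session")
def small_o2_model(small_pt_dataset):
    """A quickly trained O2 surrogate (not accuracy-critical)."""
    tr, va, _ = gf.split_dataset(small_pt_dataset, gf.SplitSpec(seed=102))
    return gf.train(tr, va, gf.TrainConfig(epochs=80, seed=103))
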