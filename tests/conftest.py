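import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sute_ac import PhantomSpec, RunConfig, generate_phantom
from sute_ac.pipeline import run_pipeline

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """Default 96^3 noisy phantom (the segmentation study condition)."""
    return generate_phantom(PhantomSpec(seed=17))


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_phantom(PhantomSpec(seed=17, noise_sigma=0.0))


@pytest.fixture(scope="session")
def small_spec():
    """Coarse 48^3 phantom for fast unit tests (same head, 4 mm voxels)."""
    return PhantomSpec(shape=(48,) * 3, spacing=(4.0,) * 3, seed=3)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full fast-profile pipeline run shared by the acceptance tests."""
    return run_pipeline(RunConfig(seed=17))
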