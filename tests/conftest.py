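import numpy as np
import pytest

from lcmsnet import BatchProfile, Sample, SimConfig, make_signatures, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_sample(rng, n_points=200, rt_span=(0.0, 100.0), mz_span=(100.0, 1000.0)):
    rt = rng.uniform(*rt_span, n_points)
    mz = rng.uniform(*mz_span, n_points)
    intensity = rng.uniform(1.0, 1e5, n_points)
    return Sample("random", rt, mz, intensity, acquisition_span=rt_span)


@pytest.fixture
def random_sample(rng):
    return make_random_sample(rng)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small deterministic simulated dataset: 3 classes x 6 samples, short gradient."""
    config = SimConfig(
        n_classes=3, samples_per_class=6, scan_interval=2.0, acquisition_span=120.0,
        mz_span=(100.0, 500.0), rt_drift_sd=1.0, height_cv=0.2,
        background_points_per_scan=2.0, seed=7,
    )
    signatures = make_signatures(3, 5, config)
    samples = simulate_dataset(config, signatures, [BatchProfile(batch_id="b0")])
    return config, signatures, samples
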