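import numpy as np
import pytest

from qmrep.phantom import PhantomSpec, build_truth, simulate_study


def noiseless_spec(**overrides) -> PhantomSpec:
    base = dict(
        sigma={k: 0.0 for k in ("dwi", "megre", "vfa", "t2w", "b1")},
        jitter_mm=0.0,
        jitter_deg=0.0,
        drift_fraction=0.0,
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def clean_spec():
    return noiseless_spec()


@pytest.fixture(scope="session")
def clean_study(clean_spec):
    """Noiseless, jitter-free, drift-free two-session study."""
    return simulate_study(clean_spec)


@pytest.fixture(scope="session")
def default_truth():
    return build_truth(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def noisy_study():
    return simulate_study(PhantomSpec(seed=42), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
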