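import numpy as np
import pytest

import sigaging as sg
from sigaging.synth import DriftConfig


def random_signature(rng: np.random.Generator, n: int | None = None):
    """A structurally valid random signature (not realistic handwriting)."""
    n = n or int(rng.integers(20, 120))
    x = np.cumsum(rng.normal(0, 20, n)) + 1000
    y = np.cumsum(rng.normal(0, 20, n)) + 1000
    p = rng.integers(1, 1024, n)
    # carve one interior pen-up run
    if n > 30:
        a = int(rng.integers(10, n - 10))
        p[a:a + 5] = 0
    t = np.arange(n) * 10.0
    return sg.DynamicSignature(user_id="u001", session_id="BID1", sample_idx=1,
                               month=0.0, t=t, x=x, y=y, p=p)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_zero_drift_db():
    """6-user, zero-drift database: intra-user jitter only."""
    manifest = sg.default_manifest(6)
    ds, scales = sg.generate_longterm_db(6, manifest, drift=DriftConfig.zero(),
                                         master_seed=7)
    return ds, scales


@pytest.fixture(scope="session")
def small_drifted_db():
    """6-user database with the default aging drift."""
    manifest = sg.default_manifest(6)
    ds, scales = sg.generate_longterm_db(6, manifest, master_seed=7)
    return ds, scales
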