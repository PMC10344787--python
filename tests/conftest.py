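import numpy as np
import pytest

from mitophos.synthdata import DynamicsSimConfig, simulate_timelapse


@pytest.fixture(scope="session")
def scripted_stack():
    """Four capsules, one fission at 300 s and one fusion at 400 s."""
    cfg = DynamicsSimConfig(
        seed=3,
        n_mitochondria=4,
        fission_events=[(300.0, 1)],
        fusion_events=[(400.0, (2, 3))],
    )
    stack, truth = simulate_timelapse(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def clean_stack():
    """Single static capsule rendered without blur, noise or drift."""
    cfg = DynamicsSimConfig(
        seed=1,
        n_mitochondria=1,
        duration=13.0,
        drift_sd=0.0,
        psf_sigma=0.0,
        noise_sd=0.0,
    )
    stack, truth = simulate_timelapse(cfg)
    return cfg, stack, truth
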