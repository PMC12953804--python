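import logging

import numpy as np
import pytest

import neurocast as nc

logging.getLogger("neurocast").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def impaired_minutes():
    """Minute table of a 120-min impaired-autoregulation patient."""
    cfg = nc.impaired_config(duration_minutes=120.0, seed=42)
    return nc.derive_minute_record(nc.generate_patient_waveforms(cfg))


@pytest.fixture(scope="session")
def intact_minutes():
    cfg = nc.intact_config(duration_minutes=120.0, seed=42)
    return nc.derive_minute_record(nc.generate_patient_waveforms(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
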