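"""Shared fixtures: tiny configs and synthetic data, generated at test time."""

import numpy as np
import pytest

from ecgfusion.ecg_io import EcgRecord
from ecgfusion.features import ScatteringConfig
from ecgfusion.synthetic import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_scattering_config():
    """Small filter bank / short window for fast unit tests."""
    return ScatteringConfig(J=3, Q=2, T=512, n_frames=16, n_tail=0, j2_max=3)


@pytest.fixture
def random_record(rng):
    return EcgRecord(rng.normal(size=8527), fs=300.0, record_id="rand")


@pytest.fixture(scope="session")
def small_balanced_records():
    """24 short balanced records across 6 subjects (4 records each)."""
    return generate_dataset(24, imbalance="balanced", seed=7,
                            fixed_duration_s=5.0, records_per_subject=4)


@pytest.fixture(scope="session")
def small_dataset(small_balanced_records):
    """Extracted tensors for the small record set (tiny feature configs)."""
    from ecgfusion.train import extract_dataset

    cfg = ScatteringConfig(J=3, Q=2, T=512, n_frames=16, n_tail=0, j2_max=3)
    return extract_dataset(small_balanced_records, scattering_config=cfg,
                           target_len=1024)
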