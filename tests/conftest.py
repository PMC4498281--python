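from __future__ import annotations

import functools

import pytest

from abanet import qc_deg
from abanet.synthetic import SyntheticConfig, generate_dataset


@functools.lru_cache(maxsize=8)
def default_run(seed: int):
    """Floored default synthetic dataset plus its called DEG table.

    Cached per seed; treat the returned objects as read-only.
    """
    matrix, design, truth = generate_dataset(SyntheticConfig(seed=seed))
    matrix = qc_deg.floor_transform(matrix)
    table = qc_deg.call_degs(qc_deg.fit_timepoint_contrasts(matrix, design))
    return matrix, design, truth, table


@pytest.fixture(scope="session")
def default_dataset():
    """Default 600-gene synthetic run at seed 1."""
    return default_run(1)


@pytest.fixture()
def clean_config():
    """Noise- and jitter-free config with a baseline clear of the floor."""
    return SyntheticConfig(
        n_genes=60,
        class_fractions={"ER_up": 0.3, "ER_down": 0.3, "LR_up": 0.2, "LR_down": 0.2, "flat": 0.0},
        noise_sd_log2=0.0,
        shape_jitter_sd=0.0,
        baseline_log2=9.0,
        seed=7,
    )
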