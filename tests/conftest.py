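"""Shared fixtures: fast generator configurations and cached simulations.

Most tests run on a reduced study: a 19-channel sensorimotor montage
sampled at 200 Hz without EMG or line noise. The statistical structure
(graded ERD at C3, trial plans, jitters) is identical to the default
configuration; only channel count, rate and acquisition extras are
scaled down so the suite stays fast.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from mfload import GeneratorConfig, PreprocessConfig
from mfload.montage import EXCLUDED, SMALL_19


def fast_config(**overrides) -> GeneratorConfig:
    base = dict(
        montage=SMALL_19,
        include_emg=False,
        fs=200.0,
        line_amplitude=0.0,
        apply_notch=False,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def emg_config(**overrides) -> GeneratorConfig:
    """Tiny montage at 1 kHz, for EMG band-limits."""
    base = dict(
        montage=("C3", "CZ", "C4"),
        include_emg=True,
        fs=1000.0,
        line_amplitude=0.0,
        apply_notch=False,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def fast_cfg() -> GeneratorConfig:
    return fast_config()


@pytest.fixture(scope="session")
def pp_cfg() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def full_cfg() -> GeneratorConfig:
    """Default study configuration (60 analysis channels + EMG, 1 kHz)."""
    return GeneratorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def small_montage_with_excluded() -> tuple[str, ...]:
    return SMALL_19 + EXCLUDED
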