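"""Shared fixtures: small and noiseless synthetic cohorts."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from myofatigue import GeneratorConfig, analyze_cohort, generate_cohort

settings.register_profile("ci", deadline=None, max_examples=40,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_config(default_config) -> GeneratorConfig:
    """Three-subject cohort with the study calibration (fast rendering)."""
    return replace(default_config, n_subjects=3)


@pytest.fixture(scope="session")
def noiseless_small_cohort(small_config):
    """Zero-SD, zero-noise degenerate cohort: every subject identical."""
    return generate_cohort(small_config.noiseless(), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=5)


@pytest.fixture(scope="session")
def small_summary(small_cohort):
    return analyze_cohort(small_cohort)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
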