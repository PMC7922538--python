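"""Shared fixtures: a seeded default study population and small helpers."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirqc import RuleThresholds, SyntheticConfig, run_qc_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STUDY_SEED = 1234


@pytest.fixture(scope="session")
def default_study():
    """One full QC study at the default conditions (n = 20,000 field records,
    90% clean / 5% extrapolated / 3% degraded / 2% mismatched), shared across
    tests that only read from it."""
    return run_qc_study(SyntheticConfig(seed=STUDY_SEED), RuleThresholds())


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
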