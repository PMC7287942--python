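"""Shared fixtures: small synthetic cohorts and feature tables.

Expensive simulation products (the 20 null cohorts, the strong-effect
cohort) are session-scoped so the parameter-recovery and type-I-error
checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import kinescreen as ks
from kinescreen.features import build_feature_table
from kinescreen.skeleton import SEGMENT_LABELS

N_NULL_COHORTS = 20


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast 6+6-subject null cohort for unit-level pipeline checks."""
    cfg = ks.CohortConfig(n_asd=6, n_td=6, duration_factor=0.05, seed=42)
    recordings, table = ks.generate_cohort(cfg)
    return recordings, table


@pytest.fixture(scope="session")
def strong_cohort():
    """47-subject cohort with the qualitative group-effect preset applied."""
    cfg = ks.CohortConfig(duration_factor=0.1, seed=11,
                          effect_map=ks.paper_like_effects())
    recordings, _ = ks.generate_cohort(cfg)
    return recordings


@pytest.fixture(scope="session")
def strong_head_table(strong_cohort):
    return build_feature_table(strong_cohort, "head", ("V", "VA", "VAO"))


@pytest.fixture(scope="session")
def null_tables():
    """Feature tables (all joints x all six segments) of 20 null cohorts."""
    tables = []
    for s in range(N_NULL_COHORTS):
        recordings, _ = ks.generate_cohort(
            ks.CohortConfig(duration_factor=0.1, seed=1000 + s)
        )
        tables.append(build_feature_table(recordings, "all", SEGMENT_LABELS))
    return tables


@pytest.fixture
def rng():
    return np.random.default_rng(0)
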