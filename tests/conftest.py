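"""Shared fixtures: spherical head model, coarse source spaces, leadfields,
inverse operators and small synthetic cohorts.

Everything is generated programmatically; session scope keeps the expensive
forward/inverse objects shared across tests.
"""

import numpy as np
import pytest

from lewyeeg import forward, inverse, synth


@pytest.fixture(scope="session")
def head():
    return forward.HeadModel()


@pytest.fixture(scope="session")
def space22(head):
    """Coarse (22 mm) cortical-shell source space for fast end-to-end runs."""
    return forward.build_source_space(22.0, head)


@pytest.fixture(scope="session")
def lf22(space22, head):
    return forward.compute_leadfield(space22, head)


@pytest.fixture(scope="session")
def op22(lf22):
    return inverse.eloreta_operator(lf22)


@pytest.fixture(scope="session")
def space10(head):
    """Mid-resolution (10 mm, ~900 voxel) space for localization tests."""
    return forward.build_source_space(10.0, head)


@pytest.fixture(scope="session")
def lf10(space10, head):
    return forward.compute_leadfield(space10, head)


def small_cohort_config(n=3, n_epochs=10, **overrides):
    """Cohort config with reduced subgroup sizes and short recordings."""
    cfg = synth.CohortConfig(**overrides)
    for key, sg in cfg.subgroups.items():
        sg.n = n
    cfg.epoch_plan = synth.EpochPlan(n_epochs=n_epochs)
    return cfg


@pytest.fixture(scope="session")
def healthy_profile():
    cfg = small_cohort_config(n=1)
    return [p for p in synth.generate_profiles(cfg, 3)
            if p.group == "Healthy"][0]


@pytest.fixture(scope="session")
def clean_recording(healthy_profile, lf22, space22):
    cfg = small_cohort_config(n=1, n_epochs=30)
    return synth.simulate_subject(healthy_profile, lf22, space22, cfg, 11)
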