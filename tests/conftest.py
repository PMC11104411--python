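"""Shared fixtures: session-scoped synthetic cohorts and optimal curves."""

import numpy as np
import pytest

from policycomp import analysis, mi_estimation, synthetic_data as sd
from policycomp.agents import AgentParams, simulate
from policycomp.rate_distortion import default_beta_grid


@pytest.fixture(scope="session")
def default_cohorts():
    """The two-cohort study dataset (36 control-like + 49 patient-like)."""
    subjects, truth = sd.simulate_cohorts(sd.default_cohort_specs(), seed=42)
    return subjects, truth


@pytest.fixture(scope="session")
def cohort_points(default_cohorts):
    subjects, _ = default_cohorts
    return mi_estimation.cohort_points(subjects)


@pytest.fixture(scope="session")
def optimal_curves_all():
    """Optimal frontier per set size 2-6 on the default beta grid."""
    return analysis.optimal_curves()


@pytest.fixture(scope="session")
def one_subject():
    """A single fixed-model subject on a default task realization."""
    task = sd.generate_task(seed=1)
    params = AgentParams(
        model="fixed", beta=5.0, alpha_theta=0.15, alpha_V=0.3, alpha_P=0.02
    )
    return params, simulate(params, task, seed=2)


def make_long_task(set_size: int, n_presentations: int, distinct_actions=True):
    """Single-block task with a fixed presentation count per stimulus."""
    cfg = sd.TaskConfig(
        set_sizes=(set_size,),
        min_presentations=n_presentations,
        max_presentations=n_presentations,
    )
    ids = np.arange(set_size)
    correct = np.arange(set_size) % 3 if distinct_actions else np.zeros(set_size, int)
    return sd.TaskDesign(config=cfg, blocks=(sd.Block(set_size, ids, correct),))
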