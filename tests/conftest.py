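import numpy as np
import pytest

from pdmilestones.milestone_engine import build_registry
from pdmilestones.study_data import VisitAssessment
from pdmilestones.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return build_registry()


def make_visit(
    pid="P1",
    month=12,
    items=None,
    motor=None,
    bp=None,
    cog=None,
    flags=None,
    actual_month=None,
):
    """Handmade visit; motor maps code -> {state: value}, bp maps
    (measure, position) -> value, cog maps test code -> z."""
    return VisitAssessment(
        participant_id=pid,
        scheduled_month=month,
        actual_month=actual_month,
        items=dict(items or {}),
        motor_state_items={k: dict(v) for k, v in (motor or {}).items()},
        bp=dict(bp or {}),
        cognitive_scores=dict(cog or {}),
        investigator_flags=dict(flags or {}),
    )


@pytest.fixture
def visit_factory():
    return make_visit


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderate simulated cohort shared across read-only tests."""
    config = SimulationConfig(n=150, seed=11)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def sim_cohort_clean():
    """Cohort with no baseline meeters and full persistence."""
    config = SimulationConfig(
        n=120, seed=5, baseline_milestone_frac=0.0, persistence_prob=1.0
    )
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
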