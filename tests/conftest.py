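"""Shared fixtures: small rosters and reduced-scale synthetic datasets."""

from datetime import date, datetime

import pytest

from rankwatch.observations import AgonisticEvent, Individual, ObservationSession
from rankwatch.pipeline import outcome_table_from_bundle
from rankwatch.simulate import SyntheticConfig, generate

START = date(2017, 1, 2)


@pytest.fixture
def tiny_roster():
    return [
        Individual(id="AA", sex="female", age_class="adult", present_from=START),
        Individual(id="BB", sex="male", age_class="adult", present_from=START),
        Individual(id="CC", sex="female", age_class="juvenile", present_from=START),
    ]


def make_event(event_id, aggressors, recipients, when=None, contact="non_contact"):
    return AgonisticEvent(
        event_id=event_id,
        timestamp=when or datetime(2017, 1, 5, 12, 0),
        aggressors=frozenset(aggressors),
        recipients=frozenset(recipients),
        contact=contact,
    )


def make_session(session_id, when, size="0-9", activity="calm"):
    return ObservationSession(
        session_id=session_id,
        start=when,
        crowd_size_category=size,
        crowd_activity=activity,
    )


def small_config(seed=0, **overrides):
    """A down-scaled study: same structure as the defaults, fewer sessions."""
    kwargs = dict(
        n_subjects=12,
        n_weeks=8,
        n_sessions=250,
        n_agonistic=250,
        sigma_b=0.5,
        beta0=-2.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """One reduced-scale generated dataset plus its modeling table."""
    cfg = small_config(seed=11)
    bundle, truth = generate(cfg)
    table, snaps, report = outcome_table_from_bundle(bundle, cfg.start_date, cfg.n_weeks)
    return cfg, bundle, truth, table, snaps
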