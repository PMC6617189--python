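"""Synthetic observation-log generator with known ground truth.

Emulates a year-long zoo observation study of a single macaque troop: a
roster with a latent linear dominance hierarchy, ten-minute sessions with
categorical crowd covariates, a stream of dyadic non-contact aggression
directed down the hierarchy with configurable directional consistency, and
per-individual per-session visitor-directed (threatening) outcomes drawn
from the random-intercept logistic model.

The visitor outcomes are driven by the standardized weekly Elo ratings
computed from the *simulated* aggression stream (not the latent rank
labels), so fitting the matching model to generator output recovers the
generating coefficients without Elo-measurement attenuation, and the rating
engine is exercised inside the generator itself.

Default sizes mirror the study the statistical design assumes: 12 subjects,
52 weeks, 2663 sessions, 1150 clean dyadic non-contact events.  The
intercept, crowd-activity coefficients, and random-intercept SD default to
the fitted values reported for that study; the rating coefficient
(-0.5 per SD) and directional consistency (0.9) have no published analogue
and are this package's own defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from . import elo as elo_mod
from .observations import (
    UNKNOWN,
    AgonisticEvent,
    CROWD_ACTIVITY_LEVELS,
    CROWD_SIZE_CATEGORIES,
    ExclusionReport,
    Individual,
    MULTI_DELIM,
    ObservationSession,
    VisitorEvent,
    filter_dyadic,
)


@dataclass
class SyntheticConfig:
    n_subjects: int = 12
    n_weeks: int = 52
    n_sessions: int = 2663
    n_agonistic: int = 1150
    directional_consistency: float = 0.9
    activity_probs: tuple = (0.6, 0.3, 0.1)  # calm, moderate, frenetic
    size_category_probs: tuple = (0.35, 0.30, 0.15, 0.10, 0.06, 0.04)
    beta0: float = -4.313
    beta_moderate: float = 0.075
    beta_frenetic: float = 0.552
    beta_size: float = 0.0
    beta_elo: float = -0.5  # per SD of standardized rating; no published analogue
    sigma_b: float = 1.272
    p_nonthreat_juvenile: float = 0.004  # per (session, juvenile)
    p_nonthreat_adult: float = 0.0004
    start_date: date = date(2017, 1, 2)
    seed: int = 0
    elo_params: elo_mod.EloParameters = field(default_factory=elo_mod.EloParameters)

    def __post_init__(self):
        if self.n_subjects < 3:
            raise DomainError("need at least 3 subjects")
        if self.n_sessions < 1 or self.n_weeks < 1 or self.n_agonistic < 0:
            raise DomainError("sizes must be positive")
        if not (0.5 <= self.directional_consistency <= 1.0):
            raise DomainError("directional_consistency must lie in [0.5, 1]")
        for probs, k in ((self.activity_probs, 3), (self.size_category_probs, 6)):
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-9:
                raise DomainError("category probabilities must sum to 1")

    def coefficients(self) -> dict:
        return {
            "Intercept": self.beta0,
            "crowd_activity[moderate]": self.beta_moderate,
            "crowd_activity[frenetic]": self.beta_frenetic,
            "crowd_size_value": self.beta_size,
            "elo_z": self.beta_elo,
        }


@dataclass
class TruthRecord:
    """Everything needed to recompute each outcome probability: the latent
    hierarchy, generating coefficients, realized random intercepts, and the
    per-row linear predictors."""

    rank_order: list  # ids, highest-ranking first
    coefficients: dict
    random_intercepts: dict  # id -> b_i
    linear_predictors: pd.DataFrame  # session_id, individual_id, eta, prob

    def to_json(self, path) -> None:
        payload = {
            "rank_order": self.rank_order,
            "coefficients": self.coefficients,
            "random_intercepts": self.random_intercepts,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class DatasetBundle:
    roster: list
    sessions: list
    agonistic_events: list
    visitor_events: list

    def write_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "id": i.id,
                    "sex": i.sex,
                    "age_class": i.age_class,
                    "present_from": i.present_from.isoformat() if i.present_from else "",
                    "present_until": i.present_until.isoformat() if i.present_until else "",
                }
                for i in self.roster
            ]
        ).to_csv(outdir / "individuals.csv", index=False)
        pd.DataFrame(
            [
                {
                    "session_id": s.session_id,
                    "start": s.start.isoformat(),
                    "duration_min": s.duration_min,
                    "crowd_size_category": s.crowd_size_category,
                    "crowd_activity": s.crowd_activity,
                }
                for s in self.sessions
            ]
        ).to_csv(outdir / "sessions.csv", index=False)
        pd.DataFrame(
            [
                {
                    "event_id": e.event_id,
                    "timestamp": e.timestamp.isoformat(),
                    "session_id": e.session_id or "",
                    "aggressors": MULTI_DELIM.join(sorted(e.aggressors)),
                    "recipients": MULTI_DELIM.join(sorted(e.recipients)),
                    "contact": e.contact,
                }
                for e in self.agonistic_events
            ]
        ).to_csv(outdir / "agonistic_events.csv", index=False)
        pd.DataFrame(
            [
                {
                    "session_id": v.session_id,
                    "individual_id": v.individual_id,
                    "category": v.category,
                }
                for v in self.visitor_events
            ]
        ).to_csv(outdir / "visitor_events.csv", index=False)


def _make_roster(cfg: SyntheticConfig, rng: np.random.Generator):
    """Roster mirroring the study troop where sizes allow: adults first
    (females then males), then juveniles; latent rank is a random permutation."""
    ids = [f"M{i + 1:02d}" for i in range(cfg.n_subjects)]
    n_adults = max(2, round(cfg.n_subjects * 2 / 3))
    n_adult_f = max(1, round(n_adults * 5 / 8))  # 12 subjects -> 5F/3M adults
    roster = []
    until = cfg.start_date + timedelta(days=7 * cfg.n_weeks - 1)
    for i, iid in enumerate(ids):
        if i < n_adults:
            sex = "female" if i < n_adult_f else "male"
            age = "adult"
        else:
            sex = "female" if i % 2 == 0 else "male"
            age = "juvenile"
        roster.append(
            Individual(
                id=iid,
                sex=sex,
                age_class=age,
                present_from=cfg.start_date,
                present_until=until,
            )
        )
    order = list(rng.permutation(ids))
    return roster, order


def _make_sessions(cfg: SyntheticConfig, rng: np.random.Generator):
    total_days = 7 * cfg.n_weeks
    days = rng.integers(0, total_days, size=cfg.n_sessions)
    minutes = rng.integers(0, 6 * 60, size=cfg.n_sessions)  # within 10:00-16:00
    starts = sorted(
        datetime.combine(cfg.start_date + timedelta(days=int(d)), datetime.min.time())
        + timedelta(hours=10, minutes=int(m))
        for d, m in zip(days, minutes)
    )
    acts = rng.choice(CROWD_ACTIVITY_LEVELS, size=cfg.n_sessions, p=cfg.activity_probs)
    sizes = rng.choice(CROWD_SIZE_CATEGORIES, size=cfg.n_sessions, p=cfg.size_category_probs)
    return [
        ObservationSession(
            session_id=f"S{i + 1:04d}",
            start=starts[i],
            duration_min=10.0,
            crowd_size_category=sizes[i],
            crowd_activity=acts[i],
        )
        for i in range(cfg.n_sessions)
    ]


def _make_agonistic(cfg: SyntheticConfig, rank_order: list, rng: np.random.Generator):
    """Uniformly random dyads at uniformly random times; aggression runs down
    the latent hierarchy with probability ``directional_consistency``."""
    n = cfg.n_agonistic
    pos = {iid: i for i, iid in enumerate(rank_order)}
    ids = list(rank_order)
    total_seconds = 7 * cfg.n_weeks * 24 * 3600
    offsets = np.sort(rng.integers(0, total_seconds, size=n))
    events = []
    for i in range(n):
        a, b = rng.choice(len(ids), size=2, replace=False)
        hi, lo = (a, b) if pos[ids[a]] < pos[ids[b]] else (b, a)
        if rng.random() < cfg.directional_consistency:
            winner, loser = ids[hi], ids[lo]
        else:
            winner, loser = ids[lo], ids[hi]
        ts = datetime.combine(cfg.start_date, datetime.min.time()) + timedelta(
            seconds=int(offsets[i])
        )
        events.append(
            AgonisticEvent(
                event_id=f"E{i + 1:05d}",
                timestamp=ts,
                aggressors=frozenset([winner]),
                recipients=frozenset([loser]),
                contact="non_contact",
            )
        )
    return events


def generate(config: SyntheticConfig) -> tuple[DatasetBundle, TruthRecord]:
    """Produce a pipeline-ready dataset bundle plus its ground truth.

    Fully deterministic given ``config.seed``; each stage (roster, sessions,
    aggression, outcomes, non-threatening noise) consumes an independent
    substream spawned from the master seed.
    """
    ss = np.random.SeedSequence(config.seed)
    r_roster, r_sessions, r_agon, r_outcome, r_nonthreat = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    roster, rank_order = _make_roster(config, r_roster)
    sessions = _make_sessions(config, r_sessions)
    agonistic = _make_agonistic(config, rank_order, r_agon)

    # ratings from the simulated aggression stream, exactly as the analysis
    # pipeline would compute them
    dyadic, _ = filter_dyadic(agonistic)
    traj = elo_mod.run_sequence(dyadic, roster, config.elo_params)
    snaps = elo_mod.weekly_snapshots(
        traj, config.start_date, config.n_weeks, roster, config.elo_params
    )
    snaps = elo_mod.standardize(snaps)
    by_week = {s.week_index: s for s in snaps}

    b = r_outcome.normal(0.0, config.sigma_b, size=config.n_subjects)
    b_map = {ind.id: float(b[i]) for i, ind in enumerate(roster)}

    visitor_events = []
    rows = []
    for sess in sessions:
        w = (sess.start.date() - config.start_date).days // 7 + 1
        snap = by_week[w]
        size_value = int(sess.crowd_size_category.split("-")[0]) + 5
        act = sess.crowd_activity
        for ind in roster:
            z = snap.z_ratings[ind.id]
            eta = (
                config.beta0
                + config.beta_moderate * (act == "moderate")
                + config.beta_frenetic * (act == "frenetic")
                + config.beta_size * size_value
                + config.beta_elo * z
                + b_map[ind.id]
            )
            prob = 1.0 / (1.0 + np.exp(-eta))
            y = r_outcome.random() < prob
            rows.append((sess.session_id, ind.id, float(eta), float(prob)))
            if y:
                visitor_events.append(
                    VisitorEvent(
                        session_id=sess.session_id,
                        individual_id=ind.id,
                        category="threatening",
                    )
                )
            p_nt = (
                config.p_nonthreat_juvenile
                if ind.age_class == "juvenile"
                else config.p_nonthreat_adult
            )
            if r_nonthreat.random() < p_nt:
                visitor_events.append(
                    VisitorEvent(
                        session_id=sess.session_id,
                        individual_id=ind.id,
                        category="non_threatening",
                    )
                )

    truth = TruthRecord(
        rank_order=rank_order,
        coefficients=config.coefficients(),
        random_intercepts=b_map,
        linear_predictors=pd.DataFrame(
            rows, columns=["session_id", "individual_id", "eta", "prob"]
        ),
    )
    bundle = DatasetBundle(
        roster=roster,
        sessions=sessions,
        agonistic_events=agonistic,
        visitor_events=visitor_events,
    )
    return bundle, truth


@dataclass(frozen=True)
class ContaminationRates:
    multi_aggressor: float = 0.0
    multi_recipient: float = 0.0
    unknown_identity: float = 0.0

    def __post_init__(self):
        for r in (self.multi_aggressor, self.multi_recipient, self.unknown_identity):
            if not (0.0 <= r < 1.0):
                raise DomainError("contamination rates must lie in [0, 1)")


def inject_contamination(
    bundle: DatasetBundle, rates: ContaminationRates, seed: int
) -> tuple[DatasetBundle, ExclusionReport]:
    """Append multi-party and unknown-identity aggression events at the given
    rates (as fractions of the existing event count) and return the
    exclusion report the dyadic filter is expected to produce."""
    rng = np.random.default_rng(seed)
    events = list(bundle.agonistic_events)
    n0 = len(events)
    ids = [ind.id for ind in bundle.roster]
    t0 = min((e.timestamp for e in events), default=datetime(2017, 1, 2))
    t1 = max((e.timestamp for e in events), default=t0 + timedelta(days=1))
    span = max(1, int((t1 - t0).total_seconds()))

    def rand_time():
        return t0 + timedelta(seconds=int(rng.integers(0, span)))

    counter = n0
    n_ma = round(rates.multi_aggressor * n0)
    n_mr = round(rates.multi_recipient * n0)
    n_unk = round(rates.unknown_identity * n0)
    added = []
    for _ in range(n_ma):
        a1, a2, r = rng.choice(len(ids), size=3, replace=False)
        counter += 1
        added.append(
            AgonisticEvent(
                event_id=f"E{counter:05d}",
                timestamp=rand_time(),
                aggressors=frozenset([ids[a1], ids[a2]]),
                recipients=frozenset([ids[r]]),
                contact="non_contact",
            )
        )
    for _ in range(n_mr):
        a, r1, r2 = rng.choice(len(ids), size=3, replace=False)
        counter += 1
        added.append(
            AgonisticEvent(
                event_id=f"E{counter:05d}",
                timestamp=rand_time(),
                aggressors=frozenset([ids[a]]),
                recipients=frozenset([ids[r1], ids[r2]]),
                contact="non_contact",
            )
        )
    for _ in range(n_unk):
        a = rng.choice(len(ids))
        counter += 1
        unknown_side = rng.random() < 0.5
        added.append(
            AgonisticEvent(
                event_id=f"E{counter:05d}",
                timestamp=rand_time(),
                aggressors=frozenset([UNKNOWN]) if unknown_side else frozenset([ids[a]]),
                recipients=frozenset([ids[a]]) if unknown_side else frozenset([UNKNOWN]),
                contact="non_contact",
            )
        )
    all_events = sorted(events + added, key=lambda e: e.timestamp)
    expected = ExclusionReport(
        n_multi_aggressor=n_ma,
        n_multi_recipient=n_mr,
        n_unknown_identity=n_unk,
        n_excluded_distinct=n_ma + n_mr + n_unk,
        n_retained=n0,
        n_contact=0,
    )
    contaminated = DatasetBundle(
        roster=bundle.roster,
        sessions=bundle.sessions,
        agonistic_events=all_events,
        visitor_events=bundle.visitor_events,
    )
    return contaminated, expected
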