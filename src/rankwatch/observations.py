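"""Data model for behavioral observation logs.

Rosters, ten-minute observation sessions with crowd covariates, agonistic
(aggression) events between troop members, and visitor-directed events are
read from plain CSV files.  This module validates them, reduces the raw
agonistic stream to clean dyadic winner/loser records for rating, and
assembles the per-individual-per-session table that the mixed-model stage
consumes.

Conventions
-----------
* Multi-party identity fields use ``|`` as the delimiter (``"AA|BB"``).
* The literal token ``UNKNOWN`` marks an unidentified party.
* Crowd size is recorded in closed ten-person bands (``0-9`` ... ``50-59``)
  and enters models as the band midpoint, defined as lower bound + 5 so
  that ``0-9`` codes to 5.
* Crowd activity has exactly three levels: calm, moderate, frenetic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .errors import DomainError, ReferentialError, SchemaError

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"
MULTI_DELIM = "|"

CROWD_SIZE_CATEGORIES = ("0-9", "10-19", "20-29", "30-39", "40-49", "50-59")
CROWD_ACTIVITY_LEVELS = ("calm", "moderate", "frenetic")
SEXES = ("female", "male", "unknown")
AGE_CLASSES = ("adult", "juvenile", "unknown")


def _canon_size_category(raw: str) -> str:
    """Normalize a crowd-size band label (en-dash or hyphen) to e.g. ``"0-9"``."""
    s = str(raw).strip().replace("–", "-").replace("—", "-")
    if s not in CROWD_SIZE_CATEGORIES:
        raise SchemaError(
            f"unknown crowd_size_category {raw!r}; expected one of {CROWD_SIZE_CATEGORIES}"
        )
    return s


def crowd_midpoint(category: str) -> int:
    """Midpoint coding of a crowd-size band: lower bound + 5 (``"0-9"`` -> 5)."""
    try:
        s = _canon_size_category(category)
    except SchemaError as exc:
        raise DomainError(str(exc)) from None
    return int(s.split("-")[0]) + 5


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str = "unknown"
    age_class: str = "unknown"
    present_from: date | None = None
    present_until: date | None = None  # None = still present (open interval)

    def __post_init__(self):
        if self.sex not in SEXES:
            raise SchemaError(f"individual {self.id!r}: sex {self.sex!r} not in {SEXES}")
        if self.age_class not in AGE_CLASSES:
            raise SchemaError(
                f"individual {self.id!r}: age_class {self.age_class!r} not in {AGE_CLASSES}"
            )
        if (
            self.present_from is not None
            and self.present_until is not None
            and self.present_from > self.present_until
        ):
            raise SchemaError(
                f"individual {self.id!r}: present_from after present_until"
            )

    def present_on(self, day: date) -> bool:
        if self.present_from is not None and day < self.present_from:
            return False
        if self.present_until is not None and day > self.present_until:
            return False
        return True


@dataclass(frozen=True)
class ObservationSession:
    session_id: str
    start: datetime
    duration_min: float = 10.0
    crowd_size_category: str = "0-9"
    crowd_activity: str = "calm"

    def __post_init__(self):
        object.__setattr__(
            self, "crowd_size_category", _canon_size_category(self.crowd_size_category)
        )
        if self.crowd_activity not in CROWD_ACTIVITY_LEVELS:
            raise SchemaError(
                f"session {self.session_id!r}: crowd_activity {self.crowd_activity!r} "
                f"not in {CROWD_ACTIVITY_LEVELS}"
            )


@dataclass(frozen=True)
class AgonisticEvent:
    """One recorded aggression occurrence, possibly multi-party or with
    unidentified participants.  ``aggressors``/``recipients`` are frozensets of
    ids; the token :data:`UNKNOWN` marks an unidentified party."""

    event_id: str
    timestamp: datetime
    aggressors: frozenset
    recipients: frozenset
    contact: str = "non_contact"
    session_id: str | None = None

    def __post_init__(self):
        if self.contact not in ("contact", "non_contact"):
            raise SchemaError(
                f"event {self.event_id!r}: contact must be 'contact' or 'non_contact'"
            )
        if not self.aggressors or not self.recipients:
            raise SchemaError(f"event {self.event_id!r}: empty party field")
        both = (self.aggressors & self.recipients) - {UNKNOWN}
        if both:
            raise SchemaError(
                f"event {self.event_id!r}: ids {sorted(both)} on both sides"
            )

    @property
    def any_unknown(self) -> bool:
        return UNKNOWN in self.aggressors or UNKNOWN in self.recipients

    @property
    def multi_aggressor(self) -> bool:
        return len(self.aggressors) > 1

    @property
    def multi_recipient(self) -> bool:
        return len(self.recipients) > 1


@dataclass(frozen=True)
class DyadicEvent:
    """A clean, directional aggression record: exactly one identified
    aggressor (the 'winner') and one identified recipient (the 'loser')."""

    timestamp: datetime
    winner_id: str
    loser_id: str

    def __post_init__(self):
        if self.winner_id == self.loser_id:
            raise SchemaError("dyadic event with identical winner and loser")


@dataclass(frozen=True)
class VisitorEvent:
    session_id: str
    individual_id: str
    category: str  # threatening | non_threatening

    def __post_init__(self):
        if self.category not in ("threatening", "non_threatening"):
            raise SchemaError(
                f"visitor event category {self.category!r} must be "
                "'threatening' or 'non_threatening'"
            )


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for :func:`filter_dyadic`.

    The three criterion counters are non-exclusive (one event may trip
    several), but each excluded event contributes exactly once to
    ``n_excluded_distinct``, so ``n_retained + n_excluded_distinct`` equals
    the number of non-contact events examined."""

    n_multi_aggressor: int
    n_multi_recipient: int
    n_unknown_identity: int
    n_excluded_distinct: int
    n_retained: int
    n_contact: int = 0


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: tuple, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _parse_date(value, path, row_label) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return None
    try:
        return pd.Timestamp(value).date()
    except (ValueError, TypeError):
        raise SchemaError(f"{path}: unparsable date {value!r} in row {row_label}") from None


def _parse_datetime(value, path, row_label) -> datetime:
    try:
        return pd.Timestamp(value).to_pydatetime()
    except (ValueError, TypeError):
        raise SchemaError(f"{path}: unparsable timestamp {value!r} in row {row_label}") from None


def read_roster(path) -> list[Individual]:
    """Read ``individuals.csv`` (id, sex, age_class, present_from, present_until)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("id",), path)
    if df.empty:
        warnings.warn(f"{path}: roster has a header but no rows", stacklevel=2)
        return []
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicated individual id {dup.iloc[0]!r}")
    roster = []
    for i, row in df.iterrows():
        roster.append(
            Individual(
                id=str(row["id"]).strip(),
                sex=str(row.get("sex", "unknown") or "unknown").strip() or "unknown",
                age_class=str(row.get("age_class", "unknown") or "unknown").strip() or "unknown",
                present_from=_parse_date(row.get("present_from"), path, row["id"]),
                present_until=_parse_date(row.get("present_until"), path, row["id"]),
            )
        )
    return roster


def read_sessions(path) -> list[ObservationSession]:
    """Read ``sessions.csv`` (session_id, start, duration_min,
    crowd_size_category, crowd_activity)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(
        df, ("session_id", "start", "crowd_size_category", "crowd_activity"), path
    )
    dup = df["session_id"][df["session_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicated session_id {dup.iloc[0]!r}")
    sessions = []
    for _, row in df.iterrows():
        sessions.append(
            ObservationSession(
                session_id=str(row["session_id"]).strip(),
                start=_parse_datetime(row["start"], path, row["session_id"]),
                duration_min=float(row.get("duration_min") or 10.0),
                crowd_size_category=row["crowd_size_category"],
                crowd_activity=str(row["crowd_activity"]).strip(),
            )
        )
    return sessions


def _split_party(raw: str) -> frozenset:
    parts = frozenset(p.strip() for p in str(raw).split(MULTI_DELIM) if p.strip())
    if not parts:
        raise SchemaError(f"empty party field {raw!r}")
    return parts


def read_agonistic(path) -> list[AgonisticEvent]:
    """Read ``agonistic_events.csv``.  Multi-party fields are split on ``|``
    and the literal ``UNKNOWN`` token is preserved."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(
        df, ("event_id", "timestamp", "aggressors", "recipients", "contact"), path
    )
    events = []
    for _, row in df.iterrows():
        sid = row.get("session_id")
        sid = None if sid is None or pd.isna(sid) or str(sid).strip() == "" else str(sid).strip()
        events.append(
            AgonisticEvent(
                event_id=str(row["event_id"]).strip(),
                timestamp=_parse_datetime(row["timestamp"], path, row["event_id"]),
                session_id=sid,
                aggressors=_split_party(row["aggressors"]),
                recipients=_split_party(row["recipients"]),
                contact=str(row["contact"]).strip(),
            )
        )
    return events


def read_visitor_events(path, sessions: list[ObservationSession] | None = None) -> list[VisitorEvent]:
    """Read ``visitor_events.csv``; if ``sessions`` is given, every event must
    reference an existing session."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("session_id", "individual_id", "category"), path)
    known = None if sessions is None else {s.session_id for s in sessions}
    events = []
    for _, row in df.iterrows():
        sid = str(row["session_id"]).strip()
        if known is not None and sid not in known:
            raise ReferentialError(f"{path}: visitor event references absent session {sid!r}")
        events.append(
            VisitorEvent(
                session_id=sid,
                individual_id=str(row["individual_id"]).strip(),
                category=str(row["category"]).strip(),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Filtering and table assembly
# ---------------------------------------------------------------------------

def filter_dyadic(events: list[AgonisticEvent]) -> tuple[list[DyadicEvent], ExclusionReport]:
    """Reduce raw agonistic events to clean dyadic records for rating.

    Only non-contact events are considered (contact events are tallied in the
    report but never emitted).  An event is excluded if it has multiple
    aggressors, multiple recipients, or any unidentified party; the three
    counters are incremented independently while the event itself is excluded
    once.  Output preserves input order (stable for equal timestamps).
    """
    dyadic: list[DyadicEvent] = []
    n_ma = n_mr = n_unk = n_excl = n_contact = 0
    for ev in events:
        if ev.contact == "contact":
            n_contact += 1
            continue
        bad = False
        if ev.multi_aggressor:
            n_ma += 1
            bad = True
        if ev.multi_recipient:
            n_mr += 1
            bad = True
        if ev.any_unknown:
            n_unk += 1
            bad = True
        if bad:
            n_excl += 1
            continue
        (winner,) = ev.aggressors
        (loser,) = ev.recipients
        dyadic.append(DyadicEvent(timestamp=ev.timestamp, winner_id=winner, loser_id=loser))
    report = ExclusionReport(
        n_multi_aggressor=n_ma,
        n_multi_recipient=n_mr,
        n_unknown_identity=n_unk,
        n_excluded_distinct=n_excl,
        n_retained=len(dyadic),
        n_contact=n_contact,
    )
    return dyadic, report


def week_of(day: date, study_start: date) -> int:
    """1-based week index: week 1 covers days 0-6 from the study start."""
    return (day - study_start).days // 7 + 1


def build_outcome_table(
    sessions: list[ObservationSession],
    visitor_events: list[VisitorEvent],
    roster: list[Individual],
    weekly_snapshots,
) -> pd.DataFrame:
    """Assemble the modeling table: one row per present individual per session.

    ``outcome`` is 1 iff the individual produced at least one *threatening*
    visitor-directed event in that session, regardless of how many;
    non-threatening events never set the outcome.  Covariates are the
    midpoint-coded crowd size, the three-level crowd activity, and the
    individual's weekly Elo rating (raw and standardized).  Rows whose
    individual has no rating for the session's week are dropped with a
    logged count (exposed as ``df.attrs["n_dropped"]``).
    """
    threat = {
        (ve.session_id, ve.individual_id)
        for ve in visitor_events
        if ve.category == "threatening"
    }
    by_week = {snap.week_index: snap for snap in weekly_snapshots}
    if not by_week:
        raise DomainError("no weekly snapshots supplied")
    first = by_week[min(by_week)]
    study_start = first.week_end - timedelta(days=6)

    rows = []
    n_dropped = 0
    for sess in sessions:
        day = sess.start.date()
        w = week_of(day, study_start)
        snap = by_week.get(w)
        size_value = crowd_midpoint(sess.crowd_size_category)
        for ind in roster:
            if not ind.present_on(day):
                continue
            if snap is None or ind.id not in snap.ratings:
                n_dropped += 1
                continue
            z = None if snap.z_ratings is None else snap.z_ratings.get(ind.id)
            rows.append(
                (
                    sess.session_id,
                    ind.id,
                    1 if (sess.session_id, ind.id) in threat else 0,
                    size_value,
                    sess.crowd_activity,
                    snap.ratings[ind.id],
                    z,
                )
            )
    if n_dropped:
        logger.warning("build_outcome_table: dropped %d rows lacking a weekly rating", n_dropped)
    df = pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "individual_id",
            "outcome",
            "crowd_size_value",
            "crowd_activity",
            "elo",
            "elo_z",
        ],
    )
    df.attrs["n_dropped"] = n_dropped
    return df


@dataclass
class DatasetSummary:
    """Descriptive summary of one observation dataset."""

    total_hours: float
    n_sessions: int
    n_visitor_events: int
    pct_threatening: float
    pct_nonthreatening: float
    pct_threatening_by_age_class: dict
    pct_nonthreatening_by_age_class: dict
    n_agonistic_dyadic: int
    pct_noncontact: float
    pct_sessions_with_aggression: float
    per_individual_threat_counts: dict
    median_threat_count: float
    threat_count_range: tuple

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["threat_count_range"] = list(self.threat_count_range)
        return d


def _pct_by_age_class(events: list[VisitorEvent], roster: list[Individual], category: str) -> dict:
    age = {ind.id: ind.age_class for ind in roster}
    sub = [ev for ev in events if ev.category == category]
    out: dict = {}
    if not sub:
        return out
    counts: dict = {}
    for ev in sub:
        counts[age.get(ev.individual_id, "unknown")] = counts.get(age.get(ev.individual_id, "unknown"), 0) + 1
    for k, v in counts.items():
        out[k] = 100.0 * v / len(sub)
    return out


def summarize_dataset(
    events: list[AgonisticEvent],
    visitor_events: list[VisitorEvent],
    sessions: list[ObservationSession],
    outcome_table: pd.DataFrame,
    roster: list[Individual] | None = None,
) -> DatasetSummary:
    """Descriptive counts and percentages of the kind reported for a field
    season: observation hours, the threatening share of visitor-directed
    events and its age-class breakdown, the dyadic-aggression tallies, and
    the share of sessions with at least one visitor-directed aggression."""
    roster = roster or []
    total_hours = sum(s.duration_min for s in sessions) / 60.0
    n_visitor = len(visitor_events)
    n_threat = sum(1 for ev in visitor_events if ev.category == "threatening")
    pct_threat = 100.0 * n_threat / n_visitor if n_visitor else float("nan")

    dyadic, report = filter_dyadic(events)
    # dyadic *identified* events regardless of contact: single-aggressor,
    # single-recipient, no UNKNOWN, across both contact classes
    clean = [
        ev
        for ev in events
        if not (ev.multi_aggressor or ev.multi_recipient or ev.any_unknown)
    ]
    n_dyadic = len(clean)
    n_nc = sum(1 for ev in clean if ev.contact == "non_contact")
    pct_nc = 100.0 * n_nc / n_dyadic if n_dyadic else float("nan")

    if len(outcome_table):
        by_sess = outcome_table.groupby("session_id")["outcome"].max()
        pct_sessions = 100.0 * float(by_sess.mean())
    else:
        pct_sessions = float("nan")

    counts: dict = {}
    for ev in visitor_events:
        if ev.category == "threatening":
            counts[ev.individual_id] = counts.get(ev.individual_id, 0) + 1
    vals = sorted(counts.values())
    median = float(np.median(vals)) if vals else float("nan")
    rng = (min(vals), max(vals)) if vals else (0, 0)

    return DatasetSummary(
        total_hours=round(total_hours, 1),
        n_sessions=len(sessions),
        n_visitor_events=n_visitor,
        pct_threatening=pct_threat,
        pct_nonthreatening=100.0 - pct_threat if n_visitor else float("nan"),
        pct_threatening_by_age_class=_pct_by_age_class(visitor_events, roster, "threatening"),
        pct_nonthreatening_by_age_class=_pct_by_age_class(visitor_events, roster, "non_threatening"),
        n_agonistic_dyadic=n_dyadic,
        pct_noncontact=pct_nc,
        pct_sessions_with_aggression=pct_sessions,
        per_individual_threat_counts=counts,
        median_threat_count=median,
        threat_count_range=rng,
    )
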