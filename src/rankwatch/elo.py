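"""Sequential Elo-rating of dominance rank from dyadic aggression.

Each individual enters the system at a fixed start rating (1000 by default)
and the winner/loser of every directed aggression event exchange points.
Let ``p`` be the expected probability that the *higher*-rated member of the
pair is the aggressor, a function of the pre-event rating difference ``d``:

* normal form (default): ``p = Phi(d / (200 * sqrt(2)))``
* logistic form:         ``p = 1 / (1 + 10 ** (-d / 400))``

If the higher-rated individual wins, both ratings move by ``(1 - p) * k``;
if the lower-rated individual wins (an upset), they move by ``p * k``.  The
exchange is zero-sum, so the rating total is conserved, and upsets move
ratings further than expected outcomes.  ``k`` (default 100) caps the
per-event change.

The printed form of the update rule is ambiguous about parenthesization
("1 - p x k"); it is implemented as ``(1 - p) * k`` since the winner must
gain points and the per-event change must stay below ``k``.

Weekly snapshots are taken at the end of consecutive 7-day blocks from the
study start (week 1 = days 0-6), carrying the last rating forward through
event-free weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np

from .errors import DomainError, ReferentialError
from .observations import DyadicEvent, Individual

DEFAULT_NORMAL_SCALE = 200.0 * math.sqrt(2.0)
DEFAULT_LOGISTIC_SCALE = 400.0


@dataclass(frozen=True)
class EloParameters:
    start_rating: float = 1000.0
    k: float = 100.0
    expectation_form: str = "normal"  # "normal" | "logistic"
    expectation_scale: float | None = None  # None -> form-specific default

    def __post_init__(self):
        if self.expectation_form not in ("normal", "logistic"):
            raise DomainError(f"unknown expectation form {self.expectation_form!r}")
        if self.k <= 0:
            raise DomainError("k must be positive")
        if not math.isfinite(self.start_rating):
            raise DomainError("start_rating must be finite")
        if self.expectation_scale is not None and self.expectation_scale <= 0:
            raise DomainError("expectation_scale must be positive")

    @property
    def scale(self) -> float:
        if self.expectation_scale is not None:
            return self.expectation_scale
        return DEFAULT_NORMAL_SCALE if self.expectation_form == "normal" else DEFAULT_LOGISTIC_SCALE


def expectation(rating_high: float, rating_low: float, params: EloParameters = EloParameters()) -> float:
    """Win expectation of the higher-rated individual, as a function of the
    rating difference ``d = rating_high - rating_low`` (>= 0 by convention)."""
    if not (math.isfinite(rating_high) and math.isfinite(rating_low)):
        raise DomainError("ratings must be finite")
    d = rating_high - rating_low
    if params.expectation_form == "normal":
        # standard normal CDF via erf; scalar-fast for the per-event hot path
        return 0.5 * (1.0 + math.erf(d / params.scale / math.sqrt(2.0)))
    return 1.0 / (1.0 + 10.0 ** (-d / params.scale))


def update(
    winner_rating: float, loser_rating: float, params: EloParameters = EloParameters()
) -> tuple[float, float]:
    """One zero-sum rating exchange; returns (winner_new, loser_new)."""
    hi, lo = max(winner_rating, loser_rating), min(winner_rating, loser_rating)
    p = expectation(hi, lo, params)
    delta = (1.0 - p) * params.k if winner_rating >= loser_rating else p * params.k
    return winner_rating + delta, loser_rating - delta


@dataclass
class EloTrajectory:
    """Time-ordered rating sequence for one individual."""

    individual_id: str
    history: list = field(default_factory=list)  # [(timestamp, rating_after_event)]
    current: float = 1000.0

    def rating_before(self, cutoff: datetime, start_rating: float) -> float:
        """Rating after the last event at or before ``cutoff``; the start
        rating if no event has occurred yet."""
        r = start_rating
        for ts, rating in self.history:
            if ts > cutoff:
                break
            r = rating
        return r


def run_sequence(
    dyadic_events: list[DyadicEvent],
    roster: list[Individual],
    params: EloParameters = EloParameters(),
) -> dict[str, EloTrajectory]:
    """Process events strictly in time order (stable for tied timestamps) and
    return a trajectory for every roster member, including non-interactors
    (flat at the start rating).  Events involving an individual outside its
    presence interval raise :class:`ReferentialError`; ratings are frozen
    after an individual's departure."""
    by_id = {ind.id: ind for ind in roster}
    traj = {
        ind.id: EloTrajectory(individual_id=ind.id, current=params.start_rating)
        for ind in roster
    }
    events = sorted(dyadic_events, key=lambda e: e.timestamp)  # stable sort
    for ev in events:
        for pid in (ev.winner_id, ev.loser_id):
            ind = by_id.get(pid)
            if ind is None:
                raise ReferentialError(
                    f"event at {ev.timestamp}: id {pid!r} not in roster"
                )
            if not ind.present_on(ev.timestamp.date()):
                raise ReferentialError(
                    f"event at {ev.timestamp}: individual {pid!r} not present"
                )
        w, l = traj[ev.winner_id], traj[ev.loser_id]
        w_new, l_new = update(w.current, l.current, params)
        w.current, l.current = w_new, l_new
        w.history.append((ev.timestamp, w_new))
        l.history.append((ev.timestamp, l_new))
    return traj


@dataclass
class WeeklySnapshot:
    week_index: int
    week_end: date
    ratings: dict  # individual_id -> rating
    z_ratings: dict | None = None  # individual_id -> standardized rating


def weekly_snapshots(
    trajectories: dict[str, EloTrajectory],
    study_start_date: date,
    n_weeks: int,
    roster: list[Individual],
    params: EloParameters = EloParameters(),
) -> list[WeeklySnapshot]:
    """Retroactively extract ratings at the end of each 7-day block.

    Week ``w`` covers days ``7*(w-1)`` .. ``7*w - 1`` from the study start;
    its snapshot is each individual's rating after the last event within the
    block (carried forward through event-free weeks).  An individual appears
    in a week's snapshot iff its presence interval overlaps that week.
    """
    if n_weeks < 1:
        raise DomainError("n_weeks must be >= 1")
    snaps = []
    for w in range(1, n_weeks + 1):
        week_start = study_start_date + timedelta(days=7 * (w - 1))
        week_end = week_start + timedelta(days=6)
        cutoff = datetime.combine(week_end, time.max)
        ratings = {}
        for ind in roster:
            overlaps = (ind.present_from is None or ind.present_from <= week_end) and (
                ind.present_until is None or ind.present_until >= week_start
            )
            if not overlaps:
                continue
            ratings[ind.id] = trajectories[ind.id].rating_before(cutoff, params.start_rating)
        snaps.append(WeeklySnapshot(week_index=w, week_end=week_end, ratings=ratings))
    return snaps


def standardize(snapshots: list[WeeklySnapshot]) -> list[WeeklySnapshot]:
    """Attach z-scored ratings, standardized globally over all subject-week
    values (sample SD), so between-week dynamics survive as covariate signal."""
    values = np.array([r for snap in snapshots for r in snap.ratings.values()], dtype=float)
    if values.size < 2:
        raise DomainError("standardize needs at least 2 subject-week values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        raise DomainError("zero variance across subject-week ratings")
    out = []
    for snap in snapshots:
        z = {k: (v - mean) / sd for k, v in snap.ratings.items()}
        out.append(
            WeeklySnapshot(
                week_index=snap.week_index,
                week_end=snap.week_end,
                ratings=dict(snap.ratings),
                z_ratings=z,
            )
        )
    return out


def snapshots_to_frame(snapshots: list[WeeklySnapshot]):
    """Long-format ratings table (week_index, week_end, individual_id, elo, elo_z)."""
    import pandas as pd

    rows = []
    for snap in snapshots:
        for iid, r in sorted(snap.ratings.items()):
            z = None if snap.z_ratings is None else snap.z_ratings.get(iid)
            rows.append((snap.week_index, snap.week_end.isoformat(), iid, r, z))
    return pd.DataFrame(
        rows, columns=["week_index", "week_end", "individual_id", "elo", "elo_z"]
    )
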