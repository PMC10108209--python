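"""Visitation rates from camera-trap event logs.

Converts timestamped flower-visit events recorded in observation sessions
(one camera watching one or two flowers overnight) into per-taxon,
per-period rates in visits per flower per hour, with standard errors across
sessions. The default diel periods follow the overnight recording design:
dusk 20:00-21:00, night 21:00-05:00 (crossing midnight), morning
05:00-10:00.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PERIODS",
    "VisitEvent",
    "ObservationSession",
    "visitation_rates",
    "aggregate_rates",
    "period_exposure_hours",
    "load_visit_log",
]

#: (start clock time, end clock time); end < start means the window
#: crosses midnight.
DEFAULT_PERIODS: dict[str, tuple[time, time]] = {
    "dusk": (time(20, 0), time(21, 0)),
    "night": (time(21, 0), time(5, 0)),
    "morning": (time(5, 0), time(10, 0)),
}


@dataclass(frozen=True)
class VisitEvent:
    timestamp: datetime
    taxon: str
    flower_id: str
    session_id: str

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("taxon label must be nonempty")


@dataclass(frozen=True)
class ObservationSession:
    session_id: str
    start: datetime
    end: datetime
    n_flowers: int = 1
    plant_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"session {self.session_id}: end must follow start")
        if self.n_flowers < 1:
            raise ValueError("n_flowers must be >= 1")


def _period_windows(session: ObservationSession,
                    clock: tuple[time, time]) -> list[tuple[datetime, datetime]]:
    """Concrete datetime windows of one diel period within a session."""
    start_c, end_c = clock
    windows = []
    day = session.start.date() - timedelta(days=1)
    last = session.end.date() + timedelta(days=1)
    while day <= last:
        w0 = datetime.combine(day, start_c)
        if end_c > start_c:
            w1 = datetime.combine(day, end_c)
        else:  # crosses midnight
            w1 = datetime.combine(day + timedelta(days=1), end_c)
        a, b = max(w0, session.start), min(w1, session.end)
        if b > a:
            windows.append((a, b))
        day += timedelta(days=1)
    return windows


def period_exposure_hours(session: ObservationSession,
                          periods: dict[str, tuple[time, time]] = DEFAULT_PERIODS,
                          ) -> dict[str, float]:
    """Observation hours of each period clipped to the session window
    (per flower; multiply by ``n_flowers`` for flower-hours)."""
    out = {}
    for name, clock in periods.items():
        hours = sum((b - a).total_seconds() / 3600.0
                    for a, b in _period_windows(session, clock))
        out[name] = hours
    return out


def _assign_period(ts: datetime, session: ObservationSession,
                   periods: dict[str, tuple[time, time]]) -> str:
    for name, clock in periods.items():
        for a, b in _period_windows(session, clock):
            if a <= ts < b:
                return name
    raise ValueError(f"event at {ts} falls outside every period window of "
                     f"session {session.session_id}")


@dataclass
class RateTable:
    """Per (taxon, period) mean rate in visits per flower per hour, with SE
    over sessions (sessions without the taxon contribute zero rates)."""

    rates: pd.DataFrame  # columns: taxon, period, rate_mean, rate_se, n_sessions

    def get(self, taxon: str, period: str) -> tuple[float, float]:
        row = self.rates[(self.rates["taxon"] == taxon)
                         & (self.rates["period"] == period)]
        if row.empty:
            raise KeyError((taxon, period))
        return float(row["rate_mean"].iloc[0]), float(row["rate_se"].iloc[0])


def visitation_rates(events: list[VisitEvent],
                     sessions: list[ObservationSession],
                     periods: dict[str, tuple[time, time]] = DEFAULT_PERIODS,
                     taxa: list[str] | None = None) -> RateTable:
    """Per-taxon, per-period visitation rates from a camera-trap event log.

    For each session x taxon x period, the rate is the event count divided
    by the exposure (period overlap hours x flowers monitored); the table
    reports the mean and standard error of these per-session rates.
    """
    by_id = {s.session_id: s for s in sessions}
    if len(by_id) != len(sessions):
        raise ValueError("duplicate session ids")
    taxa = sorted(taxa if taxa is not None else {e.taxon for e in events})
    period_names = list(periods)

    counts: dict[tuple[str, str, str], int] = {}
    for e in events:
        if e.session_id not in by_id:
            raise ValueError(f"event references unknown session {e.session_id}")
        s = by_id[e.session_id]
        if not (s.start <= e.timestamp <= s.end):
            raise ValueError(f"event at {e.timestamp} outside session "
                             f"{e.session_id} window")
        per = _assign_period(e.timestamp, s, periods)
        counts[(e.session_id, e.taxon, per)] = \
            counts.get((e.session_id, e.taxon, per), 0) + 1

    rows = []
    for taxon in taxa:
        for per in period_names:
            per_session = []
            for s in sessions:
                hours = period_exposure_hours(s, periods)[per]
                exposure = hours * s.n_flowers
                c = counts.get((s.session_id, taxon, per), 0)
                if exposure == 0:
                    if c:
                        raise ValueError(
                            f"{c} events for zero exposure: session "
                            f"{s.session_id}, period {per}")
                    continue
                per_session.append(c / exposure)
            if not per_session:
                mean, se, n = 0.0, 0.0, 0
            else:
                arr = np.asarray(per_session)
                n = arr.size
                mean = float(arr.mean())
                se = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append({"taxon": taxon, "period": per, "rate_mean": mean,
                         "rate_se": se, "n_sessions": n})
    return RateTable(pd.DataFrame(rows))


def aggregate_rates(rt: RateTable,
                    groups: dict[str, list[str]]) -> pd.DataFrame:
    """Summed rates over taxon groups, per period.

    Group means are sums of member means; the group SE combines member SEs
    in quadrature (valid when taxa vary independently across sessions).
    """
    known = set(rt.rates["taxon"])
    rows = []
    for name, members in groups.items():
        unknown = set(members) - known
        if unknown:
            raise ValueError(f"unknown taxa in group {name!r}: {sorted(unknown)}")
        sub = rt.rates[rt.rates["taxon"].isin(members)]
        agg = sub.groupby("period", sort=False).agg(
            rate_mean=("rate_mean", "sum"),
            rate_se=("rate_se", lambda s: float(np.sqrt(np.sum(np.square(s))))),
        ).reset_index()
        agg.insert(0, "group", name)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


def load_visit_log(events_csv, sessions_csv
                   ) -> tuple[list[VisitEvent], list[ObservationSession]]:
    """Read events (timestamp, taxon, flower_id, session_id) and sessions
    (session_id, start, end, n_flowers[, plant_id]) CSVs."""
    ev = pd.read_csv(events_csv, parse_dates=["timestamp"])
    se = pd.read_csv(sessions_csv, parse_dates=["start", "end"])
    events = [VisitEvent(r.timestamp.to_pydatetime(), str(r.taxon),
                         str(r.flower_id), str(r.session_id))
              for r in ev.itertuples()]
    sessions = [ObservationSession(str(r.session_id),
                                   r.start.to_pydatetime(),
                                   r.end.to_pydatetime(),
                                   int(r.n_flowers),
                                   str(getattr(r, "plant_id", "")) or None)
                for r in se.itertuples()]
    return events, sessions
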