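"""Per-trip instrumentation and summary statistics.

Every completed public-market trip — whether produced by the full agent-based
simulator or by the reduced decision hierarchy — is captured as one
:class:`TripRecord`.  The record carries the five trip outcomes

* ``obtained``   — did the customer obtain heroin,
* ``duration``   — minutes spent in the market,
* ``arrested``   — was the customer arrested (only possible when obtained),
* ``via_broker`` — purchase through a street broker vs. a street dealer
  (defined only when obtained),
* ``invited``    — invitation to deal directly with a private dealer in the
  future (defined only when via_broker),

together with the covariates the emulator regressions are fitted on, all
captured at the moment the trip begins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, fields

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError

OUTCOMES = ("obtained", "arrested", "via_broker", "invited")


@dataclass(slots=True)
class TripRecord:
    customer_id: int
    day: int
    entry_minute: float                 # minute of day at market entry
    obtained: int
    duration: float                     # minutes
    arrested: int = 0
    via_broker: int | None = None       # defined only when obtained == 1
    invited: int | None = None          # defined only when via_broker == 1
    units_sought: float = 0.0
    units_obtained: float = 0.0
    x_units_sold_before: float = 0.0    # street-dealer units sold that day, at entry
    x_collective_remaining: float = 0.0  # street dealers' collective stock, at entry
    x_broker_dealer_ratio: float = 0.0  # brokers-to-dealers ratio, at entry
    x_broker_purchases_before: int = 0  # customer's prior brokered purchases
    bust_active: int = 0

    def validate(self) -> "TripRecord":
        if self.obtained not in (0, 1) or self.arrested not in (0, 1):
            raise IntegrityError("obtained and arrested must be 0/1")
        if self.duration <= 0:
            raise IntegrityError("trip duration must be positive")
        if self.obtained == 0:
            if self.arrested != 0:
                raise IntegrityError("a customer who obtained nothing cannot be arrested")
            if self.via_broker is not None or self.invited is not None:
                raise IntegrityError("via_broker/invited are undefined on failed trips")
        else:
            if self.via_broker not in (0, 1):
                raise IntegrityError("via_broker must be 0/1 on successful trips")
            if self.via_broker == 0 and self.invited is not None:
                raise IntegrityError("invited is undefined for street-dealer purchases")
            if self.via_broker == 1 and self.invited not in (0, 1):
                raise IntegrityError("invited must be 0/1 on brokered purchases")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def trips_to_dataframe(records: list[TripRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(TripRecord)]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_dict() for r in records], columns=cols)


@dataclass
class OutcomeSummary:
    """Steady-state averages of the five trip outcomes.

    Fields are ``None`` when the conditioning set is empty (e.g. the invite
    probability when no trip went through a broker).
    """

    p_obtain: float | None
    p_arrest: float | None
    p_broker: float | None
    p_invite: float | None
    t_mean: float | None                # minutes, all trips
    t_mean_success: float | None        # minutes, obtained == 1
    t_mean_failure: float | None        # minutes, obtained == 0
    n_trips: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def steady_state_window(records: list[TripRecord], start_day: int,
                        end_day: int | float = float("inf")) -> list[TripRecord]:
    """Trips with ``start_day <= day <= end_day``, order preserved.

    The default analysis window starts at day 180, after the market's
    transient period.
    """
    if start_day > end_day:
        raise DomainError(f"start_day {start_day} exceeds end_day {end_day}")
    return [r for r in records if start_day <= r.day <= end_day]


def _eligible(records: list[TripRecord], outcome: str) -> tuple[list[TripRecord], list[int]]:
    """Apply the decision-hierarchy conditioning and return (eligible trips,
    outcome values)."""
    if outcome == "obtained":
        elig = records
        vals = [r.obtained for r in elig]
    elif outcome == "arrested":
        elig = [r for r in records if r.obtained == 1]
        vals = [r.arrested for r in elig]
    elif outcome == "via_broker":
        elig = [r for r in records if r.obtained == 1]
        vals = [int(r.via_broker) for r in elig]
    elif outcome == "invited":
        elig = [r for r in records if r.obtained == 1 and r.via_broker == 1]
        vals = [int(r.invited) for r in elig]
    else:
        raise DomainError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    return elig, vals


def hourly_rates(records: list[TripRecord], outcome: str) -> list[tuple[int, float]]:
    """Per one-hour-interval outcome rates, the raw material the Beta
    distributions are fitted to.

    Each trip is binned by the wall-clock hour in which it completes
    (``day*24 + (entry+duration)//60``); the rate in a bin is the share of
    eligible trips with outcome 1.  Bins with no eligible trip are omitted.
    """
    elig, vals = _eligible(records, outcome)
    if not elig:
        warnings.warn(f"no eligible trips for outcome {outcome!r}", stacklevel=2)
        return []
    counts: dict[int, list[int]] = {}
    for r, v in zip(elig, vals):
        hour = int((r.day * 1440 + r.entry_minute + r.duration) // 60)
        bucket = counts.setdefault(hour, [0, 0])
        bucket[0] += v
        bucket[1] += 1
    return [(hour, s / n) for hour, (s, n) in sorted(counts.items())]


def hourly_rate_table(records: list[TripRecord], outcome: str) -> pd.DataFrame:
    """Like :func:`hourly_rates` but also reporting the number of eligible
    trips per interval (columns ``hour``, ``rate``, ``n``); the counts serve
    as weights when fitting distributions to the rates."""
    elig, vals = _eligible(records, outcome)
    counts: dict[int, list[int]] = {}
    for r, v in zip(elig, vals):
        hour = int((r.day * 1440 + r.entry_minute + r.duration) // 60)
        bucket = counts.setdefault(hour, [0, 0])
        bucket[0] += v
        bucket[1] += 1
    rows = [(hour, s / n, n) for hour, (s, n) in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["hour", "rate", "n"])


def empirical_summaries(records: list[TripRecord]) -> OutcomeSummary:
    """Overall per-trip averages of the five outcomes.

    Averages are per trip, not per customer; conditional probabilities follow
    the decision hierarchy (arrest and broker rates among successful trips,
    invite rate among brokered purchases).
    """
    if not records:
        raise DomainError("cannot summarize an empty trip log")

    def _mean(xs):
        return float(np.mean(xs)) if len(xs) else None

    obtained = [r.obtained for r in records]
    succ = [r for r in records if r.obtained == 1]
    fail = [r for r in records if r.obtained == 0]
    brokered = [r for r in succ if r.via_broker == 1]
    return OutcomeSummary(
        p_obtain=_mean(obtained),
        p_arrest=_mean([r.arrested for r in succ]),
        p_broker=_mean([int(r.via_broker) for r in succ]),
        p_invite=_mean([int(r.invited) for r in brokered]),
        t_mean=_mean([r.duration for r in records]),
        t_mean_success=_mean([r.duration for r in succ]),
        t_mean_failure=_mean([r.duration for r in fail]),
        n_trips=len(records),
    )
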