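"""The reduced market simulator.

Customers keep their full pharmacology, income dynamics and private-dealer
pathway; what changes is the resolution of a public-market trip.  Instead of
moving on a grid and interacting with dealer/broker/police agents, each trip
is resolved by a five-step conditional decision hierarchy of draws from the
fitted emulator:

1. obtain probability ``p_o`` (regression on units sold today, with the
   customer's random intercept, or a Beta draw) -> Bernoulli success flag;
2. trip duration drawn from the success- or failure-conditional Gamma;
3. if successful, arrest probability ``p_a`` -> Bernoulli (a customer who
   obtained nothing cannot be arrested);
4. if successful, broker probability ``p_sb`` -> Bernoulli purchase mode;
5. if brokered, invite probability ``p_i`` (regression on the customer's
   prior brokered purchases, or a Beta draw) -> Bernoulli invitation to a
   private dealer.

Street dealers survive only as a ledger: counts in market vs. arrested
(updated from fitted Poisson arrest/release rates during busts) and the
units-sold / collective-stock covariates feeding the regressions.

The simulator is event-driven with all event times quantized to whole
simulated minutes; because concentration decay is exponential, the next
craving time has a closed form and idle minutes need not be ticked.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .customers import (CustomerState, consume, craving_trigger,
                        customer_stream, decay_area, dose_units, end_of_day,
                        init_customer, minutes_to_craving, replenish_income)
from .emulator import EmulatorSpec, OutcomeModel
from .errors import ConfigError, DomainError
from .trips import TripRecord


@dataclass
class DealerLedger:
    """Street-dealer bookkeeping retained by the reduced model."""

    n_total: int
    n_in_market: int
    n_arrested: int
    units_sold_today: float
    collective_remaining: float
    n_brokers: int

    def check(self) -> None:
        assert self.n_in_market + self.n_arrested == self.n_total
        assert self.n_in_market >= 0 and self.n_arrested >= 0

    @property
    def broker_dealer_ratio(self) -> float:
        return self.n_brokers / max(1, self.n_in_market)


# ---------------------------------------------------------------------------
# hierarchy primitives
# ---------------------------------------------------------------------------

def eval_p_obtain(x: float, model, gamma_j: float = 0.0) -> float:
    """Obtain probability: inverse-logit(beta0 + beta1*x + gamma_j), where x
    is the number of units sold by street dealers so far today."""
    if x < 0:
        raise DomainError(f"units sold cannot be negative, got {x}")
    return model.predict(x, gamma_j)


def eval_p_invite(k: int, model) -> float:
    """Invite probability: inverse-logit(beta0 + beta1*k), where k is the
    customer's number of prior successful brokered purchases."""
    if k < 0:
        raise DomainError(f"broker purchase count cannot be negative, got {k}")
    return model.predict(k)


def _probability(om: OutcomeModel, regression_x: float, gamma: float,
                 rng: np.random.Generator) -> float:
    if om.form == "distribution":
        return float(om.distribution.sample(rng))
    return om.regression.predict(regression_x, gamma)


def draw_market_trip(customer: CustomerState, ledger: DealerLedger,
                     emulator: EmulatorSpec, regime: str,
                     rng: np.random.Generator, config: SimConfig,
                     day: int, entry_minute: float,
                     units_sought: float) -> TripRecord:
    """Resolve one public-market trip through the decision hierarchy.

    Returns the trip record; the caller applies the side effects (money,
    inventory, ledger, invitations, arrests, occupation time) so that the
    draw itself stays a pure function of (state, rng).
    """
    if not emulator.has_regime(regime):
        raise ConfigError(f"emulator has no models for regime {regime!r}")

    x_sold = ledger.units_sold_today
    x_remaining = ledger.collective_remaining
    x_ratio = ledger.broker_dealer_ratio
    k_before = customer.broker_purchase_count

    om = emulator.model("obtain", regime)
    if om.form == "regression":
        x = x_remaining if om.regression.covariate == "collective_remaining" else x_sold
        p_o = eval_p_obtain(x, om.regression, customer.random_effect)
    else:
        p_o = _probability(om, 0.0, 0.0, rng)
    obtained = int(rng.random() < p_o)

    dur_model = emulator.model("time_success" if obtained else "time_failure", regime)
    duration = max(1.0, float(dur_model.distribution.sample(rng)))

    arrested = 0
    via_broker: int | None = None
    invited: int | None = None
    if obtained:
        p_a = _probability(emulator.model("arrest", regime), 0.0, 0.0, rng)
        arrested = int(rng.random() < p_a)
        om_b = emulator.model("broker", regime)
        p_sb = _probability(om_b, x_ratio, 0.0, rng)
        via_broker = int(rng.random() < p_sb)
        if via_broker:
            om_i = emulator.model("invite", regime)
            if om_i.form == "regression":
                p_i = eval_p_invite(k_before, om_i.regression)
            else:
                p_i = _probability(om_i, 0.0, 0.0, rng)
            invited = int(rng.random() < p_i)

    return TripRecord(
        customer_id=customer.id,
        day=day,
        entry_minute=entry_minute,
        obtained=obtained,
        duration=duration,
        arrested=arrested,
        via_broker=via_broker,
        invited=invited,
        units_sought=units_sought,
        units_obtained=0.0,     # caller fills in on success
        x_units_sold_before=x_sold,
        x_collective_remaining=x_remaining,
        x_broker_dealer_ratio=x_ratio,
        x_broker_purchases_before=k_before,
        bust_active=int(regime == "bust"),
    ).validate()


def update_dealer_ledger(ledger: DealerLedger, regime: str, dt_days: float,
                         rates, rng: np.random.Generator) -> DealerLedger:
    """Poisson arrest/release bookkeeping over ``dt_days``.

    Arrests are capped at the number of dealers in the market and releases at
    the number arrested, preserving ``n_in_market + n_arrested = n_total``.
    """
    if dt_days <= 0:
        raise DomainError(f"dt must be positive, got {dt_days}")
    if rates is None:
        return ledger
    arrest_rate = rates.arrest_rate_bust if regime == "bust" else rates.arrest_rate_normal
    arrests = min(int(rng.poisson(max(0.0, arrest_rate) * dt_days)), ledger.n_in_market)
    releases = min(int(rng.poisson(max(0.0, rates.release_rate) * dt_days)), ledger.n_arrested)
    ledger.n_in_market += releases - arrests
    ledger.n_arrested += arrests - releases
    ledger.check()
    return ledger


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_WAKE, _TRIP_END, _RELEASE = 0, 1, 2


def bust_windows(config: SimConfig) -> list[tuple[float, float]]:
    """(start_minute, end_minute) of each bust, on the absolute clock."""
    return [(d * 1440.0, d * 1440.0 + config.bust_duration_minutes)
            for d in config.bust_days]


def _regime_at(minute: float, windows: list[tuple[float, float]]) -> str:
    for lo, hi in windows:
        if lo <= minute < hi:
            return "bust"
    return "normal"


def run_reduced_simulation(config: SimConfig, emulator: EmulatorSpec,
                           seed: int) -> tuple[pd.DataFrame, list[TripRecord]]:
    """Simulate ``config.days`` days of the reduced market.

    Returns the per-day aggregate trajectory (mean customer money, inventory,
    addiction and concentration) and the full trip log, reproducibly for a
    given seed.
    """
    config.validate()
    master = np.random.SeedSequence([seed, 0x5EDC])
    rng_init, rng_trips, rng_ledger = [np.random.Generator(np.random.PCG64(s))
                                       for s in master.spawn(3)]

    var = 0.0
    om = emulator.regimes.get("normal", {}).get("obtain")
    if om is not None and om.regression is not None:
        var = om.regression.random_effect_variance
    sd = math.sqrt(var) if var > 0 else None

    customers = [init_customer(i, customer_stream(seed, i), config, draw_random_effect=sd)
                 for i in range(config.n_customers)]
    ledger = DealerLedger(
        n_total=config.n_street_dealers,
        n_in_market=config.n_street_dealers,
        n_arrested=0,
        units_sold_today=0.0,
        collective_remaining=config.n_street_dealers * config.dealer_inventory_units,
        n_brokers=config.n_brokers,
    )
    windows = bust_windows(config)
    horizon = config.days * 1440.0
    trips: list[TripRecord] = []
    daily_rows: list[dict] = []
    # per-customer bookkeeping outside CustomerState
    conc_minute = [0.0] * config.n_customers     # clock of last concentration update
    conc_area = [0.0] * config.n_customers       # concentration-minutes today
    private_units_today = 0.0

    events: list[tuple[float, int, int, int]] = []  # (minute, kind, customer, token)
    for c in customers:
        heapq.heappush(events, (0.0, _WAKE, c.id, 0))
    pending_units: dict[int, float] = {}

    def sync_concentration(c: CustomerState, now: float) -> None:
        dt = now - conc_minute[c.id]
        if dt > 0:
            conc_area[c.id] += decay_area(c.concentration, dt, config)
            c.concentration *= 2.0 ** (-dt / config.half_life_min)
            conc_minute[c.id] = now

    def schedule_wake(c: CustomerState, now: float) -> None:
        wait = minutes_to_craving(c, config)
        t = math.ceil(now + max(wait, 1.0))
        heapq.heappush(events, (float(min(t, horizon)), _WAKE, c.id, 0))

    day = 0
    next_midnight = 1440.0
    while events:
        minute, kind, cid, token = heapq.heappop(events)
        # day rollovers between events (also on the event that crosses the horizon)
        while minute >= next_midnight and day < config.days:
            snapshot_minute = next_midnight
            for c in customers:
                sync_concentration(c, snapshot_minute)
            daily_rows.append({
                "day": day,
                "mean_money": float(np.mean([c.money for c in customers])),
                "mean_inventory": float(np.mean([c.inventory for c in customers])),
                "mean_addiction": float(np.mean([c.addiction for c in customers])),
                "mean_concentration": float(np.mean([a / 1440.0 for a in conc_area])),
                "private_units": private_units_today,
                "units_consumed": float(np.sum([c.consumed_today for c in customers])),
            })
            private_units_today = 0.0
            for i in range(len(conc_area)):
                conc_area[i] = 0.0
            day += 1
            regime_today = _regime_at(next_midnight, windows)
            update_dealer_ledger(ledger, regime_today, 1.0,
                                 emulator.dealer_ledger_rates, rng_ledger)
            ledger.units_sold_today = 0.0
            ledger.collective_remaining = ledger.n_in_market * config.dealer_inventory_units
            for c in customers:
                end_of_day(c, config)
                replenish_income(c, day, rng_init, config)
            next_midnight += 1440.0
        if minute >= horizon or day >= config.days:
            break

        c = customers[cid]
        if kind == _RELEASE:
            # arrested customer returns; resume the normal cycle
            heapq.heappush(events, (minute, _WAKE, cid, 0))
            continue
        if kind == _TRIP_END:
            units = pending_units.pop(cid, 0.0)
            if units > 0:
                c.inventory += units
            heapq.heappush(events, (minute, _WAKE, cid, 1))
            continue

        # _WAKE: evaluate craving
        sync_concentration(c, minute)
        if c.concentration >= config.craving_threshold:
            schedule_wake(c, minute)
            continue
        if c.inventory > 0:
            consume(c, dose_units(c, config), config)
            schedule_wake(c, minute)
            continue
        wants, target = craving_trigger(c, config)
        if not wants:
            # cannot afford a unit: check again in a day (after income)
            heapq.heappush(events, (minute + 1440.0, _WAKE, cid, 0))
            continue
        # private-dealer pathway bypasses the hierarchy entirely
        if c.known_private_dealers and rng_trips.random() < config.p_private_choice:
            cost = target * config.price_per_unit
            c.money -= cost
            c.inventory += target
            private_units_today += target
            consume(c, dose_units(c, config), config)
            schedule_wake(c, minute)
            continue
        # public-market trip via the decision hierarchy
        regime = _regime_at(minute, windows)
        if regime == "bust" and not emulator.has_regime("bust"):
            regime = "normal"
        rec = draw_market_trip(c, ledger, emulator, regime, rng_trips, config,
                               day=day, entry_minute=minute - day * 1440.0,
                               units_sought=float(target))
        trip_end = math.ceil(minute + rec.duration)
        if rec.obtained:
            # a success always delivers the full amount sought (an
            # undersupplied deal fails outright, which the obtain model
            # already accounts for)
            bought = float(target)
            cost = bought * config.price_per_unit
            c.money = max(0.0, c.money - cost)
            delivered = bought
            if rec.via_broker:
                delivered = bought * (1.0 - config.broker_tax_fraction)
                c.broker_purchase_count += 1
                if rec.invited and len(c.known_private_dealers) < config.n_private_dealers:
                    known = c.known_private_dealers
                    candidates = [d for d in range(config.n_private_dealers) if d not in known]
                    if candidates:
                        known.add(candidates[int(rng_trips.integers(len(candidates)))])
            rec.units_obtained = delivered
            ledger.units_sold_today += bought
            ledger.collective_remaining = max(0.0, ledger.collective_remaining - bought)
            if rec.arrested:
                held = delivered
                days_held = config.arrest_base_days + config.arrest_days_per_unit * held
                rec.units_obtained = 0.0     # seized
                heapq.heappush(events, (trip_end + days_held * 1440.0, _RELEASE, cid, 0))
            else:
                pending_units[cid] = delivered
                heapq.heappush(events, (float(trip_end), _TRIP_END, cid, 0))
        else:
            heapq.heappush(events, (float(trip_end + config.retry_rest_minutes),
                                    _TRIP_END, cid, 0))
        trips.append(rec)

    # flush remaining day rows (only reachable with an empty event stream,
    # e.g. a market with zero customers)
    while day < config.days:
        daily_rows.append({
            "day": day,
            "mean_money": float("nan"), "mean_inventory": float("nan"),
            "mean_addiction": float("nan"), "mean_concentration": float("nan"),
            "private_units": 0.0, "units_consumed": 0.0,
        })
        day += 1

    daily = pd.DataFrame(daily_rows, columns=["day", "mean_money", "mean_inventory",
                                              "mean_addiction", "mean_concentration",
                                              "private_units", "units_consumed"])
    daily = daily.iloc[:config.days].reset_index(drop=True)
    return daily, trips
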