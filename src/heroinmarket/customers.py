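"""Customer pharmacodynamics, drug seeking and income dynamics.

These rules are shared verbatim by the full agent-based market and the
reduced (emulator-driven) market: only the *resolution of a market trip*
differs between the two simulators.

Model
-----
* Body drug concentration decays exponentially with a configurable half-life
  (default 4 h) and jumps by ``potency x units`` on consumption.
* A craving fires when concentration falls below ``craving_threshold``; the
  customer first consumes from inventory, and seeks to purchase only when the
  inventory cannot cover the addiction-implied daily need.
* Addiction level (the target daily consumption) is an exponentially-weighted
  moving average of realized daily consumption, updated at each day rollover
  with weight ``addiction_rate`` and floored at a baseline habit level.
* Income arrives on a weekly, biweekly or monthly schedule, with occasional
  random bonuses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .errors import DomainError

INCOME_PERIODS = ("weekly", "biweekly", "monthly")
_PERIOD_DAYS = {"weekly": 7, "biweekly": 14, "monthly": 30}


@dataclass
class CustomerState:
    """Mutable per-customer state shared by both simulators.

    ``random_effect`` is the customer-level intercept deviation used by the
    reduced model's obtain-probability regression; the full model leaves it
    at zero.
    """

    id: int
    money: float
    addiction: float                   # target daily consumption, units/day
    income_period: str
    income_amount: float               # per pay period
    inventory: float = 0.0             # heroin units held
    concentration: float = 0.0         # body drug concentration
    known_street_sellers: dict = field(default_factory=dict)   # seller id -> (x, y)
    known_private_dealers: set = field(default_factory=set)
    broker_purchase_count: int = 0     # cumulative successful brokered buys
    random_effect: float = 0.0
    addiction_floor: float = 0.0       # baseline habit, units/day
    consumed_today: float = 0.0

    def check(self) -> None:
        assert self.money >= 0 and self.inventory >= 0
        assert self.addiction >= 0 and self.concentration >= 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def update_pharmacology(state: CustomerState, dt_minutes: float, config: SimConfig) -> CustomerState:
    """Advance the customer's drug concentration by ``dt_minutes``.

    Concentration decays exponentially: ``C(t + dt) = C(t) * 2^(-dt / T_half)``.
    Addiction relaxes on a daily cadence (see :func:`end_of_day`).
    """
    if dt_minutes <= 0:
        raise DomainError(f"dt must be positive, got {dt_minutes}")
    state.concentration *= 2.0 ** (-dt_minutes / config.half_life_min)
    return state


def consume(state: CustomerState, units: float, config: SimConfig) -> CustomerState:
    """Use ``units`` of heroin from inventory; concentration rises by
    ``units * potency``."""
    if units < 0:
        raise DomainError(f"cannot consume a negative amount ({units})")
    if units > state.inventory + 1e-9:
        raise DomainError(
            f"cannot consume {units} units with only {state.inventory} in inventory"
        )
    state.inventory = max(0.0, state.inventory - units)
    state.concentration += units * config.potency
    state.consumed_today += units
    return state


def craving_trigger(state: CustomerState, config: SimConfig) -> tuple[bool, int]:
    """Decide whether the customer wants a purchase trip, and for how much.

    A trip is wanted when concentration is below the craving threshold and
    the inventory cannot cover the next dose.  The target tops the inventory
    up to the addiction-implied daily need — the smallest whole number of
    units covering the unmet need — capped by what the customer can afford;
    a customer who cannot afford a single unit does not travel.
    """
    if state.concentration >= config.craving_threshold:
        return False, 0
    if state.inventory >= max(1.0, state.addiction * config.dose_fraction):
        return False, 0     # can still dose from inventory
    need = math.ceil(max(0.0, state.addiction - state.inventory) - 1e-9)
    if need <= 0:
        return False, 0
    affordable = int(state.money / config.price_per_unit)
    target = min(need, affordable)
    if target <= 0:
        return False, 0
    return True, target


def dose_units(state: CustomerState, config: SimConfig) -> float:
    """Units consumed when a craving is satisfied from inventory: one dose
    (a configurable fraction of the daily addiction level) if available,
    else everything held.

    With the default constants (half-life 4 h, potency 0.25, dose a quarter
    of the daily level, threshold 1.0) the dosing cycle is self-consistent
    at roughly four doses per day and has a pharmacologic equilibrium near
    45 units/day: a dose of ``0.25 a`` raises concentration by ``0.0625 a``,
    which decays back to threshold in ``240 log2(0.0625 a)`` minutes.
    """
    return min(state.inventory, max(1.0, state.addiction * config.dose_fraction))


def replenish_income(state: CustomerState, day: int, rng: np.random.Generator,
                     config: SimConfig) -> CustomerState:
    """Apply scheduled income and the occasional random bonus for ``day``."""
    if day < 0:
        raise DomainError(f"day must be nonnegative, got {day}")
    period = _PERIOD_DAYS[state.income_period]
    if day > 0 and day % period == 0:
        state.money += state.income_amount
    if config.bonus_probability > 0 and rng.random() < config.bonus_probability:
        state.money += rng.uniform(config.bonus_min, config.bonus_max)
    return state


def end_of_day(state: CustomerState, config: SimConfig) -> CustomerState:
    """Day rollover: addiction moves toward today's consumption (EWMA), a
    share of cash on hand goes to non-drug living expenses, and the daily
    consumption accumulator resets.

    With constant daily consumption ``c`` the addiction level converges
    geometrically to ``max(c, floor)``.
    """
    a = state.addiction + config.addiction_rate * (state.consumed_today - state.addiction)
    state.addiction = max(state.addiction_floor, a)
    state.money *= 1.0 - config.living_expense_fraction
    state.consumed_today = 0.0
    return state


def decay_area(concentration: float, dt_minutes: float, config: SimConfig) -> float:
    """Integral of an exponentially-decaying concentration over ``dt_minutes``
    (concentration-minutes); used for time-averaged daily concentration."""
    if dt_minutes <= 0 or concentration <= 0:
        return 0.0
    tau = config.half_life_min / math.log(2.0)
    return concentration * tau * (1.0 - 2.0 ** (-dt_minutes / config.half_life_min))


def minutes_to_craving(state: CustomerState, config: SimConfig) -> float:
    """Closed-form time until the concentration decays to the craving
    threshold (0 if already below)."""
    c, thr = state.concentration, config.craving_threshold
    if c <= thr:
        return 0.0
    return config.half_life_min * math.log2(c / thr)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def customer_stream(seed: int, cid: int) -> np.random.Generator:
    """Per-customer random stream, stable in (seed, customer id).

    Both simulators initialize customer ``cid`` from this stream, so a full
    and a reduced run sharing a seed simulate the *same population* — a
    paired design that removes initialization luck from model comparisons.
    """
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0xC0, cid])))


def init_customer(cid: int, rng: np.random.Generator, config: SimConfig,
                  draw_random_effect: float | None = None) -> CustomerState:
    """Draw a fresh customer.

    ``draw_random_effect`` is the SD of the customer-level random intercept
    (reduced model); ``None`` leaves it at zero (full model).
    """
    addiction = rng.uniform(config.addiction_min, config.addiction_max)
    period = INCOME_PERIODS[rng.integers(len(INCOME_PERIODS))]
    daily_rate = rng.uniform(config.income_daily_min, config.income_daily_max)
    gamma = float(rng.normal(0.0, draw_random_effect)) if draw_random_effect else 0.0
    return CustomerState(
        id=cid,
        money=daily_rate * config.initial_money_days,
        addiction=addiction,
        addiction_floor=addiction * config.addiction_floor_fraction,
        income_period=period,
        income_amount=daily_rate * _PERIOD_DAYS[period],
        random_effect=gamma,
    )
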