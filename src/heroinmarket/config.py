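"""Simulation configuration.

A single :class:`SimConfig` drives both the full agent-based market and the
reduced (emulator-driven) market, so that the two can be compared under
identical study conditions.  Defaults describe a one-year simulation of an
open-air heroin market with 200 customers, 20 street dealers, 25 street
brokers, 25 private dealers, 100 homeless individuals and 1 police officer.

The demand and supply scale defaults are calibrated to the operating point
implied by the reference obtain-probability regression: a market whose street
dealers move roughly ``beta0/|beta1| ~ 8900`` units per day across 200
customers (see docs/methods.md for the derivation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Tick values (seconds) that either divide one minute or are whole minutes.
_MINUTE = 60.0


@dataclass
class SimConfig:
    # --- agent roster -----------------------------------------------------
    n_customers: int = 200
    n_street_dealers: int = 20
    n_brokers: int = 25
    n_private_dealers: int = 25
    n_homeless: int = 100
    n_police: int = 1

    # --- clock ------------------------------------------------------------
    tick_seconds: float = 60.0
    days: int = 365
    seed: int = 0

    # --- market economics -------------------------------------------------
    price_per_unit: float = 1.0
    dealer_inventory_units: float = 300.0   # units issued per dealer shift
    dealer_shift_minutes: float = 480.0
    broker_tax_fraction: float = 0.15

    # --- policing ---------------------------------------------------------
    arrest_base_days: float = 7.0
    arrest_days_per_unit: float = 0.06
    police_inspect_probability: float = 0.0005  # per tick, per officer
    bust_inspect_multiplier: float = 10.0

    # --- geometry ---------------------------------------------------------
    grid_width: int = 50
    grid_height: int = 50

    # --- busts ------------------------------------------------------------
    bust_days: tuple[int, ...] = ()
    bust_duration_minutes: float = 1440.0
    bust_police: int = 5
    dealer_return_mean_days: float = 20.0

    # --- customer market behaviour ----------------------------------------
    max_search_minutes: float = 360.0
    retry_rest_minutes: float = 60.0    # pause after a failed trip before retrying
    p_private_choice: float = 0.25      # chance a customer with a known private
                                        # dealer goes private instead of to market
    invite_base: float = 0.01           # broker invitation: base probability
    invite_slope: float = 1.0e-4        # ... plus slope per prior brokered buy
    invite_max: float = 0.3
    n_known_sellers_init: int = 2       # seeded familiarity with dealer pitches

    # --- pharmacodynamics -------------------------------------------------
    half_life_min: float = 240.0        # concentration half-life
    potency: float = 0.25               # concentration units per heroin unit
    dose_fraction: float = 0.25         # dose size as a fraction of the daily
                                        # addiction level (several doses a day)
    addiction_rate: float = 0.1         # daily EWMA weight on consumption
    craving_threshold: float = 1.0      # concentration below which craving fires
    addiction_floor_fraction: float = 0.5  # baseline habit floor, as a fraction
                                           # of the initial addiction level
    addiction_min: float = 60.0         # initial addiction, uniform range
    addiction_max: float = 110.0        # (units/day)

    # --- income -----------------------------------------------------------
    income_daily_min: float = 35.0      # daily-equivalent income rate range;
    income_daily_max: float = 65.0      # close to the drug budget, so money
                                        # stays hand-to-mouth rather than
                                        # accumulating without bound
    bonus_probability: float = 0.02     # per day
    bonus_min: float = 10.0
    bonus_max: float = 60.0
    initial_money_days: float = 14.0    # starting cash, in days of income
    living_expense_fraction: float = 0.2  # share of cash on hand spent daily on
                                          # non-drug living costs (keeps money
                                          # hand-to-mouth and mean-reverting)

    # ----------------------------------------------------------------------
    @property
    def tick_minutes(self) -> float:
        return self.tick_seconds / _MINUTE

    @property
    def minutes_per_day(self) -> float:
        return 1440.0

    def validate(self) -> "SimConfig":
        counts = {
            "n_customers": self.n_customers,
            "n_street_dealers": self.n_street_dealers,
            "n_brokers": self.n_brokers,
            "n_private_dealers": self.n_private_dealers,
            "n_homeless": self.n_homeless,
            "n_police": self.n_police,
        }
        for name, value in counts.items():
            if not isinstance(value, int) or value < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.tick_seconds <= 0:
            raise ConfigError(f"tick_seconds must be > 0, got {self.tick_seconds}")
        t = self.tick_seconds
        if not (abs(_MINUTE / t - round(_MINUTE / t)) < 1e-9 or abs(t / _MINUTE - round(t / _MINUTE)) < 1e-9):
            raise ConfigError(
                f"tick_seconds must divide 60 s or be a multiple of 60 s, got {t}"
            )
        if self.days <= 0:
            raise ConfigError(f"days must be positive, got {self.days}")
        for name in ("broker_tax_fraction", "p_private_choice", "addiction_floor_fraction",
                     "bonus_probability", "police_inspect_probability",
                     "living_expense_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("price_per_unit", "dealer_inventory_units", "dealer_shift_minutes",
                     "half_life_min", "potency", "craving_threshold", "max_search_minutes",
                     "bust_duration_minutes", "dealer_return_mean_days"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.addiction_min <= 0 or self.addiction_max < self.addiction_min:
            raise ConfigError("addiction range must satisfy 0 < addiction_min <= addiction_max")
        if self.income_daily_min <= 0 or self.income_daily_max < self.income_daily_min:
            raise ConfigError("income range must satisfy 0 < income_daily_min <= income_daily_max")
        if self.grid_width <= 0 or self.grid_height <= 0:
            raise ConfigError("grid dimensions must be positive")
        for d in self.bust_days:
            if not (0 <= int(d) < self.days):
                raise ConfigError(f"bust day {d} outside the simulated horizon [0, {self.days})")
        return self

    # --- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bust_days"] = list(self.bust_days)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        clean = dict(data)
        if "bust_days" in clean and clean["bust_days"] is not None:
            clean["bust_days"] = tuple(int(d) for d in clean["bust_days"])
        try:
            cfg = cls(**clean)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc
        return cfg.validate()


def parse_config(path: str | Path) -> SimConfig:
    """Read a YAML configuration file; absent keys fall back to defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    return SimConfig.from_dict(raw)


def write_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def demo_config(**overrides) -> SimConfig:
    """A scaled-down market for pipelines that need many replicates:
    20 customers, 6 street dealers (with smaller per-shift inventories, so
    the daily market capacity scales like the customer count), 3 brokers,
    3 private dealers, 10 homeless, 1 police officer on a 15x15 grid,
    120 days.  Demand/supply ratio matches the full-scale defaults.
    """
    base = dict(
        n_customers=20,
        n_street_dealers=6,
        n_brokers=3,
        n_private_dealers=3,
        n_homeless=10,
        n_police=1,
        grid_width=15,
        grid_height=15,
        days=120,
        dealer_inventory_units=125.0,  # daily capacity scales with the roster
        police_inspect_probability=0.0005,
    )
    base.update(overrides)
    return SimConfig(**base).validate()
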