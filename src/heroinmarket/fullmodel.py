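"""The full agent-based open-air market.

Six agent types interact on a rectangular grid of cells: customers, street
dealers, street brokers, private dealers (off-grid), police and homeless.
One tick simulates ``tick_seconds`` of clock time (one minute by default);
agents move one cell per tick (Moore neighbourhood), which is deliberately
naive — the time-step sensitivity of the summary statistics under coarser or
finer ticks is part of what the package measures.

Market mechanics
----------------
* Street dealers work one shift per day at a fixed pitch, each issued a fresh
  inventory at shift start; they leave when sold out or when the shift ends,
  whichever comes first.
* A craving customer who knows no private dealer (or chooses not to use one)
  enters the market at a random edge cell and walks toward the nearest known
  dealer pitch, falling back to a random walk.  Co-location with a stocked
  dealer closes a sale at the fixed price; co-location with an idle broker
  starts a brokered deal: the broker carries the customer's money to a
  stocked dealer, keeps a fraction of the heroin as tax, and delivers the
  rest.  Brokers are the only route to private-dealer introductions.
* Police officers random-walk and occasionally inspect one random co-located
  agent; anyone found holding heroin is arrested and removed for
  ``arrest_base_days + arrest_days_per_unit * units`` days.  During a bust a
  larger police detail with a higher inspection intensity operates for 24 h.
* Homeless agents random-walk and hold nothing; they matter only by diluting
  police inspections.

Per completed market trip one :class:`~heroinmarket.trips.TripRecord` is
emitted; per day the four customer aggregates (mean money, inventory,
addiction, concentration) are recorded.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .customers import (CustomerState, consume, craving_trigger,
                        customer_stream, decay_area, dose_units, end_of_day,
                        init_customer, minutes_to_craving, replenish_income)
from .errors import ConfigError
from .trips import TripRecord

# customer phases
_IDLE, _SEARCH, _WAIT_BROKER, _EXIT = 0, 1, 2, 3
# broker phases
_B_ROAM, _B_TO_DEALER, _B_TO_CUSTOMER = 0, 1, 2


@dataclass
class _Dealer:
    id: int
    pitch: tuple[int, int]
    inventory: float = 0.0
    money: float = 0.0
    on_shift: bool = False
    worked_today: bool = False
    shift_start: float = 0.0          # minute of day
    shift_end_abs: float = -1.0
    release_abs: float | None = None  # arrested until (absolute minute)

    @property
    def arrested(self) -> bool:
        return self.release_abs is not None


@dataclass
class _Broker:
    id: int
    pos: tuple[int, int]
    phase: int = _B_ROAM
    customer_id: int | None = None
    carry_money: float = 0.0
    carry_units: float = 0.0
    units_wanted: float = 0.0
    target: tuple[int, int] | None = None
    release_abs: float | None = None

    @property
    def arrested(self) -> bool:
        return self.release_abs is not None


@dataclass
class _CustomerSim:
    state: CustomerState
    pos: tuple[int, int] = (0, 0)
    phase: int = _IDLE
    wake_abs: float = 0.0
    conc_minute: float = 0.0          # clock of last concentration sync
    conc_area: float = 0.0            # concentration-minutes accumulated today
    # trip bookkeeping
    entry_abs: float = 0.0
    target_units: int = 0
    carry_units: float = 0.0
    via_broker: int | None = None
    invited: int | None = None
    trip_covariates: dict = field(default_factory=dict)
    pitch_queue: list = field(default_factory=list)
    exit_target: tuple[int, int] | None = None
    patience: float = 360.0           # minutes before giving up, drawn per trip


def _step_toward(pos: tuple[int, int], target: tuple[int, int]) -> tuple[int, int]:
    x, y = pos
    tx, ty = target
    return (x + (tx > x) - (tx < x), y + (ty > y) - (ty < y))


class _StepBuffer:
    """Blocked supply of random unit steps (dx, dy in {-1, 0, 1}) from one
    generator; avoids per-agent scalar RNG calls in the tick loop."""

    __slots__ = ("rng", "buf", "idx")

    def __init__(self, rng: np.random.Generator, block: int = 16384):
        self.rng = rng
        self.buf = rng.integers(-1, 2, size=(block, 2))
        self.idx = 0

    def take(self) -> tuple[int, int]:
        if self.idx >= len(self.buf):
            self.buf = self.rng.integers(-1, 2, size=(len(self.buf), 2))
            self.idx = 0
        dx, dy = self.buf[self.idx]
        self.idx += 1
        return int(dx), int(dy)


def _chebyshev(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


class MarketState:
    """Mutable state of one full-model run; advanced tick by tick."""

    def __init__(self, config: SimConfig, seed: int):
        config.validate()
        self.config = config
        self.clock = 0.0              # absolute minutes
        self.tick_count = 0
        self.day = 0

        master = np.random.SeedSequence([seed, 0xF011])
        (s_init, s_cust, s_deal, s_brok, s_pol, s_home, s_misc) = master.spawn(7)
        self.rng_init = np.random.Generator(np.random.PCG64(s_init))
        self.rng_cust = np.random.Generator(np.random.PCG64(s_cust))
        self.rng_deal = np.random.Generator(np.random.PCG64(s_deal))
        self.rng_brok = np.random.Generator(np.random.PCG64(s_brok))
        self.rng_pol = np.random.Generator(np.random.PCG64(s_pol))
        self.rng_home = np.random.Generator(np.random.PCG64(s_home))
        self.rng_misc = np.random.Generator(np.random.PCG64(s_misc))

        W, H = config.grid_width, config.grid_height
        self._wh = (W, H)

        def rand_cell(rng):
            return (int(rng.integers(W)), int(rng.integers(H)))

        self.customers = [
            _CustomerSim(state=init_customer(i, customer_stream(seed, i), config),
                         pos=rand_cell(self.rng_init))
            for i in range(config.n_customers)
        ]
        self.dealers = [_Dealer(id=i, pitch=rand_cell(self.rng_init))
                        for i in range(config.n_street_dealers)]
        self.brokers = [_Broker(id=i, pos=rand_cell(self.rng_init))
                        for i in range(config.n_brokers)]
        self.police = [rand_cell(self.rng_init) for _ in range(config.n_police)]
        self.homeless = (
            np.column_stack([self.rng_init.integers(W, size=config.n_homeless),
                             self.rng_init.integers(H, size=config.n_homeless)]).astype(np.int64)
            if config.n_homeless else np.empty((0, 2), dtype=np.int64)
        )

        # seeded familiarity with dealer pitches
        for c in self.customers:
            if self.dealers and config.n_known_sellers_init > 0:
                k = min(config.n_known_sellers_init, len(self.dealers))
                picks = self.rng_init.choice(len(self.dealers), size=k, replace=False)
                for d in picks:
                    c.state.known_street_sellers[int(d)] = self.dealers[int(d)].pitch

        # accounting
        self.private_units_today = 0.0
        self.units_sold_today = 0.0
        self.units_issued_today = 0.0
        self.units_seized_today = 0.0
        self.seized_money = 0.0
        self.seized_units = 0.0
        self.broker_tax_units = 0.0
        self.market_money_in = 0.0    # customer money handed to dealers/brokers
        self.refunds_out = 0.0        # money returned on failed brokered deals
        self.interaction_ops = 0      # count of agent-interaction computations

        self.trips: list[TripRecord] = []
        self.daily_rows: list[dict] = []
        self.dealer_events: list[dict] = []

        self._steps_cust = _StepBuffer(self.rng_cust)
        self._steps_brok = _StepBuffer(self.rng_brok)
        self._steps_pol = _StepBuffer(self.rng_pol)

        self._wake_heap: list[tuple[float, int]] = []
        for c in self.customers:
            heapq.heappush(self._wake_heap, (0.0, c.state.id))
        self.active: set[int] = set()

        self._draw_shifts()

    # ------------------------------------------------------------------
    # helpers
    # ------------------------------------------------------------------
    @property
    def bust_active(self) -> bool:
        for d in self.config.bust_days:
            start = d * 1440.0
            if start <= self.clock < start + self.config.bust_duration_minutes:
                return True
        return False

    def _draw_shifts(self) -> None:
        """Daily shift schedule: dealers stagger evenly around the clock (the
        open-air market operates day and night), with a common random
        rotation so shift boundaries move from day to day."""
        n = len(self.dealers)
        if n == 0:
            return
        spacing = 1440.0 / n
        offset = float(self.rng_deal.uniform(0.0, 1440.0))
        for i, d in enumerate(self.dealers):
            d.shift_start = (offset + i * spacing) % 1440.0

    def dealers_present(self) -> list[_Dealer]:
        return [d for d in self.dealers if d.on_shift]

    def collective_remaining(self) -> float:
        return max(0.0, self.units_issued_today - self.units_sold_today
                   - self.units_seized_today)

    def broker_dealer_ratio(self) -> float:
        n_b = sum(1 for b in self.brokers if not b.arrested)
        n_d = sum(1 for d in self.dealers if d.on_shift)
        return n_b / max(1, n_d)

    def _sync_concentration(self, c: _CustomerSim) -> None:
        dt = self.clock - c.conc_minute
        if dt > 0:
            c.conc_area += decay_area(c.state.concentration, dt, self.config)
            c.state.concentration *= 2.0 ** (-dt / self.config.half_life_min)
            c.conc_minute = self.clock

    def _police_positions(self) -> list[tuple[int, int]]:
        return self.police

    # ------------------------------------------------------------------
    # trip lifecycle
    # ------------------------------------------------------------------
    def _start_trip(self, c: _CustomerSim, target: int) -> None:
        W, H = self._wh
        rng = self.rng_cust
        edge = int(rng.integers(4))
        if edge == 0:
            pos = (0, int(rng.integers(H)))
        elif edge == 1:
            pos = (W - 1, int(rng.integers(H)))
        elif edge == 2:
            pos = (int(rng.integers(W)), 0)
        else:
            pos = (int(rng.integers(W)), H - 1)
        c.pos = pos
        c.phase = _SEARCH
        c.entry_abs = self.clock
        # heterogeneous patience: abandonment between 1/3 and all of max_search
        c.patience = float(rng.uniform(self.config.max_search_minutes / 3.0,
                                       self.config.max_search_minutes))
        c.target_units = target
        c.carry_units = 0.0
        c.via_broker = None
        c.invited = None
        c.trip_covariates = {
            "x_units_sold_before": self.units_sold_today,
            "x_collective_remaining": self.collective_remaining(),
            "x_broker_dealer_ratio": self.broker_dealer_ratio(),
            "x_broker_purchases_before": c.state.broker_purchase_count,
            "bust_active": int(self.bust_active),
        }
        pitches = sorted(c.state.known_street_sellers.items(),
                         key=lambda kv: _chebyshev(pos, kv[1]))
        c.pitch_queue = [pitch for _, pitch in pitches]
        self.active.add(c.state.id)

    def _finish_trip(self, c: _CustomerSim, obtained: int, arrested: int = 0) -> None:
        cov = c.trip_covariates
        duration = max(1.0, self.clock - c.entry_abs)
        rec = TripRecord(
            customer_id=c.state.id,
            day=self.day,
            entry_minute=c.entry_abs - self.day * 1440.0,
            obtained=obtained,
            duration=duration,
            arrested=arrested,
            via_broker=c.via_broker if obtained else None,
            invited=c.invited if (obtained and c.via_broker == 1) else None,
            units_sought=float(c.target_units),
            units_obtained=c.carry_units if (obtained and not arrested) else 0.0,
            x_units_sold_before=cov.get("x_units_sold_before", 0.0),
            x_collective_remaining=cov.get("x_collective_remaining", 0.0),
            x_broker_dealer_ratio=cov.get("x_broker_dealer_ratio", 0.0),
            x_broker_purchases_before=cov.get("x_broker_purchases_before", 0),
            bust_active=cov.get("bust_active", 0),
        ).validate()
        self.trips.append(rec)
        self.active.discard(c.state.id)
        c.phase = _IDLE
        units_held = c.carry_units
        if obtained and not arrested:
            c.state.inventory += units_held
        c.carry_units = 0.0
        if arrested:
            days = (self.config.arrest_base_days
                    + self.config.arrest_days_per_unit * units_held)
            c.wake_abs = self.clock + days * 1440.0
        elif obtained:
            c.wake_abs = self.clock   # consume at next wake
        else:
            c.wake_abs = self.clock + self.config.retry_rest_minutes
        heapq.heappush(self._wake_heap, (c.wake_abs, c.state.id))

    def _begin_exit(self, c: _CustomerSim) -> None:
        W, H = self._wh
        x, y = c.pos
        options = [(0, y), (W - 1, y), (x, 0), (x, H - 1)]
        c.exit_target = min(options, key=lambda t: _chebyshev(c.pos, t))
        c.phase = _EXIT

    def _direct_sale(self, c: _CustomerSim, d: _Dealer) -> bool:
        # a deal needs the dealer to cover the full amount sought; an
        # undersupplied dealer means no deal, not a partial one
        price = self.config.price_per_unit
        units = float(int(min(float(c.target_units), c.state.money // price)))
        if units < 1.0 or d.inventory < units:
            return False
        cost = units * price
        c.state.money -= cost
        d.money += cost
        self.market_money_in += cost
        d.inventory -= units
        self.units_sold_today += units
        c.carry_units = units
        c.via_broker = 0
        c.state.known_street_sellers[d.id] = d.pitch
        self._maybe_end_shift(d)
        self._begin_exit(c)
        return True

    def _engage_broker(self, c: _CustomerSim, b: _Broker) -> bool:
        price = self.config.price_per_unit
        units = min(float(c.target_units), c.state.money // price)
        units = float(int(units))
        stocked = [d for d in self.dealers_present() if d.inventory >= units]
        if units < 1.0 or not stocked:
            return False
        cost = units * price
        c.state.money -= cost
        self.market_money_in += cost
        b.carry_money = cost
        b.units_wanted = units
        b.customer_id = c.state.id
        b.phase = _B_TO_DEALER
        b.target = min(stocked, key=lambda d: _chebyshev(b.pos, d.pitch)).pitch
        c.phase = _WAIT_BROKER
        return True

    def _deliver(self, b: _Broker) -> None:
        c = self.customers[b.customer_id]
        if c.phase != _WAIT_BROKER:        # customer gave up; broker keeps everything
            self.broker_tax_units += b.carry_units
            self.seized_money += b.carry_money
        else:
            if b.carry_money > 0:          # refund for units the dealer couldn't cover
                c.state.money += b.carry_money
                self.refunds_out += b.carry_money
            if b.carry_units > 0:
                c.carry_units = b.carry_units
                c.via_broker = 1
                p_inv = min(self.config.invite_max,
                            self.config.invite_base
                            + self.config.invite_slope * c.state.broker_purchase_count)
                c.invited = int(self.rng_brok.random() < p_inv)
                c.state.broker_purchase_count += 1
                if c.invited:
                    known = c.state.known_private_dealers
                    pool = [i for i in range(self.config.n_private_dealers) if i not in known]
                    if pool:
                        known.add(pool[int(self.rng_brok.integers(len(pool)))])
                self._begin_exit(c)
            else:                          # deal fell through at the dealer end
                c.phase = _SEARCH
        b.carry_money = 0.0
        b.carry_units = 0.0
        b.customer_id = None
        b.phase = _B_ROAM
        b.target = None

    def _maybe_end_shift(self, d: _Dealer) -> None:
        if d.on_shift and d.inventory < 1.0:
            d.on_shift = False

    # ------------------------------------------------------------------
    # arrests
    # ------------------------------------------------------------------
    def _arrest_customer(self, c: _CustomerSim) -> None:
        self.seized_units += c.carry_units
        self._finish_trip(c, obtained=1, arrested=1)

    def _arrest_dealer(self, d: _Dealer) -> None:
        self.seized_units += d.inventory
        self.units_seized_today += d.inventory
        days = (self.config.arrest_base_days
                + self.config.arrest_days_per_unit * d.inventory)
        d.inventory = 0.0
        d.on_shift = False
        d.release_abs = self.clock + days * 1440.0
        self.dealer_events.append({"day": self.clock / 1440.0, "kind": "arrest",
                                   "bust_active": int(self.bust_active)})

    def _arrest_broker(self, b: _Broker) -> None:
        self.seized_units += b.carry_units
        self.seized_money += b.carry_money
        cid = b.customer_id
        days = (self.config.arrest_base_days
                + self.config.arrest_days_per_unit * b.carry_units)
        b.carry_units = 0.0
        b.carry_money = 0.0
        b.customer_id = None
        b.phase = _B_ROAM
        b.release_abs = self.clock + days * 1440.0
        if cid is not None and self.customers[cid].phase == _WAIT_BROKER:
            self.customers[cid].phase = _SEARCH   # deal failed; keep looking

    # ------------------------------------------------------------------
    # one tick
    # ------------------------------------------------------------------
    def step(self) -> "MarketState":
        cfg = self.config
        clock = self.clock
        minute_of_day = clock - self.day * 1440.0

        # --- day rollover ---------------------------------------------
        if self.day < int(clock // 1440.0):
            self._snapshot_day()
            self.day += 1
            self.units_sold_today = 0.0
            self.units_issued_today = 0.0
            self.units_seized_today = 0.0
            for c in self.customers:
                end_of_day(c.state, cfg)
                replenish_income(c.state, self.day, self.rng_cust, cfg)
            for d in self.dealers:
                d.worked_today = False   # shifts may run past midnight
            self._draw_shifts()
            minute_of_day = clock - self.day * 1440.0

        # --- dealer shift transitions and releases --------------------
        for d in self.dealers:
            if d.arrested:
                if clock >= d.release_abs:
                    d.release_abs = None
                    self.dealer_events.append({"day": clock / 1440.0, "kind": "release",
                                               "bust_active": int(self.bust_active)})
                continue
            if d.on_shift:
                if clock >= d.shift_end_abs:
                    d.on_shift = False
            elif not d.worked_today and minute_of_day >= d.shift_start:
                d.on_shift = True
                d.worked_today = True
                d.inventory = cfg.dealer_inventory_units
                d.shift_end_abs = clock + cfg.dealer_shift_minutes
                self.units_issued_today += d.inventory

        # --- broker releases ------------------------------------------
        for b in self.brokers:
            if b.arrested and clock >= b.release_abs:
                b.release_abs = None

        # --- customer wakes -------------------------------------------
        while self._wake_heap and self._wake_heap[0][0] <= clock:
            _, cid = heapq.heappop(self._wake_heap)
            c = self.customers[cid]
            if c.phase != _IDLE or c.wake_abs > clock:
                continue
            self._sync_concentration(c)
            st = c.state
            if st.concentration >= cfg.craving_threshold:
                c.wake_abs = clock + max(1.0, minutes_to_craving(st, cfg))
                heapq.heappush(self._wake_heap, (c.wake_abs, cid))
                continue
            if st.inventory > 0:
                consume(st, dose_units(st, cfg), cfg)
                c.wake_abs = clock + max(1.0, minutes_to_craving(st, cfg))
                heapq.heappush(self._wake_heap, (c.wake_abs, cid))
                continue
            wants, target = craving_trigger(st, cfg)
            if not wants:
                c.wake_abs = clock + 1440.0
                heapq.heappush(self._wake_heap, (c.wake_abs, cid))
                continue
            if st.known_private_dealers and self.rng_cust.random() < cfg.p_private_choice:
                st.money -= target * cfg.price_per_unit
                st.inventory += target
                self.private_units_today += target
                consume(st, dose_units(st, cfg), cfg)
                c.wake_abs = clock + max(1.0, minutes_to_craving(st, cfg))
                heapq.heappush(self._wake_heap, (c.wake_abs, cid))
                continue
            self._start_trip(c, target)

        # --- active customers -----------------------------------------
        dealers_on = [d for d in self.dealers if d.on_shift]
        for cid in list(self.active):
            c = self.customers[cid]
            if c.phase == _SEARCH:
                if clock - c.entry_abs >= c.patience:
                    self._finish_trip(c, obtained=0)
                    continue
                # co-location checks: dealers first, then free brokers
                sold = False
                for d in dealers_on:
                    self.interaction_ops += 1
                    if d.on_shift and _chebyshev(c.pos, d.pitch) <= 1:
                        if self._direct_sale(c, d):
                            sold = True
                            break
                if sold:
                    continue
                engaged = False
                for b in self.brokers:
                    self.interaction_ops += 1
                    if (b.phase == _B_ROAM and not b.arrested
                            and _chebyshev(c.pos, b.pos) <= 1):
                        if self._engage_broker(c, b):
                            engaged = True
                            break
                if engaged:
                    continue
                # movement: toward next known pitch, else random walk
                while c.pitch_queue and _chebyshev(c.pos, c.pitch_queue[0]) <= 1:
                    c.pitch_queue.pop(0)   # reached it and nobody was selling
                if c.pitch_queue:
                    c.pos = _step_toward(c.pos, c.pitch_queue[0])
                else:
                    W, H = self._wh
                    dx, dy = self._steps_cust.take()
                    c.pos = (min(max(c.pos[0] + dx, 0), W - 1),
                             min(max(c.pos[1] + dy, 0), H - 1))
            elif c.phase == _EXIT:
                if c.pos == c.exit_target:
                    self._finish_trip(c, obtained=1)
                else:
                    c.pos = _step_toward(c.pos, c.exit_target)
            # _WAIT_BROKER customers stand still

        # --- brokers ---------------------------------------------------
        W, H = self._wh
        for b in self.brokers:
            if b.arrested:
                continue
            if b.phase == _B_ROAM:
                dx, dy = self._steps_brok.take()
                b.pos = (min(max(b.pos[0] + dx, 0), W - 1),
                         min(max(b.pos[1] + dy, 0), H - 1))
            elif b.phase == _B_TO_DEALER:
                if _chebyshev(b.pos, b.target) <= 1:
                    self.interaction_ops += 1
                    dealer = next((d for d in self.dealers
                                   if d.on_shift and d.pitch == b.target
                                   and d.inventory >= b.units_wanted), None)
                    if dealer is None:
                        stocked = [d for d in self.dealers_present()
                                   if d.inventory >= b.units_wanted]
                        if stocked:
                            b.target = min(stocked,
                                           key=lambda d: _chebyshev(b.pos, d.pitch)).pitch
                        else:   # nothing left anywhere: walk back and refund
                            b.phase = _B_TO_CUSTOMER
                            b.target = self.customers[b.customer_id].pos
                    else:
                        price = self.config.price_per_unit
                        units = float(int(min(b.units_wanted, b.carry_money // price)))
                        cost = units * price
                        dealer.money += cost
                        dealer.inventory -= units
                        self.units_sold_today += units
                        b.carry_money -= cost
                        tax = self.config.broker_tax_fraction * units
                        self.broker_tax_units += tax
                        b.carry_units = units - tax
                        self._maybe_end_shift(dealer)
                        b.phase = _B_TO_CUSTOMER
                        b.target = self.customers[b.customer_id].pos
                else:
                    b.pos = _step_toward(b.pos, b.target)
            elif b.phase == _B_TO_CUSTOMER:
                if b.customer_id is not None:
                    b.target = self.customers[b.customer_id].pos
                if b.target is None or _chebyshev(b.pos, b.target) <= 1:
                    self.interaction_ops += 1
                    self._deliver(b)
                else:
                    b.pos = _step_toward(b.pos, b.target)

        # --- homeless noise -------------------------------------------
        if len(self.homeless):
            steps = self.rng_home.integers(-1, 2, size=self.homeless.shape)
            self.homeless += steps
            np.clip(self.homeless[:, 0], 0, W - 1, out=self.homeless[:, 0])
            np.clip(self.homeless[:, 1], 0, H - 1, out=self.homeless[:, 1])

        # --- police ----------------------------------------------------
        bust = self.bust_active
        n_police = cfg.bust_police if bust else cfg.n_police
        while len(self.police) < n_police:
            self.police.append((int(self.rng_pol.integers(W)), int(self.rng_pol.integers(H))))
        if len(self.police) > n_police:
            del self.police[n_police:]
        p_inspect = cfg.police_inspect_probability * (cfg.bust_inspect_multiplier if bust else 1.0)
        for i, ppos in enumerate(self.police):
            dx, dy = self._steps_pol.take()
            ppos = (min(max(ppos[0] + dx, 0), W - 1),
                    min(max(ppos[1] + dy, 0), H - 1))
            self.police[i] = ppos
            if p_inspect <= 0 or self.rng_pol.random() >= p_inspect:
                continue
            self.interaction_ops += 1
            neighbours: list[tuple[str, object]] = []
            for cid in self.active:
                c = self.customers[cid]
                if _chebyshev(c.pos, ppos) <= 1:
                    neighbours.append(("customer", c))
            for d in self.dealers:
                if d.on_shift and _chebyshev(d.pitch, ppos) <= 1:
                    neighbours.append(("dealer", d))
            for b in self.brokers:
                if not b.arrested and _chebyshev(b.pos, ppos) <= 1:
                    neighbours.append(("broker", b))
            if len(self.homeless):
                near = (np.abs(self.homeless[:, 0] - ppos[0]) <= 1) & \
                       (np.abs(self.homeless[:, 1] - ppos[1]) <= 1)
                for _ in range(int(near.sum())):
                    neighbours.append(("homeless", None))
            if not neighbours:
                continue
            kind, agent = neighbours[int(self.rng_pol.integers(len(neighbours)))]
            if kind == "customer" and agent.carry_units > 0:
                self._arrest_customer(agent)
            elif kind == "dealer":
                self._arrest_dealer(agent)
            elif kind == "broker" and agent.carry_units > 0:
                self._arrest_broker(agent)

        # --- clock -----------------------------------------------------
        self.tick_count += 1
        self.clock = self.tick_count * cfg.tick_minutes
        return self

    # ------------------------------------------------------------------
    def run(self) -> tuple[pd.DataFrame, list[TripRecord]]:
        horizon_ticks = int(round(self.config.days * 1440.0 / self.config.tick_minutes))
        while self.tick_count < horizon_ticks:
            self.step()
        # final day snapshot
        self.clock = self.config.days * 1440.0
        self.step_day_snapshot_only()
        daily = pd.DataFrame(self.daily_rows,
                             columns=["day", "mean_money", "mean_inventory",
                                      "mean_addiction", "mean_concentration",
                                      "private_units", "units_consumed"])
        daily = daily.iloc[:self.config.days].reset_index(drop=True)
        return daily, self.trips

    def _snapshot_day(self) -> None:
        """Record the day's aggregates: money/inventory/addiction at day end,
        concentration as its time average over the day."""
        for c in self.customers:
            self._sync_concentration(c)
        cs = self.customers
        nan = float("nan")
        self.daily_rows.append({
            "day": self.day,
            "mean_money": float(np.mean([c.state.money for c in cs])) if cs else nan,
            "mean_inventory": float(np.mean([c.state.inventory for c in cs])) if cs else nan,
            "mean_addiction": float(np.mean([c.state.addiction for c in cs])) if cs else nan,
            "mean_concentration": float(np.mean([c.conc_area / 1440.0 for c in cs])) if cs else nan,
            "private_units": self.private_units_today,
            "units_consumed": float(np.sum([c.state.consumed_today for c in cs])) if cs else 0.0,
        })
        self.private_units_today = 0.0
        for c in cs:
            c.conc_area = 0.0

    def step_day_snapshot_only(self) -> None:
        while self.day < self.config.days:
            self._snapshot_day()
            self.day += 1


def init_market(config: SimConfig, seed: int) -> MarketState:
    """Deterministically initialize a market from (config, seed)."""
    return MarketState(config, seed)


def step_market(state: MarketState) -> MarketState:
    """Advance the market by one tick (see module docstring for the order of
    sub-steps)."""
    return state.step()


def run_full_simulation(config: SimConfig, seed: int) -> tuple[pd.DataFrame, list[TripRecord]]:
    """Run ``config.days`` days of the full agent-based market.

    Returns the daily aggregate trajectory and the trip log; bitwise
    reproducible for a given (config, seed).
    """
    return init_market(config, seed).run()


def bust_exposure_days(config: SimConfig) -> tuple[float, float]:
    """(bust, non-bust) exposure time in days for rate estimation."""
    bust = len(config.bust_days) * config.bust_duration_minutes / 1440.0
    return bust, config.days - bust
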