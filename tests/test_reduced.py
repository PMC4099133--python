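import numpy as np
import pytest
from hypothesis import given, strategies as st

import heroinmarket as hm
from heroinmarket.customers import init_customer
from heroinmarket.emulator import (DealerLedgerRates, EmulatorSpec,
                                   FittedDistribution, LogisticModel,
                                   OutcomeModel, reference_emulator)
from heroinmarket.reduced import (DealerLedger, draw_market_trip,
                                  eval_p_invite, eval_p_obtain,
                                  update_dealer_ledger)
from heroinmarket.errors import DomainError


def _ledger(**kw):
    base = dict(n_total=20, n_in_market=20, n_arrested=0,
                units_sold_today=0.0, collective_remaining=9000.0,
                n_brokers=25)
    base.update(kw)
    return DealerLedger(**base)


def _point_mass_emulator(p_obtain, p_arrest, p_broker, p_invite):
    """Emulator whose Bernoulli stages are (numerically) deterministic."""
    def logit(p):
        eps = 1e-12
        p = min(max(p, eps), 1 - eps)
        return float(np.log(p / (1 - p)))

    def reg(p, cov):
        return OutcomeModel("regression", None, LogisticModel(logit(p), 0.0, cov))

    gamma = OutcomeModel("distribution", FittedDistribution("gamma", 4.0, 0.05))
    return EmulatorSpec(regimes={"normal": {
        "obtain": reg(p_obtain, "units_sold_today"),
        "time_success": gamma,
        "time_failure": gamma,
        "arrest": reg(p_arrest, "none"),
        "broker": reg(p_broker, "none"),
        "invite": reg(p_invite, "broker_purchase_count"),
    }})


class TestHierarchyPrimitives:
    def test_obtain_at_zero_sales(self):
        model = reference_emulator().model("obtain").regression
        assert eval_p_obtain(0.0, model) == pytest.approx(1 / (1 + np.exp(-10.19)), rel=1e-6)
        assert eval_p_obtain(0.0, model) == pytest.approx(0.99996, abs=5e-6)

    def test_obtain_at_heavy_sales(self):
        model = reference_emulator().model("obtain").regression
        assert eval_p_obtain(5000.0, model) == pytest.approx(0.9883, abs=2e-4)

    def test_obtain_decreasing_in_units_sold(self):
        model = reference_emulator().model("obtain").regression
        xs = np.linspace(0, 20000, 50)
        ps = [eval_p_obtain(x, model) for x in xs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_obtain_rejects_negative_sales(self):
        model = reference_emulator().model("obtain").regression
        with pytest.raises(DomainError):
            eval_p_obtain(-1.0, model)

    def test_invite_closed_form(self):
        model = reference_emulator().model("invite").regression
        assert eval_p_invite(0, model) == pytest.approx(0.01668, abs=2e-5)
        assert eval_p_invite(1000, model) == pytest.approx(0.0651, abs=2e-4)

    def test_invite_nondecreasing(self):
        model = reference_emulator().model("invite").regression
        ps = [eval_p_invite(k, model) for k in range(0, 5000, 100)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))


class TestDrawMarketTrip:
    def _customer(self):
        return init_customer(0, np.random.default_rng(0), hm.SimConfig())

    def test_certain_failure_path(self):
        rec = draw_market_trip(self._customer(), _ledger(),
                               _point_mass_emulator(0, 1, 1, 1), "normal",
                               np.random.default_rng(1), hm.SimConfig(),
                               day=0, entry_minute=0.0, units_sought=5)
        assert rec.obtained == 0
        assert rec.arrested == 0          # no success, no arrest possible
        assert rec.via_broker is None and rec.invited is None

    def test_forced_broker_invitation_path(self):
        rec = draw_market_trip(self._customer(), _ledger(),
                               _point_mass_emulator(1, 0, 1, 1), "normal",
                               np.random.default_rng(1), hm.SimConfig(),
                               day=0, entry_minute=0.0, units_sought=5)
        assert (rec.obtained, rec.arrested, rec.via_broker, rec.invited) == (1, 0, 1, 1)

    def test_deterministic_given_seed(self):
        emu = reference_emulator("distribution")
        recs = []
        for _ in range(2):
            recs.append(draw_market_trip(self._customer(), _ledger(), emu,
                                         "normal", np.random.default_rng(9),
                                         hm.SimConfig(), day=3,
                                         entry_minute=100.0, units_sought=4))
        assert recs[0].to_dict() == recs[1].to_dict()

    def test_covariates_captured_at_entry(self):
        led = _ledger(units_sold_today=1234.0, collective_remaining=777.0)
        rec = draw_market_trip(self._customer(), led,
                               _point_mass_emulator(1, 0, 0, 0), "normal",
                               np.random.default_rng(1), hm.SimConfig(),
                               day=0, entry_minute=0.0, units_sought=5)
        assert rec.x_units_sold_before == 1234.0
        assert rec.x_collective_remaining == 777.0


class TestDealerLedgerUpdates:
    RATES = DealerLedgerRates(arrest_rate_normal=0.5, arrest_rate_bust=2.0,
                              release_rate=0.25)

    def test_zero_rates_noop(self):
        led = _ledger()
        update_dealer_ledger(led, "normal", 1.0,
                             DealerLedgerRates(0.0, 0.0, 0.0),
                             np.random.default_rng(0))
        assert led.n_in_market == 20 and led.n_arrested == 0

    def test_empty_market_cannot_lose_dealers(self):
        led = _ledger(n_in_market=0, n_arrested=20)
        update_dealer_ledger(led, "bust", 5.0, self.RATES,
                             np.random.default_rng(0))
        assert led.n_in_market + led.n_arrested == 20
        assert led.n_in_market >= 0

    def test_poisson_mean_arrests(self):
        rng = np.random.default_rng(7)
        rates = DealerLedgerRates(2.0, 0.0, 0.0)
        draws = []
        for _ in range(10_000):
            led = _ledger(n_total=1000, n_in_market=1000)
            update_dealer_ledger(led, "normal", 1.0, rates, rng)
            draws.append(led.n_arrested)
        se = np.sqrt(2.0 / len(draws))
        assert np.mean(draws) == pytest.approx(2.0, abs=3 * se)

    @given(st.lists(st.tuples(st.sampled_from(["normal", "bust"]),
                              st.floats(0.1, 5.0)), max_size=30))
    def test_conservation_under_event_sequences(self, steps):
        led = _ledger(n_total=10, n_in_market=10)
        rng = np.random.default_rng(3)
        for regime, dt in steps:
            update_dealer_ledger(led, regime, dt, self.RATES, rng)
            assert led.n_in_market + led.n_arrested == 10
            assert led.n_in_market >= 0 and led.n_arrested >= 0


class TestReducedSimulation:
    def test_zero_customers_empty_outputs(self):
        cfg = hm.demo_config(n_customers=0, days=4)
        daily, trips = hm.run_reduced_simulation(cfg, reference_emulator(), 0)
        assert trips == []
        assert len(daily) == 4

    def test_same_seed_identical_trip_log(self):
        cfg = hm.demo_config(days=6)
        emu = reference_emulator("distribution")
        a = hm.run_reduced_simulation(cfg, emu, 5)
        b = hm.run_reduced_simulation(cfg, emu, 5)
        assert a[0].equals(b[0])
        assert [r.to_dict() for r in a[1]] == [r.to_dict() for r in b[1]]

    def test_hierarchy_conditioning_holds_in_output(self):
        cfg = hm.demo_config(days=20)
        _, trips = hm.run_reduced_simulation(cfg, reference_emulator("distribution"), 2)
        assert trips
        for r in trips:
            r.validate()
            if r.obtained == 0:
                assert r.arrested == 0 and r.via_broker is None

    def test_bust_windows_switch_regime(self):
        cfg = hm.demo_config(days=10, bust_days=(3, 7))
        base = reference_emulator("distribution")
        bust_models = dict(base.regimes["normal"])
        spec = EmulatorSpec(
            regimes={"normal": base.regimes["normal"], "bust": bust_models},
            dealer_ledger_rates=DealerLedgerRates(0.0, 2.0, 0.2),
        )
        _, trips = hm.run_reduced_simulation(cfg, spec, 4)
        bust_days = {r.day for r in trips if r.bust_active == 1}
        clean_days = {r.day for r in trips if r.bust_active == 0}
        assert bust_days <= {3, 7}
        assert not clean_days & {3, 7}

    def test_forced_success_increments_broker_count_and_private_contacts(self):
        cfg = hm.demo_config(days=4, p_private_choice=0.0)
        emu = _point_mass_emulator(1, 0, 1, 1)
        _, trips = hm.run_reduced_simulation(cfg, emu, 1)
        assert trips
        by_cust = {}
        for r in trips:
            assert r.via_broker == 1 and r.invited == 1
            assert r.x_broker_purchases_before == by_cust.get(r.customer_id, 0)
            by_cust[r.customer_id] = by_cust.get(r.customer_id, 0) + 1

    def test_sampler_means_converge_to_model_means(self):
        """Monte-Carlo means of the drawn hierarchy outcomes approach the
        fitted-model means (law of large numbers)."""
        emu = reference_emulator("distribution")
        cfg = hm.SimConfig()
        cust = init_customer(0, np.random.default_rng(0), cfg)
        led = _ledger()
        rng = np.random.default_rng(123)
        n = 40_000
        recs = [draw_market_trip(cust, led, emu, "normal", rng, cfg,
                                 day=0, entry_minute=0.0, units_sought=3)
                for _ in range(n)]
        s = hm.empirical_summaries(recs)
        checks = {
            "p_obtain": (s.p_obtain, 0.835 / (0.835 + 0.718)),
            "p_broker": (s.p_broker, 0.61 / (0.61 + 0.76)),
            "p_invite": (s.p_invite, 0.55 / (0.55 + 7.45)),
            "t_mean_failure": (s.t_mean_failure, 9.11 / 0.072),
        }
        n_succ = s.p_obtain * n
        tol = {
            "p_obtain": 4 * np.sqrt(0.25 / n),
            "p_broker": 4 * np.sqrt(0.25 / n_succ),
            "p_invite": 4 * np.sqrt(0.07 * 0.93 / (n_succ * s.p_broker)),
            "t_mean_failure": 4 * (np.sqrt(9.11) / 0.072) / np.sqrt(n * (1 - s.p_obtain)),
        }
        for key, (got, want) in checks.items():
            assert got == pytest.approx(want, abs=tol[key]), key
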