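import json

import numpy as np
import pandas as pd
import pytest

import heroinmarket as hm
from heroinmarket.emulator import (AlwaysAdequate, EmulatorSpec,
                                   FittedDistribution, LogisticModel,
                                   beta_method_of_moments, fit_beta,
                                   fit_gamma, fit_logistic,
                                   fit_mixed_logistic,
                                   gamma_method_of_moments,
                                   estimate_dealer_rates, reference_emulator)
from heroinmarket.errors import DegenerateDataError, DomainError


class TestMethodOfMoments:
    def test_beta_closed_form(self):
        a, b = beta_method_of_moments(np.array([0.2, 0.4, 0.6]))
        assert a == pytest.approx(2.0)
        assert b == pytest.approx(3.0)

    def test_gamma_closed_form(self):
        k, r = gamma_method_of_moments(np.array([1.0, 2.0, 3.0]))
        assert k == pytest.approx(4.0)
        assert r == pytest.approx(2.0)


class TestFitErrors:
    def test_beta_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_beta([0.5, 0.5, 0.5])

    def test_beta_needs_three_values(self):
        with pytest.raises(DomainError):
            fit_beta([0.2, 0.4])

    def test_beta_range_checked(self):
        with pytest.raises(DomainError):
            fit_beta([0.2, 0.5, 1.4])

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            fit_gamma([1.0, -2.0, 3.0])

    def test_gamma_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_gamma([2.0, 2.0, 2.0])

    def test_logistic_single_class(self):
        x = np.arange(20.0)
        y = np.ones(20)
        with pytest.raises(DomainError):
            fit_logistic(np.column_stack([x, y]), "x")

    def test_logistic_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        with pytest.warns(UserWarning):
            model = fit_logistic(np.column_stack([x, y]), "x")
        assert model.flags

    def test_mixed_few_groups_falls_back(self):
        rng = np.random.default_rng(0)
        g = np.zeros(200)
        x = rng.uniform(0, 10, 200)
        y = (rng.random(200) < 0.5).astype(float)
        with pytest.warns(UserWarning):
            model = fit_mixed_logistic(np.column_stack([g, x, y]), "x")
        assert "too_few_groups:plain_logistic_fallback" in model.flags
        assert model.random_effect_variance == 0.0


class TestDistributionContainers:
    def test_invalid_family_rejected(self):
        with pytest.raises(DomainError):
            FittedDistribution("lognormal", 1.0, 1.0)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(DomainError):
            FittedDistribution("beta", -1.0, 2.0)

    def test_gamma_shape_rate_mean(self):
        assert FittedDistribution("gamma", 9.11, 0.072).mean == pytest.approx(126.53, abs=0.01)

    def test_negative_random_effect_variance_rejected(self):
        with pytest.raises(DomainError):
            LogisticModel(0.0, 0.0, "x", random_effect_variance=-1.0)


@pytest.mark.parametrize("family,p1,p2", [("beta", 0.835, 0.718),
                                          ("gamma", 2.9, 0.035)])
def test_sample_refit_round_trip(family, p1, p2):
    """Parameters are recovered from a moderate sample of the fitted
    distribution (Monte-Carlo tolerance ~ 1/sqrt(n))."""
    rng = np.random.default_rng(11)
    dist = FittedDistribution(family, p1, p2)
    draws = dist.sample(rng, size=30_000)
    refit = fit_beta(draws) if family == "beta" else fit_gamma(draws)
    assert refit.param1 == pytest.approx(p1, rel=0.05)
    assert refit.param2 == pytest.approx(p2, rel=0.05)


class TestEmulatorSpec:
    def test_reference_regression_selection(self):
        spec = reference_emulator()
        assert spec.model("obtain").form == "regression"
        assert spec.model("invite").form == "regression"
        for name in ("time_success", "time_failure", "arrest", "broker"):
            assert spec.model(name).form == "distribution"

    def test_reference_distribution_variant(self):
        spec = reference_emulator("distribution")
        assert all(spec.model(n).form == "distribution"
                   for n in ("obtain", "invite", "arrest", "broker"))

    def test_reference_regression_parameters(self):
        spec = reference_emulator()
        obtain = spec.model("obtain").regression
        assert (obtain.beta0, obtain.beta1) == (10.19, -0.00115)
        assert obtain.random_effect_variance == 0.68
        invite = spec.model("invite").regression
        assert (invite.beta0, invite.beta1) == (-4.0763, 0.00141)

    def test_json_round_trip(self, tmp_path):
        spec = reference_emulator()
        path = tmp_path / "emulator.json"
        spec.save(path)
        back = EmulatorSpec.load(path)
        assert back.to_dict() == spec.to_dict()

    def test_missing_regime_raises(self):
        spec = reference_emulator()
        from heroinmarket.errors import ConfigError
        with pytest.raises(ConfigError):
            spec.model("obtain", "bust")


class TestDealerRates:
    def test_rate_is_count_over_exposure(self):
        ev = pd.DataFrame([{"day": 120.1, "kind": "arrest", "bust_active": 1}
                           for _ in range(4)])
        rates = estimate_dealer_rates(ev, bust_exposure_days=2.0,
                                      nonbust_exposure_days=100.0)
        assert rates.arrest_rate_bust == pytest.approx(2.0)
        assert rates.arrest_rate_normal == 0.0

    def test_zero_releases_warns(self):
        ev = pd.DataFrame([{"day": 1.0, "kind": "arrest", "bust_active": 0}])
        with pytest.warns(UserWarning):
            rates = estimate_dealer_rates(ev, 1.0, 10.0)
        assert rates.release_rate == 0.0


def test_build_emulator_policy_short_circuit(small_market):
    """An always-passing policy keeps the simpler distribution form for all
    five outcomes."""
    cfg, market, daily, trips = small_market
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = hm.build_emulator(trips, [daily], cfg, AlwaysAdequate(),
                                 n_replicates=0, seed=0)
    assert spec.fit_report["adequate"]
    assert all(form == "distribution"
               for form in spec.fit_report["selection"].values())


def test_fit_bust_emulator_requires_bust_trips(small_market):
    cfg, market, daily, trips = small_market
    ev = pd.DataFrame(columns=["day", "kind", "bust_active"])
    base = reference_emulator()
    with pytest.raises(DomainError):
        hm.fit_bust_emulator([], ev, 1.0, 10.0, base)
    with pytest.raises(DomainError):
        hm.fit_bust_emulator(trips[:5], ev, 1.0, 10.0, base)  # not bust-flagged
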