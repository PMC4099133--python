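import warnings

import pytest
from hypothesis import settings

import heroinmarket as hm
from heroinmarket.fullmodel import init_market

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_market():
    """One short full-model run (20 customers, 20 days) with access to the
    final MarketState for accounting invariants."""
    cfg = hm.demo_config(days=20)
    market = init_market(cfg, seed=5)
    daily, trips = market.run()
    return cfg, market, daily, trips


@pytest.fixture(scope="session")
def demo_ensemble():
    """The scaled-down comparison ensemble: 20 replicates of 120 days of the
    full model (the problem size used for the end-to-end certification)."""
    cfg = hm.demo_config(days=120)
    seeds = list(range(100, 120))
    daily, trips_by_run = [], []
    for s in seeds:
        d, t = hm.run_full_simulation(cfg, s)
        daily.append(d)
        trips_by_run.append(t)
    return cfg, seeds, daily, trips_by_run


@pytest.fixture(scope="session")
def demo_emulators(demo_ensemble):
    """Distribution-based and regression-based emulators fitted from the
    ensemble, with the policy evaluated on paired populations."""
    cfg, seeds, full_daily, trips_by_run = demo_ensemble
    all_trips = [r for t in trips_by_run for r in t]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        escalated = hm.build_emulator(all_trips, full_daily, cfg, seed=0,
                                      steady_start=40, seeds=seeds)
        regression = hm.build_emulator(all_trips, full_daily, cfg, seed=0,
                                       steady_start=40, seeds=seeds,
                                       force_regressions=("obtain", "invite"))
    return escalated, regression
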