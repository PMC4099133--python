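"""Police busts: refit the emulator for intervention periods.

Busts put a larger police detail in the market for 24 hours; street dealers
are arrested in numbers and return on average ~20 days later.  The
bust-period refit replaces the obtain covariate with the dealers' collective
remaining stock, models the broker probability on the brokers-to-dealers
ratio, and estimates the dealer arrest/release rates that drive the reduced
model's dealer ledger.
"""

import warnings

import pandas as pd

import heroinmarket as hm
from heroinmarket.fullmodel import bust_exposure_days, init_market

config = hm.demo_config(days=90, bust_days=(30, 50, 70))
seeds = range(4)
full_daily, all_trips, events = [], [], []
for s in seeds:
    market = init_market(config, s)
    daily, trips = market.run()
    full_daily.append(daily)
    all_trips.extend(trips)
    events.extend(market.dealer_events)

events = pd.DataFrame(events)
bust_trips = [r for r in all_trips if r.bust_active == 1]
print(f"{len(all_trips)} trips, {len(bust_trips)} during busts; "
      f"{int((events.kind == 'arrest').sum())} dealer arrests logged")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    base = hm.build_emulator(all_trips, full_daily, config, hm.AlwaysAdequate(),
                             n_replicates=0, seed=0, steady_start=20)
    be, ne = bust_exposure_days(config)
    spec = hm.fit_bust_emulator(bust_trips, events,
                                bust_exposure_days=be * len(list(seeds)),
                                nonbust_exposure_days=ne * len(list(seeds)),
                                base=base)

r = spec.dealer_ledger_rates
print(f"dealer arrest rate:  {r.arrest_rate_normal:.3f}/day normally, "
      f"{r.arrest_rate_bust:.2f}/day during busts")
print(f"dealer release rate: {r.release_rate:.3f}/day")
obtain = spec.regimes["bust"]["obtain"].regression
print(f"bust obtain model: logit p = {obtain.beta0:.3f} "
      f"{obtain.beta1:+.5f} x (collective remaining stock)")

daily, trips = hm.run_reduced_simulation(config, spec, seed=99)
in_bust = [t for t in trips if t.bust_active == 1]
print(f"\nreduced run with busts: {len(trips)} trips, {len(in_bust)} resolved "
      "under the bust-period models")
print("(the positive stock coefficient means scarcer dealers -> fewer successes)")
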