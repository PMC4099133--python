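"""Run a scaled-down full agent-based market and summarize the five trip
outcomes.

The market has 20 customers, 6 street dealers on staggered shifts, 3 street
brokers, 3 private dealers, 10 homeless and 1 police officer on a 15x15
grid.  Every public-market trip is logged; the summary reports the share of
trips that obtained heroin, the arrest/broker/invitation rates, and mean
trip durations in minutes.
"""

import heroinmarket as hm

config = hm.demo_config(days=60)
daily, trips = hm.run_full_simulation(config, seed=1)

steady = hm.steady_state_window(trips, start_day=20)
summary = hm.empirical_summaries(steady)
print(f"{len(trips)} market trips over {config.days} days "
      f"({len(steady)} in the steady-state window)")
for key, value in summary.to_dict().items():
    if value is not None:
        print(f"  {key:>16}: {value:.4f}" if isinstance(value, float)
              else f"  {key:>16}: {value}")
print("\np_obtain is the per-trip success probability; t_mean_failure is the")
print("average time (minutes) a customer searches before giving up.")
print("\nlast week of daily aggregates (means over customers):")
print(daily.tail(7).to_string(index=False))
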