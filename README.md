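# heroinmarket

Agent-based simulation of a local open-air heroin market, and the
statistical machinery to *reduce* it: replace the expensive in-market agent
interactions with fitted emulators — Beta/Gamma distributions and
(mixed-effects) logistic regressions arranged in a conditional decision
hierarchy — and verify that the reduced model is statistically equivalent
to the full one.

The package is aimed at simulation methodologists and drug-policy modellers
who need a worked, testable implementation of ABM surrogate reduction: a
full market model (customers, street dealers, street brokers, private
dealers, police, homeless on a grid), a reduced model driven by five
per-trip outcome models, an escalation workflow that decides distribution
vs. regression per outcome, an equivalence-testing protocol, and a
police-bust intervention extension.

## The model in brief

A market trip by customer *j* resolves through five conditional stages:

1. obtain: π_o ~ Bernoulli(p_o), with either p_o ~ Beta(α, β) or
   logit p_o = β₀ + β₁·x + γ_j, where x is the units already sold by street
   dealers that day and γ_j ~ N(0, σ²) is a customer-level random
   intercept;
2. time in market: t ~ Gamma(k, r), success- or failure-conditional;
3. arrest (only if π_o = 1): Bernoulli with p_a ~ Beta;
4. broker vs. dealer purchase (only if π_o = 1): Bernoulli with p_sb ~ Beta;
5. private-dealer invitation (only if brokered): Bernoulli with
   logit p_i = β₀ + β₁·k, k the customer's prior brokered purchases.

Customers keep their full pharmacodynamics (exponential concentration
decay, addiction as an EWMA of consumption) and income dynamics in both
simulators. Equivalence between full and reduced models is judged on four
daily aggregates — mean customer money, drug inventory, addiction level and
drug concentration — via per-day TOST equivalence tests at a 0.1-SD margin
with Benjamini–Hochberg correction, plus one two-sample Kolmogorov–Smirnov
test per statistic on the day-indexed ensemble-mean trajectories.

The packaged reference emulator carries the published fitted parameters for
a Denver open-air market: Beta(0.835, 0.718) for obtaining, Gamma(2.9,
0.035) and Gamma(9.11, 0.072) for success/failure durations, Beta(0.43,
1500) for arrest, Beta(0.61, 0.76) for broker purchases, Beta(0.55, 7.45)
for invitations, and the two regressions
`logit p_o = 10.19 − 0.00115·x + γ_j` (var γ = 0.68) and
`logit p_i = −4.0763 + 0.00141·k`.

## Worked example

```python
import heroinmarket as hm

config = hm.SimConfig(days=365).validate()          # 200 customers, 1 year
emulator = hm.reference_emulator(form="distribution")
daily, trips = hm.run_reduced_simulation(config, emulator, seed=1)

steady = hm.steady_state_window(trips, start_day=180)
print(hm.empirical_summaries(steady).to_dict())
```

prints (seed 1; about a second of compute)

```
{'p_obtain': 0.5301, 'p_arrest': 0.00017, 'p_broker': 0.4507,
 'p_invite': 0.0668, 't_mean': 103.37, 't_mean_success': 82.61,
 't_mean_failure': 126.79, 'n_trips': 22864}
```

The steady-state (days 180–365) per-trip averages reproduce the reference
model means — success probability 0.538, arrest 0.00029, broker share
0.445, invitation 0.069, failed-trip duration 126.5 min — to within
Monte-Carlo error, which is exactly what the decision hierarchy is supposed
to guarantee. The `examples/` directory has one narrative script per
capability: the full agent-based market, fitting an emulator from scratch
with escalation, equivalence testing, the time-step sensitivity sweep, and
the police-bust extension. A thin CLI mirrors the pipeline:

```bash
heroinmarket simulate-full   --config market.yaml --seed 1 --out runs/full_1
heroinmarket fit-emulator    --trips runs/full_1/trips.jsonl \
                             --full-daily runs/full_1/daily.csv --out emulator.json
heroinmarket simulate-reduced --config market.yaml --emulator emulator.json \
                             --seed 1 --out runs/reduced_1
heroinmarket compare --full runs/full_* --reduced runs/reduced_* --out report/
```

## Layout

- `src/heroinmarket/customers.py` — shared customer pharmacology/income core
- `src/heroinmarket/fullmodel.py` — the full agent-based market
- `src/heroinmarket/trips.py` — trip records and outcome summaries
- `src/heroinmarket/emulator.py` — distribution/regression fitting, escalation,
  bust refits, the packaged reference emulator
- `src/heroinmarket/reduced.py` — the decision hierarchy and reduced simulator
- `src/heroinmarket/compare.py` — TOST, BH/Holm, KS, trajectory comparison,
  time-step sweep
- `src/heroinmarket/config.py`, `io.py`, `cli.py` — configuration, plain-text
  I/O, command line
- `docs/methods.md` — models, default study conditions, numerical choices,
  limitations
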