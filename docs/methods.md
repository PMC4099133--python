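# Methods

`heroinmarket` implements two coupled simulators of a local open-air heroin
market — a full agent-based model and a statistically reduced one — together
with the machinery to fit the reduction from full-model output and to test
that the two are equivalent. This note documents the models, the default
study conditions and why they were chosen, the numerical choices, and the
limits of what the test suite demonstrates.

## The full agent-based market

Six agent types interact on a `W x H` grid with a discrete clock
(`tick_seconds`, default one minute):

* **Customers** carry a body drug concentration that decays exponentially
  (half-life `half_life_min`, default 4 h) and rises by `potency x units` on
  each dose. A craving fires when concentration drops below
  `craving_threshold`; the customer doses from inventory if a dose is
  available, otherwise travels to buy the smallest whole number of units
  covering the day's unmet need, capped by cash on hand. Addiction level —
  the target daily consumption — is a daily exponentially-weighted moving
  average of realized consumption (weight `addiction_rate`), floored at a
  baseline habit (`addiction_floor_fraction` of the initial level). Income
  arrives weekly/biweekly/monthly with occasional bonuses; a share of cash
  on hand (`living_expense_fraction`/day) goes to non-drug living costs.
* **Street dealers** sell at a fixed price from a fixed pitch, one shift per
  day (`dealer_shift_minutes`) with a fresh inventory per shift, leaving
  when sold out or when the shift ends, whichever comes first. Shifts
  stagger evenly around the clock with a daily random rotation — the market
  operates day and night. A deal requires the dealer to cover the full
  amount sought; an undersupplied dealer means a failed deal, not a partial
  one.
* **Street brokers** ferry a customer's money to a stocked dealer and the
  heroin back, keeping `broker_tax_fraction` of the units as tax. Brokers
  are the only path to a **private dealer** introduction: on delivery, the
  customer is invited with probability
  `invite_base + invite_slope x (prior brokered purchases)` (capped at
  `invite_max`). A customer who knows a private dealer buys off-market with
  probability `p_private_choice` per craving episode.
* **Police** random-walk and, with probability
  `police_inspect_probability` per tick, inspect one random co-located
  agent; anyone holding heroin is arrested for
  `arrest_base_days + arrest_days_per_unit x units` days. During a **bust**
  (`bust_days`), `bust_police` officers operate for 24 h with the
  inspection intensity multiplied by `bust_inspect_multiplier`.
* **Homeless** agents hold nothing and matter only by diluting police
  inspections.

Movement is one cell per tick with Moore-neighbourhood co-location, and
inspection is a per-tick event. Both are deliberately naive: the drift of
the outcome summaries as the tick departs from one minute (the
`timestep_sweep`) is part of what the package measures.

Every public-market trip emits a `TripRecord` with the five outcomes
(obtained, duration, arrested, via-broker, invited) and the regression
covariates captured at market entry. Per day, four customer aggregates are
recorded: mean money, mean drug inventory, mean addiction level and mean
drug concentration. Concentration is reported as its *time average* over
the day (the integral of the decay curve divided by 1440 min) rather than a
midnight point sample; a point sample would measure mostly the clock time
of the last dose, which no time-homogeneous emulator can reproduce, whereas
the time average depends on what was consumed.

## The reduced model

Customers keep the identical pharmacology, income and private-dealer code
paths. A public-market trip is resolved by a conditional decision
hierarchy of draws from a fitted emulator:

1. obtain probability `p_o` → Bernoulli success flag;
2. trip duration from the success- or failure-conditional model;
3. arrest probability `p_a` → Bernoulli, *only if successful* (a customer
   who obtained nothing cannot be arrested);
4. broker probability `p_sb` → Bernoulli, only if successful;
5. invite probability `p_i` → Bernoulli, only if brokered.

Each outcome model is either a distribution (Beta for probabilities, Gamma
for durations) sampled per trip, or a regression: a mixed-effects logistic
for `p_o` on the units sold by street dealers that day before the attempt
(each customer contributing a Gaussian random intercept, drawn once at
initialization from the fitted variance), and a logistic for `p_i` on the
customer's count of prior brokered purchases. During busts the obtain
covariate becomes the dealers' collective remaining stock, and the broker
probability becomes a logistic on the brokers-to-dealers ratio.

Street dealers survive only as a ledger: counts in market vs. arrested
(updated daily by Poisson draws from fitted arrest/release rates, capped so
`in_market + arrested = total`), plus the units-sold and remaining-stock
covariates (reset and re-issued daily). The ledger is covariate
bookkeeping only; it does not gate trip success — market capacity is
already encoded in the fitted outcome models. A successful trip delivers
the full amount sought (brokered deliveries less the tax), mirroring the
full model's no-partial-deal rule. A drawn duration occupies the customer;
failed trips are followed by the same `retry_rest_minutes` pause as in the
full model. Arrested customers are removed under the same duration rule.

The reduced simulator is event-driven with event times quantized to whole
simulated minutes: concentration decay is exponential, so the next craving
time has a closed form and idle minutes need not be ticked. Output is
identical to a one-minute tick loop at a small fraction of the cost, and
the structural test asserts the reduced model performs far fewer
interaction computations than the full model at the same configuration.

## Fitting the emulator

Distributions are fitted to the *hourly-interval outcome rates*: each trip
is binned by the hour in which it completes, the per-bin rate is the share
of eligible trips with outcome one (eligibility follows the hierarchy's
conditioning), and a Beta is fitted to the rates by maximum likelihood,
weighted by the number of trips behind each rate. Exact 0/1 rates are
clamped to `[1/(2N), 1 - 1/(2N)]` first. The fitted shape is then
recalibrated so the Beta mean equals the eligible-trip-weighted rate:
downstream the draw feeds a Bernoulli trial, so an unbiased mean matters
more than an exactly-ML shape (an unweighted fit over-weights sparse night
hours and biases the sampler by a few percent). Durations get unweighted
Gamma MLEs in the shape/rate parameterization. Method-of-moments estimates
initialize each MLE and serve as fallback on non-convergence; an outcome
whose rates are degenerate (e.g. no arrests observed) falls back to a
high-concentration Beta at the clamped mean and is flagged in the fit
report.

The plain logistic uses statsmodels' ML fit, with complete separation
flagged and resolved by a weakly penalized fit. The random-intercept
logistic is fitted by direct maximum likelihood with 25-node Gauss–Hermite
quadrature over the group effect (statsmodels offers no frequentist
random-intercept logistic); fewer than 20 groups falls back to the plain
logistic with a warning. Recovery tests generate data at the reference
coefficients and require all three parameters back within 15%.

`build_emulator` starts with distributions for all five outcomes and
escalates to regressions — first the obtain probability, then the invite
probability, the two outcomes whose distribution form misrepresents
success/failure *patterns* even when the average rate is right — until an
adequacy policy passes. The default policy requires, for each of the four
daily aggregates over the steady-state window, (a) a non-rejecting
two-sample KS test on the ensemble daily-mean trajectories at α = 0.05 and
(b) a systematic deviation of the window means below 5%. The policy object
is pluggable. Every candidate's diagnostics are recorded in the fit
report.

**Paired comparison.** Customer populations are initialized from
per-customer random streams keyed by `(seed, customer id)`, so a full and a
reduced run sharing a seed simulate the same population (addictions, income
schedules, habit floors). The adequacy check and the certification tests
exploit this by running the reduced replicates on the full replicates'
seeds: at a steady state largely set by who the customers are, an unpaired
design mostly measures initialization luck, which no number of replicates
removes from a day-indexed KS comparison.

## Equivalence testing

`tost_equivalence` runs two one-sided Welch t-tests of
H0: `|mean(a) − mean(b)| ≥ margin_sd x scale` and returns the larger
one-sided p-value (small p supports equivalence). The margin scale
defaults to the pooled SD of the two samples but should be supplied
explicitly when the samples are replicate means: the across-replicate
standard error shrinks with the number of replicates while the margin
scale should not, and with the margin tied to the replicate-mean SD the
test can never reject at typical ensemble sizes. `compare_models` uses the
full-model SD of each statistic across days and replicates as the scale,
applies Benjamini–Hochberg (Holm available) across the per-day p-values,
and adds one KS test per statistic on the day-indexed ensemble-mean
trajectories with critical value `c(α) sqrt((n+n')/(n n'))`,
`c(0.05) = 1.358`. Successive daily means are serially dependent, which
the KS critical value does not account for; the test is reproduced in this
form deliberately as a descriptive distance criterion and every report
carries a note saying so.

Calibration is verified by simulation: TOST rejects in ≥90% of repetitions
for identical generators when the replicate SE is far below the margin,
withholds equivalence under a 1-SD shift, respects its nominal size when
the true difference sits exactly at the margin, and the KS null rejection
rate is close to α.

## Default study conditions and their rationale

Roster defaults are 200 customers, 20 street dealers, 25 brokers, 25
private dealers, 100 homeless, 1 police officer over 365 days. The
scaled-down `demo_config` (20 customers, 6 dealers with proportionally
smaller inventories, 120 days) keeps the demand/supply ratio and is the
problem size used by the certification pipeline and the acceptance script
(20 replicates run in about two minutes on one CPU).

Units are "bags": the reference obtain regression places the market's
operating scale near `beta0/|beta1| ≈ 8.9k` units/day across 200 customers,
i.e. tens of units per customer-day, so initial addictions default to
uniform(60, 110) units/day. The shared pharmacology then anchors
steady-state consumption: with a dose of a quarter of the daily level,
potency 0.25 and threshold 1.0, the dosing cycle is self-consistent at
roughly four doses per day and has a fixed point near 45 units/day, which
both simulators share exactly. Income (uniform daily-equivalent 35–65) and
the daily living-expense drain keep customers hand-to-mouth, making money
mean-reverting rather than an unbounded integrator of small flow biases —
ethnographically apt and statistically necessary for a day-indexed
distributional comparison. Dealer inventories (300 units/shift; 125 at
demo scale) leave modest supply headroom: with daily demand near capacity
the true availability-vs-units-sold curve develops a sharp depletion
cutoff that a logistic cannot represent, and the regression-based reduction
degrades. Arrest duration (7 days + 0.06 days/unit) makes a dealer
arrested mid-shift serve about 20 days, matching the configured mean
return time.

The invitation rule (base 0.01, slope 1e-4 per prior brokered purchase)
keeps the private channel a minority supply route (~10% of consumption).
The private channel is the one place the two models are known to diverge
structurally: brokered-purchase counts accumulate heterogeneously across
customers in the full model and more exchangeably under a distribution-form
broker model, which shifts first-invitation times — the reason the invite
outcome escalates to a regression.

## Numerical choices

* Beta/Gamma fits: MoM initialization (`alpha = m(m(1-m)/v - 1)`;
  `shape = m^2/v, rate = m/v`, sample variance with `ddof=1`), MLE via
  scipy (Nelder–Mead on log-parameters for the weighted Beta), MoM
  fallback.
* All random streams derive from `numpy` `SeedSequence`s keyed by (seed,
  subsystem) or (seed, customer id); agent-count changes do not reshuffle
  unrelated draws, and full runs are bitwise reproducible.
* Event times are quantized to whole minutes; drawn durations are floored
  at one minute.
* Degenerate inputs (empty conditioning sets, single-class outcomes,
  all-identical samples, zero pooled SDs) raise typed errors at the public
  fitting/testing API and degrade with flags inside the emulator-build
  path, where a missing outcome model would otherwise make the reduced
  model unrunnable.

## What the tests do and do not show

The synthetic-data generator *is* the full agent-based model; the
certification shows that the reduction pipeline reproduces the aggregate
behaviour of *this* market — one with stationary roster, fixed price, and
time-homogeneous steady state — and that the testing machinery is
calibrated. It does not validate the full model against real market data,
and printed reference values from the original market (success probability
0.53, failure duration 126.5 min, and the rest) are reproduced by the
reduced model run against the packaged reference emulator, not re-derived
from our full model, whose unpublished constants are not desk-reproducible.
Known limitations: no tolerance/overdose pharmacology, no dealer
restocking economics, no social-network effects, fixed price, and a KS
criterion applied to serially dependent daily means.
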