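"""Statistical emulation of market-trip outcomes.

The reduced simulator replaces the agent interactions that resolve a public
market trip with draws from fitted statistical models, one per outcome:

========  =============================  ===================================
outcome   simpler form (distribution)    escalated form (regression)
========  =============================  ===================================
obtain    Beta on hourly success rates   mixed-effects logistic on units of
                                         heroin already sold that day
time      Gamma on trip durations        (never needed)
arrest    Beta on hourly arrest rates    (never needed)
broker    Beta on hourly broker rates    logistic on broker/dealer ratio
                                         (bust regime only)
invite    Beta on hourly invite rates    logistic on the customer's prior
                                         brokered purchases
========  =============================  ===================================

Fitting starts with the simpler distribution form for every outcome and
escalates an outcome to its regression form only when the reduced model's
aggregate trajectories fail an adequacy policy against the full model.
A bust regime carries refitted variants of all five outcomes plus the
street-dealer arrest/release rates used by the reduced model's dealer ledger.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from ._glmm import fit_random_intercept_logistic
from .errors import ConfigError, DegenerateDataError, DomainError
from .trips import TripRecord, hourly_rate_table, trips_to_dataframe

OUTCOME_NAMES = ("obtain", "time_success", "time_failure", "arrest", "broker", "invite")
REGIMES = ("normal", "bust")


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class FittedDistribution:
    """A Beta (support [0,1]) or Gamma (shape/rate, support (0, inf)) fit."""

    family: str                 # "beta" | "gamma"
    param1: float               # Beta alpha  | Gamma shape
    param2: float               # Beta beta   | Gamma rate

    def __post_init__(self):
        if self.family not in ("beta", "gamma"):
            raise DomainError(f"unknown distribution family {self.family!r}")
        if self.param1 <= 0 or self.param2 <= 0:
            raise DomainError("distribution parameters must be positive")

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.param1 / (self.param1 + self.param2)
        return self.param1 / self.param2

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.param1, self.param2, size=size)
        return rng.gamma(self.param1, 1.0 / self.param2, size=size)


@dataclass
class LogisticModel:
    """(Possibly mixed-effects) logistic regression on one covariate."""

    beta0: float
    beta1: float
    covariate: str
    random_effect_variance: float = 0.0
    beta0_se: float | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.random_effect_variance < 0:
            raise DomainError("random-effect variance cannot be negative")

    def predict(self, x: float, gamma: float = 0.0) -> float:
        """Inverse-logit of ``beta0 + beta1*x + gamma``."""
        return float(expit(self.beta0 + self.beta1 * x + gamma))


@dataclass
class OutcomeModel:
    """Per-outcome slot holding both candidate forms and the selected one."""

    form: str                                   # "distribution" | "regression"
    distribution: FittedDistribution | None = None
    regression: LogisticModel | None = None

    def __post_init__(self):
        if self.form not in ("distribution", "regression"):
            raise DomainError(f"unknown model form {self.form!r}")
        if self.form == "distribution" and self.distribution is None:
            raise DomainError("distribution form requires a fitted distribution")
        if self.form == "regression" and self.regression is None:
            raise DomainError("regression form requires a fitted regression")


@dataclass
class DealerLedgerRates:
    """Street-dealer arrest/release rates (dealers/day) for the reduced model."""

    arrest_rate_normal: float
    arrest_rate_bust: float
    release_rate: float


@dataclass
class EmulatorSpec:
    """The full set of fitted outcome models, per regime, plus ledger rates."""

    regimes: dict                                # regime -> {outcome: OutcomeModel}
    dealer_ledger_rates: DealerLedgerRates | None = None
    fit_report: dict = field(default_factory=dict)

    def model(self, outcome: str, regime: str = "normal") -> OutcomeModel:
        if outcome not in OUTCOME_NAMES:
            raise DomainError(f"unknown outcome {outcome!r}")
        models = self.regimes.get(regime)
        if models is None or outcome not in models:
            raise ConfigError(f"emulator has no {outcome!r} model for regime {regime!r}")
        return models[outcome]

    def has_regime(self, regime: str) -> bool:
        return self.regimes.get(regime) is not None

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def enc_om(om: OutcomeModel) -> dict:
            d = {"form": om.form}
            if om.distribution is not None:
                d["distribution"] = {
                    "family": om.distribution.family,
                    "param1": om.distribution.param1,
                    "param2": om.distribution.param2,
                }
            if om.regression is not None:
                r = om.regression
                d["regression"] = {
                    "beta0": r.beta0, "beta1": r.beta1, "covariate": r.covariate,
                    "random_effect_variance": r.random_effect_variance,
                    "beta0_se": r.beta0_se, "flags": list(r.flags),
                }
            return d

        out = {
            "schema_version": 1,
            "regimes": {
                reg: {name: enc_om(om) for name, om in models.items()}
                for reg, models in self.regimes.items() if models is not None
            },
            "fit_report": self.fit_report,
        }
        if self.dealer_ledger_rates is not None:
            r = self.dealer_ledger_rates
            out["dealer_ledger_rates"] = {
                "arrest_rate_normal": r.arrest_rate_normal,
                "arrest_rate_bust": r.arrest_rate_bust,
                "release_rate": r.release_rate,
            }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "EmulatorSpec":
        if data.get("schema_version") != 1:
            raise ConfigError(f"unsupported emulator schema version {data.get('schema_version')!r}")

        def dec_om(d: dict) -> OutcomeModel:
            dist = reg = None
            if "distribution" in d:
                dd = d["distribution"]
                dist = FittedDistribution(dd["family"], dd["param1"], dd["param2"])
            if "regression" in d:
                rd = d["regression"]
                reg = LogisticModel(rd["beta0"], rd["beta1"], rd["covariate"],
                                    rd.get("random_effect_variance", 0.0),
                                    rd.get("beta0_se"), list(rd.get("flags", [])))
            return OutcomeModel(d["form"], dist, reg)

        regimes = {
            reg: {name: dec_om(om) for name, om in models.items()}
            for reg, models in data["regimes"].items()
        }
        rates = None
        if data.get("dealer_ledger_rates"):
            rd = data["dealer_ledger_rates"]
            rates = DealerLedgerRates(rd["arrest_rate_normal"], rd["arrest_rate_bust"],
                                      rd["release_rate"])
        return cls(regimes=regimes, dealer_ledger_rates=rates,
                   fit_report=data.get("fit_report", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmulatorSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def reference_emulator(form: str = "regression") -> EmulatorSpec:
    """The packaged reference emulator for the Denver open-air market model.

    ``form="regression"`` selects the regression form for the obtain and
    invite outcomes (the variant that passed the published adequacy checks);
    ``form="distribution"`` selects the simpler all-distribution variant.
    """
    if form not in ("regression", "distribution"):
        raise DomainError(f"form must be 'regression' or 'distribution', got {form!r}")
    with resources.files("heroinmarket.data").joinpath("reference_emulator.json").open() as fh:
        spec = EmulatorSpec.from_dict(json.load(fh))
    if form == "distribution":
        for models in spec.regimes.values():
            for om in models.values():
                if om.distribution is not None:
                    om.form = "distribution"
    return spec


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

def _moments(values: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    if weights is None:
        m = float(np.mean(values))
        v = float(np.var(values, ddof=1))
    else:
        w = weights / weights.sum()
        m = float(np.sum(w * values))
        v = float(np.sum(w * (values - m) ** 2))
        n_eff = 1.0 / np.sum(w ** 2)
        if n_eff > 1:
            v *= n_eff / (n_eff - 1.0)
    return m, v


def beta_method_of_moments(values) -> tuple[float, float]:
    """Closed-form Beta estimate: alpha = m(m(1-m)/v - 1), beta likewise."""
    m, v = _moments(np.asarray(values, dtype=float))
    if v <= 0 or not (0 < m < 1):
        raise DegenerateDataError("method of moments needs 0 < mean < 1 and variance > 0")
    common = m * (1 - m) / v - 1.0
    if common <= 0:
        raise DegenerateDataError("sample variance too large for a Beta fit")
    return m * common, (1 - m) * common


def gamma_method_of_moments(values) -> tuple[float, float]:
    """Closed-form Gamma estimate: shape = m^2/v, rate = m/v."""
    m, v = _moments(np.asarray(values, dtype=float))
    if v <= 0 or m <= 0:
        raise DegenerateDataError("method of moments needs positive mean and variance")
    return m * m / v, m / v


def fit_beta(values, weights=None) -> FittedDistribution:
    """Maximum-likelihood Beta fit of proportions in [0, 1].

    Exact 0/1 values are clamped to [eps, 1-eps] with ``eps = 1/(2N)`` before
    fitting (a Beta density has no mass at the endpoints).  The
    method-of-moments estimate initializes the MLE and serves as fallback if
    the optimizer fails.  Optional nonnegative ``weights`` (e.g. the number
    of trips behind each hourly rate) produce a weighted fit.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise DomainError(f"need at least 3 values to fit a Beta, got {len(values)}")
    if np.any(values < 0) or np.any(values > 1):
        raise DomainError("Beta fitting requires values in [0, 1]")
    if np.allclose(values, values[0]):
        raise DegenerateDataError("all values identical; no Beta fit exists")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(values) or np.any(weights < 0) or weights.sum() <= 0:
            raise DomainError("weights must be nonnegative and match values")
    eps = 1.0 / (2.0 * len(values))
    clamped = np.clip(values, eps, 1.0 - eps)
    a0, b0 = beta_method_of_moments(clamped) if weights is None else \
        _beta_mom_weighted(clamped, weights)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if weights is None:
                a, b, _, _ = stats.beta.fit(clamped, a0, b0, floc=0.0, fscale=1.0)
            else:
                a, b = _beta_mle_weighted(clamped, weights, a0, b0)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise RuntimeError("non-finite MLE")
    except Exception:
        a, b = a0, b0
    return FittedDistribution("beta", float(a), float(b))


def _beta_mom_weighted(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    m, v = _moments(values, weights)
    if v <= 0 or not (0 < m < 1):
        raise DegenerateDataError("weighted method of moments undefined")
    common = m * (1 - m) / v - 1.0
    if common <= 0:
        raise DegenerateDataError("sample variance too large for a Beta fit")
    return m * common, (1 - m) * common


def _beta_mle_weighted(values: np.ndarray, weights: np.ndarray,
                       a0: float, b0: float) -> tuple[float, float]:
    from scipy.optimize import minimize
    from scipy.special import betaln

    w = weights / weights.sum()
    lx = np.sum(w * np.log(values))
    l1x = np.sum(w * np.log1p(-values))

    def nll(p):
        a, b = np.exp(p)
        return -( (a - 1) * lx + (b - 1) * l1x - betaln(a, b) )

    res = minimize(nll, np.log([a0, b0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    a, b = np.exp(res.x)
    return float(a), float(b)


def fit_gamma(values) -> FittedDistribution:
    """Maximum-likelihood Gamma fit (shape/rate parameterization) of positive
    reals, with method-of-moments initializer/fallback."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise DomainError(f"need at least 3 values to fit a Gamma, got {len(values)}")
    if np.any(values <= 0):
        raise DomainError("Gamma fitting requires strictly positive values")
    if np.allclose(values, values[0]):
        raise DegenerateDataError("all values identical; no Gamma fit exists")
    k0, r0 = gamma_method_of_moments(values)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k, _, scale = stats.gamma.fit(values, k0, floc=0.0, scale=1.0 / r0)
        rate = 1.0 / scale
        if not (np.isfinite(k) and np.isfinite(rate) and k > 0 and rate > 0):
            raise RuntimeError("non-finite MLE")
    except Exception:
        k, rate = k0, r0
    return FittedDistribution("gamma", float(k), float(rate))


# ---------------------------------------------------------------------------
# regression fitting
# ---------------------------------------------------------------------------

def fit_logistic(records, covariate: str) -> LogisticModel:
    """Plain maximum-likelihood logistic regression on (x, y) pairs.

    Complete separation is flagged and resolved with a weakly penalized
    (L2-regularized) fit.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("records must be (x, y) pairs")
    if len(arr) < 10:
        raise DomainError(f"need at least 10 records, got {len(arr)}")
    x, y = arr[:, 0], arr[:, 1]
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise DomainError("both outcome classes must be present")
    X = sm.add_constant(x)
    flags: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=Warning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = res.params
        se0 = float(res.bse[0])
        if not np.all(np.isfinite(params)):
            raise RuntimeError("non-finite estimates")
    except Exception:
        flags.append("separation_or_nonconvergence:penalized_fit")
        res = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0, maxiter=500)
        params = np.asarray(res.params)
        se0 = None
    if flags:
        warnings.warn("logistic fit flagged: " + flags[0], stacklevel=2)
    return LogisticModel(float(params[0]), float(params[1]), covariate,
                         random_effect_variance=0.0, beta0_se=se0, flags=flags)


def fit_mixed_logistic(records, covariate: str, min_groups: int = 20) -> LogisticModel:
    """Random-intercept logistic regression on (group, x, y) triples.

    Falls back to the plain logistic (with a warning) when fewer than
    ``min_groups`` groups are present.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DomainError("records must be (group, x, y) triples")
    groups, x, y = arr[:, 0], arr[:, 1], arr[:, 2]
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise DomainError("both outcome classes must be present")
    n_groups = len(np.unique(groups))
    if n_groups < min_groups:
        warnings.warn(
            f"only {n_groups} groups (< {min_groups}); falling back to a plain logistic",
            stacklevel=2,
        )
        model = fit_logistic(np.column_stack([x, y]), covariate)
        model.flags.append("too_few_groups:plain_logistic_fallback")
        return model
    plain = fit_logistic(np.column_stack([x, y]), covariate)
    b0, b1, sigma2, converged = fit_random_intercept_logistic(
        groups, x, y, start=(plain.beta0, plain.beta1))
    flags = [] if converged else ["glmm_optimizer_not_converged"]
    return LogisticModel(b0, b1, covariate, random_effect_variance=sigma2,
                         beta0_se=plain.beta0_se, flags=flags)


# ---------------------------------------------------------------------------
# outcome-model assembly from trip logs
# ---------------------------------------------------------------------------

def _rates(trips: list[TripRecord], outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """Hourly rates and their eligible-trip counts (used as fit weights)."""
    table = hourly_rate_table(trips, outcome)
    return table.rate.to_numpy(float), table.n.to_numpy(float)


def _fit_beta_rates(rates_weights: tuple[np.ndarray, np.ndarray], label: str,
                    flags: list) -> FittedDistribution:
    """Beta fit of hourly rates, degrading gracefully on sparse outcomes.

    The fitted shape is recalibrated so the Beta *mean* equals the
    eligible-trip-weighted rate: downstream the draw feeds a Bernoulli trial,
    so an unbiased mean matters more than an exactly-ML shape.  A rare
    outcome (e.g. arrest) can produce hourly rates that are all zero or
    nearly constant; the MLE is then undefined and the fit degrades to a
    high-concentration Beta at the clamped weighted mean, with the outcome
    flagged in the fit report.
    """
    rates, weights = rates_weights
    if len(rates) == 0:
        flags.append(f"{label}:unfittable_empty_conditioning_set")
        m = 0.25
        return FittedDistribution("beta", m * 2, (1 - m) * 2)
    n = len(rates)
    eps = 1.0 / (2.0 * max(n, 2))
    m = float(np.clip(np.average(rates, weights=weights), eps, 1 - eps))
    try:
        fitted = fit_beta(rates, weights)
        kappa = fitted.param1 + fitted.param2
    except (DegenerateDataError, DomainError):
        kappa = 2.0 * max(n, 2)
        flags.append(f"{label}:degenerate_rates_point_mass_fallback")
    return FittedDistribution("beta", m * kappa, (1 - m) * kappa)


def fit_outcome_distributions(trips: list[TripRecord],
                              flags: list | None = None) -> dict[str, OutcomeModel]:
    """Fit the simpler (distribution) form for all five outcomes.

    Sparse-outcome degeneracies are recorded in ``flags`` (if given) and
    resolved with point-mass-like Beta fallbacks.
    """
    if flags is None:
        flags = []
    df = trips_to_dataframe(trips)
    succ = df[df.obtained == 1]
    fail = df[df.obtained == 0]
    models = {
        "obtain": OutcomeModel("distribution",
                               _fit_beta_rates(_rates(trips, "obtained"), "obtain", flags)),
        "time_success": OutcomeModel("distribution", fit_gamma(succ.duration.to_numpy())),
        "time_failure": OutcomeModel("distribution", fit_gamma(fail.duration.to_numpy())),
        "arrest": OutcomeModel("distribution",
                               _fit_beta_rates(_rates(trips, "arrested"), "arrest", flags)),
        "broker": OutcomeModel("distribution",
                               _fit_beta_rates(_rates(trips, "via_broker"), "broker", flags)),
        "invite": OutcomeModel("distribution",
                               _fit_beta_rates(_rates(trips, "invited"), "invite", flags)),
    }
    return models


def fit_obtain_regression(trips: list[TripRecord], bust: bool = False) -> LogisticModel:
    """Mixed-effects logistic for the obtain probability.

    Covariate: units sold by street dealers that day before the attempt
    (normal regime) or the dealers' collective remaining stock (bust regime).
    """
    df = trips_to_dataframe(trips)
    col = "x_collective_remaining" if bust else "x_units_sold_before"
    name = "collective_remaining" if bust else "units_sold_today"
    rec = np.column_stack([df.customer_id.to_numpy(float),
                           df[col].to_numpy(float),
                           df.obtained.to_numpy(float)])
    return fit_mixed_logistic(rec, name)


def fit_invite_regression(trips: list[TripRecord]) -> LogisticModel:
    """Plain logistic for the invite probability, on the customer's count of
    prior brokered purchases; fitted among brokered purchases only."""
    df = trips_to_dataframe(trips)
    sub = df[(df.obtained == 1) & (df.via_broker == 1)]
    rec = np.column_stack([sub.x_broker_purchases_before.to_numpy(float),
                           sub.invited.to_numpy(float)])
    return fit_logistic(rec, "broker_purchase_count")


def fit_broker_ratio_regression(trips: list[TripRecord]) -> LogisticModel:
    """Bust-regime broker probability: logistic on the brokers-to-dealers
    ratio at the time of purchase, among successful trips."""
    df = trips_to_dataframe(trips)
    sub = df[df.obtained == 1]
    rec = np.column_stack([sub.x_broker_dealer_ratio.to_numpy(float),
                           sub.via_broker.to_numpy(float)])
    return fit_logistic(rec, "broker_dealer_ratio")


# ---------------------------------------------------------------------------
# adequacy policy and escalation workflow
# ---------------------------------------------------------------------------

class AdequacyPolicy:
    """Decides whether reduced-model output is 'sufficiently similar' to the
    full model.

    Default rule: for each of the four daily aggregate statistics over the
    steady-state window (``day >= steady_start``), the two-sample KS test on
    the ensemble daily-mean trajectories must not reject at ``alpha`` AND the
    mean relative deviation between the trajectories must stay below
    ``max_rel_dev``.
    """

    STATISTICS = ("mean_money", "mean_inventory", "mean_addiction", "mean_concentration")

    def __init__(self, alpha: float = 0.05, max_rel_dev: float = 0.05,
                 steady_start: int = 180):
        self.alpha = alpha
        self.max_rel_dev = max_rel_dev
        self.steady_start = steady_start

    def evaluate(self, full_daily: list[pd.DataFrame],
                 reduced_daily: list[pd.DataFrame]) -> tuple[bool, dict]:
        from .compare import ensemble_mean_trajectory, ks_two_sample

        full_mean = ensemble_mean_trajectory(full_daily)
        red_mean = ensemble_mean_trajectory(reduced_daily)
        if (full_mean.day >= self.steady_start).any():
            full_mean = full_mean[full_mean.day >= self.steady_start]
            red_mean = red_mean[red_mean.day >= self.steady_start]
        details: dict = {}
        ok = True
        for statname in self.STATISTICS:
            a = full_mean[statname].to_numpy(float)
            b = red_mean[statname].to_numpy(float)
            d, crit, reject = ks_two_sample(a, b, self.alpha)
            # systematic deviation of the window means (per-day noise cancels)
            rel = float(abs(a.mean() - b.mean()) / max(abs(a.mean()), 1e-12))
            details[statname] = {"ks_D": d, "ks_critical": crit, "ks_reject": reject,
                                 "mean_rel_dev": rel}
            if reject or rel >= self.max_rel_dev:
                ok = False
        return ok, details


class AlwaysAdequate(AdequacyPolicy):
    """Short-circuit policy: every candidate passes (keeps all distributions)."""

    def evaluate(self, full_daily, reduced_daily):
        return True, {"policy": "always_adequate"}


def build_emulator(trips: list[TripRecord], full_daily: list[pd.DataFrame],
                   config, policy: AdequacyPolicy | None = None,
                   n_replicates: int = 5, seed: int = 0,
                   steady_start: int | None = None,
                   seeds: list[int] | None = None,
                   force_regressions: tuple = ()) -> EmulatorSpec:
    """Fit an emulator from full-model output, escalating distribution fits
    to regressions until the adequacy policy passes.

    Escalation order follows the outcomes whose distribution form is known to
    misrepresent the success/failure *patterns* even when the average rate is
    right: first the obtain probability, then the invite probability.  The
    selected form per outcome and the policy diagnostics for every candidate
    are recorded in ``spec.fit_report``.

    ``seeds``: seeds for the reduced check runs; pass the seeds of the full
    replicates to obtain a paired comparison on identical customer
    populations (recommended — removes initialization luck from the policy
    decision).

    ``force_regressions``: outcomes (among "obtain", "invite") fitted with
    their regression form up front, regardless of whether the simpler
    distribution form would already satisfy the policy — used to reproduce
    the regression-based reduced model explicitly.
    """
    from .reduced import run_reduced_simulation
    from .trips import steady_state_window

    if policy is None:
        policy = AdequacyPolicy(steady_start=steady_start if steady_start is not None else 180)
    if steady_start is not None:
        trips = steady_state_window(trips, steady_start)
    if not trips:
        raise DomainError("no trips available to fit an emulator")

    fit_flags: list = []
    models = fit_outcome_distributions(trips, fit_flags)
    report: dict = {"candidates": [], "fit_flags": fit_flags}

    check_seeds = list(seeds) if seeds is not None else \
        [seed + 1000 + i for i in range(n_replicates)]

    def check(spec: EmulatorSpec, label: str) -> tuple[bool, dict]:
        reduced_daily = []
        for s in check_seeds:
            daily, _ = run_reduced_simulation(config, spec, seed=s)
            reduced_daily.append(daily)
        ok, details = policy.evaluate(full_daily, reduced_daily)
        report["candidates"].append({"label": label, "adequate": ok, "details": details})
        return ok, details

    if "obtain" in force_regressions:
        models["obtain"] = OutcomeModel("regression", models["obtain"].distribution,
                                        fit_obtain_regression(trips))
    if "invite" in force_regressions:
        models["invite"] = OutcomeModel("regression", models["invite"].distribution,
                                        fit_invite_regression(trips))
    label0 = "forced_" + "_".join(force_regressions) if force_regressions \
        else "all_distributions"
    spec = EmulatorSpec(regimes={"normal": dict(models)}, fit_report=report)
    ok, _ = check(spec, label0)
    if not ok and models["obtain"].form != "regression":
        obtain_reg = fit_obtain_regression(trips)
        models["obtain"] = OutcomeModel("regression",
                                        models["obtain"].distribution, obtain_reg)
        spec = EmulatorSpec(regimes={"normal": dict(models)}, fit_report=report)
        ok, _ = check(spec, "obtain_regression")
    if not ok and models["invite"].form != "regression":
        invite_reg = fit_invite_regression(trips)
        models["invite"] = OutcomeModel("regression",
                                        models["invite"].distribution, invite_reg)
        spec = EmulatorSpec(regimes={"normal": dict(models)}, fit_report=report)
        ok, _ = check(spec, "obtain_and_invite_regressions")
    report["adequate"] = ok
    report["selection"] = {name: om.form for name, om in models.items()}
    if not ok:
        report["flag"] = "no candidate passed the adequacy policy"
        warnings.warn("emulator flagged non-adequate: no candidate passed the policy",
                      stacklevel=2)
    return spec


# ---------------------------------------------------------------------------
# bust-period refits and the dealer ledger rates
# ---------------------------------------------------------------------------

def estimate_dealer_rates(dealer_events: pd.DataFrame, bust_exposure_days: float,
                          nonbust_exposure_days: float) -> DealerLedgerRates:
    """Event-count / exposure-time estimates of the street-dealer arrest rates
    (per regime) and release rate.

    ``dealer_events`` columns: ``day`` (float), ``kind`` ("arrest"|"release"),
    ``bust_active`` (0/1).
    """
    if bust_exposure_days < 0 or nonbust_exposure_days <= 0:
        raise DomainError("exposure times must be positive")
    ev = dealer_events
    arrests = ev[ev.kind == "arrest"]
    n_bust = int((arrests.bust_active == 1).sum())
    n_norm = int((arrests.bust_active == 0).sum())
    n_rel = int((ev.kind == "release").sum())
    total = bust_exposure_days + nonbust_exposure_days
    if n_rel == 0:
        warnings.warn("no dealer release events observed; release rate set to 0",
                      stacklevel=2)
    return DealerLedgerRates(
        arrest_rate_normal=n_norm / nonbust_exposure_days,
        arrest_rate_bust=(n_bust / bust_exposure_days) if bust_exposure_days > 0 else 0.0,
        release_rate=n_rel / total,
    )


def fit_bust_emulator(bust_trips: list[TripRecord], dealer_events: pd.DataFrame,
                      bust_exposure_days: float, nonbust_exposure_days: float,
                      base: EmulatorSpec) -> EmulatorSpec:
    """Fit the bust-regime overlay from trips recorded during bust windows.

    Obtain: regression on collective remaining dealer stock; broker:
    regression on the brokers-to-dealers ratio; arrest and both time
    outcomes: refitted distributions; invite: refitted regression.  Returns a
    new spec sharing the base's normal regime.
    """
    if not bust_trips:
        raise DomainError("no bust-period trips to fit from")
    if any(r.bust_active != 1 for r in bust_trips):
        raise DomainError("fit_bust_emulator expects bust-period trips only")
    df = trips_to_dataframe(bust_trips)
    succ = df[df.obtained == 1]
    fail = df[df.obtained == 0]
    flags: list = []

    def regression_or_fallback(label: str, fitter) -> OutcomeModel:
        # bust windows are short, so a conditioning set can be single-class;
        # reuse the non-bust model for that outcome and flag it
        try:
            return OutcomeModel("regression", None, fitter())
        except (DomainError, DegenerateDataError):
            flags.append(f"{label}:bust_refit_unfittable_reusing_normal_model")
            return base.regimes["normal"][label]

    bust_models = {
        "obtain": regression_or_fallback(
            "obtain", lambda: fit_obtain_regression(bust_trips, bust=True)),
        "time_success": OutcomeModel("distribution", fit_gamma(succ.duration.to_numpy())),
        "time_failure": OutcomeModel("distribution", fit_gamma(fail.duration.to_numpy())),
        "arrest": OutcomeModel("distribution",
                               _fit_beta_rates(_rates(bust_trips, "arrested"), "arrest", flags)),
        "broker": regression_or_fallback(
            "broker", lambda: fit_broker_ratio_regression(bust_trips)),
        "invite": regression_or_fallback(
            "invite", lambda: fit_invite_regression(bust_trips)),
    }
    rates = estimate_dealer_rates(dealer_events, bust_exposure_days, nonbust_exposure_days)
    report = dict(base.fit_report)
    if flags:
        report = {**report, "bust_fit_flags": flags}
    return EmulatorSpec(
        regimes={"normal": dict(base.regimes["normal"]), "bust": bust_models},
        dealer_ledger_rates=rates,
        fit_report=report,
    )
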