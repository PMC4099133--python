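"""Full-vs-reduced model comparison.

Implements the testing protocol used to certify a reduced model:

* per-day equivalence tests (TOST with a margin of ``delta`` standard
  deviations) on the four customer aggregates across replicate runs, with a
  multiplicity correction over the simulated days;
* one two-sample Kolmogorov-Smirnov test per statistic on the day-indexed
  ensemble-mean trajectories (n = n' = number of days), with the
  large-sample critical value ``c(alpha) * sqrt((n + n') / (n * n'))``;
* a time-step sensitivity sweep of the full model's five outcome summaries.

Note on the KS test: the day-indexed means are serially dependent, which
violates the independence assumption of the KS critical value; the test is
reproduced in this form deliberately, as a descriptive distance criterion,
and reports carry a note to that effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import SimConfig
from .errors import DegenerateDataError, DomainError
from .trips import empirical_summaries

STATISTICS = ("mean_money", "mean_inventory", "mean_addiction", "mean_concentration")

KS_SERIAL_DEPENDENCE_NOTE = (
    "KS tests are applied to day-indexed mean trajectories; successive days are "
    "serially dependent, so the nominal critical value is descriptive rather "
    "than exact."
)


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def tost_equivalence(a, b, margin_sd: float = 0.1,
                     scale_sd: float | None = None) -> float:
    """Two one-sided Welch t-tests of H0: |mean(a) - mean(b)| >= margin.

    The margin is ``margin_sd * scale_sd``; ``scale_sd`` defaults to the
    pooled standard deviation of the two samples, but callers comparing
    replicate means should pass the standard deviation of the underlying
    statistic (the across-replicate SE shrinks with the number of replicates,
    the margin scale should not).  Returns the larger of the two one-sided
    p-values; small values support equivalence.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 3 or nb < 3:
        raise DomainError("each sample needs at least 3 replicates")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if scale_sd is None:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        scale_sd = math.sqrt(pooled)
    if scale_sd <= 0 or (va == 0 and vb == 0):
        raise DegenerateDataError("zero pooled standard deviation; TOST undefined")
    margin = margin_sd * scale_sd
    d = a.mean() - b.mean()
    se = math.sqrt(va / na + vb / nb)
    if se == 0:
        raise DegenerateDataError("zero standard error; TOST undefined")
    # Welch-Satterthwaite degrees of freedom
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_lower = stats.t.sf((d + margin) / se, df)      # H0: d <= -margin
    p_upper = stats.t.cdf((d - margin) / se, df)     # H0: d >= +margin
    return float(max(p_lower, p_upper))


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-comparison adjustment; Benjamini-Hochberg by default, Holm
    available.  Adjusted values are monotone in the inputs and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm"}.get(method.lower())
    if key is None:
        raise DomainError(f"unknown adjustment method {method!r}; use 'bh' or 'holm'")
    return multipletests(p, method=key)[1]


def ks_two_sample(x, y, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sample KS test with the large-sample critical value.

    Returns ``(D, critical, reject)`` where
    ``critical = c(alpha) * sqrt((n + n') / (n * n'))`` and
    ``c(alpha) = sqrt(-ln(alpha / 2) / 2)`` (1.358 at alpha = 0.05).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DomainError("KS test requires nonempty samples")
    d = float(stats.ks_2samp(x, y, method="asymp").statistic)
    n, m = len(x), len(y)
    c_alpha = math.sqrt(-math.log(alpha / 2.0) / 2.0)
    critical = c_alpha * math.sqrt((n + m) / (n * m))
    return d, critical, d > critical


# ---------------------------------------------------------------------------
# trajectory ensembles
# ---------------------------------------------------------------------------

def ensemble_mean_trajectory(runs: list[pd.DataFrame]) -> pd.DataFrame:
    """Average the daily trajectories of an ensemble of runs day by day."""
    if not runs:
        raise DomainError("empty ensemble")
    days = runs[0]["day"].to_numpy()
    for r in runs[1:]:
        if not np.array_equal(r["day"].to_numpy(), days):
            raise DomainError("replicate runs cover different day ranges")
    out = pd.DataFrame({"day": days})
    for s in STATISTICS:
        out[s] = np.mean([r[s].to_numpy(float) for r in runs], axis=0)
    return out


@dataclass
class EquivalenceReport:
    """Outcome of the full/reduced comparison protocol."""

    pointwise: pd.DataFrame        # statistic, day, p_raw, p_adjusted
    ks: pd.DataFrame               # statistic, D, critical, reject, n, n_prime
    margin_sd: float
    alpha: float
    adjust_method: str
    n_full: int
    n_reduced: int
    notes: list = field(default_factory=lambda: [KS_SERIAL_DEPENDENCE_NOTE])

    def equivalent_fraction(self, alpha: float | None = None) -> pd.Series:
        """Per statistic: share of days where adjusted TOST p < alpha
        (equivalence supported)."""
        a = self.alpha if alpha is None else alpha
        return (self.pointwise.assign(eq=lambda d: d.p_adjusted < a)
                .groupby("statistic")["eq"].mean())


def compare_models(full_runs: list[pd.DataFrame], reduced_runs: list[pd.DataFrame],
                   margin_sd: float = 0.1, alpha: float = 0.05,
                   adjust_method: str = "bh") -> EquivalenceReport:
    """Run the full comparison protocol on two replicate ensembles.

    Per statistic and simulated day, a TOST across replicates (margin
    ``margin_sd`` times the full-model SD of that statistic across days and
    replicates), adjusted over days; plus one KS test on the day-indexed
    ensemble-mean trajectories.
    """
    if len(full_runs) < 3 or len(reduced_runs) < 3:
        raise DomainError("need at least 3 replicate runs per model")
    days = full_runs[0]["day"].to_numpy()
    for r in list(full_runs[1:]) + list(reduced_runs):
        if not np.array_equal(r["day"].to_numpy(), days):
            raise DomainError("full and reduced runs must cover identical day ranges")

    rows = []
    ks_rows = []
    full_mean = ensemble_mean_trajectory(full_runs)
    red_mean = ensemble_mean_trajectory(reduced_runs)
    for s in STATISTICS:
        fm = np.stack([r[s].to_numpy(float) for r in full_runs])     # (reps, days)
        rm = np.stack([r[s].to_numpy(float) for r in reduced_runs])
        scale = float(fm.std(ddof=1))        # across days and replicates
        praw = np.empty(len(days))
        for j in range(len(days)):
            try:
                praw[j] = tost_equivalence(fm[:, j], rm[:, j], margin_sd, scale_sd=scale)
            except DegenerateDataError:
                praw[j] = 1.0
        padj = adjust_pvalues(praw, adjust_method)
        rows.append(pd.DataFrame({"statistic": s, "day": days,
                                  "p_raw": praw, "p_adjusted": padj}))
        d, crit, reject = ks_two_sample(full_mean[s].to_numpy(float),
                                        red_mean[s].to_numpy(float), alpha)
        ks_rows.append({"statistic": s, "D": d, "critical": crit, "reject": reject,
                        "n": len(days), "n_prime": len(days)})

    return EquivalenceReport(
        pointwise=pd.concat(rows, ignore_index=True),
        ks=pd.DataFrame(ks_rows),
        margin_sd=margin_sd,
        alpha=alpha,
        adjust_method=adjust_method,
        n_full=len(full_runs),
        n_reduced=len(reduced_runs),
    )


# ---------------------------------------------------------------------------
# time-step sweep
# ---------------------------------------------------------------------------

SWEEP_TICKS_SECONDS = (3, 6, 15, 30, 60, 120, 180, 300, 600, 3600)


def timestep_sweep(config: SimConfig, ticks_seconds=SWEEP_TICKS_SECONDS,
                   replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Re-run the full model at each tick size and summarize the five trip
    outcomes.

    Returns one row per tick with replicate-averaged summaries and a
    ``log_minutes`` column (natural log of the tick in minutes; 0 is the
    reference 1-minute tick).
    """
    from dataclasses import replace

    from .fullmodel import run_full_simulation

    rows = []
    for t_idx, tick in enumerate(ticks_seconds):
        cfg = replace(config, tick_seconds=float(tick)).validate()
        acc: dict[str, list[float]] = {}
        for rep in range(replicates):
            _, trips = run_full_simulation(cfg, seed=seed + 10_000 * t_idx + rep)
            if not trips:
                continue
            summ = empirical_summaries(trips).to_dict()
            for k, v in summ.items():
                if isinstance(v, (int, float)) and v is not None:
                    acc.setdefault(k, []).append(float(v))
        row = {"tick_seconds": float(tick),
               "log_minutes": math.log(tick / 60.0),
               "replicates": replicates}
        for k, vals in acc.items():
            row[k] = float(np.mean(vals)) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
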