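"""Disproportionality analysis: 2×2 tables and four signal statistics.

For one suspect drug against the rest of a spontaneous-reporting database,
each event term (MedDRA PT, or SOC after mapping) yields a 2×2 table

    =============  ==========  ==============
                   event term  all other terms
    target drug        a             b
    other drugs        c             d
    =============  ==========  ==============

where the counting unit is the distinct (report, term) pair: a report
mentioning a PT several times contributes 1 to that PT's cell.

Implemented statistics (defaults are the canonical literature choices):

- ROR  — reporting odds ratio ``ad/bc`` with a Wald 95% CI on the log
  scale; positive when ``a ≥ 3`` and the lower bound exceeds 1.
- PRR  — proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with a log
  Wald CI and a Yates-corrected χ²; positive per the MHRA combined rule
  (``a ≥ 3``, PRR ≥ 2, χ² ≥ 4).
- BCPNN information component — posterior log2 ratio of joint to product
  marginal report probabilities under the Bate et al. Beta priors
  (α₁=β₁=1, α=β=2, γ₁₁=1 with γ tuned to prior independence); positive
  when IC025 (IC − 2 posterior SD) exceeds 0.
- MGPS — empirical-Bayes gamma-Poisson shrinkage: a 2-component gamma
  prior on the relative report rate λ is fitted by maximising the
  negative-binomial marginal likelihood over all database cells, and each
  cell's EBGM is the posterior geometric mean of λ with EBGM05 its
  posterior 5th percentile; positive when EBGM05 ≥ 2.

An event is a *signal* when at least one method is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .faers_io import CaseStore
from .meddra import MedDRAMap, UNCODED, recode_pt, soc_of

__all__ = [
    "Contingency2x2",
    "GPSPrior",
    "SignalThresholds",
    "build_tables",
    "pair_counts",
    "ror",
    "prr_chi2",
    "bcpnn_ic",
    "fit_gps_prior",
    "ebgm_scores",
    "evaluate_signal",
    "compute_signal_stats",
    "rank_report",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class Contingency2x2:
    """Counts for one (drug, event) pair against the rest of the database."""

    a: int  # target drug AND event
    b: int  # target drug, other events
    c: int  # other drugs, this event
    d: int  # other drugs, other events

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Independence expectation of cell a: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


class RorResult(NamedTuple):
    est: float
    lo95: float
    hi95: float
    reason: str | None = None


class PrrResult(NamedTuple):
    est: float
    lo95: float
    hi95: float
    chi2: float
    reason: str | None = None


class IcResult(NamedTuple):
    ic: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float
    reason: str | None = None


def ror(t: Contingency2x2) -> RorResult:
    """Reporting odds ratio ad/bc with its log-scale Wald 95% CI.

    Any zero cell makes the estimate undefined (no continuity correction
    by default); the reason is carried in the result.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorResult(math.nan, math.nan, math.nan, "zero cell")
    est = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RorResult(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se))


def prr_chi2(t: Contingency2x2) -> PrrResult:
    """PRR with log Wald CI, plus the Yates-corrected χ² of the table.

    χ² = N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)], floored at 0 when the
    continuity correction exceeds |ad−bc|.
    """
    n = t.n
    chi2 = math.nan
    margins = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if margins > 0:
        diff = abs(t.a * t.d - t.b * t.c)
        chi2 = 0.0 if diff <= n / 2 else n * (diff - n / 2) ** 2 / margins
    if t.a + t.b == 0 or t.c + t.d == 0 or t.c == 0 or t.a == 0:
        return PrrResult(math.nan, math.nan, math.nan, chi2, "zero margin or cell")
    est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    var = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    se = math.sqrt(max(var, 0.0))
    return PrrResult(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), chi2)


def bcpnn_ic(t: Contingency2x2) -> IcResult:
    """BCPNN information component and its lower bound IC025.

    Moment approximation of the posterior of
    IC = log2 p(drug, event) / [p(drug) p(event)] under the standard Beta
    priors (α₁=β₁=1 on each margin, α=β=2, γ₁₁=1, and the joint prior
    weight γ chosen so the prior IC is centred at 0).  Defined for every
    non-negative table, including a = 0.  IC025 = IC − 2√var.
    """
    n11, n = float(t.a), float(t.n)
    n1_, n_1 = float(t.a + t.b), float(t.a + t.c)
    a1 = b1 = 1.0
    alpha = beta = 2.0
    g11 = 1.0
    gamma = g11 * (n + alpha) * (n + beta) / ((n1_ + a1) * (n_1 + b1))
    ic = math.log2(
        (n11 + g11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (n1_ + a1) * (n_1 + b1))
    )
    var = (1.0 / math.log(2) ** 2) * (
        (n - n11 + gamma - g11) / ((n11 + g11) * (1 + n + gamma))
        + (n - n1_ + alpha - a1) / ((n1_ + a1) * (1 + n + alpha))
        + (n - n_1 + beta - b1) / ((n_1 + b1) * (1 + n + beta))
    )
    return IcResult(ic, ic - 2.0 * math.sqrt(var))


# ---------------------------------------------------------------------------
# MGPS: empirical-Bayes gamma-Poisson shrinkage
# ---------------------------------------------------------------------------

@dataclass
class GPSPrior:
    """Fitted 2-component gamma prior of the MGPS model.

    λ ~ π·Gamma(alpha1, rate beta1) + (1−π)·Gamma(alpha2, rate beta2);
    observed counts are Poisson(λE), so marginally each cell count is a
    mixture of negative binomials.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    pi: float
    loglik: float = math.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("mixture weight must lie in (0, 1)")

    @property
    def mean(self) -> float:
        return self.pi * self.alpha1 / self.beta1 + (1 - self.pi) * self.alpha2 / self.beta2

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.pi)


DEFAULT_GPS_INIT = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class GPSFitError(RuntimeError):
    """The marginal-likelihood optimisation failed or input was degenerate."""


def _nb_logpmf(n: np.ndarray, shape: float, rate: float, E: np.ndarray) -> np.ndarray:
    # marginal of Poisson(λE) with λ ~ Gamma(shape, rate): NB(size=shape,
    # p=rate/(rate+E)), mean shape·E/rate
    p = rate / (rate + E)
    return stats.nbinom.logpmf(n, shape, p)


def _mixture_loglik(theta: np.ndarray, n: np.ndarray, E: np.ndarray,
                    truncated: bool) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    pi = special.expit(theta[4])
    l1 = _nb_logpmf(n, a1, b1, E) + math.log(pi)
    l2 = _nb_logpmf(n, a2, b2, E) + math.log1p(-pi)
    ll = np.logaddexp(l1, l2)
    if truncated:
        z1 = _nb_logpmf(np.zeros_like(n), a1, b1, E) + math.log(pi)
        z2 = _nb_logpmf(np.zeros_like(n), a2, b2, E) + math.log1p(-pi)
        ll = ll - np.log1p(-np.exp(np.logaddexp(z1, z2)))
    return float(np.sum(ll))


def fit_gps_prior(
    n: np.ndarray,
    E: np.ndarray,
    init: tuple[float, float, float, float, float] = DEFAULT_GPS_INIT,
    truncated: bool = False,
) -> GPSPrior:
    """Fit the 2-component gamma prior by maximum marginal likelihood.

    *n* are observed cell counts (n ≥ 1 cells of the whole database), *E*
    their independence expectations.  Parameters are optimised on the log
    scale (logit for π) with L-BFGS-B.  ``truncated=True`` uses the
    zero-truncated likelihood (both variants are in published use).
    """
    n = np.asarray(n, dtype=float)
    E = np.asarray(E, dtype=float)
    if n.shape != E.shape or n.ndim != 1:
        raise ValueError("n and E must be 1-D arrays of equal length")
    if np.unique(n / np.maximum(E, 1e-12)).size < 2:
        raise GPSFitError("fewer than 2 distinct cells: cannot fit a mixture")
    if np.any(E <= 0):
        raise ValueError("expectations must be positive")
    theta0 = np.concatenate([np.log(init[:4]), [special.logit(init[4])]])
    res = optimize.minimize(
        lambda th: -_mixture_loglik(th, n, E, truncated),
        theta0,
        method="L-BFGS-B",
        bounds=[(-12, 12)] * 4 + [(-8, 8)],
    )
    if not res.success and abs(res.fun) > 1e12:
        raise GPSFitError(f"GPS optimisation failed: {res.message}")
    a1, b1, a2, b2 = np.exp(res.x[:4])
    pi = float(special.expit(res.x[4]))
    return GPSPrior(float(a1), float(b1), float(a2), float(b2), pi,
                    loglik=-float(res.fun), converged=bool(res.success))


def gps_marginal_loglik(prior: GPSPrior, n: np.ndarray, E: np.ndarray,
                        truncated: bool = False) -> float:
    """Marginal log-likelihood of (n, E) under a given prior (diagnostics)."""
    theta = np.concatenate([
        np.log(prior.as_tuple()[:4]), [special.logit(prior.pi)]])
    return _mixture_loglik(theta, np.asarray(n, float), np.asarray(E, float), truncated)


def ebgm_scores(t: Contingency2x2 | tuple[int, float], prior: GPSPrior,
                quantile_tol: float = 1e-6) -> EbgmResult:
    """EBGM (posterior geometric mean of λ) and EBGM05 (posterior 5th pct).

    The posterior is Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a, β₂+E) with Q
    the posterior component probability from the marginal masses; the
    geometric mean uses E[ln λ] = ψ(shape) − ln(rate) per component, and
    EBGM05 is found by monotone root-finding on the mixture CDF.
    """
    if isinstance(t, Contingency2x2):
        a, E = t.a, t.expected
    else:
        a, E = t
    if E <= 0:
        return EbgmResult(math.nan, math.nan, "zero expected count")
    l1 = _nb_logpmf(np.array(a, dtype=float), prior.alpha1, prior.beta1, np.array(E)) \
        + math.log(prior.pi)
    l2 = _nb_logpmf(np.array(a, dtype=float), prior.alpha2, prior.beta2, np.array(E)) \
        + math.log1p(-prior.pi)
    q = float(np.exp(l1 - np.logaddexp(l1, l2)))
    s1, r1 = prior.alpha1 + a, prior.beta1 + E
    s2, r2 = prior.alpha2 + a, prior.beta2 + E
    mean_log = q * (special.digamma(s1) - math.log(r1)) \
        + (1 - q) * (special.digamma(s2) - math.log(r2))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q * stats.gamma.cdf(x, s1, scale=1 / r1) \
            + (1 - q) * stats.gamma.cdf(x, s2, scale=1 / r2)

    lo = min(stats.gamma.ppf(0.05, s1, scale=1 / r1),
             stats.gamma.ppf(0.05, s2, scale=1 / r2))
    hi = max(stats.gamma.ppf(0.05, s1, scale=1 / r1),
             stats.gamma.ppf(0.05, s2, scale=1 / r2))
    lo, hi = max(lo * 0.5, 1e-300), hi * 2 + 1e-12
    while cdf(lo) > 0.05:
        lo *= 0.5
    while cdf(hi) < 0.05:
        hi *= 2
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi,
                                   xtol=quantile_tol, rtol=1e-12))
    return EbgmResult(ebgm, ebgm05)


# ---------------------------------------------------------------------------
# Table construction, flags, report
# ---------------------------------------------------------------------------

def _distinct_pairs(store: CaseStore, level: str, mapping: MedDRAMap | None,
                    drop_uncoded: bool) -> pd.DataFrame:
    reac = store.reac.dropna(subset=["pt"])[["primaryid", "pt"]].copy()
    if mapping is not None:
        if level == "SOC":
            reac["term"] = reac["pt"].map(lambda p: soc_of(p, mapping))
        else:
            reac["term"] = reac["pt"].map(lambda p: recode_pt(p, mapping))
    else:
        if level == "SOC":
            raise ValueError("SOC-level tables require a PT→SOC mapping")
        reac["term"] = reac["pt"]
    if drop_uncoded and level == "SOC":
        reac = reac[reac["term"] != UNCODED]
    return reac[["primaryid", "term"]].drop_duplicates()


def pair_counts(store: CaseStore, level: str = "PT",
                mapping: MedDRAMap | None = None,
                drop_uncoded: bool = False) -> pd.DataFrame:
    """Distinct (report, term) pair counts for the whole database.

    Returns one row per (PS-drug-agnostic) term with its total pair count;
    used for the MGPS prior fit, where every drug's cells enter.
    """
    pairs = _distinct_pairs(store, level, mapping, drop_uncoded)
    return pairs.groupby("term").size().rename("count").reset_index()


def build_tables(
    store: CaseStore,
    cohort_ids: pd.Index,
    level: str = "PT",
    mapping: MedDRAMap | None = None,
    drop_uncoded: bool = False,
) -> pd.DataFrame:
    """One 2×2 table per term with a ≥ 1, as a DataFrame [term, a, b, c, d].

    Margins are consistent across terms: a+b is the cohort's distinct-pair
    total and N the database's, so doubling-counting a repeated PT within
    one report is impossible by construction.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"unknown level {level!r}")
    pairs = _distinct_pairs(store, level, mapping, drop_uncoded)
    cohort = set(cohort_ids)
    in_cohort = pairs["primaryid"].isin(cohort)
    n_pairs = len(pairs)
    cohort_pairs = int(in_cohort.sum())
    a = pairs[in_cohort].groupby("term").size()
    all_counts = pairs.groupby("term").size()
    rows = []
    for term, a_t in a.sort_index().items():
        c_t = int(all_counts[term] - a_t)
        b_t = cohort_pairs - int(a_t)
        d_t = n_pairs - cohort_pairs - c_t
        rows.append((term, int(a_t), b_t, c_t, d_t))
    return pd.DataFrame(rows, columns=["term", "a", "b", "c", "d"])


@dataclass(frozen=True)
class SignalThresholds:
    """Positivity thresholds; defaults are the canonical literature values."""

    min_count: int = 3          # minimum a for ROR and PRR (MHRA rule)
    ror_lo: float = 1.0         # ROR lower 95% bound must exceed this
    prr_min: float = 2.0        # MHRA combined: PRR ≥ 2 ...
    chi2_min: float = 4.0       # ... and χ² ≥ 4
    ic025_min: float = 0.0      # IC025 > 0
    ebgm05_min: float = 2.0     # EBGM05 ≥ 2


def evaluate_signal(row: dict, thresholds: SignalThresholds = SignalThresholds()) -> dict:
    """Per-method positivity flags and the at-least-one-method verdict.

    Undefined statistics (NaN) flag negative for their method.
    """
    a = row["a"]
    th = thresholds

    def ok(x) -> bool:
        return x is not None and isinstance(x, (int, float)) and math.isfinite(x)

    flag_ror = ok(row.get("ror_lo95")) and a >= th.min_count and row["ror_lo95"] > th.ror_lo
    flag_prr = (
        ok(row.get("prr")) and ok(row.get("chi2"))
        and a >= th.min_count and row["prr"] >= th.prr_min and row["chi2"] >= th.chi2_min
    )
    flag_ic = ok(row.get("ic025")) and row["ic025"] > th.ic025_min
    flag_ebgm = ok(row.get("ebgm05")) and row["ebgm05"] >= th.ebgm05_min
    return {
        "flag_ror": bool(flag_ror),
        "flag_prr": bool(flag_prr),
        "flag_bcpnn": bool(flag_ic),
        "flag_mgps": bool(flag_ebgm),
        "positive": bool(flag_ror or flag_prr or flag_ic or flag_ebgm),
    }


def compute_signal_stats(
    tables: pd.DataFrame,
    prior: GPSPrior | None = None,
    thresholds: SignalThresholds = SignalThresholds(),
) -> pd.DataFrame:
    """All four statistics, interval bounds and flags for every term.

    *tables* is the output of :func:`build_tables`.  When *prior* is None
    the MGPS columns are NaN and its flag false (e.g. too few cells to fit).
    """
    records = []
    for row in tables.itertuples(index=False):
        t = Contingency2x2(row.a, row.b, row.c, row.d)
        r = ror(t)
        p = prr_chi2(t)
        ic = bcpnn_ic(t)
        if prior is not None:
            eb = ebgm_scores(t, prior)
        else:
            eb = EbgmResult(math.nan, math.nan, "no prior fitted")
        rec = {
            "term": row.term, "a": row.a, "b": row.b, "c": row.c, "d": row.d,
            "ror": r.est, "ror_lo95": r.lo95, "ror_hi95": r.hi95,
            "prr": p.est, "prr_lo95": p.lo95, "prr_hi95": p.hi95, "chi2": p.chi2,
            "ic": ic.ic, "ic025": ic.ic025,
            "ebgm": eb.ebgm, "ebgm05": eb.ebgm05,
        }
        rec.update(evaluate_signal(rec, thresholds))
        records.append(rec)
    return pd.DataFrame.from_records(records)


RANK_KEYS = {"frequency": "a", "ebgm": "ebgm", "ror": "ror"}


def rank_report(stats: pd.DataFrame, by: str = "frequency",
                top_n: int | None = 50) -> pd.DataFrame:
    """Stable descending sort by the chosen key, ties broken by term name."""
    if by not in RANK_KEYS:
        raise ValueError(f"unknown ranking key {by!r}")
    key = RANK_KEYS[by]
    out = stats.sort_values([key, "term"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out
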