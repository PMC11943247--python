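"""Time-to-onset analysis: onset intervals, Weibull model, incidence curve.

Onset is the whole-day interval from the earliest therapy start of the
target drug (THER) to the reported event date (DEMO).  Records with a
missing or partial date, or a negative interval, are marked unreliable —
with exactly one reason — and excluded from the summary, never silently
dropped.

The Weibull model f(t) = (β/α)(t/α)^{β−1} exp(−(t/α)^β) is fitted by
maximum likelihood on adjusted times t' = onset_days + 0.5 (the half-day
offset makes the day-0 point mass representable on the Weibull support; an
interval-censored likelihood treating day d as [d, d+1) is available as an
option).  β < 1 (upper CI below 1) marks a decreasing hazard — the
"early-failure" profile typical of administration-triggered reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._dates import days_between, is_full_date, is_partial_date
from .cohort import normalize_drugname
from .faers_io import CaseStore

__all__ = [
    "compute_onset",
    "OnsetSummary",
    "weibull_fit",
    "WeibullFit",
    "cumulative_incidence",
]

Z95 = 1.959963984540054

ONSET_BINS = [
    ("0 days", 0, 0),
    ("1-30 days", 1, 30),
    ("31-60 days", 31, 60),
    ("61-180 days", 61, 180),
    ("181-365 days", 181, 365),
    (">365 days", 366, None),
]


@dataclass
class OnsetSummary:
    n_linked: int            # cohort reports with a linked therapy row
    n_reliable: int
    n_unreliable: int
    median: float
    q1: float
    q3: float
    bins: list[tuple[str, int]]
    day0_percent: float      # share of reliable onsets at exactly 0 days

    def to_dict(self) -> dict:
        return {
            "n_linked": self.n_linked,
            "n_reliable": self.n_reliable,
            "n_unreliable": self.n_unreliable,
            "median_days": self.median,
            "iqr_days": [self.q1, self.q3],
            "bins": dict(self.bins),
            "day0_percent": self.day0_percent,
        }


def _classify_dates(start: object, event: object) -> str | None:
    """Unreliability reason, or None when both dates are complete."""
    for value in (start, event):
        if not isinstance(value, str) or value == "" or value is None \
                or (isinstance(value, float) and math.isnan(value)):
            return "missing date"
    if is_partial_date(start) or is_partial_date(event):
        return "partial date"
    if not is_full_date(start) or not is_full_date(event):
        return "missing date"  # unparseable ≡ not reported usably
    return None


def compute_onset(
    store: CaseStore,
    cohort_ids: pd.Index,
    drug_synonyms: list[str],
) -> tuple[pd.DataFrame, OnsetSummary]:
    """Per-report onset records and the summary (median, IQR, timeline bins).

    For each cohort report, therapy rows are linked through the drug
    sequence number of a primary-suspect row naming the target drug; the
    earliest fully-dated start is used.  Exactly one unreliability reason
    is recorded per excluded record ('missing date' > 'partial date' >
    'negative interval', in precedence).
    """
    cohort = set(cohort_ids)
    synonyms = {normalize_drugname(s) for s in drug_synonyms}
    drug = store.drug
    is_target = (
        (drug["role_cod"].astype(str).str.upper() == "PS")
        & (drug["drugname"].map(normalize_drugname).isin(synonyms)
           | (drug["prod_ai"].map(normalize_drugname).isin(synonyms)
              if "prod_ai" in drug.columns else False))
        & drug["primaryid"].isin(cohort)
    )
    target_seqs = drug.loc[is_target, ["primaryid", "drug_seq"]].astype(str)
    ther = store.ther.copy()
    ther["dsg_drug_seq"] = ther["dsg_drug_seq"].astype(str)
    linked = target_seqs.merge(
        ther, left_on=["primaryid", "drug_seq"],
        right_on=["primaryid", "dsg_drug_seq"], how="inner")

    event_of = store.demo.drop_duplicates("primaryid").set_index("primaryid")["event_dt"]

    records = []
    for pid, grp in linked.groupby("primaryid", sort=True):
        starts = [s for s in grp["start_dt"] if is_full_date(s)]
        # earliest complete start; if none complete, fall back to the raw
        # field for reason classification
        if starts:
            start = min(starts)
        else:
            raw = [s for s in grp["start_dt"] if isinstance(s, str) and s]
            start = raw[0] if raw else None
        event = event_of.get(pid)
        reason = _classify_dates(start, event)
        if reason is None:
            onset = days_between(start, event)
            if onset < 0:
                records.append((pid, None, False, "negative interval"))
            else:
                records.append((pid, onset, True, None))
        else:
            records.append((pid, None, False, reason))
    onsets = pd.DataFrame(records, columns=["primaryid", "onset_days", "reliable", "reason"])

    reliable = onsets.loc[onsets["reliable"], "onset_days"].astype(float)
    n_rel = len(reliable)
    if n_rel:
        q1, med, q3 = reliable.quantile([0.25, 0.5, 0.75])
        day0 = float((reliable == 0).mean() * 100)
        bins = []
        for label, lo, hi in ONSET_BINS:
            mask = reliable >= lo
            if hi is not None:
                mask &= reliable <= hi
            bins.append((label, int(mask.sum())))
    else:
        q1 = med = q3 = math.nan
        day0 = math.nan
        bins = [(label, 0) for label, _, _ in ONSET_BINS]
    summary = OnsetSummary(
        n_linked=len(onsets),
        n_reliable=n_rel,
        n_unreliable=int((~onsets["reliable"]).sum()),
        median=float(med), q1=float(q1), q3=float(q3),
        bins=bins, day0_percent=round(day0, 2) if math.isfinite(day0) else day0,
    )
    return onsets, summary


@dataclass
class WeibullFit:
    """Maximum-likelihood Weibull fit with observed-information CIs."""

    shape: float
    shape_lo95: float
    shape_hi95: float
    scale: float
    scale_lo95: float
    scale_hi95: float
    loglik: float
    n_used: int
    classification: str     # early-failure | random | wear-out | indeterminate
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "shape": self.shape, "shape_ci95": [self.shape_lo95, self.shape_hi95],
            "scale_days": self.scale, "scale_ci95": [self.scale_lo95, self.scale_hi95],
            "loglik": self.loglik, "n_used": self.n_used,
            "classification": self.classification, "reason": self.reason,
        }


def _weibull_nll_exact(theta: np.ndarray, t: np.ndarray) -> float:
    log_shape, log_scale = theta
    beta, alpha = math.exp(log_shape), math.exp(log_scale)
    z = t / alpha
    return -float(np.sum(
        math.log(beta) - math.log(alpha) + (beta - 1) * np.log(z) - z ** beta))


def _weibull_nll_interval(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    log_shape, log_scale = theta
    beta, alpha = math.exp(log_shape), math.exp(log_scale)

    def sf(x):
        return np.exp(-((x / alpha) ** beta))

    p = np.clip(sf(lo) - sf(hi), 1e-300, None)
    return -float(np.sum(np.log(p)))


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def weibull_fit(
    onset_days: np.ndarray | pd.Series,
    day_offset: float = 0.5,
    interval_censored: bool = False,
    min_n: int = 10,
) -> WeibullFit:
    """Fit the Weibull onset model and classify the hazard profile.

    Default likelihood: exact density at t' = onset_days + *day_offset*.
    ``interval_censored=True`` instead scores day d by P(t ∈ [d, d+1)),
    which needs no offset.  CIs come from the observed information on
    (log shape, log scale); classification: early-failure when the shape's
    upper CI < 1, wear-out when its lower CI > 1, random when the CI
    contains 1, indeterminate when the fit is impossible.
    """
    days = np.asarray(pd.Series(onset_days).dropna(), dtype=float)
    nan_fit = dict(shape=math.nan, shape_lo95=math.nan, shape_hi95=math.nan,
                   scale=math.nan, scale_lo95=math.nan, scale_hi95=math.nan,
                   loglik=math.nan, n_used=len(days))
    if len(days) < min_n:
        return WeibullFit(**nan_fit, classification="indeterminate",
                          reason=f"fewer than {min_n} reliable records")
    if np.unique(days).size == 1:
        return WeibullFit(**nan_fit, classification="indeterminate",
                          reason="degenerate data (all onsets identical)")
    if interval_censored:
        lo, hi = days, days + 1.0
        nll = lambda th: _weibull_nll_interval(th, lo, hi)
    else:
        t = days + day_offset
        nll = lambda th: _weibull_nll_exact(th, t)
    t_adj = days + day_offset
    theta0 = np.array([0.0, math.log(max(float(np.mean(t_adj)), 1e-3))])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success or not np.all(np.isfinite(res.x)):
        return WeibullFit(**nan_fit, classification="indeterminate",
                          reason=f"optimiser failure: {res.message}")
    H = _numeric_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.array([math.nan, math.nan])
    shape, scale = math.exp(res.x[0]), math.exp(res.x[1])
    sh_lo, sh_hi = shape * math.exp(-Z95 * se[0]), shape * math.exp(Z95 * se[0])
    sc_lo, sc_hi = scale * math.exp(-Z95 * se[1]), scale * math.exp(Z95 * se[1])
    if not np.all(np.isfinite(se)):
        classification = "indeterminate"
        reason = "singular observed information"
    elif sh_hi < 1.0:
        classification, reason = "early-failure", None
    elif sh_lo > 1.0:
        classification, reason = "wear-out", None
    else:
        classification, reason = "random", None
    return WeibullFit(
        shape=shape, shape_lo95=sh_lo, shape_hi95=sh_hi,
        scale=scale, scale_lo95=sc_lo, scale_hi95=sc_hi,
        loglik=-float(res.fun), n_used=len(days),
        classification=classification, reason=reason,
    )


def cumulative_incidence(onset_days: np.ndarray | pd.Series) -> pd.DataFrame:
    """Empirical CDF of onset days as a step curve [day, cum_frac].

    Monotone non-decreasing; the last value is exactly 1.0.
    """
    days = np.asarray(pd.Series(onset_days).dropna(), dtype=float)
    if len(days) == 0:
        raise ValueError("no reliable onset records")
    values, counts = np.unique(days, return_counts=True)
    frac = np.cumsum(counts) / len(days)
    frac[-1] = 1.0
    return pd.DataFrame({"day": values, "cum_frac": frac})
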