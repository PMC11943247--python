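"""Primary-suspect cohort selection and descriptive demographics.

A case enters the cohort when at least one of its drug rows carries the
primary-suspect role (``PS``) and a drug name (or active ingredient)
matching the target drug's synonym list after normalisation.  The
descriptive summary mirrors the usual "Table 1" of FAERS safety studies:
sex, age bands, reporter occupation, severity, reporting year and top
reporting countries, with percentages of the cohort total.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .faers_io import CaseStore

__all__ = [
    "select_primary_suspect",
    "severity_flags",
    "summarize_demographics",
    "DemographicsSummary",
    "percentage",
    "AGE_UNIT_TO_YEARS",
    "SERIOUS_OUTCOME_CODES",
]

#: FAERS outcome codes that mark a report as serious (FDA convention).
SERIOUS_OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI"}

#: Multiplicative factor from one unit of the coded age field to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8765.8,
}

AGE_BANDS = ["<18", "18-44", "45-64", ">=65", "Not specified"]

REPORTER_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "HP": "Other health professionals",
}


def percentage(count: int, total: int) -> float:
    """100·count/total rounded half-up to 2 decimals (table convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def normalize_drugname(name: object) -> str:
    """Trim, uppercase, strip edge punctuation and collapse whitespace."""
    if not isinstance(name, str):
        return ""
    s = re.sub(r"\s+", " ", name.strip().upper())
    return s.strip(" .,:;!?*\"'()[]")


def select_primary_suspect(
    store: CaseStore,
    drug_synonyms: list[str],
    match: str = "exact",
) -> pd.Index:
    """PRIMARYIDs whose report names the target drug as primary suspect.

    ``match='exact'`` compares normalised names for equality (default);
    ``match='substring'`` accepts any normalised name containing a synonym.
    Reports without any reaction row are excluded (a safety report must
    describe at least one event).
    """
    if not drug_synonyms:
        raise ValueError("drug synonym list must be non-empty")
    if match not in ("exact", "substring"):
        raise ValueError(f"unknown match mode {match!r}")
    synonyms = {normalize_drugname(s) for s in drug_synonyms}
    drug = store.drug
    ps = drug[drug["role_cod"].astype(str).str.upper() == "PS"]
    names = ps["drugname"].map(normalize_drugname)
    if "prod_ai" in ps.columns:
        ais = ps["prod_ai"].map(normalize_drugname)
    else:
        ais = pd.Series("", index=ps.index)
    if match == "exact":
        hit = names.isin(synonyms) | ais.isin(synonyms)
    else:
        pattern = "|".join(re.escape(s) for s in sorted(synonyms))
        hit = names.str.contains(pattern) | ais.str.contains(pattern)
    ids = set(ps.loc[hit, "primaryid"])
    with_reac = set(store.reac.loc[store.reac["pt"].notna(), "primaryid"])
    keep = [pid for pid in store.demo["primaryid"] if pid in ids and pid in with_reac]
    return pd.Index(keep, name="primaryid")


def severity_flags(store: CaseStore) -> pd.Series:
    """Per-PRIMARYID boolean: any serious outcome code (DE/LT/HO/DS/CA/RI).

    Reports without outcome rows are non-severe (no seriousness criterion
    was reported).
    """
    outc = store.outc
    serious_ids = set(
        outc.loc[outc["outc_cod"].astype(str).str.upper().isin(SERIOUS_OUTCOME_CODES),
                 "primaryid"]
    )
    return pd.Series(
        [pid in serious_ids for pid in store.demo["primaryid"]],
        index=pd.Index(store.demo["primaryid"]),
        dtype=bool,
    )


def age_in_years(age: object, unit: object) -> float:
    """Convert a coded age to years; NaN when unconvertible."""
    try:
        value = float(age)
    except (TypeError, ValueError):
        return math.nan
    unit_s = str(unit).strip().upper() if isinstance(unit, str) else "YR"
    if unit_s in ("", "NAN"):
        unit_s = "YR"  # FAERS convention: blank unit defaults to years
    factor = AGE_UNIT_TO_YEARS.get(unit_s)
    if factor is None or not math.isfinite(value):
        return math.nan
    return value * factor


def _age_band(years: float) -> str:
    if not math.isfinite(years):
        return "Not specified"
    if years < 18:
        return "<18"
    if years < 45:
        return "18-44"
    if years < 65:
        return "45-64"
    return ">=65"


@dataclass
class DemographicsSummary:
    """Counts and percentages per category, cohort-total denominated."""

    total_reports: int
    total_events: int
    sex: list[tuple[str, int, float]]
    age_bands: list[tuple[str, int, float]]
    age_median: float
    age_q1: float
    age_q3: float
    reporter: list[tuple[str, int, float]]
    severity: list[tuple[str, int, float]]
    year: list[tuple[str, int, float]]
    countries: list[tuple[str, int, float]]

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=1, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_tsv(self) -> str:
        """Table-1-shaped TSV: characteristic, category, count, percent."""
        lines = ["characteristic\tcategory\tcount\tpercent"]
        lines.append(f"Number of AE reports\t\t{self.total_reports}\t")
        lines.append(f"Number of AEs\t\t{self.total_events}\t")
        for block, rows in [
            ("Sex", self.sex), ("Age", self.age_bands), ("Reporter", self.reporter),
            ("Severity", self.severity), ("Reporting year", self.year),
            ("Top reporting countries", self.countries),
        ]:
            for cat, n, pct in rows:
                lines.append(f"{block}\t{cat}\t{n}\t{pct:.2f}")
        return "\n".join(lines) + "\n"


def summarize_demographics(store: CaseStore, cohort_ids: pd.Index,
                           top_countries: int = 5) -> DemographicsSummary:
    """Descriptive summary of the cohort (counts, percentages, age quartiles).

    Category counts within each breakdown sum to the cohort total (a
    "Not specified" bucket absorbs missing values); percentages are
    100·count/total rounded half-up to 2 decimals.  ``total_events`` counts
    distinct (report, PT) pairs.
    """
    cohort = set(cohort_ids)
    total = len(cohort)
    if total == 0:
        raise ValueError("empty cohort: no demographics to summarise")
    demo = store.demo[store.demo["primaryid"].isin(cohort)]
    reac = store.reac[store.reac["primaryid"].isin(cohort)]
    total_events = len(reac.dropna(subset=["pt"]).drop_duplicates(["primaryid", "pt"]))

    def breakdown(series: pd.Series, order: list[str] | None = None,
                  missing_label: str = "Not specified") -> list[tuple[str, int, float]]:
        filled = series.fillna(missing_label).replace("", missing_label)
        counts = filled.value_counts()
        cats = order if order is not None else list(counts.index)
        rows = []
        for cat in cats:
            n = int(counts.get(cat, 0))
            rows.append((cat, n, percentage(n, total)))
        return rows

    sex = breakdown(demo.get("sex"), order=["M", "F", "Not specified"])

    ages = pd.Series(
        [age_in_years(a, u) for a, u in zip(demo.get("age"), demo.get("age_cod"))],
        index=demo.index,
    )
    bands = ages.map(_age_band)
    age_rows = breakdown(bands, order=AGE_BANDS)
    known = ages[np.isfinite(ages)]
    if len(known):
        q1, med, q3 = known.quantile([0.25, 0.5, 0.75])
    else:
        q1 = med = q3 = math.nan

    reporter = demo.get("occp_cod").map(
        lambda c: REPORTER_LABELS.get(str(c).strip().upper(), np.nan)
        if isinstance(c, str) else np.nan)
    reporter_rows = breakdown(reporter, order=list(REPORTER_LABELS.values()) + ["Not specified"])

    sev = severity_flags(store)
    sev_cohort = sev.loc[sev.index.isin(cohort)]
    n_severe = int(sev_cohort.sum())
    severity_rows = [
        ("Severe", n_severe, percentage(n_severe, total)),
        ("Non-severe", total - n_severe, percentage(total - n_severe, total)),
    ]

    years = demo["fda_dt"].astype(str).str[:4]
    year_rows = breakdown(years, order=sorted(years.unique()))

    country_counts = demo.get("reporter_country").fillna("Not specified").value_counts()
    country_rows = [
        (str(c), int(n), percentage(int(n), total))
        for c, n in country_counts.head(top_countries).items()
    ]

    return DemographicsSummary(
        total_reports=total,
        total_events=total_events,
        sex=sex,
        age_bands=age_rows,
        age_median=float(med),
        age_q1=float(q1),
        age_q3=float(q3),
        reporter=reporter_rows,
        severity=severity_rows,
        year=year_rows,
        countries=country_rows,
    )
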