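"""Synthetic FAERS-like quarterly packages with known ground truth.

The generator emulates the structural features of the public FAERS archive
that matter for a single-drug safety analysis:

- quarterly ``$``-delimited ASCII tables (DEMO/DRUG/REAC/THER/OUTC), one
  file per table and quarter, plus per-quarter deletion lists for quarters
  from 2019Q1 onward;
- case duplication across quarters: a duplicated case re-appears under the
  same CASEID with an incremented PRIMARYID and a later FDA_DT, and the
  latest version is the one a correct deduplication must retain;
- role-coded drug rows (primary suspect vs concomitant), PT-coded reactions
  under a fixed PT→SOC table, demographic fields with configurable
  missingness, and partially-specified dates (YYYYMM / YYYY);
- drug–event counts drawn as Poisson around the independence expectation
  times a per-pair relative risk, with a configurable list of planted
  elevated-risk pairs and a gamma-mixture background;
- onset times built as therapy start plus a Weibull draw with a point mass
  at day 0, so the event date is derived from the start date, never sampled
  independently.

Everything the generator decides is returned (and serialised) as a
:class:`GroundTruth`, so every downstream stage — parsing, deduplication,
cohort selection, disproportionality, time-to-onset — can be tested against
known truth without any download.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._dates import date_str

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_package",
    "ground_truth_signal_set",
    "SOC_NAMES",
]

#: The 27 MedDRA system organ classes (primary SOC vocabulary of the toy
#: dictionary the generator writes alongside the package).
SOC_NAMES = [
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Congenital, familial and genetic disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Eye disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Nervous system disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Product issues",
    "Psychiatric disorders",
    "Renal and urinary disorders",
    "Reproductive system and breast disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Social circumstances",
    "Surgical and medical procedures",
    "Vascular disorders",
]

SERIOUS_OUTCOMES = ["DE", "LT", "HO", "DS", "CA", "RI"]

#: Default background relative-risk prior: 2-component gamma mixture
#: (shape1, rate1, shape2, rate2, weight-of-component-1).  With these values
#: the mixture mean is exactly 1 (1/3·2 + 2/3·0.5), i.e. the background is
#: unbiased around independence while allowing realistic overdispersion.
DEFAULT_BACKGROUND_PRIOR = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _parse_quarter(label: str) -> tuple[int, int]:
    """'2024Q3' -> (2024, 3); raises ValueError on malformed labels."""
    try:
        year_s, q_s = label.upper().split("Q")
        year, q = int(year_s), int(q_s)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed quarter label: {label!r}") from exc
    if not (1 <= q <= 4) or not (1900 <= year <= 2200):
        raise ValueError(f"malformed quarter label: {label!r}")
    return year, q


def quarter_code(label: str) -> str:
    """'2024Q3' -> '24Q3' (the code used in FAERS file names)."""
    year, q = _parse_quarter(label)
    return f"{year % 100:02d}Q{q}"


def quarter_dates(label: str) -> tuple[_dt.date, _dt.date]:
    year, q = _parse_quarter(label)
    start = _dt.date(year, 3 * (q - 1) + 1, 1)
    end_month = 3 * q
    last_day = (_dt.date(year + (end_month == 12), end_month % 12 + 1, 1) - _dt.timedelta(days=1))
    return start, last_day


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic FAERS package.

    Drug index 0 is the target (suspect) drug; indices ``1..n_drugs`` are
    background drugs.  ``planted_signals`` entries are
    ``(drug_index, event_index, relative_risk)`` with relative risk > 1.
    """

    n_drugs: int = 25                      # background drugs (target drug is extra)
    n_events: int = 60                     # PT vocabulary size
    n_reports: int = 5000
    quarters: tuple[str, ...] = ("2023Q4", "2024Q1", "2024Q2", "2024Q3")
    target_drug: str = "REGADENOSON"
    target_synonym: str = "LEXISCAN"       # trade name used on a fraction of rows
    planted_signals: list[tuple[int, int, float]] = field(default_factory=list)
    #: gamma-mixture (shape1, rate1, shape2, rate2, weight1) for background
    #: relative risks; ``None`` pins every non-planted pair at exactly 1.
    background_prior: tuple[float, float, float, float, float] | None = DEFAULT_BACKGROUND_PRIOR
    duplication_rate: float = 0.05
    deletion_rate: float = 0.02
    onset_shape: float = 0.6               # Weibull shape for non-day-0 onsets
    onset_scale: float = 5.0               # Weibull scale, days
    day0_mass: float = 0.99                # probability an onset is exactly day 0
    events_per_report_mean: float = 2.4
    concomitant_rate: float = 0.3          # probability a report lists an extra C-role drug
    synonym_fraction: float = 0.15         # target-drug rows written under the trade name
    partial_date_fraction: float = 0.05    # event/start dates truncated to YYYYMM or YYYY
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.44,
            "sex": 0.20,
            "occp_cod": 0.04,
            "event_dt": 0.35,
            "start_dt": 0.35,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_drugs < 1 or self.n_events < 1 or self.n_reports < 1:
            raise ValueError("n_drugs, n_events and n_reports must be positive")
        if not self.quarters:
            raise ValueError("at least one quarter is required")
        for label in self.quarters:
            _parse_quarter(label)
        probs = {
            "duplication_rate": self.duplication_rate,
            "deletion_rate": self.deletion_rate,
            "day0_mass": self.day0_mass,
            "concomitant_rate": self.concomitant_rate,
            "synonym_fraction": self.synonym_fraction,
            "partial_date_fraction": self.partial_date_fraction,
            **{f"missingness[{k}]": v for k, v in self.missingness.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.onset_shape <= 0 or self.onset_scale <= 0:
            raise ValueError("onset_shape and onset_scale must be positive")
        for d, e, lam in self.planted_signals:
            if not (0 <= d <= self.n_drugs):
                raise ValueError(f"planted drug index {d} out of bounds")
            if not (0 <= e < self.n_events):
                raise ValueError(f"planted event index {e} out of bounds")
            if lam <= 0:
                raise ValueError("planted relative risks must be positive")
        if self.background_prior is not None:
            a1, b1, a2, b2, pi = self.background_prior
            if min(a1, b1, a2, b2) <= 0 or not (0 < pi < 1):
                raise ValueError("invalid background gamma-mixture parameters")


@dataclass
class GroundTruth:
    """Everything the generator decided, for downstream verification."""

    config: dict
    drug_names: list[str]
    event_pts: list[str]
    event_socs: list[str]
    lambda_: list[list[float]]             # (n_drugs+1) × n_events true relative risks
    expected_counts: list[list[float]]     # independence expectation per pair
    planted_signals: list[tuple[int, int, float]]
    n_raw_demo_rows: int
    n_cases: int
    duplicate_caseids: list[str]
    deleted_caseids: list[str]
    retained_primaryids: list[str]         # latest version per case (before deletions)
    target_caseids: list[str]              # cases whose PS drug is the target
    onset_days: dict[str, int]             # caseid -> true onset, where both dates were
                                           # emitted complete (the 'reliable' subset)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_signals"] = [tuple(x) for x in raw["planted_signals"]]
        return cls(**raw)


def ground_truth_signal_set(truth: GroundTruth) -> set[tuple[int, int]]:
    """The planted (drug index, event index) pairs — the reference set for
    signal-recovery tests."""
    return {(d, e) for d, e, _ in truth.planted_signals}


def _draw_lambda(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n_rows = cfg.n_drugs + 1
    if cfg.background_prior is None:
        lam = np.ones((n_rows, cfg.n_events))
    else:
        a1, b1, a2, b2, pi = cfg.background_prior
        comp1 = rng.random((n_rows, cfg.n_events)) < pi
        lam = np.where(
            comp1,
            rng.gamma(a1, 1.0 / b1, size=(n_rows, cfg.n_events)),
            rng.gamma(a2, 1.0 / b2, size=(n_rows, cfg.n_events)),
        )
        lam = np.maximum(lam, 1e-6)
    for d, e, l in cfg.planted_signals:
        lam[d, e] = l
    return lam


def _rand_date(rng: np.random.Generator, lo: _dt.date, hi: _dt.date) -> _dt.date:
    span = (hi - lo).days
    return lo + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _maybe_truncate(rng: np.random.Generator, s: str, p: float) -> str:
    if rng.random() < p:
        return s[:6] if rng.random() < 0.5 else s[:4]
    return s


def generate_package(config: GeneratorConfig, out_dir: str | os.PathLike) -> GroundTruth:
    """Write a FAERS-like quarterly package under *out_dir*; return ground truth.

    Files written: ``DEMO<yy>Q<q>.txt`` (and DRUG/REAC/THER/OUTC likewise)
    for each quarter, ``DELETED<yy>Q<q>.txt`` for quarters ≥ 2019Q1,
    ``pt_soc_map.tsv`` (the toy PT→SOC dictionary) and
    ``ground_truth.json``.
    """
    config.validate()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    drug_names = [config.target_drug] + [f"DRUG{i:04d}" for i in range(1, config.n_drugs + 1)]
    event_pts = [f"Adverse event pt {i:03d}" for i in range(config.n_events)]
    event_socs = [SOC_NAMES[i % len(SOC_NAMES)] for i in range(config.n_events)]

    lam = _draw_lambda(config, rng)

    # --- assign each report a primary-suspect drug (uniform over vocabulary)
    ps_drug = rng.integers(0, config.n_drugs + 1, size=config.n_reports)
    n_per_drug = np.bincount(ps_drug, minlength=config.n_drugs + 1)

    # --- base event probabilities: mildly uneven, scaled to the target
    # events-per-report mean (pair counts then follow Poisson(E·λ))
    q_raw = rng.dirichlet(np.full(config.n_events, 4.0))
    q_scaled = q_raw * config.events_per_report_mean

    expected = n_per_drug[:, None] * q_scaled[None, :]
    report_events: list[set[int]] = [set() for _ in range(config.n_reports)]
    reports_by_drug = [np.flatnonzero(ps_drug == d) for d in range(config.n_drugs + 1)]
    for d in range(config.n_drugs + 1):
        members = reports_by_drug[d]
        if members.size == 0:
            continue
        counts = rng.poisson(expected[d] * lam[d])
        for e in range(config.n_events):
            k = min(int(counts[e]), members.size)
            if k == 0:
                continue
            for r in rng.choice(members, size=k, replace=False):
                report_events[int(r)].add(e)
    # every report must mention at least one reaction
    for r in range(config.n_reports):
        if not report_events[r]:
            report_events[r].add(int(rng.choice(config.n_events, p=q_raw)))

    # --- per-report attributes -------------------------------------------
    quarters = list(config.quarters)
    q_bounds = {q: quarter_dates(q) for q in quarters}
    miss = config.missingness

    sexes = rng.choice(["F", "M", ""], size=config.n_reports, p=[0.50, 0.30, 0.20])
    sex_missing = rng.random(config.n_reports) < miss.get("sex", 0.0)
    occp = rng.choice(["CN", "PH", "MD", "HP"], size=config.n_reports, p=[0.55, 0.24, 0.19, 0.02])
    occp_missing = rng.random(config.n_reports) < miss.get("occp_cod", 0.0)
    countries = rng.choice(["US", "GB", "DE", "SE", "FR"], size=config.n_reports,
                           p=[0.98, 0.008, 0.005, 0.004, 0.003])
    ages = np.clip(rng.normal(66.0, 15.0, size=config.n_reports), 1.0, 95.0)
    age_missing = rng.random(config.n_reports) < miss.get("age", 0.0)
    age_units = rng.choice(["YR", "YR", "YR", "MON", "DY"], size=config.n_reports)

    onset0 = rng.random(config.n_reports) < config.day0_mass
    weib = config.onset_scale * rng.weibull(config.onset_shape, size=config.n_reports)
    onset_days_true = np.where(onset0, 0, np.floor(weib).astype(int))

    start_missing = rng.random(config.n_reports) < miss.get("start_dt", 0.0)
    event_missing = rng.random(config.n_reports) < miss.get("event_dt", 0.0)

    report_quarter = rng.integers(0, len(quarters), size=config.n_reports)
    dup_mask = rng.random(config.n_reports) < config.duplication_rate
    del_mask = rng.random(config.n_reports) < config.deletion_rate

    deletion_quarters = [q for q in quarters if _parse_quarter(q) >= (2019, 1)]

    demo_rows: dict[str, list[list[str]]] = {q: [] for q in quarters}
    drug_rows: dict[str, list[list[str]]] = {q: [] for q in quarters}
    reac_rows: dict[str, list[list[str]]] = {q: [] for q in quarters}
    ther_rows: dict[str, list[list[str]]] = {q: [] for q in quarters}
    outc_rows: dict[str, list[list[str]]] = {q: [] for q in quarters}
    deletions: dict[str, list[str]] = {q: [] for q in deletion_quarters}

    duplicate_caseids: list[str] = []
    deleted_caseids: list[str] = []
    retained_primaryids: list[str] = []
    target_caseids: list[str] = []
    onset_truth: dict[str, int] = {}
    n_raw = 0

    for r in range(config.n_reports):
        caseid = str(10_000_000 + r)
        q_label = quarters[report_quarter[r]]
        q_lo, q_hi = q_bounds[q_label]
        fda = _rand_date(rng, q_lo, q_hi)
        start = fda - _dt.timedelta(days=int(rng.integers(0, 30)))
        event = start + _dt.timedelta(days=int(onset_days_true[r]))

        start_s = "" if start_missing[r] else _maybe_truncate(
            rng, date_str(start), config.partial_date_fraction)
        event_s = "" if event_missing[r] else _maybe_truncate(
            rng, date_str(event), config.partial_date_fraction)

        if ages[r] is not None and not age_missing[r]:
            unit = age_units[r]
            if unit == "YR":
                age_s = str(int(round(ages[r])))
            elif unit == "MON":
                age_s = str(int(round(ages[r] * 12)))
            else:
                age_s = str(int(round(ages[r] * 365.25)))
        else:
            age_s, unit = "", ""
        sex_s = "" if sex_missing[r] else str(sexes[r])
        occp_s = "" if occp_missing[r] else str(occp[r])

        d_idx = int(ps_drug[r])
        ps_name = drug_names[d_idx]
        if d_idx == 0 and rng.random() < config.synonym_fraction:
            ps_written = config.target_synonym
        else:
            ps_written = ps_name

        versions = [(1, q_label, fda)]
        if dup_mask[r]:
            later_q_idx = min(int(report_quarter[r]) + 1, len(quarters) - 1)
            later_label = quarters[later_q_idx]
            later_fda = fda + _dt.timedelta(days=int(rng.integers(10, 120)))
            lo2, hi2 = q_bounds[later_label]
            later_fda = max(min(later_fda, hi2), max(lo2, fda + _dt.timedelta(days=1)))
            versions.append((2, later_label, later_fda))
            duplicate_caseids.append(caseid)

        init_fda_s = date_str(fda)
        for version, v_label, v_fda in versions:
            primaryid = f"{caseid}{version}"
            n_raw += 1
            demo_rows[v_label].append([
                primaryid, caseid, date_str(v_fda), event_s, age_s, unit,
                sex_s, occp_s, str(countries[r]), init_fda_s,
            ])
            drug_rows[v_label].append([primaryid, caseid, "1", "PS", ps_written, ps_name])
            if rng.random() < config.concomitant_rate:
                other = drug_names[int(rng.integers(0, config.n_drugs + 1))]
                drug_rows[v_label].append([primaryid, caseid, "2", "C", other, other])
            for e in sorted(report_events[r]):
                reac_rows[v_label].append([primaryid, caseid, event_pts[e]])
            ther_rows[v_label].append([primaryid, caseid, "1", start_s, ""])
            if rng.random() < 0.55:
                code = SERIOUS_OUTCOMES[int(rng.integers(0, len(SERIOUS_OUTCOMES)))]
                outc_rows[v_label].append([primaryid, caseid, code])
            elif rng.random() < 0.5:
                outc_rows[v_label].append([primaryid, caseid, "OT"])

        retained_primaryids.append(f"{caseid}{versions[-1][0]}")

        is_deleted = bool(del_mask[r]) and deletion_quarters
        if is_deleted:
            deleted_caseids.append(caseid)
            deletions[deletion_quarters[int(rng.integers(0, len(deletion_quarters)))]].append(caseid)

        if d_idx == 0 and not is_deleted:
            target_caseids.append(caseid)
            if not start_missing[r] and not event_missing[r] \
                    and len(start_s) == 8 and len(event_s) == 8:
                onset_truth[caseid] = int(onset_days_true[r])

    # --- write files ------------------------------------------------------
    headers = {
        "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
                 "sex", "occp_cod", "reporter_country", "init_fda_dt"],
        "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        "REAC": ["primaryid", "caseid", "pt"],
        "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
        "OUTC": ["primaryid", "caseid", "outc_cod"],
    }
    all_rows = {"DEMO": demo_rows, "DRUG": drug_rows, "REAC": reac_rows,
                "THER": ther_rows, "OUTC": outc_rows}
    for table, by_quarter in all_rows.items():
        for q_label in quarters:
            path = os.path.join(out_dir, f"{table}{quarter_code(q_label)}.txt")
            with open(path, "w") as fh:
                fh.write("$".join(headers[table]) + "\n")
                for row in by_quarter[q_label]:
                    fh.write("$".join(row) + "\n")
    for q_label in deletion_quarters:
        path = os.path.join(out_dir, f"DELETED{quarter_code(q_label)}.txt")
        with open(path, "w") as fh:
            for caseid in deletions[q_label]:
                fh.write(caseid + "\n")

    with open(os.path.join(out_dir, "pt_soc_map.tsv"), "w") as fh:
        fh.write("pt\tsoc\told_pt\n")
        for pt, soc in zip(event_pts, event_socs):
            fh.write(f"{pt}\t{soc}\t\n")

    truth = GroundTruth(
        config=dataclasses.asdict(config),
        drug_names=drug_names,
        event_pts=event_pts,
        event_socs=event_socs,
        lambda_=lam.tolist(),
        expected_counts=expected.tolist(),
        planted_signals=[(int(d), int(e), float(l)) for d, e, l in config.planted_signals],
        n_raw_demo_rows=n_raw,
        n_cases=config.n_reports,
        duplicate_caseids=duplicate_caseids,
        deleted_caseids=deleted_caseids,
        retained_primaryids=retained_primaryids,
        target_caseids=target_caseids,
        onset_days=onset_truth,
    )
    truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    return truth
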