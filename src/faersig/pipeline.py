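"""One-shot orchestration: ingest → code → cohort → signals → onset.

`run_pipeline` runs the whole analysis reproducibly and writes a report
bundle (demographics summary, PT- and SOC-level signal tables, onset
summary and cumulative-incidence curve) plus a run manifest that mirrors
the filtering funnel: raw rows, unique cases, after deduplication, after
deletions, cohort size, distinct pairs, reliable onsets.

Report TSVs format statistics to 2 decimals so reruns are byte-identical;
JSON artefacts retain full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .cohort import select_primary_suspect, summarize_demographics
from .disproportionality import (
    GPSFitError,
    SignalThresholds,
    build_tables,
    compute_signal_stats,
    fit_gps_prior,
    rank_report,
)
from .faers_io import build_case_store, load_package
from .meddra import load_meddra_tsv
from .synthetic_faers import _parse_quarter
from .tto import compute_onset, cumulative_incidence, weibull_fit

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    package_dir: str
    quarters: list[str]
    dictionary_path: str
    out_dir: str
    drug: str = "REGADENOSON"
    synonyms: list[str] = field(default_factory=lambda: ["LEXISCAN"])
    match: str = "exact"
    levels: tuple[str, ...] = ("PT", "SOC")
    top_n: int = 50
    rank_by: str = "frequency"
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    tto_day_offset: float = 0.5
    tto_interval_censored: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not os.path.isdir(self.package_dir):
            raise FileNotFoundError(f"package directory not found: {self.package_dir}")
        if not os.path.isfile(self.dictionary_path):
            raise FileNotFoundError(f"dictionary not found: {self.dictionary_path}")
        for q in self.quarters:
            _parse_quarter(q)  # raises naming the malformed label


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_STAT_COLUMNS = ["ror", "ror_lo95", "ror_hi95", "prr", "prr_lo95", "prr_hi95",
                 "chi2", "ic", "ic025", "ebgm", "ebgm05"]


def _format_signals(stats: pd.DataFrame) -> pd.DataFrame:
    out = stats.copy()
    for col in _STAT_COLUMNS:
        out[col] = out[col].map(lambda x: f"{x:.2f}" if pd.notna(x) else "NA")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artefacts written before the failure are preserved in ``out_dir``.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "software": {"name": "faersig", "version": __version__},
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "thresholds"},
            "thresholds": dataclasses.asdict(config.thresholds),
        },
        "inputs": {},
        "funnel": {},
    }

    stage = "ingest"
    try:
        tables = load_package(config.package_dir, config.quarters)
        for fname in sorted(os.listdir(config.package_dir)):
            path = os.path.join(config.package_dir, fname)
            if os.path.isfile(path) and fname.upper().endswith(".TXT"):
                manifest["inputs"].setdefault("files", {})[fname] = _sha256(path)
        store = build_case_store(tables)
        manifest["funnel"]["raw_demo_rows"] = store.n_raw_reports
        manifest["funnel"]["unique_cases"] = store.n_unique_cases
        manifest["funnel"]["after_dedup"] = store.n_after_dedup
        manifest["funnel"]["deleted"] = store.n_deleted
        manifest["funnel"]["retained"] = len(store.demo)

        stage = "coding"
        mapping = load_meddra_tsv(config.dictionary_path)

        stage = "cohort"
        synonyms = [config.drug] + list(config.synonyms)
        cohort_ids = select_primary_suspect(store, synonyms, match=config.match)
        manifest["funnel"]["cohort_reports"] = len(cohort_ids)
        summary = summarize_demographics(store, cohort_ids)
        summary.to_json(os.path.join(config.out_dir, "summary.json"))
        with open(os.path.join(config.out_dir, "summary.tsv"), "w") as fh:
            fh.write(summary.to_tsv())
        manifest["funnel"]["cohort_event_pairs"] = summary.total_events

        stage = "signals"
        for level in config.levels:
            tab = build_tables(store, cohort_ids, level=level, mapping=mapping)
            # MGPS prior fitted over every (PS drug, term) cell of the database
            prior = _fit_prior_all_cells(store, level, mapping)
            stats = compute_signal_stats(tab, prior=prior, thresholds=config.thresholds)
            ranked = rank_report(stats, by=config.rank_by, top_n=config.top_n)
            _format_signals(ranked).to_csv(
                os.path.join(config.out_dir, f"signals_{level}.tsv"),
                sep="\t", index=False)
            stats.to_json(os.path.join(config.out_dir, f"signals_{level}.json"),
                          orient="records", indent=1)
            if prior is not None:
                with open(os.path.join(config.out_dir, f"gps_prior_{level}.json"), "w") as fh:
                    json.dump(dataclasses.asdict(prior), fh, indent=1)
            manifest["funnel"][f"terms_{level}"] = len(stats)
            manifest["funnel"][f"positive_{level}"] = int(stats["positive"].sum())

        stage = "tto"
        onsets, onset_summary = compute_onset(store, cohort_ids, synonyms)
        manifest["funnel"]["onset_linked"] = onset_summary.n_linked
        manifest["funnel"]["onset_reliable"] = onset_summary.n_reliable
        reliable = onsets.loc[onsets["reliable"], "onset_days"]
        fit = weibull_fit(reliable, day_offset=config.tto_day_offset,
                          interval_censored=config.tto_interval_censored)
        with open(os.path.join(config.out_dir, "onset.json"), "w") as fh:
            json.dump({"summary": onset_summary.to_dict(),
                       "weibull": fit.to_dict()}, fh, indent=1)
        if onset_summary.n_reliable:
            curve = cumulative_incidence(reliable)
            curve.to_csv(os.path.join(config.out_dir, "onset_cdf.tsv"),
                         sep="\t", index=False, float_format="%.6f")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _fit_prior_all_cells(store, level, mapping):
    """Fit the MGPS prior over all (PS drug, term) cells of the database."""
    from .meddra import UNCODED, recode_pt, soc_of

    drug = store.drug
    ps = drug[drug["role_cod"].astype(str).str.upper() == "PS"].copy()
    # prefer the active ingredient when present: trade names of one drug
    # must not split its row margin
    if "prod_ai" in ps.columns:
        ps["_name"] = ps["prod_ai"].fillna(ps["drugname"])
    else:
        ps["_name"] = ps["drugname"]
    ps_name = ps.drop_duplicates("primaryid").set_index("primaryid")["_name"]
    reac = store.reac.dropna(subset=["pt"])[["primaryid", "pt"]].copy()
    if level == "SOC":
        reac["term"] = reac["pt"].map(lambda p: soc_of(p, mapping))
        reac = reac[reac["term"] != UNCODED]
    else:
        reac["term"] = reac["pt"].map(lambda p: recode_pt(p, mapping))
    pairs = reac[["primaryid", "term"]].drop_duplicates()
    pairs["drug"] = pairs["primaryid"].map(ps_name)
    pairs = pairs.dropna(subset=["drug"])
    cells = pairs.groupby(["drug", "term"]).size().rename("n").reset_index()
    row_tot = pairs.groupby("drug").size()
    col_tot = pairs.groupby("term").size()
    n_tot = len(pairs)
    cells["E"] = cells["drug"].map(row_tot) * cells["term"].map(col_tot) / n_tot
    if len(cells) < 50:
        logger.warning("only %d database cells: skipping MGPS prior fit", len(cells))
        return None
    try:
        return fit_gps_prior(cells["n"].to_numpy(), cells["E"].to_numpy())
    except GPSFitError as exc:
        logger.warning("MGPS prior fit failed: %s", exc)
        return None
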