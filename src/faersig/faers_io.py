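"""Parsing of FAERS-style quarterly ASCII packages and case deduplication.

The FAERS quarterly dialect: one record per line, ``$``-separated fields,
first line a header of column names, one file per (table, quarter), e.g.
``DEMO24Q3.txt``.  Quarters from 2019Q1 additionally ship a deletion list
(one retracted CASEID per line) that is applied *after* deduplication.

Deduplication follows the FDA-recommended rule: within each CASEID keep the
report with the latest FDA_DT; on FDA_DT ties keep the largest PRIMARYID.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from ._dates import pad_for_order
from .synthetic_faers import quarter_code

__all__ = [
    "FaersFormatError",
    "FaersTables",
    "CaseStore",
    "parse_quarter",
    "load_package",
    "deduplicate",
    "apply_deletions",
    "build_case_store",
]

logger = logging.getLogger(__name__)

#: Mandatory columns per table (matching is case-insensitive and
#: order-tolerant; FAERS header conventions drifted across years).
REQUIRED_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "outc_cod"],
}

TABLES = ("demo", "drug", "reac", "ther", "outc")


class FaersFormatError(ValueError):
    """A quarterly file does not conform to the expected dialect."""


def parse_quarter(path: str | os.PathLike, table_name: str) -> pd.DataFrame:
    """Parse one ``$``-delimited quarterly file into a string DataFrame.

    Empty fields become ``NaN``; malformed lines (wrong field count) are
    counted and logged, never silently dropped without a trace.  Raises
    :class:`FaersFormatError` naming the first missing mandatory column.
    """
    table_name = table_name.lower()
    if table_name not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table name: {table_name!r}")
    bad_lines: list = []

    def _on_bad(line):  # pragma: no cover - depends on malformed input
        bad_lines.append(line)
        return None

    try:
        df = pd.read_csv(
            path, sep="$", dtype=str, engine="python",
            keep_default_na=False, na_values=[""],
            on_bad_lines=_on_bad,
        )
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS[table_name]:
        if col not in df.columns:
            raise FaersFormatError(
                f"{os.fspath(path)}: missing mandatory column {col!r} for table {table_name}"
            )
    if bad_lines:
        logger.warning("%s: skipped %d malformed line(s)", path, len(bad_lines))
    df.attrs["n_malformed"] = len(bad_lines)
    return df


def _find_table_file(package_dir: str, table: str, quarter: str) -> str | None:
    code = quarter_code(quarter)
    pattern = os.path.join(package_dir, f"{table.upper()}{code}*")
    hits = sorted(glob.glob(pattern)) or sorted(
        glob.glob(os.path.join(package_dir, f"{table.lower()}{code.lower()}*")))
    return hits[0] if hits else None


@dataclass
class FaersTables:
    """All quarters of a package concatenated, one DataFrame per table."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    deletions: dict[str, list[str]] = field(default_factory=dict)
    quarters: tuple[str, ...] = ()


def load_package(package_dir: str | os.PathLike, quarters: list[str]) -> FaersTables:
    """Load and concatenate the five tables plus deletion lists for *quarters*.

    A missing DEMO file for a requested quarter is an error (the quarter
    label is reported); other missing tables yield empty frames.
    """
    package_dir = os.fspath(package_dir)
    frames: dict[str, list[pd.DataFrame]] = {t: [] for t in TABLES}
    deletions: dict[str, list[str]] = {}
    for q in quarters:
        for table in TABLES:
            path = _find_table_file(package_dir, table, q)
            if path is None:
                if table == "demo":
                    raise FileNotFoundError(
                        f"no DEMO file for quarter {q} in {package_dir}")
                continue
            frames[table].append(parse_quarter(path, table))
        del_path = _find_table_file(package_dir, "deleted", q) or _find_table_file(
            package_dir, "delete", q)
        if del_path is not None:
            with open(del_path) as fh:
                deletions[q] = [line.strip() for line in fh if line.strip()]
    out = {}
    for table in TABLES:
        if frames[table]:
            out[table] = pd.concat(frames[table], ignore_index=True)
        else:
            out[table] = pd.DataFrame(columns=REQUIRED_COLUMNS[table])
    return FaersTables(**out, deletions=deletions, quarters=tuple(quarters))


def deduplicate(demo: pd.DataFrame) -> pd.Index:
    """Retained PRIMARYIDs after the FDA-recommended case deduplication.

    Within each CASEID the record with the latest FDA_DT wins; FDA_DT ties
    go to the largest PRIMARYID.  Partial FDA_DT values are padded to their
    earliest completion for ordering only.  PRIMARYID comparison is numeric
    when every value parses as an integer, otherwise lexicographic (with a
    warning).  The result is independent of input row order and idempotent.
    """
    if demo.empty:
        return pd.Index([], name="primaryid")
    for col in ("primaryid", "caseid", "fda_dt"):
        if demo[col].isna().any():
            raise ValueError(f"deduplicate: missing values in mandatory column {col!r}")
    work = demo[["primaryid", "caseid", "fda_dt"]].copy()
    work["_fda_key"] = work["fda_dt"].map(pad_for_order)
    pid_num = pd.to_numeric(work["primaryid"], errors="coerce")
    if pid_num.isna().any():
        logger.warning("non-numeric PRIMARYID values: falling back to lexicographic tie-break")
        work["_pid_key"] = work["primaryid"].astype(str)
    else:
        work["_pid_key"] = pid_num
    work = work.sort_values(["caseid", "_fda_key", "_pid_key"], kind="mergesort")
    winners = work.groupby("caseid", sort=False).tail(1)
    return pd.Index(winners["primaryid"].tolist(), name="primaryid")


def apply_deletions(
    demo: pd.DataFrame,
    retained: pd.Index,
    deletion_lists: dict[str, list[str]],
) -> tuple[pd.Index, int]:
    """Drop retained reports whose CASEID appears on any deletion list.

    Returns the surviving PRIMARYIDs and the number removed.  CASEIDs on a
    deletion list that match no retained case are ignored (logged).
    """
    deleted: set[str] = set()
    for ids in deletion_lists.values():
        deleted.update(str(x) for x in ids)
    if not deleted:
        return retained, 0
    case_of = demo.drop_duplicates("primaryid").set_index("primaryid")["caseid"]
    retained_cases = case_of.reindex(retained)
    keep_mask = ~retained_cases.astype(str).isin(deleted)
    removed = int((~keep_mask).sum())
    unknown = deleted - set(retained_cases.astype(str))
    if unknown:
        logger.info("%d deletion-list CASEID(s) matched no retained case", len(unknown))
    return pd.Index(retained[keep_mask.to_numpy()], name="primaryid"), removed


@dataclass
class CaseStore:
    """Deduplicated, deletion-applied snapshot of a package.

    All five tables are filtered to the retained PRIMARYIDs; the funnel
    counts record how many rows/cases each cleaning step touched.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    n_raw_reports: int
    n_unique_cases: int
    n_after_dedup: int
    n_deleted: int

    @property
    def primaryids(self) -> pd.Index:
        return pd.Index(self.demo["primaryid"])


def build_case_store(tables: FaersTables) -> CaseStore:
    """Deduplicate, apply deletion lists, and filter every table."""
    retained = deduplicate(tables.demo)
    n_after_dedup = len(retained)
    retained, n_deleted = apply_deletions(tables.demo, retained, tables.deletions)
    keep = set(retained)
    demo = tables.demo[tables.demo["primaryid"].isin(keep)].reset_index(drop=True)
    return CaseStore(
        demo=demo,
        drug=tables.drug[tables.drug["primaryid"].isin(keep)].reset_index(drop=True),
        reac=tables.reac[tables.reac["primaryid"].isin(keep)].reset_index(drop=True),
        ther=tables.ther[tables.ther["primaryid"].isin(keep)].reset_index(drop=True),
        outc=tables.outc[tables.outc["primaryid"].isin(keep)].reset_index(drop=True),
        n_raw_reports=len(tables.demo),
        n_unique_cases=tables.demo["caseid"].nunique(),
        n_after_dedup=n_after_dedup,
        n_deleted=n_deleted,
    )


def write_store(store: CaseStore, out_dir: str | os.PathLike) -> None:
    """Serialise a case store as five TSV tables plus a counts manifest."""
    import json

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for name in TABLES:
        getattr(store, name).to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "store_manifest.json"), "w") as fh:
        json.dump({
            "n_raw_reports": store.n_raw_reports,
            "n_unique_cases": store.n_unique_cases,
            "n_after_dedup": store.n_after_dedup,
            "n_deleted": store.n_deleted,
            "n_retained": len(store.demo),
        }, fh, indent=1)


def read_store(in_dir: str | os.PathLike) -> CaseStore:
    import json

    in_dir = os.fspath(in_dir)
    with open(os.path.join(in_dir, "store_manifest.json")) as fh:
        man = json.load(fh)
    frames = {
        name: pd.read_csv(os.path.join(in_dir, f"{name}.tsv"), sep="\t", dtype=str)
        for name in TABLES
    }
    return CaseStore(
        **frames,
        n_raw_reports=man["n_raw_reports"],
        n_unique_cases=man["n_unique_cases"],
        n_after_dedup=man["n_after_dedup"],
        n_deleted=man["n_deleted"],
    )
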