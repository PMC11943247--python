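"""Preferred-term recoding and PT→SOC mapping.

MedDRA itself is licensed and cannot be redistributed, so the package
consumes a plain TSV stand-in with columns ``pt`` (preferred term), ``soc``
(its single primary system organ class) and optionally ``old_pt`` (a
superseded term renamed to ``pt`` in the current dictionary version).
Tests ship a toy dictionary; real users export their licensed copy into
the same schema.

Terms absent from the dictionary are never dropped: lookups return the
``"uncoded"`` sentinel and the query is collected into an uncoded report.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["MedDRAMap", "load_meddra_tsv", "recode_pt", "soc_of", "UNCODED"]

UNCODED = "uncoded"


@dataclass
class MedDRAMap:
    """PT → primary SOC table plus old-PT → current-PT renames."""

    pt_to_soc: dict[str, str]
    synonyms: dict[str, str] = field(default_factory=dict)
    version: str = ""
    uncoded_seen: set[str] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        # synonym closure must be acyclic (and is resolved transitively)
        for start in self.synonyms:
            seen = {start}
            cur = start
            while cur in self.synonyms:
                cur = self.synonyms[cur]
                if cur in seen:
                    raise ValueError(f"synonym cycle involving {start!r}")
                seen.add(cur)

    def uncoded_report(self) -> list[str]:
        """PTs queried so far that the dictionary does not know, sorted."""
        return sorted(self.uncoded_seen)


def load_meddra_tsv(path: str | os.PathLike, version: str = "") -> MedDRAMap:
    """Load the TSV stand-in dictionary (columns: pt, soc, optional old_pt)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("pt", "soc"):
        if col not in df.columns:
            raise ValueError(f"{os.fspath(path)}: dictionary lacks column {col!r}")
    pt_to_soc: dict[str, str] = {}
    for pt, soc in zip(df["pt"], df["soc"]):
        if pt and soc:
            if pt in pt_to_soc and pt_to_soc[pt] != soc:
                raise ValueError(f"PT {pt!r} mapped to two SOCs")
            pt_to_soc[pt] = soc
    synonyms: dict[str, str] = {}
    if "old_pt" in df.columns:
        for pt, old in zip(df["pt"], df["old_pt"]):
            if old and pt and old != pt:
                synonyms[old] = pt
    return MedDRAMap(pt_to_soc=pt_to_soc, synonyms=synonyms, version=version)


def recode_pt(pt: str, mapping: MedDRAMap) -> str:
    """Rename *pt* to its current dictionary term, following synonym chains.

    Unknown terms pass through unchanged and are recorded in the uncoded
    report (never dropped).
    """
    cur = pt
    while cur in mapping.synonyms:
        cur = mapping.synonyms[cur]
    if cur not in mapping.pt_to_soc:
        mapping.uncoded_seen.add(pt)
    return cur


def soc_of(pt: str, mapping: MedDRAMap) -> str:
    """Primary SOC of *pt* (after synonym resolution), or ``"uncoded"``."""
    cur = recode_pt(pt, mapping)
    return mapping.pt_to_soc.get(cur, UNCODED)
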