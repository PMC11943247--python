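"""Date helpers for FAERS-style 8-digit dates, tolerant of partial values.

FAERS date fields are strings of 8 (YYYYMMDD), 6 (YYYYMM) or 4 (YYYY)
digits; any other value is treated as missing.
"""

from __future__ import annotations

import datetime as _dt

__all__ = ["is_full_date", "pad_for_order", "parse_full_date", "date_str", "days_between"]


def is_full_date(s: object) -> bool:
    """True when *s* is a complete, calendar-valid YYYYMMDD string."""
    if not isinstance(s, str) or len(s) != 8 or not s.isdigit():
        return False
    try:
        _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return False
    return True


def is_partial_date(s: object) -> bool:
    """True for a YYYY or YYYYMM string (present but incomplete)."""
    return isinstance(s, str) and s.isdigit() and len(s) in (4, 6)


def pad_for_order(s: object) -> str:
    """Pad a possibly-partial date to YYYYMMDD for *ordering only*.

    Missing month/day become '01' (the earliest completion), so padded
    strings sort deterministically without inventing precision.  Missing or
    unparseable values sort first.
    """
    if not isinstance(s, str) or not s.isdigit():
        return "00000000"
    if len(s) == 8:
        return s
    if len(s) == 6:
        return s + "01"
    if len(s) == 4:
        return s + "0101"
    return "00000000"


def parse_full_date(s: str) -> _dt.date:
    return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))


def date_str(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def days_between(start: str, end: str) -> int:
    """Whole days from *start* to *end*, both full YYYYMMDD strings."""
    return (parse_full_date(end) - parse_full_date(start)).days
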