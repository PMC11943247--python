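"""Select the primary-suspect cohort and tabulate its characteristics.

Writes the Table-1-shaped descriptive summary (sex, age bands, reporter,
severity, reporting year, countries) to results/cohort_summary.tsv/.json.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from _common import CONFIG, PACKAGE_DIR, RESULTS_DIR, SYNONYMS, ensure_dirs  # noqa: E402

from faersig.cohort import select_primary_suspect, summarize_demographics  # noqa: E402
from faersig.faers_io import build_case_store, load_package  # noqa: E402


def main() -> None:
    ensure_dirs()
    store = build_case_store(load_package(PACKAGE_DIR, list(CONFIG.quarters)))
    ids = select_primary_suspect(store, SYNONYMS)
    summary = summarize_demographics(store, ids)
    print(f"cohort: {summary.total_reports} reports, "
          f"{summary.total_events} drug-event pairs")
    print(f"  age median (IQR): {summary.age_median:.0f} "
          f"({summary.age_q1:.0f}, {summary.age_q3:.0f})")
    for label, rows in [("sex", summary.sex), ("severity", summary.severity)]:
        cells = ", ".join(f"{c}: {n} ({p:.2f}%)" for c, n, p in rows)
        print(f"  {label}: {cells}")
    summary.to_json(os.path.join(RESULTS_DIR, "cohort_summary.json"))
    with open(os.path.join(RESULTS_DIR, "cohort_summary.tsv"), "w") as fh:
        fh.write(summary.to_tsv())
    print(f"written to {RESULTS_DIR}/cohort_summary.tsv")


if __name__ == "__main__":
    main()
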