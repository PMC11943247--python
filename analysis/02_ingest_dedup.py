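"""Parse the quarterly package, deduplicate cases, apply deletion lists.

Prints the cleaning funnel (raw rows → unique cases → after deletions)
and writes it to results/ingest_funnel.json.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from _common import CONFIG, PACKAGE_DIR, RESULTS_DIR, ensure_dirs  # noqa: E402

from faersig.faers_io import build_case_store, load_package  # noqa: E402


def main() -> None:
    ensure_dirs()
    store = build_case_store(load_package(PACKAGE_DIR, list(CONFIG.quarters)))
    funnel = {
        "raw_demo_rows": store.n_raw_reports,
        "unique_cases": store.n_unique_cases,
        "after_dedup": store.n_after_dedup,
        "removed_by_deletion_lists": store.n_deleted,
        "retained_reports": len(store.demo),
    }
    print("ingestion funnel:")
    for key, value in funnel.items():
        print(f"  {key}: {value}")
    with open(os.path.join(RESULTS_DIR, "ingest_funnel.json"), "w") as fh:
        json.dump(funnel, fh, indent=1)


if __name__ == "__main__":
    main()
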