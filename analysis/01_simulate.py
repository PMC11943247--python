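"""Generate the synthetic FAERS-like quarterly package with known truth.

Writes the $-delimited DEMO/DRUG/REAC/THER/OUTC files, deletion lists and
the toy PT→SOC dictionary under scratch/faers_package, and reports what
was planted.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from _common import CONFIG, PACKAGE_DIR, PLANTED, RESULTS_DIR, ensure_dirs  # noqa: E402

from faersig.synthetic_faers import generate_package  # noqa: E402


def main() -> None:
    ensure_dirs()
    truth = generate_package(CONFIG, PACKAGE_DIR)
    print(f"package written to {PACKAGE_DIR}")
    print(f"  raw DEMO rows: {truth.n_raw_demo_rows}  (cases: {truth.n_cases})")
    print(f"  duplicated cases: {len(truth.duplicate_caseids)}")
    print(f"  deleted cases: {len(truth.deleted_caseids)}")
    print(f"  target-drug cases (ground truth cohort): {len(truth.target_caseids)}")
    print("  planted signals (drug 0 = target):")
    for d, e, lam in PLANTED:
        print(f"    event {truth.event_pts[e]!r}: relative risk {lam}")
    with open(os.path.join(RESULTS_DIR, "simulation_truth.json"), "w") as fh:
        json.dump({
            "n_raw_demo_rows": truth.n_raw_demo_rows,
            "n_cases": truth.n_cases,
            "n_duplicates": len(truth.duplicate_caseids),
            "n_deleted": len(truth.deleted_caseids),
            "n_target_cases": len(truth.target_caseids),
            "planted": [[truth.event_pts[e], lam] for _, e, lam in PLANTED],
        }, fh, indent=1)


if __name__ == "__main__":
    main()
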