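"""Time-to-onset of the target drug's adverse events.

Computes onset intervals (therapy start → event date), the day-0-dominated
summary, the Weibull hazard-profile fit and the cumulative-incidence
curve; compares the reliable onsets against the generator's ground truth.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from _common import CONFIG, PACKAGE_DIR, RESULTS_DIR, SYNONYMS, ensure_dirs  # noqa: E402

from faersig.cohort import select_primary_suspect  # noqa: E402
from faersig.faers_io import build_case_store, load_package  # noqa: E402
from faersig.synthetic_faers import GroundTruth  # noqa: E402
from faersig.tto import compute_onset, cumulative_incidence, weibull_fit  # noqa: E402


def main() -> None:
    ensure_dirs()
    store = build_case_store(load_package(PACKAGE_DIR, list(CONFIG.quarters)))
    ids = select_primary_suspect(store, SYNONYMS)
    onsets, summary = compute_onset(store, ids, SYNONYMS)
    truth = GroundTruth.from_json(os.path.join(PACKAGE_DIR, "ground_truth.json"))

    print(f"linked reports: {summary.n_linked}; reliable onsets: "
          f"{summary.n_reliable} (ground truth {len(truth.onset_days)})")
    print(f"  median {summary.median} days, IQR {summary.q1}-{summary.q3}, "
          f"day-0 share {summary.day0_percent}%")
    print("  timeline bins:", dict(summary.bins))

    reliable = onsets.loc[onsets["reliable"], "onset_days"]
    fit = weibull_fit(reliable)
    print(f"  Weibull shape {fit.shape:.3f} "
          f"({fit.shape_lo95:.3f}-{fit.shape_hi95:.3f}), "
          f"scale {fit.scale:.3f} days -> {fit.classification}")

    with open(os.path.join(RESULTS_DIR, "onset.json"), "w") as fh:
        json.dump({"summary": summary.to_dict(), "weibull": fit.to_dict()}, fh, indent=1)
    curve = cumulative_incidence(reliable)
    curve.to_csv(os.path.join(RESULTS_DIR, "onset_cdf.tsv"), sep="\t",
                 index=False, float_format="%.6f")
    print(f"written to {RESULTS_DIR}/onset.json and onset_cdf.tsv")


if __name__ == "__main__":
    main()
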