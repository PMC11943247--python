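"""Disproportionality analysis of the target drug at PT and SOC level.

Computes ROR, PRR+χ², BCPNN IC and MGPS EBGM for every event term of the
cohort, flags positives by the at-least-one-method rule, checks the
flagged set against the planted ground truth, and writes the ranked
signal tables to results/.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from _common import CONFIG, DICTIONARY, PACKAGE_DIR, RESULTS_DIR, SYNONYMS, ensure_dirs  # noqa: E402

from faersig.cohort import select_primary_suspect  # noqa: E402
from faersig.disproportionality import build_tables, compute_signal_stats, rank_report  # noqa: E402
from faersig.faers_io import build_case_store, load_package  # noqa: E402
from faersig.meddra import load_meddra_tsv  # noqa: E402
from faersig.pipeline import _fit_prior_all_cells  # noqa: E402
from faersig.synthetic_faers import GroundTruth, ground_truth_signal_set  # noqa: E402


def main() -> None:
    ensure_dirs()
    store = build_case_store(load_package(PACKAGE_DIR, list(CONFIG.quarters)))
    mapping = load_meddra_tsv(DICTIONARY)
    ids = select_primary_suspect(store, SYNONYMS)
    truth = GroundTruth.from_json(os.path.join(PACKAGE_DIR, "ground_truth.json"))
    planted_terms = {truth.event_pts[e] for _, e in ground_truth_signal_set(truth)}

    for level in ("PT", "SOC"):
        tables = build_tables(store, ids, level=level, mapping=mapping)
        prior = _fit_prior_all_cells(store, level, mapping)
        stats = compute_signal_stats(tables, prior=prior)
        ranked = rank_report(stats, by="frequency", top_n=50)
        out = os.path.join(RESULTS_DIR, f"signals_{level}.tsv")
        ranked.to_csv(out, sep="\t", index=False, float_format="%.4f")
        print(f"{level} level: {len(stats)} terms, "
              f"{int(stats['positive'].sum())} positive -> {out}")
        if level == "PT":
            planted = stats[stats["term"].isin(planted_terms)]
            null = stats[~stats["term"].isin(planted_terms) & (stats["a"] >= 3)]
            print(f"  planted pairs flagged: {int(planted['positive'].sum())}"
                  f"/{len(planted_terms)}")
            print(f"  false positives among {len(null)} null terms (a>=3): "
                  f"{int(null['positive'].sum())}")
            cols = ["term", "a", "ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"]
            print(planted[cols].to_string(index=False,
                                          float_format=lambda x: f"{x:.2f}"))


if __name__ == "__main__":
    main()
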