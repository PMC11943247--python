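"""Shared study conditions for the numbered analysis scripts.

One synthetic FAERS-like database stands in for the public archive: 20 000
reports over four quarters, 25 background drugs plus the target, 60 event
terms, five planted elevated-risk pairs on the target drug, duplicate and
deleted cases, and a day-0-dominated onset distribution.  Scripts share
the package directory under scratch/ and write their tables to results/.
"""

import os

from faersig.synthetic_faers import GeneratorConfig

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
PACKAGE_DIR = os.path.join(ROOT, "scratch", "faers_package")
RESULTS_DIR = os.path.join(ROOT, "results")
DICTIONARY = os.path.join(PACKAGE_DIR, "pt_soc_map.tsv")

PLANTED = [(0, 3, 10.0), (0, 7, 5.0), (0, 11, 8.0), (0, 19, 6.0), (0, 30, 5.0)]

CONFIG = GeneratorConfig(
    n_reports=20000,
    n_drugs=25,
    n_events=60,
    seed=7,
    background_prior=None,   # null background so planted pairs are the only signals
    planted_signals=list(PLANTED),
)

SYNONYMS = ["REGADENOSON", "LEXISCAN"]


def ensure_dirs() -> None:
    os.makedirs(RESULTS_DIR, exist_ok=True)
    os.makedirs(os.path.dirname(PACKAGE_DIR), exist_ok=True)
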