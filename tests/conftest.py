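"""Shared fixtures: toy in-memory stores and seed-fixed synthetic packages."""

from __future__ import annotations

import pandas as pd
import pytest

from faersig.faers_io import CaseStore, build_case_store, load_package
from faersig.meddra import load_meddra_tsv
from faersig.synthetic_faers import GeneratorConfig, generate_package


def make_store(demo=None, drug=None, reac=None, ther=None, outc=None) -> CaseStore:
    """Build a CaseStore directly from row dicts (already deduplicated)."""
    def frame(rows, cols):
        if rows is None:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(rows, columns=cols, dtype=object)

    demo_df = frame(demo, ["primaryid", "caseid", "fda_dt", "event_dt", "age",
                           "age_cod", "sex", "occp_cod", "reporter_country",
                           "init_fda_dt"])
    return CaseStore(
        demo=demo_df,
        drug=frame(drug, ["primaryid", "caseid", "drug_seq", "role_cod",
                          "drugname", "prod_ai"]),
        reac=frame(reac, ["primaryid", "caseid", "pt"]),
        ther=frame(ther, ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"]),
        outc=frame(outc, ["primaryid", "caseid", "outc_cod"]),
        n_raw_reports=len(demo_df),
        n_unique_cases=demo_df["caseid"].nunique() if len(demo_df) else 0,
        n_after_dedup=len(demo_df),
        n_deleted=0,
    )


@pytest.fixture()
def four_report_store() -> CaseStore:
    """The enumerable 4-report database: target reports r1:(E1), r2:(E1,E2);
    other reports r3:(E1), r4:(E2)."""
    demo = [[f"r{i}", f"c{i}", "20240101", "", "", "", "", "", "US", "20240101"]
            for i in range(1, 5)]
    drug = [
        ["r1", "c1", "1", "PS", "TARGET", "TARGET"],
        ["r2", "c2", "1", "PS", "TARGET", "TARGET"],
        ["r3", "c3", "1", "PS", "OTHER", "OTHER"],
        ["r4", "c4", "1", "PS", "OTHER", "OTHER"],
    ]
    reac = [
        ["r1", "c1", "E1"],
        ["r2", "c2", "E1"], ["r2", "c2", "E2"],
        ["r3", "c3", "E1"],
        ["r4", "c4", "E2"],
    ]
    return make_store(demo=demo, drug=drug, reac=reac)


PLANTED = [(0, 3, 10.0), (0, 7, 5.0), (0, 11, 8.0), (0, 19, 6.0), (0, 30, 5.0)]


@pytest.fixture(scope="session")
def recovery_package(tmp_path_factory):
    """Seed-fixed 20000-report database with five planted signals (λ ≥ 5)
    on the target drug and a λ≡1 background, shared across recovery tests."""
    out = tmp_path_factory.mktemp("recovery_pkg")
    cfg = GeneratorConfig(
        n_reports=20000, n_drugs=25, n_events=60, seed=7,
        background_prior=None, planted_signals=list(PLANTED),
    )
    truth = generate_package(cfg, out)
    return cfg, truth, out


@pytest.fixture(scope="session")
def recovery_store(recovery_package):
    cfg, truth, out = recovery_package
    store = build_case_store(load_package(out, list(cfg.quarters)))
    mapping = load_meddra_tsv(out / "pt_soc_map.tsv")
    return store, mapping, truth


@pytest.fixture(scope="session")
def recovery_stats(recovery_store):
    """Full PT-level signal table of the recovery database."""
    from faersig.cohort import select_primary_suspect
    from faersig.disproportionality import build_tables, compute_signal_stats
    from faersig.pipeline import _fit_prior_all_cells

    store, mapping, truth = recovery_store
    ids = select_primary_suspect(store, ["REGADENOSON", "LEXISCAN"])
    tables = build_tables(store, ids, level="PT", mapping=mapping)
    prior = _fit_prior_all_cells(store, "PT", mapping)
    stats = compute_signal_stats(tables, prior=prior)
    return stats, prior, truth


@pytest.fixture(scope="session")
def small_package(tmp_path_factory):
    """2000-report package with default (gamma-mixture) background."""
    out = tmp_path_factory.mktemp("small_pkg")
    cfg = GeneratorConfig(n_reports=2000, n_drugs=10, n_events=30, seed=11,
                          planted_signals=[(0, 5, 8.0)])
    truth = generate_package(cfg, out)
    return cfg, truth, out
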