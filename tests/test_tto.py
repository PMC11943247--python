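"""Onset intervals, Weibull recovery and the cumulative-incidence curve."""

import math

import numpy as np
import pandas as pd
import pytest

from faersig.tto import compute_onset, cumulative_incidence, weibull_fit

from conftest import make_store

SYN = ["REGADENOSON", "LEXISCAN"]


def onset_store(rows):
    """rows: (primaryid, start_dt, event_dt) for target PS reports."""
    demo = [[pid, f"c{pid}", "20240601", ev, "", "", "", "", "US", "20240601"]
            for pid, st, ev in rows]
    drug = [[pid, f"c{pid}", "1", "PS", "REGADENOSON", "REGADENOSON"]
            for pid, _, _ in rows]
    reac = [[pid, f"c{pid}", "Nausea"] for pid, _, _ in rows]
    ther = [[pid, f"c{pid}", "1", st, ""] for pid, st, _ in rows]
    return make_store(demo=demo, drug=drug, reac=reac, ther=ther)


class TestComputeOnset:
    def test_same_day_is_zero(self):
        store = onset_store([("1", "20240105", "20240105")])
        onsets, s = compute_onset(store, pd.Index(["1"]), SYN)
        assert onsets.loc[0, "onset_days"] == 0 and onsets.loc[0, "reliable"]
        assert s.median == 0.0

    def test_negative_interval_unreliable(self):
        store = onset_store([("1", "20240110", "20240105")])
        onsets, s = compute_onset(store, pd.Index(["1"]), SYN)
        assert not onsets.loc[0, "reliable"]
        assert onsets.loc[0, "reason"] == "negative interval"

    @pytest.mark.parametrize("start,event,reason", [
        ("", "20240105", "missing date"),
        ("20240101", "", "missing date"),
        ("202401", "20240105", "partial date"),
        ("20240101", "2024", "partial date"),
    ])
    def test_unreliable_reasons(self, start, event, reason):
        store = onset_store([("1", start, event)])
        onsets, _ = compute_onset(store, pd.Index(["1"]), SYN)
        assert not onsets.loc[0, "reliable"]
        assert onsets.loc[0, "reason"] == reason

    def test_earliest_target_start_used(self):
        store = onset_store([("1", "20240110", "20240112")])
        # second therapy row for the same target drug, earlier start
        extra_drug = pd.DataFrame(
            [["1", "c1", "2", "PS", "LEXISCAN", "REGADENOSON"]],
            columns=store.drug.columns, dtype=object)
        store.drug = pd.concat([store.drug, extra_drug], ignore_index=True)
        extra = pd.DataFrame([["1", "c1", "2", "20240102", ""]],
                             columns=store.ther.columns, dtype=object)
        store.ther = pd.concat([store.ther, extra], ignore_index=True)
        onsets, _ = compute_onset(store, pd.Index(["1"]), SYN)
        assert onsets.loc[0, "onset_days"] == 10

    def test_no_silent_drops(self):
        store = onset_store([("1", "20240101", "20240105"),
                             ("2", "", ""), ("3", "202401", "20240105")])
        onsets, s = compute_onset(store, pd.Index(["1", "2", "3"]), SYN)
        assert s.n_reliable + s.n_unreliable == s.n_linked == 3

    def test_median_iqr_match_sort_oracle(self, recovery_store):
        store, mapping, truth = recovery_store
        from faersig.cohort import select_primary_suspect

        ids = select_primary_suspect(store, SYN)
        onsets, s = compute_onset(store, ids, SYN)
        days = sorted(onsets.loc[onsets["reliable"], "onset_days"])
        arr = np.array(days, dtype=float)
        assert s.median == np.quantile(arr, 0.5)
        assert (s.q1, s.q3) == (np.quantile(arr, 0.25), np.quantile(arr, 0.75))
        # generator truth: every reliable record's onset matches
        got = {pid[:-1]: d for pid, d in
               zip(onsets["primaryid"], onsets["onset_days"]) if d is not None}
        matched = {k: truth.onset_days[k] for k in got if k in truth.onset_days}
        assert matched and all(got[k] == v for k, v in matched.items())


class TestWeibullFit:
    def test_recovers_early_failure_shape(self):
        rng = np.random.default_rng(123)
        t = 5.0 * rng.weibull(0.6, size=2000)
        fit = weibull_fit(t, day_offset=0.0)
        assert 0.55 <= fit.shape <= 0.65
        assert fit.classification == "early-failure"
        assert fit.scale == pytest.approx(5.0, rel=0.15)

    def test_exponential_classified_random(self):
        rng = np.random.default_rng(124)
        t = rng.exponential(5.0, size=2000)
        fit = weibull_fit(t, day_offset=0.0)
        assert fit.shape_lo95 < 1.0 < fit.shape_hi95
        assert fit.classification == "random"

    def test_increasing_hazard_classified_wear_out(self):
        rng = np.random.default_rng(125)
        t = 5.0 * rng.weibull(2.5, size=1500)
        fit = weibull_fit(t, day_offset=0.0)
        assert fit.classification == "wear-out"

    def test_matches_lifelines_oracle(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(126)
        t = 4.0 * rng.weibull(0.8, size=800) + 0.01
        fit = weibull_fit(t, day_offset=0.0)
        wf = lifelines.WeibullFitter().fit(t)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.scale == pytest.approx(wf.lambda_, rel=1e-3)

    def test_loglik_dominance_at_truth(self):
        rng = np.random.default_rng(127)
        t = 5.0 * rng.weibull(0.6, size=1000)
        fit = weibull_fit(t, day_offset=0.0)
        b, a = 0.6, 5.0
        ll_true = float(np.sum(np.log(b / a) + (b - 1) * np.log(t / a) - (t / a) ** b))
        assert fit.loglik >= ll_true - 2.0

    def test_all_identical_is_indeterminate(self):
        fit = weibull_fit(np.zeros(50))
        assert fit.classification == "indeterminate"
        assert "degenerate" in fit.reason

    def test_too_few_records_indeterminate(self):
        fit = weibull_fit(np.arange(5))
        assert fit.classification == "indeterminate"

    def test_interval_censored_option_close_to_offset_fit(self):
        rng = np.random.default_rng(128)
        days = np.floor(5.0 * rng.weibull(0.8, size=1500))
        f1 = weibull_fit(days, day_offset=0.5)
        f2 = weibull_fit(days, interval_censored=True)
        assert f2.shape == pytest.approx(f1.shape, rel=0.25)


class TestCumulativeIncidence:
    def test_all_day_zero(self):
        curve = cumulative_incidence(np.zeros(10))
        assert list(curve["day"]) == [0.0]
        assert list(curve["cum_frac"]) == [1.0]

    def test_hand_countable(self):
        curve = cumulative_incidence([0, 0, 10]).set_index("day")["cum_frac"]
        assert curve.loc[0.0] == pytest.approx(2 / 3)
        assert curve.loc[10.0] == 1.0

    def test_monotone_and_ends_at_one(self):
        rng = np.random.default_rng(9)
        curve = cumulative_incidence(np.floor(rng.weibull(0.6, 500) * 20))
        assert (curve["cum_frac"].diff().dropna() >= 0).all()
        assert curve["cum_frac"].iloc[-1] == 1.0

    def test_within_ks_band_of_true_cdf(self):
        """Empirical curve from known Weibull draws stays inside the 99%
        Kolmogorov–Smirnov band around the true CDF."""
        rng = np.random.default_rng(10)
        n = 2000
        t = 5.0 * rng.weibull(0.6, size=n)
        curve = cumulative_incidence(t)
        true_cdf = 1 - np.exp(-((curve["day"] / 5.0) ** 0.6))
        ks_99 = 1.6276 / math.sqrt(n)
        assert float(np.max(np.abs(curve["cum_frac"] - true_cdf))) <= ks_99

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cumulative_incidence([])
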