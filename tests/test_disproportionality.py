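"""Signal statistics against independent oracles and their invariants.

Oracles: statsmodels' Table2x2 for the odds ratio and its CI, scipy's
Yates-corrected χ², Monte-Carlo sampling of the BCPNN Beta posteriors, and
Monte-Carlo sampling of the gamma-mixture posterior for EBGM.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from faersig.disproportionality import (
    Contingency2x2,
    GPSFitError,
    GPSPrior,
    bcpnn_ic,
    build_tables,
    compute_signal_stats,
    ebgm_scores,
    evaluate_signal,
    fit_gps_prior,
    gps_marginal_loglik,
    prr_chi2,
    rank_report,
    ror,
)
from faersig.meddra import MedDRAMap

SMALL_TABLES = [
    (10, 90, 100, 9900),
    (3, 7, 11, 400),
    (25, 300, 250, 12000),
    (1, 1, 1, 1),
    (5, 5, 50, 50),
    (200, 1500, 900, 55000),
]


class TestContingency:
    def test_toy_enumeration(self, four_report_store):
        ids = pd.Index(["r1", "r2"])
        tab = build_tables(four_report_store, ids, level="PT")
        e1 = tab.set_index("term").loc["E1"]
        assert (e1.a, e1.b, e1.c, e1.d) == (2, 1, 1, 1)
        e2 = tab.set_index("term").loc["E2"]
        assert (e2.a, e2.b, e2.c, e2.d) == (1, 2, 1, 1)

    def test_conservation_and_margins(self, four_report_store):
        ids = pd.Index(["r1", "r2"])
        tab = build_tables(four_report_store, ids, level="PT")
        assert tab["a"].sum() == 3  # distinct (cohort report, term) pairs
        assert (tab["a"] + tab["b"]).nunique() == 1  # consistent drug margin
        assert ((tab["a"] + tab["b"] + tab["c"] + tab["d"]).nunique()) == 1

    def test_term_absent_from_cohort_not_emitted(self, four_report_store):
        tab = build_tables(four_report_store, pd.Index(["r1"]), level="PT")
        assert set(tab["term"]) == {"E1"}

    def test_soc_level_aggregates_through_map(self, four_report_store):
        mapping = MedDRAMap(pt_to_soc={"E1": "SOC_A", "E2": "SOC_A"})
        tab = build_tables(four_report_store, pd.Index(["r1", "r2"]),
                           level="SOC", mapping=mapping)
        row = tab.set_index("term").loc["SOC_A"]
        # r1 and r2 each contribute one (report, SOC) pair
        assert (row.a, row.b, row.c, row.d) == (2, 0, 2, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(1, -1, 0, 0)


class TestRor:
    def test_symmetric_table_is_null(self):
        r = ror(Contingency2x2(10, 10, 10, 10))
        assert r.est == 1.0 and r.lo95 < 1.0 < r.hi95

    def test_hand_value(self):
        assert ror(Contingency2x2(10, 90, 100, 9900)).est == pytest.approx(11.0)

    @pytest.mark.parametrize("a,b,c,d", SMALL_TABLES)
    def test_matches_statsmodels_oracle(self, a, b, c, d):
        from statsmodels.stats.contingency_tables import Table2x2

        t2 = Table2x2(np.array([[a, b], [c, d]]))
        r = ror(Contingency2x2(a, b, c, d))
        assert r.est == pytest.approx(t2.oddsratio, rel=1e-12)
        lo, hi = t2.oddsratio_confint(0.05)
        assert r.lo95 == pytest.approx(lo, rel=1e-9)
        assert r.hi95 == pytest.approx(hi, rel=1e-9)

    def test_doubling_cells_keeps_estimate_narrows_ci(self):
        r1 = ror(Contingency2x2(10, 90, 100, 9900))
        r2 = ror(Contingency2x2(20, 180, 200, 19800))
        assert r2.est == pytest.approx(r1.est)
        assert (r2.hi95 - r2.lo95) < (r1.hi95 - r1.lo95)

    def test_zero_cell_undefined_with_reason(self):
        r = ror(Contingency2x2(0, 5, 5, 5))
        assert math.isnan(r.est) and r.reason == "zero cell"


class TestPrrChi2:
    def test_null_case(self):
        # a/(a+b) = c/(c+d) = 0.1 exactly
        p = prr_chi2(Contingency2x2(10, 90, 50, 450))
        assert p.est == pytest.approx(1.0)

    def test_hand_value_and_chi2_oracle(self):
        p = prr_chi2(Contingency2x2(10, 90, 100, 9900))
        assert p.est == pytest.approx(10.0)
        chi2_ref, _, _, _ = sps.chi2_contingency(
            np.array([[10, 90], [100, 9900]]), correction=True)[:4]
        assert p.chi2 == pytest.approx(chi2_ref, rel=1e-12)
        assert p.chi2 == pytest.approx(66.33, abs=0.05)

    @pytest.mark.parametrize("a,b,c,d", SMALL_TABLES)
    def test_yates_chi2_matches_scipy(self, a, b, c, d):
        p = prr_chi2(Contingency2x2(a, b, c, d))
        chi2_ref = sps.chi2_contingency(np.array([[a, b], [c, d]]),
                                        correction=True)[0]
        assert p.chi2 == pytest.approx(chi2_ref, rel=1e-10, abs=1e-10)

    def test_chi2_floored_at_zero(self):
        # |ad − bc| = 0 ≤ N/2 → continuity correction floors χ² at 0
        assert prr_chi2(Contingency2x2(1, 1, 1, 1)).chi2 == 0.0

    def test_row_swap_inverts_prr(self):
        p = prr_chi2(Contingency2x2(10, 90, 100, 9900))
        q = prr_chi2(Contingency2x2(100, 9900, 10, 90))
        assert q.est == pytest.approx(1 / p.est)

    def test_zero_denominator_undefined(self):
        p = prr_chi2(Contingency2x2(5, 5, 0, 10))
        assert math.isnan(p.est) and p.reason is not None


def _mc_ic_oracle(t: Contingency2x2, n_draws: int = 100_000, seed: int = 0):
    """Monte-Carlo posterior of IC under the Beta model the moment formulas
    approximate: independent Beta posteriors for the joint and the two
    marginal report probabilities."""
    rng = np.random.default_rng(seed)
    n11, n = t.a, t.n
    n1_, n_1 = t.a + t.b, t.a + t.c
    g11, a1, b1, alpha, beta = 1.0, 1.0, 1.0, 2.0, 2.0
    gamma = g11 * (n + alpha) * (n + beta) / ((n1_ + a1) * (n_1 + b1))
    p11 = rng.beta(g11 + n11, gamma - g11 + n - n11, size=n_draws)
    p1 = rng.beta(a1 + n1_, alpha - a1 + n - n1_, size=n_draws)
    p2 = rng.beta(b1 + n_1, beta - b1 + n - n_1, size=n_draws)
    ic_draws = np.log2(p11 / (p1 * p2))
    return ic_draws


class TestBcpnn:
    def test_independence_limit(self):
        # a = (a+b)(a+c)/N exactly at N = 10^6
        t = Contingency2x2(100, 9900, 9900, 980100)
        assert abs(bcpnn_ic(t).ic) < 0.01

    def test_a_zero_is_finite_and_negative(self):
        r = bcpnn_ic(Contingency2x2(0, 5, 5, 5))
        assert math.isfinite(r.ic) and r.ic < 0
        assert math.isfinite(r.ic025) and r.ic025 < r.ic

    @pytest.mark.parametrize("a,b,c,d", [(10, 90, 100, 9900), (3, 7, 11, 400),
                                         (50, 450, 200, 20000)])
    def test_matches_monte_carlo_oracle(self, a, b, c, d):
        t = Contingency2x2(a, b, c, d)
        draws = _mc_ic_oracle(t)
        r = bcpnn_ic(t)
        assert r.ic == pytest.approx(float(np.mean(draws)), abs=0.15)
        assert r.ic025 == pytest.approx(float(np.quantile(draws, 0.023)), abs=0.3)

    def test_large_count_ic_approaches_raw_ratio(self):
        # shrinkage vanishes when the joint count is large
        t = Contingency2x2(2000, 18000, 20000, 1_980_000)
        raw = math.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c)))
        assert bcpnn_ic(t).ic == pytest.approx(raw, abs=0.15)


def _simulate_cells(rng, n_cells, prior: GPSPrior | None):
    E = rng.uniform(5.0, 50.0, size=n_cells)
    if prior is None:
        lam = np.ones(n_cells)
    else:
        comp1 = rng.random(n_cells) < prior.pi
        lam = np.where(comp1,
                       rng.gamma(prior.alpha1, 1 / prior.beta1, n_cells),
                       rng.gamma(prior.alpha2, 1 / prior.beta2, n_cells))
    n = rng.poisson(lam * E)
    keep = n >= 1
    return n[keep], E[keep]


DEFAULT_PRIOR = GPSPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class TestGpsPrior:
    def test_pure_poisson_recovers_unit_mean(self):
        rng = np.random.default_rng(42)
        n, E = _simulate_cells(rng, 5000, None)
        fit = fit_gps_prior(n, E)
        assert fit.mean == pytest.approx(1.0, rel=0.10)

    def test_likelihood_dominance_at_truth(self):
        rng = np.random.default_rng(43)
        n, E = _simulate_cells(rng, 5000, DEFAULT_PRIOR)
        fit = fit_gps_prior(n, E)
        ll_true = gps_marginal_loglik(DEFAULT_PRIOR, n, E)
        assert fit.loglik >= ll_true - 1.0

    def test_single_component_data_recovered_as_distribution(self):
        """Data from a single gamma component: the fitted *mixture
        distribution* must reproduce its mean and variance (the component
        split itself is not identifiable when one component suffices)."""
        rng = np.random.default_rng(44)
        one_comp = GPSPrior(2.0, 4.0, 2.0, 4.0, 0.5)  # effectively 1 component
        n, E = _simulate_cells(rng, 4000, one_comp)
        fit = fit_gps_prior(n, E)
        m1, m2 = fit.alpha1 / fit.beta1, fit.alpha2 / fit.beta2
        second_moment = fit.pi * (fit.alpha1 / fit.beta1**2 + m1**2) \
            + (1 - fit.pi) * (fit.alpha2 / fit.beta2**2 + m2**2)
        assert fit.mean == pytest.approx(0.5, rel=0.10)
        assert second_moment - fit.mean**2 == pytest.approx(2.0 / 16.0, rel=0.30)

    def test_too_few_distinct_cells(self):
        with pytest.raises(GPSFitError):
            fit_gps_prior(np.array([3, 3, 3]), np.array([1.0, 1.0, 1.0]))


class TestEbgm:
    def test_shrinkage_vanishes_asymptotically(self):
        r = ebgm_scores((1000, 200.0), DEFAULT_PRIOR)  # a/E = 5, a ≥ 500
        assert r.ebgm == pytest.approx(5.0, rel=0.02)
        assert r.ebgm05 < r.ebgm

    def test_matches_monte_carlo_posterior(self):
        a, E = 1, 1.0
        r = ebgm_scores((a, E), DEFAULT_PRIOR)
        rng = np.random.default_rng(7)
        n_draws = 1_000_000
        l1 = sps.nbinom.logpmf(a, DEFAULT_PRIOR.alpha1,
                               DEFAULT_PRIOR.beta1 / (DEFAULT_PRIOR.beta1 + E)) \
            + math.log(DEFAULT_PRIOR.pi)
        l2 = sps.nbinom.logpmf(a, DEFAULT_PRIOR.alpha2,
                               DEFAULT_PRIOR.beta2 / (DEFAULT_PRIOR.beta2 + E)) \
            + math.log(1 - DEFAULT_PRIOR.pi)
        q = math.exp(l1 - np.logaddexp(l1, l2))
        comp1 = rng.random(n_draws) < q
        lam = np.where(comp1,
                       rng.gamma(DEFAULT_PRIOR.alpha1 + a, 1 / (DEFAULT_PRIOR.beta1 + E), n_draws),
                       rng.gamma(DEFAULT_PRIOR.alpha2 + a, 1 / (DEFAULT_PRIOR.beta2 + E), n_draws))
        assert r.ebgm == pytest.approx(math.exp(np.mean(np.log(lam))), rel=0.01)
        assert r.ebgm05 == pytest.approx(np.quantile(lam, 0.05), rel=0.02)
        assert 0 < r.ebgm05 < r.ebgm < a / E + DEFAULT_PRIOR.mean

    def test_ebgm05_below_ebgm_on_synthetic_database(self, recovery_stats):
        stats, prior, truth = recovery_stats
        ok = stats.dropna(subset=["ebgm"])
        assert len(ok) and (ok["ebgm05"] < ok["ebgm"]).all()

    def test_collapsed_prior_matches_closed_form(self):
        """With both components equal the posterior is a single gamma, so
        EBGM has the closed form exp(ψ(α+a) − ln(β+E)) and EBGM05 is the
        analytic gamma quantile; the mixture code must collapse to them.
        The posterior *mean* (α+a)/(β+E) then sits between the prior mean
        and the raw ratio a/E — the shrinkage ordering."""
        from scipy.special import digamma

        prior = GPSPrior(2.0, 2.0, 2.0, 2.0, 0.5)  # collapsed, mean 1
        rng = np.random.default_rng(8)
        n, E = _simulate_cells(rng, 300, DEFAULT_PRIOR)
        for a, e in zip(n, E):
            r = ebgm_scores((int(a), float(e)), prior)
            assert r.ebgm == pytest.approx(
                math.exp(digamma(2.0 + a) - math.log(2.0 + e)), rel=1e-10)
            assert r.ebgm05 == pytest.approx(
                sps.gamma.ppf(0.05, 2.0 + a, scale=1 / (2.0 + e)), rel=1e-6)
            post_mean = (2.0 + a) / (2.0 + e)
            lo, hi = sorted([1.0, a / e])
            assert lo - 1e-12 <= post_mean <= hi + 1e-12

    def test_mixture_ebgm_between_component_posterior_means(self):
        rng = np.random.default_rng(81)
        n, E = _simulate_cells(rng, 200, DEFAULT_PRIOR)
        from scipy.special import digamma

        for a, e in zip(n, E):
            r = ebgm_scores((int(a), float(e)), DEFAULT_PRIOR)
            gm1 = math.exp(digamma(DEFAULT_PRIOR.alpha1 + a) - math.log(DEFAULT_PRIOR.beta1 + e))
            gm2 = math.exp(digamma(DEFAULT_PRIOR.alpha2 + a) - math.log(DEFAULT_PRIOR.beta2 + e))
            lo, hi = sorted([gm1, gm2])
            assert lo - 1e-9 <= r.ebgm <= hi + 1e-9

    def test_zero_expectation_undefined(self):
        r = ebgm_scores((0, 0.0), DEFAULT_PRIOR)
        assert math.isnan(r.ebgm) and r.reason is not None


class TestFlagsAndRanking:
    def test_min_count_rule(self):
        row = {"a": 2, "ror_lo95": 50.0, "prr": 100.0, "chi2": 500.0,
               "ic025": -1.0, "ebgm05": 1.0}
        flags = evaluate_signal(row)
        assert not flags["flag_ror"] and not flags["flag_prr"]
        assert not flags["positive"]

    def test_mhra_combined_rule(self):
        t = Contingency2x2(10, 90, 100, 9900)
        p = prr_chi2(t)
        row = {"a": t.a, "ror_lo95": ror(t).lo95, "prr": p.est, "chi2": p.chi2,
               "ic025": bcpnn_ic(t).ic025, "ebgm05": 0.0}
        assert evaluate_signal(row)["flag_prr"]

    def test_all_null_statistics_negative(self):
        row = {"a": 100, "ror_lo95": 0.8, "prr": 1.0, "chi2": 0.1,
               "ic025": -0.5, "ebgm05": 1.0}
        assert not evaluate_signal(row)["positive"]

    def test_undefined_statistics_flag_false(self):
        row = {"a": 5, "ror_lo95": math.nan, "prr": math.nan, "chi2": math.nan,
               "ic025": 0.5, "ebgm05": math.nan}
        flags = evaluate_signal(row)
        assert not flags["flag_ror"] and not flags["flag_prr"] and not flags["flag_mgps"]
        assert flags["flag_bcpnn"] and flags["positive"]

    def test_rank_report(self, four_report_store):
        tab = build_tables(four_report_store, pd.Index(["r1", "r2"]), level="PT")
        stats = compute_signal_stats(tab)
        top1 = rank_report(stats, by="frequency", top_n=1)
        assert list(top1["term"]) == ["E1"]  # frequency puts E1 before E2
        assert len(rank_report(stats, by="frequency", top_n=50)) == 2

    def test_rank_tie_broken_lexicographically(self):
        stats = pd.DataFrame({"term": ["B", "A"], "a": [5, 5],
                              "ebgm": [1.0, 1.0], "ror": [1.0, 1.0]})
        assert list(rank_report(stats, by="frequency")["term"]) == ["A", "B"]


@given(a=st.integers(1, 500), b=st.integers(1, 500),
       c=st.integers(1, 500), d=st.integers(1, 500))
@settings(max_examples=150, deadline=None)
def test_sign_concordance(a, b, c, d):
    """sign(ROR−1) = sign(PRR−1) = sign(ad−bc) for all-positive tables."""
    t = Contingency2x2(a, b, c, d)
    s = np.sign(a * d - b * c)
    assert np.sign(round(ror(t).est - 1, 12)) == s
    assert np.sign(round(prr_chi2(t).est - 1, 12)) == s
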