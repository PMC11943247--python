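# Methods

This note documents the models and procedures implemented in `faersig`,
the defaults and why, and what the synthetic benchmark does and does not
establish about real spontaneous-reporting data.

## Data model and cleaning

A quarterly package is a set of `$`-delimited ASCII tables — DEMO
(demographics, one row per report version), DRUG (role-coded drug rows),
REAC (MedDRA PT reactions), THER (therapy episodes), OUTC (outcome
codes) — plus, from 2019Q1 on, a deletion list of retracted CASEIDs.
Reports are re-submitted as new versions under the same CASEID, so the
raw tables over-count cases.

**Deduplication** keeps, within each CASEID, the row with the latest
FDA_DT, breaking FDA_DT ties by the largest PRIMARYID. Two numerical
choices are deliberate:

- PRIMARYID is compared numerically when every value parses as an
  integer, otherwise lexicographically with a warning. FAERS PRIMARYIDs
  are numeric in practice; the fallback keeps the rule total.
- Partial FDA_DT values (YYYYMM / YYYY) are padded to their earliest
  completion (day/month = 01) *for ordering only*, which makes the sort
  deterministic without inventing precision.

Deletion lists are applied after deduplication, matching the order of
the cleaning recommendations the rule derives from; CASEIDs on a list
that match no retained case are logged and ignored. The retained set is
order-independent and idempotent (property-tested).

## Event coding

MedDRA is licensed, so the package consumes a TSV stand-in with columns
`pt`, `soc`, and optional `old_pt` (a superseded term renamed to `pt`).
Synonym chains are resolved transitively; cycles are rejected at load.
Each PT maps to exactly one primary SOC, so SOC-level counts are exact
aggregations of PT-level counts. Terms missing from the dictionary are
returned unchanged and collected into an uncoded report — dropping them
silently would bias the database margins.

## Cohort and descriptives

A report enters the cohort when at least one drug row has the
primary-suspect role and a name (drugname or active ingredient) equal —
after trimming, uppercasing and stripping edge punctuation — to one of
the target drug's synonyms. Substring matching is available behind a
flag but off by default: FAERS drug-name free text makes substring rules
over-inclusive.

Severity follows the FDA seriousness convention: any outcome code in
{DE, LT, HO, DS, CA, RI} marks the report severe; reports without
outcome rows are non-severe. Ages are converted to years with the usual
unit factors (DEC ×10, YR ×1, MON ÷12, WK ÷52.14, DY ÷365.25,
HR ÷8765.8); unconvertible ages land in "Not specified". Percentages are
100·count/total rounded **half-up** to 2 decimals — the convention of
published summary tables, pinned by test (banker's rounding would differ
at e.g. 41/2000).

## Disproportionality

The counting unit everywhere is the **distinct (report, term) pair**: a
report mentioning a PT twice contributes one. For a term with pair count
a in the cohort, the 2×2 margins are the cohort's total pair count (a+b)
and the database's (N), so margins are consistent across terms by
construction.

Statistics and default thresholds (all configurable):

| method | estimate | interval | signal rule |
|---|---|---|---|
| ROR | ad/bc | exp(ln ROR ∓ 1.96·√(1/a+1/b+1/c+1/d)) | a ≥ 3 and lower > 1 |
| PRR | [a/(a+b)]/[c/(c+d)] | exp(ln PRR ∓ 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))) | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
| BCPNN | IC (moment posterior) | IC025 = IC − 2√var | IC025 > 0 |
| MGPS | EBGM (posterior geometric mean) | EBGM05 = posterior 5th pct | EBGM05 ≥ 2 |

χ² uses the Yates continuity correction (flag to disable), floored at 0
when the correction exceeds |ad − bc|. Zero cells make ROR/PRR undefined
with an explicit reason rather than silently corrected; an optional
Haldane +0.5 exists for users who want it. Cells with a ≥ 1 are
guaranteed by construction, so undefined values arise only from
pathological margins.

**BCPNN.** The information component uses the standard Beta-prior moment
approximation: marginal priors Beta(1, 1), joint prior weight γ scaled
so the prior IC is centred at 0. It is finite for a = 0 (the prior
regularises empty cells) and approaches log₂ of the raw relative ratio
as counts grow; at small counts it shrinks strongly toward 0 — tests
validate it against Monte-Carlo sampling of the matching Beta
posteriors, not against the raw ratio.

**MGPS.** The relative report rate λ of each (drug, term) cell has a
2-component gamma prior; marginally each observed count is a mixture of
negative binomials with means scaled by the cell's independence
expectation E. The prior is fitted to all database cells with n ≥ 1 by
L-BFGS-B on log-transformed parameters (logit for the weight), from the
conventional start (0.2, 0.1, 2.0, 4.0, 1/3). The default likelihood is
untruncated; a zero-truncation-adjusted likelihood is available and is
the right choice when the n ≥ 1 filter meaningfully censors the data
(the two variants coexist in published software). Posterior scores use
the exact conjugate mixture: EBGM from the digamma identity
E[ln λ] = ψ(shape) − ln(rate) per component, EBGM05 by monotone
root-finding on the mixture CDF to 10⁻⁶ in λ.

Two subtleties worth recording:

- With a 2-component prior, EBGM is *not* guaranteed to lie between the
  raw ratio a/E and the global prior mean: the posterior shrinks toward
  the mean of the component the data select, which can sit past the raw
  ratio. The tested invariants are the ones that actually hold: EBGM
  always lies between the two per-component posterior geometric means,
  and under a collapsed (single-component) prior it equals the gamma
  closed form while the posterior arithmetic mean obeys the classic
  shrinkage ordering.
- When the data are compatible with a single component, the mixture
  split (weights and per-component parameters) is not identifiable even
  though the fitted *distribution* is; recovery tests therefore check
  the mixture's mean and variance, not the raw parameters.

## Time-to-onset

Onset is the whole-day difference between the report's event date and
the **earliest** fully-dated therapy start of the target drug (the first
exposure is the conservative reading of "start of treatment"). Records
with a missing or partial date, or a negative interval, are excluded
from the summary with exactly one recorded reason — partial dates are
excluded rather than imputed, since imputing days around a same-day
phenomenon would manufacture onsets.

The Weibull density is supported on t > 0, but spontaneous reports of an
infusion-triggered reaction are dominated by onset = 0 days. The default
fit therefore uses t′ = days + 0.5 (half-day offset); an
interval-censored likelihood treating day d as the interval [d, d+1) is
available and needs no offset. CIs come from the observed information on
(log α, log β), and the hazard classification uses the CI, not the point
estimate: early-failure only when the shape's upper bound is below 1,
wear-out only when its lower bound exceeds 1, random otherwise, and
indeterminate when fewer than 10 reliable records exist or all onsets
are identical. The last case matters in practice: a sample that is
entirely day-0 carries no shape information, and the honest output is
"indeterminate", not a fitted β — the worked example in the README shows
exactly this.

## Synthetic benchmark: what it emulates, and what it does not

The generator's defaults are the study conditions of a single-drug
FAERS analysis: ~2.4 events per report, 44% missing age, 20% missing
sex, 35% missing therapy/event dates, 5% partial dates, 98% US reports,
5% duplicated cases, 2% deleted cases, onset with a 0.99 point mass at
day 0 and a Weibull(shape 0.6, scale 5 days) tail. Drug–event pair
counts are Poisson around n_drug·q_event·λ, with λ = 1 (or a planted
elevated value) under the null-background option, or drawn from the
2-component gamma mixture matching the MGPS initial prior (mean exactly
1) under the default background. The benchmark database used by the
analysis scripts and the acceptance script plants five pairs at λ ∈
{5, 6, 8, 10} on the target drug over a λ≡1 background, so "null pair"
has an exact meaning for the false-positive measurement.

Passing the recovery tests shows the pipeline's plumbing and statistics
are correct under a model whose assumptions the estimators share. It
does **not** show robustness to what real FAERS contains and the
generator deliberately omits: free-text drug-name noise and misspelling,
indication-driven confounding, reporting waves after media coverage,
duplicate cases that change content between versions, or
country-specific reporting cultures.

## Problem sizes and numerical settings

The benchmark database is 20 000 reports × 26 drugs × 60 terms (~1500
MGPS cells); prior-recovery simulations use 5000 cells; Monte-Carlo
oracles use 10⁵ draws (BCPNN) and 10⁶ (EBGM); Weibull recovery uses 2000
draws. Report TSVs are formatted to fixed precision so identical
configurations reproduce byte-identical outputs; JSON artefacts keep
full precision. All randomness flows through numpy Generators seeded
from a single integer.
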