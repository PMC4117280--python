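# Methods

## The analysis model

The pipeline implements crude (unstratified) disproportionality analysis
of a spontaneous reporting database. The unit of counting is the *report*:
a report with several target drugs or several group terms still counts
once. For a drug ingredient set *D*, a reaction term group *G* and one
calendar-year period, the 2×2 table (a, b, c, d) partitions the period's
initial reports by drug mention × term mention, and the statistics are

* PRR = [a/(a+c)] / [b/(b+d)], with a = 0 giving PRR = 0 and b = 0 with
  a > 0 giving +∞ — no continuity corrections (no Haldane–Anscombe 0.5)
  anywhere, matching the convention under which a zero-exposed-case cell
  prints PRR = 0;
* Yates χ² = N·(max(|ad − bc| − N/2, 0))² / [(a+b)(c+d)(a+c)(b+d)],
  clamped at zero, undefined (reported as a dash) when a margin is zero;
* two-sided Fisher exact p summing hypergeometric point probabilities at
  most (1 + 1e−7)× the observed one; degenerate margins give p = 1;
* Evans signal criteria a ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4 (each threshold
  configurable); an infinite PRR satisfies the PRR criterion.

Reports enter the analysis once per case: the record flagged initial
(sequence 0) is kept, earliest receipt date then smallest report_id
breaking ties among several initials. Cases represented only by follow-ups
are dropped by default (`paper` mode), since follow-up-only content is
deliberately excluded from the frequencies; `retain-earliest` mode keeps
the earliest follow-up instead. Pooled input files are deduplicated before
period assignment; each period is then analyzed independently with its own
denominator N.

### Confidence intervals

Published PRR tables do not always state their interval formula, and the
two common candidates genuinely differ. The package computes both and
labels them:

* `wald-log-prr` (default report): exp(ln PRR ± z·√(1/a − 1/(a+c) + 1/b −
  1/(b+d))); requires a > 0 and b > 0;
* `exact-conditional-or`: limits from inverting the noncentral (Fisher)
  hypergeometric tails at (1−level)/2 per side (via
  `scipy.stats.contingency.odds_ratio`), which stays defined at a = 0
  (low = 0, finite upper limit) and is reported whenever the Wald interval
  is not computable.

The exact interval bounds the odds ratio, not the PRR; the two agree
closely when cases are rare.

### Display rounding

Internally all statistics are kept at full precision. For display, PRR is
rounded to the nearest integer (half away from zero) and χ² to one
decimal, the rounding used in published tables of this analysis (which
print 10 for a computed 9.86 and 2 for 2.001). Two published χ² cells —
hypersexuality 2004 (printed 22.6, computed 22.5447) and pathological
gambling 2007 (printed 16,752.8, computed 16,752.749) — differ from the
closed form in the last printed digit; the package reports the computed
values.

## Vocabulary and drug-name resolution

Reaction terms are matched exactly after case normalization: spontaneous
reporting systems recode reactions to standardized preferred terms at data
entry, so string variance lives in the drug fields, not the reactions. The
four bundled term groups ship as editable YAML; compulsive shopping
matches no preferred term (substring searches for *buy*, *shop*, *spend*
find nothing relevant once shop-lifting is excluded) and is carried as a
non-evaluable group producing dash rows.

Verbatim drug strings resolve in two stages: an exact case-insensitive hit
on any generic name, trade name, or curated misspelling variant wins
outright; otherwise strings of ≥ 6 characters fall back to Levenshtein
distance (edlib) against the generic and trade names, accepting the
nearest ingredient within a configurable maximum distance (default 2) and
refusing ties between ingredients. The ≥ 6-character guard prevents
short-string false hits. All drug roles (primary suspect, secondary
suspect, concomitant, interacting) count as exposure.

## The synthetic generator

The generator emulates a year-stratified spontaneous reporting process
with fully known ground truth. Per report, each of the five ingredients is
an independent Bernoulli(`drug_exposure_prob`) exposure; each vocabulary
term is an independent Bernoulli draw whose probability is the background
rate times the product of the planted `association_multipliers` of the
ingredients present, capped at 1. Every report must carry at least one
reaction, so zero-reaction draws are resampled; this is implemented as
exact conditional (≥ 1 success) sampling via the chain rule, which is
distributionally identical to rejection but O(n·T). Follow-up duplicates
(same case id, copied content, 1–90 days later truncated at year end) and
misspelled drug mentions (rewritten to lexicon variants) are separate,
seeded injections, so the dedup and matching stages can be tested as exact
inverses.

Because all mechanisms are independent Bernoulli draws, the reporting-rate
ratio a planted multiplier induces has a closed form; `expected_prr`
computes P(case | exposed, ≥1 reaction) / P(case | unexposed, ≥1 reaction)
exactly, marginalizing over other multiplier-bearing ingredients. With a
multiplier of 50 on the two-term gambling group at per-term background
1e−3, the implied PRR is 48.6, not 50 — the target the recovery tests use.

Defaults mirror the scale of the 2004/2007 snapshots the pipeline targets:
per-period totals of 199,754 and 254,162 reports; per-ingredient exposure
probability 1e−3 (≈ 0.5% of reports mention any of the five agonists,
matching 927/199,754 and 2,345/254,162); behavioral-addiction term
probability 1e−4 per preferred term (case counts of order 30–300 per
period); and twelve common neutral ADR terms at probability 0.25 each, so
that ~97% of reports carry a reaction before conditioning and the ≥ 1
constraint barely perturbs term frequencies.

What the generator does *not* emulate: publicity-driven secular trends in
reporting rates (beyond running different configs per period),
demographics, dosing, indications, outcomes, correlated drug–drug or
term–term structure, and probabilistic duplicates across distinct case
identifiers. Passing calibration tests therefore show that the estimators
recover the parameters of this idealized process, not that FAERS data meet
its assumptions.

## Fixture databases

The bundled reference fixture realizes the published 2004/2007 cell
counts (total reports, dopamine-agonist reports, exposed/unexposed cases
per group) as synthetic records — one reaction term per report, drug
mentions cycling through generic and trade spellings and odd casing. It
reproduces the published margins and statistics exactly through the full
pipeline; the raw-count denominators themselves are inputs (they require
the original database download and are not derivable at a desk).

## Problem sizes and numerical choices

* Exhaustive Fisher validation enumerates all 135,751 tables with N ≤ 40
  against exact-rational enumeration at 1e−10.
* Null calibration uses 100 databases of 20,000 reports with exposure 0.02
  and per-term background 0.01, sizing every (ingredient, group) pair to
  ≥ 3 expected cases; the joint Evans criteria are conservative, so the
  observed firing rate sits well below 5%.
* Parameter recovery uses one 200,000-report database with a planted
  multiplier of 50 (±30% tolerance) plus a smaller 60,000-report setting.
* Point-probability ties in the Fisher test use relative tolerance 1e−7;
  the exact-CI inversion relies on scipy's root-finding defaults.
* Dates are ISO in memory regardless of file dialect; period = receipt
  year. The writer rejects field values containing the dialect delimiter
  rather than escaping them, keeping the legacy format trivially parseable.
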