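# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
report databases, built around the analysis of behavioral addictions
(binge eating, compulsive shopping, hypersexuality, pathological gambling)
reported with five dopamine agonists (bromocriptine, cabergoline,
pergolide, pramipexole, ropinirole) in FAERS-style data, together with a
synthetic report generator so the entire pipeline can be exercised — and
its estimators validated against known ground truth — without access to
the real database.

It is aimed at pharmacovigilance analysts and methods researchers who want
a tested, scriptable implementation of the classic proportional-reporting-
ratio workflow: parse legacy quarterly ASCII report files, exclude
follow-up reports, resolve verbatim drug names (trade names and
misspellings included), build 2×2 report contingency tables per reaction
term group and calendar year, and apply threshold-based signal criteria.

## The statistic

For a drug set *D* and a reaction term group *G*, each initial report
falls into one cell of a 2×2 table: *a* (mentions a drug in *D* and a term
in *G*), *b* (term only), *c* (drug only), *d* (neither). The proportional
reporting ratio is

```
PRR = [a / (a + c)] / [b / (b + d)]
```

with the Yates continuity-corrected chi-square

```
χ² = N · (max(|ad − bc| − N/2, 0))² / [(a+b)(c+d)(a+c)(b+d)],   N = a+b+c+d
```

and a two-sided Fisher exact p-value by point-probability ordering. A
drug–reaction pair is flagged as a *signal* by the Evans criteria when
a ≥ 3, PRR ≥ 2 and χ² ≥ 4 — a screening threshold that marks a pair as
worth manual review, not evidence of causation. Confidence intervals are
reported as Wald intervals on the log PRR, with exact conditional
odds-ratio limits (noncentral hypergeometric inversion) as a labelled
alternative that remains finite when a = 0.

## Worked example

Run the pipeline on the bundled fixture databases, which realize the
published 2004/2007 dopamine-agonist report counts record by record:

```
$ pvsignal reference
group	period	evaluable	a	b	prr	ci_low	ci_high	ci_method	chi2_yates	fisher_p	signal
binge_eating	2004	True	0	251	0	0.0	3.2	exact-conditional-or	0.4	0.636	False
compulsive_shopping	2004	False	0	0	-	-	-	-	-	-	False
hypersexuality	2004	True	4	87	10	3.6	26.8	wald-log-prr	22.5	0.000894	True
pathological_gambling	2004	True	28	5	1201	464.8	3103.8	wald-log-prr	4906.9	7.12e-61	True
binge_eating	2007	True	6	322	2	0.9	4.5	wald-log-prr	2.0	0.133	False
compulsive_shopping	2007	False	0	0	-	-	-	-	-	-	False
hypersexuality	2007	True	30	65	50	32.2	76.2	wald-log-prr	943.8	1.97e-37	True
pathological_gambling	2007	True	170	14	1304	757.3	2245.3	wald-log-prr	16752.7	0	True
```

Reading the pathological-gambling rows: of the 33 reports mentioning
gambling terms in 2004, 28 also mention a dopamine agonist, a reporting
rate about 1,201 times that of all other drugs — a robust signal in both
years. Hypersexuality signals weakly in 2004 (4 cases, PRR 10) and
strongly in 2007; binge eating never crosses the threshold (χ² stays below
4); compulsive shopping has no matching preferred term at all and is
reported as a non-evaluable dash row.

The same pipeline runs on synthetic data with planted associations:

```python
from pvsignal import SyntheticConfig, AnalysisConfig, run_analysis

cfg = AnalysisConfig(
    synthetic=SyntheticConfig(
        n_reports_per_period=200_000,
        periods=("2004",),
        drug_exposure_prob=0.01,
        background_term_prob=0.001,
        association_multipliers={"pramipexole": {"pathological_gambling": 50}},
        random_seed=1,
    ),
    periods=("2004",),
)
report = run_analysis(cfg)
print(report.to_tsv())
```

Here the planted reporting-rate ratio of 50 implies an analytic PRR of
48.6 (`pvsignal.expected_prr`), and the pipeline's estimate lands within a
few percent of it at this sample size.

Other entry points: `pvsignal simulate` writes a synthetic database as
legacy quarter files, `pvsignal analyze` runs a configured analysis,
`pvsignal convert` / `pvsignal validate` re-dialect and check quarter
directories, `pvsignal vocab list|check` inspects the bundled term groups
and drug lexicon.

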