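# Methods

## Setting

Spontaneous reporting systems such as the FDA Adverse Event Reporting System
(FAERS) collect voluntary reports of suspected drug adverse events. They have
no denominators — nobody knows how many patients took a drug without an event
being reported — so association between a drug and an event is assessed by
*disproportionality*: does the event make up a larger share of the reports
mentioning the drug than of the reports mentioning other drugs?

pvkit implements the standard analysis chain for such data, oriented toward a
HER2-inhibitor safety cohort (trastuzumab, pertuzumab, the antibody–drug
conjugates TDM-1 and T-DXd, and the small molecules lapatinib, neratinib,
tucatinib, pyrotinib), with hemorrhagic events and their time to onset as the
focal outcomes.

## Report cleaning

FAERS distributes quarterly '$'-delimited ASCII tables (DEMO, DRUG, REAC,
OUTC, THER) keyed by PRIMARYID, with CASEID linking versions of one safety
report. Cleaning follows the conventional rules:

* **Deduplication.** Per CASEID keep the record with the most recent FDA
  receipt date (FDA_DT), breaking ties by the higher PRIMARYID. FAERS dates
  may be year- or month-precision; missing components compare as smallest,
  which makes the order total and the rule deterministic.
* **Exposure.** Only drugs in primary-suspect (PS) or secondary-suspect (SS)
  roles define exposure. Concomitant (C) and interacting (I) drugs stay on
  the case as context.
* **Drug matching.** Reported drug names are matched to canonical active
  ingredients through a synonym dictionary (trade names, generic names,
  active-ingredient strings), whole-string after case-folding and
  punctuation stripping. Substring matching is deliberately avoided so the
  bare antibody name does not swallow its conjugates ("trastuzumab" vs
  "trastuzumab emtansine"); combination-ingredient strings must be listed
  explicitly. The active-ingredient field (PROD_AI, present after 2014) is a
  fallback when the free-text name fails.
* **Regimen.** A case is monotherapy when its suspect drugs map to exactly
  one distinct canonical target ingredient, combination at two or more.
  Counting distinct canonical ingredients means trade/generic aliases never
  masquerade as a combination.

## Disproportionality statistics

For a drug–event pair the 2×2 table is

|              | target event | other events |
|--------------|--------------|--------------|
| target drug  | a            | b            |
| other drugs  | c            | d            |

counted over deduplicated cases (a case counts once per pair regardless of
repeats). Two statistics are computed:

* **PRR** = (a/(a+b)) / (c/(c+d)), with the log-normal 95% CI
  exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
  When a = 0 or c = 0 the Haldane–Anscombe 0.5 correction is applied to all
  four cells and the result is flagged; this keeps estimates finite and is
  conventional. The point estimate is computed as a·(c+d) / ((a+b)·c) with a
  single final division, so for integer counts it is the correctly rounded
  value of the underlying rational number.
* **Information component** (BCPNN family): IC = log₂((a+0.5)/(E+0.5)) with
  E = (a+b)(a+c)/N, and the closed-form credibility lower bound
  IC025 = IC − 3.3·(a+0.5)^(−1/2) − 2.0·(a+0.5)^(−3/2).
  This observed/expected shrinkage form with the closed-form percentile
  approximation is the variant standard in modern practice; it is isolated
  behind one function so the original Beta/Dirichlet formulation could be
  swapped in.

A pair is a **signal** when n > 3 (i.e. at least 4 cases), PRR ≥ 2 and the
PRR CI lower limit exceeds 1.0. `min_cases` is configurable (some analyses
use n ≥ 3). The background ("other drugs") is by default every other case in
the supplied collection; `background="cohort"` restricts it to cases exposed
to at least one screened drug. No multiplicity correction is applied across
the screen — signals are hypotheses, not inferences.

## Event classification and summaries

Hemorrhagic events are recognised lexically: any PT containing the stem
"haemorrhag" (or the American "hemorrhag"), plus a whitelist (default
{"Haemorrhoids"}) for hemorrhagic conditions without the stem. Intracranial
hemorrhage and thrombocytopenia are explicit PT lists (configurable;
defaults cover the nine intracranial PTs and
{Thrombocytopenia, Platelet count decreased}).

Reporting rates are case-level: exposed cases reporting ≥ 1 matching PT over
all exposed cases. Characteristic tables count Regimen/Age/Sex as partitions
of the case total; outcome codes, SOCs and PTs count a case once per level
it touches (FAERS multiplicity). Percents are rendered at two significant
figures: ≥ 10% as integers, below 10% with one decimal, positive values
under 0.1% as "<0.1%".

Time to onset is the DEMO event date minus the earliest therapy start date
for the drug, in months of 30.4375 days (Gregorian mean, configurable).
Dates missing only the day are imputed to day 15, bounding the error at ±15
days; month-missing dates are excluded, as are negative intervals. Medians
are compared with rank tests: Wilcoxon rank-sum for two strata (exact
two-sided p by full enumeration with midranks when the combined sample size
is ≤ 10, otherwise the normal approximation with tie correction and no
continuity correction), Kruskal–Wallis beyond two. The chi-square test is
Pearson's without Yates correction by default (a flag enables it); zero
expected counts raise an error pointing to exact tests.

## Synthetic reporting system

The generator emulates the FAERS structure with known truth so every stage
is testable without the external download. Per case: drug exposures are
independent Bernoulli draws from per-drug marginals (defaults echo the
cohort's relative report volumes, trastuzumab 0.25 down to pyrotinib 0.005);
with probability `polypharmacy_rate` (0.15) a case is forced to carry ≥ 2
target drugs. Each PT in a toy 22-term vocabulary is reported with its
baseline probability, multiplied by ρ when an injected association applies
to an exposed drug (clamped to 1). Because the injected effect multiplies
the per-case reporting probability, ρ is exactly the reporting-rate ratio
the PRR estimates, which makes recovery tolerances interpretable.

Drug rows use a randomly chosen synonym (PS for the first target drug, SS
for later ones); 5% of rows carry an unmatchable free-text name with the
correct active-ingredient string, exercising the PROD_AI fallback. Therapy
start dates anchor a log-normal onset interval per drug (medians ≈ 0.5
months for trastuzumab, 0.75 for TDM-1, 6 for lapatinib, 2 otherwise);
event dates are start + interval, receipt dates follow after a short delay.
Partial-date missingness (event 20%, start 30%, day component 10%) and age
missingness (25%) are injected. Default injected associations mirror the
class's known profile: TDM-1–thrombocytopenia (ρ=6), TDM-1– and
T-DXd–cerebral haemorrhage (4, 3), T-DXd–interstitial lung disease (8),
tucatinib–memory impairment (5).

Duplicates: with probability `duplicate_rate` (0.10) a case emits a second
report version with the same CASEID, a higher PRIMARYID and an
equal-or-later FDA_DT (half later, half equal, so both branches of the
dedup rule are exercised). The full report is cloned — child DRUG/REAC/
OUTC/THER rows are re-keyed to the new PRIMARYID — matching how FAERS
follow-ups carry complete content; cloning only the DEMO row would leave
the surviving version empty after deduplication.

All randomness flows from one `numpy` generator seeded from the config, so
a configuration reproduces byte-identical files.

**What the generator does not emulate:** drug-name misspellings,
longitudinal patient histories across cases, country- or period-specific
reporting effects, correlated adverse events within a case, regimen-
dependent onset times, and real MedDRA breadth (the toy vocabulary has 22
PTs). Passing recovery and calibration tests therefore demonstrates that
the statistics and plumbing are correct under the stated generative model,
not that real-FAERS point estimates would be reproduced.

## Benchmark problem sizes

Effect-size recovery uses a single injected association (exposure marginal
0.1, baseline 0.01) at 50,000 cases, ρ ∈ {2, 4, 8}, median over 20 seeds,
with a 15% tolerance; at these sizes the exposed cell holds a ≈ 500·ρ/2
events and the seed-to-seed spread of the median is a few percent. Null
calibration screens 20 seeds of 20,000 cases with no injected associations
and requires under 5% of pairs flagged. The end-to-end pipeline checks run
at 3,000–20,000 cases.

## Known limitations

* Disproportionality flags reporting imbalances, not causation; the package
  inherits every bias of spontaneous reports (under-reporting, notoriety,
  confounding by indication).
* The PT→SOC vocabulary is user-supplied (MedDRA is licensed); analyses are
  only as good as the supplied mapping, and only PT and SOC levels are
  supported (no HLT/HLGT).
* Sequential exposure to two inhibitors within one report is
  indistinguishable from concomitant combination therapy.
* Time to onset uses the DEMO event date; therapy end dates are parsed but
  not used in interval logic.
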