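# Methods

## Scope and design

The package quantifies differential adverse-event reporting among the three
FDA-approved BCMA-directed T-cell therapies for relapsed/refractory multiple
myeloma (ide-cel, cilta-cel, teclistamab) from spontaneous-report data in
the FAERS quarterly ASCII format. It is a case/non-case (disproportionality)
design: no denominators of treated patients exist, so every statistic is a
contrast of reporting odds, not of incidence. The comparator set for each
drug is the union of the other in-scope study drugs, not the whole database
background — the three products share an indication and a reporting era,
which removes much of the indication bias a whole-database comparator would
carry.

## Ingestion and case definition

FAERS distributes four relevant tables per quarter (DEMO, DRUG, REAC, OUTC),
dollar-delimited with no quoting or escaping. Parsing therefore splits on
the literal `$`; rows whose field count disagrees with the header are
rejected with a logged line number, undecodable bytes are replaced (logged),
and child rows without a DEMO parent are dropped with a logged count rather
than failing the quarter.

A case may appear under several report versions. Deduplication keeps, per
`caseid`, the row with the highest `(caseversion, numeric primaryid)` —
the standard latest-version rule; the source analysis does not state its
rule, so this choice is recorded here as an assumption.

The analysis cohort contains cases whose drug rows map to **exactly one**
distinct canonical study drug. "More than one drug" is read as more than one
*study* drug: concomitant non-study medication (lenalidomide,
dexamethasone, …) never excludes a case, because essentially every myeloma
report lists supportive drugs and the exclusion would otherwise empty the
cohort. Drug-name matching is exact after normalization (uppercase, trim,
whitespace collapse, strip one trailing parenthetical) against an editable
lexicon of brand/generic/development-code variants; fuzzy matching is
deliberately out of scope. Role codes are ignored by default (an option
restricts mapping to primary/secondary suspect rows). Ages convert to years
(months ÷ 12, days ÷ 365.25).

## Event taxonomy

Reaction preferred terms map to composite categories through an editable
dictionary; matching is exact and case-insensitive after whitespace
collapse, never substring-based, and the category term sets must be pairwise
disjoint (validated at load). The shipped default encodes the entities named
in the source analysis — CRS, ICANS, a non-ICANS neurotoxicity composite
(Bell's palsy, facial paralysis, parkinsonism, encephalopathy, tremor,
aphasia, delirium, cranial nerve disorder, peripheral neuropathy, PML), and
infection subcategories (pneumonia, sepsis, COVID-19, unspecified infection,
PJP, CMV reactivation, CMV pneumonia) — plus an `infection (composite)`
union used for a single infection-wide ROR. The exact preferred-term lists
behind the published counts are not public, so the shipped dictionary is a
documented default, not a reconstruction; the published infection ROR in
particular is not reproducible from the published count table under any
composite we form, and is not asserted anywhere.

## Outcomes and non-relapse mortality

Seriousness flags come from the OUTC codes only (DE death, LT
life-threatening, HO hospitalization; DS/CA/RI/OT pooled as other-serious),
non-exclusively. Death is defined by the DE code alone — a "Death" reaction
term without DE is logged but not counted, keeping the reaction and outcome
channels separate. A fatal case is non-relapse mortality when none of its
reaction terms is in the progression set (default: disease progression,
malignant neoplasm progression, multiple myeloma). Emptying the progression
set reduces NRM to all-cause fatal reports; both all-cause and NRM odds
ratios are exposed, because the published NRM odds ratios are numerically
consistent with all-cause fatal counts and the exact convention used there
cannot be determined.

## Estimation

ROR and mortality OR are cross-product odds ratios with Wald log-normal
intervals, `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))` — the only interval method
consistent with the published CIs. Reaction RORs use event-level
denominators and mortality ORs case-level denominators; recomputation of the
published percentages confirms exactly this convention. Zero cells receive
the Haldane–Anscombe +0.5 on all four cells and set a `corrected` flag; a
category unseen in both arms yields a no-estimate marker (`None`) rather
than a number, and a drug with no reports at all yields an empty panel row.
Reported numbers round half-away-from-zero (ratios two decimals,
percentages one); medians and IQRs use type-7 (midpoint) quantiles. No
multiplicity adjustment is applied, matching the source analysis;
PRR/IC/EBGM-style shrinkage estimators are out of scope.

## Synthetic data generator

`simulate_quarter` emulates the statistical structure the analysis assumes,
per drug: case count `n_cases`; events per case ~ Poisson(λ) truncated at 1
(every report carries a reaction); reaction terms i.i.d. multinomial within
case; independent Bernoulli outcome flags (death, life-threatening,
hospitalization), so a case can be fatal and hospitalized; a
disease-progression term appended with `p_progression_given_death` when
fatal. Two nuisance processes exercise ingestion: `duplicate_rate` emits an
earlier case version (reactions copied, age perturbed, one outcome row
dropped) that deduplication must discard, and `polypharmacy_rate` adds a
second study-drug row that cohort building must exclude. Ages are uniform
45–80 years and sex is Bernoulli(0.35 female) — cosmetic fields that match
the observed magnitudes but feed no statistic. Determinism: one
`numpy.random.Generator` seeded from the config drives all sampling, so a
fixed seed reproduces the emitted files byte for byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-case term correlation (real CRS and ICANS
co-report), reporting-date structure and dose/latency timing, free-text
drug-name noise beyond the configured variants, regional/reporter fields,
and the true MedDRA vocabulary breadth. Recovery results validate the
estimator machinery, not FAERS epidemiology.

`expected_ror` is the closed-form target for parameter recovery: with `p`
the index drug's probability mass over a category's terms and `q` the
mixture of comparator masses weighted by expected event volume
(`n_cases × λ/(1−e^{−λ})`, the truncated-Poisson mean), the implied ROR is
`(p/(1−p))/(q/(1−q))`. The appended progression terms are outside this
closed form; benchmark configurations share death rates across drugs so the
small (<1%) event-denominator dilution cancels in the ratio.

## Calibration benchmarks

The standard recovery benchmark (`benchmark_recovery_config`) uses three
drugs with high-frequency composite categories (event masses 0.15–0.37,
expected RORs ≈ 0.5–2.2), λ = 2.5 events per case (FAERS-like: the observed
table averages ≈ 1.8–3.7 reaction rows per case), shared outcome rates, 5%
duplication and 3% polypharmacy. Problem sizes were chosen so each check is
statistically decisive at desk scale: end-to-end bias is measured as the
mean log-ROR deviation from the closed form over 20 replicates of
3 × 2000 cases (per-cell Monte-Carlo SE ≈ 0.007, against a 0.05 bound — a
single 2000-case quarter has per-cell sampling noise of 0.03–0.05 log
units, so the mean over replicates is the meaningful bias measure, and the
single-draw 0.05 bound is only reached around 20,000 cases per drug);
Wald coverage uses 1000 binomial tables at true OR = 2 with 500 reports per
arm (binomial SE ≈ 0.7%, against a 93–97% band); null coverage of unity
uses 200 replicates of 3 × 500 cases with a ≥ 90% per-cell bound.

## Known limitations

* Spontaneous-report data: no incidence, reporting bias, and channel-mix
  differences between products are inherited by every ROR.
* The term dictionary and drug lexicon are defaults; analyses of real
  quarters should review both against the current MedDRA release and
  product vocabulary.
* Exact-match drug mapping will miss misspelled verbatim names; unmatched
  rows are logged, not imputed.
* Case-version deduplication assumes numerically comparable `primaryid`s
  for tie-breaking; non-numeric identifiers fall to the end of the order.
* The generator's i.i.d. reactions understate within-case clustering, so
  real-data CIs may be anti-conservative relative to the simulated coverage
  reported here.
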