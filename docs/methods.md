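# Methods

## The model

`tariffva` assigns causes of death to verbal-autopsy (VA) interview
records and estimates population cause-specific mortality fractions
(CSMFs). The diagnostic engine is the tariff method: a purely data-driven
score that asks, for every symptom–cause pair, how unusually often deaths
of that cause endorse that symptom.

Given a gold-standard database (deaths whose cause is reliably known,
e.g. hospital-confirmed) the endorsement rate `x[c, s]` is the fraction of
cause-`c` deaths answering "yes" to symptom `s`. The tariff is the
per-symptom robust z-score across causes,

    t[c, s] = (x[c, s] − median_c' x[c', s]) / IQR_c' x[c', s],

with median and interquartile range taken over causes using linear
interpolation between order statistics (the convention is recorded in the
matrix metadata so independent recomputations can match exactly). A
symptom endorsed identically across causes carries no signal: its column
is zero, which also covers the degenerate IQR = 0 case. At least three
causes are required for the median/IQR to be meaningful.

Two optional post-processing steps, on by default and recorded in
metadata, mirror deployed practice: rounding scores to the nearest 0.5
(midpoint ties away from zero, for determinism) and truncating each
cause's row to its 40 largest-|tariff| symptoms (ties at the cut broken by
symptom order). Bootstrap significance filtering of individual tariffs is
not implemented; the metadata marks it unavailable.

A record's score for cause `c` is the sum of `t[c, s]` over symptoms
endorsed "yes". Missing responses are preserved in storage but score as
"not endorsed" — the tariff sum is over positive endorsements only, which
keeps the data auditable.

## Assignment and the undetermined category

Raw tariff scores are not comparable across causes, so assignment is by
rank: the gold standard is resampled with replacement to a uniform cause
composition (`per_cause_n` of each cause, default 100), the resample is
scored, and a record's rank for cause `c` is 1 + the number of baseline
scores under `c` strictly greater than its own (ties favour the record).
The uniform composition matters: it prevents the training database's cause
mix from leaking into population estimates. The resample is seeded and
reproducible.

The best-ranked eligible cause is assigned unless a cutoff rule declares
the death undetermined: (a) best rank > `rank_quantile_cutoff` × baseline
size, (b) best score < `minimum_score`, or (c) best rank >
`overall_rank_cap` × baseline size. Defaults are 0.89, 0 and 1.0.
A practical note on these defaults: because the assigned rank is the
*minimum* over C causes, its distribution concentrates well below the
baseline size (around size/(C+1) for signal-free records), so rule (a) at
0.89 fires only in extreme cases. The regime in which the undetermined
mechanism is genuinely active is a much tighter cap — deployed tariff
software uses an overall cap near 0.18 — and the test-bed exercises the
mechanism there. All three thresholds are configuration, not code, and a
`NO_CUTOFFS` policy is provided for accuracy studies. Demographic
restrictions (e.g. maternal causes female-only, 12–49 years) are an
editable table applied before ranking; unknown age or sex never excludes
a cause, only positively contradicting evidence does.

The top-3 ranked causes, with scores and ranks, are exposed separately for
decision-support workflows in which a physician reviews candidates before
certifying. Ties are broken by ascending rank, then descending score, then
cause-list order, so output is deterministic under permutation of the
cause list up to the documented final tie-break.

## Redistribution of undetermined deaths

Undetermined deaths are reallocated at the population level only —
individual predictions are never altered. Per (sex, age-group) stratum the
allocation weight is `λ·w_frac + (1−λ)·w_ref`, renormalised, with λ = 0.5
(the unweighted mean) by default:

* `w_frac` — undetermined-propensity weights: run the gold standard
  through the trained pipeline and count, per true cause, how often it
  comes back undetermined; weights are the normalised per-cause rates.
  Conditions that are inherently hard to diagnose from an interview
  (classically pneumonia) earn larger weights than, say, road-traffic
  deaths. Estimated by stratified 5-fold cross-validation by default to
  avoid resubstitution bias (an in-sample mode exists and is cheaper but
  optimistic). If no gold-standard record is undetermined the weights are
  undefined; the implementation falls back to uniform weights with a
  logged warning rather than failing a batch run.
* `w_ref` — the reference (GBD-style) cause fractions for the stratum,
  renormalised over the causes the pipeline can assign. Unknown sex
  averages the male and female strata; unknown age uses the unweighted
  mean over the sex's age strata (a population-weighted marginal would
  need denominators the reference table does not carry).

`w_frac` is global rather than age-sex-specific: per-cause undetermined
counts in a single stratum would be far too sparse to estimate reliably at
realistic gold-standard sizes. Mass is conserved to 1e-6 by construction,
and a ranking-stability check (is the cause ordering the same before and
after redistribution?) is computed and reported on every run rather than
assumed.

## CSMFs, uncertainty and validation metrics

Before redistribution the undetermined category is reported as its own
entry; after redistribution it is zero and the assignable causes sum
to 1. Uncertainty is a percentile bootstrap over deaths (B = 1000 by
default, seeded): each replicate resamples the n predictions with
replacement, recounts causes and per-stratum undetermined deaths, and
reapplies the fixed combined weights — the weights are inputs estimated
from the gold standard, not resampled quantities. Every replicate
conserves mass exactly. The same replicates yield broad-group CIs. On a
two-cause 50/50 CSMF at n = 100 the bootstrap interval agrees with the
exact binomial quantile interval to within 0.02 (checked in the tests
against `scipy.stats.binom`, an independent closed form).

Chance-corrected CSMF accuracy is

    1 − Σ_c |true_c − pred_c| / (2 (1 − min_c true_c)),

which is 1 iff the distributions are equal and 0 when all predicted mass
sits on the truth's rarest cause (the worst attainable error). With a
single-cause truth the denominator vanishes; the metric is then defined as
1 exactly on agreement.

The plausibility report operationalises a qualitative review into two
quantitative triggers: the index of dissimilarity between the VA and
reference age distributions (half the sum of absolute percentage-point
differences, in [0, 100]) and a flag for each broad group whose reference
fraction falls outside the VA 95% CI. Age-table percentages are rounded to
one decimal, the precision at which such tables are printed.
Registration-completeness checks need population denominators outside this
package's scope; the report prints a placeholder prompting external input.

## Synthetic data

Real gold-standard databases and CRVS extracts are licence-restricted, so
the test-bed runs on a generative model: each cause owns a disjoint block
of `signature_size = 3` signature symptoms endorsed with probability
`signal = 0.95`; all other symptoms are endorsed at `background_rate =
0.05`; symptoms are independent given the cause. Defaults are 10 causes,
40 symptoms, 500 training records per cause and 5,000 field deaths, with
the true CSMF a normalised geometric sequence (ratio 0.8) — a realistic
gradient from common to rare causes in which the rarest cause still
expects ~170 deaths at the default n. Ages and sexes follow three
archetypes cycled over causes (young-injury: age ~ N(32, 12²), 70% male;
mid-infectious: N(48, 15²), 55% male; old-NCD: N(72, 12²), 48% male;
ages clipped to [12, 99] and floored to integer years), which also fixes
each cause's broad group and gives Table-style age gradients
qualitatively.

The reference distribution is the *analytic* stratified cause distribution
implied by the same model (normal CDFs for the age bins), optionally
perturbed: multiplicative `exp(d·U(−1,1))` noise per stratum-cause cell,
or a directed `shift_group_mass` move for constructing scenarios where the
reference disagrees with the field truth in one broad group.

What the model omits — symptom dependence within a cause, interviewer and
recall error, free-text narratives, cause lists with overlapping symptom
profiles — bounds what passing tests show: they demonstrate the pipeline's
arithmetic and its behaviour under a known signal, not field diagnostic
accuracy, which can only be established against real validation data.

## Numerical and design choices

* Age bins are closed integer ranges (12–19 means 12 ≤ age ≤ 19);
  fractional ages are floored; the adult floor is 12 and younger deaths
  are an error, as they belong to child/neonate instruments. Unknown age
  is a first-class bin.
* Quantiles everywhere use numpy's linear interpolation; tariff metadata
  records this so oracle recomputations can match bitwise.
* All stochastic steps (baseline resampling, cross-validation folds,
  bootstrap, generators) take explicit seeds; batch outputs are stamped
  with the seed and a hash of the configuration, and a rerun with the same
  inputs is byte-identical.
* Problem sizes in the test-bed (e.g. 5 seeds × 5,000 deaths for recovery
  checks, B = 500 for CI-width comparisons, n scaled to 10,000 for the
  large-sample arm) were chosen as the smallest sizes at which the checked
  effects are unambiguous.

## Known limitations

* The shipped demographic-restriction table is empty by default: synthetic
  causes are abstract, and real deployments should populate it per their
  cause list.
* Fractional weights degrade to the uniform fallback when the cutoff
  policy never produces undetermined gold-standard deaths; the provenance
  field records when this happened.
* Free-text narratives and child/neonate modules are out of scope; the
  pipeline covers adult, structured-questionnaire deaths only.
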