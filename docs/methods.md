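# Methods

## The analysis model

The unit of analysis throughout is the **treatment day**: a calendar day on
which a patient has at least one active antipsychotic prescription
(prescriptions are date spans with inclusive endpoints and a constant daily
dose; dose tapering within a span is not modelled). Days without an active
prescription are not zero-dose days — they are simply outside the analysis.

Each treatment day's drug load is normalized three ways:

| method | table entry | conversion | bin width |
|---|---|---|---|
| `ddd` | mg per defined daily dose | dose ÷ entry (unit: DDDs) | 0.5 DDD |
| `olanzapine_eq` | mg olanzapine per mg drug | dose × entry (mg OLZ) | 5 mg |
| `chlorpromazine_eq` | mg chlorpromazine per mg drug | dose × entry (mg CPZ) | 100 mg |

Polypharmacy sums over all active prescriptions, including two overlapping
prescriptions of the same drug (summation is the only reading consistent
with totalling a day's exposure; taking a maximum would discard real
co-prescription). A day with any drug outside a method's coverage is
*unconvertible* — never silently zero — and any such day excludes the
patient from that method's cohort, after the prior exclusion of patients
with ambiguous prescription records. The packaged conversion file pins the
*coverage pattern* (21 drugs convertible to DDDs, 19 to olanzapine
equivalents, 9 to chlorpromazine equivalents); the factor values themselves
are literature-typical maintenance equivalences and are user-overridable —
the package's tests deliberately pin coverage and linearity, not any
third-party factor value.

**Word counts** follow POSIX `wc -w` exactly: a word is a maximal run of
characters outside {space, tab, newline, CR, FF, VT}. This is chosen for
bit-compatibility with the standard Unix tool rather than linguistic
sophistication; punctuation stays attached and no Unicode segmentation is
applied. Daily counts are formed for all staff, physicians only, and
nursing only. A treatment day with no notes contributes zero words (the
conservative reading: the day was observed and nothing was written), while
notes on non-treatment days never enter the dose analyses.

**Binning and association.** Bin k of width w is ((k−1)·w, k·w] —
lower-open, upper-closed, so a dose exactly at a cut-off belongs to the
lower bin. Per bin, each member patient contributes the arithmetic mean of
their daily word counts over exactly their days in that bin; a patient with
days in several bins legitimately appears in each. The bin statistic is the
median of patient means (median of means, not of raw days — the per-patient
averaging step is integral to the procedure), with the usual
midpoint-of-two convention at even counts. Bins under the patient floor
(default 100 for the note-length analysis) are dropped. The association is
summarized as Spearman's ρ between bin index and bin median over surviving
bins — a deliberately minimal, rank-based statistic matching the monotone
visual comparison the analysis is after; fewer than three surviving bins is
reported as insufficient data, and an all-tied median sequence as ρ = 0.
No regression modelling or confounder adjustment is attempted.

**Adverse events per word.** From the bins retaining ≥10 patients, the dose
span (0, k_max·w] is rounded up to a whole multiple of three bins and cut
into three equal-width contiguous intervals; "equally wide" is interpreted
on the dose axis, not as equal patient counts. Within each interval, 125
treatment days (not patients — one patient may contribute several days) are
sampled uniformly **without replacement**; with replacement would allow
reviewing the same day twice, which makes no sense for chart review. If
fewer than 125 days qualify, all are used with a warning. The estimate
pools all notes from all staff categories on the sampled days:
rate = Σ mentions ÷ Σ words. The pooled ratio is invariant to how days are
grouped, unlike a mean of per-day ratios, which would overweight short
days. Mentions are whole whitespace tokens whose case-folded form appears
in a plain-text dictionary (~50 single-token terms: tremor, akathisia,
sedation, ...). This exact matcher is a stand-in for manual curation; it
performs no negation, context, or multi-word handling and is exhaustive
only on text whose adverse-event tokens come from the same dictionary — as
the synthetic generator guarantees.

**Report arithmetic.** Percentages are rounded half-away-from-zero —
integer percent for note shares, one decimal for cohort characteristics.
Age is reference-year − birth-year, with the reference year taken as the
midpoint of the prescription span.

## The synthetic cohort generator

The generator exists because the records this analysis design targets are
restricted; it emulates their *structure*, not their content:

* **Patients** (default n = 500): 65.5% male, age ≈ N(40, 6.3) at the study
  midpoint, ICD-10 codes drawn independently per code with prevalences
  typical of a tertiary psychiatric antipsychotic-treated population
  (schizophrenia most frequent, heavy substance-use comorbidity).
* **Prescriptions**: 1–3 episodes per patient of 10–45 days within a
   2000–2010 window; drug from a 21-drug formulary weighted toward
  second-generation agents (olanzapine, risperidone, quetiapine dominate —
  which also makes the chlorpromazine-equivalent method lose a large
  minority of patients to coverage gaps, as a narrow method should); daily
  dose log-normal with median one DDD (σ = 0.5); a second concurrent drug
  with probability 0.25; each prescription flagged ambiguous with
  probability 0.05.
* **Notes**: for each treatment day and staff category c, the daily word
  count is negative-binomial with mean α_c·(1 + β·d) and dispersion θ = 1,
  where d is the day's true summed DDD load, realized as one note of that
  many whitespace tokens. Defaults α = 80 (physician), 300 (nursing), 5
  (each of five allied categories) put ~74% of words with nursing, ~20%
  with physicians and ~6% with allied staff; the staff mix is thus emulated
  at the *word* level (one note per category-day cannot reproduce
  note-count shares, and words are what the downstream analyses consume).
  β defaults to 0.5 per DDD — a strong but plausible documentation gradient.
* **Adverse events**: every token is independently a dictionary token with
  probability r = 0.009 (the ballpark of curated adverse-event densities in
  psychiatric narratives), otherwise a draw from a neutral vocabulary kept
  disjoint from the dictionary so ground-truth counts are exact.

Everything is driven by one `numpy` generator seeded from the config, and
equal configs produce byte-identical fixture files.

What the generator does **not** model — and hence what passing recovery
tests do not establish about real data: realistic (Danish) narrative text,
admission/discharge structure, diagnosis-conditional prescribing, dose
tapering, within-day staff interactions, multi-word or negated adverse-event
mentions, and any confounding between severity, dose and documentation
other than the planted linear mean relationship.

## Validation choices and problem sizes

Recovery tests run 20 seeded replicates of 500-patient cohorts for the
association direction (positive for all three methods and all three staff
subsets when β > 0; no systematic sign when β = 0) and single cohorts for
adverse-event rate recovery (each interval estimate within the 99% binomial
interval of r, and the three estimates mutually consistent under pairwise
two-proportion tests at α = 0.01). At 500 patients the recovery analyses
use the 10-patient bin floor that applies to every analysis rather than the
100-patient note-length floor: that floor is calibrated to ~1500-patient
cohorts, and at a third of that size it routinely leaves the
chlorpromazine-equivalent method — which retains the fewest patients and
the narrowest dose range — with too few bins for a rank correlation at all.
The pipeline default for the note-length analysis remains 100.

## Numerical notes

* Bin assignment is ⌈dose/width⌉ in floating point; the packaged widths
  (0.5, 5, 100) are exactly representable, so boundary doses land in the
  lower bin as specified. Pathological widths could in principle misplace a
  dose within one ulp of a boundary.
* Day sampling sorts qualifying days by (patient, date) before drawing, so
  samples depend only on the seed, not on input row order.
* Negative-binomial counts are realized as gamma-mixed Poisson draws.
* Rounding goes through `decimal` with `ROUND_HALF_UP`, avoiding the
  round-half-even surprises of binary floats on report percentages.

## Known limitations

Exact-token matching undercounts real adverse-event language (inflections,
compounds, misspellings, negation); depot formulations must arrive already
resolved to a daily dose; drug names are matched by case-insensitive exact
string against the formulary; and the equivalence-factor values shipped are
conventional defaults, not a validated consensus — analyses sensitive to
the factors themselves should supply their own table.
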