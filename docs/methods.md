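# Methods

## Scales and severity ordering

The JCS has ten categories (0, 1, 2, 3, 10, 20, 30, 100, 200, 300) grouped
into four arousability grades: alert (0), awake without stimuli (single
digits), arousable by stimuli (double digits), unarousable (triple digits).
The codes are labels, not magnitudes: severity ordering is position in the
category list, never numeric subtraction. Suffix-modified scores such as
"30R" are rejected at validation rather than silently stripped — coercion
would hide data-entry errors. The GCS is handled as an opaque total score
in 3–15; component-wise (E/V/M) representation and GCS→JCS reverse
conversion are out of scope.

## Table derivation

For each JCS category present in a development cohort, the table entry is
the **lower median** of the observed GCS values: the order statistic at
position ⌈n/2⌉. For odd n this is the ordinary middle value; for even n it
is the lower of the two middle values. The choice matters because a sample
median of an even-sized integer multiset can be half-integer, and a
conversion table must be integer-valued. The lower median is deterministic,
always an observed value, and conservative toward severity (lower GCS =
more impaired). The raw, possibly half-integer sample median is reported
alongside each entry in the `DerivationReport` for transparency.

Categories absent from the cohort are absent from the table — derived
tables may be partial and conversion through them raises a missing-entry
error rather than imputing. Two diagnostics are attached as warnings, never
as automatic corrections:

- **monotonicity** — a derived table that is not non-increasing with JCS
  severity is flagged; no isotonic adjustment is applied, since the
  derivation procedure itself applies none;
- **sparsity** — any category with fewer than `sparsity_threshold`
  observations (default 10, configurable) is flagged; intermediate
  consciousness levels are sparse in general-ED cohorts and their medians
  are fragile.

Box-plot summaries (`boxplot_stats`) use nearest-order-statistic (type-1)
quantiles, consistent with the lower median at p = 0.5; whiskers follow the
Tukey 1.5 × IQR convention. The same conventions govern median/IQR age in
cohort summaries.

## Concordance validation

Given a table T and a validation cohort, **absolute concordance** counts
patients with observed GCS equal to T(JCS); **relative concordance** counts
|observed − T(JCS)| ≤ 1. The ±1 window is clipped to [3, 15]; clipping
cannot change any classification because observed GCS values outside that
range are impossible. Relative successes are ≥ absolute successes on every
cohort, by construction.

Each proportion k/n carries an exact two-sided Clopper–Pearson interval

    lower = BetaInv(α/2; k, n−k+1)        (0 when k = 0)
    upper = BetaInv(1−α/2; k+1, n−k)      (1 when k = n)

computed via `scipy.stats.beta`. The interval is exact: coverage is at
least 1−α for every true proportion, hence conservative. α defaults to
0.05 and is a parameter.

The **sensitivity analysis** recomputes both statistics after removing
alert patients (JCS = 0), whose near-certain (0 → 15) conversions inflate
agreement. When the exclusion empties the cohort the sensitivity results
are reported as "not computable", never as NaN or fabricated values.

Printed percentages use one decimal place with round-half-even, applied
only at formatting time; raw fractions are retained in every result
object. The rounding convention is a package choice — it makes report
formatting reproducible without hiding precision.

## Synthetic-cohort generator

The original cohorts are not publicly available, so testing and
demonstration run on synthetic cohorts. The generator emulates two
structural features of a general adult ED population:

1. **JCS marginal dominated by alert patients.** The default marginal puts
   0.675 of the mass at JCS 0 — the alert fraction implied by a validation
   cohort of 821 patients of whom 267 were non-alert — with decreasing
   mass over deeper categories. The split of the remaining mass is
   configuration chosen to exercise every category, not an empirical claim.
2. **Conditional GCS whose median is the target table entry.** GCS given
   JCS is drawn from a discretized symmetric triangular kernel centred at
   `target_table[jcs] + miscalibration[jcs]` with half-width `dispersion`
   (weights `max(0, dispersion + 1 − |offset|)` on integer offsets).
   Support falling outside [3, 15] is *folded* onto the nearer boundary
   rather than renormalized away; folding preserves the cumulative mass on
   each side of the centre, so the population lower median equals the
   centre for every dispersion — the property the median-based derivation
   recovery tests rely on. At dispersion 0 the draw is the centre with
   probability 1, so a calibrated dispersion-free cohort has absolute
   concordance exactly 1. A `miscalibration` shift whose centre would
   leave [3, 15] is rejected at configuration time rather than clipped,
   since clipping would silently restore concordance at the boundary.

One integer seed drives a single `numpy.random.Generator`; no global state
is touched and identical configurations produce byte-identical cohort
CSVs. JCS categories are drawn first, then GCS values by inverse-CDF on a
shared uniform stream, then (optionally) covariates.

Covariates — age over the standard ED age bins (≤34, 35–54, 55–64, 65–84,
≥85), sex, ambulance use, admission, and an ICD-10 letter — are generated
from fixed categorical/Bernoulli rates loosely matching a general-ED case
mix. They exist to exercise I/O and summary code and carry **no** claimed
clinical realism: no correlation with consciousness level, diagnosis or
disposition is modelled. Consequently, passing tests demonstrate that the
statistical machinery is correct under the stated simulation model, not
that real ED data would reproduce any particular concordance rate.

## ICD-10 chapters

Diagnoses are grouped into 17 categories by the first letter of the ICD-10
code (A,B infectious; C,D neoplasms; E endocrine/metabolic; F mental; G
nervous; H eye/ear; I circulatory; J respiratory; K digestive; L skin; M
musculoskeletal; N genitourinary; O,P pregnancy/perinatal; R
symptoms/signs; S,T injury/poisoning; X,Z,Q others; missing). Parsing is
case-insensitive on the first character with whitespace stripped. Letters
outside the scheme (U, V, W, Y) fold into "others" with a logged warning:
the category list is not exhaustive over the ICD-10 alphabet, and
inventing new categories would break comparability of case-mix tables.

## Problem sizes in the test suite

Derivation-recovery checks run 100 seeded replicates of 3,000–5,000-row
balanced cohorts (a few hundred observations per category); interval
coverage is simulated with 2,000 binomial draws at each of twelve (p, n)
combinations; the brute-force interval oracle enumerates every (k, n) with
n ≤ 30. These sizes make every Monte-Carlo tolerance explicit in the test
(3 standard errors for concordance, nominal minus one MC standard error
for coverage) while keeping the suite fast.

## Known limitations

- The conversion is population-level: a median-based table cannot ensure
  accurate conversion for an individual patient, and intermediate JCS
  categories (3–200) rest on few observations in any realistic cohort.
- The generator's dispersion parameters are arbitrary configuration; the
  real per-category spread of GCS within JCS cannot be recovered from the
  published summaries.
- Agreement is measured by concordance proportions with exact binomial
  intervals only; chance-corrected statistics (kappa) are deliberately out
  of scope.
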