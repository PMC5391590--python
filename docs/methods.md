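# Methods

## The design

The package implements a population-based **case-crossover** analysis of
how the risk of a postpartum pulmonary embolism (PE) changes with time
since delivery. Each PE case serves as her own control: the probability
that a delivery occurred in a *case window* shortly before the event is
compared with the probability that a delivery occurred in *control
windows* about a year earlier, far from the event. Self-matching removes
all time-constant confounding (age, thrombophilia, BMI, …); only
within-person timing information is used. Control windows precede the
case window because a woman who has just had a PE is unlikely to become
pregnant soon afterwards — referent periods after the event would be
biased by the event itself.

Concretely, for index date *T* (the PE admission, or for a PE during the
delivery stay, admission plus the earliest dated diagnostic procedure):

* case window *k* is the closed day interval `[14k, 14k+13]` before *T*,
  for *k* = 0…9 (day 0 = day of delivery);
* the M = 5 control windows are days 330–343, 344–357, 358–371, 372–385
  and 386–399 before *T*.

Closed-interval membership in whole days is used throughout: the
enumerated boundaries (…343/344…) tile the timeline without gaps or
overlaps only under that convention. A 6-week aggregation variant
(width 42, three case windows, controls 330–371/372–413/414–455) and the
negative-control geometry (width 30, seven case windows, five controls
starting at day 330) reuse the same machinery. The choice of the three
6-week control windows is this package's own, since only "three control
groups" is specified for that variant; its output is therefore labelled
an approximation.

## Estimation

For matched set *i* with binary exposure indicators
`x_i0` (case period) and `x_i1..x_iM` (control periods), the conditional
log-likelihood of the log odds ratio β is

    l(β) = Σ_i [ β·x_i0 − log Σ_j exp(β·x_ij) ].

Because exposure is binary, a set enters only through `(x_i0, m_i)` with
`m_i` the number of exposed periods, so the likelihood collapses to at
most 2M patterns and Newton iteration on the scalar score is exact and
cheap. Safeguards: start at β = 0, halve the step whenever the
log-likelihood fails to increase, stop when |score| < 1e-10 (the
likelihood is strictly concave on the informative sets, so the score is
monotone and the root unique). Concordant sets (all periods exposed or
none) carry no information and are dropped with a logged count;
doubly-exposed sets are handled by the general likelihood. If every
informative set is case-exposed the MLE is +∞ (flagged `infinite-OR`),
if none is, it is 0 (flagged `zero-OR`); flagged windows report counts
but no estimate.

When every informative set has exactly one exposed period — the typical
situation here, since consecutive pregnancies are more than a year
apart — the MLE has the closed form `OR = M·a/b` with
`se(β) = sqrt(1/a + 1/b)`, where `a` is the number of case-exposed sets
and `b` the total number of exposed control indicators. This closed form
is kept as an internal cross-check; the Newton path is the estimator.
Confidence intervals are Wald intervals on the log-OR scale from the
observed information, `exp(β̂ ± z_{0.975}·se)`.

Reported tables truncate (never round) to one decimal place, matching the
reporting convention of the administrative tables this format mirrors;
full-precision columns are emitted alongside. The event rate is
`100000·a / n_deliveries` with the number of eligible deliveries dated
inside the inclusion window as denominator.

Reproducing the published table needs only its printed counts: `a` and
`b = 5 × (mean control count)` per window are sufficient statistics, so
`analysis/01_reproduce_published_table.py` rebuilds matched sets from
them and recovers every OR, CI bound and rate cell exactly.

## Cohort extraction

* **Cases** — first-ever PE admission per patient, inside the inclusion
  window (defaults: 2008-07-01 to 2013-12-31 within a 2007–2013 data
  window, leaving ≥ 546 days of lookback so every control window is
  observable). Patients whose first PE predates the window are excluded
  entirely. Ties on the same day keep the smaller row index. Diagnosis
  matching uses ICD-10 family semantics: `O35.x` and bare categories
  (`I26`) match as prefixes, dotted codes exactly. The PE code list
  defaults to {I26.0, I26.9, O88.2} and is configurable, as is the list
  of dated PE-diagnostic procedures — both stand in for locally validated
  lists that a real extraction must supply.
* **Within-stay events** — a PE coded on the delivery stay itself is
  dated by the earliest dated diagnostic procedure within the stay and
  accepted only when the primary diagnosis is delivery-compatible
  (prefixes O80–O84, Z37); otherwise the postpartum interval is
  unresolvable and the case is dropped with a logged count.
* **Exposures** — stays with Z37.0 (single live birth), no O35.x/O28.x
  code, mother aged 15–45 inclusive. The delivery date is the dated
  delivery procedure when present, else the admission date (the legacy
  default-to-day-zero behaviour of older records).
* **Post-hoc conservative exclusions** — (i) exposing delivery stay with
  length of stay ≥ 10 days, then (ii) any other admission *strictly*
  between delivery discharge and PE admission ("intercurrent").
  Strict inequalities are this package's reading; the rules are applied
  in order, so the two counts are disjoint.
* **Negative control** — exposure defined by carpal-tunnel syndrome
  (G56.0) *and* the median-nerve release procedure (AHPA009) on the same
  stay: the stricter conjunctive reading of the two codes.

## The synthetic-claims generator

No real claims data are distributed or required; the generator emulates
the *structure* of a national inpatient database at a scale a single CPU
can simulate:

| parameter | default | meaning |
|---|---|---|
| `n_women` | 50,000 | women of childbearing age (16–40 at entry) |
| `study_start`–`study_end` | 2007-01-01 – 2013-12-31 | data window (days) |
| `delivery_rate` | 0.12 /woman-year | delivery renewal intensity |
| `baseline_pe_rate` | 0.01 /woman-year | PE hazard outside postpartum |
| `rr_profile` | `1 + 16·exp(−t/25)` | postpartum hazard multiplier |
| `negative_control_rate` | 0.05 /woman-year | carpal-tunnel stays |
| `background_admission_rate` | 0.02 /woman-year | unrelated stays |
| `legacy_date_fraction` | 0.2 | stays with procedure date forced to day 0 |

Two rates are deliberately unrealistic and chosen once: the baseline PE
rate (~100× the real-world incidence in this age group) and the
carpal-tunnel rate. At realistic rates the case counts of a national
database (millions of deliveries) would require simulating millions of
women; scaling the rates up instead preserves every structural property
the pipeline exercises — timing, window membership, matched-set
composition, estimand — while keeping event counts comparable to the
published table at a simulable population size. Consequently the
*rates per 100,000 deliveries* printed for synthetic cohorts are on the
scaled axis and are not comparable to published incidences; the odds
ratios are, because the multiplier, not the baseline, determines them.

Mechanics: deliveries follow a per-woman renewal process (exponential
waiting times plus a 420-day minimum inter-delivery gap, stopping at age
45) started 600 days before the study window so the process is stationary
from day 0. The 420-day minimum guarantees by arithmetic that no delivery
pair can put one delivery in a case window and another in a 330–399-day
control window of the same index date (the largest such gap is 399 days);
the estimator does not rely on this, but it makes the single-exposure
closed form an exact description of simulated matched sets. PE events are
drawn by thinning a homogeneous proposal process at the maximal hazard;
a PE landing inside the woman's delivery stay is recorded on that stay
(associated diagnosis plus dated diagnostic procedure), exercising the
within-stay branch. The exponential default profile mirrors the
empirically observed decay shape of postpartum thromboembolic risk;
piecewise-constant profiles (e.g. the published OR column itself) are the
generating truth in recovery experiments. A 2% contamination fraction
adds O35.x/O28.x codes to delivery stays so exclusion logic is exercised.

What the generator does **not** emulate: realistic billing semantics,
coding error and under-ascertainment, risk-factor heterogeneity between
women, seasonality, multiple gestation, or death. Passing recovery tests
therefore demonstrates correctness of the extraction/estimation chain
under a known generative truth, not robustness to real-world coding
artifacts.

## Experiments and their sizes

All experiment sizes are fixed design choices:

* **Recovery** — 20 replicates, 60,000 women each, generating profile =
  the published OR column over 14-day bins, `legacy_date_fraction = 0`
  (recovery is judged against the known truth, so dates are recorded
  exactly). This yields roughly 250–300 case-window-0 exposures per
  replicate. Checked: each window's 95% CI covers its generating value in
  ≥ 18 of 20 replicates.
* **Null coverage** — same size, multiplier ≡ 1; the window-0 CI must
  cover 1.0 in ≥ 17 of 20 replicates (three-standard-deviation binomial
  tolerance around the nominal 95%).
* **Negative control** — 20 replicates, 40,000 women; across the
  7 windows × 20 replicates the CIs must cover 1.0 at a rate ≥ 18/20,
  and the pooled mean log-OR must be within 3 standard errors of 0.
  The pooled criterion is used because requiring *every* window of
  *every* replicate to cover simultaneously has, at nominal 95% per-window
  coverage, a substantial probability of failure by construction
  (0.95⁷ ≈ 0.70 per replicate) and would test the binomial lottery rather
  than the design.

## Numerical and degenerate-input conventions

* Truncation guard: `floor(10x + 1e-8)/10`, so a value that is
  mathematically n.m but floats a hair below is not pushed down a
  decimal; estimator precision (score < 1e-10) is far inside the guard.
* Empty claims tables, windows with zero exposure anywhere, and
  zero-rate simulations are all legal inputs and produce empty/flagged
  outputs rather than errors.
* Seeds: every random quantity flows from one `numpy` Generator seeded
  from the config; replicate seeds are derived as
  `(base·100003 + r) mod 2³¹`.

## Known limitations

* The Wald CI is first-order; with very small counts (a ≲ 5) its
  coverage drifts and flagged/degenerate windows carry no interval at all.
* The exact PE ICD-10 list and the dated-diagnostic-procedure list of the
  original national-database study are not public; defaults are
  placeholders and results on real data would depend on the locally
  validated lists supplied via configuration.
* The 6-week control-window layout is an explicit artifact decision (see
  above), so 6-week outputs approximate, rather than reproduce, the
  corresponding published comparison row.
* Absolute case counts of the original study depend on the confidential
  national database and are out of reach by design; only count-free
  properties (ORs, CIs, coverage) are reproduced or tested.
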