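# Methods

## Unit of analysis and cohort construction

A *referral episode* pairs one referral order with the patient's first
specialty visit occurring in the closed interval `[referral, referral + 183
days]`. "Six months" is fixed at 183 days for both the visit-wait window and
the chart lookback, with both intervals closed, so episode construction is
bit-reproducible; nothing in the method depends delicately on the convention.
Each patient contributes at most one episode, anchored at the earliest
referral with a qualifying visit — repeat referrals are out of scope, which
keeps patient counts and episode counts interchangeable.

Query items are every distinct clinical item on the chart in the lookback
window, across all four domains (conditions, measurements, procedures,
medications). Target items are the laboratory and imaging orders — domains
`measurement` and `procedure` — placed on the visit date itself, with any
normal/high/low qualifier stripped, because an order has no result at the
time it is placed. Orders on later dates belong to follow-up care, not the
initial workup.

Numeric lab results with a complete reference range are categorized before
any counting: strictly below the range is `low`, strictly above is `high`,
otherwise `normal`, and a value equal to a bound is `normal` (flags fire
strictly outside the range, matching laboratory flagging conventions). A
categorized result is its own vocabulary item — `TSH/high` and `TSH/low`
carry opposite clinical meaning and must not share counts. Measurements
lacking a value or a complete range keep qualifier `none` rather than being
dropped. The rare-item filter (distinct-patient support < 10, configurable)
runs *after* categorization, on qualified items, so a lab that is common
overall but rarely abnormal does not smuggle its rare abnormal variant into
the vocabulary.

## The association model

Training counts, per item and per (query item, target order) pair, the
number of distinct patients — sets on both sides of an episode make the
per-patient dedup automatic. Pairs are directional (chart item before
referral → specialist order at the visit); a symmetric co-occurrence variant
was considered and rejected because the ranking statistic is the posttest
probability of a *future* order given a *present* finding. PPV is the raw
ratio `N_AB / N_A` with no additive smoothing: the support filter already
bounds the variance of any surviving estimate, and raw ratios keep the
output interpretable as observed frequencies.

The relative ratio `P(B|A) / P(B|¬A)` is computed from the same counts.
When B never occurs without A it is reported as `+inf`, and as `NaN` when B
occurs in neither stratum; both sentinels survive JSON round-trips as
`null`/omitted fields rather than being silently clamped.

The relative-risk weight divides the item's cohort prevalence by its
prevalence among outpatients *outside* the cohort; the outside counts are
obtained by subtracting the cohort's own contribution from outpatient-wide
counts. A zero outside-denominator yields a configurable cap (default 100),
and finite ratios are clipped at the same cap: unbounded weights would let a
single ultra-rare chart item dominate the aggregation sum.

## Aggregation and ranking

Scores are the weighted sum of per-query-item PPVs. Normalizing by the
weight sum would not change any ranking for a fixed query and is therefore
omitted from the score; the *reported* per-entry `ppv` column, however, is
the weight-normalized aggregate, so that it reduces exactly to the
single-item PPV when the query has one effective item and stays on the
probability scale otherwise. The reported relative ratio for a multi-item
query is the maximum over effective query items — the most specific link
between chart and order. Ties in the ranking break by descending cohort
prevalence, then lexicographic concept identity, making every ranking
deterministic. Candidate orders are all target items seen in training;
query items that are themselves lab concepts may be recommended back
(specialists routinely re-order the abnormal test that triggered the
referral).

The inverse-frequency penalty uses the bounded form `1/ln(1 + N_A)`; a raw
`1/N_A` alternative sits behind the same interface (`inverse_form="linear"`).
The `combined` scheme multiplies the relative-risk weight by the
inverse-frequency penalty and is the default, with 10-fold patient-level
cross-validation (`select_weighting`) available to re-select the scheme on
any training set; folds are seeded and rebuilt matrices never see the
held-out fold's targets. Scheme ties break in the documented candidate
order (uniform, inverse_frequency, relative_risk, combined).

Cold-start queries — no item in the trained vocabulary — are ranked by
cohort target prevalence (the "best seller" list) and flagged.

## Evaluation

Precision@k uses a fixed denominator k (default 4) even when a ranker
returns fewer candidates: a short list is a set of withheld predictions, not
a smaller denominator. Recall@k divides by the episode's actual order count;
episodes with zero target orders are excluded from all metrics and counted
in the log. ROC analysis pools every (episode, candidate) pair over the full
trained target vocabulary, scoring unranked items 0, with midrank tie
handling; per-episode AUC averaging is available behind a flag
(`per_episode=True`) since the pooling construction is a design choice, not
a forced one. Confidence intervals are percentile bootstraps over episode
resamples (default 1000); a resample on which a metric is undefined is
redrawn up to 10 times. Ranker comparisons use a paired bootstrap of the
per-episode metric difference with a two-sided tail-fraction p-value.

## The synthetic cohort generator

The generator emulates the *structure* of an outpatient specialty-referral
extract: ~10 condition profiles (thyroid disease, obesity, amenorrhea, short
stature, precocious puberty, and others) with planted conditional order
probabilities; marker labs (TSH, BMI, glucose, vitamin D) measured with
numeric values that land outside the reference range at high rates when the
matching condition is present; high-prevalence specialty-irrelevant noise
items with equal prevalence inside and outside the cohort; ~40 low-signal
filler items padding the vocabulary to ~120 retained items; referral dates
uniform over 2015–2019 for training patients and 2020 for test patients;
and exponential visit delays (mean 45 days) so a few percent of referrals
exceed the 183-day wait and are excluded, exercising the episode filter.
Specialist orders are drawn by a noisy-OR over the patient's condition set
plus small base rates for generic labs, so multi-condition patients have a
well-defined planted truth; conditions are 20× enriched in the cohort
relative to the outpatient background, which is the planted relative-risk
weight. Defaults are 2000 training + 500 test patients — large enough for
stable rank orderings and parameter recovery, small enough for interactive
runs — and all draws come from one seeded generator, so output tables are
byte-identical across runs.

Background (outpatient-wide) counts are binomial draws at the configured
outside-cohort prevalences over `N_outpt − N_cohort` patients (default
`N_outpt` = 100 000), with the trained matrix's own query counts folded in
when provided, so enrichment estimates against the generated background are
unbiased. The `single_association_config` helper builds a one-condition,
one-target cohort in which the planted `P(B|A)` and enrichment are exactly
the marginal truths, used for estimator-recovery checks.

What the generator does **not** emulate: real coding ontologies (concepts
are readable slugs, not OMOP concept ids), correlated comorbidity structure
beyond independent condition assignment, temporal trends in practice
patterns across years, order-set bundling, missing-not-at-random chart
sparsity, and free-text reasons for referral. Passing tests therefore
demonstrate that the machinery is correct and that the method behaves as
designed under its own assumptions — not that any particular performance
level transfers to institutional EHR data.

## Numerical and degenerate-input choices

- All counts are exact integers; probabilities are formed only at the point
  of use, so no accumulation error enters the statistics.
- `split_by_year` treats an episode dated after the test year as a
  configuration error; an empty training partition is legal but logged.
- An untrained or empty matrix raises rather than returning an empty
  ranking; an unknown item has prevalence 0 with a warning.
- Bootstrap quantiles use the default linear-interpolation definition of
  `numpy.quantile`; a constant metric collapses the interval to the point
  exactly.
- The evaluation driver precomputes per-episode score vectors once per
  ranker (the random baseline consumes its stream in episode order), so
  bootstrap resamples reuse identical scores and seeded runs are exactly
  reproducible.

## Known limitations

Single-episode-per-patient modelling discards repeat referrals; the matrix
captures only pairwise (not higher-order) associations; the relative-risk
cap is a pragmatic bound, not an estimated quantity; and the evaluation's
pooled-AUC construction treats every candidate order as equally eligible in
every episode, which understates per-episode discrimination when target
vocabularies differ by specialty context.
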