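# Methods

## Problem setting

Participants of a long-running cohort answer, at roughly semiannual
follow-up visits, three questionnaire items: (a) sex with non-steady
partners, (b) anal intercourse with those partners, (c) condom use "all the
time". Two binary behaviour flags derive from them: nsP = 1 iff (a) is yes,
and nsCAI = 1 iff (a) yes, (b) yes, (c) no. The derivation is evaluated
left to right, and the first unanswered item on the still-open path makes
the flag missing; a "no" at a gate decides the flag regardless of later
items. Consequently nsCAI = 1 implies nsP = 1 on all 27 three-state answer
combinations (this is tested exhaustively).

The analysis asks whether *unsupervised exposure categories* built from the
full pre-cut-off behaviour history predict post-cut-off outcomes better
than conventional summaries.

## Trajectories

Flags are binned onto a fixed calendar grid of half-year bins (default
2001-H2 … 2017-H1, 32 bins; the final partial half-year before the May 1
cut-off folds into the last bin). Bins are half-open (Jan 1–Jul 1 /
Jul 1–Jan 1), so a boundary-day visit belongs to the later bin. Calendar
time, not time-on-study, indexes the columns: trajectories of all
participants are aligned on the same axis, so era effects show up as column
structure that the clustering can use. If several visits fall in one bin
the flags combine by OR (any report marks the half-year); a latest-visit-
wins rule is available via `bin_combine: last`. A bin with no informative
visit is missing; missingness is carried through, never imputed.

Inclusion requires ≥ 2 non-missing feature records before the cut-off
spanning ≥ 2 years (calendar-exact for whole years), and ≥ 1 post-cut-off
visit with a non-missing feature value, so the first-follow-up outcome is
always defined for included participants.

## Distance and clustering

For two trajectories the distance is the Jaccard distance restricted to
pairwise-complete bins: with bins where both values are observed,

d(x, y) = #{bins with exactly one 1} / #{bins with at least one 1}.

Bins missing in either trajectory are excluded from numerator and
denominator. If no co-observed bin carries a 1, the pair is maximally
dissimilar (d = 1); a pair with no co-observed bin at all is an error (the
inclusion criteria preclude it on the default grid). On complete rows this
is a metric; symmetry, identity and the triangle inequality are
property-tested.

Participants who never report the behaviour are set aside before
clustering and appended afterwards as baseline cluster 0 — a deterministic,
perfectly homogeneous reference category. The remaining participants are
agglomerated bottom-up under the Ward criterion via the Lance–Williams
recurrence. The default "ward.D2" form applies the recurrence to squared
distances and reports square-root merge heights,

d(i∪j, k) = sqrt[((nᵢ+nₖ)d²ᵢₖ + (nⱼ+nₖ)d²ⱼₖ − nₖ d²ᵢⱼ) / (nᵢ+nⱼ+nₖ)];

the classic "ward.D" form (same coefficients on raw distances) is available
behind a flag, and the variant used is recorded in the run metadata. Exact
ties in the minimal linkage are broken by the lexicographically smallest
(left id, right id) pair, making merge order deterministic across
platforms. Heights are monotone non-decreasing (Ward is reducible).
Correctness is checked two independent ways: against an O(n⁴) oracle that
recomputes every candidate merge height from scratch via the centroid
decomposition of pairwise squared distances, and against
`scipy.cluster.hierarchy.linkage(..., "ward")` on the same inputs.

Cutting the dendrogram at k undoes the last k−1 merges. Cluster labels
1..k are assigned by ascending mean trajectory positivity of members, so
cluster 1 is always the least-active hierarchical cluster; the numbering is
presentational. Cuts at k and k+1 are nested refinements. Per-cluster trend
curves report, for each bin, the proportion of 1s among non-missing values
together with the denominators; the baseline cluster's curve is identically
zero wherever it is defined.

## Outcomes and model comparison

The cut-off split is half-open: [start, cutoff) is the observation period
(clustering input), [cutoff, end] the outcome period. A record dated
exactly on the cut-off is an outcome record. Outcomes per participant: the
behaviour flag at the first post-cut-off follow-up with a non-missing
value; any/count of nurse- or physician-reported STIs; any/count of
laboratory-confirmed incident syphilis. Incident syphilis is classified
from serial serology as (i) treponemal seroconversion relative to the most
recent non-missing prior result, or (ii) a VDRL titer strictly above 1:8
that is also strictly more than four-fold the most recent prior non-missing
titer. Both comparisons are strict by default and configurable (`>=` fold
rule, and whether a rise from a non-reactive titer of 0 to above 1:8
qualifies — default yes). A record with no prior titer cannot trigger rule
(ii).

The conventional adjustment model contains age at cut-off (linear, years),
the last pre-cut-off flag, and prior syphilis — as an indicator in binary
(logistic) models and as an episode count in count (Poisson; negative
binomial optional) models. The augmented model adds either the cluster
covariate (reference-coded against baseline cluster 0; if cluster 0 is
empty, e.g. when clustering on nsP, the lowest present label becomes the
reference) or one of the simple summaries. Model pairs are compared by the
likelihood-ratio test (statistic 2Δll against χ² with Δparams degrees of
freedom), AIC = −2ll + 2k, BIC = −2ll + k ln n, and auROC computed as the
Mann–Whitney rank statistic (ties count ½; for count outcomes the fitted
rate is scored against the any-event indicator). No multiple-testing
correction is applied across outcomes; each row of the comparison table is
a raw per-outcome test.

Two coding details are worth noting. The newer of the "last two" values is
definitionally the last flag, so augmenting the adjustment model with the
last-two summary adds only the older value (keeping both would be exactly
rank-deficient); and the "last" comparator reduces to the adjustment model
itself (p = 1), since the last flag is already adjusted for. Rank-deficient
designs raise an error naming the collinear columns; perfect separation
and constant outcomes yield flagged fits rather than silent divergence.

Cross-validation uses seeded stratified folds (round-robin assignment with
a shared counter, so overall fold sizes differ by at most one). Cluster
labels are treated as fixed covariates across folds: they derive from the
observation period only, and the CV assesses the regression, not the
clustering; a strict re-cluster-per-fold mode was considered and not made
default for that reason. Accuracy classifies at a fitted probability of
0.5.

The cluster-number sweep re-cuts the dendrogram for each k in a range,
rebuilds the cluster covariate (baseline 0 always included), refits, and
reports the BIC-optimal k, or none when no k beats the cluster-free model.
Model log-likelihood is non-decreasing in k because successive cuts are
nested.

## Synthetic cohorts

The generator emulates the study design, not any particular cohort's
demographics. Latent subgroups have smooth per-bin event-probability
curves; the default templates are flat-low (0.12), flat-high (0.72), a
rising logistic ramp (0.05 → 0.85), its falling mirror, flat-mid (0.42)
and a mid-study hump, in that order, with equal mixture weights — any two
templates differ by ≥ 0.15 mean absolute probability, keeping planted
structure recoverable in principle. Default study conditions: 600
participants, K = 3 subgroups, 32 half-year bins, a 30% never-reporter
baseline stratum, and 20% independent per-(participant, bin) visit
missingness; an optional late-entry setting truncates leading bins to mimic
staggered enrolment. Visit dates are uniform within their bin, one
scheduled visit per bin before thinning. Within a participant, bins are
conditionally independent given the subgroup: the generator plants no
serial correlation beyond cluster membership, which real behaviour data
certainly have. Passing recovery tests therefore show that the pipeline
finds structure of the planted kind; they do not certify performance under
strong within-person autocorrelation.

Covariates: age ~ Normal(40, 10) truncated to [18, 80]; prior syphilis
Bernoulli with cluster-dependent probability (0.05 + 0.04 per label step)
plus a small Poisson count of further episodes; the last pre-cut-off flag
is read off the generated visits. Outcomes follow planted GLMs: binary
outcomes Bernoulli(expit(lp)), counts Poisson(exp(lp)), with lp =
intercept + cluster effect + effects of last flag, prior syphilis and age
centred at 40. Default planted cluster effects alternate ±1 on the
log-odds scale for the binary behaviour outcome (±0.6 log-rate for
counts), with last-flag, prior-syphilis and age effects of 0.5/0.7/−0.02
(binary). The full study simulator additionally encodes syphilis episodes
into an ingestible serology history — seroconversion for a first episode,
a titer rise 2 → 32 for recurrences, with an inter-episode decline record —
which the classifier recovers exactly (tested), and emits post-cut-off
visits whose first record encodes the planted behaviour outcome.

All generators draw from a single explicitly seeded `numpy` Generator per
call; the study simulator derives per-stage child seeds from the master
seed via `SeedSequence`. Identical seeds give byte-identical tables.

## Numerical and degenerate-input choices

- Distances are computed vectorised via boolean matrix products (O(n²T));
  equality with the scalar per-pair definition is tested.
- The Lance–Williams recurrence is run on transformed distances (squared
  for ward.D2) and heights transformed back once per merge; oracle
  agreement is required to 1e-9.
- LRT statistics are clamped at 0 (full fits can trail nested fits by
  floating-point slack, tolerance 1e-6); df = 0 returns p = 1.
- An all-zero co-observed pair gets distance 1, treating "both silent where
  both seen" as uninformative rather than identical — only ever-positive
  participants are clustered, so such pairs share no evidence of similar
  activity. The alternative (imputing missing as 0 before clustering) is
  not offered; pairwise-complete handling is the package's choice.
- A trajectory row with a single observed value repeats it as both entries
  of the last-two summary (inclusion criteria make this unreachable in the
  pipeline).

## Problem sizes in tests

The test-bed uses the default study conditions above for recovery checks
(20 seeds), 1000 simulated cohorts of n = 1000 for type-I calibration of
the cluster LRT, 200 replicates of n = 2000 for power and BIC ordering,
200 random matrices of n ≤ 12 for oracle equivalence, and a 150-participant
cohort for the byte-identity end-to-end run. The acceptance script uses one
600-participant study plus 200 + 200 regression replicates.

## Known limitations

- No within-person serial correlation in the generator (see above).
- The generator makes baseline-stratum participants literally never report
  the behaviour; real "never" strata are defined only over the observed
  window.
- Count-outcome auROC against the any-event indicator is a pragmatic
  scoring choice, not a proper scoring rule for counts.
- Nurse/physician STI reports and syphilis episodes are not de-duplicated
  against each other.
- The ZPHI-style mixed-effects analysis of partner counts and any
  geographic association analyses are out of scope.
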