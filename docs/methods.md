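# Methods

This note documents the models and procedures implemented in `egsnet`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Episode linkage

Encounters (one row per ED-only visit or inpatient stay) are grouped per
patient, sorted by admission date with ties broken by discharge date and
then hospital id lexicographically, and chained greedily under the temporal
adjacency rule: the next encounter joins the current episode when its
admission date is the same day or the day after the previous discharge date
**and** either (a) it is at a different hospital, or (b) it is an inpatient
admission at the same hospital immediately following an ED-only visit there
(an ED visit that resulted in admission). Same-hospital inpatient-to-
inpatient adjacency is a readmission and starts a new episode; readmission
analytics are out of scope.

Adjacency is evaluated on calendar dates only, matching what discharge
databases carry; time of day is ignored even if present. Temporally
overlapping encounters at two hospitals (the second admits before the first
discharges) cannot be ordered from dates alone; they are logged as data
anomalies and deliberately not linked. Same-day bidirectional pairs fall
under the same rule.

A **transfer event** is emitted for every adjacent cross-hospital pair whose
downstream portion resolves to an inpatient encounter at the destination
hospital. The type is taken from the origin encounter's setting (ED→IP or
IP→IP); ED→ED links that end in an admission at the second hospital are
therefore typed ED→IP. The operation flag is true when any procedure code
from the surgery-flag list appears at the origin encounter or at the
destination-hospital encounters of the pair. Within an episode, every
qualifying adjacent pair counts: a chain A→B→C contributes two transfers.

An episode is an **EGS episode** only when an *inpatient* encounter carries
an EGS diagnosis code; an EGS code on an ED-only visit does not qualify.
The transfer cohort keeps EGS episodes with at least one transfer and
patient age ≥ 18 at the first encounter (boundary inclusive).

## Networks and centrality

Hospitals appearing in any retained cohort encounter form the node set of
all five networks (isolates allowed, and they stay in the normalising `n`).
Edges aggregate transfer counts per ordered pair; the five networks are the
full transfer set and the ED→IP / IP→IP / with-operation / without-operation
partitions, which satisfy the edge-weight identities
`all = ED→IP + IP→IP = with-op + without-op` by construction.

Degree centralities are normalised by the maximum possible magnitude given
the node count and scaled by 10 000. Two conventions are implemented:

* **weighted** (default): `C_in(v) = Σ_u w(u,v) / ((n−1)·w_max)`, with
  `w_max` the largest edge weight in that network. Dividing two such
  quantities cancels the normalisation, so the centrality ratio equals the
  raw incoming/outgoing transfer-count quotient.
* **binary**: distinct in-(out-)neighbours divided by `n−1`.

The weighted convention is the default because published claims analyses of
this kind report scaled in-degree medians far below the smallest nonzero
binary value (1/(n−1) × 10 000), which is only possible when edge weights
enter the numerator and the network-wide maximum weight enters the
denominator. The convention used is recorded in the output metadata, and
the exact denominator is the one point where network tools differ — both
readings are available so the choice is explicit rather than silent.

The centrality **ratio** is undefined where out-degree is zero, and its
natural log is additionally undefined where in-degree is zero. Both kinds
of hospitals are excluded from log-ratio analyses and counted in an
exclusion tally, rather than patched with a pseudo-count (an optional
epsilon offset exists but is off by default); this mirrors the reduced
per-network denominators reported in practice. The log base only shifts
contrasts by a constant factor; natural log is used throughout.

## Hospital outcomes

**EGS volume** is the number of adult EGS inpatient episodes treated at the
hospital that did not involve any transfer within the simulated year.

**Risk adjustment** is indirect standardisation. A patient-level logistic
model is fitted on the pooled eligible population — all adult EGS inpatient
episodes for mortality; operated episodes with a complication for failure
to rescue — with age (linear, in years), sex (categorical), the weighted
comorbidity index, and EGS diagnosis-category indicators. Constant
covariates are dropped automatically so degenerate populations reduce to
the intercept-only model, whose fitted probability is exactly the pooled
rate. Whether the patient received an operation is deliberately not
adjusted for, as it is plausibly endogenous to hospital quality. The
hospital's adjusted rate is `(observed / expected) × overall rate`; it is
undefined for hospitals with no eligible episodes. Because the logistic
intercept's score equation forces `Σ observed = Σ expected`, adjusted rates
average to the overall rate in the fitted population.

**Failure to rescue** classifies each episode as: not applicable (no
operation), outside the denominator (operated, no complication code), or in
the denominator with the outcome equal to in-hospital death. This is the
death-given-complication reading; the alternative (complication-and-death
among all operated episodes) is a different measure and is not the default.

Outcomes of transferred episodes are attributed to the treating hospital,
defined as the hospital of the last inpatient encounter — standard
profiling practice, with the usual caveat that transferring out patients
likely to die deflates the sender's apparent mortality (discharge bias).

**Quartiles** (1 = lowest) cut at the empirical 25th/50th/75th percentiles
of the defined values; values equal to a cut point fall in the lower
quartile, undefined values get no label, and fewer than four defined values
is an error.

The comorbidity index is a weighted sum over *distinct* comorbidity
categories mapped from diagnosis codes. The weight table and code map are
replaceable JSON configuration; the shipped fixture is a small synthetic
stand-in in the style of summary-weight Elixhauser groupers and is not a
licensed code list.

## Inference

For each characteristic separately, a one-way ANOVA compares the log
centrality ratio across levels, with groups of fewer than two observations
dropped (with a warning). Post hoc pairwise contrasts default to Tukey HSD
with simultaneous 95% intervals — the standard companion to a one-way
ANOVA when the generating analysis does not name its correction —
with unadjusted and Bonferroni pairwise t tests available; outputs label
the method used.

The primary model is OLS of the log ratio on all characteristic blocks
simultaneously (total-bed category, ICU-bed category, trauma level,
fellowship presence, teaching status, and quartiles of volume, mortality
and failure to rescue), each entered as treatment-coded indicators against
the lowest-resource reference level. The covariance is the cluster-robust
sandwich clustered on state with the finite-sample scaling
`G/(G−1) × (n−1)/(n−k)`, and confidence intervals and p-values use the t
distribution with `G−1` degrees of freedom — with as few as 8 states the
asymptotic normal sandwich is anticonservative, and `G−1` is the standard
small-cluster default. With singleton clusters this covariance reduces
exactly to HC1. Per block, a partial F (Wald) test under the clustered
covariance tests all of the block's levels jointly; for a single-indicator
block it equals the squared t statistic. Hospitals missing any
characteristic are dropped listwise and tallied. The identical model is
refitted on each of the four subnetworks as the sensitivity suite;
degenerate subnetwork frames yield structured skip records.

Significance is two-tailed at 0.05 throughout.

## Synthetic data generator

The generator emulates a one-year, multi-state claims sample at desk scale.
Each hospital gets a state (eight states, each guaranteed at least one
hospital), log-normal bed counts, ICU beds as a Beta-distributed fraction
of beds, size-correlated teaching status, trauma level and fellowship
presence (with deterministic promotion of the largest hospitals into any
unobserved level once n ≥ 12, so categorical contrasts are estimable), a
latent `resource_score` built from standardised log bed/ICU counts plus
noise, and a latent `quality_effect` drawn uniformly on ± a configurable
scale (default 0.3 log-odds).

Each patient contributes one episode: an ED-only visit, a single inpatient
stay, or a transfer chain. Transfer destinations are drawn with probability
proportional to `exp(strength × resource_score)` (Gumbel-max sampling),
excluding the current hospital; a configurable chain probability (default
0.05) adds a second, IP→IP, transfer. Dates are integer day offsets within
the year, with geometric lengths of stay; when a zero-day upstream stay
would tie the two admission dates, the next-day variant of the adjacency
rule is used, because calendar dates cannot order same-day admissions and
the planted transfer list is meant to be exactly recoverable. Death and
complication are Bernoulli draws from logistic models in age (centred at
60), male sex, the comorbidity index (drawn as independent category flags
scored with the shipped weights), and the treating hospital's quality
effect; death additionally shifts by a configurable amount when a
complication occurred, which is what makes failure to rescue informative.

Default rates were calibrated once to the magnitudes reported for EGS
claims populations — overall inpatient mortality ≈ 5%, failure to rescue
≈ 0.12–0.14, about 40% of inpatient encounters operated, slightly more than
half of transfers originating in the ED — and are not tuned per analysis.
The defaults use 150 hospitals and 40 000 patients, which runs the full
pipeline in a few seconds while leaving every categorical level populated.

What the generator does **not** emulate: revisits and readmissions beyond
one episode per patient, seasonal patterns, within-state referral geography
(destinations ignore state lines), coding idiosyncrasies, present-on-
admission distinctions, or correlated comorbidity structure. Passing tests
therefore certify the *pipeline* — exact linkage, correct network algebra,
calibrated inference, recoverable parameters — under the stated model, not
the realism of any particular claims source.

## Numerical conventions and degenerate inputs

* Empty networks: centralities are zero and `w_max` is treated as 1;
  networks with fewer than two nodes are an error.
* ANOVA with zero between-group variance reports F = 0, p = 1; distinct
  group means with zero within-group variance report F = ∞, p = 0.
* Rank-deficient regression designs raise an error naming the blocks before
  fitting; a single error cluster is rejected.
* All simulation randomness flows from one seed through named substreams
  (`SeedSequence(seed, spawn_key=(stage,))`), so stages are independently
  reproducible and two identical runs are byte-identical.
* CSV/TSV/JSON outputs are plain text with ISO-8601 dates and empty fields
  for missing values.

## Known limitations

Hospital-level adjusted rates from small hospitals are noisy; no shrinkage
is applied (the transparent O/E estimator is the default deliberately).
The discharge-bias caveat above applies to any transfer-heavy subset. The
cluster-robust t with `G−1` degrees of freedom is an approximation at very
small G; a wild-cluster bootstrap would be the next refinement and is not
implemented. The shipped code lists are illustrative fixtures — substantive
analyses must supply the licensed AAST diagnosis list, Surgery Flags
procedure list, complication definitions, and a full comorbidity grouper.
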