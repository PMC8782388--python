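# Methods

## Scope and data model

`egowave` analyzes two-wave egocentric interview data from a small
randomized trial of a network-focused behavior-change intervention. The unit
of analysis is the ego (one randomized participant). Raw data are three
long-format tables: egos (demographics, site, arm, AUDIT-C and DAST
screener scores, follow-up response status), alter observations (one row per
ego x wave x alter with twelve 0/1 name-interpreter flags: drinking partner,
drug-use partner, AOD-use influence, and emotional / informational /
tangible support, each "ever" and "recent" — recent meaning the past four
weeks), and alter-alter ties ("do these two people know each other").

Names are free text; the package normalizes them (trim, case-fold, collapse
internal whitespace) at ingest and matches across waves exactly on the
normalized key. Real interviews resolved ambiguous name matches by hand; a
deterministic canonical key is the testable analogue, and no fuzzy linkage
is attempted. Unanswered flag items become missing at ingest and count as
"flag absent" in measures (with a logged count), so every proportion keeps
the wave's full alter count as its denominator. Ties are undirected, stored
with lexicographically ordered pair keys; an absent pair and an explicit
`knows=0` row are equivalent.

Structural invariants (1–20 alters per wave network, recent implies ever per
flag pair, ties referencing listed alters, pair uniqueness) are checked by a
pure validator that reports violations as data rather than correcting them.

## Measures

**Composition (16 measures per ego-wave).** For each of drinking / drug use
/ AOD influence / any-risk and emotional / informational / tangible /
any-support, ever and recent: the count of alters with the classification
divided by the number of alters named at that wave. "Any" families are
disjunctions of their three components, so `any >= max(component)` and
`recent <= ever` hold identically.

**Cross-wave structure.** The cross-wave network is the union of both
waves' alters. Alters named at both waves are *retained*, baseline-only
*dropped*, follow-up-only *added*; by construction `retained + dropped =
baseline size`, `retained + added = follow-up size`, and `total unique =
retained + dropped + added`. A pair is tied in the union if tied at either
wave; the ego is not a node (including it would merge everything into one
component). Density is ties over C(n, 2); components are connected
components with isolates as singletons (computed via networkx; tests verify
against a hand-rolled depth-first search). Two consequences are documented
rather than hidden: dropped x added pairs are never co-observed and are
structurally untied, and no per-wave density/components are reported.

**Relationship change.** Stopping (had the characteristic at baseline, not
at follow-up) and starting (the reverse) counts are computed over retained
alters only, for drink / drug / influence / any-risk. The default uses the
"ever at that wave" flags: the recent window (4 weeks) is much shorter than
the 3-month between-wave gap, so recent-flag churn conflates timing with
change. `flag_version="recent"` switches the definition.

## Synthetic cohort generator

The generator (`SimConfig`) emulates the trial's statistical structure so
every downstream stage is testable without human-subjects data:

- **Screening.** ~149 contacted residents; AUDIT-C and DAST scores drawn
  from discrete distributions calibrated so ~1/3 screen eligible (AUDIT-C
  >= 4 for men, >= 3 for women, or DAST > 2), matching a 49-of-149 yield.
  80% male.
- **Randomization.** Permuted blocks (size 4) stratified by gender; every
  complete block is half intervention, half control.
- **Demographics.** Age ~ N(48, 10) clipped to 18–85; race 56% African
  American; 68% high school or less; 66% never married; children ~
  Poisson(0.89) (so ~59% have at least one); monthly income lognormal with
  median $471 and log-SD 0.8; site 70% primary.
- **Baseline networks.** Size distribution defaults to a point mass at the
  20-alter name-generator cap. Flags are drawn ever-first, recent
  conditional on ever, with marginal prevalences set to the midpoints of
  the trial's weighted baseline descriptives (e.g. drinking partner .26,
  recent .11; emotional support .78, recent .61). Ties are i.i.d.
  Bernoulli(.2) per pair.
- **Follow-up networks.** Each alter is retained with an arm-specific
  probability (.48 control, .67 intervention — ratios chosen to mirror the
  observed retained/dropped rate ratios). Retained alters' ever-flags
  follow per-flag stopping/starting transitions; recent-flags are then
  drawn conditional on the follow-up ever-flag with probabilities that
  depend on the baseline recent state, so recent implies ever by
  construction at both waves. New alters are added back to the baseline
  size and draw flags at baseline prevalences. Retained-pair ties persist
  from baseline; pairs involving an entrant are drawn fresh — so frozen
  dynamics (retention 1, zero transitions, zero effect) reproduce the
  baseline network exactly, ties included. Under usual care the recent
  risk-engagement starting rates are high (e.g. .50 for recent drinking),
  reflecting that control participants' recent drinking roughly doubled
  over the transition into housing.
- **Intervention effect.** `arm_effect_recent_drink` is the *target* arm
  difference in the marginal follow-up prevalence of the recent-drinking
  flag. The generator computes the control expectation in closed form under
  the dynamics above and applies an exactly calibrated extra
  stopping (or starting) perturbation to intervention egos' follow-up
  networks — retained and added alters alike — so the expected difference
  equals the configured value. A value of 0 is calibrated to a true null
  (without calibration, arm-specific retention alone would leak a ~+.01
  difference into this flag); `None` disables calibration. Targets are
  clipped per ego into [0, P(ever)] with a logged warning.
  `arm_effect_income_interaction` adds effect modification per SD of log
  income (default 0), used to study selection bias under dropout.
- **Nonresponse.** Dropout follows a logistic model in standardized log
  income and secondary-site residence (defaults -0.6 and +0.8 log-odds),
  with the intercept solved numerically so the expected dropout rate equals
  the configured 8/49 ≈ 16.3%; zero coefficients give MCAR.
  Nonresponders' follow-up network rows are removed from emitted tables.

All randomness flows from one numpy Generator; a fixed seed yields
byte-identical CSVs. Risk and support flags are independent within alter
given the ever/recent coupling — the trial reports no joint distribution,
and this is stated as an assumption.

**What the generator does not emulate.** Between-ego heterogeneity in flag
prevalence (every ego shares the same marginals, so per-ego proportions
have smaller SDs than real cohorts — Cohen's d values computed on synthetic
data run correspondingly large); name ambiguity and reporting error;
social-process tie dynamics (ties are i.i.d. or persistent, not triadic);
and arm effects on support composition, turnover counts beyond retention,
or structure beyond what retention induces. Passing tests therefore
demonstrate the *estimators'* correctness and calibration under a known
mechanism, not that real network change looks like the simulation.

## Nonresponse weighting

Response propensities are estimated by gradient boosting
(`GradientBoostingClassifier`: 1,000 trees, depth 3, learning rate .01 —
the trial's source names boosting but no settings; these mirror common
propensity-boosting practice). The stopping iteration minimizes the mean
absolute standardized mean difference (SMD) between inverse-propensity-
weighted responders and the full randomized sample, scanned every 25
iterations. Covariates: the 16 baseline proportions, baseline network size,
baseline density and components, age, gender, log income, race, education,
marital status, site, and arm. A plain-MLE logistic alternative is
selectable; when its Hessian is singular or the sample separates (common
with ~30 covariates and ~40 responders), it falls back to ridge-stabilized
logistic regression on standardized covariates and labels the result
accordingly.

Responder weights are 1/propensity, truncated at the 99th percentile of raw
responder weights, rescaled to sum to the responder count; nonresponders
get no weight. SMD uses the full-sample SD in the denominator, with 0 by
convention for zero-variance covariates.

If response depends only on baseline covariates and the treatment effect is
homogeneous, the complete-case arm estimate is already unbiased and
weighting changes little; weighting earns its keep when the effect varies
with a selection covariate (e.g. income), which is exactly the scenario the
bias-reduction simulation exercises.

## Effect models

Intent-to-treat: egos are analyzed by randomized arm; nonresponders enter
only through the weights. Proportions: weighted least squares of the
follow-up measure on {intervention indicator, baseline measure}. Counts:
weighted Poisson regression (log link) on {intervention indicator, baseline
network size}, arm coefficients exponentiated to IRRs with exponentiated
CIs. Cross-wave density is reported with the counts but fitted linearly. A
zero-variance baseline covariate (e.g. network size when all networks are
at the 20-alter cap) is dropped to keep the design full rank.

Variance: HC1 sandwich under the weights — t reference (df = n − p) for
linear models, normal reference for Poisson — mirroring design-based
survey practice; model-based variance is available via `robust=False`.
Under the generator's null this yields a 4–5% rejection rate at nominal 5%
with 50 egos.

Cohen's d = |arm effect| / pooled weighted baseline SD, with the pooled SD
from the usual (n−1)-weighted formula. For Poisson models the arm effect is
first converted to a response-scale mean difference (predicted counts per
arm at the mean baseline size): the single-sentence convention "parameter
estimates and pooled baseline SD" is silent on link scale, and this keeps d
in outcome units. For change/turnover counts, which have no baseline
analogue, the pooled SD is of the outcome itself across arms.

The two-stage procedure fits all 30 outcomes (16 proportions + 14
count-family measures) first on primary-site egos only, then on the full
sample, re-estimating weights within each analysis sample (whether the
original analysis re-estimated them per stage is unstated; re-estimation is
the internally consistent choice). Degenerate outcomes (all-zero counts)
are reported as inestimable rows rather than dropped, keeping the table
inventory fixed. No multiple-testing correction is applied, matching the
exploratory framing; the rendered report states the number of tests run.

## Numerical and design notes

- Proportions are exact integer-count ratios; tests reconstruct the counts
  by multiplying back.
- The logistic propensity path uses exact MLE when the problem is
  well-conditioned (verified against an independent IRLS implementation to
  1e-6) and ridge stabilization otherwise.
- Poisson fits are verified against an independent Newton solver to 1e-6.
- Weight truncation and normalization guard small-sample instability; both
  are switchable.
- Simulation problem sizes in the test suite (e.g. 1,000 null replicates of
  50 egos; 200 recovery replicates of 500 egos; 12 MAR replicates of 2,000
  egos) were chosen to hold Monte-Carlo error well below each check's
  tolerance while keeping the default test run fast.

## Known limitations

- Exact-label matching cannot represent real name ambiguity; two different
  "J"s collapse, a renamed alter splits.
- Cross-wave tie union is one of several defensible definitions (baseline-
  only and follow-up-only are the alternatives); dropped x added pairs are
  untied by construction.
- No multilevel ego–alter models, no mediation to individual-level AOD
  outcomes, no doubly-robust estimators, no multiple imputation, and no
  support for more than two waves.
- The generator's Bernoulli alter dynamics are deliberately simple; it is a
  measurement and inference testbed, not an agent-based model of social
  change.
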