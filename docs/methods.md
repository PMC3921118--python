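# Methods

## Cohort assembly on a backward time axis

The unit of analysis is the subject-examination: repeated clinical visits
with OGTT glucose values, BMI and optional risk factors. Glycemic status is
classified per examination by the WHO 1999 OGTT rule (diabetes iff fasting
plasma glucose ≥ 7.0 mmol/l or 2-hour glucose ≥ 11.1 mmol/l); an
examination with a documented fast under 8 hours, or with both glucose
values missing, is indeterminate. A missing fasting-duration field is
treated as a valid fast — only documented short fasts invalidate the OGTT.

Exclusions run sequentially, each subject counted at the first rule it
violates: (1) no examination at or after the first OGTT phase, (2) diabetes
at the first in-study examination (by OGTT or by an outside diagnosis dated
on or before it), (3) status never assessable, (4) no BMI at any
examination. The flow report telescopes by construction, so the final count
always equals the initial count minus the per-step exclusions.

Time zero is the date of the diagnosing OGTT for screen-detected incident
diabetes; the calendar midpoint between the first self-reported diagnosis
and the last prior diabetes-free screening for doctor-diagnosed cases (a
self-report predating every diabetes-free screening is an error, not a
silent guess); and the last examination for diabetes-free subjects. When a
subject carries both kinds of evidence, OGTT detection takes precedence.
Backward time is t = (exam date − time zero)/365.25 in years; the few
records after time zero are post-diagnosis and are dropped, not modelled.
Subjects whose only BMI values were after time zero are dropped with an
extra flow step rather than silently.

## The latent class linear mixed model

For subject *i* in latent class *g* (probability π_g):

y_ij = Σ_k δ_gk t_ij^k + β'x_ij + b_0i + b_1i t_ij + ε_ij,  k = 0..D

with D = 3 by default, shared confounders x (age at time zero, sex,
examination-phase indicators with the earliest phase as reference; sex
coded 0 = female, 1 = male), (b_0i, b_1i) ~ N(0, B) unstructured, and
ε ~ N(0, σ²). The class-specific block includes an intercept so classes can
differ in level, not only in shape. Age enters as age at time zero
(constant within subject) because age at examination is exactly collinear
with t. Confounder effects are constrained equal across classes.

Free parameters: (G−1) mixing + G(D+1) class polynomials + |β| shared +
3 covariance + 1 residual; BIC = −2ℓ + p·log N with N the subject count.

### Estimation

EM treats the class label and the random effects as missing data. The
E-step computes posterior class weights w_ig and the conditional moments of
b_i given class and data; the M-step has closed forms for every block: π
from mean weights, fixed effects from a posterior-weighted least-squares
system, B from the weighted conditional second moments, σ² from the
weighted residual sum of squares plus trace correction. Each update
maximises the same E-step Q function (an ECM scheme), so the observed
log-likelihood is non-decreasing — asserted in the test suite. A
closed-form variance update was preferred over an inner numerical
optimisation because it is exact, faster, and keeps the monotonicity
guarantee.

Because EM creeps near flat ridges of mixture likelihoods, each start is
finished by an L-BFGS pass on the observed log-likelihood (multinomial-logit
mixing weights, log-Cholesky covariance, log residual variance) with an
analytic gradient from the EM gradient identity. The polish is optional
(`polish=False` recovers plain EM) but on by default; it never replaces an
EM solution with a worse one.

Multi-start design: the likelihood has well-separated local optima, the
most seductive being a split of the majority class into two level-shifted
halves (profitable because a split trades against the shared random-
intercept variance). Deterministic starts therefore target minority
structure explicitly: an equal-quantile split of subject mean levels, two
"tail" starts seeding the minority classes from the top 5% and top 15% of
subject levels, and a k-means start on per-subject (level, slope) features;
further starts perturb the single-class fit at random. Starts are compared
on their fully converged log-likelihoods. Classes are reported in
descending modal-class size; posterior ties break toward the lower index.

### Class enumeration

Candidate class counts are fitted over a range (default 1–4); any candidate
whose smallest modal class holds under 2% of the diabetes population is
disqualified (kept in the report with the reason), and the lowest BIC among
qualifying candidates wins. The 2% rule is evaluated on modal assignments,
after BIC-ranking all candidates, as a post-fit filter. Near the 2%
boundary this rule is genuinely stochastic: with a true minority share of
2.3% and 2,000 subjects, the drawn share falls below 2% in a non-trivial
fraction of replicates, and modal assignment additionally shrinks small
classes slightly (boundary subjects are pulled toward the majority by the
mixing weights). The enumeration simulation study in the acceptance suite
runs at this boundary by design, so a selection rate of ~80–90% for the
true G = 3, not ~100%, is the expected behaviour.

## Class-stratified growth curves and contrasts

Each risk factor is fitted in one joint linear mixed model across all
groups (latent classes plus the diabetes-free reference): group-specific
time polynomials, shared covariate adjustments (age at time zero, sex,
phase; lipids additionally adjust for lipid-lowering treatment and blood
pressure for antihypertensive treatment when those columns are supplied),
and a random intercept + slope per subject, by maximum likelihood. A joint
fit (rather than separate per-group fits) gives a single coefficient
covariance for valid between-group contrasts. Skewed outcomes — fasting and
2-hour insulin, HOMA-%B, HOMA-IR, adiponectin, IL-1Ra — are fitted on the
natural-log scale; predictions are reported on the log scale with an
optional exponentiated (median-curve) back-transform.

Starting from a cubic, the highest-order time term of a diabetes group is
dropped (one term per refit, largest p first) while its two-sided Wald p ≥
0.05; a term is never dropped below a retained higher-order term, so final
term sets are always an initial segment {1, t, t², t³}. The diabetes-free
group is always linear: its time zero is just the end of follow-up, not a
clinical event. A group with fewer subjects than polynomial terms has its
degree reduced with a warning.

The engine is a profiled-ML routine: fixed effects are concentrated out by
GLS at each variance point and the profile likelihood is maximised over the
log-Cholesky variance parameters with analytic gradients (envelope
theorem). It matches `statsmodels` MixedLM (ML) on fixtures — a unit test
asserts this — but is ~100× faster on the simulation studies, whose
thousands of refits made the general-purpose implementation impractical.

Pairwise group differences use a Wald-type F-test of the curve of
contrasts against the zero line: c = differences of intercept and time
coefficients, F = c'[LVL']⁻¹c/q on F(q, n_obs − n_fixed). Contrasts are
evaluated on the *unpruned* companion fit (kept alongside the pruned one),
for two reasons: the union of terms then always has a full variance block,
and contrasting pruned models is anticonservative — a term retained
*because* it was significant contributes a conditionally inflated
component, which simulation puts at a type-I error of ~0.11 at nominal
0.05, versus ~0.05 for the unpruned contrast. Structurally absent terms
(the always-linear diabetes-free group) enter as exact zeros without
variance, which involves no selection. The denominator df is the residual
count approximation; exact small-sample df methods are out of scope.

## Synthetic cohorts

The generator emulates a long-running cohort with clinical examinations
every ~5 years (4 visits, uniform ±1-year jitter, anchored so the last
visit falls near t = 0), completely-at-random per-visit dropout (default
10%, at least one visit kept), and an incident-diabetes population of 645
subjects in three latent classes with proportions 604/15/26 ≈
93.6%/2.3%/4.0% next to 6,060 diabetes-free subjects. Class mean
trajectories anchor at BMI 28.1, 41.1 and 32.7 kg/m² at diagnosis with
cubic backward-time shapes; the reference group drifts 24.5 → 26.2 kg/m²
over 18 years. Variance components default to between-subject intercept SD
3 kg/m², slope SD 0.15 kg/m²/yr (correlation 0.2) and residual SD
0.8 kg/m²; covariates are age at time zero ~ N(60, 7²), 72% male, and
small configured sex/age/phase effects so the confounder adjustments have
something to do. Risk-factor tracks are class-specific polynomials plus a
subject random intercept; log-flagged tracks are generated on the log
scale and exponentiated. All draws flow from one seed through named
substreams, so adding an outcome never perturbs the cohort draw, and the
ground-truth labels/random effects are returned separately and never read
by fitting code.

Under these defaults the stable-overweight and persistently-obese classes
overlap substantially relative to the intercept SD: classifying subjects
with the *true* parameters yields an adjusted Rand index of only ~0.80–0.90
in the incident population. Recovery results on this generator should be
read against that ceiling; the generator does not emulate informative
dropout, measurement-batch effects, or a realistic joint correlation
structure across the full risk-factor panel, so passing tests speak to the
method under its own assumptions, not to robustness against those features
of real data.

A purpose-built raw-cohort generator (`generate_flow_cohort`) plants exact
numbers of violators of each exclusion rule (9,181 subjects with
830/211/776/659 disjoint violations and 645 incident cases by default) to
exercise the flow accounting, including overlapping violations that must be
counted once.

## Problem sizes and numerical choices

Simulation studies in the test suite are sized for a single CPU: parameter
recovery and class enumeration use 10 replicates of 2,000 subjects with
G ∈ {1..4} and 4 deterministic starts (EM to relative tolerance 10⁻⁶,
≤150 iterations, then polish); contrast calibration uses 1,000 null
replicates of 150 subjects per group; the end-to-end run uses the full
default cohort (645 + 6,060) twice to verify byte-identical reports.
Library defaults are more conservative (20 starts, tolerance 10⁻⁸, ≤500
iterations). Degenerate cases: a class whose posterior mass vanishes keeps
its coefficients frozen in that M-step; the random-effects covariance
update is symmetrised and the residual variance floored at 10⁻¹⁰; an
indefinite covariance supplied to the likelihood raises rather than being
clamped.

## Known limitations

- Class-membership submodels with covariates, non-Gaussian outcomes and
  spline trajectory shapes are not implemented.
- External risk scores (e.g. the Framingham diabetes and CVD scores) are a
  pluggable interface — coefficient tables must be supplied by the user;
  score trajectories are then just another outcome for the growth-curve
  module.
- The 2-hour-insulin/HOMA medians printed in cohort descriptions do not
  compose under unit conversion (medians are not linear); the calculators
  here take the conventional formula route (insulin in µU/ml, 1 µU/ml =
  6.945 pmol/l).
- No multiplicity correction is applied across the outcome panel.
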