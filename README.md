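# lctraj — latent class BMI trajectories before type 2 diabetes

`lctraj` implements a reusable analysis pipeline for a question from
diabetes epidemiology: in a longitudinal cohort, do people who develop type
2 diabetes follow distinct patterns of BMI change in the years *before*
their diagnosis, and how do other cardiometabolic risk factors (glucose,
insulin, HOMA indices, lipids, blood pressure, inflammatory markers) track
alongside each pattern?

It is written for biostatisticians and epidemiologists who want to run a
latent class trajectory analysis on their own cohort data, or to study the
behaviour of the method itself on simulated cohorts with known structure.

## The model

Time is measured backwards from each subject's anchor: the date of diabetes
diagnosis for incident cases (set to the diagnosing OGTT for screen-detected
disease, or the midpoint between first self-report and the last
diabetes-free screening for doctor-diagnosed disease), and the last
examination for diabetes-free subjects. With t ≤ 0 in years, subject *i* in
latent class *g* has

    y_ij = δ_g0 + δ_g1 t_ij + δ_g2 t_ij² + δ_g3 t_ij³
           + β' x_ij + b_0i + b_1i t_ij + ε_ij,

with class membership probabilities π_g, shared confounder effects β (age
at time zero, sex, examination phase), random intercept and slope
(b_0i, b_1i) ~ N(0, B), and ε_ij ~ N(0, σ²). Marginally each subject's
response vector is a G-component mixture of multivariate normals, fitted by
multi-start EM (class labels and random effects as missing data). The
number of classes is chosen by BIC = −2ℓ + p log N among candidates whose
smallest modal class holds at least 2% of the diabetes population, and each
subject is assigned to its highest-posterior class.

Given the class allocation, every other risk factor is modelled by a joint
linear mixed model with group-specific polynomials in t (pruned cubic → 
quadratic → linear at the 5% level; the diabetes-free reference group is
always linear), and pairs of groups are compared with a Wald-type F-test of
the curve of contrasts against the zero line.

Deterministic clinical calculators are included: WHO OGTT classification
(FPG ≥ 7.0 or 2-h PG ≥ 11.1 mmol/l), HOMA-IR = I·G/22.5 and
HOMA-%B = 20·I/(G − 3.5) with insulin in µU/ml (1 µU/ml = 6.945 pmol/l),
and Friedewald LDL = TC − HDL − TG/2.2 (mmol/l, undefined above
TG = 4.52 mmol/l).

Because cohort data of this kind are access-controlled, the package ships a
first-class synthetic-data module: seeded cohorts with a configurable
latent-class structure (defaults: three classes with proportions
93.6% / 2.3% / 4.0% anchored at BMI 28.1 / 41.1 / 32.7 kg/m² at diagnosis),
clinical examinations every ~5 years, random dropout, and correlated
risk-factor tracks.

## Worked example

```python
from lctraj import (SyntheticConfig, generate_cohort, LCLMMSpec,
                    select_num_classes)

cfg = SyntheticConfig(seed=0, n_subjects=645, n_diabetes_free=0)
dataset, truth = generate_cohort(cfg)

G, fits, report = select_num_classes(
    dataset, LCLMMSpec(outcome_name="bmi"), G_range=(1, 2, 3),
    min_share=0.02, n_starts=4, tol=1e-6, max_iter=500, seed=0,
)
print(report[["bic", "min_modal_share", "qualified"]].round(2))
print("selected G =", G)
print("class proportions:", fits[G].pi.round(3))
```

prints

```
        bic  min_modal_share  qualified
G
1  10006.09             1.00       True
2   9877.42             0.03       True
3   9787.94             0.03       True
selected G = 3
class proportions: [0.937 0.036 0.027]
```

BIC drops steadily from one to three classes, every candidate keeps at
least 2% of subjects in its smallest class, and the three-class model is
selected; the recovered mixing proportions (93.7% / 3.6% / 2.7%) are close
to this draw's realised 93.2% / 4.2% / 2.6% split of the generating
93.6% / 4.0% / 2.3% classes. At this cohort size the smallest class hovers
near the 2% relevance floor, so on some draws the three-class fit is
legitimately disqualified and two classes are reported instead — the rule,
not a bug. `fits[G].assignment` then feeds `fit_growth_curve` /
`curve_contrast_test` for the risk-factor panel, or run everything at once
from the shell:

```bash
lctraj run-all --seed 0 --out results/
```

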