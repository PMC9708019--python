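# Methods

This note documents the models, calibrations and numerical choices behind
`tavica`, and what the synthetic experiments do and do not demonstrate.

## Coordinate conventions

The aortic root lives on a cylindrical grid attached to the annular plane:
axial coordinate `z` in mm with the plane at `z = 0` and `z` increasing
toward the left ventricle (the direction of implantation), circumferential
angle `theta` in degrees. The plane's unit normal points from ventricle
toward aorta, so the signed P3 depth `D3 = (P3 − origin) · normal` is
negative when P3 lies on the ventricular side — the convention under which
cohort means of D3 are negative — while the implantation depth DOI is
positive below the annulus, sharing sign with the grid axis. Default grid
resolution is 1° × 0.25 mm; all surface integrals are cellwise sums with
membership decided at cell centres (cell = node + half-widths), which makes
patch areas converge to the analytic values and keeps frame-edge boundaries
exact when they align with the grid.

The conduction-system ROI is the wall patch between the IBMS curve and the
plane 15 mm below the annulus. The IBMS is piecewise-linear through P2 when
P2 is given, else the straight P1–P3 segment; the 25° extension toward the
right coronary cusp is applied on the circumferential axis at the IBMS's
annular projection, continuing the curve at its endpoint depth (the
construction axis of the extension is a design choice; the angle itself is a
standard landmark-protocol value). The extension direction follows the side
of the RCC reference angle, and a larger extension always yields a superset
mask.

## Deployment model

Full finite-element simulation of valve deployment requires proprietary
frame models and constitutive laws. `tavica` instead uses an
independent-radial-spring equilibrium per grid node, chosen to be
deterministic, fast and analytically verifiable while preserving the
quantities the downstream analysis consumes (a non-negative contact-pressure
field and its ROI summaries Cpmax and CPI) and their qualitative drivers
(oversizing, implantation depth, calcification, wall stiffness):

* wall: `p_wall(r) = k_eff (r − r_free)` for `r > r_free`, else 0, with
  `k_eff` the base wall stiffness (default 0.2 MPa/mm) times the local
  calcification multiplier (≥ 1, nodules are rectangular patches in
  `(z, theta)`);
* self-expanding frames (CoreValve, Evolut R/PRO): a non-increasing radial
  pressure curve `p_dev(d)`, by default a linear ramp from a peak pressure
  (default 2 MPa) at the crimped diameter to zero at the nominal diameter.
  The equilibrium radius solves `p_wall(r) = p_dev(2r)`, unique by
  monotonicity; it is found by vectorized bisection on
  `[r_free, d_nom/2]` to 1e-9 mm (64 iterations bound the bracket width well
  below that), with bracket expansion for user-supplied curves that remain
  positive beyond the nominal diameter;
* mechanically expanding frames (Lotus): displacement-controlled to the
  nominal diameter, the wall carrying `max(0, p_wall(d_nom/2))` wherever the
  frame interferes.

The frame occupies `z ∈ [DOI − frame_length, DOI]` at zero rotation
(per-patient rotation sweeps are out of scope; rotation is an input default
of 0°). Frame lengths and crimped diameters in the packaged catalogue are
nominal manufacturer-scale values; the peak pressure is a package default,
overridable in the catalogue file. Because the spring model is not
calibrated against bench radial-force data, absolute pressure magnitudes are
model-specific; the statistical cohort mode (below) carries the published
pressure scale, and the mechanistic mode is used for qualitative,
direction-of-effect studies.

CPI counts ROI area with pressure above ε = 1e-6 MPa; the threshold only
guards float noise (the equilibrium is exactly zero without interference)
and the resulting percentage is clamped to [0, 100] against accumulation
round-off.

## Synthetic cohorts

### Statistical emulation (default mode)

The composite outcome CA is Bernoulli(89/151 ≈ 0.589). Given CA, the eight
model features are drawn independently — the published exploratory analysis
found no significant pairwise feature correlation, making conditional
independence the natural emulation default (a correlation structure can be
layered on via the calibration object). Families per feature:

* mean ± SD entries (IBMS length, IBMS angle, D3, annular diameter, sizing
  index, DOI) — normal truncated to physical bounds (e.g. angle ∈ [0°, 90°],
  DOI ∈ [0, 25] mm), with the underlying location/scale *moment-matched* so
  the truncated law reproduces the printed mean and SD. The match is exact
  for 11 of 12 cells; the no-CA IBMS-angle cell (mean 16.5°, SD 18.7° on
  [0°, 90°]) is infeasible — on a left-truncated support the SD cannot
  exceed the mean in the exponential limit — so the fit keeps the mean and
  attains the closest achievable spread (SD ≈ 16.4°).
* Cpmax — log-normal, `mu = log(median)` and `sigma` solved so the IQR width
  matches the printed quartile range (a two-parameter family cannot match
  both quartiles and the median simultaneously; median and IQR width are
  matched to 1e-6).
* CPI — logit-normal on [0, 100] %, matched the same way (median exact, IQR
  width solved by bracketed root-finding).
* device size — categorical with the published per-group size frequencies;
  the device *type* (CV / ER-EPRO / LT) is derived from the size.

Within the CA group, PPI and L/RBBB labels are allocated with the published
overlap (32 PPI, 79 L/RBBB, 22 both among 89), so the composite identity
`ca = lbbb_rbbb OR ppi` holds row-wise and the pacemaker-free sub-cohort has
the published relative size (119/151).

The generator carries a self-rejection check: scoring each sampled patient by
the exact log-likelihood ratio of the generating densities (the Bayes-optimal
scorer under conditional independence) must yield AUC ≥ 0.84 at n = 50,000;
the default calibration achieves ≈ 0.92 with all eight features and ≈ 0.78
without the two mechanistic ones. This anchors what the ML experiments can
show: a learner approaching the generator's Bayes AUC demonstrates that the
*protocol* extracts the available signal, not that real patients are equally
separable.

Seeds: one master seed spawns independent per-stage streams (outcome,
labels, device, one per feature) via `numpy.random.SeedSequence`, and every
written cohort embeds mode, seed and a config hash, so statistical-mode
outputs regenerate bit-identically.

### Mechanistic forward mode

Anatomies are sampled from the all-patients marginals (annular diameter,
IBMS length/angle/D3, Poisson-count calcification nodules with uniform
position, extent and stiffness multiplier in [2, 8]); the landmark pair is
constructed on the cylinder so its re-measured length/angle/depth equal the
sampled values (the angle is clamped where the sampled combination would
push P1 off the grid). The device follows the sizing-matrix rule — smallest
size in the sampled family with sizing index ≥ 1.0, capped at 1.3 — and
DOI is truncated-normal. Each patient is deployed (default 2° × 0.5 mm grid
for throughput; the deployment model is grid-stable to < 2% under halving)
and CA follows `logit P = β0 + β1·Cpmax + β2·CPI + β3·DOI` with defaults
β1 = 8 /MPa, β2 = 0.05 /%, β3 = 0.10 /mm — positive effects scaled to this
model's biomarker magnitudes — and β0 calibrated on the sampled cohort so
the mean predicted probability equals the target prevalence (with all slopes
zero this reduces exactly to the logit of the prevalence).

### Fixture

A deterministic 151-row table whose device-size × CA cross-tab and outcome
counts equal the published population table exactly; numeric features are
group-level summaries (means, medians for Cpmax/CPI) intended as
placeholders for categorical-structure tests, not for model fitting.

## ML protocol

Preprocessing: device one-hot (3 fixed categories) plus min-max scaling of
the seven numeric features with parameters learned on training rows only and
applied without clipping (out-of-range validation values may leave [0, 1]);
a constant training column scales to 0 with a warning. Correlation
screening greedily drops one member of any numeric pair with |r| > 0.9 (all
features survive on the default generator). The 70–30 split takes
`|train| = round(0.7 n)` (106/45 at n = 151), stratifies by outcome with
largest-remainder allocation, and redraws until all three device categories
appear in both partitions.

Base classifiers and their (deliberately small) accuracy-scored 5-fold CV
grids: KNN `k ∈ {3,5,7,9,11}`; logistic regression `C ∈ {0.1,1,10}`;
RBF-SVC `C ∈ {1,10}`; Gaussian naive Bayes (no grid); hinge-loss SGD
`alpha ∈ {1e-4,1e-3,1e-2}`; XGBoost (100 trees) `max_depth ∈ {2,4}`;
decision tree `max_depth ∈ {3,5,None}`; random forest (100 trees)
`min_samples_leaf ∈ {1,5}`.

Ensembles: bagging fits B = 50 clones of the tuned base learner on
bootstrap resamples of training size (resamples missing a class are
redrawn); the ensemble score is the mean of members' continuous scores —
class probability where available, otherwise a logistic squash of the
decision margin so the 0.5 threshold maps to the decision boundary — and
labels use the 0.5 threshold. The mixed ensemble is an unweighted majority
vote over the eight tuned bases with ties broken toward the positive (CA)
class.

Evaluation on the held-out set: confusion counts at the 0.5 score
threshold; sensitivity, specificity, PPV, NPV; F1 as the harmonic mean of
PPV and sensitivity; ROC by threshold sweep with trapezoidal AUC (equal to
the normalized Mann–Whitney U statistic); AUC 95% CI by stratified
percentile bootstrap with 2,000 resamples. Model selection is argmax
validation accuracy, ties broken by CV accuracy, then AUC, then model id.
Two derived analyses re-run the identical protocol: the ablation drops
Cpmax and CPI (6 features), and the sub-cohort analysis removes PPI rows and
predicts L/RBBB.

## Statistics layer

Two-group numeric comparisons are gated by Shapiro–Wilk at α = 0.05 per
group (both must pass): the parametric branch uses Welch's t-test — the
equal-variance assumption is not imposed — with mean ± SD summaries, the
non-parametric branch the two-sided Mann–Whitney U with median (IQR).
Zero-range groups bypass Shapiro–Wilk (its statistic is undefined there) and
take the parametric branch. Categorical tables use chi-square without
continuity correction when all expected counts are ≥ 5, Fisher's exact test
on 2×2 tables otherwise, and a fixed-margin Monte-Carlo permutation of the
chi-square statistic for wider sparse tables. No multiple-testing
correction is applied.

## Problem sizes and determinism

The calibration checks use 20,000-patient statistical cohorts (Monte-Carlo
error on group medians well below the reported tolerances) and the
end-to-end ML experiments 5,000-patient cohorts, sizes at which the selected
model's held-out AUC is stable to about ±0.01 across seeds. Everything is
reproducible from a single integer seed; protocol runs derive independent
sub-seeds for the split, the CV folds, the bagging resamples and the
bootstrap CIs.

## Known limitations

* The spring model has no axial/circumferential coupling, no frame bending
  stiffness, no friction, and no leaflet or haemodynamic outputs; its
  absolute pressures are model-scale, not bench-calibrated.
* The statistical emulator is conditionally independent given the outcome;
  real anatomical/procedural features are weakly dependent (e.g. sizing
  index mechanically involves the annular diameter), and real cohorts carry
  centre effects, comorbidities and measurement error that the generator
  does not model. Passing the synthetic-twin benchmarks therefore validates
  the implementation of the protocol and the attainability of the published
  operating point on a matched-signal population — not clinical performance.
* The outcome timing (periprocedural vs pre-discharge) is not modelled, and
  single-digit subgroup counts (e.g. RBBB n = 1) are reproduced only in the
  deterministic fixture.
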