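# Methods

This note documents the models and procedures `pufakit` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## 1. WMH segmentation (`pufakit.segmentation`)

### Model

White-matter hyperintensities are segmented on a FLAIR volume referenced to
the subject's own normal-appearing white matter. Writing `mu` and `sigma`
for the mean and sample SD (n−1 denominator) of FLAIR intensity over the
WM-labeled voxels:

1. **Seeds** — connected components (26-connectivity by default) of voxels
   with intensity ≥ `mu + 2.5 sigma`, restricted to WM∪GM labels, keeping
   components of ≥ 3 voxels.
2. **Batch growth** — per cluster, repeatedly: compute the cluster mean
   `m`; collect *all* adjacent voxels (26-adjacency) in WM∪GM with
   intensity ≥ `0.95 m`; add them simultaneously; recompute. Growth stops
   when the batch is empty, or when applying the batch would drop the
   cluster mean below `mu + 2 sigma` — in that case the batch is discarded
   and the pre-batch cluster retained. Every retained cluster therefore
   keeps a mean at or above the stop threshold.
3. **Merging** — clusters whose grown extents overlap or become adjacent
   are merged and the union re-grown to convergence, iterating until no
   two clusters touch. Processing order is deterministic (seeds sorted by
   descending maximum intensity, ties broken by minimal coordinate).
4. **Classification** — a cluster with any voxel adjacent (26) to a
   ventricle-labeled voxel is *periventricular*; all others are *deep*;
   total WMH is their union, and `total = deep + periventricular` holds
   exactly by construction.
5. Volumes are voxel counts × voxel volume, reported in cm³.

WM statistics are computed once from the original label volume and never
updated during growth. Growth is confined to WM∪GM because lesions are
frequently mislabeled GM by T1-based tissue segmentation (WMH is
iso-intense with GM on T1); it never enters CSF, ventricle, or background.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `z_seed` | 2.5 | seed threshold in WM SD units |
| `min_seed_size` | 3 voxels | smallest admissible seed component |
| `growth_fraction` | 0.95 | relative intensity floor for joining a cluster |
| `z_stop` | 2.0 | retention floor for the cluster mean, WM SD units |
| `seed_connectivity` / `growth_adjacency` | 26 | "surrounding voxels" read inclusively; 6/18/26 configurable |
| `allowed_labels` | {WM, GM} | tissue classes growth may enter |

### Numerical and design choices

* **Batch (not sequential) growth**: all qualifying neighbors join
  simultaneously, then the mean is recomputed. Sequential single-voxel
  addition would make results depend on an arbitrary within-batch order.
* **Rollback at the stop condition**: the mean-lowering final batch is
  discarded rather than kept. Keeping it would admit a terminal flood of
  near-threshold voxels into normal WM precisely at the moment the cluster
  statistic signals the boundary has been reached.
* **Ties and determinism**: for fixed inputs and parameters the pipeline is
  a pure function; re-running reproduces the mask bit for bit.
* **Relative-threshold sensitivity**: the 95%-of-mean growth rule is
  invariant to multiplicative intensity rescaling (`a·x`, `a > 0`) but not
  to additive offsets (`x + b`), because `0.95·(m + b) ≠ 0.95·m + b`. The
  test suite documents this with an explicit example rather than asserting
  an invariance the rule does not have. Intensity calibration of the input
  therefore matters.
* **Noise floor**: with i.i.d. Gaussian WM noise, `P(voxel ≥ mu + 2.5
  sigma) ≈ 0.62%`, so a volume with `N` WM voxels is expected to contain a
  few spurious ≥3-voxel supra-threshold components once `N` reaches the
  10⁴–10⁵ range (the expected count grows roughly linearly in `N`). These
  specks are why the original workflow ended with visual inspection and
  manual correction. The package replaces that manual step with a QC
  summary (cluster count, size histogram, volume-boundary contact); it does
  not pretend the noise floor is zero, and the acceptance suite measures it
  explicitly on lesion-free phantoms.
* **Recovery metric**: planted-lesion recovery is scored by
  `recovery_dice` — Dice between the truth mask and the union of segmented
  clusters that intersect it — so that the noise-floor specks, which are
  accounted separately, do not dilute the recovery measure. Whole-mask
  `dice` is also available.

## 2. Synthetic phantoms (`pufakit.phantom`)

The phantom is a nested-box geometry: background, peripheral-CSF, and GM
shells enclosing a WM interior with a central ventricle slab (CSF-valued,
separately labeled so periventricular adjacency is well defined). WM
intensities are i.i.d. `Normal(wm_mean=100, wm_sd=10)`; GM sits at +10 and
CSF/ventricle at −60 relative to the WM mean (FLAIR-like contrast: GM
mildly hyperintense, CSF attenuated). Ellipsoidal lesions are *set* — not
added — to `wm_mean + z·wm_sd`, giving exact, analyzable contrast; planted
lesions must lie inside WM∪GM, and their intended class (deep vs
periventricular) is validated against the adjacency rule at generation
time. A voxel-centered ellipsoid always covers an odd number of voxels
(point symmetry), which constrains exact-volume constructions.

Deliberately not modeled: cortical folding, bias fields, partial-volume
effects, scanner noise correlation, T1 images. Consequently, passing
recovery tests demonstrates correctness of the algorithm's logic under its
own intensity model — not clinical accuracy on real FLAIR, where bias
fields and partial volume would interact with the fixed thresholds.

## 3. Cohort and trajectory simulation (`pufakit.cohort`)

### Baseline cohort

Defaults reproduce the enrolled population's marginals: age mean 81.1 y,
SD 4.4, floored at 75 (sampled from a truncated normal whose underlying
location/scale are solved numerically so the *truncated* moments match —
naive truncation of N(81.1, 4.4²) at 75 would inflate the mean to ≈81.8);
60.8% female; education (≤HS / some college / bachelor+) = 23.5/19.6/56.9%;
total WMH log-normal moment-matched to mean 19.4, SD 16.1 cm³ (positive,
right-skewed; ≈89.7% periventricular); plasma EPA and DHA log-normal
matched to 22.43 (11.49) and 63.20 (20.46) µg/mL, summed per record (the
printed sum SD of 29.21 reflects correlation the generator does not model);
MMSE 27.9 (1.7) rounded and clipped to 0–30; CDR 0 with probability 0.696,
else 0.5; GDS 1.5 (1.4); APOE4 carriage 27.5%. The weight-percent measure
is coupled to the µg/mL sum as `wt% = (EPA+DHA)/20`, making the two
screening thresholds (110 µg/mL, 5.5 wt%) coincide; the trial reports no
joint distribution to calibrate against. Per-criterion `ineligibility_rates`
force violations (low MMSE, high GDS, small WMH, high n-3, exclusion flags)
so the screening funnel has realistic attrition to account for.

### Longitudinal model

For outcome `y` of participant `i` at `t` years,

    y_it = baseline_i + delta3 · (t/3) · (1 − f·active_i) + b0_i + b1_i·t + e_it

with `delta3` the placebo-arm 3-year change, `f` the proportional slope
reduction in the active arm, `b0 ~ N(0, sd_int²)`, `b1 ~ N(0, sd_slope²)`,
`e ~ N(0, sd_res²)`. The trend is parameterized through `t/3` so the
noise-free 36-month change equals `delta3` bit-exactly. Design values:
WMH `delta3 = +7.0` cm³ (active 3.5 at `f = 0.5`); sICAM-1 +50.15 ng/mL;
trail-making B +12 s; digit symbol −2.25 points. Variance splits are
chosen so the implied 3-year change SD, `sqrt(9·sd_slope² + 2·sd_res²)`,
matches the stated design SDs (WMH 5 → slope SD 1.6/yr with residual SD
1.0; trails B 13; digit symbol 2); the split between slope and residual
variance is not identified by a single change SD, and this allocation puts
most of it in stable participant-level rates, which is what longitudinal
WMH data show. Imaging/cognitive outcomes follow the 0/12/24/36-month
schedule; blood outcomes the 0/3/6/12/18/24/30/36-month schedule.

**Dropout** is a constant per-scheduled-visit hazard `h` solved from
`(1 − h)^k = 1 − a` over the `k = 7` distinct follow-up months, with
`a = 0.30` the design three-year attrition; dropout is monotone
(missing-once ⇒ missing-thereafter) and independent of outcomes, i.e.
missing *completely* at random — a stronger condition than the
missing-at-random assumption the analysis needs, so the simulation cannot
probe MAR-violation sensitivity. The increment distribution is normal;
the trial specifies only the mean ± SD of 3-year change, so the
distributional family is an assumption.

## 4. Screening and randomization (`pufakit.screening`, `.randomization`)

Eligibility (all required): age ≥ 75, CDR ≤ 0.5, MMSE ≥ 24, GDS < 6, total
WMH ≥ 5 cm³, suboptimal n-3 status (EPA+DHA < 110 µg/mL strict, or weight
percent ≤ 5.5 inclusive — the source documents state the wt% boundary both
ways and the inclusive reading is adopted), and no exclusion flag. The
funnel reports per-stage survivors and percent-of-prior with half-up
rounding to two decimals (e.g. 108/233 → 46.35%). Final eligibility is
criterion-order invariant; order affects only first-failure attribution.

Allocation is Pocock–Simon marginal minimization over five equally
weighted factors — age band (75–79/80–84/85–89/90+), sex, education (3
levels), WMH stratum, CDR (0/0.5) — with a biased coin `p_best = 0.8` and
a fair coin on ties. The published design cites a "modified" minimization
variant whose modification is not described; standard Pocock–Simon with a
biased coin is implemented as the stand-in, with `p_best` configurable.
WMH strata are fixed a priori at 5–15/15–30/≥30 cm³ for reproducibility
rather than data-adaptive quantiles. The assignment log stores factor
levels, both hypothetical imbalance totals, the uniform draw, and the arm,
so any sequence can be replayed from its seed and verified.

## 5. Power and sample-size arithmetic (`pufakit.power`)

Two-arm comparisons of mean change. `normal_approx` is the design formula
`n = (z_{1−α/tails} + z_{power})²(sd1² + sd2²)/delta²`, ceiled;
`noncentral_t` computes exact power `P(|T| > t_crit)` with
`ncp = delta/sqrt(sd1²/n1 + sd2²/n2)` (pooled df for equal SDs,
Welch–Satterthwaite otherwise) and iterates to the smallest n meeting the
target. For the primary scenario (delta 3.5, SD 5, α 0.05 two-tailed, 80%
power) the normal formula gives 32.04 → **33 per arm** — the published
design number — while the exact t power at 33 is 0.7997, i.e. 80% at the
two-decimal precision power claims are quoted at, so a strict power-floor
iteration lands on 34. Both numbers are real; the package reports the
design calculation as the headline and exposes the exact method alongside.
The sICAM-1 scenario's "over 93%" claim is tail-convention dependent
(two-tailed Welch ≈ 0.92, one-tailed ≈ 0.96); both are computable and
neither is asserted as a fixed target. Attrition arithmetic is
`completers = n·(1 − rate)` with a ceiled inverse.

## 6. Longitudinal analysis (`pufakit.analysis`)

Populations: mITT = randomized with ≥1 observed post-baseline
primary-outcome record; per-protocol = mITT ∩ (pill-count compliance ≥ 0.80
or plasma n-3 above the 110 threshold) ∩ no protocol violation. The
per-protocol plasma threshold appears in the source documents as both
110 µg/mL and 110 µmol/L; the package applies 110 in the data's declared
unit. Pill-count compliance is `(dispensed − returned)/expected`, clipped
to [0, 1.5] with a warning above 1.

The treatment model is a linear mixed-effects regression with fixed
effects group (placebo reference), time in years, group×time (the
estimand: difference in annual slopes), and optional covariates (baseline
age, sex, hypertension/vascular history, APOE4, depression score); random
intercept and slope per participant with unstructured 2×2 covariance; REML
estimation. "Unstructured error covariance" in the design is read as the
unstructured random-effects covariance (a fully unstructured residual
covariance over visits is the documented alternative reading).
Missingness is handled by the likelihood under MAR; no imputation.

Numerics: estimation is delegated to statsmodels' `MixedLM`. The optimizer
is Powell (derivative-free, `xtol = ftol = 1e-4`); on this near-singular
REML profile the gradient-based optimizers stall measurably short of the
optimum while Powell attains it and reports convergence reliably.
Convergence failures are flagged on the result, never silently replaced.
Reported p-values are Wald normal-based, mildly liberal relative to a
t-reference at small n; the suite's null simulation checks the realized
size at n = 100 stays within binomial bounds of nominal 5%. Quadratic
time is added only when it lowers the small-sample-corrected AIC; because
REML likelihoods are not comparable across fixed-effect structures, that
comparison runs under ML and the selected structure is refit by REML. Note
that with a strongly skewed random intercept (log-normal baseline WMH, SD
16 cm³) the Gaussian likelihood is misspecified and AICc can prefer the
quadratic term on genuinely linear data; the selection mechanism is
therefore tested for internal consistency and for detecting real
curvature, not for never electing the extra term. The planned secondary
analysis adds group×time×APOE4 with all nested terms and flags
non-estimability when only one carrier stratum is present. Bonferroni
adjustment is `min(1, m·p)`.

## 7. Pipeline (`pufakit.pipeline`, CLI `pufa-kit`)

Stages (phantom → segment → cohort → screen → randomize → simulate →
power → analyze) run from a YAML config with a single global seed; each
stochastic stage derives its stream as
`SHA-256(seed:stage_name) mod 2³¹`, so stages are independently
re-runnable yet jointly reproducible. Every artifact is hash-recorded in a
run manifest. Units are centralized: volumes in cm³, schedules in months,
model time in years.

## 8. Validation problem sizes

The suite validates at sizes chosen to exercise the stated study
conditions: exhaustive oracle comparison on random ≤6³ integer grids
(vectorized pipeline vs an independent pure-Python batch-growth
simulation); planted-lesion recovery and the noise-floor measurement on
64³ phantoms over 100 noise seeds; allocation balance over 10⁴ simulated
cohorts of n = 102; mixed-model parameter recovery over 500 replicates and
null size over 1000 replicates at n = 100 with 30% attrition. Each
mixed-model replicate is an *independent simulated trial* — fresh cohort,
fresh randomization, fresh trajectories — so the measured bias and size
are marginal over the design. (Conditioning every replicate on a single
fixed cohort instead measures size conditional on that particular draw of
skewed baselines, which can deviate noticeably from the nominal level;
the Wald test is calibrated marginally, which is the claim a validity
check should make.)

## 9. Known limitations

* Phantoms are geometric, not anatomical; thresholds tuned on them do not
  transfer to scanner data without intensity calibration.
* The cohort generator draws covariates independently (no age–WMH or
  EPA–DHA correlation) and the trajectory model's random effects are
  Gaussian around a skewed baseline.
* The "modified" element of the published minimization algorithm is
  unreproducible from the available description.
* Real follow-up outcomes of the trial are not public; all longitudinal
  validation is against the simulator's own ground truth.
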