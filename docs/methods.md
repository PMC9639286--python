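# Methods

This note documents the statistical models implemented in `taucog`, the
generative model behind the synthetic cohorts, the numerical choices, and
the limits of what the test suite establishes.

## 1. Analysis models

### ROI construction

Six ROIs are defined on a shared voxel grid. Each cognitive-domain ROI is
the binary activation mask intersected with cortical gray matter, minus any
voxel carrying an off-target label (hippocampus, subcortex, cerebellum) —
off-target exclusion always takes precedence, including for Braak-stage-1
voxels inside the hippocampus label. The global ROI is all cortical GM
minus off-target labels; the temporal-lobe ROI is the union of Braak-stage
1, 3 and 4 regions minus off-target labels. No resampling is performed:
volumes must share dimensions and affine to 1e-6 or a geometry error is
raised, because spatial normalization is treated as an upstream
responsibility.

### Voxel-wise Gaussian mixture and TPP

For every ROI-union voxel the across-subject SUVR sample (the full cohort:
Aβ− controls and Aβ+ pooled, so the two components can represent the
tau-negative and tau-positive subpopulations) is fitted with a 1-D
two-component Gaussian mixture by EM, vectorised over voxels.

Numerical choices: components initialised at the 25th/75th percentiles of
the voxel sample with equal weights and SDs at half the sample SD;
log-likelihood tolerance 1e-8; maximum 500 iterations; SD floor 1e-3 SUVR.
A voxel is *non-informative* — excluded from TPP averaging — when the fit
did not converge, the sample is degenerate, the sorted component means are
closer than 0.05 SUVR, or a component weight falls below 0.01; these voxels
have no identifiable tau-positive component and their posteriors would be
arbitrary. The ROI summary in TPP mode is the **mean posterior
probability** over informative voxels (≥ 50% of the ROI must be
informative), not a thresholded positive-voxel fraction: the mean preserves
graded information and needs no extra cut-off parameter. SUVR mode simply
averages raw SUVR over all ROI voxels; on coupled synthetic cohorts the two
modes agree in rank (Spearman ρ > 0.8), mirroring the sensitivity analysis
in which raw-SUVR results stay consistent.

### Annual change rates

Per domain, on the full cohort (controls and Aβ+ jointly, so the change
rates are defined identically for the main Aβ+ and pooled analyses):

    score_ij = (b0 + u0_i) + (b1 + u1_i) * t_ij + e_ij,
    (u0_i, u1_i) ~ N(0, G),  e_ij ~ N(0, s2)

estimated by REML (statsmodels MixedLM); REML rather than ML because the
variance components are the quantity of interest at these sample sizes. The
subject's annual change rate is b1 + BLUP(u1_i); the baseline score is the
*observed* time-0 score, not the fitted intercept. Subjects with fewer than
two distinct visits are excluded before fitting and reported. A singular
random-effects covariance triggers a constrained refit with independent
(diagonal) random effects. Exactly-linear data (zero residual variance)
are detected up front and returned as per-subject OLS slopes — the analytic
BLUP limit — because the mixed likelihood is degenerate there.

### Bootstrapped partial R²

Per domain and ROI, OLS of change rate on the tau signal plus covariates
(age, sex, education, clinical-status dummies with CN reference, APOE4,
baseline score; education and APOE4 droppable). Partial R² is computed
against the reduced model without the tau term,
(RSS_red − RSS_full)/RSS_red — the *partial*, not semi-partial, form,
i.e. the share of covariate-unexplained outcome variance captured by tau.
Within a bootstrap iteration one subject resample (with replacement,
original size, unstratified) is shared across all ROIs: the downstream
paired t-test across iterations is only coherent if pairs share the
resample. Resamples with a singular design for any ROI are redrawn (more
than 10% redraws aborts). No multiple-testing correction is applied across
the 4 domains × 2 ROI pairs; p-values are reported per comparison.

### Personalized composites

The prediction ensemble is trained on the Aβ+ discovery sample only, with
covariates age, sex, clinical status and (optionally) APOE4 — deliberately
*without* baseline score and education, so the trained equations transfer
to cohorts where education is unavailable. Predicted decline per domain is
the mean over the B linear predictions. Squared-rank weights: the most
negative predicted change receives 16, then 9, 4, 1; ties below 1e-12 are
broken by the canonical domain order MEM < LAN < EF < VS with the earlier
domain taking the larger weight (a documented, deterministic rule — ties
are measure-zero in practice). The personalized composite is the weighted
*mean* Σ w_d z_d / Σ w_d (Σ w = 30) of the subject's actual z-scored change
rates; normalising by Σw keeps it on the same scale as the unweighted mean
z-score so the paired t-test between them is meaningful.

z-scores are referenced to the **whole cohort** (controls plus Aβ+). An
earlier design standardised within the Aβ+ analysis sample itself, but that
forces the unweighted composite to have mean exactly 0 by construction,
which degenerates the downstream power analysis (no intervention effect to
detect); referencing a normative sample that includes controls keeps a
declining patient group at a nonzero mean, which is the only reading
consistent with the finite published sample sizes for the standard
composite endpoint. The standardization constants are stored with the
ensemble so a validation cohort can be scored with either its own or the
discovery constants.

### Power simulation

An intervention attenuates every subject's change rate multiplicatively by
(1 − f), f ∈ {0.2, 0.3, 0.4}, regardless of sign. Effect size is the
two-sample Cohen's d between actual and attenuated vectors (pooled SD);
although the vectors share subjects, the two-sample form matches the
configured trial analysis (two independent arms). Required per-arm n is the
smallest integer ≥ 2 whose two-tailed two-sample t-test power, computed
from the noncentral t distribution with df = 2n − 2 and noncentrality
|d|·√(n/2), reaches 0.80 at α = 0.05; minimality is verified by direct
power evaluation at n and n − 1. Degenerate endpoints (zero-mean change)
are reported as not-detectable cells rather than aborting the table.

## 2. Synthetic cohort generator

The generator is the package's stand-in for the restricted study data; its
defaults *are* the study conditions, targeted at the published cohort
description.

**Structure.** Four groups — Aβ− controls (CN only, by the exclusion rule
that amyloid-negative cognitive impairment is not part of the AD spectrum)
and Aβ+ CN/MCI/dementia — with default sizes 121/62/53/25. Covariates
(age, sex, education, APOE4 carriage) are drawn per group from the
published group means/SDs/frequencies. An A05-like variant (46/5/35/25, no
education variable, compressed change-rate scale, near-complete three-visit
follow-up) is provided for transfer experiments.

**Latent tau burden.** Per subject, a 4-vector (one entry per domain) of
lognormal burdens: log-scale SD 0.8, cross-domain correlation 0.5 on the
log scale, group-specific means 0.05/0.38/1.13/3.0 chosen so that, through
the image model below, group-mean global SUVR lands on the published
1.06/1.11/1.21/1.46. Burdens are capped at 8: tracer signal saturates
physiologically, and an uncapped lognormal tail concentrates all regression
leverage in a single subject.

**Atlas and domain maps.** The anatomy is schematic: background shell,
basal cerebellar slab, central subcortical core, small hippocampal block,
and a cortical remainder split into six Braak-stage shells by distance from
the hippocampus. Domain maps are seeded random voxel sets over cortical GM:
each voxel has one "home" domain (inclusion probability 0.8, or 0.9 in
Braak-1/3/4 regions) and low cross-inclusion (0.05, or 0.07 in temporal
regions), plus deliberate 30% overlap with the hippocampus label so the
off-target exclusion path is exercised. Spatial contiguity is irrelevant
here because only ROI means enter the analysis. The temporal enrichment
makes temporal-lobe SUVR run above the global mean, as in real
flortaucipir data.

**Images.** In-brain voxels are i.i.d. N(1.05, 0.07²) around the
tau-negative SUVR level plus, inside each domain map, an elevation of
0.133 SUVR per unit of that domain's burden, scaled by a per-voxel gain
drawn once per cohort from Uniform(0.4, 1.6). The gain emulates spatially
varying deposition intensity; without it every ROI voxel crosses its
mixture threshold at the same burden and the ROI-mean TPP degenerates to a
step function of burden. Values are floored at 0.2 (SUVR is a positive
ratio). There is no spatial autocorrelation, partial-volume effect, or PET
physics.

**Cognition.** True slope per subject and domain = published group mean +
coupling_d × (burden_d − sample group-mean burden) + N(0, residual SD).
Coupling defaults (−0.049, −0.034, −0.018, −0.010 score units/year per
unit burden for MEM/LAN/EF/VS) are negative — more tau, faster decline —
and sized near the ceiling the published group SDs allow. The residual SD
is derived by subtracting the analytically known coupling variance
(coupling² × lognormal group variance) from the published total SD²
(floored at 20% of it), so generated group-level change-rate means *and*
SDs sit on their published targets; centring on the sample rather than the
analytic group mean keeps group means on target despite the heavy-tailed
burden. Observations are baseline + slope·t + N(0, per-domain measurement
SD) at visits {0, 0.75, 1.5} years with 35% dropout of the last visit.
Measurement SDs (0.05/0.03/0.03/0.004) are small relative to the slope
spread so that the mixed-model *estimated* rates — the quantity the
published table describes — retain that table's spread; the visit schedule
cannot simultaneously match the published mean visit count (2.33) and mean
follow-up (~1.5–2.0 y), and the chosen dropout favours follow-up time.

**Determinism.** All draws flow from one root seed through named
substreams (CRC-32 of the stage name), so any stage is bit-reproducible
independently of execution order.

## 3. What the tests show — and do not

The acceptance-style checks run the full pipeline on the default synthetic
discovery cohort (261 subjects, 20³ grid, B = 1000, fixed seed) and verify
the study's qualitative result patterns: each domain ROI out-predicting the
global and temporal ROIs for its own domain; the personalized composite
declining faster than the unweighted one; and the personalized composite
requiring the smallest per-arm n at every intervention strength, with n
monotone in attenuation. These demonstrate that the implementation recovers
the patterns *when the data have the assumed structure* (domain-coupled
tau). They cannot certify the patterns in real ADNI/A05 data, whose exact
regression values additionally depend on restricted subject-level
distributions; published exact partial R², t statistics and per-arm n are
therefore not reproduction targets, with two exceptions that are pure
analytic identities (d = t/√n at the published (t, n) pairs, and the
noncentral-t reference sizes n(d=0.5) = 64, n(d=1.0) = 17).

Problem sizes used throughout testing (20³ grids, 50–261 subjects,
B ≤ 1000) were chosen as the smallest at which the group structure, the
voxel-wise mixture fits, and the bootstrap distributions are all stable.

## 4. Known limitations

* The mixture is fitted per cohort; fitting on a reference sample and
  transferring the voxel models is not implemented.
* The generator's dropout model is a plain stand-in; per-visit missingness
  patterns of the real cohorts are not published.
* The ensemble transfer assumes identically defined predictors in the
  validation cohort (same ROI/TPP pipeline, same covariate coding).
* With only ~2–3 visits over ≤ 1.5 years, BLUP change rates are noticeably
  shrunken toward the fixed slope; all ROI comparisons operate on the same
  shrunken outcome, so rankings are unaffected, but absolute partial R²
  values depend on the measurement-noise setting.
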