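# Methods

This note documents the models implemented in `mpfi`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Imaging models

### DWI and IVIM

Diffusion signal over the 10-step b-ladder (0/10/25/50/75/150/300/500/750/
1000 s/mm²) follows the bi-exponential intravoxel-incoherent-motion model

    S(b) = S0 · [ f·exp(−b·D*) + (1−f)·exp(−b·D) ],

with tissue diffusion coefficient D, pseudo-diffusion coefficient D* (both
carried in 10⁻³ mm²/s) and perfusion fraction f ∈ [0, 1]. The mono-exponential
ADC is minus the OLS slope of ln S against b over all b-values.

Fitting is **segmented**, the standard stabilisation for this
poorly-conditioned model: D and the high-b intercept come from a log-linear
fit over b ≥ 300 s/mm² (the natural gap in the ladder), f from the intercept
ratio 1 − S0_high/S(0), and D* from a one-parameter bounded nonlinear fit
with D and f fixed. Bounds: D ∈ [0, 4], D* ∈ [D, 500] (10⁻³ mm²/s),
f ∈ [0, 1]. A joint 4-parameter refinement is available via
`fit_ivim(..., method="joint")`. Optimiser failure is recorded in the voxel's
fit status, never raised, so map fitting and failure-rate accounting proceed.

**Identifiability.** At b=0 SNR 50, the perfusion compartment carries an
effective SNR of only ~5, so per-voxel f and D* errors of 20–45% are
intrinsic — a dense grid-search maximum-likelihood fit does no better. The
pipeline therefore summarises an ROI by the **median of its voxel fits**, and
recovery is judged on that median estimate: over 500 voxels at SNR 50 the
ROI-median D and f recover truth within ~1% and D* within ~10%. D* remains
the least identifiable parameter and should be interpreted accordingly.

ROI histogram features use central moments: skewness m₃/m₂^1.5 and kurtosis
m₄/m₂² in the **Pearson convention** (normal → 3); the convention is
switchable (`kurtosis_convention="excess"`) and recorded where emitted.

### DCE-MRI

The chain is: (i) native T1 from variable-flip-angle (2/5/10/15/20°) spoiled
gradient-echo scans, S = M0·sin α·(1−E1)/(1−E1·cos α), E1 = exp(−TR/T1),
fitted by nonlinear least squares initialised from the linearised S/sin α vs
S/tan α estimator; data that the SPGR curve cannot represent (relative
residual > 5%) are flagged failed. (ii) Frame-by-frame inversion of the
dynamic SPGR signal for R1(t), with the dynamic-scan M0 re-derived from the
pre-bolus baseline frames at the fitted T1 — this accommodates different
scaling between the VFA pre-scan and the dynamic scan and pins baseline
concentration to exactly zero; C(t) = (R1(t) − R1₀)/r1. Relaxivity defaults
to r1 = 3.5 L·mmol⁻¹·s⁻¹ (literature-typical for Gd-DOTA at 3 T;
configurable). No haematocrit correction is applied anywhere, so plasma and
blood concentration scales coincide by construction on both the simulation
and fitting side. (iii) Two-compartment Tofts fitting of C_t(t) with a
**Parker-form population AIF** (two Gaussians plus exponential-decay sigmoid;
parameters in `mpfi.dce._PARKER_DEFAULTS`, bolus arrival at the end of the
3 baseline frames). The same `PopulationAIF` object drives simulation and
fitting, which makes parameter-recovery results insensitive to the
particular AIF shape chosen.

The Tofts convolution is evaluated by **exponential-kernel recursion**,
exact for piecewise-linear C_p, so forward and inverse models agree to
machine precision on the 4.16 s frame grid (the constant-input closed form
v_e·c₀·(1−e^(−k_ep t)) is matched to <0.1%). k_ep is always reported as the
ratio K^trans/v_e (deviation ≤ 10⁻¹² asserted). Fitted v_e > 1 is retained
and flagged, never clipped.

**Fit failure.** A voxel fit fails on optimiser non-convergence or when the
residual norm exceeds 25% of the signal norm (configurable) — at frame-SNR
20 this fails ~17% of voxels, consistent with noise being the dominant
failure mode. A scan is excluded when **strictly more than 30%** of ROI
voxels fail: 31/100 excludes, 30/100 retains.

### PET

SUV = activity concentration / (injected dose / body weight). SUVpeak is the
maximum, over candidate centres, of the mean SUV of voxels whose centres lie
within 6.2035 mm (an exact 1 mL sphere); ties break lexicographically and a
voxel larger than the sphere is an error. MATV segmentation thresholds at

    T = 0.5·(SUVpeak − BG) + BG,

the standard background-adapted 50% form, keeping the 26-connected component
containing the peak centre; BG is the mean over a 2-voxel shell starting
1 voxel outside the lesion boundary. TLG = SUVmean × MATV holds identically
for every segmentation.

## Feature table and statistics

Fifteen imaging features per timepoint: ADC_GTV, ADC_median, ADC_skewness,
ADC_kurtosis, D, D*, f, DCE_GTV, K^trans, v_e, k_ep, MATV, SUV_mean,
SUV_peak, TLG. Continuous features are the **mean over two observers of each
observer's ROI median**; delta features are (intra − pre)/pre, undefined
(missing) when pre = 0. Seven clinical covariates: age, gender (1 = male),
tobacco, HPV (1 = positive), site, T-stage, N-stage (1 = N2–3). The
assembled table has 45 imaging columns (15 × PRE/INTRA/Δ) plus clinical.

Mann–Whitney U uses the exact null for both groups ≤ 8 without ties, else
the tie-corrected normal approximation (via scipy). Univariate Cox fits use
the Efron partial likelihood (lifelines) with Wald p-values; monotone
likelihood (quasi-separation) is detected by checking that the partial
likelihood stops increasing beyond the fitted coefficient, and is flagged
rather than raised. Interobserver agreement is Pearson r (the alternative,
an ICC, is not implemented).

For 2-year logistic endpoints, patients censored before 2 years without an
event are excluded (they are neither events nor confirmed event-free), which
is why logistic and Cox cells of the model grid can have different n.

## Prognostic models

LASSO logistic regression (scikit-learn, liblinear) for dichotomised
endpoints scored by AUC, and LASSO Cox (scikit-survival Coxnet, l1_ratio=1)
for censored endpoints scored by Harrell's C. Validation is repeated
**stratified 5-fold cross-validation** (500 repeats by default; validation
experiments use 5–10 repeats per cohort). Within every training fold
features are standardised and the penalty is chosen by an **inner 5-fold CV**
(log-loss for logistic, held-out concordance for Cox; λ_min rule, 1-SE
available) — nested, so the held-out fold never influences scaling or
penalty. Held-out predictions are pooled per repeat; the reported metric is
the mean over repeats with its SD across repeats. Final coefficients come
from a refit on all data at the inner-CV-chosen penalty. Selection frequency
is the fraction of outer-fold fits in which a feature's coefficient is
nonzero.

AUC is computed by the rank (Mann–Whitney) formulation and Harrell's C by
pair counting (usable pair: the shorter observed time carries an event;
predictor ties count ½); both are verified against exhaustive O(n²)
enumeration and against the corresponding library implementations.

**Calibration.** On null cohorts (n = 57, 15 features, outcomes independent
of all features) the cross-validated AUC centres on 0.50 and the C-index on
~0.52 — pooling held-out linear predictors across folds carries a known
mild optimism of ~0.02, well inside the ±0.05 acceptance band. Calibration
is averaged over several independent cohorts to separate such systematic
effects from single-draw sampling noise (a single 57-patient null cohort's
CV-AUC has an SD of ~0.05 by itself). On recoverable-truth cohorts (n = 200,
3 informative features with per-SD odds ratios of ~4.5–7.4, chosen as a
clearly-strong effect), CV-AUC is ~0.90 and the true features are selected
in 100% of folds.

## Risk calculators and stratification

The three published 2-year calculators (locoregional recurrence, distant
metastasis, death) are shipped as data: Y = intercept + Σ coefᵢ·xᵢ,
p = 1/(1+exp(−Y)). The operation is **scale-agnostic**: it applies the
printed affine map to whatever predictor values it is given, and the
pipeline records which scaling produced its inputs. In particular the MATV
coefficient of the death calculator (8.64) implies a transformed predictor
scale that the source does not state — applying that calculator to raw mL
values is not meaningful, and users must supply predictors on the scale the
calculator was derived on.

Risk groups use fixed probability cuts — low < 0.33 ≤ medium < 0.66 ≤ high
(both intervals left-closed; the boundary convention at exactly 0.33/0.66 is
a documented choice) — with cohort-tertile cuts available. Kaplan–Meier
curves and the multigroup log-rank test come from lifelines; high-risk
sensitivity/specificity treats high-vs-rest as a diagnostic test for the
event.

## Synthetic cohorts

The generator forward-simulates, per patient and timepoint: 10-b DWI voxel
signals with **Rician** noise (magnitude statistics; default σ = S0/50),
dynamic SPGR + VFA signals through the forward Tofts chain with **Gaussian**
noise, and PET spheres on a 4 mm grid over local background with Gaussian
noise and optional post-reconstruction smoothing. Lesion truth is drawn from
literature-plausible HNSCC ranges (D ≈ 1.0±0.15, f ≈ 0.12±0.03,
D* ≈ 20±5 ×10⁻³ mm²/s; T1 ≈ 1200±100 ms; K^trans ≈ 0.25±0.08 min⁻¹,
v_e ≈ 0.35±0.10; SUV ≈ 8±2 over background 1). Intratreatment scans apply
multiplicative shifts (ADC/D up ~20%, K^trans down ~15%, SUV down ~30%,
radius down ~10%; illustrative early-response magnitudes, not calibrated to
any cohort) so delta features carry recoverable signal. A second observer is
simulated by random dilation/erosion plus boundary flips, constrained to
Dice ≥ 0.6 of the original.

Outcomes are drawn from a linear-logistic event model: per patient,
P(event ≤ 2 y) = 1/(1+exp(−Y)) with Y a linear predictor over named
features; event times are exponential with the rate chosen so that the
2-year event probability holds exactly, and non-events are administratively
censored at 2 years (optional uniform early dropout). This matches the
functional form of the risk calculators, giving the modelling and
stratification stages a recoverable truth.

**What the generator does not emulate:** anatomical head-and-neck geometry,
partial-volume effects beyond optional smoothing, motion (series are
generated aligned; motion correction is upstream of this pipeline),
inter-scanner variability, and correlated multi-lesion disease. Passing
recovery tests therefore demonstrate the correctness of the estimators under
the stated noise models, not clinical-grade performance on real data.

## Problem sizes

Validation experiments use: 500 IVIM voxels, 200 DCE voxels (75 frames),
null calibration over 5–8 cohorts of 57 patients with 5–10 CV repeats each,
truth recovery over 3 cohorts of 200, and 20 stratification simulations of
500 patients. The full image-level pipeline demo runs 6–20 patients with
small grids. These sizes were chosen to make all results stable to the
asserted tolerances while keeping a complete run in the minutes range on a
single CPU; every number scales up through configuration.

## Known limitations

* D* is weakly identified at clinical SNR; only ROI-level medians are
  reliable.
* The extended Tofts model (vascular term v_p), 2CXM, patient-specific AIF
  extraction and B1 correction are out of scope.
* The Cox pooled-CV C-index carries ~0.02 optimism under the null (see
  Calibration); fold-level averaging would remove it at the cost of higher
  variance.
* The calculators' predictor scaling (notably MATV for the death
  calculator) is inherited from their source and not re-derivable here.
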