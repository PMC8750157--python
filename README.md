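# mpfi — multi-parametric functional imaging response prediction

Patients with locally advanced head-and-neck squamous cell carcinoma (HNSCC)
respond very differently to (chemo)radiotherapy. Quantitative functional
imaging — diffusion-weighted MRI with intravoxel-incoherent-motion (IVIM)
modelling, dynamic contrast-enhanced (DCE) MRI with Tofts pharmacokinetics,
and ¹⁸F-FDG-PET lesion metrics — acquired before and early during treatment
captures tumour changes that precede anatomical response. `mpfi` implements
the full analysis chain that turns such paired scans into 2-year outcome
predictions:

1. **DWI/IVIM** — voxelwise mono-exponential ADC and segmented bi-exponential
   IVIM fitting, `S(b) = S0·[f·e^(−b·D*) + (1−f)·e^(−b·D)]`, over a 10-step
   b-ladder (0–1000 s/mm²), plus ROI histogram features (median, skewness,
   Pearson kurtosis).
2. **DCE-MRI** — variable-flip-angle T1 mapping from the spoiled
   gradient-echo equation, signal-to-gadolinium-concentration conversion, and
   voxelwise two-compartment Tofts fitting
   `C_t(t) = K^trans ∫ C_p(u)·e^(−k_ep(t−u)) du`, `k_ep = K^trans/v_e`, under
   a shared Parker-form population arterial input function. Scans with
   fit failure in more than 30% of ROI voxels are flagged for exclusion.
3. **PET** — SUV scaling, SUVpeak (maximum-mean 1 mL spherical VOI),
   background-corrected 50%-SUVpeak segmentation of the metabolically active
   tumour volume (MATV), and TLG = SUVmean × MATV.
4. **Feature table** — 15 imaging features per timepoint (observer-averaged
   ROI medians), fractional intratreatment deltas `Δ = (intra − pre)/pre`,
   and clinical covariates.
5. **Prognostic models** — LASSO logistic and LASSO Cox models over
   PRE/INTRA/Δ/ALL feature sets, validated by repeated stratified 5-fold
   cross-validation with nested penalty selection (AUC / Harrell's C).
6. **Risk stratification** — published linear-logistic risk calculators for
   locoregional recurrence, distant metastasis and death; low/medium/high
   risk groups at fixed probability cuts (<33% / 33–66% / ≥66%); Kaplan–Meier
   curves, log-rank tests, and high-risk sensitivity/specificity.

Because clinical cohorts of this kind are not publicly deposited, the
package ships a first-class synthetic-cohort generator (`mpfi.synthetic`)
that forward-simulates every modality from known ground truth, so each stage
is tested by parameter recovery rather than by fixture files.

## Worked example

```python
import numpy as np
from mpfi.core_io import AcquisitionMeta
from mpfi.dwi import fit_ivim
from mpfi.dce import PopulationAIF, fit_t1_vfa, fit_tofts, signal_to_concentration
from mpfi.synthetic import simulate_dwi_signals, simulate_dce_series
from mpfi.risk import LRFFS_CALCULATOR, apply_calculator

meta = AcquisitionMeta()          # 10 b-values, VFA 2/5/10/15/20 deg, TR 4.8 ms ...

# --- IVIM: 200 tumour voxels at Rician SNR 50, summarised by the ROI median
truth = dict(D=1.0, D_star=20.0, f=0.1)
signals = simulate_dwi_signals(truth, meta.b_values, sigma=20.0, seed=7, n_voxels=200)
fits = [fit_ivim(s, meta.b_values) for s in signals]
ok = [f for f in fits if f.status == "ok"]
print(np.median([f.D for f in ok]), np.median([f.D_star for f in ok]),
      np.median([f.f for f in ok]))

# --- DCE: forward-simulate one voxel, then recover Ktrans/ve through the chain
aif = PopulationAIF(bolus_arrival_s=meta.n_baseline_frames * meta.frame_duration_s)
dyn, vfa, times = simulate_dce_series(dict(Ktrans=0.2, ve=0.3, T1_0=1100.0),
                                      aif, meta, 75, 0.0, 7)
t1 = fit_t1_vfa(vfa, meta.vfa_angles_deg, meta.tr_ms)
conc = signal_to_concentration(dyn, t1, meta.tr_ms, meta.flip_angle_deg,
                               meta.relaxivity_r1, meta.n_baseline_frames)
tofts = fit_tofts(conc, aif, times)
print(t1.T1_0, tofts.Ktrans, tofts.ve, tofts.kep)

# --- risk: the 2-year locoregional-recurrence calculator for one patient
patient = {"PRE_ADC_kurtosis": 3.1, "PRE_kep": 0.52, "PRE_SUV_peak": 1.21,
           "delta_ADC_skewness": 0.35, "delta_f": -0.12,
           "delta_SUV_peak": -0.31, "delta_TLG": -0.42}
print(apply_calculator(LRFFS_CALCULATOR, patient))
```

This prints (formatted):

```
ROI medians over 200 voxels: D=1.020e-3 mm2/s  D*=22.0e-3 mm2/s  f=0.087
T1 = 1100.0 ms;  Tofts: Ktrans=0.2000/min  ve=0.3000  kep=0.6667/min
2-year locoregional recurrence risk: 67.9%
```

The ROI medians recover the generating truth (D = 1.0, D* = 20, f = 0.1)
within a few percent even though individual noisy voxels scatter widely; the
noiseless DCE chain recovers T1 and the Tofts parameters essentially
exactly; and the risk calculator converts the patient's predictor vector
into an absolute 2-year event probability (here a high-risk patient,
p ≥ 0.66).

## Command line

```bash
mpfi simulate-cohort --out cohort/ --seed 1 --n-patients 12
mpfi build-features  --cohort cohort/ --out features.csv
mpfi train-models    --features features.csv --outcomes cohort/outcomes.csv --out report/
mpfi risk-calc       --calculator lrffs --features features.csv --out risks.csv
mpfi stratify        --risks risks.csv --outcomes cohort/outcomes.csv --out km/
mpfi run-all         --out mpfi_run --seed 1     # everything, one seed
```

Per-modality fitting is also exposed (`mpfi fit-dwi`, `mpfi fit-dce`,
`mpfi pet-metrics`); every run writes a resolved configuration with the seed
and package version next to its outputs.

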