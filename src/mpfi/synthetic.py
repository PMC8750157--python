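"""Synthetic phantoms and cohorts with known ground truth.

Because the clinical cohort this pipeline targets is not publicly deposited,
every downstream stage is exercised on simulated data whose generating
parameters are recorded, so that fitted values can be compared against truth:

* multi-b-value DWI voxel signals from the bi-exponential IVIM forward model
  with Rician (magnitude) noise;
* dynamic SPGR (DCE) signals from a forward Tofts model under the shared
  population AIF, plus matched variable-flip-angle pre-scans, with Gaussian
  noise;
* PET lesions as uniform spheres on a 4 mm grid over a local background,
  with Gaussian noise and optional post-reconstruction smoothing;
* paired PRE/INTRA timepoints produced by multiplicative treatment shifts of
  the true parameters, so delta features carry recoverable signal;
* 2-year outcomes drawn from a linear-logistic event model with
  exponential event times, matching the functional form of the risk
  calculators downstream.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import AcquisitionMeta, DynamicSeries, ImageVolume, ROIMask
from .dce import PopulationAIF, spgr_signal, tofts_forward
from .dwi import ivim_signal

__all__ = [
    "TruthRecord",
    "CohortSpec",
    "simulate_dwi_signals",
    "simulate_dce_series",
    "simulate_pet_volume",
    "simulate_outcomes",
    "perturb_roi",
    "spherical_mask",
    "simulate_feature_cohort",
    "generate_cohort",
]


@dataclass
class TruthRecord:
    """Per-lesion generating parameters for one patient.

    Diffusion coefficients in 1e-3 mm^2/s, Ktrans/kep in 1/min, T1 in ms.
    ``shifts`` are multiplicative INTRA/PRE factors per parameter.
    """

    patient_id: str
    ADC: float
    D: float
    D_star: float
    f: float
    T1_0: float
    Ktrans: float
    ve: float
    SUV: float
    background_SUV: float
    lesion_radius_mm: float
    shifts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.f <= 1:
            raise ValueError("perfusion fraction f must be in [0, 1]")
        if self.D < 0 or self.D_star < 0 or self.Ktrans < 0:
            raise ValueError("D, D* and Ktrans must be nonnegative")
        if self.ve <= 0:
            raise ValueError("ve must be positive")

    def at_timepoint(self, timepoint: str) -> dict:
        """True parameter values at PRE or INTRA (shifts applied)."""
        base = {k: getattr(self, k) for k in
                ("ADC", "D", "D_star", "f", "T1_0", "Ktrans", "ve", "SUV", "lesion_radius_mm")}
        if timepoint == "PRE":
            return base
        if timepoint != "INTRA":
            raise ValueError(f"unknown timepoint {timepoint!r}")
        out = dict(base)
        for k, factor in self.shifts.items():
            out[k] = base[k] * factor
        out["f"] = min(max(out["f"], 0.0), 1.0)
        return out


# Treatment-shift distributions (mean multiplicative change, sd) for the
# intratreatment scan: diffusion rises with cell kill, perfusion-related and
# metabolic parameters fall, lesions shrink.  Illustrative magnitudes typical
# of early chemoradiotherapy response; not calibrated to any single cohort.
DEFAULT_SHIFT_DISTRIBUTIONS = {
    "ADC": (1.20, 0.10),
    "D": (1.20, 0.10),
    "D_star": (1.00, 0.10),
    "f": (0.90, 0.15),
    "Ktrans": (0.85, 0.10),
    "ve": (1.05, 0.10),
    "SUV": (0.70, 0.15),
    "lesion_radius_mm": (0.90, 0.07),
}


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort.

    Defaults mirror the study conditions this pipeline is designed for: a
    57-patient head-and-neck cohort, DWI at Rician SNR 50, 75-frame DCE at
    4.16 s with 3 baseline frames, and PET lesions on a 4 mm grid.
    """

    n_patients: int = 57
    dwi_sigma: float = 20.0        # Rician sigma at S0 = 1000 (SNR 50)
    dce_sigma: float = 0.0         # Gaussian signal sd (signal units)
    pet_sigma: float = 0.2         # Gaussian SUV sd
    pet_smoothing_fwhm_mm: float = 0.0
    seed: int = 0
    shift_distributions: dict = field(default_factory=lambda: dict(DEFAULT_SHIFT_DISTRIBUTIONS))
    event_horizon_years: float = 2.0
    dropout_rate: float = 0.0      # early random censoring fraction
    mri_grid: tuple = (20, 20, 10)
    mri_spacing: tuple = (2.0, 2.0, 2.0)
    max_mri_lesion_radius_mm: float = 8.0  # keeps voxelwise fitting tractable
    pet_grid: tuple = (32, 32, 32)
    n_dce_frames: int = 75

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for s in (self.dwi_sigma, self.dce_sigma, self.pet_sigma):
            if s < 0:
                raise ValueError("noise sigmas must be nonnegative")


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return noiseless.copy()
    re = noiseless + rng.normal(0, sigma, noiseless.shape)
    im = rng.normal(0, sigma, noiseless.shape)
    return np.sqrt(re**2 + im**2)


def simulate_dwi_signals(truth: dict | TruthRecord, b_values, sigma: float, seed: int,
                         n_voxels: int = 1, S0: float = 1000.0) -> np.ndarray:
    """Simulate per-voxel multi-b DWI magnitude signals, shape (n_voxels, n_b).

    Noiseless signals follow the bi-exponential IVIM model exactly; Rician
    noise (magnitude of a complex Gaussian) is added when sigma > 0.
    """
    p = truth if isinstance(truth, dict) else asdict(truth)
    rng = np.random.default_rng(seed)
    clean = ivim_signal(b_values, S0, p["D"], p["D_star"], p["f"])
    clean = np.broadcast_to(clean, (n_voxels, len(tuple(b_values)))).copy()
    return _rician(clean, sigma, rng)


def simulate_dce_series(truth: dict | TruthRecord, aif: PopulationAIF, meta: AcquisitionMeta,
                        n_frames: int = 75, sigma: float = 0.0, seed: int = 0,
                        M0: float = 1000.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-simulate one voxel's dynamic DCE signal and VFA pre-scans.

    Returns ``(dynamic_signal, vfa_signals, times_s)``.  Tissue concentration
    is zero during the baseline frames (the AIF bolus arrival is placed at
    the end of frame ``n_baseline_frames``); the VFA signals share the same
    T1_0 and M0.  Gaussian noise models reconstructed MR signal noise.
    """
    p = truth if isinstance(truth, dict) else asdict(truth)
    if p["Ktrans"] < 0 or p["ve"] <= 0:
        raise ValueError("Ktrans must be >= 0 and ve > 0")
    if meta.tr_ms <= 0 or p["T1_0"] <= 0:
        raise ValueError("TR and T1 must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * meta.frame_duration_s
    ct = tofts_forward(p["Ktrans"], p["ve"], aif, times)
    r1_0 = 1.0 / (p["T1_0"] / 1000.0)
    r1_t = r1_0 + meta.relaxivity_r1 * ct
    t1_t = 1000.0 / r1_t
    dyn = spgr_signal(M0, t1_t, meta.tr_ms, meta.flip_angle_deg)
    vfa = spgr_signal(M0, p["T1_0"], meta.tr_ms, np.asarray(meta.vfa_angles_deg))
    if sigma > 0:
        dyn = dyn + rng.normal(0, sigma, dyn.shape)
        vfa = vfa + rng.normal(0, sigma, vfa.shape)
    return dyn, vfa, times


def spherical_mask(shape, center_vox, radius_mm: float, spacing) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within radius_mm of centre."""
    spacing = np.asarray(spacing, dtype=float)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center_vox, spacing))
    return d2 <= radius_mm**2


def simulate_pet_volume(truth: dict | TruthRecord, grid_shape=(32, 32, 32),
                        spacing=(4.0, 4.0, 4.0), sigma: float = 0.0, seed: int = 0,
                        smoothing_fwhm_mm: float = 0.0,
                        center_vox=None) -> tuple[ImageVolume, ROIMask]:
    """A uniform spherical lesion in SUV units over a local background.

    Optional Gaussian noise and post-reconstruction Gaussian smoothing; the
    true lesion mask is returned alongside for recovery checks.
    """
    p = truth if isinstance(truth, dict) else asdict(truth)
    suv, bg = p["SUV"], p["background_SUV"]
    if not suv > bg >= 0:
        raise ValueError("lesion SUV must exceed background >= 0")
    radius = p["lesion_radius_mm"]
    spacing = tuple(float(s) for s in spacing)
    if any(2 * radius > n * s for n, s in zip(grid_shape, spacing)):
        raise ValueError("lesion does not fit in the grid")
    if center_vox is None:
        center_vox = tuple(n // 2 for n in grid_shape)
    lesion = spherical_mask(grid_shape, center_vox, radius, spacing)
    vox = np.full(grid_shape, float(bg))
    vox[lesion] = suv
    if smoothing_fwhm_mm > 0:
        sig_vox = smoothing_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / np.asarray(spacing)
        vox = ndimage.gaussian_filter(vox, sigma=sig_vox)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        vox = vox + rng.normal(0, sigma, vox.shape)
    return ImageVolume(voxels=vox, spacing=spacing), ROIMask(mask=lesion)


def simulate_outcomes(features: pd.DataFrame, coefficients: dict, seed: int,
                      intercept: float = 0.0, horizon_years: float = 2.0,
                      dropout_rate: float = 0.0) -> pd.DataFrame:
    """Simulate censored time-to-event outcomes from a linear-logistic model.

    Per patient, Y = intercept + sum(coef * feature) and the probability of
    an event within ``horizon_years`` is 1/(1+exp(-Y)).  Event times are
    exponential with the rate chosen so that P(T <= horizon) equals that
    probability exactly; patients without an event by the horizon are
    administratively censored there.  ``dropout_rate`` adds uniform early
    censoring.
    """
    missing = set(coefficients) - set(features.columns)
    if missing:
        raise ValueError(f"coefficient names missing from features: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    y = np.full(len(features), float(intercept))
    for name, coef in coefficients.items():
        y = y + coef * features[name].to_numpy(dtype=float)
    p_event = 1.0 / (1.0 + np.exp(-y))
    # rate such that P(T <= horizon) = p_event; p -> 1 capped for stability
    rate = -np.log(np.clip(1 - p_event, 1e-12, 1)) / horizon_years
    with np.errstate(divide="ignore"):
        t_event = rng.exponential(1.0, len(y)) / np.where(rate > 0, rate, np.inf)
    censor = np.full(len(y), horizon_years)
    if dropout_rate > 0:
        drop = rng.random(len(y)) < dropout_rate
        if drop.any():
            censor[drop] = rng.uniform(0, horizon_years, int(drop.sum()))
    event = t_event <= censor
    time = np.minimum(t_event, censor)
    return pd.DataFrame({
        "linear_predictor": y,
        "event_probability": p_event,
        "time": time,
        "event": event.astype(int),
    }, index=features.index)


def perturb_roi(mask: ROIMask, magnitude: int = 1, seed: int = 0,
                flip_fraction: float = 0.3, min_dice: float = 0.6) -> ROIMask:
    """A simulated second observer's delineation of the same lesion.

    Randomly dilates or erodes by ``magnitude`` iterations, then flips a
    random fraction of boundary voxels.  Guaranteed nonempty and within a
    Dice floor of the original (falls back to milder perturbation if not).
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot perturb an empty mask")
    if magnitude == 0:
        return ROIMask(mask=mask.mask.copy(), observer_id=2, lesion_id=mask.lesion_id)
    rng = np.random.default_rng(seed)
    struct = ndimage.generate_binary_structure(3, 1)
    base = mask.mask

    def attempt(mag: int, frac: float) -> np.ndarray:
        if rng.random() < 0.5:
            m = ndimage.binary_dilation(base, struct, iterations=mag)
        else:
            m = ndimage.binary_erosion(base, struct, iterations=mag)
            if not m.any():
                m = ndimage.binary_dilation(base, struct, iterations=mag)
        boundary = ndimage.binary_dilation(m, struct) & ~ndimage.binary_erosion(m, struct)
        flips = np.argwhere(boundary)
        k = int(frac * len(flips))
        if k:
            sel = flips[rng.choice(len(flips), size=k, replace=False)]
            m = m.copy()
            m[sel[:, 0], sel[:, 1], sel[:, 2]] = ~m[sel[:, 0], sel[:, 1], sel[:, 2]]
        return m

    def dice(a, b):
        inter = (a & b).sum()
        return 2 * inter / (a.sum() + b.sum())

    m = attempt(magnitude, flip_fraction)
    tries = 0
    while (not m.any() or dice(base, m) < min_dice) and tries < 10:
        m = attempt(max(1, magnitude - 1), flip_fraction / 2)
        tries += 1
    if not m.any():
        m = base.copy()
    return ROIMask(mask=m, observer_id=2, lesion_id=mask.lesion_id)


# ---------------------------------------------------------------------------
# feature-level cohorts for prognostic-model calibration


def simulate_feature_cohort(n_patients: int, n_features: int, seed: int,
                            informative: dict | None = None,
                            intercept: float = 0.0,
                            horizon_years: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standard-normal feature matrix plus outcomes from a known linear predictor.

    ``informative`` maps feature names (``"x0"`` ... ) to true logistic
    coefficients; omit or empty for a null cohort where outcomes are
    independent of every feature.  Returns ``(features, outcomes)``.
    """
    rng = np.random.default_rng(seed)
    cols = [f"x{i}" for i in range(n_features)]
    X = pd.DataFrame(rng.normal(0, 1, (n_patients, n_features)), columns=cols)
    X.index = [f"P{i:04d}" for i in range(n_patients)]
    coeffs = dict(informative or {})
    outcomes = simulate_outcomes(X, coeffs, seed=int(rng.integers(2**31)),
                                 intercept=intercept, horizon_years=horizon_years)
    return X, outcomes


# ---------------------------------------------------------------------------
# full image-level cohort


def _draw_truth(rng: np.random.Generator, patient_id: str, shift_dists: dict) -> TruthRecord:
    def tn(mean, sd, lo, hi):  # truncated normal draw
        for _ in range(100):
            v = rng.normal(mean, sd)
            if lo < v < hi:
                return float(v)
        return float(np.clip(mean, lo, hi))

    D = tn(1.0, 0.15, 0.4, 2.5)
    f = tn(0.12, 0.03, 0.02, 0.35)
    D_star = tn(20.0, 5.0, 8.0, 60.0)
    shifts = {k: tn(m, s, 0.3, 2.5) for k, (m, s) in shift_dists.items()}
    return TruthRecord(
        patient_id=patient_id,
        ADC=D * (1 + f * 5),  # pseudo-diffusion inflates the mono-exponential ADC
        D=D, D_star=D_star, f=f,
        T1_0=tn(1200.0, 100.0, 600.0, 2000.0),
        Ktrans=tn(0.25, 0.08, 0.02, 1.0),
        ve=tn(0.35, 0.10, 0.05, 0.9),
        SUV=tn(8.0, 2.0, 3.0, 20.0),
        background_SUV=1.0,
        lesion_radius_mm=tn(11.0, 2.0, 6.0, 18.0),
        shifts=shifts,
    )


def generate_cohort(spec: CohortSpec, out_dir=None, aif: PopulationAIF | None = None,
                    meta: AcquisitionMeta | None = None,
                    outcome_coefficients: dict | None = None,
                    outcome_intercept: float = -1.0):
    """Generate a full synthetic cohort: truth table, images per patient, outcomes.

    Returns ``(truths, outcomes)`` and, when ``out_dir`` is given, writes
    NIfTI volumes (DWI 4-D, DCE 4-D + VFA, PET), masks for two observers,
    JSON metadata and ``truth.csv`` / ``outcomes.csv`` under per-patient
    directories.  Outcome truth defaults to a mix of pre and delta
    parameters so the modelling stage has a recoverable signal.
    """
    from pathlib import Path
    from . import core_io

    rng = np.random.default_rng(spec.seed)
    meta = meta or AcquisitionMeta()
    aif = aif or PopulationAIF(bolus_arrival_s=meta.n_baseline_frames * meta.frame_duration_s)
    truths = [_draw_truth(rng, f"P{i:03d}", spec.shift_distributions)
              for i in range(spec.n_patients)]

    truth_rows = []
    for tr in truths:
        row = {"patient_id": tr.patient_id}
        for tp in ("PRE", "INTRA"):
            for k, v in tr.at_timepoint(tp).items():
                row[f"{tp}_{k}"] = v
        truth_rows.append(row)
    truth_df = pd.DataFrame(truth_rows).set_index("patient_id")

    # outcomes from true parameters: default links events to low ADC rise,
    # high metabolic burden and persistent perfusion
    feat = pd.DataFrame({
        "PRE_SUV": truth_df["PRE_SUV"],
        "delta_ADC": (truth_df["INTRA_ADC"] - truth_df["PRE_ADC"]) / truth_df["PRE_ADC"],
        "delta_SUV": (truth_df["INTRA_SUV"] - truth_df["PRE_SUV"]) / truth_df["PRE_SUV"],
    })
    coeffs = outcome_coefficients or {"PRE_SUV": 0.2, "delta_ADC": -3.0, "delta_SUV": 2.0}
    outcomes = simulate_outcomes(
        feat, coeffs, seed=int(rng.integers(2**31)), intercept=outcome_intercept,
        horizon_years=spec.event_horizon_years, dropout_rate=spec.dropout_rate,
    )
    # independent outcome draws per endpoint family
    out_df = pd.DataFrame(index=truth_df.index)
    for name, shift in (("LRFFS", 0), ("DMFS", 1), ("OS", 2)):
        oc = simulate_outcomes(feat, coeffs, seed=int(rng.integers(2**31)) ,
                               intercept=outcome_intercept - 0.2 * shift,
                               horizon_years=spec.event_horizon_years,
                               dropout_rate=spec.dropout_rate)
        out_df[f"{name}_time"] = oc["time"]
        out_df[f"{name}_event"] = oc["event"]
    # clinical covariates
    out_df["age"] = rng.normal(62, 8, spec.n_patients).round(1)
    out_df["gender"] = rng.integers(0, 2, spec.n_patients)
    out_df["tobacco"] = rng.integers(0, 2, spec.n_patients)
    out_df["HPV"] = (rng.random(spec.n_patients) < 0.35).astype(int)
    out_df["site"] = rng.integers(0, 2, spec.n_patients)
    out_df["T_stage"] = rng.integers(2, 5, spec.n_patients)
    out_df["N_stage"] = (rng.random(spec.n_patients) < 0.63).astype(int)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        truth_df.to_csv(out_dir / "truth.csv")
        out_df.to_csv(out_dir / "outcomes.csv", index_label="patient_id")
        core_io.save_meta(meta, out_dir / "acquisition.json")
        for tr in truths:
            pseed = int(rng.integers(2**31))
            _write_patient_images(tr, spec, meta, aif, out_dir / tr.patient_id, pseed)
    return truth_df, out_df


def _write_patient_images(tr: TruthRecord, spec: CohortSpec, meta: AcquisitionMeta,
                          aif: PopulationAIF, pdir, seed: int) -> None:
    from . import core_io
    pdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    mri_shape, mri_spacing = tuple(spec.mri_grid), tuple(spec.mri_spacing)
    pet_shape, pet_spacing = tuple(spec.pet_grid), (4.0, 4.0, 4.0)
    for tp in ("PRE", "INTRA"):
        p = tr.at_timepoint(tp)
        sub = pdir / tp
        sub.mkdir(exist_ok=True)
        lesion = spherical_mask(mri_shape, tuple(n // 2 for n in mri_shape),
                                min(p["lesion_radius_mm"], spec.max_mri_lesion_radius_mm),
                                mri_spacing)
        # DWI: lesion voxels at the true IVIM parameters, background more diffuse
        nb = len(meta.b_values)
        dwi = np.empty(mri_shape + (nb,))
        dwi[...] = ivim_signal(meta.b_values, 1000.0, 1.8, 25.0, 0.05)
        clean = ivim_signal(meta.b_values, 1000.0, p["D"], p["D_star"], p["f"])
        dwi[lesion] = clean
        dwi = _rician(dwi, spec.dwi_sigma, rng)
        frames = [ImageVolume(dwi[..., i], mri_spacing, timepoint=tp) for i in range(nb)]
        core_io.save_series(DynamicSeries(frames, 1.0, 1, 90.0, 500.0), sub / "dwi.nii.gz")
        # DCE: voxelwise forward Tofts in the lesion, flat elsewhere
        n_frames = spec.n_dce_frames
        dyn, vfa, _ = simulate_dce_series(p, aif, meta, n_frames, 0.0,
                                          int(rng.integers(2**31)))
        bg_dyn = np.full(n_frames, spgr_signal(1000.0, 900.0, meta.tr_ms, meta.flip_angle_deg))
        dce = np.empty(mri_shape + (n_frames,))
        dce[...] = bg_dyn
        dce[lesion] = dyn
        vfa_vol = np.empty(mri_shape + (len(meta.vfa_angles_deg),))
        vfa_vol[...] = spgr_signal(1000.0, 900.0, meta.tr_ms, np.asarray(meta.vfa_angles_deg))
        vfa_vol[lesion] = vfa
        if spec.dce_sigma > 0:
            dce += rng.normal(0, spec.dce_sigma, dce.shape)
            vfa_vol += rng.normal(0, spec.dce_sigma, vfa_vol.shape)
        dce_frames = [ImageVolume(dce[..., i], mri_spacing, timepoint=tp) for i in range(n_frames)]
        core_io.save_series(DynamicSeries(dce_frames, meta.frame_duration_s,
                                          meta.n_baseline_frames, meta.flip_angle_deg,
                                          meta.tr_ms, meta.te_ms), sub / "dce.nii.gz")
        vfa_frames = [ImageVolume(vfa_vol[..., i], mri_spacing, timepoint=tp)
                      for i in range(len(meta.vfa_angles_deg))]
        core_io.save_series(DynamicSeries(vfa_frames, 1.0, 1, 90.0, meta.tr_ms), sub / "vfa.nii.gz")
        # PET
        pet, pet_mask = simulate_pet_volume(p | {"background_SUV": tr.background_SUV},
                                            pet_shape, pet_spacing, spec.pet_sigma,
                                            int(rng.integers(2**31)),
                                            spec.pet_smoothing_fwhm_mm)
        core_io.save_volume(pet, sub / "pet_suv.nii.gz")
        core_io.save_mask(ROIMask(pet_mask.mask), pet_spacing, sub / "pet_seed.nii.gz")
        # observer masks on the MRI grid
        obs1 = ROIMask(lesion, observer_id=1)
        obs2 = perturb_roi(obs1, magnitude=1, seed=int(rng.integers(2**31)))
        core_io.save_mask(obs1, mri_spacing, sub / "roi_obs1.nii.gz")
        core_io.save_mask(obs2, mri_spacing, sub / "roi_obs2.nii.gz")
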