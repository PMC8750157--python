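"""End-to-end orchestration: simulate -> fit -> features -> models -> stratify.

Every stage reads/writes plain files under one output directory so stages can
also be run individually from the command line.  A resolved copy of the
configuration (with the seed and package version) is written next to the
outputs of every run for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, dce, dwi, features, models, pet, risk, synthetic
from .core_io import AcquisitionMeta, ROIMask
from .dce import PopulationAIF

log = logging.getLogger("mpfi")

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {"n_patients": 12, "dwi_sigma": 20.0, "dce_sigma": 0.0, "pet_sigma": 0.2,
               "max_mri_lesion_radius_mm": 5.0},
    "models": {"repeats": 5, "folds": 5, "metrics": ["AUC"]},
    "stratify": {"calculator": "LRFFS", "mode": "fixed"},
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _write_resolved_config(cfg: dict, out_dir: Path) -> None:
    from . import __version__

    resolved = dict(cfg)
    resolved["package_version"] = __version__
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))


def stage_simulate(cfg: dict, out_dir: Path) -> Path:
    spec = synthetic.CohortSpec(seed=cfg["seed"], **{
        k: tuple(v) if isinstance(v, list) else v for k, v in cfg.get("cohort", {}).items()
    })
    cohort_dir = out_dir / "cohort"
    log.info("simulate: %d patients -> %s", spec.n_patients, cohort_dir)
    synthetic.generate_cohort(spec, cohort_dir)
    return cohort_dir


def _dwi_features_for_observer(maps: dict, mask: ROIMask, spacing) -> dict:
    vals_adc = maps["ADC"][mask.mask & (maps["status"] == 1)]
    hist = dwi.histogram_features(vals_adc)
    out = {
        "ADC_GTV": core_io.roi_volume_ml(mask, spacing),
        "ADC_median": hist.median,
        "ADC_skewness": hist.skewness,
        "ADC_kurtosis": hist.kurtosis,
    }
    for key, name in (("D", "D"), ("D_star", "D_star"), ("f", "f")):
        v = maps[key][mask.mask & (maps["status"] == 1)]
        out[name] = float(np.nanmedian(v))
    return out


def _dce_features_for_observer(maps: dict, mask: ROIMask, spacing) -> tuple[dict, bool]:
    roi_status = maps["status"][mask.mask]
    fraction, excluded = dce.scan_fit_failure_rate(roi_status)
    ok = mask.mask & (maps["status"] == 1)
    out = {"DCE_GTV": core_io.roi_volume_ml(mask, spacing)}
    for key in ("Ktrans", "ve", "kep"):
        v = maps[key][ok]
        out[key] = float(np.nanmedian(v)) if v.size else float("nan")
    return out, excluded


def extract_patient_timepoint(tp_dir: Path, meta: AcquisitionMeta) -> dict:
    """The 15 observer-averaged imaging features for one patient timepoint."""
    dwi_frames = core_io.load_volume(tp_dir / "dwi.nii.gz", kind="dynamic")
    spacing = dwi_frames[0].spacing
    obs1 = core_io.load_mask(tp_dir / "roi_obs1.nii.gz", observer_id=1)
    obs2 = core_io.load_mask(tp_dir / "roi_obs2.nii.gz", observer_id=2)
    union = ROIMask(obs1.mask | obs2.mask)

    dwi_series = np.stack([f.voxels for f in dwi_frames], axis=-1)
    dwi_maps = dwi.fit_ivim_volume(dwi_series, meta.b_values, union.mask)

    vfa_frames = core_io.load_volume(tp_dir / "vfa.nii.gz", kind="dynamic")
    dce_frames = core_io.load_volume(tp_dir / "dce.nii.gz", kind="dynamic")
    dce_arr = np.stack([f.voxels for f in dce_frames], axis=-1)
    vfa_arr = np.stack([f.voxels for f in vfa_frames], axis=-1)
    times = np.arange(dce_arr.shape[-1]) * meta.frame_duration_s
    aif = PopulationAIF(bolus_arrival_s=meta.n_baseline_frames * meta.frame_duration_s)

    conc = np.full(dce_arr.shape, np.nan)
    t1_status = np.zeros(dce_arr.shape[:3], dtype=np.int8)
    for idx in np.argwhere(union.mask):
        i, j, k = idx
        t1fit = dce.fit_t1_vfa(vfa_arr[i, j, k, :], meta.vfa_angles_deg, meta.tr_ms)
        if t1fit.status != "ok":
            continue
        t1_status[i, j, k] = 1
        conc[i, j, k, :] = dce.signal_to_concentration(
            dce_arr[i, j, k, :], t1fit, meta.tr_ms, meta.flip_angle_deg,
            meta.relaxivity_r1, meta.n_baseline_frames)
    tofts_maps = dce.fit_tofts_volume(conc, aif, times, union.mask & (t1_status == 1))

    pet_vol = core_io.load_volume(tp_dir / "pet_suv.nii.gz")
    pet_seed = core_io.load_mask(tp_dir / "pet_seed.nii.gz")
    _, lesion_metrics = pet.matv_segment(pet_vol, pet_seed)

    feats: dict = {}
    per_obs = [
        _dwi_features_for_observer(dwi_maps, m, spacing) for m in (obs1, obs2)
    ]
    for name in ("ADC_GTV", "ADC_median", "ADC_skewness", "ADC_kurtosis", "D", "D_star", "f"):
        feats[name], _ = features.observer_average(per_obs[0][name], per_obs[1][name])
    dce_obs, excl = [], []
    for m in (obs1, obs2):
        d, ex = _dce_features_for_observer(tofts_maps, m, spacing)
        dce_obs.append(d)
        excl.append(ex)
    for name in ("DCE_GTV", "Ktrans", "ve", "kep"):
        feats[name], _ = features.observer_average(dce_obs[0][name], dce_obs[1][name])
    feats["dce_excluded"] = bool(any(excl))
    feats["MATV"] = lesion_metrics.MATV_ml
    feats["SUV_mean"] = lesion_metrics.SUV_mean
    feats["SUV_peak"] = lesion_metrics.SUV_peak
    feats["TLG"] = lesion_metrics.TLG
    return feats


def stage_features(cohort_dir: Path, out_dir: Path) -> pd.DataFrame:
    meta = core_io.load_meta(cohort_dir / "acquisition.json")
    outcomes = pd.read_csv(cohort_dir / "outcomes.csv", index_col="patient_id")
    per_patient = {}
    for pdir in sorted(d for d in cohort_dir.iterdir() if d.is_dir()):
        pid = pdir.name
        log.info("features: %s", pid)
        per_patient[pid] = {}
        for tp in ("PRE", "INTRA"):
            f = extract_patient_timepoint(pdir / tp, meta)
            f.pop("dce_excluded", None)
            per_patient[pid][tp] = f
    clinical = outcomes[list(features.CLINICAL_FEATURES)]
    table = features.assemble_feature_table(per_patient, clinical)
    table.to_csv(out_dir / "features.csv")
    return table


def stage_models(table: pd.DataFrame, outcomes: pd.DataFrame, cfg: dict, out_dir: Path) -> pd.DataFrame:
    mc = cfg.get("models", {})
    grid = models.run_model_grid(
        table[features.feature_columns() + [c for c in features.CLINICAL_FEATURES
                                            if c in table.columns]],
        outcomes, repeats=mc.get("repeats", 5), folds=mc.get("folds", 5),
        seed=cfg["seed"], metrics=tuple(mc.get("metrics", ["AUC"])),
    )
    grid.to_csv(out_dir / "model_grid.csv", index=False)
    return grid


def stage_stratify(table: pd.DataFrame, outcomes: pd.DataFrame, cfg: dict, out_dir: Path) -> dict:
    sc = cfg.get("stratify", {})
    calc = risk.CALCULATORS[sc.get("calculator", "LRFFS")]
    probs = risk.apply_calculator(calc, table)
    groups = risk.stratify(probs, mode=sc.get("mode", "fixed"))
    out = pd.DataFrame({"probability": groups.probability, "group": groups.group})
    out.to_csv(out_dir / "risk_groups.csv", index_label="patient_id")
    t = outcomes[f"{calc.name}_time"]
    e = outcomes[f"{calc.name}_event"]
    curves = risk.km_estimator(t, e, groups.group)
    for g, df in curves.items():
        df.to_csv(out_dir / f"km_{g}.csv", index=False)
    report = {"calculator": calc.name, "cut_points": list(groups.cut_points),
              "group_sizes": groups.group.value_counts().to_dict()}
    if groups.group.nunique() >= 2 and e.sum() >= 1:
        chi2, p = risk.log_rank(t, e, groups.group)
        report.update(log_rank_chi2=chi2, log_rank_p=p)
    (out_dir / "stratification.json").write_text(json.dumps(report, indent=2))
    return report


def run_pipeline(config: dict | str | Path | None = None, out_dir: str | Path = "mpfi_run") -> Path:
    """Run the full pipeline under one seed; returns the report directory."""
    cfg = config if isinstance(config, dict) else load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    _write_resolved_config(cfg, out_dir)
    try:
        cohort_dir = stage_simulate(cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[simulate] stage failed: {exc}") from exc
    try:
        table = stage_features(cohort_dir, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[features] stage failed: {exc}") from exc
    outcomes = pd.read_csv(cohort_dir / "outcomes.csv", index_col="patient_id")
    try:
        stage_models(table, outcomes, cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[models] stage failed: {exc}") from exc
    try:
        stage_stratify(table, outcomes, cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"[stratify] stage failed: {exc}") from exc
    return out_dir
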