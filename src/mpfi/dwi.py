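"""ADC and IVIM (intravoxel incoherent motion) fitting, plus ROI histogram features.

The bi-exponential IVIM signal model is

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

with tissue diffusion coefficient D, pseudo-diffusion coefficient D* (capillary
perfusion, D* >= D) and perfusion fraction f in [0, 1].  Diffusion coefficients
are carried in units of 1e-3 mm^2/s throughout; b-values in s/mm^2.

Fitting is segmented, the standard stabilisation: D and the high-b intercept
come from a log-linear fit over b >= ``b_split`` (default 300 s/mm^2, the gap
in the 10-step b ladder), f from the intercept ratio, and D* from a bounded
one-parameter nonlinear fit with D and f held fixed.  A joint 4-parameter fit
is available behind ``method="joint"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "IvimFit",
    "HistogramFeatures",
    "ivim_signal",
    "fit_adc",
    "fit_ivim",
    "fit_ivim_volume",
    "histogram_features",
]

# bounds in 1e-3 mm^2/s
D_MAX = 4.0
D_STAR_MAX = 500.0
B_SPLIT_DEFAULT = 300.0


@dataclass
class IvimFit:
    """Voxelwise IVIM parameter estimates."""

    D: float  # 1e-3 mm^2/s
    D_star: float  # 1e-3 mm^2/s
    f: float
    S0: float
    status: str = "ok"  # ok | failed


@dataclass
class HistogramFeatures:
    """ROI distribution summary: median, skewness and Pearson kurtosis."""

    median: float
    skewness: float
    kurtosis: float
    n_voxels: int


def ivim_signal(b_values, S0, D, D_star, f):
    """Noiseless bi-exponential IVIM signal (D, D* in 1e-3 mm^2/s)."""
    b = np.asarray(b_values, dtype=float)
    if D < 0 or D_star < 0 or S0 < 0:
        raise ValueError("IVIM parameters must be nonnegative")
    if not 0 <= f <= 1:
        raise ValueError(f"perfusion fraction must be in [0, 1], got {f}")
    return S0 * (f * np.exp(-b * D_star * 1e-3) + (1 - f) * np.exp(-b * D * 1e-3))


def fit_adc(signals, b_values) -> tuple[float, float]:
    """Mono-exponential ADC by ordinary least squares on log signals.

    Returns ``(ADC, S0)`` with ADC in 1e-3 mm^2/s: ADC is minus the slope of
    ln S against b.  Requires at least two positive signals at distinct
    b-values; non-positive signals raise (callers flag the voxel failed).
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signals and b_values must align")
    if np.any(s <= 0):
        raise ValueError("non-positive signal; voxel cannot be log-fit")
    if len(np.unique(b)) < 2:
        raise ValueError("need >= 2 distinct b-values")
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return float(-slope * 1e3), float(np.exp(intercept))


def _segmented_ivim(s: np.ndarray, b: np.ndarray, b_split: float) -> IvimFit:
    high = b >= b_split
    if high.sum() < 2:
        raise ValueError(f"need >= 2 b-values at b >= {b_split}")
    # tissue compartment from the perfusion-free high-b regime
    D, S0_high = fit_adc(s[high], b[high])
    D = min(max(D, 0.0), D_MAX)
    S0_all = float(s[b == 0][0]) if np.any(b == 0) else float(np.exp(np.polyfit(b, np.log(s), 1)[1]))
    f = 1.0 - S0_high / S0_all
    f = min(max(f, 0.0), 1.0)
    if f < 1e-12:
        # mono-exponential voxel: D* unidentifiable, report the lower bound
        return IvimFit(D=D, D_star=D, f=0.0, S0=S0_all, status="ok")

    def resid(d_star):
        return ivim_signal(b, S0_all, D, d_star[0], f) - s

    try:
        sol = optimize.least_squares(
            resid, x0=[max(10.0, 2 * D)], bounds=([D], [D_STAR_MAX]), method="trf"
        )
        if not sol.success:
            return IvimFit(D=D, D_star=np.nan, f=f, S0=S0_all, status="failed")
        return IvimFit(D=D, D_star=float(sol.x[0]), f=f, S0=S0_all, status="ok")
    except ValueError:
        return IvimFit(D=D, D_star=np.nan, f=f, S0=S0_all, status="failed")


def _joint_ivim(s: np.ndarray, b: np.ndarray, init: IvimFit) -> IvimFit:
    def resid(p):
        S0, D, d_star, f = p
        return S0 * (f * np.exp(-b * d_star * 1e-3) + (1 - f) * np.exp(-b * D * 1e-3)) - s

    x0 = [init.S0, init.D, init.D_star if np.isfinite(init.D_star) else 10.0, init.f]
    lo = [0.0, 0.0, 0.0, 0.0]
    hi = [np.inf, D_MAX, D_STAR_MAX, 1.0]
    x0 = np.clip(x0, lo, hi)
    sol = optimize.least_squares(resid, x0=x0, bounds=(lo, hi), method="trf")
    if not sol.success:
        return IvimFit(D=init.D, D_star=np.nan, f=init.f, S0=init.S0, status="failed")
    S0, D, d_star, f = sol.x
    return IvimFit(D=float(D), D_star=float(d_star), f=float(f), S0=float(S0), status="ok")


def fit_ivim(signals, b_values, b_split: float = B_SPLIT_DEFAULT, method: str = "segmented") -> IvimFit:
    """Fit the bi-exponential IVIM model to one voxel's multi-b signal.

    Optimiser failure is reported as ``status="failed"``, not an exception,
    so voxelwise map fitting can proceed and downstream exclusion rules can
    count failures.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signals and b_values must align")
    if np.any(s < 0):
        raise ValueError("negative signals are not magnitude data")
    if np.any(s == 0):
        return IvimFit(D=np.nan, D_star=np.nan, f=np.nan, S0=np.nan, status="failed")
    fit = _segmented_ivim(s, b, b_split)
    if method == "joint" and fit.status == "ok":
        fit = _joint_ivim(s, b, fit)
    elif method not in ("segmented", "joint"):
        raise ValueError(f"unknown method {method!r}")
    return fit


def fit_ivim_volume(series: np.ndarray, b_values, mask: np.ndarray | None = None,
                    b_split: float = B_SPLIT_DEFAULT):
    """Voxelwise IVIM maps over a 4-D (x, y, z, b) series.

    Returns a dict of 3-D maps ``{"ADC", "D", "D_star", "f", "status"}``
    where ``status`` is 1 for ok voxels and 0 for failed/outside-mask.
    """
    series = np.asarray(series, dtype=float)
    shape = series.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    maps = {k: np.full(shape, np.nan) for k in ("ADC", "D", "D_star", "f")}
    status = np.zeros(shape, dtype=np.int8)
    for idx in np.argwhere(mask):
        i, j, k = idx
        sig = series[i, j, k, :]
        try:
            adc, _ = fit_adc(sig, b_values)
            fit = fit_ivim(sig, b_values, b_split=b_split)
        except ValueError:
            continue
        if fit.status != "ok":
            continue
        maps["ADC"][i, j, k] = adc
        maps["D"][i, j, k] = fit.D
        maps["D_star"][i, j, k] = fit.D_star
        maps["f"][i, j, k] = fit.f
        status[i, j, k] = 1
    maps["status"] = status
    return maps


def histogram_features(values, kurtosis_convention: str = "pearson") -> HistogramFeatures:
    """Median, skewness and kurtosis of an ROI value sample.

    Skewness is m3 / m2^1.5 and kurtosis m4 / m2^2 over central moments
    (Pearson convention: a normal sample tends to 3).  ``"excess"`` subtracts
    3.  Zero-variance samples get NaN shape statistics; the median is still
    returned.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for histogram features")
    med = float(np.median(v))
    m2 = float(np.mean((v - v.mean()) ** 2))
    if m2 == 0:
        return HistogramFeatures(median=med, skewness=np.nan, kurtosis=np.nan, n_voxels=v.size)
    m3 = float(np.mean((v - v.mean()) ** 3))
    m4 = float(np.mean((v - v.mean()) ** 4))
    skew = m3 / m2**1.5
    kurt = m4 / m2**2
    if kurtosis_convention == "excess":
        kurt -= 3.0
    elif kurtosis_convention != "pearson":
        raise ValueError(f"unknown kurtosis convention {kurtosis_convention!r}")
    return HistogramFeatures(median=med, skewness=skew, kurtosis=kurt, n_voxels=v.size)
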