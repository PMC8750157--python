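"""FDG-PET lesion metrics: SUV scaling, SUVpeak, background-corrected MATV, TLG.

SUVpeak follows the 1 mL spherical VOI definition: among candidate sphere
centres, the maximum mean SUV over voxels whose centres lie within the radius
of an exactly-1 mL sphere (6.2035 mm).  The metabolically active tumour volume
(MATV) is segmented at the local-background-corrected 50% SUVpeak threshold

    T = 0.5 * (SUVpeak - BG) + BG,

taking the 26-connected component above T that contains the peak-sphere
centre.  TLG = SUVmean * MATV by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import ImageVolume, ROIMask

__all__ = [
    "LesionMetrics",
    "SPHERE_RADIUS_MM",
    "suv_scale",
    "sphere_offsets",
    "suv_peak",
    "local_background",
    "matv_segment",
]

# radius of a 1 mL (1000 mm^3) sphere
SPHERE_RADIUS_MM = (3 * 1000.0 / (4 * np.pi)) ** (1.0 / 3.0)  # 6.2035 mm


@dataclass
class LesionMetrics:
    MATV_ml: float
    SUV_mean: float
    SUV_peak: float
    TLG: float  # SUV * mL
    background_SUV: float
    n_voxels: int


def suv_scale(activity: ImageVolume, injected_dose_MBq: float, body_weight_kg: float) -> ImageVolume:
    """Scale a decay-corrected activity-concentration volume (Bq/mL) to SUV.

    SUV = concentration / (injected dose / body weight); a voxel at exactly
    dose/weight concentration maps to SUV 1 (body weight taken at 1 g/mL).
    """
    if injected_dose_MBq <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    factor = (injected_dose_MBq * 1e6) / (body_weight_kg * 1000.0)  # Bq/mL per SUV unit
    return ImageVolume(
        voxels=activity.voxels / factor,
        spacing=activity.spacing,
        origin=activity.origin,
        timepoint=activity.timepoint,
    )


def sphere_offsets(spacing, radius_mm: float = SPHERE_RADIUS_MM) -> np.ndarray:
    """Integer voxel offsets whose centres fall within ``radius_mm`` of a centre."""
    spacing = np.asarray(spacing, dtype=float)
    if np.prod(spacing) > 4 / 3 * np.pi * radius_mm**3:
        raise ValueError(
            f"sphere of radius {radius_mm} mm contains no voxel centres beyond its own "
            f"at spacing {spacing} (voxel larger than the sphere)")
    half = np.floor(radius_mm / spacing).astype(int)
    rng = [np.arange(-h, h + 1) for h in half]
    ii, jj, kk = np.meshgrid(*rng, indexing="ij")
    d2 = (ii * spacing[0]) ** 2 + (jj * spacing[1]) ** 2 + (kk * spacing[2]) ** 2
    sel = d2 <= radius_mm**2
    offs = np.stack([ii[sel], jj[sel], kk[sel]], axis=1)
    if offs.shape[0] == 0:
        raise ValueError(f"sphere of radius {radius_mm} mm contains no voxel centres at spacing {spacing}")
    return offs


def suv_peak(volume: ImageVolume, search: ROIMask | np.ndarray,
             radius_mm: float = SPHERE_RADIUS_MM) -> tuple[float, tuple[int, int, int]]:
    """Maximum 1 mL-sphere mean SUV over candidate centres in ``search``.

    The sphere is discretised by voxel-centre inclusion; voxels outside the
    grid are simply absent from the mean.  Ties are broken by lexicographic
    centre index so the result is deterministic.
    """
    region = search.mask if isinstance(search, ROIMask) else np.asarray(search, dtype=bool)
    if region.shape != volume.shape:
        raise ValueError("search region must share the volume grid")
    centers = np.argwhere(region)
    if centers.shape[0] == 0:
        raise ValueError("empty search region")
    offs = sphere_offsets(volume.spacing, radius_mm)
    shape = np.asarray(volume.shape)
    best_val, best_center = -np.inf, None
    for c in centers:  # argwhere is already lexicographic
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        val = float(volume.voxels[pts[:, 0], pts[:, 1], pts[:, 2]].mean())
        if val > best_val + 1e-15:
            best_val, best_center = val, tuple(int(x) for x in c)
    return best_val, best_center


def local_background(volume: ImageVolume, lesion: ROIMask | np.ndarray,
                     gap_voxels: int = 1, shell_voxels: int = 2) -> float:
    """Mean SUV over a shell around the lesion.

    The shell is ``shell_voxels`` thick and starts ``gap_voxels`` outside the
    lesion boundary, so partial-volume voxels at the edge are skipped.
    """
    les = lesion.mask if isinstance(lesion, ROIMask) else np.asarray(lesion, dtype=bool)
    if les.shape != volume.shape:
        raise ValueError("lesion mask must share the volume grid")
    if not les.any():
        raise ValueError("empty lesion mask")
    struct = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    inner = ndimage.binary_dilation(les, structure=struct, iterations=gap_voxels)
    outer = ndimage.binary_dilation(inner, structure=struct, iterations=shell_voxels)
    shell = outer & ~inner
    if not shell.any():
        raise ValueError("background shell does not fit in the grid")
    return float(volume.voxels[shell].mean())


def matv_segment(volume: ImageVolume, seed_region: ROIMask | np.ndarray,
                 radius_mm: float = SPHERE_RADIUS_MM,
                 gap_voxels: int = 1, shell_voxels: int = 2) -> tuple[ROIMask, LesionMetrics]:
    """Background-corrected 50%-SUVpeak lesion segmentation and metrics.

    Steps: SUVpeak within the seed region; local background from a shell
    around the seed; threshold T = 0.5*(SUVpeak - BG) + BG; keep the
    26-connected component above T containing the peak-sphere centre.
    """
    peak, center = suv_peak(volume, seed_region, radius_mm)
    bg = local_background(volume, seed_region, gap_voxels, shell_voxels)
    if peak <= bg:
        raise ValueError(f"SUVpeak ({peak:.3g}) must exceed background ({bg:.3g})")
    threshold = 0.5 * (peak - bg) + bg
    above = volume.voxels >= threshold
    if not above.any():
        raise ValueError("no voxels above segmentation threshold")
    struct = ndimage.generate_binary_structure(3, 3)
    labels, _ = ndimage.label(above, structure=struct)
    lab = labels[center]
    if lab == 0:
        # peak centre itself below threshold (very heterogeneous lesion):
        # fall back to the component nearest the centre within the seed
        seed = seed_region.mask if isinstance(seed_region, ROIMask) else np.asarray(seed_region, bool)
        cand = np.unique(labels[seed & above])
        cand = cand[cand > 0]
        if cand.size == 0:
            raise ValueError("no above-threshold component overlaps the seed region")
        lab = int(cand[0])
    mask = labels == lab
    n = int(mask.sum())
    matv = n * volume.voxel_volume_mm3 / 1000.0
    suv_mean = float(volume.voxels[mask].mean())
    metrics = LesionMetrics(
        MATV_ml=matv,
        SUV_mean=suv_mean,
        SUV_peak=peak,
        TLG=suv_mean * matv,
        background_SUV=bg,
        n_voxels=n,
    )
    return ROIMask(mask=mask, lesion_id="matv"), metrics
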