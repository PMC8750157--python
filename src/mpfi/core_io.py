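"""Containers and I/O for volumes, masks, acquisition metadata and cohort tables.

Volumes live on regular 3-D voxel grids with millimetre spacing.  Masks must
share the grid of the volume they index: no cross-modality resampling is
performed anywhere in the package — features are computed on each modality's
native grid, mirroring per-modality delineation practice.

NIfTI (via nibabel) is the on-disk format for volumes, masks and 4-D dynamic
series.  Acquisition physics that NIfTI headers cannot hold (b-values, flip
angles, dynamic timing, tracer dose) travels in a JSON sidecar next to each
image, modelled by :class:`AcquisitionMeta`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "DynamicSeries",
    "ROIMask",
    "AcquisitionMeta",
    "load_volume",
    "save_volume",
    "load_mask",
    "extract_roi_values",
    "roi_volume_ml",
    "load_meta",
    "save_meta",
    "load_cohort_table",
]


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    voxels
        3-D array of voxel values (modality-specific units).
    spacing
        Voxel edge lengths in mm, one per axis.
    origin
        Position of voxel (0, 0, 0) in mm.
    timepoint
        Optional label, ``"PRE"`` or ``"INTRA"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.voxels.ndim}")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError("grid must have at least one voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if self.timepoint is not None and self.timepoint not in ("PRE", "INTRA"):
            raise ValueError(f"timepoint must be PRE or INTRA, got {self.timepoint!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DynamicSeries:
    """A time-ordered stack of :class:`ImageVolume` frames on one grid."""

    frames: list[ImageVolume]
    frame_duration_s: float
    n_baseline_frames: int
    flip_angle_deg: float
    tr_ms: float
    te_ms: float = 0.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("dynamic series needs at least one frame")
        shape0 = self.frames[0].shape
        if any(f.shape != shape0 for f in self.frames):
            raise ValueError("all frames must share one grid")
        if self.frame_duration_s <= 0:
            raise ValueError("frame_duration_s must be positive")
        if self.n_baseline_frames < 1:
            raise ValueError("need at least one baseline frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        """Frame mid-acquisition times, starting at 0."""
        return np.arange(self.n_frames) * self.frame_duration_s

    def as_array(self) -> np.ndarray:
        """(x, y, z, t) array of the whole series."""
        return np.stack([f.voxels for f in self.frames], axis=-1)


@dataclass
class ROIMask:
    """Binary lesion mask aligned to an :class:`ImageVolume` grid."""

    mask: np.ndarray
    observer_id: int = 1
    lesion_id: str = "primary"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={self.mask.ndim}")
        if self.observer_id not in (1, 2):
            raise ValueError("observer_id must be 1 or 2")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class AcquisitionMeta:
    """Physics parameters the fitting forward models need.

    Defaults reflect a 3 T head-and-neck protocol: a 10-step b-value ladder
    for DWI/IVIM, a 5-angle variable-flip-angle T1 pre-scan, a 12 deg dynamic
    flip angle with TR/TE = 4.8/2.4 ms and 4.16 s frames, and a weight-scaled
    FDG dose of 2.5 MBq/kg.
    """

    b_values: tuple[float, ...] = (0, 10, 25, 50, 75, 150, 300, 500, 750, 1000)
    vfa_angles_deg: tuple[float, ...] = (2, 5, 10, 15, 20)
    flip_angle_deg: float = 12.0
    tr_ms: float = 4.8
    te_ms: float = 2.4
    frame_duration_s: float = 4.16
    n_baseline_frames: int = 3
    injected_dose_MBq: float = 175.0
    body_weight_kg: float = 70.0
    relaxivity_r1: float = 3.5  # L mmol^-1 s^-1, Gd-DOTA at 3 T

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b_values)
        if len(b) < 2 or b[0] != 0 or any(x < 0 for x in b) or any(
            b[i] >= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError("b_values must be nonnegative, strictly increasing and include 0")
        self.b_values = b
        a = tuple(float(x) for x in self.vfa_angles_deg)
        if len(set(a)) != len(a) or any(not 0 < x < 90 for x in a):
            raise ValueError("vfa angles must be distinct and in (0, 90) degrees")
        self.vfa_angles_deg = a

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        return cls(**json.loads(Path(path).read_text()))


def save_meta(meta: AcquisitionMeta, path: str | Path) -> None:
    meta.to_json(path)


def load_meta(path: str | Path) -> AcquisitionMeta:
    return AcquisitionMeta.from_json(path)


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def save_series(series: DynamicSeries, path: str | Path) -> None:
    """Write a dynamic series as a 4-D NIfTI (x, y, z, t)."""
    f0 = series.frames[0]
    img = nib.Nifti1Image(series.as_array().astype(np.float64), _affine(f0.spacing, f0.origin))
    nib.save(img, str(path))


def save_mask(mask: ROIMask, spacing: Sequence[float], path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(spacing, (0, 0, 0)))
    nib.save(img, str(path))


def load_volume(path: str | Path, kind: str = "volume", timepoint: str | None = None):
    """Read a NIfTI file as an :class:`ImageVolume` or list of frames.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file.
    kind
        ``"volume"`` for 3-D payloads, ``"dynamic"`` for 4-D (returns the list
        of frame volumes; combine with sidecar metadata to build a
        :class:`DynamicSeries`), ``"mask"`` for a binary 3-D payload.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, non-finite voxels, or payload dimensionality that does
        not match ``kind``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite voxel values")
    if kind in ("volume", "mask"):
        if data.ndim != 3:
            raise ValueError(f"{path}: kind={kind!r} needs a 3-D payload, got ndim={data.ndim}")
        if kind == "mask":
            return ROIMask(mask=data > 0.5)
        return ImageVolume(voxels=data, spacing=spacing, origin=origin, timepoint=timepoint)
    if kind == "dynamic":
        if data.ndim != 4:
            raise ValueError(f"{path}: kind='dynamic' needs a 4-D payload, got ndim={data.ndim}")
        return [
            ImageVolume(voxels=data[..., t], spacing=spacing, origin=origin, timepoint=timepoint)
            for t in range(data.shape[3])
        ]
    raise ValueError(f"unknown kind {kind!r}")


def load_mask(path: str | Path, observer_id: int = 1) -> ROIMask:
    m = load_volume(path, kind="mask")
    m.observer_id = observer_id
    return m


def extract_roi_values(volume: ImageVolume, mask: ROIMask) -> np.ndarray:
    """Voxel values of ``volume`` where ``mask`` is set.

    Returned in lexicographic voxel-index order (C order), so the output is
    order-stable across calls and platforms.
    """
    if volume.shape != mask.mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs mask {mask.mask.shape}")
    if mask.n_voxels == 0:
        raise ValueError("empty ROI mask")
    return volume.voxels[mask.mask]  # boolean indexing is C-ordered


def roi_volume_ml(mask: ROIMask, spacing: Sequence[float]) -> float:
    """Volume of the masked region in mL (voxel count x voxel volume)."""
    if mask.n_voxels == 0:
        raise ValueError("empty ROI mask")
    voxel_mm3 = float(np.prod([float(s) for s in spacing]))
    return mask.n_voxels * voxel_mm3 / 1000.0


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a per-patient clinical/outcome CSV keyed by ``patient_id``."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("cohort table must have a patient_id column")
    return df
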