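"""Regional DTI metric extraction from co-registered volumes.

Turns a label volume (the five-region parcellation), metric volumes (FA,
MD, ...) and a binary lesion/microbleed exclusion mask into per-region
mean metrics over normal-appearing tissue.  The masking rules:

1. every region mask is eroded by 1 voxel in all dimensions (full 3×3×3
   26-neighborhood structuring element);
2. the four primarily-white-matter regions (FT, PO, CC, BS) are further
   restricted to voxels with FA strictly > 0.3 to reduce partial-volume
   contamination; BT (grey matter) is not thresholded;
3. voxels inside the exclusion mask (outlined lesions and microbleeds)
   are removed, leaving normal-appearing tissue only.

A helper assigns cerebral white-matter voxels to the nearest cortical
label in physical (mm) distance, supporting anisotropic voxels; ties are
broken deterministically toward the lowest label id.

Inputs are assumed co-registered; NIfTI affines are consulted only for
voxel size, never for reorientation.  All voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .regions import (
    BACKGROUND_LABEL,
    LABEL_TO_REGION,
    REGION_LABELS,
    REGIONS,
    WM_REGIONS,
)

__all__ = [
    "VolumeSet",
    "EmptyRegionError",
    "assign_wm_to_nearest_label",
    "erode_mask",
    "build_region_masks",
    "extract_regional_metrics",
    "load_volume_set",
    "save_volume_set",
]

DEFAULT_FA_THRESHOLD = 0.3

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptyRegionError(ValueError):
    """A region retained no voxels after erosion/thresholding/exclusion."""


@dataclass
class VolumeSet:
    """Co-registered label volume, metric volumes and exclusion mask.

    Attributes
    ----------
    label_volume : int ndarray
        Region labels per voxel (see :data:`ptapls.regions.REGION_LABELS`),
        0 = background.
    metric_volumes : dict of name -> float ndarray
        e.g. ``{"FA": ..., "MD": ...}``; FA unitless in [0, 1], MD in mm²/s.
    exclusion_mask : bool ndarray
        True marks lesion/microbleed voxels to exclude.
    voxel_size : (3,) mm per axis.
    """

    label_volume: np.ndarray
    metric_volumes: dict = field(default_factory=dict)
    exclusion_mask: np.ndarray | None = None
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            lab = np.rint(self.label_volume)
            if not np.allclose(lab, self.label_volume):
                raise ValueError("label volume must contain integer labels")
            self.label_volume = lab.astype(np.int32)
        shape = self.label_volume.shape
        present = set(np.unique(self.label_volume).tolist())
        allowed = set(REGION_LABELS.values()) | {BACKGROUND_LABEL}
        if not present <= allowed:
            raise ValueError(
                f"label volume contains undeclared labels {sorted(present - allowed)}"
            )
        for name, vol in self.metric_volumes.items():
            vol = np.asarray(vol, dtype=float)
            if vol.shape != shape:
                raise ValueError(
                    f"metric volume {name!r} shape {vol.shape} != label shape {shape}"
                )
            if name == "FA":
                finite = vol[np.isfinite(vol)]
                if finite.size and (finite.min() < 0 or finite.max() > 1):
                    raise ValueError("FA values must lie in [0, 1]")
            self.metric_volumes[name] = vol
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(shape, dtype=bool)
        else:
            self.exclusion_mask = np.asarray(self.exclusion_mask).astype(bool)
            if self.exclusion_mask.shape != shape:
                raise ValueError("exclusion mask shape mismatch")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.label_volume.ndim:
            raise ValueError("voxel_size must give one spacing per axis")


def assign_wm_to_nearest_label(
    wm_mask: np.ndarray,
    cortical_labels: np.ndarray,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Propagate cortical labels to white-matter voxels by physical distance.

    Every True voxel of ``wm_mask`` receives the label of the
    Euclidean-nearest labeled voxel (distance in mm via ``voxel_size``);
    voxels outside the mask keep their original value.  Exact distance
    ties go to the lowest label id.
    """
    wm_mask = np.asarray(wm_mask).astype(bool)
    labels = np.asarray(cortical_labels)
    if wm_mask.shape != labels.shape:
        raise ValueError("wm_mask and cortical_labels must share shape")
    ids = sorted(int(v) for v in np.unique(labels) if v != BACKGROUND_LABEL)
    if not ids:
        raise ValueError("cortical_labels contains no labeled voxel")
    best_dist = np.full(labels.shape, np.inf)
    assigned = np.zeros(labels.shape, dtype=labels.dtype)
    for lab in ids:  # ascending: ties keep the lowest id
        dist = ndimage.distance_transform_edt(labels != lab, sampling=voxel_size)
        better = dist < best_dist - 1e-9
        assigned[better] = lab
        best_dist = np.minimum(best_dist, dist)
    out = labels.copy()
    out[wm_mask] = assigned[wm_mask]
    return out


def erode_mask(mask: np.ndarray) -> np.ndarray:
    """Erode a boolean mask by 1 voxel in all dimensions (26-neighborhood).

    A voxel survives iff its full 3×3×3 neighborhood lies inside the
    mask; voxels beyond the grid border count as outside.
    """
    mask = np.asarray(mask).astype(bool)
    return ndimage.binary_erosion(mask, structure=_STRUCT_26, border_value=0)


def build_region_masks(
    volumes: VolumeSet,
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
    erode: bool = True,
) -> dict[str, np.ndarray]:
    """Final per-region analysis masks after erosion, FA threshold, exclusion.

    Order of operations: erode the label mask, then (WM regions only) keep
    voxels with FA strictly above ``fa_threshold``, then remove exclusion
    voxels.  Non-finite FA voxels never pass the threshold.  Empty regions
    are returned as all-False masks; downstream averaging refuses them.
    """
    if any(r in WM_REGIONS for r in REGIONS) and "FA" not in volumes.metric_volumes:
        raise ValueError("an FA volume is required to threshold the WM regions")
    fa = volumes.metric_volumes.get("FA")
    masks: dict[str, np.ndarray] = {}
    for region in REGIONS:
        m = volumes.label_volume == REGION_LABELS[region]
        if erode:
            m = erode_mask(m)
        if region in WM_REGIONS:
            with np.errstate(invalid="ignore"):
                m = m & np.isfinite(fa) & (fa > fa_threshold)
        m = m & ~volumes.exclusion_mask
        masks[region] = m
    return masks


def extract_regional_metrics(
    volumes: VolumeSet,
    metrics: Sequence[str] | None = None,
    subject_id: str = "subject",
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
    erode: bool = True,
) -> pd.DataFrame:
    """Per-region mean of each metric over the final analysis masks.

    Returns a long table with columns ``subject, region, metric, mean,
    n_voxels``.  Non-finite metric voxels are dropped from both the mean
    and the count.

    Raises
    ------
    EmptyRegionError
        Naming the first region with no contributing voxels — an empty
        region is never silently reported as zero.
    """
    if metrics is None:
        metrics = list(volumes.metric_volumes)
    for name in metrics:
        if name not in volumes.metric_volumes:
            raise KeyError(f"metric volume {name!r} not present")
    masks = build_region_masks(volumes, fa_threshold=fa_threshold, erode=erode)
    rows = []
    for region in REGIONS:
        m = masks[region]
        for name in metrics:
            vol = volumes.metric_volumes[name]
            vals = vol[m]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise EmptyRegionError(
                    f"region {region} has no voxels left for metric {name!r} "
                    f"after erosion/thresholding/exclusion"
                )
            rows.append(
                {
                    "subject": subject_id,
                    "region": region,
                    "metric": name,
                    "mean": float(vals.mean()),
                    "n_voxels": int(vals.size),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "region", "metric", "mean", "n_voxels"])


def _read_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), zooms


def load_volume_set(
    labels_path,
    metric_paths: Mapping[str, str],
    exclusion_path=None,
) -> VolumeSet:
    """Assemble a :class:`VolumeSet` from NIfTI files (voxel size from header)."""
    labels, zooms = _read_nifti(labels_path)
    metrics = {}
    for name, p in metric_paths.items():
        vol, z = _read_nifti(p)
        if not np.allclose(z, zooms):
            raise ValueError(f"voxel size of {name!r} ({z}) differs from labels ({zooms})")
        metrics[name] = np.asarray(vol, dtype=float)
    excl = None
    if exclusion_path is not None:
        excl, _ = _read_nifti(exclusion_path)
        excl = np.asarray(excl) > 0
    return VolumeSet(
        label_volume=np.asarray(labels),
        metric_volumes=metrics,
        exclusion_mask=excl,
        voxel_size=zooms,
    )


def save_volume_set(volumes: VolumeSet, out_dir) -> dict[str, Path]:
    """Write a :class:`VolumeSet` as NIfTI-1 files; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volumes.voxel_size) + [1.0])
    paths = {}

    def _save(name, data, dtype):
        path = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(path))
        paths[name] = path

    _save("labels", volumes.label_volume, np.int16)
    for mname, vol in volumes.metric_volumes.items():
        _save(mname, vol, np.float32)
    _save("exclusion", volumes.exclusion_mask, np.uint8)
    return paths
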