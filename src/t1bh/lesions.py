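"""Mask algebra, connected-component lesion labeling and per-ROI T1 statistics.

All volumes of one patient live on a single voxel grid; physical lesion
volumes are derived from the NIfTI header spacing (mm), with no
partial-volume weighting — a lesion's volume is its whole-voxel count times
the voxel volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "Volume",
    "LesionClass",
    "GridMismatchError",
    "load_volume",
    "load_mask",
    "save_volume",
    "consensus_mask",
    "pure_flair_mask",
    "label_components",
    "lesion_stats",
    "cortex_stats",
    "dice",
    "pooled_dice",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class LesionClass(str, Enum):
    """Lesion taxonomy.

    ``BH_vis`` — visually marked black holes (T1-hypointense, below-cortex
    intensity); ``CE`` — contrast-enhancing lesions; ``total_FLAIR`` — all
    FLAIR-hyperintense lesions; ``pure_FLAIR`` — FLAIR lesions that are
    neither black holes nor contrast-enhancing.  By construction
    ``pure_FLAIR``, ``BH_vis`` and ``CE`` are pairwise disjoint subsets of
    ``total_FLAIR``.
    """

    BH_VIS = "BH_vis"
    CE = "CE"
    TOTAL_FLAIR = "total_FLAIR"
    PURE_FLAIR = "pure_FLAIR"


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice shared by all of one patient's volumes."""

    shape: tuple[int, ...]
    voxel_size_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"non-positive grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"non-positive voxel spacing {self.voxel_size_mm}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def matches(self, other: "VolumeGrid", rtol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm, rtol=rtol
        )

    @classmethod
    def from_image(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(int(s) for s in img.shape[:3]), tuple(float(z) for z in zooms))


@dataclass
class Volume:
    """A scalar or binary volume together with its grid and affine."""

    data: np.ndarray
    grid: VolumeGrid
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )


def _check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise GridMismatchError(f"volumes on different grids: shapes {sorted(shapes)}")


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return Volume(data, VolumeGrid.from_image(img), np.asarray(img.affine))


def load_mask(path: str | Path) -> Volume:
    """Read a mask, binarizing at > 0; reports non-{0,1} values."""
    vol = load_volume(path)
    vals = np.unique(vol.data)
    if not set(np.round(vals, 6)).issubset({0.0, 1.0}):
        warnings.warn(
            f"mask {path} contains non-binary values {vals[:8]}; binarizing at > 0",
            stacklevel=2,
        )
    vol.data = vol.data > 0
    return vol


def save_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write NIfTI-1 with a diagonal affine built from the grid spacing."""
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def consensus_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Two-rater consensus: voxel-wise AND of the binarized masks."""
    _check_same_shape(mask_a, mask_b)
    return (mask_a > 0) & (mask_b > 0)


def pure_flair_mask(
    total: np.ndarray, bh: np.ndarray, ce: np.ndarray
) -> np.ndarray:
    """FLAIR lesions that are neither black holes nor contrast-enhancing.

    Subtracts the BH and CE masks from the total-FLAIR mask, i.e.
    ``total AND NOT (bh OR ce)``.  BH or CE voxels lying outside the
    total-FLAIR mask violate the nesting the lesion taxonomy assumes; they
    are reported with their count and the subtraction clips at zero.
    """
    _check_same_shape(total, bh, ce)
    total_b, bh_b, ce_b = total > 0, bh > 0, ce > 0
    outside = int(np.count_nonzero((bh_b | ce_b) & ~total_b))
    if outside:
        warnings.warn(
            f"{outside} BH/CE voxel(s) outside the total-FLAIR mask",
            stacklevel=2,
        )
    return total_b & ~(bh_b | ce_b)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def label_components(
    mask: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, int]:
    """Label maximal connected foreground components.

    ``connectivity`` counts the 3D voxel neighbours considered adjacent:
    6 (faces), 18 (faces+edges) or 26 (faces+edges+corners).  26 is the
    default, the usual convention for counting discrete lesions in 3D.
    Returns ``(labels, n_components)`` with labels 1..n.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask > 0, structure=structure)
    return labels, int(n)


def lesion_stats(
    labels: np.ndarray,
    t1: np.ndarray,
    voxel_volume_mm3: float,
    lesion_class: LesionClass | str,
    patient_id: str,
) -> pd.DataFrame:
    """One record per labeled lesion: voxel count, mm³ volume, mean T1-RT.

    The mean is the arithmetic mean of the T1 map over the lesion's member
    voxels; the volume is whole-voxel count × voxel volume from the header
    spacing.
    """
    _check_same_shape(labels, t1)
    lesion_class = LesionClass(lesion_class)
    n = int(labels.max())
    if n == 0:
        return _empty_lesion_table()
    idx = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    means = ndimage.mean(t1, labels=labels, index=idx)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "lesion_id": idx,
            "lesion_class": lesion_class.value,
            "voxel_count": counts.astype(int),
            "volume_mm3": counts * float(voxel_volume_mm3),
            "mean_t1_ms": np.asarray(means, dtype=float),
        }
    )


def _empty_lesion_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "lesion_id": pd.Series(dtype=int),
            "lesion_class": pd.Series(dtype=str),
            "voxel_count": pd.Series(dtype=int),
            "volume_mm3": pd.Series(dtype=float),
            "mean_t1_ms": pd.Series(dtype=float),
        }
    )


def cortex_stats(t1: np.ndarray, cortex_mask: np.ndarray) -> dict[str, float]:
    """Mean and sample SD of T1-RT over the cortical ROI voxels.

    Raises on an empty ROI rather than returning NaN silently.
    """
    _check_same_shape(t1, cortex_mask)
    vals = np.asarray(t1)[np.asarray(cortex_mask) > 0]
    if vals.size == 0:
        raise ValueError("cortex ROI mask is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {"mean_ms": float(np.mean(vals)), "sd_ms": sd, "n_voxels": int(vals.size)}


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Both masks empty is taken as perfect agreement (1.0) by convention.
    """
    _check_same_shape(mask_a, mask_b)
    a, b = mask_a > 0, mask_b > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks: returning 1.0 by convention", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def pooled_dice(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Overall Dice pooled over patients: Σ2|A∩B| / Σ(|A|+|B|)."""
    inter = 0
    denom = 0
    for a, b in pairs:
        a, b = a > 0, b > 0
        _check_same_shape(a, b)
        inter += int((a & b).sum())
        denom += int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom
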