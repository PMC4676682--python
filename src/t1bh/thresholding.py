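"""Lesion-wise and voxel-wise T1-RT threshold sweeps.

A lesion-wise threshold keeps whole lesions whose *mean* T1-RT lies
strictly above the cut (a boundary-equal lesion drops, following the
"> threshold" convention); a voxel-wise threshold keeps individual mask
voxels by their own T1-RT.  Contrast-enhancing lesions are never
thresholded — they are excluded from the input by contract and rejected if
present.  A patient with no surviving lesion is excluded from that
threshold's lesion-wise correlation, but contributes volume 0 in voxel-wise
mode, where no patient is ever excluded.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .lesions import LesionClass, _check_same_shape

__all__ = [
    "default_grid",
    "validate_grid",
    "lesionwise_threshold",
    "voxelwise_threshold",
    "sweep_lesionwise",
    "sweep_voxelwise",
]

#: default threshold grid in ms: 700, 800, ..., 1800
DEFAULT_GRID = tuple(float(t) for t in range(700, 1801, 100))


def default_grid() -> tuple[float, ...]:
    return DEFAULT_GRID


def validate_grid(grid: Sequence[float]) -> tuple[float, ...]:
    grid = tuple(float(t) for t in grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    return grid


def _reject_ce(records: pd.DataFrame) -> None:
    if (records["lesion_class"] == LesionClass.CE.value).any():
        raise ValueError(
            "CE lesions must not enter thresholding (they are unaffected by "
            "T1-RT thresholds); remove them from the input"
        )


def lesionwise_threshold(
    records: pd.DataFrame, thr_ms: float
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep lesions with mean T1-RT strictly above ``thr_ms``.

    Returns the surviving records and the per-patient cumulative surviving
    volume (mm³), indexed by patient_id.  Patients present in ``records``
    but with no survivor appear with volume 0.
    """
    _reject_ce(records)
    surviving = records[records["mean_t1_ms"] > thr_ms]
    all_patients = records["patient_id"].unique()
    vol = (
        surviving.groupby("patient_id")["volume_mm3"]
        .sum()
        .reindex(all_patients, fill_value=0.0)
    )
    vol.name = "volume_mm3"
    return surviving, vol


def voxelwise_threshold(
    mask: np.ndarray, t1: np.ndarray, thr_ms: float, voxel_volume_mm3: float
) -> float:
    """Volume (mm³) of mask voxels with T1-RT strictly above ``thr_ms``."""
    _check_same_shape(mask, t1)
    n = int(np.count_nonzero((mask > 0) & (t1 > thr_ms)))
    return n * float(voxel_volume_mm3)


def sweep_lesionwise(
    records: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_GRID,
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Lesion-wise sweep over a threshold grid.

    ``patient_ids`` fixes the cohort (patients with zero lesions of this
    class still get rows, excluded at every threshold).  Output is long
    format: patient_id, threshold_ms, mode, volume_mm3, n_lesions, included,
    where ``included`` is True iff at least one lesion survives.  The
    per-lesion table is scanned once; each threshold filters it.
    """
    grid = validate_grid(grid)
    _reject_ce(records)
    if patient_ids is None:
        patient_ids = list(records["patient_id"].unique())
    patient_ids = list(patient_ids)
    means = records["mean_t1_ms"].to_numpy(dtype=float)
    vols = records["volume_mm3"].to_numpy(dtype=float)
    pids = records["patient_id"].to_numpy()
    rows = []
    for thr in grid:
        keep = means > thr
        sub_p, sub_v = pids[keep], vols[keep]
        vol_by_p = pd.Series(sub_v).groupby(pd.Series(sub_p)).sum()
        cnt_by_p = pd.Series(sub_p).value_counts()
        for pid in patient_ids:
            n_les = int(cnt_by_p.get(pid, 0))
            rows.append(
                {
                    "patient_id": pid,
                    "threshold_ms": thr,
                    "mode": "lesion",
                    "volume_mm3": float(vol_by_p.get(pid, 0.0)),
                    "n_lesions": n_les,
                    "included": n_les > 0,
                }
            )
    return pd.DataFrame(rows)


def sweep_voxelwise(
    volumes_by_patient: dict[str, tuple[np.ndarray, np.ndarray, float]],
    grid: Sequence[float] = DEFAULT_GRID,
) -> pd.DataFrame:
    """Voxel-wise sweep: per patient ``(mask, t1, voxel_volume_mm3)``.

    Every patient is retained at every threshold (``included`` always True);
    ``n_lesions`` reports surviving voxel count instead of a lesion count.
    """
    grid = validate_grid(grid)
    rows = []
    for pid, (mask, t1, voxvol) in volumes_by_patient.items():
        _check_same_shape(mask, t1)
        vals = np.asarray(t1)[np.asarray(mask) > 0]
        for thr in grid:
            n = int(np.count_nonzero(vals > thr))
            rows.append(
                {
                    "patient_id": pid,
                    "threshold_ms": thr,
                    "mode": "voxel",
                    "volume_mm3": n * float(voxvol),
                    "n_lesions": n,
                    "included": True,
                }
            )
    return pd.DataFrame(rows)
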