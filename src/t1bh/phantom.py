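"""Synthetic MS cohort phantom: T1 maps, lesion masks, clinical tables, truth.

The phantom plants axis-aligned ellipsoidal lesions of three classes on a
white-matter background:

* ``BH_vis`` — black holes, lesion-level mean T1-RT ~ N(1453.3, 213.4) ms;
  each black hole sits inside a FLAIR-hyperintense footprint one voxel
  larger per semi-axis (every black hole is FLAIR-visible).
* ``pure_FLAIR`` — FLAIR-only lesions, T1 ~ N(1331.2, 226.8) ms.
* ``CE`` — contrast-enhancing lesions, present in a fraction of patients,
  disjoint from black holes and unaffected by thresholding downstream.

Voxels inside a lesion scatter around the lesion-level mean with
``within_lesion_sd_ms``; cortex ROI voxels scatter around a patient-level
cortical mean ~ N(1305.6, 35.8) ms; background white matter is ~ N(850, 50).
Lesions are planted pairwise non-touching (≥ 2 voxels gap between bounding
regions) so connected-component labeling recovers the planted count
exactly.

Disability is linked to the volume of lesions whose *true* lesion-level
T1-RT exceeds a planted threshold τ*: the latent score is
η = β·log(1 + V*) + ε, discretized to EDSS by rank-quantile mapping onto
the 0–6.5 half-point grid; MSFC subtest z-scores are a negatively oriented
standardization of η plus independent noise.  A second rater's black-hole
mask is a per-lesion morphological perturbation (jittered semi-axes and
center, re-voxelized) of the first rater's, calibrated so that two-rater
Dice agreement averages ≈ 0.8 over a cohort.

One master seed spawns per-patient sub-seeds by fixed arithmetic
(`numpy.random.SeedSequence` spawn keys), so each patient is independently
reproducible.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import expon, norm

from .clinical import ReferencePopulation
from .lesions import LesionClass, VolumeGrid, save_volume

__all__ = [
    "PhantomConfig",
    "PatientPhantom",
    "CohortPhantom",
    "DEFAULT_REFERENCE",
    "generate_patient",
    "generate_clinical",
    "generate_cohort",
    "generate_cohort_records",
    "bh_records",
    "flair_records",
    "write_cohort",
    "patient_seed_for",
]

#: reference population for MSFC z-scoring of phantom cohorts (healthy-adult
#: scale values: SDMT correct responses, timed 25-foot walk seconds, 9-HPT
#: reciprocal seconds)
DEFAULT_REFERENCE = ReferencePopulation(
    sdmt_mean=55.0,
    sdmt_sd=11.0,
    t25fw_mean_s=4.8,
    t25fw_sd_s=1.2,
    hpt9_recip_mean=1.0 / 19.0,
    hpt9_recip_sd=0.006,
)


@dataclass
class PhantomConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the published cohort characteristics: per-patient
    black-hole count ~ N(22.3, 17.07), pure-FLAIR count ~ N(19.95, 17.18),
    CE lesions in 37.5% of patients, lesion-level T1-RT distributions per
    class, cortex 1305.6 ± 35.8 ms, EDSS centered at 2.2 (SD 1.5, median 2,
    range 0–6.5), disease duration roughly exponential with mean 6.8 y, and
    an MSFC composite centered near 1 with SD ≈ 1.1 available for 75% of
    patients.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_patients: int = 40
    # per-patient lesion-count distributions {class: (mean, sd)}
    bh_count: tuple[float, float] = (22.3, 17.07)
    pure_flair_count: tuple[float, float] = (19.95, 17.18)
    ce_fraction: float = 0.375
    ce_count_max: int = 3
    # ellipsoid semi-axis range, mm
    lesion_radius_mm: tuple[float, float] = (1.5, 4.0)
    # lesion-level mean T1-RT (ms) per class: (mean, sd)
    t1_class_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "BH_vis": (1453.3, 213.4),
            "pure_FLAIR": (1331.19, 226.78),
            "CE": (1350.0, 150.0),
        }
    )
    cortex_t1: tuple[float, float] = (1305.6, 35.8)
    wm_t1: tuple[float, float] = (850.0, 50.0)
    within_lesion_sd_ms: float = 50.0
    # intra-patient correlation of lesion-level T1: a patient-level severity
    # shift shared by all of a patient's lesions (the marginal per-class
    # distribution is preserved); 0 makes lesion T1s i.i.d. across patients
    t1_icc: float = 0.6
    flair_rim_vox: float = 1.0
    # disability link
    true_threshold_ms: float = 1500.0
    effect_beta: float = 0.45
    noise_sd: float = 1.0
    edss_loc: float = 2.2
    edss_scale: float = 1.5
    msfc_noise_sd: float = 0.6
    msfc_offset: float = 0.98
    msfc_missing_fraction: float = 0.25
    duration_scale_y: float = 6.8
    duration_max_y: float = 22.0
    duration_link: float = 0.45
    # two-rater perturbation magnitude, voxels (semi-axis and center jitter)
    rater_perturb: float = 0.6
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.t1_class_params = {
            k: tuple(v) for k, v in self.t1_class_params.items()
        }
        for name in ("bh_count", "pure_flair_count", "lesion_radius_mm",
                     "cortex_t1", "wm_t1"):
            setattr(self, name, tuple(float(v) for v in getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel spacing must be positive")
        if not 0.0 <= self.ce_fraction <= 1.0:
            raise ValueError("ce_fraction must lie in [0, 1]")
        for name, (_, sd) in self.t1_class_params.items():
            if sd < 0:
                raise ValueError(f"t1_class_params[{name}] sd must be ≥ 0")
        for name in ("bh_count", "pure_flair_count", "cortex_t1", "wm_t1"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be ≥ 0")
        if self.within_lesion_sd_ms < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be ≥ 0")
        if not 0.0 <= self.t1_icc < 1.0:
            raise ValueError("t1_icc must lie in [0, 1)")
        rmin, rmax = self.lesion_radius_mm
        if not 0 < rmin <= rmax:
            raise ValueError("lesion_radius_mm must satisfy 0 < min ≤ max")
        margin = self._interior_margin()
        if any(hi - lo < 1 for lo, hi in self._interior_bounds()):
            raise ValueError(
                f"grid {self.grid_shape} too small for lesions of max radius "
                f"{rmax} mm (interior margin {margin} voxels)"
            )

    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.grid_shape, self.voxel_size_mm)

    def _interior_margin(self) -> int:
        rmax = self.lesion_radius_mm[1]
        s_max = max(
            rmax / v + self.flair_rim_vox + self.rater_perturb + 1
            for v in self.voxel_size_mm
        )
        return int(np.ceil(s_max)) + _CORTEX_BAND

    def _interior_bounds(self) -> list[tuple[int, int]]:
        m = self._interior_margin()
        return [(m, s - m) for s in self.grid_shape]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


_CORTEX_BAND = 8  # outer shell (voxels) reserved for cortex ROIs


# ---------------------------------------------------------------------------
# seeding: master seed → per-patient and per-purpose streams by fixed keys

def patient_seed_for(master_seed: int, patient_index: int) -> int:
    """Deterministic per-patient sub-seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(patient_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _stream(patient_seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=patient_seed, spawn_key=(purpose,))
    )


_ATTR, _PLACE, _VOXNOISE, _RATER, _FASTMEAN = range(5)


# ---------------------------------------------------------------------------
# ellipsoid voxelization

def ellipsoid_offsets(
    semi_axes_mm: np.ndarray,
    voxel_size_mm: np.ndarray,
    frac_offset: np.ndarray,
) -> np.ndarray:
    """Integer voxel offsets (relative to an integer base voxel) inside an
    axis-aligned ellipsoid centered at base + frac_offset.

    A voxel j belongs to the lesion iff Σ_k ((j_k − c_k)·Δ_k / a_k)² ≤ 1,
    with c the (possibly fractional) center in voxel coordinates, Δ the
    spacing and a the semi-axes in mm.
    """
    s = np.asarray(semi_axes_mm, dtype=float) / np.asarray(voxel_size_mm, dtype=float)
    c = np.asarray(frac_offset, dtype=float)
    lo = np.floor(c - s).astype(int)
    hi = np.ceil(c + s).astype(int)
    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    d = (
        ((gx - c[0]) / s[0]) ** 2
        + ((gy - c[1]) / s[1]) ** 2
        + ((gz - c[2]) / s[2]) ** 2
    )
    inside = d <= 1.0
    return np.stack([gx[inside], gy[inside], gz[inside]], axis=1)


# ---------------------------------------------------------------------------
# lesion attribute sampling (shared by the volumetric and record-level paths)

def _sample_lesion_attributes(cfg: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-lesion class, semi-axes, fractional offset and lesion T1.

    Voxel counts (core and FLAIR footprint) are deterministic functions of
    the drawn geometry, so the record-level fast path and the volumetric
    path agree exactly on lesion volumes.
    """
    n_bh = max(0, int(round(rng.normal(*cfg.bh_count))))
    n_pure = max(0, int(round(rng.normal(*cfg.pure_flair_count))))
    u_ce = rng.random()
    n_ce_draw = int(rng.integers(1, cfg.ce_count_max + 1))
    n_ce = n_ce_draw if u_ce < cfg.ce_fraction else 0
    severity = float(rng.normal())  # patient-level T1 severity shift (z units)

    rows = []
    voxvol = float(np.prod(cfg.voxel_size_mm))
    vox = np.asarray(cfg.voxel_size_mm)
    rim_mm = cfg.flair_rim_vox * vox
    rmin, rmax = cfg.lesion_radius_mm
    lesion_id = 0
    for cls, n in (
        (LesionClass.BH_VIS, n_bh),
        (LesionClass.PURE_FLAIR, n_pure),
        (LesionClass.CE, n_ce),
    ):
        mean, sd = cfg.t1_class_params[cls.value]
        shift = np.sqrt(cfg.t1_icc) * severity
        resid = np.sqrt(1.0 - cfg.t1_icc)
        pf_mean, pf_sd = cfg.t1_class_params[LesionClass.PURE_FLAIR.value]
        for _ in range(n):
            lesion_id += 1
            semi = rng.uniform(rmin, rmax, size=3)
            frac = rng.random(3)
            t1 = float(mean + sd * (shift + resid * rng.normal()))
            core = ellipsoid_offsets(semi, vox, frac)
            if cls is LesionClass.BH_VIS:
                flair_n = len(ellipsoid_offsets(semi + rim_mm, vox, frac))
                # the FLAIR-hyperintense rim around a black hole is less
                # damaged tissue: its T1 follows the pure-FLAIR distribution
                rim_t1 = float(
                    pf_mean + pf_sd * (shift + resid * rng.normal())
                )
            else:
                flair_n = len(core)
                rim_t1 = t1
            rows.append(
                {
                    "lesion_id": lesion_id,
                    "lesion_class": cls.value,
                    "semi_a_mm": semi[0],
                    "semi_b_mm": semi[1],
                    "semi_c_mm": semi[2],
                    "frac_x": frac[0],
                    "frac_y": frac[1],
                    "frac_z": frac[2],
                    "t1_ms": t1,
                    "rim_t1_ms": rim_t1,
                    "voxel_count": len(core),
                    "volume_mm3": len(core) * voxvol,
                    "flair_voxel_count": flair_n,
                    "flair_volume_mm3": flair_n * voxvol,
                }
            )
    cortex_mean = float(rng.normal(*cfg.cortex_t1))
    df = pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "lesion_class", "semi_a_mm", "semi_b_mm", "semi_c_mm",
            "frac_x", "frac_y", "frac_z", "t1_ms", "rim_t1_ms", "voxel_count",
            "volume_mm3", "flair_voxel_count", "flair_volume_mm3",
        ],
    )
    df.attrs["cortex_mean_ms"] = cortex_mean
    return df


def _place_lesions(
    cfg: PhantomConfig, lesions: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign non-touching integer base positions by box rejection sampling.

    Each lesion reserves an axis-aligned exclusion box (its FLAIR + jitter
    extent plus a 2-voxel gap); boxes of distinct lesions must not overlap,
    which guarantees ≥ 2 voxels separation between any two lesion
    footprints.  If a lesion cannot be placed, placement stops and the
    count actually placed is reported.
    """
    bounds = cfg._interior_bounds()
    vox = np.asarray(cfg.voxel_size_mm)
    placed_boxes: list[np.ndarray] = []
    bases = np.full((len(lesions), 3), -1, dtype=int)
    placed = np.zeros(len(lesions), dtype=bool)
    gap = 2
    rows = list(lesions.itertuples(index=False))
    # place the biggest lesions first: sequential random packing succeeds
    # far more often when small lesions fill the gaps last
    order = sorted(
        range(len(rows)),
        key=lambda i: -(rows[i].semi_a_mm * rows[i].semi_b_mm * rows[i].semi_c_mm),
    )
    for i in order:
        row = rows[i]
        semi = np.array([row.semi_a_mm, row.semi_b_mm, row.semi_c_mm])
        half = (
            semi / vox + cfg.flair_rim_vox + cfg.rater_perturb + 1 + gap / 2
        )
        ok = False
        for _ in range(400):
            base = np.array(
                [rng.integers(lo, hi) for lo, hi in bounds], dtype=int
            )
            box = np.concatenate([base - half, base + half])
            if cfg.allow_overlap or not any(
                np.all(box[:3] <= b[3:]) and np.all(b[:3] <= box[3:])
                for b in placed_boxes
            ):
                ok = True
                break
        if not ok:
            warnings.warn(
                f"could only place {int(placed.sum())} of {len(lesions)} "
                f"lesions on grid {cfg.grid_shape}",
                stacklevel=2,
            )
            break
        placed_boxes.append(box)
        bases[i] = base
        placed[i] = True
    out = lesions.copy()
    out["base_x"], out["base_y"], out["base_z"] = bases.T
    out["placed"] = placed
    return out


@dataclass
class PatientPhantom:
    patient_id: str
    t1: np.ndarray
    masks: dict[str, np.ndarray]
    truth: pd.DataFrame
    cortex_mean_ms: float
    grid: VolumeGrid


def _stamp(mask: np.ndarray, offsets: np.ndarray, base: np.ndarray) -> np.ndarray:
    idx = offsets + base
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return idx


def _cortex_centers(shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    cx, cy, cz = (s // 2 for s in shape)
    off = 4
    return [
        (cx, cy, off),
        (cx, cy, shape[2] - 1 - off),
        (cx, off, cz),
        (cx, shape[1] - 1 - off, cz),
    ]


def generate_patient(cfg: PhantomConfig, patient_seed: int, patient_id: str | None = None) -> PatientPhantom:
    """Generate one patient's T1 map, masks and ground truth.

    Masks: ``bh_rater1`` (true black-hole footprints), ``bh_rater2``
    (per-lesion jittered re-voxelization of rater 1), ``ce``,
    ``total_flair`` (FLAIR footprints of all lesions, containing every BH
    voxel of both raters), ``cortex`` (four spherical ROIs in the reserved
    outer band).
    """
    if patient_id is None:
        patient_id = f"P{patient_seed % 10**6:06d}"
    grid = cfg.grid()
    vox = np.asarray(cfg.voxel_size_mm)
    rim_mm = cfg.flair_rim_vox * vox

    lesions = _sample_lesion_attributes(cfg, _stream(patient_seed, _ATTR))
    cortex_mean = lesions.attrs["cortex_mean_ms"]
    lesions = _place_lesions(cfg, lesions, _stream(patient_seed, _PLACE))

    rng_vox = _stream(patient_seed, _VOXNOISE)
    rng_rater = _stream(patient_seed, _RATER)

    t1 = rng_vox.normal(cfg.wm_t1[0], cfg.wm_t1[1], size=cfg.grid_shape)
    masks = {
        name: np.zeros(cfg.grid_shape, dtype=bool)
        for name in ("bh_rater1", "bh_rater2", "ce", "total_flair", "cortex")
    }

    for row in lesions.itertuples(index=False):
        if not row.placed:
            continue
        base = np.array([row.base_x, row.base_y, row.base_z])
        semi = np.array([row.semi_a_mm, row.semi_b_mm, row.semi_c_mm])
        frac = np.array([row.frac_x, row.frac_y, row.frac_z])
        core = ellipsoid_offsets(semi, vox, frac)
        if row.lesion_class == LesionClass.BH_VIS.value:
            flair = ellipsoid_offsets(semi + rim_mm, vox, frac)
        else:
            flair = core
        fidx = _stamp(masks["total_flair"], flair, base)
        t1[fidx[:, 0], fidx[:, 1], fidx[:, 2]] = rng_vox.normal(
            row.rim_t1_ms, cfg.within_lesion_sd_ms, size=len(fidx)
        )
        if row.lesion_class == LesionClass.BH_VIS.value:
            cidx = core + base
            t1[cidx[:, 0], cidx[:, 1], cidx[:, 2]] = rng_vox.normal(
                row.t1_ms, cfg.within_lesion_sd_ms, size=len(cidx)
            )
            _stamp(masks["bh_rater1"], core, base)
            jit_semi = semi + rng_rater.uniform(
                -cfg.rater_perturb, cfg.rater_perturb, size=3
            ) * vox
            jit_semi = np.maximum(jit_semi, 0.9 * vox)
            jit_frac = frac + rng_rater.uniform(
                -cfg.rater_perturb, cfg.rater_perturb, size=3
            )
            core2 = ellipsoid_offsets(jit_semi, vox, jit_frac)
            _stamp(masks["bh_rater2"], core2, base)
        elif row.lesion_class == LesionClass.CE.value:
            _stamp(masks["ce"], core, base)

    # a rater stays within the FLAIR-visible extent of each lesion
    masks["bh_rater2"] &= masks["total_flair"]

    for center in _cortex_centers(cfg.grid_shape):
        roi = ellipsoid_offsets(3.0 * vox, vox, np.zeros(3))
        ridx = _stamp(masks["cortex"], roi, np.array(center))
        t1[ridx[:, 0], ridx[:, 1], ridx[:, 2]] = rng_vox.normal(
            cortex_mean, cfg.within_lesion_sd_ms, size=len(ridx)
        )

    truth = lesions.copy()
    truth.insert(0, "patient_id", patient_id)
    truth["in_vstar"] = (
        (truth["lesion_class"] == LesionClass.BH_VIS.value)
        & (truth["t1_ms"] > cfg.true_threshold_ms)
        & truth["placed"]
    )
    return PatientPhantom(
        patient_id=patient_id,
        t1=t1.astype(np.float32),
        masks=masks,
        truth=truth,
        cortex_mean_ms=cortex_mean,
        grid=grid,
    )


def truth_summary(
    truths: pd.DataFrame,
    cfg: PhantomConfig,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-patient V* (mm³ of non-CE lesions with true T1 > τ*) and totals.

    ``patient_ids`` fixes the cohort so that patients with zero lesions (an
    empty truth block) still get a row with V* = 0.
    """
    placed = truths[truths["placed"]] if len(truths) else truths
    if len(truths):
        non_ce = placed[placed["lesion_class"] != LesionClass.CE.value]
    else:
        non_ce = placed
    if patient_ids is None:
        patient_ids = list(truths["patient_id"].unique()) if len(truths) else []
    pids = np.asarray(patient_ids)
    if not len(truths):
        return pd.DataFrame(
            {
                "patient_id": pids,
                "v_star_mm3": np.zeros(len(pids)),
                "total_volume_mm3": np.zeros(len(pids)),
                "n_lesions": np.zeros(len(pids), dtype=int),
                "true_threshold_ms": cfg.true_threshold_ms,
            }
        )
    v_star = (
        non_ce[non_ce["in_vstar"]].groupby("patient_id")["volume_mm3"].sum()
        .reindex(pids, fill_value=0.0)
    )
    total = (
        non_ce.groupby("patient_id")["flair_volume_mm3"].sum()
        .reindex(pids, fill_value=0.0)
    )
    n_lesions = non_ce.groupby("patient_id").size().reindex(pids, fill_value=0)
    return pd.DataFrame(
        {
            "patient_id": pids,
            "v_star_mm3": v_star.to_numpy(),
            "total_volume_mm3": total.to_numpy(),
            "n_lesions": n_lesions.to_numpy(),
            "true_threshold_ms": cfg.true_threshold_ms,
        }
    )


# ---------------------------------------------------------------------------
# clinical generation

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.floor(2.0 * x + 0.5) / 2.0


def generate_clinical(
    summary: pd.DataFrame,
    cfg: PhantomConfig,
    seed: int | None = None,
    reference: ReferencePopulation = DEFAULT_REFERENCE,
) -> pd.DataFrame:
    """Generate the cohort clinical table from per-patient truth.

    Latent disability η = effect_beta · log(1 + V*) + N(0, noise_sd).  EDSS
    is η's cohort rank mapped through a N(2.2, 1.5) quantile function,
    clipped to [0, 6.5] and rounded to the half-point grid — an ordinal,
    tie-heavy score.  MSFC subtest z-scores are msfc_offset − standardized(η)
    plus independent N(0, msfc_noise_sd) noise (higher disability → lower
    MSFC); raw subtest scores are back-computed from the reference
    population so re-scoring the table reproduces the z-scores.  Disease
    duration is drawn positively correlated with total lesion volume and
    mapped onto a truncated exponential.  A fixed fraction of patients lacks
    the MSFC subtests entirely.
    """
    if seed is None:
        seed = patient_seed_for(cfg.seed, 10_000_019)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    n = len(summary)
    v_star = summary["v_star_mm3"].to_numpy(dtype=float)
    eta = cfg.effect_beta * np.log1p(v_star) + rng.normal(0.0, cfg.noise_sd, n)

    order = np.argsort(eta, kind="stable")
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(n)
    q = (rank + 0.5) / n
    edss = _round_half(
        np.clip(norm.ppf(q, loc=cfg.edss_loc, scale=cfg.edss_scale), 0.0, 6.5)
    )

    s = _standardize(eta)
    z_true = {
        name: cfg.msfc_offset - s + rng.normal(0.0, cfg.msfc_noise_sd, n)
        for name in ("sdmt", "t25fw", "hpt9")
    }
    sdmt = reference.sdmt_mean + z_true["sdmt"] * reference.sdmt_sd
    t25fw = np.maximum(
        reference.t25fw_mean_s - z_true["t25fw"] * reference.t25fw_sd_s, 0.3
    )
    recip = np.maximum(
        reference.hpt9_recip_mean + z_true["hpt9"] * reference.hpt9_recip_sd,
        0.005,
    )
    hpt9 = 1.0 / recip

    total = summary["total_volume_mm3"].to_numpy(dtype=float)
    w = cfg.duration_link
    lat_d = w * _standardize(np.log1p(total)) + np.sqrt(1 - w**2) * rng.normal(
        0.0, 1.0, n
    )
    order_d = np.argsort(lat_d, kind="stable")
    rank_d = np.empty(n, dtype=float)
    rank_d[order_d] = np.arange(n)
    duration = np.round(
        np.minimum(
            expon.ppf((rank_d + 0.5) / n, scale=cfg.duration_scale_y),
            cfg.duration_max_y,
        ),
        1,
    )

    clinical = pd.DataFrame(
        {
            "patient_id": summary["patient_id"].to_numpy(),
            "edss": edss,
            "sdmt": np.round(sdmt, 1),
            "t25fw_s": np.round(t25fw, 2),
            "hpt9_s": np.round(hpt9, 2),
            "duration_y": duration,
        }
    )
    n_missing = int(round(cfg.msfc_missing_fraction * n))
    if n_missing:
        missing = rng.choice(n, size=n_missing, replace=False)
        clinical.loc[missing, ["sdmt", "t25fw_s", "hpt9_s"]] = np.nan
    return clinical


# ---------------------------------------------------------------------------
# cohort-level generation

@dataclass
class CohortPhantom:
    config: PhantomConfig
    patients: list[PatientPhantom]
    truth: pd.DataFrame
    summary: pd.DataFrame
    clinical: pd.DataFrame


def generate_cohort(cfg: PhantomConfig) -> CohortPhantom:
    """Generate the full volumetric cohort (T1 maps + masks + clinical)."""
    patients = []
    for i in range(cfg.n_patients):
        pseed = patient_seed_for(cfg.seed, i)
        patients.append(generate_patient(cfg, pseed, patient_id=f"P{i:03d}"))
    blocks = [p.truth for p in patients if len(p.truth)]
    truth = (
        pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    )
    pids = [p.patient_id for p in patients]
    summary = truth_summary(truth, cfg, patient_ids=pids)
    clinical = generate_clinical(summary, cfg)
    return CohortPhantom(cfg, patients, truth, summary, clinical)


def generate_cohort_records(
    cfg: PhantomConfig,
    voxel_grid: "Sequence[float] | None" = None,
) -> tuple:
    """Record-level cohort: per-lesion records without volume rasterization.

    Draws the same lesion-level attributes as :func:`generate_patient`
    (identical sub-seed streams, hence identical classes, geometry, voxel
    counts and lesion T1s), then draws each lesion's individual voxel T1
    values around the lesion-level mean, so that the *observed* per-lesion
    mean T1-RT carries exactly the sampling noise of averaging
    ``within_lesion_sd_ms`` voxel noise over the lesion.  Placement is
    skipped — lesions are non-touching by construction, so the record-level
    cohort corresponds to a single-rater, perfectly labeled segmentation.

    Returns ``(records, summary, clinical)``; with ``voxel_grid`` given,
    additionally returns a dict of voxel-wise sweep tables
    ``{"bh": ..., "flair": ...}`` computed by counting the drawn voxel
    values above each threshold (the FLAIR family pools core and rim voxels
    of non-CE lesions).
    """
    grid = None if voxel_grid is None else np.asarray(voxel_grid, dtype=float)
    voxvol = float(np.prod(cfg.voxel_size_mm))
    all_rows = []
    pids = []
    vox_rows: dict[str, list[dict]] = {"bh": [], "flair": []}
    for i in range(cfg.n_patients):
        pseed = patient_seed_for(cfg.seed, i)
        pid = f"P{i:03d}"
        pids.append(pid)
        lesions = _sample_lesion_attributes(cfg, _stream(pseed, _ATTR))
        rng_vox = _stream(pseed, _FASTMEAN)
        counts = {"bh": None, "flair": None}
        if grid is not None:
            counts = {"bh": np.zeros(len(grid)), "flair": np.zeros(len(grid))}
        if len(lesions):
            lesions.insert(0, "patient_id", pid)
            lesions["placed"] = True
            means, flair_means = [], []
            for row in lesions.itertuples(index=False):
                n_core = int(row.voxel_count)
                n_rim = int(row.flair_voxel_count) - n_core
                core = rng_vox.normal(row.t1_ms, cfg.within_lesion_sd_ms, n_core)
                rim = rng_vox.normal(row.rim_t1_ms, cfg.within_lesion_sd_ms, n_rim)
                means.append(core.mean())
                flair_means.append(
                    (core.sum() + rim.sum()) / (n_core + n_rim)
                )
                if grid is not None:
                    if row.lesion_class == LesionClass.BH_VIS.value:
                        counts["bh"] += (core[None, :] > grid[:, None]).sum(1)
                    if row.lesion_class != LesionClass.CE.value:
                        both = np.concatenate([core, rim])
                        counts["flair"] += (both[None, :] > grid[:, None]).sum(1)
            lesions["mean_t1_ms"] = means
            lesions["flair_mean_t1_ms"] = flair_means
            lesions["in_vstar"] = (
                (lesions["lesion_class"] == LesionClass.BH_VIS.value)
                & (lesions["t1_ms"] > cfg.true_threshold_ms)
            )
            all_rows.append(lesions)
        if grid is not None:
            for fam in ("bh", "flair"):
                c = counts[fam] if counts[fam] is not None else np.zeros(len(grid))
                vox_rows[fam] += [
                    {
                        "patient_id": pid,
                        "threshold_ms": float(g),
                        "mode": "voxel",
                        "volume_mm3": float(n) * voxvol,
                        "n_lesions": int(n),
                        "included": True,
                    }
                    for g, n in zip(grid, c)
                ]
    records = (
        pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    )
    summary = truth_summary(records, cfg, patient_ids=pids)
    clinical = generate_clinical(summary, cfg)
    if grid is None:
        return records, summary, clinical
    sweeps = {fam: pd.DataFrame(rows) for fam, rows in vox_rows.items()}
    return records, summary, clinical, sweeps


def bh_records(records: pd.DataFrame) -> pd.DataFrame:
    """Black-hole lesion records (core volumes) for the BH mask family."""
    sub = records[records["lesion_class"] == LesionClass.BH_VIS.value]
    return sub[["patient_id", "lesion_id", "lesion_class", "voxel_count",
                "volume_mm3", "mean_t1_ms"]].reset_index(drop=True)


def flair_records(records: pd.DataFrame) -> pd.DataFrame:
    """Non-CE lesion records with FLAIR-footprint volumes (total-FLAIR family)."""
    sub = records[records["lesion_class"] != LesionClass.CE.value].copy()
    out = pd.DataFrame(
        {
            "patient_id": sub["patient_id"].to_numpy(),
            "lesion_id": sub["lesion_id"].to_numpy(),
            "lesion_class": LesionClass.TOTAL_FLAIR.value,
            "voxel_count": sub["flair_voxel_count"].to_numpy(),
            "volume_mm3": sub["flair_volume_mm3"].to_numpy(),
            "mean_t1_ms": sub["flair_mean_t1_ms"].to_numpy(),
        }
    )
    return out


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: CohortPhantom, out_dir: str | Path) -> dict:
    """Write NIfTI volumes, clinical/truth CSVs and a JSON manifest.

    Re-running with the same config and seed reproduces byte-identical CSVs
    and voxel-identical volumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cohort.config.grid()
    entries = []
    for p in cohort.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        save_volume(p.t1, grid, pdir / "t1.nii.gz")
        files = {"t1": str(pdir / "t1.nii.gz")}
        for name, key in (
            ("bh_rater1", "bh_r1"),
            ("bh_rater2", "bh_r2"),
            ("ce", "ce"),
            ("total_flair", "flair"),
            ("cortex", "cortex"),
        ):
            path = pdir / f"{name}.nii.gz"
            save_volume(p.masks[name].astype(np.uint8), grid, path)
            files[key] = str(path)
        entries.append({"id": p.patient_id, **files})
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    cohort.summary.to_csv(out / "truth_summary.csv", index=False)
    manifest = {
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "patients": entries,
        "clinical_csv": str(out / "clinical.csv"),
        "truth_csv": str(out / "truth.csv"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
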