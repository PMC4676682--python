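"""End-to-end pipeline: volumes → lesion tables → sweeps → profiles.

Consumes a JSON manifest pointing at co-registered per-patient NIfTI
volumes (quantitative T1 map, two raters' black-hole masks, CE mask,
total-FLAIR mask, cortex ROIs) plus a clinical CSV, and writes a
reproducible report bundle: per-lesion tables, threshold sweeps, Spearman
correlation profiles for {black-hole, total-FLAIR} × {EDSS, MSFC} (each
with lesion-wise and voxel-wise rows), group T1-RT comparisons, a two-rater
Dice summary, and a run log carrying the config hash and every
patient/threshold exclusion.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import thresholding
from .clinical import ReferencePopulation, validate_edss_series, add_scores
from .correlation import (
    auxiliary_correlations,
    build_profile,
    compare_group_t1,
    optimal_threshold,
)
from .lesions import (
    GridMismatchError,
    LesionClass,
    consensus_mask,
    cortex_stats,
    dice,
    label_components,
    lesion_stats,
    load_mask,
    load_volume,
    pooled_dice,
    pure_flair_mask,
)

__all__ = ["PipelineConfig", "ValidationReport", "validate_inputs", "run_pipeline"]

MASK_KEYS = ("bh_r1", "bh_r2", "ce", "flair", "cortex")


@dataclass
class PipelineConfig:
    manifest: str | Path
    out_dir: str | Path
    threshold_grid: tuple[float, ...] = thresholding.DEFAULT_GRID
    connectivity: int = 26
    modes: tuple[str, ...] = ("lesion", "voxel")
    scores: tuple[str, ...] = ("edss", "msfc")
    alpha: float = 0.05
    reference_population: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.threshold_grid = thresholding.validate_grid(self.threshold_grid)
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest {self.manifest} not found")

    def reference(self) -> ReferencePopulation:
        if self.reference_population is not None:
            return ReferencePopulation.from_dict(self.reference_population)
        from .phantom import DEFAULT_REFERENCE

        return DEFAULT_REFERENCE

    def config_hash(self) -> str:
        payload = {
            "manifest": str(self.manifest),
            "threshold_grid": list(self.threshold_grid),
            "connectivity": self.connectivity,
            "modes": list(self.modes),
            "scores": list(self.scores),
            "alpha": self.alpha,
            "reference_population": self.reference_population,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def validate_inputs(manifest_path: str | Path) -> ValidationReport:
    """Check grids, mask binarity, lesion-class nesting and clinical validity.

    Errors (blocking): missing files, grid mismatches within a patient.
    Warnings: non-binary mask values, black-hole voxels outside the
    total-FLAIR mask (with voxel counts), CE/BH overlap, off-grid EDSS,
    clinical rows missing for imaged patients.
    """
    rep = ValidationReport()
    man = _load_manifest(manifest_path)
    clinical = None
    if man.get("clinical_csv"):
        cpath = Path(man["clinical_csv"])
        if not cpath.exists():
            rep.errors.append(f"clinical table {cpath} not found")
        else:
            clinical = pd.read_csv(cpath)
            bad = validate_edss_series(
                clinical.set_index("patient_id")["edss"]
            )
            if bad:
                rep.errors.append(f"off-grid EDSS for patient(s): {bad}")
    for entry in man.get("patients", []):
        pid = entry["id"]
        paths = {k: entry.get(k) for k in ("t1",) + tuple(MASK_KEYS)}
        missing = [k for k, v in paths.items() if not v or not Path(v).exists()]
        if missing:
            rep.errors.append(f"{pid}: missing volume(s) {missing}")
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            t1 = load_volume(paths["t1"])
            vols = {k: load_mask(paths[k]) for k in MASK_KEYS}
        for w in caught:
            rep.warnings.append(f"{pid}: {w.message}")
        grids = {k: v.grid for k, v in vols.items()}
        grids["t1"] = t1.grid
        base = grids["t1"]
        bad = [k for k, g in grids.items() if not g.matches(base)]
        if bad:
            rep.errors.append(f"{pid}: grid mismatch in {bad} vs t1")
            continue
        bh = consensus_mask(vols["bh_r1"].data, vols["bh_r2"].data)
        outside = int(np.count_nonzero(bh & ~vols["flair"].data))
        if outside:
            rep.warnings.append(
                f"{pid}: {outside} consensus BH voxel(s) outside total-FLAIR"
            )
        overlap = int(np.count_nonzero(bh & vols["ce"].data))
        if overlap:
            rep.warnings.append(f"{pid}: {overlap} voxel(s) shared by BH and CE")
        if clinical is not None and pid not in set(clinical["patient_id"]):
            rep.warnings.append(f"{pid}: no clinical row; patient skipped in profiles")
    return rep


def _patient_tables(entry: dict, connectivity: int) -> dict:
    pid = entry["id"]
    t1v = load_volume(entry["t1"])
    masks = {k: load_mask(entry[k]) for k in MASK_KEYS}
    base = t1v.grid
    for k, v in masks.items():
        if not v.grid.matches(base):
            raise GridMismatchError(f"patient {pid}: {k} grid differs from t1")
    t1 = t1v.data
    voxvol = base.voxel_volume_mm3

    bh = consensus_mask(masks["bh_r1"].data, masks["bh_r2"].data)
    flair = masks["flair"].data
    ce = masks["ce"].data
    pure = pure_flair_mask(flair, bh, ce)
    flair_thr = flair & ~ce  # thresholded FLAIR family: CE never thresholded

    tables = []
    for cls, mask in (
        (LesionClass.BH_VIS, bh),
        (LesionClass.TOTAL_FLAIR, flair_thr),
        (LesionClass.PURE_FLAIR, pure),
        (LesionClass.CE, ce),
    ):
        labels, _ = label_components(mask, connectivity)
        tables.append(lesion_stats(labels, t1, voxvol, cls, pid))
    lesion_table = pd.concat(tables, ignore_index=True)

    ctx = cortex_stats(t1, masks["cortex"].data)
    return {
        "pid": pid,
        "lesions": lesion_table,
        "cortex": {"patient_id": pid, **ctx},
        "dice": dice(masks["bh_r1"].data, masks["bh_r2"].data),
        "rater_masks": (masks["bh_r1"].data, masks["bh_r2"].data),
        "voxel_inputs": {
            "BH_vis": (bh, t1, voxvol),
            "total_FLAIR": (flair_thr, t1, voxvol),
        },
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``cfg.out_dir``.

    Returns a summary dict (also written as ``summary.json``).  Deterministic
    given fixed inputs: rerunning produces byte-identical CSVs.
    """
    report = validate_inputs(cfg.manifest)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))
    man = _load_manifest(cfg.manifest)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_patient = [
        _patient_tables(entry, cfg.connectivity) for entry in man["patients"]
    ]
    patient_ids = [p["pid"] for p in per_patient]
    lesions = pd.concat([p["lesions"] for p in per_patient], ignore_index=True)
    cortex = pd.DataFrame([p["cortex"] for p in per_patient])
    dice_df = pd.DataFrame(
        {"patient_id": patient_ids, "dice": [p["dice"] for p in per_patient]}
    )
    lesions.to_csv(out / "lesions.csv", index=False)
    cortex.to_csv(out / "cortex.csv", index=False)
    dice_df.to_csv(out / "dice.csv", index=False)

    clinical = pd.read_csv(man["clinical_csv"])
    clinical = add_scores(clinical, cfg.reference())
    missing_clin = sorted(set(patient_ids) - set(clinical["patient_id"]))
    clinical.to_csv(out / "clinical_scored.csv", index=False)

    families = {
        "bh": LesionClass.BH_VIS.value,
        "flair": LesionClass.TOTAL_FLAIR.value,
    }
    sweeps: dict[tuple[str, str], pd.DataFrame] = {}
    for fam, cls in families.items():
        if "lesion" in cfg.modes:
            recs = lesions[lesions["lesion_class"] == cls]
            sweeps[(fam, "lesion")] = thresholding.sweep_lesionwise(
                recs, cfg.threshold_grid, patient_ids=patient_ids
            )
        if "voxel" in cfg.modes:
            vox_inputs = {
                p["pid"]: p["voxel_inputs"][cls] for p in per_patient
            }
            sweeps[(fam, "voxel")] = thresholding.sweep_voxelwise(
                vox_inputs, cfg.threshold_grid
            )
    for (fam, mode), df in sweeps.items():
        df.to_csv(out / f"sweep_{fam}_{mode}.csv", index=False)

    score_available = {
        s: s in clinical.columns and clinical[s].notna().sum() >= 3
        for s in cfg.scores
    }
    optima: dict[str, float | None] = {}
    exclusions: list[dict] = []
    for fam in families:
        for score in cfg.scores:
            if not score_available.get(score, False):
                continue
            parts = []
            for mode in cfg.modes:
                prof = build_profile(
                    sweeps[(fam, mode)], clinical, score, mode, alpha=cfg.alpha
                )
                parts.append(prof)
                if mode == "lesion":
                    sw = sweeps[(fam, mode)]
                    for _, row in sw[~sw["included"]].iterrows():
                        exclusions.append(
                            {
                                "patient_id": row["patient_id"],
                                "threshold_ms": row["threshold_ms"],
                                "family": fam,
                                "score": score,
                                "reason": "no lesion above threshold",
                            }
                        )
            profile = pd.concat(parts, ignore_index=True)
            profile.to_csv(out / f"profile_{fam}_{score}.csv", index=False)
            lw = profile[profile["mode"] == "lesion"]
            optima[f"{fam}_{score}_lesionwise"] = optimal_threshold(
                lw if len(lw) else profile
            )

    groups = compare_group_t1(
        lesions[lesions["lesion_class"] != LesionClass.TOTAL_FLAIR.value],
        cortex.rename(columns={"mean_ms": "mean_ms"}),
    ) if len(lesions) else pd.DataFrame()
    groups.to_csv(out / "group_comparisons.csv", index=False)

    aux = {}
    if score_available.get("edss", False) and ("bh", "lesion") in sweeps:
        aux = auxiliary_correlations(sweeps[("bh", "lesion")], clinical, "edss")
        aux["count_vs_score"].to_csv(out / "aux_count_vs_edss.csv", index=False)
        aux["duration"].to_csv(out / "aux_duration.csv", index=False)

    pd.DataFrame(exclusions).to_csv(out / "exclusions.csv", index=False)

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_patients": len(patient_ids),
        "patients_without_clinical": missing_clin,
        "mean_dice": float(dice_df["dice"].mean()) if len(dice_df) else None,
        "pooled_dice": pooled_dice([p["rater_masks"] for p in per_patient]),
        "optimal_thresholds_ms": optima,
        "validation_warnings": report.warnings,
        "n_exclusions": len(exclusions),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
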