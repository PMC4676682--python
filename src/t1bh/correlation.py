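"""Spearman rank correlation, threshold-correlation profiles and group tests.

The central statistic is the Spearman rank correlation between per-patient
cumulative lesion volume at a T1-RT threshold and a disability score (EDSS
or MSFC).  EDSS is heavily tied, so ranks are average ranks and the
statistic is the Pearson correlation of the rank vectors (the standard
tie-corrected form).  Two-sided p-values use the t approximation
t = r·sqrt((n−2)/(1−r²)), adequate at the cohort sizes this analysis runs
at (n ≈ 30–40); an exact permutation p-value is available for tiny n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import isnan

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "SpearmanResult",
    "spearman",
    "build_profile",
    "optimal_threshold",
    "compare_group_t1",
    "auxiliary_correlations",
]


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return not isnan(self.r)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0.0:  # a constant vector: every rank tied
        return float("nan")
    return float((rx * ry).sum() / denom)


def _t_approx_p(r: float, n: int) -> float:
    if isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman(x, y, method: str = "t-approx") -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    ``method`` is ``"t-approx"`` (default), ``"exact"`` (permutation null of
    the rank correlation, feasible for n < 10) or ``"auto"`` (exact below
    n = 10, t approximation otherwise).  A constant input vector leaves the
    correlation undefined; the result then carries r = p = NaN — reachable
    in practice when every included patient shares one EDSS step.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed; drop them first")
    rx, ry = rankdata(x), rankdata(y)
    r = _rank_corr(rx, ry)
    if isnan(r):
        return SpearmanResult(float("nan"), float("nan"), n)
    if method == "auto":
        method = "exact" if n < 10 else "t-approx"
    if method == "t-approx":
        return SpearmanResult(r, _t_approx_p(r, n), n)
    if method == "exact":
        if n >= 10:
            raise ValueError("exact permutation p only supported for n < 10")
        count = 0
        total = 0
        for perm in permutations(ry):
            rp = _rank_corr(rx, np.asarray(perm))
            total += 1
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        return SpearmanResult(r, count / total, n)
    raise ValueError(f"unknown method {method!r}")


def build_profile(
    sweep: pd.DataFrame,
    clinical: pd.DataFrame,
    score_field: str,
    mode: str,
    alpha: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Correlate per-patient thresholded volumes with a clinical score.

    ``sweep`` is long-format output of the thresholding module (columns
    patient_id, threshold_ms, volume_mm3, n_lesions, included); ``clinical``
    carries one row per patient with ``score_field``.  In lesion-wise mode
    only included patients (≥1 surviving lesion) enter the correlation; in
    voxel-wise mode every patient contributes, zero volumes included.
    Patients without the score (e.g. no MSFC composite) always drop.

    Returns one row per threshold: mean volumes under both averaging
    conventions (all patients vs included only), Spearman r and p, the
    included-patient count, an ``estimable`` flag (≥ ``min_n`` patients and
    defined r) and a ``significant`` flag at ``alpha``.  A profile also
    reports how many thresholds would survive a Bonferroni correction across
    the grid — an extension beyond per-threshold testing, flagged as such.
    """
    if mode not in ("lesion", "voxel"):
        raise ValueError("mode must be 'lesion' or 'voxel'")
    merged = sweep.merge(
        clinical[["patient_id", score_field]], on="patient_id", how="inner"
    )
    merged = merged[pd.notna(merged[score_field])]
    thresholds = sorted(merged["threshold_ms"].unique())
    if not thresholds:
        raise ValueError("empty sweep/clinical intersection")
    rows = []
    for thr in thresholds:
        sub = merged[merged["threshold_ms"] == thr]
        use = sub[sub["included"]] if mode == "lesion" else sub
        n_inc = len(use)
        r = p = float("nan")
        estimable = n_inc >= min_n
        if estimable:
            res = spearman(use["volume_mm3"], use[score_field])
            r, p = res.r, res.p
            estimable = res.defined
        rows.append(
            {
                "threshold_ms": thr,
                "mode": mode,
                "score": score_field,
                "mean_volume_all_mm3": float(sub["volume_mm3"].mean()),
                "mean_volume_included_mm3": (
                    float(use["volume_mm3"].mean()) if n_inc else 0.0
                ),
                "spearman_r": r,
                "p_value": p,
                "n_included": n_inc,
                "estimable": estimable,
                "significant": bool(estimable and p < alpha),
            }
        )
    prof = pd.DataFrame(rows)
    m = int(prof["estimable"].sum())
    prof["bonferroni_significant"] = prof["estimable"] & (
        prof["p_value"] < (alpha / m if m else alpha)
    )
    return prof


def optimal_threshold(profile: pd.DataFrame) -> float | None:
    """Threshold with the largest |r| among significant points.

    Returns None when no threshold reaches significance; ties resolve to the
    lowest threshold (the one retaining the most lesion volume).
    """
    if profile.empty:
        raise ValueError("empty profile")
    sig = profile[profile["significant"]].sort_values("threshold_ms")
    if sig.empty:
        return None
    best_thr, best_abs = None, -1.0
    for _, row in sig.iterrows():
        a = abs(row["spearman_r"])
        if a > best_abs + 1e-15:
            best_abs, best_thr = a, float(row["threshold_ms"])
    return best_thr


def compare_group_t1(
    lesions: pd.DataFrame, cortex: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Welch unpaired t-tests on mean T1-RT between lesion classes.

    ``lesions`` is the per-lesion table; observations are lesion-level mean
    T1-RTs grouped by class.  If ``cortex`` (per-patient cortical means,
    column ``mean_ms``) is given, each lesion class is also tested against
    the cortex patient means.  Requires ≥ 2 observations per group.
    """
    groups: dict[str, np.ndarray] = {}
    for cls, sub in lesions.groupby("lesion_class"):
        groups[str(cls)] = sub["mean_t1_ms"].to_numpy(dtype=float)
    if cortex is not None and len(cortex):
        groups["cortex"] = cortex["mean_ms"].to_numpy(dtype=float)
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = groups[a], groups[b]
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError(f"group {a if len(xa) < 2 else b} has < 2 observations")
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "mean_a": float(xa.mean()),
                    "sd_a": float(xa.std(ddof=1)),
                    "mean_b": float(xb.mean()),
                    "sd_b": float(xb.std(ddof=1)),
                    "t": float(t),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def auxiliary_correlations(
    sweep: pd.DataFrame,
    clinical: pd.DataFrame,
    score_field: str = "edss",
) -> dict[str, pd.DataFrame]:
    """Secondary associations: lesion number vs score, and disease duration.

    Returns ``{"count_vs_score": ..., "duration": ...}``.  The first table
    gives, per threshold, the Spearman correlation between surviving lesion
    count and the score over included patients; the second correlates
    unthresholded (lowest-threshold) lesion count and cumulative volume with
    disease duration (column ``duration_y``).
    """
    merged = sweep.merge(clinical, on="patient_id", how="inner")
    rows = []
    for thr in sorted(merged["threshold_ms"].unique()):
        sub = merged[(merged["threshold_ms"] == thr) & merged["included"]]
        sub = sub[pd.notna(sub[score_field])]
        if len(sub) < 3:
            rows.append({"threshold_ms": thr, "spearman_r": float("nan"),
                         "p_value": float("nan"), "n": len(sub)})
            continue
        res = spearman(sub["n_lesions"], sub[score_field])
        rows.append({"threshold_ms": thr, "spearman_r": res.r,
                     "p_value": res.p, "n": res.n})
    count_vs_score = pd.DataFrame(rows)

    thr0 = sorted(merged["threshold_ms"].unique())[0]
    base = merged[merged["threshold_ms"] == thr0]
    base = base[pd.notna(base["duration_y"])]
    dur_rows = []
    for field, label in (("n_lesions", "lesion_count"), ("volume_mm3", "cumulative_volume")):
        if len(base) >= 3:
            res = spearman(base[field], base["duration_y"])
            dur_rows.append({"measure": label, "spearman_r": res.r,
                             "p_value": res.p, "n": res.n})
        else:
            dur_rows.append({"measure": label, "spearman_r": float("nan"),
                             "p_value": float("nan"), "n": len(base)})
    return {"count_vs_score": count_vs_score, "duration": pd.DataFrame(dur_rows)}
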