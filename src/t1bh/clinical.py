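"""Clinical disability scores: EDSS validation and the MSFC composite.

The MSFC used here substitutes the Symbol Digit Modalities Test (SDMT) for
the PASAT; the composite is the arithmetic mean of the three subtest
z-scores, MSFC = (z_9HPT + z_T25FW + z_SDMT) / 3.  Z-scores are computed
against an external reference population supplied by configuration, with
the standard orientations: higher SDMT is better (z on the raw score),
longer walk time is worse (sign-flipped z), and the 9-Hole Peg Test is
scored on the reciprocal of time.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePopulation",
    "zscore_subtest",
    "msfc_composite",
    "validate_edss",
    "validate_edss_series",
    "add_scores",
    "EDSS_GRID",
]

#: the EDSS ordinal grid: 0 to 10 in half-point steps
EDSS_GRID = tuple(np.arange(0.0, 10.5, 0.5))

SUBTESTS = ("sdmt", "t25fw", "9hpt")


@dataclass(frozen=True)
class ReferencePopulation:
    """Reference mean/SD per MSFC subtest.

    ``hpt9`` statistics are for the *reciprocal* of the 9-HPT time in 1/s,
    following the standard MSFC scoring convention.
    """

    sdmt_mean: float
    sdmt_sd: float
    t25fw_mean_s: float
    t25fw_sd_s: float
    hpt9_recip_mean: float
    hpt9_recip_sd: float

    def __post_init__(self) -> None:
        for name in ("sdmt_sd", "t25fw_sd_s", "hpt9_recip_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"reference {name} must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ReferencePopulation":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferencePopulation":
        return cls.from_dict(json.loads(Path(path).read_text()))


def zscore_subtest(raw: float, ref: ReferencePopulation, subtest: str) -> float:
    """Z-score one subtest raw value against the reference population.

    SDMT: z = (raw − mean) / sd.
    T25-FW: z = (mean − raw) / sd  (longer time → lower z).
    9-HPT: z = (1/raw − mean_recip) / sd_recip.
    """
    if subtest not in SUBTESTS:
        raise ValueError(f"unknown subtest {subtest!r}; expected one of {SUBTESTS}")
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return float("nan")
    if subtest == "sdmt":
        return (raw - ref.sdmt_mean) / ref.sdmt_sd
    if raw <= 0:
        raise ValueError(f"{subtest} time must be positive, got {raw}")
    if subtest == "t25fw":
        return (ref.t25fw_mean_s - raw) / ref.t25fw_sd_s
    return (1.0 / raw - ref.hpt9_recip_mean) / ref.hpt9_recip_sd


def msfc_composite(z_9hpt: float, z_t25fw: float, z_sdmt: float) -> float:
    """Arithmetic mean of the three subtest z-scores; NaN if any is missing."""
    zs = (z_9hpt, z_t25fw, z_sdmt)
    if any(z is None or math.isnan(z) for z in zs):
        return float("nan")
    return sum(zs) / 3.0


def validate_edss(value: float) -> float:
    """Accept an EDSS on the 0–10 half-point grid; reject anything else."""
    v = float(value)
    if not (0.0 <= v <= 10.0) or round(v * 2) != v * 2:
        raise ValueError(f"EDSS {value} is not on the 0–10 grid in 0.5 steps")
    return v


def validate_edss_series(edss: pd.Series) -> list[str]:
    """Return the patient ids (index values) with off-grid EDSS."""
    bad = []
    for pid, v in edss.items():
        try:
            validate_edss(v)
        except (ValueError, TypeError):
            bad.append(str(pid))
    return bad


def add_scores(clinical: pd.DataFrame, ref: ReferencePopulation) -> pd.DataFrame:
    """Attach z_sdmt, z_t25fw, z_9hpt and the MSFC composite to a clinical table.

    Expects columns ``sdmt``, ``t25fw_s``, ``hpt9_s``; patients missing any
    subtest get a missing composite and drop out of MSFC analyses.
    """
    out = clinical.copy()
    out["z_sdmt"] = [
        zscore_subtest(v, ref, "sdmt") if pd.notna(v) else float("nan")
        for v in out["sdmt"]
    ]
    out["z_t25fw"] = [
        zscore_subtest(v, ref, "t25fw") if pd.notna(v) else float("nan")
        for v in out["t25fw_s"]
    ]
    out["z_9hpt"] = [
        zscore_subtest(v, ref, "9hpt") if pd.notna(v) else float("nan")
        for v in out["hpt9_s"]
    ]
    out["msfc"] = [
        msfc_composite(a, b, c)
        for a, b, c in zip(out["z_9hpt"], out["z_t25fw"], out["z_sdmt"])
    ]
    return out
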