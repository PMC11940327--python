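"""Carotid artery blood flow from B-mode diameters and Doppler velocity.

Per-video mean diameter is the diastole-weighted average
``(systolic * 1/3) + (diastolic * 2/3)`` (the artery spends roughly two
thirds of the cardiac cycle near its diastolic calibre); per-artery
diameters from multiple videos are averaged, and volumetric flow is
cross-sectional area times the time-averaged mean velocity:

    CABF = pi * (d/2)^2 * TAMEAN * 60   [mL/min]

Input units are fixed: diameters in mm, TAMEAN in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "mean_diameter",
    "average_videos",
    "cabf",
    "FlowResult",
    "compute_flow",
    "process_carotid_table",
]

LATERALITY_MODES = ("mean", "left", "right", "sum")

#: mm^2 -> m^2 is 1e-6; m^3/s -> mL/min is 1e6 * 60
_ML_MIN_PER_M3_S = 6.0e7


def mean_diameter(systolic: float, diastolic: float) -> float:
    """Diastole-weighted mean diameter (mm): sys/3 + 2*dia/3."""
    if not (0 < diastolic <= systolic):
        raise ValidationError(
            f"require 0 < diastolic <= systolic, got ({systolic}, {diastolic})"
        )
    return systolic / 3.0 + 2.0 * diastolic / 3.0


def average_videos(diameters: Sequence[float] | Iterable[float]) -> float:
    """Arithmetic mean of per-video mean diameters for one artery (mm)."""
    diameters = list(diameters)
    if not diameters:
        raise ValidationError("at least one video measurement required")
    if any(d <= 0 for d in diameters):
        raise ValidationError("diameters must be positive")
    return float(np.mean(diameters))


def cabf(mean_diameter_mm: float, tamean_mps: float) -> float:
    """Volumetric carotid blood flow in mL/min.

    ``pi * (d/2)^2`` (area, converted mm -> m) times TAMEAN (m/s), scaled
    to mL/min.
    """
    if mean_diameter_mm <= 0 or tamean_mps <= 0:
        raise ValidationError("mean diameter and TAMEAN must be positive")
    radius_m = mean_diameter_mm / 2.0 * 1e-3
    area_m2 = np.pi * radius_m**2
    return float(area_m2 * tamean_mps * _ML_MIN_PER_M3_S)


@dataclass
class FlowResult:
    """Per-artery flow computation output."""

    mean_diameter: float  # mm
    csa: float  # mm^2
    cabf: float  # mL/min


def compute_flow(
    video_diameters: Sequence[tuple[float, float]], tamean_mps: float
) -> FlowResult:
    """Full per-artery chain: per-video mean diameters -> average -> flow."""
    per_video = [mean_diameter(s, d) for s, d in video_diameters]
    d_mm = average_videos(per_video)
    return FlowResult(
        mean_diameter=d_mm,
        csa=float(np.pi * (d_mm / 2.0) ** 2),
        cabf=cabf(d_mm, tamean_mps),
    )


def process_carotid_table(table: pd.DataFrame, laterality: str = "mean") -> pd.DataFrame:
    """Per-subject/visit CABF from a long table of video measurements.

    Expects columns ``subject, visit, side, video_idx, sys_diam_mm,
    dia_diam_mm, tamean_mps``. Per artery, per-video mean diameters are
    averaged and per-video TAMEAN values are averaged; per subject/visit
    the two arteries are combined according to ``laterality`` (default
    ``"mean"``; the aggregation choice is stamped into the output).
    """
    required = {
        "subject", "visit", "side", "sys_diam_mm", "dia_diam_mm", "tamean_mps",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"carotid table missing columns: {sorted(missing)}")
    if laterality not in LATERALITY_MODES:
        raise ValidationError(
            f"laterality must be one of {LATERALITY_MODES}, got {laterality!r}"
        )

    per_artery = []
    for (subject, visit, side), grp in table.groupby(["subject", "visit", "side"]):
        videos = list(zip(grp["sys_diam_mm"], grp["dia_diam_mm"]))
        res = compute_flow(videos, float(grp["tamean_mps"].mean()))
        per_artery.append(
            {
                "subject": subject,
                "visit": visit,
                "side": side,
                "n_videos": len(grp),
                "mean_diam_mm": res.mean_diameter,
                "csa_mm2": res.csa,
                "cabf_ml_min": res.cabf,
            }
        )
    arteries = pd.DataFrame(per_artery)

    rows = []
    for (subject, visit), grp in arteries.groupby(["subject", "visit"]):
        if laterality in ("left", "right"):
            sel = grp[grp["side"] == laterality]
            if sel.empty:
                continue
            value = float(sel["cabf_ml_min"].iloc[0])
        elif laterality == "sum":
            value = float(grp["cabf_ml_min"].sum())
        else:
            value = float(grp["cabf_ml_min"].mean())
        rows.append(
            {
                "subject": subject,
                "visit": visit,
                "laterality": laterality,
                "cabf_ml_min": value,
            }
        )
    return pd.DataFrame(rows)
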