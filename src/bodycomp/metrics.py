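"""Body-composition metrics: compartment areas, fatty muscle fraction, and
per-case agreement with reference analyses.

The fatty muscle fraction (FMF) is the share of skeletal-muscle-labeled
pixels whose native (unclipped) HU falls in an adipose window, a counting
statistic marking fatty muscle degeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import BACKGROUND, SAT, SM, VAT, CTSlice, CompartmentMask
from .quality_control import QCDecision

__all__ = [
    "FMFSpec",
    "UndefinedFMF",
    "BodyCompositionReport",
    "compartment_area",
    "fatty_muscle_fraction",
    "agreement",
    "aggregate_agreement",
]


class UndefinedFMF(ValueError):
    """FMF is undefined when no pixel is labeled skeletal muscle."""


@dataclass(frozen=True)
class FMFSpec:
    """Definition of the fatty-muscle HU window.

    The default [-190, -30] HU window is the established inter/intramuscular
    adipose range in CT body composition; the denominator is the full
    SM-labeled pixel count.
    """

    fat_hu_range: tuple[float, float] = (-190.0, -30.0)
    denominator: str = "all_muscle_pixels"

    def __post_init__(self):
        if self.fat_hu_range[0] >= self.fat_hu_range[1]:
            raise ValueError("fat HU range must have lower < upper")


@dataclass
class BodyCompositionReport:
    """Per-patient result of the end-to-end pipeline."""

    patient_id: str
    z_index: int | None
    z_mm: float | None
    area_sm_cm2: float | None
    area_vat_cm2: float | None
    area_sat_cm2: float | None
    fmf: float | None
    qc: QCDecision
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for a in (self.area_sm_cm2, self.area_vat_cm2, self.area_sat_cm2):
            if a is not None and a < 0:
                raise ValueError("areas must be non-negative")
        if self.fmf is not None and not (0 <= self.fmf <= 1):
            raise ValueError("FMF must lie in [0, 1]")

    def to_dict(self):
        return {
            "patient_id": self.patient_id,
            "z_index": self.z_index,
            "z_mm": self.z_mm,
            "area_sm_cm2": self.area_sm_cm2,
            "area_vat_cm2": self.area_vat_cm2,
            "area_sat_cm2": self.area_sat_cm2,
            "fmf": self.fmf,
            **self.qc.to_dict(),
            "provenance": self.provenance,
        }


def compartment_area(mask: CompartmentMask, class_code: int) -> float:
    """Area of one compartment in cm² (pixel count x pixel area / 100)."""
    if class_code not in (BACKGROUND, SM, VAT, SAT):
        raise ValueError(f"unknown class code {class_code}")
    return float((mask.labels == class_code).sum() * mask.pixel_area_mm2() / 100.0)


def fatty_muscle_fraction(sl: CTSlice, mask: CompartmentMask,
                          spec: FMFSpec = FMFSpec()) -> float:
    """Share of SM-labeled pixels whose native HU lies in the adipose window."""
    if sl.pixels.shape != mask.labels.shape:
        raise ValueError("slice and mask shapes differ")
    sm = mask.labels == SM
    n_sm = int(sm.sum())
    if n_sm == 0:
        raise UndefinedFMF("no skeletal-muscle pixels; FMF undefined")
    lo, hi = spec.fat_hu_range
    in_fat = (sl.pixels >= lo) & (sl.pixels <= hi) & sm
    return float(in_fat.sum() / n_sm)


_METRICS = ("area_sm_cm2", "area_vat_cm2", "area_sat_cm2", "fmf")


def agreement(auto: BodyCompositionReport, manual: dict) -> dict:
    """Absolute and relative deviations of automated vs reference values.

    ``manual`` maps metric names (``area_sm_cm2`` ... ``fmf``) to reference
    values. Relative deviation is ``|auto - manual| / manual * 100`` percent,
    undefined (None) when the reference is 0 or either value is missing.
    """
    if "patient_id" in manual and manual["patient_id"] != auto.patient_id:
        raise ValueError(
            f"case mismatch: {auto.patient_id!r} vs {manual['patient_id']!r}")
    out = {}
    for m in _METRICS:
        a = getattr(auto, m)
        r = manual.get(m)
        if a is None or r is None:
            out[m] = {"abs": None, "rel_pct": None}
            continue
        d = abs(a - r)
        out[m] = {"abs": float(d),
                  "rel_pct": float(d / r * 100.0) if r != 0 else None}
    return out


def aggregate_agreement(per_case: list) -> dict:
    """Mean ± SD of per-case deviations (missing values skipped)."""
    out = {}
    for m in _METRICS:
        for kind in ("abs", "rel_pct"):
            vals = [c[m][kind] for c in per_case
                    if c[m][kind] is not None]
            key = f"{m}_{kind}"
            if vals:
                out[key] = {"mean": float(np.mean(vals)),
                            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                            "n": len(vals)}
            else:
                out[key] = {"mean": None, "sd": None, "n": 0}
    return out
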