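"""ATP-production accounting from lactate secretion and oxygen consumption.

Fermentative glycolysis yields 2 ATP and 2 lactate per glucose, so the
glycolytic ATP production rate equals the lactate secretion rate (LSR,
ATP:lactate = 1).  Respiratory ATP production is derived from the
leak-corrected oxygen consumption rate (basal OCR minus OCR under
Antimycin A) times an ATP yield of 24 ATP per O2.  Rates are normalised
per microgram of cellular protein.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Rate",
    "UnitError",
    "LactateTimecourse",
    "WellMeasurement",
    "RegressionResult",
    "PartitionSummary",
    "lactate_secretion_rate",
    "glycolytic_atp_rate",
    "respiratory_atp_rate",
    "partition_summary",
    "ATP_PER_O2",
]

logger = logging.getLogger(__name__)

#: ATP yield per molecule of O2 consumed (oxidative phosphorylation, full coupling)
ATP_PER_O2 = 24.0


class UnitError(ValueError):
    """A quantity carries a unit this module cannot reconcile."""


# conversion factors to the base unit pmol/min/ug for per-protein molar rates
_RATE_UNITS = {
    "pmol/min/ug": 1.0,
    "nmol/h/ug": 1000.0 / 60.0,
    "nmol/min/ug": 1000.0,
    "pmol/h/ug": 1.0 / 60.0,
}


@dataclass(frozen=True)
class Rate:
    """A per-protein molar rate with an explicit unit.

    Only the handful of units produced by the supported instruments are
    recognised; any other unit string raises ``UnitError`` rather than being
    silently passed through.
    """

    value: float
    unit: str = "pmol/min/ug"

    def __post_init__(self) -> None:
        if self.unit not in _RATE_UNITS:
            raise UnitError(f"unknown rate unit {self.unit!r}; known: {sorted(_RATE_UNITS)}")
        if not math.isfinite(self.value):
            raise ValueError("rate value must be finite")

    def to(self, unit: str) -> "Rate":
        if unit not in _RATE_UNITS:
            raise UnitError(f"unknown rate unit {unit!r}; known: {sorted(_RATE_UNITS)}")
        return Rate(self.value * _RATE_UNITS[self.unit] / _RATE_UNITS[unit], unit)


@dataclass(frozen=True)
class LactateTimecourse:
    """Lactate accumulation in spent medium (nmol per well) over hours."""

    times_h: np.ndarray
    lactate_nmol: np.ndarray
    protein_ug: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        y = np.asarray(self.lactate_nmol, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "lactate_nmol", y)
        if t.size != y.size:
            raise ValueError("times and lactate arrays must have equal length")
        if t.size < 2:
            raise ValueError("a lactate time course needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("lactate amounts must be >= 0")
        if self.protein_ug <= 0:
            raise ValueError("protein mass must be > 0")


@dataclass(frozen=True)
class WellMeasurement:
    """Per-well respirometry: basal OCR and OCR under Antimycin A (pmol O2/min)."""

    ocr_basal: float
    ocr_antimycin: float
    protein_ug: float
    ecar_basal: float | None = None
    ecar_max: float | None = None

    def __post_init__(self) -> None:
        if self.ocr_basal < 0 or self.ocr_antimycin < 0:
            raise ValueError("OCR values must be >= 0")
        if self.protein_ug <= 0:
            raise ValueError("protein mass must be > 0")


@dataclass(frozen=True)
class RegressionResult:
    rate: Rate
    slope: float  # nmol/h per well
    intercept: float
    r_squared: float
    stderr: float
    negative_flagged: bool = False


@dataclass(frozen=True)
class PartitionSummary:
    glycolytic_fraction: float
    ratio: float  # glycolytic / respiratory
    fold_change: float | None = None


def lactate_secretion_rate(tc: LactateTimecourse) -> RegressionResult:
    """OLS slope of lactate vs time, normalised per microgram protein.

    A negative slope is physically suspect (lactate should accumulate) and
    is flagged but returned as-is.
    """
    res = stats.linregress(tc.times_h, tc.lactate_nmol)
    negative = res.slope < 0
    if negative:
        logger.warning("negative lactate secretion slope %.3g nmol/h", res.slope)
    return RegressionResult(
        rate=Rate(res.slope / tc.protein_ug, "nmol/h/ug"),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr / tc.protein_ug),
        negative_flagged=negative,
    )


def glycolytic_atp_rate(lsr: Rate) -> Rate:
    """Glycolytic ATP production rate = lactate secretion rate (ATP:lactate 1:1)."""
    if lsr.value < 0:
        raise ValueError("lactate secretion rate must be >= 0 for ATP accounting")
    return Rate(lsr.value, lsr.unit)


def respiratory_atp_rate(w: WellMeasurement, atp_per_o2: float = ATP_PER_O2) -> Rate:
    """Leak-corrected OCR times the ATP:O2 yield, per microgram protein.

    When the Antimycin-A (leak) OCR exceeds the basal OCR — as happens in
    noisy wells — the corrected OCR clamps to zero with a warning.
    """
    corrected = w.ocr_basal - w.ocr_antimycin
    if corrected < 0:
        logger.warning(
            "Antimycin-A OCR %.3g exceeds basal %.3g; clamping corrected OCR to 0",
            w.ocr_antimycin, w.ocr_basal,
        )
        corrected = 0.0
    return Rate(corrected * atp_per_o2 / w.protein_ug, "pmol/min/ug")


def partition_summary(
    glyc: Rate, resp: Rate, reference: tuple[Rate, Rate] | None = None
) -> PartitionSummary:
    """Glycolytic fraction and glycolysis:respiration ratio of ATP production.

    Rates are reconciled to a common unit first.  With a reference
    (glycolytic, respiratory) pair, the fold-change of the ratio relative to
    the reference condition is also reported.
    """
    g = glyc.to("pmol/min/ug").value
    r = resp.to("pmol/min/ug").value
    if g < 0 or r < 0:
        raise ValueError("ATP production rates must be >= 0")
    if g + r == 0:
        raise ValueError("glycolytic fraction undefined: both rates are zero")
    ratio = g / r if r > 0 else math.inf
    fold = None
    if reference is not None:
        ref = partition_summary(*reference)
        if not math.isfinite(ref.ratio) or ref.ratio == 0:
            raise ValueError("reference ratio is zero or undefined; fold-change unavailable")
        fold = ratio / ref.ratio
    return PartitionSummary(glycolytic_fraction=g / (g + r), ratio=ratio, fold_change=fold)
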