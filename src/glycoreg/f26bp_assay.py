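"""F26BP quantification via the PPi-PFK coupled enzyme assay.

The pyrophosphate-dependent PFK reaction rate responds hyperbolically to
F26BP in the assay well.  Because no F26BP standard exists, samples are
quantified by serial dilution: reaction rates (NADH consumption slopes at
340 nm) are normalised to controls, a dose-response curve is fitted over
the dilution series with its top and bottom constrained to the positive and
negative control rates, and the dilution achieving the half-maximal rate is
equated to 5 nM F26BP in the well.  The sample's F26BP content follows from
that calibration and the dilution bookkeeping back to the extract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticTrace",
    "DilutionSeries",
    "LinearSlopeFit",
    "Ec50Fit",
    "F26bpQuant",
    "longest_linear_slope",
    "relative_rates",
    "fit_constrained_ec50",
    "f26bp_concentration",
    "CALIBRATION_NM",
]

logger = logging.getLogger(__name__)

#: assay-well F26BP concentration assigned to the half-maximal dilution (nM)
CALIBRATION_NM = 5.0


@dataclass(frozen=True)
class KineticTrace:
    """Plate-reader absorbance trace (NADH consumption at 340 nm)."""

    times_s: np.ndarray
    a340: np.ndarray
    label: str = ""
    well: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.a340, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "a340", y)
        if t.size != y.size or t.size < 2:
            raise ValueError("trace needs matching time/absorbance arrays of length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    @property
    def cadence(self) -> float:
        """Nominal (median) sampling interval, seconds."""
        return float(np.median(np.diff(self.times_s)))


@dataclass(frozen=True)
class DilutionSeries:
    """(dilution factor, relative rate) pairs plus the constraining controls."""

    dilution_factors: np.ndarray
    relative_rates: np.ndarray
    positive_rate: float = 1.0  # relative rate at saturating F26BP (curve top)
    negative_rate: float = 0.0  # relative rate without F26BP (curve bottom)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.dilution_factors, dtype=float)
        r = np.asarray(self.relative_rates, dtype=float)
        object.__setattr__(self, "dilution_factors", d)
        object.__setattr__(self, "relative_rates", r)
        if d.size != r.size or d.size < 2:
            raise ValueError("dilution series needs matching arrays of length >= 2")
        if np.any(d < 1):
            raise ValueError("dilution factors must be >= 1")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dilution factors must be strictly increasing")
        if self.positive_rate <= self.negative_rate:
            raise ValueError("positive control rate must exceed negative control rate")


@dataclass(frozen=True)
class LinearSlopeFit:
    slope: float  # absorbance per second
    intercept: float
    r_squared: float
    window: tuple[float, float]  # (t_start, t_end) seconds
    flagged: bool = False  # True when no window met the linearity criterion


@dataclass(frozen=True)
class Ec50Fit:
    ec50_dilution: float
    top: float
    bottom: float
    hill: float
    rss: float
    converged: bool
    extrapolated: bool  # EC50 outside the sampled dilution range


@dataclass(frozen=True)
class F26bpQuant:
    pmol_per_ug: float
    extract_conc_nm: float
    low_confidence: bool


def _window_ols(S: dict[str, np.ndarray], i: int, j: int) -> tuple[float, float, float]:
    """OLS slope/intercept/R^2 on samples [i, j] inclusive, from prefix sums."""
    n = j - i + 1
    st = S["t"][j + 1] - S["t"][i]
    sy = S["y"][j + 1] - S["y"][i]
    stt = S["tt"][j + 1] - S["tt"][i]
    sty = S["ty"][j + 1] - S["ty"][i]
    syy = S["yy"][j + 1] - S["yy"][i]
    var_t = stt - st * st / n
    cov = sty - st * sy / n
    var_y = syy - sy * sy / n
    slope = cov / var_t
    intercept = (sy - slope * st) / n
    if var_y <= 0:
        r2 = 1.0 if abs(cov) < 1e-300 else 0.0  # exactly flat signal
    else:
        r2 = cov * cov / (var_t * var_y)
    return slope, intercept, r2


def longest_linear_slope(
    trace: KineticTrace, min_span: float, r2_min: float = 0.99
) -> LinearSlopeFit:
    """Slope of the longest linear region of an absorbance trace.

    Scans every contiguous sample window spanning at least ``min_span``
    seconds and returns the OLS slope of the longest window whose R^2 meets
    the linearity criterion (ties broken by earliest start).  When no
    window qualifies — e.g. a flat noisy control — the best-R^2 window of
    exactly the minimum span is returned, flagged.
    """
    t, y = trace.times_s, trace.a340
    if trace.duration < min_span:
        raise ValueError(f"trace spans {trace.duration:.1f} s < min_span {min_span:.1f} s")
    S = {
        "t": np.concatenate(([0.0], np.cumsum(t))),
        "y": np.concatenate(([0.0], np.cumsum(y))),
        "tt": np.concatenate(([0.0], np.cumsum(t * t))),
        "ty": np.concatenate(([0.0], np.cumsum(t * y))),
        "yy": np.concatenate(([0.0], np.cumsum(y * y))),
    }
    n = t.size
    # j_min[i]: smallest end index giving span >= min_span from start i
    j_min = np.searchsorted(t, t + min_span, side="left")
    best = None  # (span, -t_start, i, j)
    fallback = None  # (r2, -t_start, i, j) over minimal windows
    for i in range(n):
        j0 = j_min[i]
        if j0 >= n:
            break
        slope, _, r2 = _window_ols(S, i, j0)
        if fallback is None or r2 > fallback[0] + 1e-15:
            fallback = (r2, -t[i], i, j0)
        for j in range(j0, n):
            _, _, r2 = _window_ols(S, i, j)
            if r2 >= r2_min:
                key = (t[j] - t[i], -t[i])
                if best is None or key > best[:2]:
                    best = (*key, i, j)
    if best is not None:
        i, j = best[2], best[3]
        flagged = False
    else:
        i, j = fallback[2], fallback[3]
        flagged = True
        logger.warning(
            "no window of >= %.0f s met R^2 >= %.3g; returning best minimal window (R^2=%.3g)",
            min_span, r2_min, fallback[0],
        )
    slope, intercept, r2 = _window_ols(S, i, j)
    return LinearSlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        window=(float(t[i]), float(t[j])),
        flagged=flagged,
    )


def relative_rates(slopes: dict[str, float], control_label: str) -> dict[str, float]:
    """Each |slope| divided by the |slope| of the control sample."""
    if control_label not in slopes:
        raise ValueError(f"control {control_label!r} not present in slopes")
    control = abs(slopes[control_label])
    if control == 0:
        raise ValueError("control slope is zero; relative rates undefined")
    return {label: abs(s) / control for label, s in slopes.items()}


def _logistic(log_d: np.ndarray, log_ec50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_d - log_ec50)))


def fit_constrained_ec50(series: DilutionSeries, fix_hill: float | None = None) -> Ec50Fit:
    """Constrained dose-response fit over a serial dilution.

    Fits relative_rate = bottom + (top - bottom)/(1 + (d/EC50)^h) in
    log-dilution space with top and bottom fixed to the control rates.  The
    Hill slope h is free by default or fixed via ``fix_hill``.  An EC50
    outside the sampled dilution range is flagged as extrapolated.
    """
    d = series.dilution_factors
    r = series.relative_rates
    if d.size < 4:
        raise ValueError("EC50 fitting needs at least 4 dilution points")
    top, bottom = series.positive_rate, series.negative_rate
    log_d = np.log(d)
    # crude start: dilution where the response crosses half-max
    half = (top + bottom) / 2.0
    idx = int(np.argmin(np.abs(r - half)))
    p0_log_ec50 = log_d[idx]
    try:
        if fix_hill is None:
            popt, _ = curve_fit(
                lambda x, le, h: _logistic(x, le, h, top, bottom),
                log_d, r, p0=[p0_log_ec50, 1.0], maxfev=10000,
            )
            log_ec50, hill = popt
        else:
            popt, _ = curve_fit(
                lambda x, le: _logistic(x, le, fix_hill, top, bottom),
                log_d, r, p0=[p0_log_ec50], maxfev=10000,
            )
            log_ec50, hill = popt[0], fix_hill
        converged = True
    except RuntimeError as exc:
        logger.warning("EC50 fit failed to converge: %s", exc)
        log_ec50, hill, converged = p0_log_ec50, fix_hill or 1.0, False
    resid = r - _logistic(log_d, log_ec50, hill, top, bottom)
    ec50 = float(np.exp(log_ec50))
    extrapolated = not (d[0] <= ec50 <= d[-1])
    if extrapolated:
        logger.warning("EC50 dilution %.3g outside sampled range [%.3g, %.3g]", ec50, d[0], d[-1])
    return Ec50Fit(
        ec50_dilution=ec50,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        rss=float(np.sum(resid**2)),
        converged=converged,
        extrapolated=extrapolated,
    )


def f26bp_concentration(
    fit: Ec50Fit,
    extract_volume_ul: float,
    protein_ug: float,
    well_dilution_to_extract: float,
) -> F26bpQuant:
    """Back-calculate sample F26BP content from the fitted EC50 dilution.

    The assay well at the EC50 dilution contains 5 nM F26BP by calibration,
    so the undiluted extract concentration is
    5 nM x EC50_dilution x well_dilution_to_extract; multiplied by the
    extract volume and normalised per microgram protein.
    """
    if not fit.converged:
        raise ValueError("cannot quantify from a non-converged EC50 fit")
    if extract_volume_ul <= 0 or protein_ug <= 0 or well_dilution_to_extract <= 0:
        raise ValueError("volumes, protein and dilution factors must be > 0")
    extract_nm = CALIBRATION_NM * fit.ec50_dilution * well_dilution_to_extract
    # nM * uL = 1e-9 mol/L * 1e-6 L = 1e-15 mol = 1e-3 pmol
    pmol = extract_nm * extract_volume_ul * 1e-3
    return F26bpQuant(
        pmol_per_ug=pmol / protein_ug,
        extract_conc_nm=extract_nm,
        low_confidence=fit.extrapolated,
    )
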