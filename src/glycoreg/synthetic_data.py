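"""Seeded synthetic-data generators with embedded ground truth.

Each generator is the measurable inverse of exactly one analysis stage:
NADH traces for linear-slope extraction, dilution series for the
constrained EC50 fit, and lactate/OCR well sets for the ATP-production
accounting.  Noise is additive Gaussian on the observed signal (the
plate-reader regime), never on the underlying parameters, and every
generator is bit-reproducible under a fixed seed.  Ground truth travels in
the returned objects' ``meta``/``truth`` attributes so round-trip tests
never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_flux_accounting import LactateTimecourse, WellMeasurement
from .f26bp_assay import CALIBRATION_NM, DilutionSeries, KineticTrace

__all__ = [
    "GeneratorConfig",
    "gen_nadh_trace",
    "gen_dilution_series",
    "gen_flux_wells",
]

#: lactate sampling schedule (hours) of the secretion-rate protocol
LACTATE_TIMES_H = (2.0, 4.0, 8.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs: seed, per-signal noise scale, read cadence, truth mapping."""

    seed: int = 0
    noise_sd: float = 0.0
    cadence_s: float = 6.0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cadence_s <= 0:
            raise ValueError("cadence must be > 0")


def gen_nadh_trace(
    true_rate: float,
    duration: float = 120.0,
    cadence: float = 6.0,
    noise_sd: float = 0.0,
    depletion_floor: float = 0.05,
    a0: float = 0.93,
    seed: int = 0,
    label: str = "",
) -> KineticTrace:
    """Linear-then-saturating NADH consumption trace.

    The absorbance falls linearly at ``true_rate`` (A340/s, negative for
    consumption) until it reaches the depletion knee, then relaxes
    exponentially toward ``depletion_floor`` with the slope continuous at
    the changepoint.  Gaussian noise of ``noise_sd`` is added to every read.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + cadence / 2, cadence)
    clean = a0 + true_rate * t
    changepoint = np.inf
    if true_rate < 0:
        # knee one e-folding scale above the floor keeps slope continuous
        knee = depletion_floor + (a0 - depletion_floor) * 0.1
        t_c = (knee - a0) / true_rate
        if t_c < duration:
            changepoint = t_c
            tau = (knee - depletion_floor) / (-true_rate)
            post = t > t_c
            clean[post] = depletion_floor + (knee - depletion_floor) * np.exp(
                -(t[post] - t_c) / tau
            )
    noisy = clean + rng.normal(0.0, noise_sd, size=t.size)
    return KineticTrace(
        times_s=t,
        a340=noisy,
        label=label,
        meta={
            "true_rate": true_rate,
            "changepoint_s": changepoint,
            "noise_sd": noise_sd,
            "seed": seed,
            "a0": a0,
        },
    )


def gen_dilution_series(
    true_well_conc_at_unit_dilution_nm: float,
    factors: np.ndarray | None = None,
    top: float = 1.0,
    bottom: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Dilution series whose relative rates follow the calibrated response.

    The assay well at dilution d contains c0/d F26BP; the PPi-PFK rate
    responds hyperbolically with half-maximum at the 5 nM calibration
    point, so in dilution space the response is a Hill-1 logistic with
    EC50 dilution = c0 / 5 nM.
    """
    c0 = true_well_conc_at_unit_dilution_nm
    if c0 <= 0:
        raise ValueError("true well concentration must be > 0")
    if factors is None:
        factors = np.logspace(0, 4, 9)  # 1 .. 10^4, half-decade steps
    factors = np.asarray(factors, dtype=float)
    rng = np.random.default_rng(seed)
    conc = c0 / factors
    clean = bottom + (top - bottom) * conc / (conc + CALIBRATION_NM)
    noisy = clean + rng.normal(0.0, noise_sd, size=factors.size)
    return DilutionSeries(
        dilution_factors=factors,
        relative_rates=noisy,
        positive_rate=top,
        negative_rate=bottom,
        meta={
            "true_well_conc_nm": c0,
            "true_ec50_dilution": c0 / CALIBRATION_NM,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def gen_flux_wells(
    true_glyc_fraction: float,
    true_total_atp: float = 30.0,  # pmol ATP/min/ug
    leak_fraction: float = 0.2,
    n_wells: int = 6,
    noise_sd: float = 0.0,  # relative (fraction of each clean signal)
    protein_ug: float = 20.0,
    seed: int = 0,
) -> tuple[list[LactateTimecourse], list[WellMeasurement], dict]:
    """Paired lactate time courses and respirometry wells at a known partition.

    Glycolytic ATP (= lactate secretion, ATP:lactate 1) and respiratory ATP
    (= 24 x leak-corrected OCR) are split according to
    ``true_glyc_fraction`` of ``true_total_atp``; the Antimycin-A OCR is
    ``leak_fraction`` of basal.  Gaussian noise of ``noise_sd`` (relative)
    perturbs lactate reads and both OCR phases.
    """
    if not 0.0 <= true_glyc_fraction <= 1.0:
        raise ValueError("true_glyc_fraction must be in [0, 1]")
    if not 0.0 <= leak_fraction < 1.0:
        raise ValueError("leak_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    glyc_rate = true_glyc_fraction * true_total_atp  # pmol/min/ug
    resp_rate = (1.0 - true_glyc_fraction) * true_total_atp
    lsr_nmol_h_ug = glyc_rate * 60.0 / 1000.0  # pmol/min -> nmol/h
    corrected_ocr = resp_rate * protein_ug / 24.0  # pmol O2/min per well
    basal = corrected_ocr / (1.0 - leak_fraction)
    antimycin = basal * leak_fraction
    times = np.array(LACTATE_TIMES_H)
    courses, wells = [], []
    for _ in range(n_wells):
        clean_lac = lsr_nmol_h_ug * protein_ug * times
        scale = np.where(clean_lac > 0, clean_lac, lsr_nmol_h_ug * protein_ug * times[-1])
        lac = clean_lac + rng.normal(0.0, noise_sd, size=times.size) * np.maximum(scale, 1e-12)
        courses.append(
            LactateTimecourse(times_h=times, lactate_nmol=np.clip(lac, 0.0, None),
                              protein_ug=protein_ug)
        )
        ocr_b = basal * (1.0 + rng.normal(0.0, noise_sd))
        ocr_a = antimycin * (1.0 + rng.normal(0.0, noise_sd))
        wells.append(
            WellMeasurement(ocr_basal=max(ocr_b, 0.0), ocr_antimycin=max(ocr_a, 0.0),
                            protein_ug=protein_ug)
        )
    truth = {
        "true_glyc_fraction": true_glyc_fraction,
        "true_total_atp": true_total_atp,
        "true_lsr_nmol_h_ug": lsr_nmol_h_ug,
        "true_resp_atp": resp_rate,
        "leak_fraction": leak_fraction,
        "seed": seed,
    }
    return courses, wells, truth
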