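"""PFKFB3 regulator screen and reconstituted-glycolysis simulation.

PFKFB3's kinase activity sets F26BP levels; glycolytic intermediates (PEP,
2PG, 3PG) and TCA-cycle acids (citrate, cis-aconitate) inhibit it, while
inorganic phosphate activates it.  The screen analysis normalises measured
activities to no-regulator and no-substrate controls, and single-regulator
titrations are summarised by a Hill-1 inhibition fit.  The coupled-assay
simulation reproduces the two-phase reconstituted experiment: PFKFB3 is
pre-incubated to accumulate F26BP, then PFK (platelet isoform) is added and
its flux read out as NADH consumption (2 NADH per FBP through the excess
aldolase/TPI/G3PDH coupling system).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .f26bp_assay import KineticTrace
from .kinetic_core import MetaboliteState, MwcPfkParams, mwc_pfk_rate

__all__ = [
    "Pfkfb3Params",
    "ScreenPlate",
    "Ic50Fit",
    "pfkfb3_kinase_rate",
    "screen_fold_change",
    "fit_ic50_hill1",
    "simulate_coupled_assay",
    "NADH_EXTINCTION",
]

logger = logging.getLogger(__name__)

#: NADH extinction x nominal pathlength at 340 nm, 1/M (6.22 / mM / cm x 1 cm)
NADH_EXTINCTION = 6220.0


@dataclass(frozen=True)
class Pfkfb3Params:
    """PFKFB3 kinase kinetics with multiplicative Hill-1 effector terms.

    Each inhibitor I contributes 1/(1 + [I]/K_i); each activator A
    contributes (1 + fold x [A]/K_a)/(1 + [A]/K_a), saturating at
    ``activation_fold``.  The K values are synthetic-data settings chosen to
    reproduce the qualitative potency ordering of the screen (PEP most
    potent, then 2PG/cis-aconitate, then citrate and 3PG); they are not
    measured constants.  The bisphosphatase activity of kinase-dominant
    PFKFB3 is retained as a parameter but defaults to zero.
    """

    vmax: float = 4e-10
    km_f6p: float = 3e-5
    km_atp: float = 1e-4
    inhibitors: dict[str, float] = field(
        default_factory=lambda: {
            "PEP": 1e-4,
            "2PG": 5e-4,
            "3PG": 2e-3,
            "citrate": 1e-3,
            "cis-aconitate": 5e-4,
            "ADP": 8e-4,
        }
    )
    activators: dict[str, float] = field(default_factory=lambda: {"Pi": 1e-3})
    activation_fold: float = 2.0
    phosphatase_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, val in (
            ("vmax", self.vmax), ("km_f6p", self.km_f6p), ("km_atp", self.km_atp),
            ("activation_fold", self.activation_fold),
        ):
            if val <= 0 or not math.isfinite(val):
                raise ValueError(f"{name} must be finite and > 0")
        for table in (self.inhibitors, self.activators):
            for eff, k in table.items():
                if k <= 0:
                    raise ValueError(f"effector constant for {eff!r} must be > 0")
        if self.phosphatase_rate < 0:
            raise ValueError("phosphatase_rate must be >= 0")


@dataclass(frozen=True)
class ScreenPlate:
    """Measured activities for a panel of candidate regulators plus controls."""

    conditions: list[tuple[str, float, float]]  # (regulator, concentration M, activity)
    control: float  # no-regulator activity
    negative: float  # no-F6P activity (background)

    def __post_init__(self) -> None:
        if self.control <= self.negative:
            raise ValueError("no-regulator control must exceed the no-F6P background")


@dataclass(frozen=True)
class Ic50Fit:
    ic50: float  # molar
    stderr: float
    rss: float
    converged: bool
    non_inhibitor: bool  # folds never drop meaningfully below 1
    out_of_range: bool  # IC50 outside the 10x-extended sampled range


def pfkfb3_kinase_rate(
    f6p: float, atp: float, effectors: dict[str, float], p: Pfkfb3Params
) -> float:
    """PFKFB3 kinase flux (M/s): F6P + ATP -> F26BP + ADP with Hill-1 modulation."""
    if f6p < 0 or atp < 0 or any(c < 0 for c in effectors.values()):
        raise ValueError("concentrations must be >= 0")
    v = p.vmax * (f6p / (p.km_f6p + f6p)) * (atp / (p.km_atp + atp)) if f6p > 0 and atp > 0 else 0.0
    for name, conc in effectors.items():
        if name in p.inhibitors:
            v /= 1.0 + conc / p.inhibitors[name]
        elif name in p.activators:
            x = conc / p.activators[name]
            v *= (1.0 + p.activation_fold * x) / (1.0 + x)
        else:
            raise ValueError(f"unknown effector {name!r}; known: "
                             f"{sorted(p.inhibitors) + sorted(p.activators)}")
    return v


def screen_fold_change(plate: ScreenPlate) -> list[dict[str, float]]:
    """Background-subtracted activity fold-change per screened regulator.

    fold = (measured - negative) / (control - negative); the no-regulator
    control is 1 by construction and a fully inhibitory regulator gives 0.
    """
    span = plate.control - plate.negative
    return [
        {
            "regulator": reg,
            "concentration": conc,
            "fold": (measured - plate.negative) / span,
        }
        for reg, conc, measured in plate.conditions
    ]


def fit_ic50_hill1(concs: np.ndarray, folds: np.ndarray) -> Ic50Fit:
    """Least-squares Hill-1 inhibition fit: fold = 1/(1 + c/IC50).

    Top and bottom are fixed at 1 and 0 and the Hill coefficient at 1.  A
    titration whose folds never fall below 0.8 is flagged as a
    non-inhibitor; an IC50 outside ten times the sampled concentration
    range is flagged as out of range.
    """
    c = np.asarray(concs, dtype=float)
    f = np.asarray(folds, dtype=float)
    if c.size < 4:
        raise ValueError("IC50 fitting needs at least 4 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any((f < 0) | (f > 1.2)):
        raise ValueError("folds must lie in [0, 1.2]")
    non_inhibitor = bool(np.min(f) > 0.8)
    log_c = np.log(c)
    p0 = float(np.median(log_c))
    try:
        popt, pcov = curve_fit(
            lambda x, log_ic50: 1.0 / (1.0 + np.exp(x - log_ic50)),
            log_c, f, p0=[p0], maxfev=10000,
        )
        converged = True
        log_ic50 = float(popt[0])
        se_log = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("inf")
    except RuntimeError:
        converged, log_ic50, se_log = False, p0, float("inf")
    ic50 = math.exp(log_ic50)
    resid = f - 1.0 / (1.0 + c / ic50)
    out_of_range = not (c.min() / 10.0 <= ic50 <= c.max() * 10.0)
    if non_inhibitor or out_of_range:
        logger.warning("IC50 %.3g M flagged (non_inhibitor=%s, out_of_range=%s)",
                       ic50, non_inhibitor, out_of_range)
    return Ic50Fit(
        ic50=ic50,
        stderr=ic50 * se_log,  # delta method on the log-scale parameter
        rss=float(np.sum(resid**2)),
        converged=converged,
        non_inhibitor=non_inhibitor,
        out_of_range=out_of_range,
    )


#: reconstituted-assay starting composition (M)
ASSAY_F6P = 2e-4
ASSAY_ATP = 3e-3
ASSAY_ADP = 3e-4
ASSAY_PI = 1e-3
ASSAY_NADH = 1.5e-4

#: PFK effectors recognised in the coupled-assay effector mapping
_PFK_EFFECTORS = {"citrate"}


def _assay_pfk_state(f6p: float, f26bp: float, citrate: float) -> MetaboliteState:
    return MetaboliteState(
        f6p=max(f6p, 0.0), fbp=0.0, atp=ASSAY_ATP, adp=ASSAY_ADP, amp=0.0,
        pi=ASSAY_PI, f26bp=max(f26bp, 0.0), citrate=citrate, glucose_ext=0.0,
    )


def simulate_coupled_assay(
    pfkfb3: Pfkfb3Params | None,
    pfk: MwcPfkParams | None = None,
    effectors: dict[str, float] | None = None,
    preincubation: float = 1200.0,
    duration: float = 3600.0,
    cadence: float = 13.0,
    f6p0: float = ASSAY_F6P,
    nadh0: float = ASSAY_NADH,
) -> KineticTrace:
    """Two-phase reconstituted-glycolysis simulation returning an A340 trace.

    Phase 1 (pre-incubation): PFKFB3 alone converts F6P to F26BP.  Phase 2:
    PFK is added; each FBP it produces is instantly converted by the excess
    coupling enzymes, consuming 2 NADH, while PFKFB3 keeps running.  ATP,
    ADP and Pi are treated as non-depleting at assay scale.  The returned
    trace covers phase 2 at the plate-reader cadence; metadata records the
    final composition and whether NADH was depleted.
    """
    # PFKP defaults: weaker ADP activation than the cellular lumped PFK, so
    # the 10:1 ATP/ADP assay composition leaves PFKP strongly ATP-inhibited
    # unless F26BP relieves it
    pfk = pfk if pfk is not None else MwcPfkParams(vmax=2e-8, k_act_adp=3e-4)
    effectors = dict(effectors or {})
    citrate = effectors.get("citrate", 0.0)
    pfkfb3_effectors = effectors if pfkfb3 is not None else {}
    if pfkfb3 is not None:
        for name in pfkfb3_effectors:
            if name not in pfkfb3.inhibitors and name not in pfkfb3.activators:
                raise ValueError(f"unknown effector {name!r} for PFKFB3")
    elif any(name not in _PFK_EFFECTORS for name in effectors):
        unknown = sorted(set(effectors) - _PFK_EFFECTORS)
        logger.info("effectors %s have no target without PFKFB3", unknown)

    def kinase(f6p: float) -> float:
        if pfkfb3 is None:
            return 0.0
        return pfkfb3_kinase_rate(f6p, ASSAY_ATP, pfkfb3_effectors, pfkfb3)

    # phase 1: y = [f6p, f26bp]
    def rhs1(t, y):
        vk = kinase(y[0])
        vp_ase = (pfkfb3.phosphatase_rate if pfkfb3 is not None else 0.0) * max(y[1], 0.0)
        return [-vk + vp_ase, vk - vp_ase]

    sol1 = solve_ivp(rhs1, (0.0, preincubation), [f6p0, 0.0], method="LSODA",
                     rtol=1e-9, atol=1e-15)
    if not sol1.success:
        raise RuntimeError(f"pre-incubation integration failed: {sol1.message}")
    f6p1, f26bp1 = sol1.y[:, -1]

    # phase 2: y = [f6p, f26bp, nadh, cum_fbp]; coupling is instantaneous
    def rhs2(t, y):
        f6p, f26bp, nadh = y[0], y[1], y[2]
        vk = kinase(f6p)
        vp_ase = (pfkfb3.phosphatase_rate if pfkfb3 is not None else 0.0) * max(f26bp, 0.0)
        vp = mwc_pfk_rate(_assay_pfk_state(f6p, f26bp, citrate), pfk)
        readout = vp if nadh > 0 else 0.0
        return [-vk - vp + vp_ase, vk - vp_ase, -2.0 * readout, vp]

    def depleted(t, y):
        return y[2]
    depleted.terminal = True
    depleted.direction = -1

    t_eval = np.arange(0.0, duration + 1e-9, cadence)
    sol2 = solve_ivp(
        rhs2, (0.0, duration), [f6p1, f26bp1, nadh0, 0.0], method="LSODA",
        rtol=1e-9, atol=1e-15, t_eval=t_eval, events=depleted,
    )
    if not sol2.success:
        raise RuntimeError(f"assay integration failed: {sol2.message}")
    times = sol2.t
    nadh = np.clip(sol2.y[2], 0.0, None)
    depleted_flag = bool(sol2.t_events[0].size)
    if depleted_flag:
        # pad the remaining reads at the depletion floor
        t_dep = sol2.t_events[0][0]
        tail = t_eval[t_eval > times[-1] + 1e-9]
        times = np.concatenate([times, tail])
        nadh = np.concatenate([nadh, np.zeros(tail.size)])
        logger.warning("NADH depleted at t=%.0f s; trace floored thereafter", t_dep)
    return KineticTrace(
        times_s=times,
        a340=nadh * NADH_EXTINCTION,
        label="+PFKFB3" if pfkfb3 is not None else "-PFKFB3",
        meta={
            "depleted": depleted_flag,
            "f26bp_after_preincubation": float(f26bp1),
            "f6p_final": float(sol2.y[0, -1]),
            "f26bp_final": float(sol2.y[1, -1]),
            "cum_fbp": float(sol2.y[3, -1]),
            "nadh_final": float(nadh[-1]),
            "nadh0": float(nadh0),
            "f6p0": float(f6p0),
        },
    )
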