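"""Reduced kinetic model of glycolysis coupled to respiration.

The network lumps glycolysis into three stages around its allosteric
control point, phosphofructokinase (PFK), and represents respiration as a
single reversible ATP synthase reaction:

    upper:    GLC + ATP -> F6P + ADP            (lumped HK/PGI)
    PFK:      F6P + ATP -> FBP + ADP            (MWC rate law)
    lower:    FBP + 4 ADP + 2 Pi -> 2 LAC + 4 ATP  (lumped GAPDH..LDH)
    synthase: ADP + Pi -> ATP                   (reversible MM, product inh.)
    ATPase:   ATP -> ADP + Pi                   (lumped cellular demand)
    AK:       2 ADP <-> ATP + AMP               (adenylate kinase, mass action)

F6P, FBP, ATP, ADP, AMP and Pi are dynamic; fructose-2,6-bisphosphate
(F26BP), citrate and external glucose are clamped control variables with
zero derivative.  Net glycolytic ATP yield is 2 per glucose (fermentation),
so at steady state glycolytic ATP flux equals twice the PFK flux.

All quantities are SI: molar concentrations, fluxes in M/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "MetaboliteState",
    "AtpSynthaseParams",
    "MwcPfkParams",
    "ModelParams",
    "atp_synthase_rate",
    "mwc_pfk_rate",
    "auxiliary_rates",
    "system_derivatives",
]

#: order of the dynamic species in the ODE state vector
DYNAMIC_SPECIES = ("f6p", "fbp", "atp", "adp", "amp", "pi")


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite concentration or parameter: {v!r}")


@dataclass(frozen=True)
class MetaboliteState:
    """Concentrations (M) of the modelled pools.

    ``f26bp``, ``citrate`` and ``glucose_ext`` are clamped effectors: they
    enter the rate laws but carry zero derivative, so the adenine and
    phosphorus conservation laws over the dynamic species are exact.
    """

    f6p: float
    fbp: float
    atp: float
    adp: float
    amp: float
    pi: float
    f26bp: float = 0.0
    citrate: float = 0.0
    glucose_ext: float = 5e-3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _check_finite(v)
            if v < -1e-12:
                raise ValueError(f"negative concentration {f.name}={v}")

    @property
    def adenine_total(self) -> float:
        return self.atp + self.adp + self.amp

    @property
    def phosphorus_total(self) -> float:
        """Total phosphorus over dynamic pools (Pi + 3 ATP + 2 ADP + AMP + F6P + 2 FBP)."""
        return self.pi + 3 * self.atp + 2 * self.adp + self.amp + self.f6p + 2 * self.fbp

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in DYNAMIC_SPECIES], dtype=float)

    def with_vector(self, y: np.ndarray) -> "MetaboliteState":
        return replace(self, **{k: float(max(v, 0.0)) for k, v in zip(DYNAMIC_SPECIES, y)})


def _require_positive(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        _check_finite(v)
        if v <= 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {v}")


@dataclass(frozen=True)
class AtpSynthaseParams:
    """Reversible Michaelis-Menten ATP synthase with competitive product inhibition.

    The default ``km_atp`` of 1000 M effectively removes ATP competitive
    inhibition from the denominator; it is kept verbatim as the model's
    operating convention rather than "corrected" to a physiological value.
    ``keq`` is the mass-action equilibrium constant [ATP]/([ADP][Pi]) in 1/M.
    """

    vmax: float
    km_atp: float = 1000.0
    km_adp: float = 1e-5
    km_pi: float = 1e-5
    keq: float = 1e6

    def __post_init__(self) -> None:
        if self.vmax < 0 or not math.isfinite(self.vmax):
            raise ValueError("vmax must be finite and >= 0")
        _require_positive(self, ("km_atp", "km_adp", "km_pi", "keq"))


@dataclass(frozen=True)
class MwcPfkParams:
    """Monod-Wyman-Changeux rate law for tetrameric PFK.

    Exclusive R-state substrate binding (c = 0).  Activators (F26BP, ADP,
    AMP, Pi) and inhibitors (ATP, citrate) shift the R<->T equilibrium by
    scaling the allosteric constant L with (1 + x/K)^n factors.
    """

    vmax: float
    n_sites: int = 4
    l0: float = 4000.0
    k_r_f6p: float = 1e-4
    k_cat_atp: float = 1e-4
    k_act_f26bp: float = 5e-7
    k_act_adp: float = 3e-5
    k_act_amp: float = 1e-4
    k_act_pi: float = 2e-3
    k_inh_atp: float = 1e-3
    k_inh_citrate: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.vmax < 0 or not math.isfinite(self.vmax):
            raise ValueError("vmax must be finite and >= 0")
        _require_positive(
            self,
            (
                "l0",
                "k_r_f6p",
                "k_cat_atp",
                "k_act_f26bp",
                "k_act_adp",
                "k_act_amp",
                "k_act_pi",
                "k_inh_atp",
                "k_inh_citrate",
            ),
        )


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the reduced network.

    The lumped-stage constants (upper, lower, ATPase, AK) are modelling
    conveniences of the reduced network, not literature values.  The
    ``ki_upper_f6p`` product-inhibition constant on the upper stage stands
    in for hexokinase inhibition by hexose phosphates and is what makes the
    F6P pool self-limiting.
    """

    pfk: MwcPfkParams
    synthase: AtpSynthaseParams
    vmax_upper: float = 2.5e-3
    km_upper_glc: float = 1e-3
    km_upper_atp: float = 1e-4
    ki_upper_f6p: float = 1e-5
    vmax_lower: float = 2.5e-3
    km_lower_fbp: float = 5e-5
    km_lower_adp: float = 1e-5
    km_lower_pi: float = 1e-4
    vmax_atpase: float = 2e-4
    km_atpase_atp: float = 1e-9
    vmax_ak: float = 1e5  # second-order, 1/(M s): rapid near-equilibrium AK
    keq_ak: float = 1.0
    adenine_total: float = 5e-3
    phosphorus_total: float = 1.905e-2

    def __post_init__(self) -> None:
        for name in ("vmax_upper", "vmax_lower"):
            v = getattr(self, name)
            _check_finite(v)
            if v < 0:
                raise ValueError(f"ModelParams.{name} must be >= 0, got {v}")
        _require_positive(
            self,
            (
                "km_upper_glc",
                "km_upper_atp",
                "ki_upper_f6p",
                "km_lower_fbp",
                "km_lower_adp",
                "km_lower_pi",
                "vmax_atpase",
                "km_atpase_atp",
                "vmax_ak",
                "keq_ak",
                "adenine_total",
                "phosphorus_total",
            ),
        )
        capacity = 2 * self.pfk.vmax + self.synthase.vmax
        if self.vmax_atpase >= capacity:
            raise ValueError(
                f"ATP demand vmax_atpase={self.vmax_atpase} must lie below total "
                f"production capacity 2*Vmax_PFK + Vmax_synthase = {capacity}"
            )

    @classmethod
    def default(cls) -> "ModelParams":
        """Half-glycolytic / half-respiratory capacity split at 1 mM/s total."""
        from .steady_state_sim import configure_capacity_split

        base = cls(pfk=MwcPfkParams(vmax=2.5e-4), synthase=AtpSynthaseParams(vmax=5e-4))
        return configure_capacity_split(1e-3, 0.5, 0.2, base)


def atp_synthase_rate(state: MetaboliteState, p: AtpSynthaseParams) -> float:
    """Net ATP synthase flux (M/s), positive when [ADP][Pi] > [ATP]/Keq."""
    atp, adp, pi = state.atp, state.adp, state.pi
    _check_finite(atp, adp, pi)
    a, b = adp / p.km_adp, pi / p.km_pi
    denom = 1.0 + atp / p.km_atp + a + b + a * b
    return (p.vmax / (p.km_adp * p.km_pi)) * (adp * pi - atp / p.keq) / denom


def mwc_pfk_rate(state: MetaboliteState, p: MwcPfkParams) -> float:
    """MWC PFK flux (M/s).

    v = Vmax * [ATP]/(K_cat+[ATP]) * s(1+s)^(n-1) / ((1+s)^n + L_eff)
    with s = [F6P]/K_R and L_eff = L0 * (prod_i (1+I/K_i) / prod_a (1+A/K_a))^n.

    The allosteric fraction is evaluated in log space so that large effector
    ratios (e.g. saturating F26BP) cannot overflow (1+x)^n.
    """
    _check_finite(state.f6p, state.atp, state.adp, state.amp, state.pi, state.f26bp, state.citrate)
    if state.f6p <= 0:
        return 0.0
    n = p.n_sites
    log_l_eff = math.log(p.l0) + n * (
        math.log1p(state.atp / p.k_inh_atp)
        + math.log1p(state.citrate / p.k_inh_citrate)
        - math.log1p(state.f26bp / p.k_act_f26bp)
        - math.log1p(state.adp / p.k_act_adp)
        - math.log1p(state.amp / p.k_act_amp)
        - math.log1p(state.pi / p.k_act_pi)
    )
    s = state.f6p / p.k_r_f6p
    log1s = math.log1p(s)
    # s(1+s)^(n-1) / ((1+s)^n + L_eff) = [s/(1+s)] / (1 + exp(log L_eff - n log(1+s)))
    allosteric = (s / (1.0 + s)) / (1.0 + math.exp(log_l_eff - n * log1s))
    cat = state.atp / (p.k_cat_atp + state.atp)
    return p.vmax * cat * allosteric


def _mm(x: float, km: float) -> float:
    return x / (km + x) if x > 0 else 0.0


def auxiliary_rates(state: MetaboliteState, p: ModelParams) -> dict[str, float]:
    """Lumped-stage fluxes: upper, lower, ATPase (all >= 0) and signed AK."""
    upper = (
        p.vmax_upper
        * _mm(state.glucose_ext, p.km_upper_glc)
        * _mm(state.atp, p.km_upper_atp)
        / (1.0 + state.f6p / p.ki_upper_f6p)
    )
    lower = (
        p.vmax_lower
        * _mm(state.fbp, p.km_lower_fbp)
        * _mm(state.adp, p.km_lower_adp)
        * _mm(state.pi, p.km_lower_pi)
    )
    atpase = p.vmax_atpase * _mm(state.atp, p.km_atpase_atp)
    ak = p.vmax_ak * (state.adp**2 - state.atp * state.amp / p.keq_ak)
    return {"upper": upper, "lower": lower, "atpase": atpase, "ak": ak}


def system_derivatives(state: MetaboliteState, p: ModelParams) -> dict[str, float]:
    """Time derivatives (M/s) of the dynamic species.

    Stoichiometry guarantees d(ATP)+d(ADP)+d(AMP) = 0 and conservation of
    total phosphorus (Pi + 3 ATP + 2 ADP + AMP + F6P + 2 FBP) exactly.
    """
    v_pfk = mwc_pfk_rate(state, p.pfk)
    v_syn = atp_synthase_rate(state, p.synthase)
    aux = auxiliary_rates(state, p)
    u, l, a, k = aux["upper"], aux["lower"], aux["atpase"], aux["ak"]
    return {
        "f6p": u - v_pfk,
        "fbp": v_pfk - l,
        "atp": -u - v_pfk + 4 * l + v_syn - a + k,
        "adp": u + v_pfk - 4 * l - v_syn + a - 2 * k,
        "amp": k,
        "pi": -2 * l - v_syn + a,
    }


def rhs_vector(t: float, y: np.ndarray, template: MetaboliteState, p: ModelParams) -> np.ndarray:
    """ODE right-hand side over the DYNAMIC_SPECIES vector (clamps from template)."""
    state = template.with_vector(y)
    d = system_derivatives(state, p)
    return np.array([d[k] for k in DYNAMIC_SPECIES])
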