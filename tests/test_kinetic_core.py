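"""Rate laws and stoichiometry of the reduced glycolysis/respiration network."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from glycoreg.kinetic_core import (
    AtpSynthaseParams,
    MetaboliteState,
    ModelParams,
    MwcPfkParams,
    atp_synthase_rate,
    auxiliary_rates,
    mwc_pfk_rate,
    system_derivatives,
)


def state(**kw) -> MetaboliteState:
    defaults = dict(f6p=5e-5, fbp=5e-5, atp=4e-3, adp=9e-4, amp=1e-4, pi=5e-3)
    defaults.update(kw)
    return MetaboliteState(**defaults)


class TestAtpSynthase:
    def test_zero_substrates_give_zero_flux(self):
        p = AtpSynthaseParams(vmax=1e-3)
        assert atp_synthase_rate(state(atp=0.0, adp=0.0, pi=1e-3), p) == 0.0

    def test_net_rate_vanishes_at_mass_action_equilibrium(self):
        # [ATP]/([ADP][Pi]) = Keq = 1e6 => numerator is (numerically) zero
        p = AtpSynthaseParams(vmax=1e-3)
        s = state(adp=1e-4, pi=1e-3, atp=1e6 * 1e-4 * 1e-3)
        assert abs(atp_synthase_rate(s, p)) < 1e-11 * p.vmax

    def test_quarter_vmax_at_km_substrates(self):
        # [ATP]=0, [ADP]=KM_ADP, [Pi]=KM_Pi: denominator 1+0+1+1+1 = 4
        p = AtpSynthaseParams(vmax=1e-3)
        rate = atp_synthase_rate(state(atp=0.0, adp=1e-5, pi=1e-5), p)
        assert rate == pytest.approx(p.vmax / 4.0, rel=1e-12)

    def test_sign_change_exactly_at_keq(self):
        p = AtpSynthaseParams(vmax=1e-3)
        adp, pi = 2e-4, 3e-3

        def net(atp):
            return atp_synthase_rate(state(adp=adp, pi=pi, atp=atp), p)

        atp_star = brentq(net, 1e-9, 10.0, xtol=1e-18, rtol=1e-15)
        assert atp_star / (adp * pi) == pytest.approx(p.keq, rel=1e-9)
        assert net(atp_star * 0.99) > 0 > net(atp_star * 1.01)

    def test_non_finite_input_rejected(self):
        p = AtpSynthaseParams(vmax=1e-3)
        with pytest.raises(ValueError):
            MetaboliteState(f6p=0, fbp=0, atp=float("nan"), adp=0, amp=0, pi=0)
        with pytest.raises(ValueError):
            state(adp=-1e-3)

    def test_km_atp_default_is_printed_value(self):
        # the 1000 M ATP Michaelis constant is part of the model definition
        assert AtpSynthaseParams(vmax=1.0).km_atp == 1000.0


def naive_mwc(st: MetaboliteState, p: MwcPfkParams) -> float:
    """Term-by-term R/T-state polynomial evaluation (no log-space guard)."""
    n = p.n_sites
    t_poly = p.l0 * ((1 + st.atp / p.k_inh_atp) * (1 + st.citrate / p.k_inh_citrate)) ** n
    r_scale = (
        (1 + st.f26bp / p.k_act_f26bp)
        * (1 + st.adp / p.k_act_adp)
        * (1 + st.amp / p.k_act_amp)
        * (1 + st.pi / p.k_act_pi)
    ) ** n
    s = st.f6p / p.k_r_f6p
    cat = st.atp / (p.k_cat_atp + st.atp)
    return p.vmax * cat * s * (1 + s) ** (n - 1) / ((1 + s) ** n + t_poly / r_scale)


class TestMwcPfk:
    def test_no_substrate_no_flux(self):
        assert mwc_pfk_rate(state(f6p=0.0), MwcPfkParams(vmax=1e-4)) == 0.0

    def test_saturating_f26bp_reduces_to_michaelis_menten(self):
        p = MwcPfkParams(vmax=1e-4)
        st = state(f26bp=10.0)  # L_eff -> 0
        s = st.f6p / p.k_r_f6p
        expected = p.vmax * st.atp / (p.k_cat_atp + st.atp) * s / (1 + s)
        assert mwc_pfk_rate(st, p) == pytest.approx(expected, rel=1e-6)

    def test_matches_polynomial_oracle(self, random_state_factory):
        p = MwcPfkParams(vmax=1e-4)
        rng = np.random.default_rng(7)
        for _ in range(50):
            st = random_state_factory(rng)
            assert mwc_pfk_rate(st, p) == pytest.approx(naive_mwc(st, p), rel=1e-12)

    def test_huge_substrate_does_not_overflow(self):
        p = MwcPfkParams(vmax=1e-4)
        st = state(f6p=1e120)
        v = mwc_pfk_rate(st, p)
        assert math.isfinite(v)
        assert v == pytest.approx(p.vmax * st.atp / (p.k_cat_atp + st.atp), rel=1e-6)

    @pytest.mark.parametrize("effector,sign", [
        ("f26bp", +1), ("adp", +1), ("amp", +1), ("pi", +1),
        ("citrate", -1),
    ])
    def test_monotone_in_each_effector(self, effector, sign):
        p = MwcPfkParams(vmax=1e-4)
        grid = np.logspace(-8, -2, 25)
        rates = [mwc_pfk_rate(state(**{effector: c}), p) for c in grid]
        diffs = sign * np.diff(rates)
        assert np.all(diffs >= -1e-20)

    def test_atp_inhibits_once_catalytic_site_saturated(self):
        # above the catalytic K, with activators modest, T-state
        # stabilisation by ATP dominates the rate
        p = MwcPfkParams(vmax=1e-4)
        grid = np.logspace(-3, -1, 20)
        rates = [mwc_pfk_rate(state(atp=c, adp=1e-5, amp=1e-6, pi=1e-3), p) for c in grid]
        assert np.all(np.diff(rates) <= 1e-20)

    def test_bounded_by_vmax(self, random_state_factory):
        p = MwcPfkParams(vmax=1e-4)
        rng = np.random.default_rng(11)
        for _ in range(100):
            v = mwc_pfk_rate(random_state_factory(rng), p)
            assert 0.0 <= v <= p.vmax


class TestAuxiliaryRates:
    def test_zero_substrates_zero_rates(self, base_params):
        st = MetaboliteState(f6p=0, fbp=0, atp=0, adp=0, amp=0, pi=0, glucose_ext=0)
        rates = auxiliary_rates(st, base_params)
        assert all(r == 0.0 for r in rates.values())

    def test_adenylate_kinase_equilibrium(self, base_params):
        # [ADP]^2 = [ATP][AMP]/Keq_AK => zero net AK flux
        st = state(atp=4e-3, amp=1e-4, adp=math.sqrt(4e-3 * 1e-4 / base_params.keq_ak))
        assert abs(auxiliary_rates(st, base_params)["ak"]) < 1e-12 * base_params.vmax_ak * st.adp**2

    def test_atpase_saturates(self, base_params):
        st = state(atp=5e-3)  # >> km_atpase_atp
        atpase = auxiliary_rates(st, base_params)["atpase"]
        assert atpase == pytest.approx(base_params.vmax_atpase, rel=1e-3)


# reduced network stoichiometry: rows = dynamic species, cols = reactions
# (upper, pfk, lower, synthase, atpase, ak)
STOICH = {
    "f6p": (+1, -1, 0, 0, 0, 0),
    "fbp": (0, +1, -1, 0, 0, 0),
    "atp": (-1, -1, +4, +1, -1, +1),
    "adp": (+1, +1, -4, -1, +1, -2),
    "amp": (0, 0, 0, 0, 0, +1),
    "pi": (0, 0, -2, -1, +1, 0),
}


class TestSystemDerivatives:
    def test_adenine_and_phosphorus_conserved_pointwise(self, base_params, random_state_factory):
        rng = np.random.default_rng(3)
        for _ in range(100):
            st = random_state_factory(rng)
            d = system_derivatives(st, base_params)
            rate_scale = max(abs(v) for v in d.values()) + 1e-30
            assert abs(d["atp"] + d["adp"] + d["amp"]) < 1e-10 * rate_scale
            phos = d["pi"] + 3 * d["atp"] + 2 * d["adp"] + d["amp"] + d["f6p"] + 2 * d["fbp"]
            assert abs(phos) < 1e-10 * rate_scale

    def test_matches_hand_stoichiometry(self, base_params):
        st = state()
        p = base_params
        # independent flux evaluation
        u = (
            p.vmax_upper
            * (st.glucose_ext / (p.km_upper_glc + st.glucose_ext))
            * (st.atp / (p.km_upper_atp + st.atp))
            / (1 + st.f6p / p.ki_upper_f6p)
        )
        v = naive_mwc(st, p.pfk)
        low = (
            p.vmax_lower
            * (st.fbp / (p.km_lower_fbp + st.fbp))
            * (st.adp / (p.km_lower_adp + st.adp))
            * (st.pi / (p.km_lower_pi + st.pi))
        )
        syn = atp_synthase_rate(st, p.synthase)
        atpase = p.vmax_atpase * st.atp / (p.km_atpase_atp + st.atp)
        ak = p.vmax_ak * (st.adp**2 - st.atp * st.amp / p.keq_ak)
        fluxes = (u, v, low, syn, atpase, ak)
        d = system_derivatives(st, p)
        for species, coeffs in STOICH.items():
            expected = sum(c * f for c, f in zip(coeffs, fluxes))
            assert d[species] == pytest.approx(expected, rel=1e-9), species


class TestValidation:
    def test_demand_above_capacity_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            ModelParams(
                pfk=MwcPfkParams(vmax=1e-5),
                synthase=AtpSynthaseParams(vmax=1e-5),
                vmax_atpase=1e-3,
            )

    def test_adenine_total_property(self):
        st = state()
        assert st.adenine_total == pytest.approx(st.atp + st.adp + st.amp)

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValueError):
            MwcPfkParams(vmax=1e-4, l0=-1.0)
        with pytest.raises(ValueError):
            AtpSynthaseParams(vmax=1e-3, km_adp=0.0)
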