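"""Shared fixtures: model parameter sets and the algebraic steady-state oracle."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import root

from glycoreg.kinetic_core import (
    AtpSynthaseParams,
    MetaboliteState,
    ModelParams,
    MwcPfkParams,
    system_derivatives,
)


@pytest.fixture()
def base_params() -> ModelParams:
    return ModelParams(pfk=MwcPfkParams(vmax=2.5e-4), synthase=AtpSynthaseParams(vmax=5e-4))


@pytest.fixture()
def random_state_factory():
    """Seeded generator of valid metabolite states spanning the working ranges."""

    def make(rng: np.random.Generator) -> MetaboliteState:
        return MetaboliteState(
            f6p=10 ** rng.uniform(-7, -3),
            fbp=10 ** rng.uniform(-7, -3),
            atp=10 ** rng.uniform(-5, -2),
            adp=10 ** rng.uniform(-7, -3),
            amp=10 ** rng.uniform(-9, -4),
            pi=10 ** rng.uniform(-5, -2),
            f26bp=10 ** rng.uniform(-9, -4),
            citrate=10 ** rng.uniform(-6, -3),
        )

    return make


def steady_state_by_root(p: ModelParams, start: MetaboliteState, perturb: float = 1.01):
    """Independent steady-state solve: algebraic root of the derivative system.

    Unknowns are log concentrations of (F6P, FBP, ADP, AMP); ATP and Pi are
    eliminated through the adenine and phosphorus conservation laws, so the
    solution lies exactly on the conserved manifold of ``start``.  Returns
    the six concentrations in state-vector order.
    """
    A = start.adenine_total
    P = start.phosphorus_total
    scale = np.array(
        [
            max(p.pfk.vmax, p.vmax_atpase),
            max(p.pfk.vmax, p.vmax_atpase),
            p.vmax_atpase,
            p.vmax_ak * start.atp * max(start.amp, 1e-12),
        ]
    )

    def eqs(z):
        f6p, fbp, adp, amp = np.exp(z)
        atp = A - adp - amp
        pi = P - 3 * atp - 2 * adp - amp - f6p - 2 * fbp
        if atp <= 0 or pi <= 0:
            return np.full(4, 1e6)
        st = replace(start, f6p=f6p, fbp=fbp, atp=atp, adp=adp, amp=amp, pi=pi)
        d = system_derivatives(st, p)
        return np.array([d["f6p"], d["fbp"], d["adp"], d["amp"]]) / scale

    z0 = np.log(np.array([start.f6p, start.fbp, start.adp, start.amp]) * perturb)
    sol = root(eqs, z0, method="hybr", options={"xtol": 1e-13})
    assert sol.success, f"root solve failed: {sol.message}"
    f6p, fbp, adp, amp = np.exp(sol.x)
    atp = A - adp - amp
    pi = P - 3 * atp - 2 * adp - amp - f6p - 2 * fbp
    return np.array([f6p, fbp, atp, adp, amp, pi])
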