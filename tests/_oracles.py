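"""Independent brute-force oracles used by the test suite.

These integrate explicit mass-action ODE systems to steady state; they share no
code with the package's reduced/equilibrium solvers.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root


def monomer_mass_action_steady_state(
    Kd, KS, kcat, kp, Etot, Stot, dose, *, stiff_scale=1e8, t_end=200.0
):
    """Steady state of the explicit 6-species scheme E,S,ES,EI,ESI,P.

    Binding steps use elementary constants fast enough (off-rates
    ``stiff_scale`` times the catalytic scale) that the rapid-equilibrium
    reduction is exact to well below 1e-6.  The inhibitor is clamped at
    ``dose``.  The system is integrated for an initial guess and the steady
    state is then polished with a Newton solve of the full mass-action
    equations plus the two moiety conservation laws.  Returns (E, S).
    """
    k_scale = stiff_scale * max(kcat, kp)
    kSn = k_scale
    kSp = kSn / KS
    kIn = k_scale
    kIp = kIn / Kd

    def fluxes(y):
        E, S, ES, EI, ESI, P = y
        return (
            kSp * E * S - kSn * ES,       # E + S <-> ES
            kIp * E * dose - kIn * EI,    # E + I <-> EI
            kIp * ES * dose - kIn * ESI,  # ES + I <-> ESI
            kSp * EI * S - kSn * ESI,     # EI + S <-> ESI
            kcat * ES,                    # ES -> E + P
            kp * P,                       # P -> S
        )

    def rhs(_, y):
        v_es, v_ei, v_esi_1, v_esi_2, v_cat, v_p = fluxes(y)
        return [
            -v_es - v_ei + v_cat,
            -v_es - v_esi_2 + v_p,
            v_es - v_esi_1 - v_cat,
            v_ei - v_esi_2,
            v_esi_1 + v_esi_2,
            v_cat - v_p,
        ]

    y0 = [Etot, Stot, 0.0, 0.0, 0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=1e-10, atol=1e-12)
    assert sol.success, sol.message

    scale = max(Etot, Stot)

    def residual(y):
        d = rhs(0.0, y)
        E, S, ES, EI, ESI, P = y
        return [
            d[2] / k_scale, d[3] / k_scale, d[4] / k_scale, d[5],
            (E + ES + EI + ESI - Etot) / scale,
            (S + ES + ESI + P - Stot) / scale,
        ]

    polished = root(residual, sol.y[:, -1], method="hybr")
    assert np.max(np.abs(residual(polished.x))) < 1e-9
    y = polished.x
    assert np.all(y > -1e-9 * scale)
    return y[0], y[1]


def dimer_mass_action_steady_state(
    Rtot, I, Kdim, KdI, f, g, *, kon=100.0, kond=10.0, t_end=200.0
):
    """Relax the full five-species dimer scheme to steady state (I clamped).

    Rate constants are chosen so every equilibrium ratio matches the
    statistical-factor bookkeeping of the reduced model; the relaxation path is
    independent of the package's one-dimensional conservation solve.
    Returns concentrations [R, RI, RR, RRI, IRRI].
    """

    def rhs(_, y):
        R, RI, RR, RRI, IRRI = y
        v_dim = kond * R * R - kond * Kdim * RR
        v_ri = kon * I * R - kon * KdI * RI
        v_rri_i = 2.0 * kon * I * RR - kon * (KdI / f) * RRI
        v_rri_d = kond * RI * R - kond * (Kdim / (2.0 * f)) * RRI
        v_irri_i = kon * I * RRI - 2.0 * kon * (KdI / (f * g)) * IRRI
        v_irri_d = kond * RI * RI - kond * (Kdim / (f * f * g)) * IRRI
        return [
            -2.0 * v_dim - v_ri - v_rri_d,
            v_ri - v_rri_d - 2.0 * v_irri_d,
            v_dim - v_rri_i,
            v_rri_i + v_rri_d - v_irri_i,
            v_irri_i + v_irri_d,
        ]

    y0 = [Rtot, 0.0, 0.0, 0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=1e-12, atol=1e-13)
    assert sol.success, sol.message
    y = sol.y[:, -1]
    assert np.max(np.abs(rhs(0.0, y))) < 1e-8 * Rtot
    return y
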