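"""Rate laws and single-liver-unit FFA/TAG kinetics.

A liver unit (LU) is a two-compartment system: the sinusoidal blood space,
perfused with plasma at Poiseuille flows, exchanges free fatty acids (FFA)
with the hepatocyte compartment, which takes FFA up, oxidizes it, esterifies
it into the TAG storage pool, hydrolyses TAG back and exports TAG as VLDL.
State variables: sinusoidal FFA, cellular FFA and cellular TAG (all mM, TAG
counted in FFA equivalents), plus the fraction ``eta`` of intact hepatocytes
which scales every cellular flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import LUMetabolicParams, SinusoidGeometry

__all__ = [
    "LUState",
    "flux_vector",
    "sinusoid_flow",
    "diurnal_release_rate",
    "lu_metabolic_rhs",
    "solve_lu_metabolic_steady_state",
]


@dataclass
class LUState:
    """Concentration state of one liver unit (mM; eta dimensionless)."""

    ffa_sin: float
    ffa_cell: float
    tag: float
    eta: float = 1.0

    def __post_init__(self):
        if min(self.ffa_sin, self.ffa_cell, self.tag) < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")


def sinusoid_flow(g: SinusoidGeometry) -> tuple[float, float]:
    """Arterial and venous volumetric flows per sinusoid volume (min^-1).

    Poiseuille's law for the average sinusoid:
    ``v = pi * r_s**4 / (8 * viscosity * l_s * omega_s) * dp``.
    With the default geometry and dp = 0.2 each flow is 10 min^-1, i.e. the
    unit is perfused with one LU volume of blood per minute at a vascular
    volume fraction of 0.1.
    """
    omega_um3 = g.omega_s * 1e15  # L -> µm^3
    coef = math.pi * g.r_s**4 / (8.0 * g.viscosity * g.l_s * omega_um3)
    return coef * g.dp_a, coef * g.dp_v


def diurnal_release_rate(t, f) -> np.ndarray | float:
    """Adipose FFA release rate (mM/min) at time ``t`` (minutes).

    ``v_at(t) = (vmax + vmin)/2 + (vmax - vmin)/2 * cos(2*pi*t/period)``:
    maximal at t = 0, minimal half a period later, mean (vmax + vmin)/2.
    """
    t = np.asarray(t, dtype=float)
    value = f.mean + 0.5 * (f.vat_max - f.vat_min) * np.cos(2.0 * np.pi * t / f.period)
    return value if value.ndim else float(value)


def flux_vector(state: LUState, p: LUMetabolicParams) -> dict[str, float]:
    """The six cellular rate laws, per LU volume (mM/min).

    ``v_uptake`` is the gradient-driven exchange with the sinusoid and may be
    negative (net efflux) when cellular FFA exceeds sinusoidal FFA; all other
    fluxes are non-negative.  Multiply by 100 to express in µmol/100 mL/min.
    """
    f = state.ffa_cell
    return {
        "v_uptake": p.k_u * (state.ffa_sin - f),
        "v_beta": p.k_beta * f,
        "v_plusTAG": p.k_plusTAG * f * (f / p.ffa_crit_syn) ** 2,
        "v_minusTAG": p.k_minusTAG * state.tag,
        "v_VLDL": p.k_VLDL * state.tag,
        "v_denovo": p.v_denovo,
    }


def lu_metabolic_rhs(state: LUState, ffa_plasma: float, p: LUMetabolicParams,
                     g: SinusoidGeometry, eta_on_vldl: bool = False) -> tuple[float, float, float]:
    """Time derivatives of (ffa_sin, ffa_cell, tag) in mM/min at fixed eta.

    The sinusoid receives plasma at the arterial flow, drains at the venous
    flow, and loses the eta-scaled uptake flux amplified by the cell-to-
    sinusoid volume ratio.  Cellular FFA and TAG balance the eta-scaled rate
    laws of :func:`flux_vector`; VLDL export is not scaled by eta unless
    ``eta_on_vldl`` is set (so TAG drains out of units that have lost their
    hepatocytes instead of staying frozen).
    """
    if ffa_plasma < 0:
        raise ValueError("ffa_plasma must be non-negative")
    v_ap, v_vp = sinusoid_flow(g)
    fl = flux_vector(state, p)
    eta = state.eta
    d_sin = (ffa_plasma * v_ap - state.ffa_sin * v_vp
             - eta * fl["v_uptake"] * g.phi_cell_over_sin)
    d_cell = eta * (fl["v_uptake"] - fl["v_plusTAG"] + fl["v_minusTAG"]
                    - fl["v_beta"] + fl["v_denovo"])
    d_tag = (eta * (fl["v_plusTAG"] - fl["v_minusTAG"])
             - (eta if eta_on_vldl else 1.0) * fl["v_VLDL"])
    return d_sin, d_cell, d_tag


def _steady_tag(f: float, eta: float, p: LUMetabolicParams, eta_on_vldl: bool) -> float:
    gross = p.k_plusTAG * f * (f / p.ffa_crit_syn) ** 2
    if eta_on_vldl:
        return gross / (p.k_minusTAG + p.k_VLDL)
    return eta * gross / (eta * p.k_minusTAG + p.k_VLDL)


def solve_lu_metabolic_steady_state(ffa_plasma: float, eta: float,
                                    p: LUMetabolicParams, g: SinusoidGeometry,
                                    eta_on_vldl: bool = False) -> LUState:
    """Steady state of the single-unit kinetics at fixed eta and plasma FFA.

    Eliminates the sinusoid and TAG balances analytically and solves the
    remaining scalar cellular-FFA balance by bracketing.  For eta > 0 the
    balance is strictly decreasing in cellular FFA, so the root is unique.
    For eta = 0 the cellular equations decouple; the sinusoid equilibrates
    with the plasma and the TAG pool drains through VLDL export, so the
    returned cellular state is (0, 0).
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    if ffa_plasma < 0:
        raise ValueError("ffa_plasma must be non-negative")
    v_ap, v_vp = sinusoid_flow(g)
    if v_vp <= 0:
        raise ValueError("venous flow must be positive to define a steady state")
    if eta == 0.0:
        return LUState(ffa_sin=ffa_plasma * v_ap / v_vp, ffa_cell=0.0,
                       tag=0.0 if not eta_on_vldl else 0.0, eta=0.0)

    c = g.phi_cell_over_sin
    exch = eta * c * p.k_u

    def cell_balance(f: float) -> float:
        s = (ffa_plasma * v_ap + exch * f) / (v_vp + exch)
        uptake = p.k_u * (s - f)
        tag = _steady_tag(f, eta, p, eta_on_vldl)
        return (uptake + p.v_denovo + p.k_minusTAG * tag
                - p.k_beta * f - p.k_plusTAG * f * (f / p.ffa_crit_syn) ** 2)

    hi = max(1.0, 2.0 * ffa_plasma * v_ap / v_vp + 1.0)
    for _ in range(60):
        if cell_balance(hi) < 0:
            break
        hi *= 2.0
    else:  # pragma: no cover - balance is strictly decreasing
        raise RuntimeError(
            f"cellular FFA balance not bracketed (ffa_plasma={ffa_plasma}, eta={eta})")
    f = brentq(cell_balance, 0.0, hi, xtol=1e-14, rtol=1e-14)
    s = (ffa_plasma * v_ap + exch * f) / (v_vp + exch)
    return LUState(ffa_sin=s, ffa_cell=f, tag=_steady_tag(f, eta, p, eta_on_vldl), eta=eta)


def integrate_lu_metabolism(state0: LUState, ffa_plasma: float,
                            p: LUMetabolicParams, g: SinusoidGeometry,
                            t_final: float, eta_on_vldl: bool = False,
                            rtol: float = 1e-8, atol: float = 1e-12) -> LUState:
    """Integrate the single-unit kinetics at fixed plasma FFA for ``t_final`` minutes.

    Stiff (BDF) integration; used as the independent long-time oracle for
    :func:`solve_lu_metabolic_steady_state`.
    """
    def rhs(_t, y):
        st = LUState(max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0), state0.eta)
        return lu_metabolic_rhs(st, ffa_plasma, p, g, eta_on_vldl)

    sol = solve_ivp(rhs, (0.0, t_final),
                    [state0.ffa_sin, state0.ffa_cell, state0.tag],
                    method="BDF", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"metabolic integration failed: {sol.message}")
    s, f, tag = sol.y[:, -1]
    return LUState(max(s, 0.0), max(f, 0.0), max(tag, 0.0), state0.eta)
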