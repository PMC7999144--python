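"""FFA-induced hepatocyte damage and tissue regeneration.

The intact-cell fraction eta of a liver unit obeys ``deta/dt = v_r - v_d``
(per day).  Regeneration ``v_r = k_r * eta**2 * (1 - eta)`` combines the
rising repair stimulus of lost tissue with the need for interacting intact
cells, so it vanishes at eta = 0 and eta = 1 and peaks at eta = 2/3.  Damage
is first order in eta with a rate constant that is basal below a cytotoxic
cellular FFA threshold and rises linearly, with slope gamma, above it.
Transient damaging hits (toxins, infections) add Gaussian bumps to the
damage rate constant.

Because the damage line and the regeneration curve intersect twice (or not
at all), the dynamics are bistable: for effective damage rates below k_r/4 a
liver unit started intact settles at the upper intersection, while above
k_r/4 the only attractor is complete loss of the unit (eta = 0).
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import DamageRepairParams, HitEvent

__all__ = [
    "regen_rate",
    "damage_rate",
    "hit_excess_damage",
    "eta_rhs",
    "stable_eta",
    "damage_bifurcation",
    "integrate_eta",
]

#: eta values below this are treated as extinct (absorbing); prevents
#: numerical resurrection through the eta**2 regeneration term.
ETA_EXTINCT = 1e-6


def regen_rate(eta, p: DamageRepairParams):
    """Regeneration rate v_r = k_r * eta^2 * (1 - eta) (d^-1)."""
    eta = np.asarray(eta, dtype=float)
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("eta must lie in [0, 1]")
    out = p.k_r * eta**2 * (1.0 - eta)
    return out if out.ndim else float(out)


def damage_amplification(ffa_cell, p: DamageRepairParams):
    """Factor multiplying k_d: 1 below the threshold, 1 + gamma*(F/Fc - 1) above."""
    ratio = np.asarray(ffa_cell, dtype=float) / p.ffa_critical
    out = 1.0 + p.gamma * np.maximum(0.0, ratio - 1.0)
    return out if out.ndim else float(out)


def damage_rate(eta, ffa_cell, p: DamageRepairParams):
    """Cell-loss rate v_d (d^-1): first order in eta, FFA-amplified above threshold."""
    eta = np.asarray(eta, dtype=float)
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("eta must lie in [0, 1]")
    if np.any(np.asarray(ffa_cell) < 0):
        raise ValueError("ffa_cell must be non-negative")
    out = p.k_d * eta * damage_amplification(ffa_cell, p)
    return out if out.ndim else float(out)


def hit_excess_damage(t, hits: Sequence[HitEvent]):
    """Sum of Gaussian hit bumps DF(t) (d^-1) at time ``t`` in days."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for h in hits:
        out = out + h.k_damage * np.exp(-((t - h.t_peak) ** 2) / (2.0 * h.delta))
    return out if out.ndim else float(out)


def eta_rhs(eta, ffa_cell, t, p: DamageRepairParams, hits: Sequence[HitEvent] = ()):
    """deta/dt = v_r - (v_d + DF(t) * eta) in d^-1; eta = 0 is absorbing."""
    return (regen_rate(eta, p) - damage_rate(eta, ffa_cell, p)
            - hit_excess_damage(t, hits) * np.asarray(eta, dtype=float))


def stable_eta(kd_eff: float, p: DamageRepairParams) -> float | None:
    """Upper root of ``k_r * eta * (1 - eta) = kd_eff``, or None past collapse.

    This is the non-trivial stationary intact-cell fraction reached from
    eta = 1; it exists only while the effective damage rate constant
    ``kd_eff`` does not exceed the tangency value k_r/4.
    """
    if kd_eff < 0:
        raise ValueError("kd_eff must be non-negative")
    disc = 1.0 - 4.0 * kd_eff / p.k_r
    if disc < 0:
        return None
    return 0.5 * (1.0 + math.sqrt(disc))


def damage_bifurcation(p: DamageRepairParams) -> dict[str, float]:
    """Collapse thresholds: critical damage rate and critical FFA ratio.

    ``kd_crit = k_r / 4`` is where the damage line becomes tangent to the
    regeneration curve; ``ffa_ratio_crit`` is the cellular FFA level, in
    multiples of the cytotoxicity threshold, whose amplified damage rate
    reaches it: ``1 + (k_r / (4 k_d) - 1) / gamma``.
    """
    kd_crit = p.k_r / 4.0
    return {
        "kd_crit": kd_crit,
        "ffa_ratio_crit": 1.0 + (kd_crit / p.k_d - 1.0) / p.gamma,
    }


def integrate_eta(eta0: float, ffa_cell: float, p: DamageRepairParams,
                  t_final_days: float, hits: Sequence[HitEvent] = (),
                  rtol: float = 1e-10, atol: float = 1e-12) -> float:
    """Integrate eta at fixed cellular FFA for ``t_final_days``; oracle for stable_eta."""
    def rhs(t, y):
        e = min(max(y[0], 0.0), 1.0)
        if e < ETA_EXTINCT:
            return [0.0]
        return [eta_rhs(e, ffa_cell, t, p, hits)]

    sol = solve_ivp(rhs, (0.0, t_final_days), [eta0], method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"eta integration failed: {sol.message}")
    return float(min(max(sol.y[0, -1], 0.0), 1.0))
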