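"""Parameter containers for the liver-unit NAFLD model.

All concentrations are in mM, metabolic rate constants in min^-1, damage and
repair rate constants in d^-1.  Per-unit metabolic fluxes are expressed per
total liver-unit (LU) volume, so 1 mM/min corresponds to 100 µmol/100 mL/min;
this makes the model fluxes directly comparable to whole-organ transport rates
reported per 100 mL of liver.

The TAG-turnover defaults assign the faster constant (0.018 min^-1) to
hydrolysis and the slower one (0.006 min^-1) to VLDL export: this is the only
assignment consistent with the healthy steady-state flux pattern
(esterification ≈ hydrolysis + export ≈ 14 ≈ 11 + 3.5 µmol/100 mL/min).
``LUMetabolicParams.printed_table_constants`` selects the opposite assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "LUMetabolicParams",
    "SinusoidGeometry",
    "PlasmaParams",
    "DiurnalForcing",
    "DamageRepairParams",
    "HitEvent",
    "params_to_dict",
    "params_from_dict",
]


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


def _require_nonnegative(obj, names):
    for name in names:
        value = getattr(obj, name)
        if value < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class LUMetabolicParams:
    """Rate constants of FFA/TAG turnover in one liver unit.

    Parameters
    ----------
    k_u : float
        FFA uptake rate constant (min^-1); uptake flux is
        ``k_u * (FFA_sinusoid - FFA_cell)`` and may reverse sign.
    k_beta : float
        beta-oxidation rate constant (min^-1).
    k_plusTAG : float
        Esterification rate constant (min^-1); the rate law is
        ``k_plusTAG * F * (F / ffa_crit_syn)**2``, super-linear in cellular
        FFA ``F`` to mimic upregulation of lipogenic enzymes.
    k_minusTAG : float
        TAG hydrolysis rate constant (min^-1).
    k_VLDL : float
        VLDL export rate constant (min^-1).
    v_denovo : float
        Constant de novo lipogenesis flux (mM/min).
    ffa_crit_syn : float
        Cellular FFA threshold of the esterification rate law (mM).
    """

    k_u: float = 0.78
    k_beta: float = 0.6
    k_plusTAG: float = 3.6
    k_minusTAG: float = 0.018
    k_VLDL: float = 0.006
    v_denovo: float = 0.012
    ffa_crit_syn: float = 0.1

    def __post_init__(self):
        # rate constants may be zero (e.g. to switch off TAG synthesis);
        # the esterification threshold must stay positive
        _require_nonnegative(self, [f.name for f in fields(self)])
        _require_positive(self, ["ffa_crit_syn"])

    @classmethod
    def printed_table_constants(cls, **overrides) -> "LUMetabolicParams":
        """Variant with the hydrolysis/VLDL constants as printed (0.006/0.018)."""
        return cls(k_minusTAG=0.006, k_VLDL=0.018, **overrides)


# Poiseuille prefactor for the default geometry, per unit pressure gradient:
# pi * r_s^4 / (8 * l_s * Omega_s), lengths in µm, Omega_s in µm^3.
_R_S = 3.15
_L_S = 375.0
_OMEGA_S_L = 1.169e-11
_POISEUILLE = math.pi * _R_S**4 / (8.0 * _L_S * (_OMEGA_S_L * 1e15))

#: Effective blood viscosity (model pressure · min units), set so that the
#: default geometry with dp = 0.2 perfuses 1 mL blood per mL liver per minute
#: (i.e. 1/phi_sin = 10 sinusoid volumes per minute).
DEFAULT_VISCOSITY = _POISEUILLE * 0.2 / 10.0


@dataclass(frozen=True)
class SinusoidGeometry:
    """Sinusoid geometry and perfusion of one liver unit.

    ``sinusoid_flow`` turns these into volumetric flows per sinusoid volume
    (min^-1) via the Poiseuille law.  ``phi_sin`` is the vascular volume
    fraction of the LU and ``phi_cell_over_sin`` the ratio of cellular to
    sinusoidal volume used to couple cellular fluxes into the sinusoid
    balance (defaults treat the cellular compartment as the whole LU volume,
    consistent with expressing metabolic fluxes per LU volume).
    """

    r_s: float = _R_S            # µm
    l_s: float = _L_S            # µm
    omega_s: float = _OMEGA_S_L  # L
    viscosity: float = DEFAULT_VISCOSITY
    dp_a: float = 0.2
    dp_v: float = 0.2
    phi_sin: float = 0.1
    phi_cell_over_sin: float = 10.0

    def __post_init__(self):
        _require_positive(self, ["r_s", "l_s", "omega_s", "viscosity", "phi_cell_over_sin"])
        if not 0.0 < self.phi_sin < 1.0:
            raise ValueError(f"phi_sin must lie in (0, 1), got {self.phi_sin!r}")
        if self.dp_a < 0 or self.dp_v < 0:
            raise ValueError("pressure gradients must be non-negative")


@dataclass(frozen=True)
class PlasmaParams:
    """Plasma FFA pool: adipose release, extra-hepatic clearance, liver coupling.

    ``liver_closure`` is the single aggregation constant that scales the mean
    per-LU arterio-venous extraction into the plasma balance (it lumps the
    ratio of liver blood volume to total blood volume).  ``None`` means
    "calibrate": :func:`nafldsim.ensemble.calibrate_closure` chooses it once so
    the reference liver at ``k_at`` = 1.17 mM/min rests at 0.26 mM plasma FFA.
    """

    k_at: float = 1.17   # mM/min, baseline adipose FFA release
    k_et: float = 2.34   # min^-1, extra-hepatic clearance (may be 0)
    liver_closure: float | None = None

    def __post_init__(self):
        _require_positive(self, ["k_at"])
        _require_nonnegative(self, ["k_et"])
        if self.liver_closure is not None and not self.liver_closure > 0:
            raise ValueError("liver_closure must be positive when given")


@dataclass(frozen=True)
class DiurnalForcing:
    """Cosinusoidal adipose-release forcing, three cycles per day by default."""

    vat_min: float = 0.35   # mM/min
    vat_max: float = 2.45   # mM/min
    period: float = 480.0   # min

    def __post_init__(self):
        if not 0 < self.vat_min <= self.vat_max:
            raise ValueError("need 0 < vat_min <= vat_max")
        if not self.period > 0:
            raise ValueError("period must be positive")

    @property
    def mean(self) -> float:
        return 0.5 * (self.vat_min + self.vat_max)


@dataclass(frozen=True)
class DamageRepairParams:
    """Damage and regeneration constants of the intact-cell fraction eta.

    Regeneration ``v_r = k_r * eta**2 * (1 - eta)`` peaks at eta = 2/3; damage
    ``v_d = k_d * eta`` below the cytotoxicity threshold ``ffa_critical`` and
    is amplified by ``1 + gamma * (F/ffa_critical - 1)`` above it.
    """

    k_d: float = 3.456e-4    # d^-1
    k_r: float = 3e-2        # d^-1
    gamma: float = 30.0
    ffa_critical: float = 0.1  # mM

    def __post_init__(self):
        _require_positive(self, ["k_d", "k_r", "gamma", "ffa_critical"])


@dataclass(frozen=True)
class HitEvent:
    """One transient liver-damaging hit, a Gaussian bump in the damage rate.

    ``exp(-(t - t_peak)**2 / (2 * delta))`` with ``t`` in days and ``delta``
    in days^2; the default width gives a full width at half maximum of about
    one year.  ``k_damage`` is the peak excess damage rate constant (d^-1),
    six times the basal damage rate by default.
    """

    t_peak: float                 # days
    delta: float = 2.4e4          # days^2
    k_damage: float = 2.1e-3      # d^-1

    def __post_init__(self):
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.k_damage < 0:
            raise ValueError("k_damage must be non-negative")

    @property
    def fwhm_days(self) -> float:
        return 2.0 * math.sqrt(2.0 * math.log(2.0) * self.delta)

    @classmethod
    def from_years(cls, t_peak_years: float, fwhm_years: float = 1.0,
                   strength_multiple_of_kd: float | None = None,
                   k_d: float = DamageRepairParams.k_d,
                   k_damage: float | None = None) -> "HitEvent":
        """Build a hit from the configuration units (years, multiples of k_d)."""
        delta = (fwhm_years * 365.0) ** 2 / (8.0 * math.log(2.0))
        if k_damage is None:
            k_damage = (strength_multiple_of_kd if strength_multiple_of_kd is not None else 6.0) * k_d
        return cls(t_peak=t_peak_years * 365.0, delta=delta, k_damage=k_damage)


_PARAM_TYPES = (LUMetabolicParams, SinusoidGeometry, PlasmaParams,
                DiurnalForcing, DamageRepairParams)


def params_to_dict(obj) -> dict:
    """Flatten a parameter dataclass into a plain {field: value} mapping."""
    return {f.name: getattr(obj, f.name) for f in fields(obj)}


def params_from_dict(cls, mapping: dict):
    """Build a parameter dataclass from a flat mapping, ignoring extra keys."""
    names = {f.name for f in fields(cls)}
    return cls(**{k: v for k, v in mapping.items() if k in names})


def perturbed(obj, name: str, factor: float):
    """Return a copy of a frozen parameter set with one field scaled."""
    return replace(obj, **{name: getattr(obj, name) * factor})
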