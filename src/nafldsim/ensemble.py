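"""Whole-liver ensembles: heterogeneous liver units coupled through plasma FFA.

The liver is modelled as ``n_lu`` functionally heterogeneous liver units
(LUs) exchanging FFA with one shared plasma pool.  Functional heterogeneity
is generated by drawing selected rate constants from truncated normal
distributions around the reference values (default relative SD 20%).

Disease progression is simulated with a two-timescale scheme: lipid
metabolism relaxes within minutes to hours, hepatocyte loss and regeneration
evolve over months to years.  At every outer step (default one day) the
plasma pool and all LU lipid states are placed at their joint quasi-steady
state for the current intact-cell fractions, and the intact-cell fractions
are then advanced one step with the damage-repair dynamics evaluated at the
frozen cellular FFA levels.
"""

from __future__ import annotations

import functools
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import observables
from .damage import ETA_EXTINCT, hit_excess_damage, stable_eta
from .metabolism import (LUState, diurnal_release_rate, sinusoid_flow,
                         solve_lu_metabolic_steady_state)
from .params import (DamageRepairParams, DiurnalForcing, HitEvent,
                     LUMetabolicParams, PlasmaParams, SinusoidGeometry,
                     perturbed)

__all__ = [
    "EnsembleSpec",
    "VirtualLiver",
    "ChallengeSchedule",
    "SimulationResult",
    "DiurnalResult",
    "PROGRESSION_RANDOMIZED",
    "DIURNAL_RANDOMIZED",
    "sample_virtual_liver",
    "sample_cohort",
    "calibrate_closure",
    "whole_liver_metabolic_equilibrium",
    "simulate_progression",
    "simulate_progression_cohort",
    "simulate_diurnal",
]

#: Parameters randomized in progression runs: perfusion, FFA handling and
#: damage/repair capacities vary independently between liver units.
PROGRESSION_RANDOMIZED = ("dp", "k_u", "k_beta", "k_plusTAG", "k_minusTAG", "k_d", "k_r")

#: Parameters randomized in the diurnal noise experiment: all kinetic
#: constants of the lipid-turnover table plus perfusion.
DIURNAL_RANDOMIZED = ("dp", "k_u", "k_beta", "k_plusTAG", "k_minusTAG", "k_VLDL", "v_denovo")

_METABOLIC_FIELDS = {"k_u", "k_beta", "k_plusTAG", "k_minusTAG", "k_VLDL",
                     "v_denovo", "ffa_crit_syn"}
_DAMAGE_FIELDS = {"k_d", "k_r", "gamma", "ffa_critical"}
_GEOMETRY_FIELDS = {"dp"}

#: Fraction of the mean below which parameter draws are rejected and redrawn.
TRUNCATION_FRACTION = 0.05


@dataclass
class EnsembleSpec:
    """How to build one virtual liver (or a cohort of them).

    ``homogeneous`` livers share a single parameter draw across all LUs, so
    each liver is internally uniform but livers still differ from each other.
    ``lu_volume_ml`` defaults to a 1500 mL liver split evenly across units.
    """

    n_lu: int = 100
    cv: float = 0.2
    randomized_params: tuple[str, ...] = PROGRESSION_RANDOMIZED
    homogeneous: bool = False
    seed: int = 0
    lu_volume_ml: float | None = None

    def __post_init__(self):
        if self.n_lu < 1:
            raise ValueError("n_lu must be >= 1")
        if not 0.0 <= self.cv < 1.0:
            raise ValueError("cv must lie in [0, 1)")
        unknown = set(self.randomized_params) - _METABOLIC_FIELDS - _DAMAGE_FIELDS - _GEOMETRY_FIELDS
        if unknown:
            raise ValueError(f"unknown randomized parameter(s): {sorted(unknown)}")
        self.randomized_params = tuple(self.randomized_params)
        if self.lu_volume_ml is None:
            self.lu_volume_ml = 1500.0 / self.n_lu


@dataclass
class VirtualLiver:
    """N parameterized liver units plus the shared plasma compartment."""

    lus: list[tuple[LUMetabolicParams, SinusoidGeometry, DamageRepairParams]]
    plasma: PlasmaParams
    spec: EnsembleSpec

    @property
    def n_lu(self) -> int:
        return len(self.lus)


@dataclass(frozen=True)
class ChallengeSchedule:
    """Piecewise-constant adipose FFA release rate over the simulation.

    ``segments`` is a sequence of (start_time_years, vat_mM_per_min) pairs
    with nondecreasing start times; the first segment must start at 0.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        times = [s[0] for s in self.segments]
        if times[0] != 0.0:
            raise ValueError("first segment must start at time 0")
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("segment start times must be nondecreasing")
        if any(s[1] <= 0 for s in self.segments):
            raise ValueError("release rates must be positive")
        object.__setattr__(self, "segments", tuple((float(t), float(v)) for t, v in self.segments))

    def rate_at(self, t_years: float) -> float:
        rate = self.segments[0][1]
        for start, vat in self.segments:
            if t_years >= start:
                rate = vat
            else:
                break
        return rate

    @classmethod
    def constant(cls, vat: float = 1.17) -> "ChallengeSchedule":
        return cls(((0.0, vat),))

    @classmethod
    def standard_challenge(cls, onset_years: float = 5.0, vat_base: float = 1.17,
                           vat_challenge: float = 1.76,
                           cessation_years_after_onset: float | None = None) -> "ChallengeSchedule":
        """Baseline release stepping up at onset, optionally back down later."""
        segments = [(0.0, vat_base), (onset_years, vat_challenge)]
        if cessation_years_after_onset is not None:
            segments.append((onset_years + cessation_years_after_onset, vat_base))
        return cls(tuple(segments))


@dataclass
class SimulationResult:
    """Time series of one progression run (time in days from simulation start)."""

    time_days: np.ndarray
    plasma_ffa: np.ndarray
    tfh: np.ndarray
    steatosis_fraction: np.ndarray
    sps: np.ndarray
    eta: np.ndarray | None = None       # (T, n_lu)
    ffa_cell: np.ndarray | None = None  # (T, n_lu)
    tag: np.ndarray | None = None       # (T, n_lu)
    onset_years: float | None = None

    def value_at(self, series: str, t_years: float) -> float:
        """Value of a liver-level series at the last stored time <= t_years."""
        idx = int(np.searchsorted(self.time_days, t_years * 365.0, side="right") - 1)
        return float(getattr(self, series)[max(idx, 0)])

    def per_lu_at(self, series: str, t_years: float) -> np.ndarray:
        arr = getattr(self, series)
        if arr is None:
            raise ValueError(f"per-LU series {series!r} was not stored")
        idx = int(np.searchsorted(self.time_days, t_years * 365.0, side="right") - 1)
        return arr[max(idx, 0)]

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-format trajectories: (time_days, variable, lu_index, value).

        Liver-level series carry lu_index -1; per-LU series one row per unit.
        """
        frames = []
        for name in ("plasma_ffa", "tfh", "steatosis_fraction", "sps"):
            frames.append(pd.DataFrame({
                "time_days": self.time_days, "variable": name,
                "lu_index": -1, "value": getattr(self, name)}))
        for name in ("eta", "ffa_cell", "tag"):
            arr = getattr(self, name)
            if arr is None:
                continue
            t_rep = np.repeat(self.time_days, arr.shape[1])
            frames.append(pd.DataFrame({
                "time_days": t_rep, "variable": name,
                "lu_index": np.tile(np.arange(arr.shape[1]), arr.shape[0]),
                "value": arr.ravel()}))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sampling


def _draw_factors(rng: np.random.Generator, spec: EnsembleSpec) -> dict[str, np.ndarray]:
    """Per-LU multiplicative factors, mean 1, relative SD ``cv``, truncated."""
    n = 1 if spec.homogeneous else spec.n_lu
    factors = {}
    for name in spec.randomized_params:
        x = rng.normal(1.0, spec.cv, n)
        while True:
            bad = x < TRUNCATION_FRACTION
            if not bad.any():
                break
            x[bad] = rng.normal(1.0, spec.cv, int(bad.sum()))
        factors[name] = np.repeat(x, spec.n_lu) if spec.homogeneous else x
    return factors


def sample_virtual_liver(spec: EnsembleSpec,
                         base_metabolic: LUMetabolicParams | None = None,
                         base_geometry: SinusoidGeometry | None = None,
                         base_damage: DamageRepairParams | None = None,
                         plasma: PlasmaParams | None = None,
                         rng: np.random.Generator | None = None) -> VirtualLiver:
    """Draw one virtual liver: each randomized parameter is Normal(ref, cv*ref).

    Draws below 5% of the reference are rejected and redrawn to keep all rate
    constants physically meaningful.  With ``spec.homogeneous`` a single draw
    is shared by all LUs; with ``cv = 0`` every LU equals the reference.
    Fully reproducible from ``spec.seed`` (or an explicitly passed generator).
    """
    base_metabolic = base_metabolic or LUMetabolicParams()
    base_geometry = base_geometry or SinusoidGeometry()
    base_damage = base_damage or DamageRepairParams()
    plasma = plasma or PlasmaParams()
    if rng is None:
        rng = np.random.default_rng([spec.seed, 1500])
    factors = _draw_factors(rng, spec)

    lus = []
    for i in range(spec.n_lu):
        met, geo, dam = base_metabolic, base_geometry, base_damage
        for name, fac in factors.items():
            if name in _METABOLIC_FIELDS:
                met = perturbed(met, name, fac[i])
            elif name in _DAMAGE_FIELDS:
                dam = perturbed(dam, name, fac[i])
            else:  # dp scales both pressure gradients (single perfusion knob)
                geo = perturbed(perturbed(geo, "dp_a", fac[i]), "dp_v", fac[i])
        lus.append((met, geo, dam))
    return VirtualLiver(lus=lus, plasma=plasma, spec=spec)


def sample_cohort(n_livers: int, spec: EnsembleSpec, master_seed: int | None = None,
                  **base_params) -> list[VirtualLiver]:
    """Sample ``n_livers`` independent livers; liver i uses stream (seed, i)."""
    seed = spec.seed if master_seed is None else master_seed
    livers = []
    for i in range(n_livers):
        rng = np.random.default_rng([seed, i])
        livers.append(sample_virtual_liver(spec, rng=rng, **base_params))
    return livers


# ---------------------------------------------------------------------------
# calibration


@functools.lru_cache(maxsize=32)
def calibrate_closure(metabolic: LUMetabolicParams = LUMetabolicParams(),
                      geometry: SinusoidGeometry = SinusoidGeometry(),
                      damage: DamageRepairParams = DamageRepairParams(),
                      k_at_ref: float = 1.17, k_et: float = 2.34,
                      plasma_ref: float = 0.26) -> float:
    """Whole-liver closure constant making the reference liver rest at 0.26 mM.

    The closure lumps the never-quantified scaling between liver blood volume
    and total blood volume into one number: at the healthy stationary state
    (eta at its basal stable value) the plasma balance
    ``k_at = k_et * FFA_p + closure * <arterio-venous extraction>``
    must hold at the reference release rate.  Chosen once and reused
    unchanged in every scenario.
    """
    eta0 = stable_eta(damage.k_d, damage)
    st = solve_lu_metabolic_steady_state(plasma_ref, eta0, metabolic, geometry)
    v_ap, v_vp = sinusoid_flow(geometry)
    extraction = v_ap * plasma_ref - v_vp * st.ffa_sin
    residual = k_at_ref - k_et * plasma_ref
    if extraction <= 0 or residual <= 0:
        raise ValueError("calibration anchor infeasible for these parameters")
    return residual / extraction


def _resolve_closure(liver: VirtualLiver) -> float:
    if liver.plasma.liver_closure is not None:
        return liver.plasma.liver_closure
    return calibrate_closure(k_at_ref=liver.plasma.k_at, k_et=liver.plasma.k_et)


# ---------------------------------------------------------------------------
# vectorized cohort arrays and quasi-steady equilibrium


class _Cohort:
    """Stacked (n_livers, n_lu) parameter arrays for the vectorized engine."""

    __slots__ = ("ku", "kb", "kp", "km", "kv", "vdn", "fc2", "vap", "vvp", "c",
                 "kd", "kr", "gamma", "fcrit", "ket", "closure", "eta_on_vldl",
                 "shape")

    def __init__(self, livers: Sequence[VirtualLiver], eta_on_vldl: bool = False):
        n_lu = livers[0].n_lu
        if any(lv.n_lu != n_lu for lv in livers):
            raise ValueError("all livers in a cohort must have the same n_lu")
        ket = livers[0].plasma.k_et
        closure = _resolve_closure(livers[0])
        if any(lv.plasma.k_et != ket for lv in livers):
            raise ValueError("all livers in a cohort must share plasma parameters")

        def stack(getter):
            return np.array([[getter(*lu) for lu in lv.lus] for lv in livers])

        self.ku = stack(lambda m, g, d: m.k_u)
        self.kb = stack(lambda m, g, d: m.k_beta)
        self.kp = stack(lambda m, g, d: m.k_plusTAG)
        self.km = stack(lambda m, g, d: m.k_minusTAG)
        self.kv = stack(lambda m, g, d: m.k_VLDL)
        self.vdn = stack(lambda m, g, d: m.v_denovo)
        self.fc2 = stack(lambda m, g, d: m.ffa_crit_syn) ** 2
        self.vap = stack(lambda m, g, d: sinusoid_flow(g)[0])
        self.vvp = stack(lambda m, g, d: sinusoid_flow(g)[1])
        self.c = livers[0].lus[0][1].phi_cell_over_sin
        self.kd = stack(lambda m, g, d: d.k_d)
        self.kr = stack(lambda m, g, d: d.k_r)
        self.gamma = stack(lambda m, g, d: d.gamma)
        self.fcrit = stack(lambda m, g, d: d.ffa_critical)
        self.ket = ket
        self.closure = closure
        self.eta_on_vldl = eta_on_vldl
        self.shape = (len(livers), n_lu)


def _equilibrium(co: _Cohort, eta: np.ndarray, vat, p_guess: np.ndarray,
                 f_guess: np.ndarray, label: str = ""):
    """Joint quasi-steady state of plasma and all LU lipid pools.

    Newton on the scalar plasma balance per liver, with the per-LU cellular
    FFA balance solved by an inner (damped, vectorized) Newton at each trial
    plasma level.  Both balances are strictly monotone, so the fixed point is
    unique; warm starts make the solve cheap along a slowly drifting
    trajectory.
    """
    alive = eta > 0
    exch = eta * co.c * co.ku                  # sinusoid <-> cell exchange rate
    denom = co.vvp + exch
    fac = np.where(co.eta_on_vldl, co.kv / (co.km + co.kv),
                   co.kv / (eta * co.km + co.kv))
    k3 = co.kp / co.fc2 * fac                  # effective cubic removal coeff
    uf = co.ku / denom                         # uptake = uf*(vap*P - vvp*F)

    P = np.array(p_guess, dtype=float)
    F = np.array(f_guess, dtype=float)
    Pcol = P[:, None]
    for outer in range(120):
        for inner in range(80):
            g = uf * (co.vap * Pcol - co.vvp * F) + co.vdn - co.kb * F - k3 * F**3
            if np.max(np.abs(np.where(alive, g, 0.0))) < 1e-13:
                break
            dg = -uf * co.vvp - co.kb - 3.0 * k3 * F**2
            F = np.clip(F - g / dg, 0.0, 50.0)
        uptake = uf * (co.vap * Pcol - co.vvp * F)
        psi = co.ket * P + co.closure * np.mean(
            np.where(alive, eta * co.c * uptake, 0.0), axis=1) - vat
        if np.max(np.abs(psi)) < 1e-11:
            break
        dFdP = (uf * co.vap) / (uf * co.vvp + co.kb + 3.0 * k3 * F**2)
        dpsi = co.ket + co.closure * np.mean(
            np.where(alive, eta * co.c * uf * (co.vap - co.vvp * dFdP), 0.0), axis=1)
        P = np.maximum(P - psi / dpsi, 1e-12)
        Pcol = P[:, None]
    else:  # pragma: no cover
        raise RuntimeError(f"plasma equilibrium did not converge {label} "
                           f"(max residual {np.max(np.abs(psi)):.3e})")
    F = np.where(alive, F, 0.0)
    if co.eta_on_vldl:
        tag = co.kp * F**3 / co.fc2 / (co.km + co.kv)
    else:
        tag = np.where(alive, eta * co.kp * F**3 / co.fc2 / (eta * co.km + co.kv), 0.0)
    S = np.where(alive, (Pcol * co.vap + exch * F) / denom, Pcol * co.vap / co.vvp)
    return P, S, F, tag


# ---------------------------------------------------------------------------
# public simulation API


def whole_liver_metabolic_equilibrium(liver: VirtualLiver, etas, vat: float,
                                      eta_on_vldl: bool = False):
    """Quasi-steady plasma FFA and per-LU lipid states at fixed eta values.

    Returns ``(plasma_ffa, states)`` where ``states`` is a list of
    :class:`~nafldsim.metabolism.LUState`, one per liver unit.
    """
    etas = np.asarray(etas, dtype=float)
    if etas.shape != (liver.n_lu,):
        raise ValueError(f"etas must have shape ({liver.n_lu},)")
    if np.any((etas < 0) | (etas > 1)):
        raise ValueError("etas must lie in [0, 1]")
    co = _Cohort([liver], eta_on_vldl=eta_on_vldl)
    eta = etas[None, :]
    P, S, F, tag = _equilibrium(co, eta, float(vat),
                                np.array([0.5 * vat / co.ket]),
                                np.full((1, liver.n_lu), 0.08))
    states = [LUState(S[0, i], F[0, i], tag[0, i], etas[i]) for i in range(liver.n_lu)]
    return float(P[0]), states


def _hit_rate(t_days: float, hits) -> float:
    return float(hit_excess_damage(t_days, hits)) if hits else 0.0


def simulate_progression_cohort(livers: Sequence[VirtualLiver],
                                challenge: ChallengeSchedule | None = None,
                                hits: Sequence[HitEvent] = (),
                                horizon_years: float = 35.0,
                                dt_outer_days: float = 1.0,
                                save_every_days: float = 30.0,
                                store_per_lu: bool = False,
                                eta_on_vldl: bool = False,
                                steatosis_threshold: float = 30.0,
                                onset_years: float | None = 5.0) -> list[SimulationResult]:
    """Run the two-timescale progression for a cohort of livers in lockstep.

    All livers share the same release-rate schedule and hit sequence, and are
    advanced simultaneously on (n_livers, n_lu) arrays.  Every outer step the
    coupled plasma/LU lipid quasi-steady state is recomputed, then the
    intact-cell fractions advance by one classical Runge-Kutta step of the
    damage-repair dynamics at frozen cellular FFA; units whose eta falls
    below the extinction threshold are absorbed at zero.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    challenge = challenge or ChallengeSchedule.standard_challenge()
    co = _Cohort(livers, eta_on_vldl=eta_on_vldl)
    L, N = co.shape
    dt = float(dt_outer_days)
    n_steps = int(round(horizon_years * 365.0 / dt))
    stride = max(1, int(round(save_every_days / dt)))

    eta = np.ones((L, N))
    P = np.full(L, challenge.rate_at(0.0) / co.ket * 0.5)
    F = np.full((L, N), 0.08)
    times, recs = [], {"plasma": [], "tfh": [], "steat": [], "sps": []}
    snaps = {"eta": [], "ffa_cell": [], "tag": []} if store_per_lu else None

    for step in range(n_steps + 1):
        t_days = step * dt
        vat = challenge.rate_at(t_days / 365.0)
        P, S, F, tag = _equilibrium(co, eta, vat, P, F, label=f"at day {t_days:g}")
        if step % stride == 0 or step == n_steps:
            times.append(t_days)
            recs["plasma"].append(P.copy())
            recs["tfh"].append(observables.tfh(eta))
            recs["steat"].append(observables.steatosis_fraction(tag, steatosis_threshold))
            recs["sps"].append(observables.steatosis_pattern_score(tag, steatosis_threshold))
            if store_per_lu:
                snaps["eta"].append(eta.copy())
                snaps["ffa_cell"].append(F.copy())
                snaps["tag"].append(tag.copy())
        if step == n_steps:
            break
        kd_eff = co.kd * damage_amplification_arr(F, co.fcrit, co.gamma)
        df0 = _hit_rate(t_days, hits)
        dfh = _hit_rate(t_days + dt / 2.0, hits)
        df1 = _hit_rate(t_days + dt, hits)

        def rhs(e, df):
            return co.kr * e * e * (1.0 - e) - (kd_eff + df) * e

        k1 = rhs(eta, df0)
        k2 = rhs(np.clip(eta + dt / 2.0 * k1, 0.0, 1.0), dfh)
        k3 = rhs(np.clip(eta + dt / 2.0 * k2, 0.0, 1.0), dfh)
        k4 = rhs(np.clip(eta + dt * k3, 0.0, 1.0), df1)
        eta = np.clip(eta + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4), 0.0, 1.0)
        eta[eta < ETA_EXTINCT] = 0.0

    time_days = np.asarray(times)
    results = []
    for i in range(L):
        results.append(SimulationResult(
            time_days=time_days,
            plasma_ffa=np.array([p[i] for p in recs["plasma"]]),
            tfh=np.array([x[i] for x in recs["tfh"]]),
            steatosis_fraction=np.array([x[i] for x in recs["steat"]]),
            sps=np.array([x[i] for x in recs["sps"]]),
            eta=np.array([s[i] for s in snaps["eta"]]) if store_per_lu else None,
            ffa_cell=np.array([s[i] for s in snaps["ffa_cell"]]) if store_per_lu else None,
            tag=np.array([s[i] for s in snaps["tag"]]) if store_per_lu else None,
            onset_years=onset_years,
        ))
    return results


def damage_amplification_arr(ffa_cell: np.ndarray, fcrit: np.ndarray,
                             gamma: np.ndarray) -> np.ndarray:
    """Vectorized damage amplification factor (see :func:`nafldsim.damage.damage_rate`)."""
    return 1.0 + gamma * np.maximum(0.0, ffa_cell / fcrit - 1.0)


def simulate_progression(liver: VirtualLiver, **kwargs) -> SimulationResult:
    """Single-liver wrapper around :func:`simulate_progression_cohort`."""
    kwargs.setdefault("store_per_lu", True)
    return simulate_progression_cohort([liver], **kwargs)[0]


@dataclass
class DiurnalResult:
    """Minute-scale limit cycle of a liver under periodic release forcing.

    Arrays cover one forcing period after the transient has decayed;
    per-LU arrays have shape (T, n_lu).
    """

    time_min: np.ndarray
    plasma_ffa: np.ndarray
    ffa_sin: np.ndarray
    ffa_cell: np.ndarray
    tag: np.ndarray
    forcing: DiurnalForcing

    def limit_cycle_stats(self) -> dict[str, dict[str, np.ndarray | float]]:
        out = {}
        for name in ("plasma_ffa", "ffa_sin", "ffa_cell", "tag"):
            arr = getattr(self, name)
            out[name] = {"min": arr.min(axis=0), "max": arr.max(axis=0),
                         "mean": arr.mean(axis=0)}
        return out


def simulate_diurnal(liver: VirtualLiver, forcing: DiurnalForcing | None = None,
                     n_days: float = 10.0, etas=None, initial_state=None,
                     full_series: bool = False,
                     rtol: float = 1e-8, atol: float = 1e-11) -> DiurnalResult:
    """Full minute-scale integration of plasma + all LUs under diurnal forcing.

    The intact-cell fractions are frozen (healthy, eta = 1, unless ``etas``
    is given); the returned series sample the final forcing period on a
    1-minute grid, by which time the slowest lipid mode (TAG) has relaxed to
    the limit cycle.
    """
    from scipy.integrate import solve_ivp
    from scipy.sparse import lil_matrix

    if n_days < 2:
        raise ValueError("n_days must be at least 2 (transient + limit cycle)")
    forcing = forcing or DiurnalForcing()
    co = _Cohort([liver])
    N = liver.n_lu
    eta = np.ones((1, N)) if etas is None else np.asarray(etas, dtype=float)[None, :]

    if initial_state is None:
        # start on the quasi-steady state at the mean release rate
        P0, S0, F0, T0 = _equilibrium(co, eta, forcing.mean,
                                      np.array([0.5 * forcing.mean / max(co.ket, 1.0)]),
                                      np.full((1, N), 0.08))
        y0 = np.concatenate((P0, S0[0], F0[0], T0[0]))
    else:
        p0, s0, f0, t0 = initial_state
        y0 = np.concatenate(([p0], np.broadcast_to(s0, N), np.broadcast_to(f0, N),
                             np.broadcast_to(t0, N)))
    ku, kb, kp, km, kv = co.ku[0], co.kb[0], co.kp[0], co.km[0], co.kv[0]
    vdn, fc2, vap, vvp = co.vdn[0], co.fc2[0], co.vap[0], co.vvp[0]
    e = eta[0]

    def rhs(t, y):
        P, S, F, TG = y[0], y[1:1 + N], y[1 + N:1 + 2 * N], y[1 + 2 * N:]
        vat = diurnal_release_rate(t, forcing)
        up = ku * (S - F)
        est = kp * F**3 / fc2
        dP = vat - co.ket * P - co.closure * np.mean(vap * P - vvp * S)
        dS = P * vap - S * vvp - e * co.c * up
        dF = e * (up - est + km * TG - kb * F + vdn)
        dT = e * (est - km * TG) - (e if co.eta_on_vldl else 1.0) * kv * TG
        return np.concatenate(([dP], dS, dF, dT))

    sparsity = lil_matrix((1 + 3 * N, 1 + 3 * N), dtype=np.int8)
    sparsity[0, :1 + N] = 1
    for i in range(N):
        sparsity[1 + i, [0, 1 + i, 1 + N + i]] = 1
        sparsity[1 + N + i, [1 + i, 1 + N + i, 1 + 2 * N + i]] = 1
        sparsity[1 + 2 * N + i, [1 + N + i, 1 + 2 * N + i]] = 1

    t_end = n_days * 1440.0
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=rtol, atol=atol,
                    jac_sparsity=sparsity.tocsr(), dense_output=True)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"diurnal integration failed: {sol.message}")
    t_start = 0.0 if full_series else np.ceil(t_end - forcing.period)
    tt = np.arange(t_start, t_end + 0.5, 1.0)
    Y = sol.sol(tt)
    return DiurnalResult(time_min=tt, plasma_ffa=Y[0],
                         ffa_sin=Y[1:1 + N].T, ffa_cell=Y[1 + N:1 + 2 * N].T,
                         tag=Y[1 + 2 * N:].T, forcing=forcing)
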