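"""Whole-liver assembly: sampling, calibration, equilibrium, progression engine."""

import numpy as np
import pytest

from nafldsim import (ChallengeSchedule, DiurnalForcing, EnsembleSpec,
                      LUMetabolicParams, PlasmaParams, calibrate_closure,
                      sample_virtual_liver, simulate_diurnal,
                      simulate_progression, stable_eta,
                      solve_lu_metabolic_steady_state,
                      whole_liver_metabolic_equilibrium)
from nafldsim.ensemble import (PROGRESSION_RANDOMIZED, sample_cohort,
                               simulate_progression_cohort)
from nafldsim.metabolism import lu_metabolic_rhs


class TestSampling:
    def test_same_seed_identical_livers(self):
        spec = EnsembleSpec(n_lu=10, cv=0.2, seed=7)
        a = sample_virtual_liver(spec)
        b = sample_virtual_liver(spec)
        assert a.lus == b.lus

    def test_zero_cv_reproduces_reference(self, ref_metabolic):
        liver = sample_virtual_liver(EnsembleSpec(n_lu=5, cv=0.0, seed=1))
        assert all(met == ref_metabolic for met, _, _ in liver.lus)

    def test_homogeneous_shares_one_draw(self):
        liver = sample_virtual_liver(EnsembleSpec(n_lu=8, cv=0.2, seed=3,
                                                  homogeneous=True))
        mets = {met for met, _, _ in liver.lus}
        assert len(mets) == 1
        assert next(iter(mets)) != LUMetabolicParams()

    def test_sample_relative_sd_near_cv(self):
        """n = 1000 draws: the empirical relative SD of every randomized
        parameter lies within the sampling-error band [0.17, 0.23]."""
        liver = sample_virtual_liver(EnsembleSpec(n_lu=1000, cv=0.2, seed=11))
        for name in PROGRESSION_RANDOMIZED:
            if name == "dp":
                vals = np.array([g.dp_a for _, g, _ in liver.lus])
            elif name in ("k_d", "k_r"):
                vals = np.array([getattr(d, name) for _, _, d in liver.lus])
            else:
                vals = np.array([getattr(m, name) for m, _, _ in liver.lus])
            assert 0.17 < vals.std() / vals.mean() < 0.23, name

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown randomized"):
            EnsembleSpec(n_lu=5, randomized_params=("k_turbo",))

    def test_cohort_streams_independent_of_order(self):
        spec = EnsembleSpec(n_lu=4, cv=0.2, seed=5)
        cohort = sample_cohort(3, spec)
        # liver 2 alone is bit-identical to liver 2 within the cohort
        import numpy.random as npr
        lone = sample_virtual_liver(spec, rng=npr.default_rng([5, 2]))
        assert cohort[2].lus == lone.lus


class TestCalibrationAndEquilibrium:
    def test_reference_resting_point(self, healthy_eta):
        """Closure calibration pins plasma FFA at 0.26 mM for v_at = 1.17."""
        liver = sample_virtual_liver(EnsembleSpec(n_lu=1, cv=0.0, seed=0))
        p, _ = whole_liver_metabolic_equilibrium(liver, [healthy_eta], 1.17)
        assert p == pytest.approx(0.26, abs=1e-9)

    def test_calibration_independent_of_granularity(self, healthy_eta):
        for n_lu in (3, 17):
            liver = sample_virtual_liver(EnsembleSpec(n_lu=n_lu, cv=0.0, seed=0))
            etas = np.full(n_lu, healthy_eta)
            p, _ = whole_liver_metabolic_equilibrium(liver, etas, 1.17)
            assert p == pytest.approx(0.26, abs=1e-9)

    def test_dead_liver_closed_form(self):
        liver = sample_virtual_liver(EnsembleSpec(n_lu=4, cv=0.0, seed=0))
        p, states = whole_liver_metabolic_equilibrium(liver, np.zeros(4), 1.17)
        assert p == pytest.approx(1.17 / liver.plasma.k_et, rel=1e-9)
        assert all(s.tag == 0.0 for s in states)

    def test_per_unit_states_satisfy_rate_balance(self):
        """Dual route: the vectorized equilibrium leaves the scalar ODE
        right-hand side at zero for every unit, heterogeneous case."""
        liver = sample_virtual_liver(EnsembleSpec(n_lu=6, cv=0.2, seed=9))
        etas = np.linspace(0.5, 1.0, 6)
        p, states = whole_liver_metabolic_equilibrium(liver, etas, 1.4)
        for (met, geo, _), st in zip(liver.lus, states):
            d = lu_metabolic_rhs(st, p, met, geo)
            assert np.max(np.abs(d)) < 1e-9

    def test_matches_single_unit_solver(self, healthy_eta):
        liver = sample_virtual_liver(EnsembleSpec(n_lu=1, cv=0.0, seed=0))
        p, (state,) = whole_liver_metabolic_equilibrium(liver, [healthy_eta], 1.17)
        met, geo, _ = liver.lus[0]
        ref = solve_lu_metabolic_steady_state(p, healthy_eta, met, geo)
        assert state.ffa_cell == pytest.approx(ref.ffa_cell, abs=1e-10)
        assert state.tag == pytest.approx(ref.tag, abs=1e-8)

    def test_calibration_rejects_infeasible_anchor(self):
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_closure(k_at_ref=0.5, k_et=2.34)  # clearance alone exceeds release


class TestProgression:
    def test_unchallenged_liver_stays_at_basal_state(self):
        """Without a challenge the total intact fraction holds the stationary
        value set by basal damage and repair."""
        liver = sample_virtual_liver(EnsembleSpec(n_lu=20, cv=0.2, seed=13))
        res = simulate_progression(liver, challenge=ChallengeSchedule.constant(1.17),
                                   horizon_years=10.0, store_per_lu=False)
        expected = np.mean([stable_eta(d.k_d, d) for _, _, d in liver.lus])
        assert res.tfh[-1] == pytest.approx(expected, abs=1e-3)
        assert res.tfh.min() > expected - 2e-3

    def test_outer_step_halving_converges(self):
        liver = sample_virtual_liver(EnsembleSpec(n_lu=20, cv=0.2, seed=17))
        kw = dict(horizon_years=35.0, save_every_days=365.0, store_per_lu=False)
        coarse = simulate_progression(liver, dt_outer_days=1.0, **kw)
        fine = simulate_progression(liver, dt_outer_days=0.5, **kw)
        assert abs(coarse.tfh[-1] - fine.tfh[-1]) < 1e-3

    def test_bit_identical_reruns(self):
        livers = sample_cohort(2, EnsembleSpec(n_lu=10, cv=0.2, seed=19))
        kw = dict(horizon_years=6.0, store_per_lu=False)
        a = simulate_progression_cohort(livers, **kw)
        b = simulate_progression_cohort(livers, **kw)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.plasma_ffa, rb.plasma_ffa)
            assert np.array_equal(ra.tfh, rb.tfh)

    def test_unit_failure_raises_plasma_ffa(self):
        """Self-amplification: when units go extinct the lost extraction
        capacity shows up as a (weakly) higher plasma FFA level."""
        from nafldsim import DamageRepairParams, SinusoidGeometry
        from nafldsim.ensemble import VirtualLiver
        base = sample_virtual_liver(EnsembleSpec(n_lu=10, cv=0.1, seed=23))
        doomed = [(m, g, DamageRepairParams(k_d=0.02, k_r=d.k_r))  # beyond k_r/4
                  if i < 5 else (m, g, d)
                  for i, (m, g, d) in enumerate(base.lus)]
        liver = VirtualLiver(lus=doomed, plasma=base.plasma, spec=base.spec)
        res = simulate_progression(liver, challenge=ChallengeSchedule.constant(1.17),
                                   horizon_years=4.0, save_every_days=5.0)
        extinct = (res.eta == 0.0).any(axis=1)
        assert extinct.any(), "engineered units should be lost"
        first = int(np.argmax(extinct))
        assert res.plasma_ffa[first] >= res.plasma_ffa[0] - 1e-12
        assert np.all(np.diff(res.plasma_ffa) > -1e-12)
        assert res.plasma_ffa[-1] > res.plasma_ffa[0]

    def test_extinct_units_stay_extinct(self):
        from nafldsim import DamageRepairParams
        from nafldsim.ensemble import VirtualLiver
        base = sample_virtual_liver(EnsembleSpec(n_lu=2, cv=0.0, seed=1))
        lus = [(m, g, DamageRepairParams(k_d=0.02)) for m, g, d in base.lus]
        liver = VirtualLiver(lus=lus, plasma=base.plasma, spec=base.spec)
        res = simulate_progression(liver, challenge=ChallengeSchedule.constant(1.17),
                                   horizon_years=3.0, save_every_days=10.0)
        eta = res.eta[:, 0]
        gone = np.flatnonzero(eta == 0.0)
        assert gone.size and np.all(eta[gone[0]:] == 0.0)


class TestDiurnal:
    def test_constant_forcing_degenerates_to_steady_state(self, healthy_eta):
        liver = sample_virtual_liver(EnsembleSpec(n_lu=1, cv=0.0, seed=0))
        forcing = DiurnalForcing(vat_min=1.17, vat_max=1.17)
        res = simulate_diurnal(liver, forcing, n_days=3.0)
        met, geo, _ = liver.lus[0]
        ref = solve_lu_metabolic_steady_state(float(res.plasma_ffa.mean()), 1.0, met, geo)
        assert np.ptp(res.tag[:, 0]) < 1e-6
        assert res.ffa_cell[-1, 0] == pytest.approx(ref.ffa_cell, abs=1e-7)
        assert res.tag[-1, 0] == pytest.approx(ref.tag, abs=1e-4)

    def test_relative_amplitude_shrinks_into_the_cell(self):
        """Oscillations are damped along the transport chain
        plasma -> sinusoid -> cellular FFA."""
        liver = sample_virtual_liver(EnsembleSpec(n_lu=1, cv=0.0, seed=0))
        res = simulate_diurnal(liver, n_days=10.0)
        def rel_amp(x):
            return np.ptp(x) / x.mean()
        assert rel_amp(res.plasma_ffa) > rel_amp(res.ffa_sin[:, 0]) > rel_amp(res.ffa_cell[:, 0])


class TestChallengeSchedule:
    def test_piecewise_rates(self):
        s = ChallengeSchedule.standard_challenge(cessation_years_after_onset=10.0)
        assert s.rate_at(0.0) == 1.17
        assert s.rate_at(5.0) == 1.76
        assert s.rate_at(14.9) == 1.76
        assert s.rate_at(15.0) == 1.17

    def test_validation(self):
        with pytest.raises(ValueError):
            ChallengeSchedule(((1.0, 1.17),))
        with pytest.raises(ValueError):
            ChallengeSchedule(((0.0, 1.17), (2.0, -1.0)))
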