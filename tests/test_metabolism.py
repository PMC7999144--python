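"""Single-liver-unit kinetics: rate laws, flows, forcing, steady states."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nafldsim import (DiurnalForcing, LUMetabolicParams, LUState,
                      SinusoidGeometry, diurnal_release_rate, flux_vector,
                      lu_metabolic_rhs, sinusoid_flow,
                      solve_lu_metabolic_steady_state)
from nafldsim.metabolism import integrate_lu_metabolism


class TestFluxVector:
    def test_unit_ratio_esterification(self, ref_metabolic):
        """At F = ffa_crit_syn the super-linear factor is exactly one."""
        st_ = LUState(0.2, ref_metabolic.ffa_crit_syn, 5.0)
        fl = flux_vector(st_, ref_metabolic)
        assert fl["v_plusTAG"] == pytest.approx(
            ref_metabolic.k_plusTAG * ref_metabolic.ffa_crit_syn)

    def test_gradient_free_uptake_is_zero(self, ref_metabolic):
        st_ = LUState(0.08, 0.08, 5.0)
        assert flux_vector(st_, ref_metabolic)["v_uptake"] == 0.0

    def test_uptake_reverses_when_cell_exceeds_sinusoid(self, ref_metabolic):
        fl = flux_vector(LUState(0.05, 0.2, 5.0), ref_metabolic)
        assert fl["v_uptake"] < 0
        for name in ("v_beta", "v_plusTAG", "v_minusTAG", "v_VLDL", "v_denovo"):
            assert fl[name] >= 0

    def test_negative_concentrations_rejected(self):
        with pytest.raises(ValueError):
            LUState(-0.1, 0.05, 5.0)


class TestSinusoidFlow:
    def test_zero_pressure_zero_flow(self):
        g = SinusoidGeometry(dp_a=0.0)
        assert sinusoid_flow(g)[0] == 0.0

    def test_fourth_power_radius_law(self, ref_geometry):
        doubled = SinusoidGeometry(r_s=2 * ref_geometry.r_s)
        v0 = sinusoid_flow(ref_geometry)
        v1 = sinusoid_flow(doubled)
        assert v1[0] == pytest.approx(16 * v0[0])
        assert v1[1] == pytest.approx(16 * v0[1])

    def test_default_geometry_gives_unit_perfusion(self, ref_geometry):
        """dp = 0.2 perfuses 1 mL blood per mL liver per minute."""
        v_ap, v_vp = sinusoid_flow(ref_geometry)
        assert v_ap * ref_geometry.phi_sin == pytest.approx(1.0, rel=1e-12)
        assert v_vp == pytest.approx(v_ap)


class TestDiurnalRelease:
    def test_extremes_and_mean(self):
        f = DiurnalForcing()
        assert diurnal_release_rate(0.0, f) == pytest.approx(2.45)
        assert diurnal_release_rate(f.period / 2, f) == pytest.approx(0.35)
        tt = np.linspace(0, f.period, 100_001)
        assert np.trapezoid(diurnal_release_rate(tt, f), tt) / f.period == pytest.approx(
            1.40, abs=1e-6)

    @given(st.floats(0.01, 3.0), st.floats(0.0, 3.0), st.floats(0.0, 5000.0))
    def test_bounded_by_min_max(self, vmin, extra, t):
        f = DiurnalForcing(vat_min=vmin, vat_max=vmin + extra)
        v = diurnal_release_rate(t, f)
        assert f.vat_min - 1e-12 <= v <= f.vat_max + 1e-12


class TestMetabolicRhs:
    def test_zero_at_steady_state(self, ref_metabolic, ref_geometry):
        st_ = solve_lu_metabolic_steady_state(0.26, 1.0, ref_metabolic, ref_geometry)
        d = lu_metabolic_rhs(st_, 0.26, ref_metabolic, ref_geometry)
        assert np.max(np.abs(d)) < 1e-9

    def test_dead_unit_equilibrated_sinusoid_is_inert(self, ref_metabolic, ref_geometry):
        st_ = LUState(0.26, 0.05, 5.0, eta=0.0)
        d_sin, d_cell, d_tag = lu_metabolic_rhs(st_, 0.26, ref_metabolic, ref_geometry)
        assert d_sin == pytest.approx(0.0)
        assert d_cell == 0.0
        # TAG still drains through VLDL export (not eta-scaled)
        assert d_tag == pytest.approx(-ref_metabolic.k_VLDL * 5.0)

    def test_no_synthesis_tag_decays(self, ref_geometry):
        p = LUMetabolicParams(k_plusTAG=0.0)
        st_ = LUState(0.2, 0.08, 5.0, eta=1.0)
        _, _, d_tag = lu_metabolic_rhs(st_, 0.26, p, ref_geometry)
        assert d_tag == pytest.approx(-(p.k_minusTAG + p.k_VLDL) * 5.0)
        assert d_tag < 0


class TestSteadyStateSolver:
    def test_healthy_single_unit_ranges(self, ref_metabolic, ref_geometry):
        """Frozen fixed point at the reference plasma level, eta = 1."""
        st_ = solve_lu_metabolic_steady_state(0.26, 1.0, ref_metabolic, ref_geometry)
        assert 0.06 <= st_.ffa_cell <= 0.09
        assert 4.0 <= st_.tag <= 9.0

    def test_dead_unit_decouples(self, ref_metabolic, ref_geometry):
        st_ = solve_lu_metabolic_steady_state(0.31, 0.0, ref_metabolic, ref_geometry)
        assert st_.ffa_sin == pytest.approx(0.31)
        assert st_.ffa_cell == 0.0 and st_.tag == 0.0

    def test_empty_system_fixed_point(self, ref_geometry):
        p = LUMetabolicParams(v_denovo=0.0)
        st_ = solve_lu_metabolic_steady_state(0.0, 1.0, p, ref_geometry)
        assert st_.ffa_sin == pytest.approx(0.0, abs=1e-12)
        assert st_.ffa_cell == pytest.approx(0.0, abs=1e-12)
        assert st_.tag == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_long_time_integration(self, seed, ref_metabolic, ref_geometry):
        """Fixed-point solver agrees with the t -> infinity ODE limit."""
        rng = np.random.default_rng(seed)
        factors = dict(zip(
            ("k_u", "k_beta", "k_plusTAG", "k_minusTAG", "k_VLDL", "v_denovo"),
            np.clip(rng.normal(1.0, 0.2, 6), 0.3, None)))
        p = LUMetabolicParams(**{k: getattr(ref_metabolic, k) * v
                                 for k, v in factors.items()})
        plasma = float(rng.uniform(0.1, 0.6))
        eta = float(rng.uniform(0.3, 1.0))
        st_ = solve_lu_metabolic_steady_state(plasma, eta, p, ref_geometry)
        oracle = integrate_lu_metabolism(LUState(0.2, 0.05, 3.0, eta), plasma,
                                         p, ref_geometry, 1e5)
        assert abs(st_.ffa_cell - oracle.ffa_cell) < 1e-6
        assert abs(st_.ffa_sin - oracle.ffa_sin) < 1e-6
        assert abs(st_.tag - oracle.tag) < 1e-5
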