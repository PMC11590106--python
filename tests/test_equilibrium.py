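"""Competitive-binding cubic solver: oracles, conservation, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucompete import (
    AssayMixture,
    BindingConstants,
    IntensityReading,
    anisotropy,
    cubic_coefficients,
    fraction_difference,
    free_ligand_fraction,
    g_factor,
    mgdl_to_molar,
    molar_to_mgdl,
    solve_equilibrium,
)
from glucompete.equilibrium import EquilibriumError

from conftest import (
    G400_MOLAR,
    K_GLUCOSE,
    K_TETRAOSE,
    bisect_c_free,
    bisect_free_fraction,
)


def poly_eval(coeffs, x):
    return ((coeffs[0] * x + coeffs[1]) * x + coeffs[2]) * x + coeffs[3]


class TestCubicCoefficients:
    def test_no_ligands_root_is_total_receptor(self):
        c = cubic_coefficients(
            BindingConstants(K_M=1e-7, K_G=1e-3),
            AssayMixture(M0=0.0, C0=2e-7, G0=0.0),
        )
        # with nothing to bind, all receptor stays free: C = C0
        assert abs(poly_eval(c, 2e-7)) < 1e-12 * 2e-7

    def test_no_receptor_root_is_zero(self):
        c = cubic_coefficients(
            BindingConstants(K_M=1e-7, K_G=1e-3),
            AssayMixture(M0=1e-7, C0=0.0, G0=1e-3),
        )
        assert poly_eval(c, 0.0) == 0.0

    def test_physical_root_matches_bisection(self):
        K_M, K_G, M0, C0, G0 = K_TETRAOSE, K_GLUCOSE, 1e-7, 3e-7, 0.0
        oracle = bisect_c_free(K_M, K_G, M0, C0, G0)
        state = solve_equilibrium(
            BindingConstants(K_M=K_M, K_G=K_G), AssayMixture(M0=M0, C0=C0, G0=G0)
        )
        assert state.C_free == pytest.approx(oracle, rel=1e-10)

    def test_combined_mass_balance_residual(self):
        K_M, K_G, M0, C0, G0 = 5.4e-8, 2.5e-3, 1e-7, 3e-7, 1e-3
        state = solve_equilibrium(
            BindingConstants(K_M=K_M, K_G=K_G), AssayMixture(M0=M0, C0=C0, G0=G0)
        )
        C = state.C_free
        resid = C + C * M0 / (K_M + C) + C * G0 / (K_G + C) - C0
        assert abs(resid) < 1e-9 * C0

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(EquilibriumError):
            BindingConstants(K_M=float("nan"), K_G=1e-3)
        with pytest.raises(EquilibriumError):
            AssayMixture(M0=float("inf"), C0=1e-7)


class TestSolveEquilibrium:
    def test_no_receptor_everything_free(self):
        state = solve_equilibrium(
            BindingConstants(K_M=1e-8, K_G=1e-3),
            AssayMixture(M0=2e-7, C0=0.0, G0=5e-3),
        )
        assert state.M_free == 2e-7
        assert state.G_free == 5e-3
        assert state.CM == state.CG == state.C_free == 0.0

    def test_two_component_closed_form(self):
        # no glucose: quadratic mass action, CM = (b - sqrt(b^2-4*C0*M0))/2
        K_M, M0, C0 = K_TETRAOSE, 1e-7, 3e-7
        b = C0 + M0 + K_M
        CM = (b - math.sqrt(b * b - 4.0 * C0 * M0)) / 2.0
        expected_free = 1.0 - CM / M0
        assert expected_free == pytest.approx(0.197, abs=5e-4)  # frozen oracle
        state = solve_equilibrium(
            BindingConstants(K_M=K_M, K_G=K_GLUCOSE), AssayMixture(M0=M0, C0=C0)
        )
        mix = AssayMixture(M0=M0, C0=C0)
        assert free_ligand_fraction(state, mix) == pytest.approx(
            expected_free, rel=1e-9
        )

    def test_glucose_displaces_ligand_400_mgdl(self):
        # 400 mg/dL of glucose frees most of the ligand
        K_M, M0, C0, G0 = K_TETRAOSE, 1e-7, 3e-7, 0.0222
        oracle = bisect_free_fraction(K_M, K_GLUCOSE, M0, C0, G0)
        assert oracle == pytest.approx(0.667, abs=5e-3)
        state = solve_equilibrium(
            BindingConstants(K_M=K_M, K_G=K_GLUCOSE),
            AssayMixture(M0=M0, C0=C0, G0=G0),
        )
        assert state.M_free / M0 == pytest.approx(oracle, rel=1e-8)

    def test_oracle_equivalence_random_systems(self, rng):
        # cubic solve vs bisection on 300 random systems
        for _ in range(300):
            K_M, K_G = 10 ** rng.uniform(-9, -2, size=2)
            M0, C0 = 10 ** rng.uniform(-9, -4, size=2)
            G0 = 0.0 if rng.random() < 0.25 else 10 ** rng.uniform(-6, -1)
            state = solve_equilibrium(
                BindingConstants(K_M=K_M, K_G=K_G),
                AssayMixture(M0=M0, C0=C0, G0=G0),
            )
            oracle = bisect_c_free(K_M, K_G, M0, C0, G0)
            assert state.C_free == pytest.approx(oracle, rel=1e-8, abs=1e-18)

    def test_conservation_on_solved_states(self, rng):
        for _ in range(100):
            K_M, K_G = 10 ** rng.uniform(-9, -2, size=2)
            M0, C0 = 10 ** rng.uniform(-9, -4, size=2)
            G0 = 10 ** rng.uniform(-6, -1)
            mix = AssayMixture(M0=M0, C0=C0, G0=G0)
            s = solve_equilibrium(BindingConstants(K_M=K_M, K_G=K_G), mix)
            assert s.C_free + s.CM + s.CG == pytest.approx(C0, rel=1e-9)
            assert s.M_free + s.CM == pytest.approx(M0, rel=1e-9)
            assert s.G_free + s.CG == pytest.approx(G0, rel=1e-9)
            assert min(s.C_free, s.M_free, s.G_free, s.CM, s.CG) >= 0.0


class TestMonotonicityAndLimits:
    def test_free_fraction_decreases_with_receptor(self, tetraose_constants):
        fracs = []
        for C0 in np.logspace(-8, -5, 25):
            s = solve_equilibrium(tetraose_constants, AssayMixture(M0=1e-7, C0=C0))
            fracs.append(s.M_free / 1e-7)
        assert np.all(np.diff(fracs) <= 1e-12)

    def test_free_fraction_increases_with_glucose(self, tetraose_constants):
        fracs = []
        for G0 in np.logspace(-5, -1, 25):
            s = solve_equilibrium(
                tetraose_constants, AssayMixture(M0=1e-7, C0=3e-7, G0=G0)
            )
            fracs.append(s.M_free / 1e-7)
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_saturating_glucose_frees_all_ligand(self, tetraose_constants):
        s = solve_equilibrium(
            tetraose_constants, AssayMixture(M0=1e-7, C0=3e-7, G0=100.0)
        )
        assert s.M_free / 1e-7 == pytest.approx(1.0, abs=1e-3)

    def test_weak_glucose_equals_no_glucose(self):
        base = solve_equilibrium(
            BindingConstants(K_M=K_TETRAOSE, K_G=K_GLUCOSE),
            AssayMixture(M0=1e-7, C0=3e-7, G0=0.0),
        )
        weak = solve_equilibrium(
            BindingConstants(K_M=K_TETRAOSE, K_G=1e6),
            AssayMixture(M0=1e-7, C0=3e-7, G0=0.02),
        )
        assert weak.M_free == pytest.approx(base.M_free, rel=1e-6)

    def test_delta_f_vanishes_at_receptor_extremes(self, tetraose_constants):
        lo = fraction_difference(tetraose_constants, 1e-7, 1e-12, 0.0, G400_MOLAR)
        hi = fraction_difference(tetraose_constants, 1e-7, 1e-2, 0.0, G400_MOLAR)
        assert lo < 1e-4 and hi < 1e-3


class TestFractionDifference:
    def test_identical_endpoints_zero(self, tetraose_constants):
        assert fraction_difference(tetraose_constants, 1e-7, 3e-7, 1e-3, 1e-3) == 0.0

    def test_no_receptor_zero(self, tetraose_constants):
        assert fraction_difference(tetraose_constants, 1e-7, 0.0, 0.0, G400_MOLAR) == 0.0

    def test_design_point_near_half(self, tetraose_constants):
        dF = fraction_difference(
            tetraose_constants, 0.1e-6, 0.3e-6, 0.0, G400_MOLAR
        )
        oracle = bisect_free_fraction(
            K_TETRAOSE, K_GLUCOSE, 0.1e-6, 0.3e-6, G400_MOLAR
        ) - bisect_free_fraction(K_TETRAOSE, K_GLUCOSE, 0.1e-6, 0.3e-6, 0.0)
        assert dF == pytest.approx(oracle, rel=1e-8)
        assert dF == pytest.approx(0.47, abs=5e-3)

    def test_reversed_endpoints_rejected(self, tetraose_constants):
        with pytest.raises(EquilibriumError):
            fraction_difference(tetraose_constants, 1e-7, 3e-7, 1e-3, 0.0)


class TestAnisotropy:
    @pytest.mark.parametrize(
        "I_VV,I_VH,G,expected",
        [
            (1.0, 0.0, 1.0, 1.0),
            (1.0, 1.0, 1.0, 0.0),
            (0.5, 0.25, 0.8, 0.3 / 0.9),
        ],
    )
    def test_formula(self, I_VV, I_VH, G, expected):
        r = anisotropy(IntensityReading(I_VV=I_VV, I_VH=I_VH, G=G))
        assert r == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        scale=st.floats(1e-6, 1e6),
        I_VV=st.floats(0.01, 10.0),
        I_VH=st.floats(0.0, 10.0),
        G=st.floats(0.1, 5.0),
    )
    def test_scale_invariance(self, scale, I_VV, I_VH, G):
        r1 = anisotropy(IntensityReading(I_VV=I_VV, I_VH=I_VH, G=G))
        r2 = anisotropy(IntensityReading(I_VV=scale * I_VV, I_VH=scale * I_VH, G=G))
        assert r2 == pytest.approx(r1, abs=1e-12, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(EquilibriumError):
            anisotropy(IntensityReading(I_VV=0.0, I_VH=0.0, G=1.0))


class TestGFactorAndUnits:
    @pytest.mark.parametrize(
        "I_VH,I_VV,expected", [(1.0, 1.0, 1.0), (0.0, 2.0, 0.0), (0.6, 0.8, 0.75)]
    )
    def test_g_factor(self, I_VH, I_VV, expected):
        assert g_factor(I_VH, I_VV) == pytest.approx(expected, rel=1e-12)

    def test_g_factor_zero_reference_rejected(self):
        with pytest.raises(EquilibriumError):
            g_factor(1.0, 0.0)

    def test_g_factor_scale_invariant(self):
        assert g_factor(0.6, 0.8) == pytest.approx(g_factor(600.0, 800.0), rel=1e-12)

    def test_mgdl_conversion(self):
        assert mgdl_to_molar(0.0) == 0.0
        assert mgdl_to_molar(400.0) == pytest.approx(0.022203, abs=5e-7)

    @given(x=st.floats(0.0, 5000.0))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, x):
        assert molar_to_mgdl(mgdl_to_molar(x)) == pytest.approx(x, rel=1e-12, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(EquilibriumError):
            mgdl_to_molar(-1.0)
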