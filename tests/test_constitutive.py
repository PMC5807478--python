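"""Unit and property tests for the closed-form constitutive relations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from brainshift.constitutive import (
    D_from_nu,
    FluidPhase,
    KinematicState,
    MaterialCard,
    OgdenParams,
    PronySeries,
    conductivity_from_permeability,
    effective_stress_split,
    hereditary_shear_stress,
    nu_from_D,
    ogden_uniaxial_stress,
    permeability_from_conductivity,
    porosity_from_void_ratio,
    relaxation_modulus,
    strain_energy,
    table_card,
)

GEL = OgdenParams(mu0=794.36, alpha=-2.8, D=0.0)
GEL_PRONY = PronySeries(g=(0.13, 0.32), tau=(14.0, 333.0))


class TestStrainEnergy:
    def test_reference_state_is_zero(self):
        state = KinematicState(lam=(1.0, 1.0, 1.0))
        assert strain_energy(state, GEL) == 0.0

    def test_incompressible_uniaxial_value(self):
        # frozen from direct evaluation; cross-checked below by
        # integrating the uniaxial stress over stretch
        lam = 0.7
        state = KinematicState(lam=(lam, lam**-0.5, lam**-0.5))
        assert strain_energy(state, GEL) == pytest.approx(188.1699046149444)

    def test_energy_equals_integrated_uniaxial_work(self):
        # independent oracle: U(lam) = -int_1^lam P_nominal dlam for the
        # incompressible uniaxial path (work done on the sample)
        lam = 0.7
        val, _ = quad(
            lambda l: ogden_uniaxial_stress(l, GEL, "nominal"), 1.0, lam)
        state = KinematicState(lam=(lam, lam**-0.5, lam**-0.5))
        assert strain_energy(state, GEL) == pytest.approx(val, rel=1e-9)

    def test_deviatoric_part_linear_in_mu0(self):
        state = KinematicState(lam=(0.8, 0.8**-0.5, 0.8**-0.5))
        double = OgdenParams(mu0=2 * GEL.mu0, alpha=GEL.alpha, D=0.0)
        assert strain_energy(state, double) == pytest.approx(
            2.0 * strain_energy(state, GEL))

    def test_incompressibility_violation_raises(self):
        state = KinematicState(lam=(0.7, 1.0, 1.0))  # J != 1
        with pytest.raises(ValueError, match="J = 1"):
            strain_energy(state, GEL)


class TestUniaxialStress:
    def test_reference_state(self):
        assert ogden_uniaxial_stress(1.0, GEL) == 0.0

    def test_small_strain_modulus_is_3mu0(self):
        # incompressible small-strain Young's modulus E = 3 mu0
        eps = 1e-4
        sigma = ogden_uniaxial_stress(1.0 + eps, GEL, "cauchy")
        assert sigma / eps == pytest.approx(3.0 * GEL.mu0, rel=1e-3)

    def test_compression_value_and_sign(self):
        sigma = ogden_uniaxial_stress(0.7, GEL, "cauchy")
        assert sigma == pytest.approx(-1195.9626954551609)
        assert sigma < 0  # compression is negative

    def test_nominal_is_cauchy_over_stretch(self):
        lam = np.array([0.7, 0.9, 1.2])
        np.testing.assert_allclose(
            ogden_uniaxial_stress(lam, GEL, "nominal"),
            ogden_uniaxial_stress(lam, GEL, "cauchy") / lam,
        )

    def test_matches_energy_derivative_on_stretch_grid(self):
        # central-difference differentiation of the strain energy along
        # the incompressible uniaxial path, 1e-6 relative on [0.6, 1.4]
        d = 1e-6

        def U(l):
            return strain_energy(
                KinematicState(lam=(l, l**-0.5, l**-0.5)), GEL)

        for lam in np.linspace(0.6, 1.4, 17):
            num = (U(lam + d) - U(lam - d)) / (2.0 * d)
            ana = ogden_uniaxial_stress(lam, GEL, "nominal")
            if lam == 1.0:
                assert abs(num - ana) < 1e-6 * GEL.mu0
            else:
                assert num == pytest.approx(ana, rel=1e-6)


class TestRelaxation:
    def test_instantaneous_value(self):
        assert relaxation_modulus(0.0, GEL.mu0, GEL_PRONY) == GEL.mu0

    def test_long_term_fraction(self):
        # 1 - sum(g) = 0.55 -> 436.898 Pa for the characterized gel
        assert relaxation_modulus(1e9, GEL.mu0, GEL_PRONY) == pytest.approx(
            436.898, abs=1e-3)

    def test_value_at_end_of_hold(self):
        assert relaxation_modulus(500.0, GEL.mu0, GEL_PRONY) == pytest.approx(
            493.5315165026113)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            relaxation_modulus(-1.0, GEL.mu0, GEL_PRONY)

    @given(
        g1=st.floats(0.0, 0.45),
        g2=st.floats(0.0, 0.45),
        t1=st.floats(0.1, 100.0),
        t2=st.floats(0.1, 1000.0),
    )
    def test_non_increasing_and_bounded(self, g1, g2, t1, t2):
        series = PronySeries(g=(g1, g2), tau=(t1, t2))
        t = np.linspace(0.0, 5000.0, 200)
        mu = relaxation_modulus(t, GEL.mu0, series)
        assert np.all(np.diff(mu) <= 1e-12 * GEL.mu0)
        lo = GEL.mu0 * (1.0 - g1 - g2)
        assert np.all(mu <= GEL.mu0 * (1 + 1e-12))
        assert np.all(mu >= lo * (1 - 1e-12))


def _direct_convolution(t, gamma, mu0, prony):
    """O(N^2) trapezoidal hereditary integral — independent oracle."""
    out = np.empty_like(gamma)
    out[0] = mu0 * gamma[0]
    rate = np.diff(gamma) / np.diff(t)
    for i in range(1, len(t)):
        # step applied at t=0 plus piecewise-constant-rate segments
        acc = mu0 * prony.g_R(t[i]) * gamma[0]
        for j in range(i):
            # integrate mu(t_i - s) * rate_j over [t_j, t_{j+1}] exactly
            a, b = t[j], t[j + 1]
            seg = 1.0 * (b - a)
            for g, tau in zip(prony.g, prony.tau):
                seg -= g * (b - a)
                seg += g * tau * (np.exp(-(t[i] - b) / tau)
                                  - np.exp(-(t[i] - a) / tau))
            acc += mu0 * rate[j] * seg
        out[i] = acc
    return out


class TestHereditaryIntegral:
    def test_zero_strain_gives_zero_stress(self):
        t = np.linspace(0, 10, 50)
        tau = hereditary_shear_stress(t, np.zeros_like(t), GEL.mu0, GEL_PRONY)
        assert np.all(tau == 0.0)

    def test_step_strain_matches_relaxation_modulus(self):
        t = np.linspace(0, 800, 400)
        gamma0 = 0.05
        tau = hereditary_shear_stress(t, np.full_like(t, gamma0),
                                      GEL.mu0, GEL_PRONY)
        expected = relaxation_modulus(t, GEL.mu0, GEL_PRONY) * gamma0
        np.testing.assert_allclose(tau, expected, rtol=1e-6)

    def test_constant_rate_ramp_matches_analytic_convolution(self):
        t = np.linspace(0, 100, 500)
        c = 2e-3
        tau = hereditary_shear_stress(t, c * t, GEL.mu0, GEL_PRONY)
        ana = c * GEL.mu0 * (
            t - sum(g * (t - ti * (1 - np.exp(-t / ti)))
                    for g, ti in zip(GEL_PRONY.g, GEL_PRONY.tau)))
        np.testing.assert_allclose(tau[1:], ana[1:], rtol=1e-4)

    def test_recursive_update_matches_direct_convolution(self, rng):
        # exactness for piecewise-linear strain vs the O(N^2) oracle
        t = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 60.0, 40))])
        gamma = rng.normal(0.0, 0.02, len(t))
        fast = hereditary_shear_stress(t, gamma, GEL.mu0, GEL_PRONY)
        slow = _direct_convolution(t, gamma, GEL.mu0, GEL_PRONY)
        np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-9)

    def test_empty_series_is_elastic(self):
        t = np.linspace(0, 10, 30)
        gamma = np.sin(t) * 0.01
        tau = hereditary_shear_stress(t, gamma, GEL.mu0, PronySeries())
        np.testing.assert_allclose(tau, GEL.mu0 * gamma)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            hereditary_shear_stress(np.array([0.0, 2.0, 1.0]),
                                    np.zeros(3), GEL.mu0, GEL_PRONY)


class TestEffectiveStress:
    def test_pure_pressure(self):
        out = effective_stress_split(np.zeros((3, 3)), 1000.0)
        np.testing.assert_allclose(out, -1000.0 * np.eye(3))

    def test_zero_pressure_is_identity(self):
        sig = np.diag([1.0, 2.0, 3.0])
        np.testing.assert_allclose(effective_stress_split(sig, 0.0), sig)

    def test_trace_identity_on_random_tensors(self, rng):
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            sig = a + a.T
            p = rng.normal() * 100
            out = effective_stress_split(sig, p)
            assert np.trace(out) == pytest.approx(np.trace(sig) - 3 * p)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            effective_stress_split(np.array([[0.0, 1.0], [0.0, 0.0]]), 1.0)


class TestParameterConversions:
    def test_characterized_gel_D(self):
        # two significant figures of the published 0.84e-3 1/Pa
        assert D_from_nu(794.36, 0.35) == pytest.approx(0.84e-3, rel=5e-3)

    def test_incompressible_limit(self):
        assert D_from_nu(794.36, 0.5) == 0.0

    def test_direct_evaluation(self):
        assert D_from_nu(1000.0, 0.3) == pytest.approx(9.230769e-4, rel=1e-6)

    @given(nu=st.floats(0.0, 0.499), mu0=st.floats(1.0, 1e6))
    def test_round_trip(self, nu, mu0):
        assert nu_from_D(mu0, D_from_nu(mu0, nu)) == pytest.approx(
            nu, abs=1e-10)

    @pytest.mark.parametrize("e, n", [(0.0, 0.0), (1.0, 0.5), (0.2, 1 / 6)])
    def test_porosity(self, e, n):
        assert porosity_from_void_ratio(e) == pytest.approx(n, abs=1e-4)

    def test_permeability_conversion(self):
        Pi = permeability_from_conductivity(1.57e-9, 1e-3, 1000.0, 9.812)
        assert Pi == pytest.approx(1.6000815e-16, rel=1e-6)
        assert permeability_from_conductivity(2 * 1.57e-9, 1e-3, 1000.0,
                                              9.812) == pytest.approx(2 * Pi)
        back = conductivity_from_permeability(Pi, 1e-3, 1000.0, 9.812)
        assert back == pytest.approx(1.57e-9, abs=1e-12)


class TestMaterialCards:
    def test_table_cards_parse(self):
        phve = table_card("PHVE")
        assert phve.ogden.mu0 == 794.36
        assert phve.ogden.alpha == -2.8
        assert phve.prony.g == (0.13, 0.32)
        assert phve.fluid.k == 1.57e-9
        assert table_card("PHE").prony.long_term_fraction == 1.0
        hve = table_card("HVE")
        assert hve.fluid is None and hve.ogden.nu == 0.5

    def test_hve_with_fluid_rejected(self):
        with pytest.raises(ValueError):
            MaterialCard(name="HVE",
                         ogden=OgdenParams(mu0=794.36, alpha=-2.8, D=0.0),
                         prony=GEL_PRONY, fluid=FluidPhase(k=1e-9))

    def test_phe_with_prony_rejected(self):
        with pytest.raises(ValueError):
            MaterialCard(name="PHE",
                         ogden=OgdenParams(mu0=794.36, alpha=-2.8, D=8.4e-4),
                         prony=GEL_PRONY, fluid=FluidPhase(k=1e-9))

    def test_overfull_prony_rejected(self):
        with pytest.raises(ValueError):
            PronySeries(g=(0.6, 0.5), tau=(1.0, 10.0))

    def test_gamma_w_consistency_enforced(self):
        with pytest.raises(ValueError, match="gamma_w"):
            FluidPhase(k=1e-9, gamma_w=5000.0, rho_w=1000.0)
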