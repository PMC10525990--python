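"""Material laws: Gruneisen EOS, linear elasticity, Newtonian viscosity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocufsi.constitutive import (ElasticMaterial, FluidMaterial, PRESETS,
                                 cauchy_stress_small_strain,
                                 compression_from_relative_volume,
                                 gruneisen_pressure,
                                 relative_volume_from_compression,
                                 viscous_deviatoric_stress)

AQ = PRESETS["aqueous_humor"]
JCT = PRESETS["jct_high_flow"]


class TestCompression:
    @pytest.mark.parametrize("V, mu", [(1.0, 0.0), (0.5, 1.0),
                                       (0.99, 1.0 / 0.99 - 1.0)])
    def test_closed_form(self, V, mu):
        assert compression_from_relative_volume(V) == pytest.approx(mu)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            compression_from_relative_volume(0.0)

    @given(st.floats(0.3, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, V):
        mu = compression_from_relative_volume(V)
        assert relative_volume_from_compression(mu) == pytest.approx(V)


class TestGruneisen:
    def test_reference_state(self):
        assert gruneisen_pressure(0.0, 0.0, AQ) == 0.0

    def test_energy_only_term(self):
        # at mu=0 only (gamma0 + a*mu) * E survives
        assert gruneisen_pressure(0.0, 1000.0, AQ) == pytest.approx(500.0)

    def test_compression_closed_form(self):
        # frozen from an independent single-line evaluation of the cubic
        # Hugoniot form with the aqueous-humor constants
        assert gruneisen_pressure(0.01, 0.0, AQ) == pytest.approx(
            2.2764e7, rel=1e-3)

    def test_continuity_and_acoustic_limit(self):
        k0 = AQ.rho0 * AQ.C ** 2
        for mu in (1e-8, -1e-8):
            p = gruneisen_pressure(mu, 0.0, AQ)
            assert p == pytest.approx(k0 * mu, rel=1e-4)

    def test_expansion_branch_linear(self):
        k0 = AQ.rho0 * AQ.C ** 2
        assert gruneisen_pressure(-0.01, 0.0, AQ) == pytest.approx(-0.01 * k0)

    def test_invalid_compression(self):
        with pytest.raises(ValueError):
            gruneisen_pressure(-1.0, 0.0, AQ)


class TestElastic:
    def test_lame_parameters(self):
        m = ElasticMaterial(E=3.05e3, nu=0.495, rho=700.0)
        lam = 3.05e3 * 0.495 / ((1 + 0.495) * (1 - 2 * 0.495))
        G = 3.05e3 / (2 * 1.495)
        assert m.lam == pytest.approx(lam)
        assert m.shear_modulus == pytest.approx(G)

    def test_zero_strain(self):
        assert np.allclose(cauchy_stress_small_strain(np.zeros((3, 3)), JCT), 0)

    def test_pure_shear(self):
        g = 0.02
        eps = np.zeros((3, 3))
        eps[0, 1] = eps[1, 0] = g / 2
        sig = cauchy_stress_small_strain(eps, JCT)
        assert sig[0, 1] == pytest.approx(JCT.shear_modulus * g)
        assert sig[0, 0] == sig[1, 1] == sig[2, 2] == 0.0

    def test_against_stiffness_matrix_oracle(self):
        # independent oracle: assemble the 6x6 isotropic stiffness in Voigt
        # notation and multiply
        lam, G = JCT.lam, JCT.shear_modulus
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.diag_indices(3)] = lam + 2 * G
        C[3, 3] = C[4, 4] = C[5, 5] = G
        rng = np.random.default_rng(42)
        for _ in range(100):
            e = rng.normal(size=(3, 3))
            e = 0.5 * (e + e.T) * 0.01
            voigt = np.array([e[0, 0], e[1, 1], e[2, 2],
                              2 * e[1, 2], 2 * e[0, 2], 2 * e[0, 1]])
            s_v = C @ voigt
            expected = np.array([[s_v[0], s_v[5], s_v[4]],
                                 [s_v[5], s_v[1], s_v[3]],
                                 [s_v[4], s_v[3], s_v[2]]])
            got = cauchy_stress_small_strain(e, JCT)
            assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            ElasticMaterial(E=-1, nu=0.3, rho=1000)
        with pytest.raises(ValueError):
            ElasticMaterial(E=1e3, nu=0.5, rho=1000)


class TestViscous:
    def test_rigid_rotation_stress_free(self):
        W = np.array([[0.0, 3.0], [-3.0, 0.0]])
        assert np.allclose(viscous_deviatoric_stress(W, AQ.mu_dyn), 0.0)

    def test_simple_shear(self):
        k = 100.0
        L = np.array([[0.0, k], [0.0, 0.0]])
        tau = viscous_deviatoric_stress(L, AQ.mu_dyn)
        assert tau[0, 1] == pytest.approx(AQ.mu_dyn * k)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_traceless(self, seed):
        L = np.random.default_rng(seed).normal(size=(3, 3)) * 100
        tau = viscous_deviatoric_stress(L, AQ.mu_dyn)
        assert abs(np.trace(tau)) < 1e-12 * max(1.0, np.abs(tau).max())


def test_presets_are_reported_constants():
    assert JCT.E == pytest.approx(3.05e3)
    assert JCT.nu == 0.495
    assert JCT.rho == 700.0
    scl = PRESETS["sclera"]
    assert scl.E == pytest.approx(2.54e6)
    assert (AQ.rho0, AQ.mu_dyn) == (1000.0, 0.7185e-3)
    assert (AQ.C, AQ.S1, AQ.S2, AQ.S3, AQ.gamma0, AQ.a) == (
        1480.0, 2.56, -1.98, 0.226, 0.5, 0.0)
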