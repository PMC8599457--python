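"""Transversely isotropic algebra and the axis-aligned indentation moduli."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberindent.elastic import (
    AdmissibilityError,
    TransverseIsotropicConstants,
    compliance_from_engineering,
    ellipticity,
    indentation_modulus_longitudinal,
    indentation_modulus_transverse,
    isotropic_indentation_modulus,
    rotate_stiffness,
    stiffness_from_compliance,
    stiffness_from_engineering,
)

from conftest import isotropic, random_admissible


class TestCompliance:
    def test_isotropic_unit_modulus_zero_poisson_is_identity_diagonal(self):
        S = compliance_from_engineering(isotropic(1.0, 0.0))
        assert np.allclose(S, np.diag([1, 1, 1, 2, 2, 2]))

    def test_pulp_constants_elementwise(self, pulp_constants):
        S = compliance_from_engineering(pulp_constants)
        assert S[2, 2] == pytest.approx(0.125)
        assert S[0, 0] == pytest.approx(1 / 1.1, abs=1e-4)
        assert S[0, 2] == pytest.approx(-0.03125)
        assert np.allclose(S, S.T)

    def test_negative_modulus_rejected(self):
        with pytest.raises(AdmissibilityError):
            TransverseIsotropicConstants(8.0, -1.0, 0.25, 0.25, 2.51)

    def test_inadmissible_poisson_combination_rejected(self):
        # nu_TT near -1 with large nu_LT violates positive definiteness
        with pytest.raises(AdmissibilityError):
            compliance_from_engineering(
                TransverseIsotropicConstants(2.0, 2.0, 0.9, 0.9, 1.0)
            )


class TestStiffness:
    def test_identity_round_trip(self):
        C = stiffness_from_compliance(np.eye(6))
        assert np.allclose(C.matrix, np.eye(6))

    def test_isotropic_lame_closed_form(self):
        # E=4, nu=0.3: lambda = E nu/((1+nu)(1-2nu)), mu = E/(2(1+nu))
        C = stiffness_from_engineering(isotropic(4.0, 0.3))
        assert C.C1111 == pytest.approx(5.3846, abs=1e-4)
        assert C.C1133 == pytest.approx(2.3077, abs=1e-4)
        assert C.C2323 == pytest.approx(1.5385, abs=1e-4)

    def test_round_trip_and_positive_definite_random(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = random_admissible(rng)
            S = compliance_from_engineering(c)
            C = stiffness_from_compliance(S)
            assert np.linalg.eigvalsh(C.matrix).min() > 0
            back = np.linalg.inv(C.matrix)
            assert np.max(np.abs(back - S)) < 1e-10 * max(1.0, np.abs(S).max())

    def test_in_plane_isotropy_relation(self, pulp_constants):
        C = stiffness_from_engineering(pulp_constants)
        assert C.matrix[5, 5] == pytest.approx(C.C6666, rel=1e-12)
        assert C.matrix[0, 0] == pytest.approx(C.matrix[1, 1], rel=1e-12)
        assert C.matrix[0, 2] == pytest.approx(C.matrix[1, 2], rel=1e-12)


class TestRotation:
    def test_zero_rotation_is_identity(self, pulp_constants):
        C = stiffness_from_engineering(pulp_constants)
        assert np.array_equal(rotate_stiffness(C, 0.0), C.matrix)

    def test_ninety_degrees_swaps_axes(self, pulp_constants):
        C = stiffness_from_engineering(pulp_constants)
        R = rotate_stiffness(C, 90.0)
        assert R[0, 0] == pytest.approx(C.C3333, rel=1e-10)
        assert R[2, 2] == pytest.approx(C.C1111, rel=1e-10)
        assert R[1, 1] == pytest.approx(C.matrix[1, 1], rel=1e-10)

    def test_inverse_rotation_composes_to_identity(self, pulp_constants):
        C = stiffness_from_engineering(pulp_constants)
        back = rotate_stiffness(rotate_stiffness(C, 20.0), -20.0)
        assert np.max(np.abs(back - C.matrix)) < 1e-12 * np.abs(C.matrix).max()

    def test_trace_invariant(self, pulp_constants):
        # the (ii)(jj) block trace of the elasticity tensor is rotation-invariant
        C = stiffness_from_engineering(pulp_constants).matrix
        R = rotate_stiffness(C, 35.0)
        assert R[:3, :3].sum() == pytest.approx(C[:3, :3].sum(), rel=1e-10)


class TestIndentationModuli:
    @given(
        E=st.floats(0.5, 50.0),
        nu=st.floats(-0.3, 0.45),
    )
    @settings(max_examples=50, deadline=None)
    def test_isotropic_limit_both_directions(self, E, nu):
        """In the isotropic limit both moduli equal E/(1-nu^2) to 1e-9 E."""
        M_ref = isotropic_indentation_modulus(E, nu)
        C = stiffness_from_engineering(isotropic(E, nu))
        assert abs(indentation_modulus_longitudinal(C) - M_ref) < 1e-9 * E
        assert abs(indentation_modulus_transverse(C) - M_ref) < 1e-9 * E

    def test_isotropic_oracle_values(self):
        assert isotropic_indentation_modulus(1.0, 0.0) == pytest.approx(1.0)
        assert isotropic_indentation_modulus(4.0, 0.3) == pytest.approx(
            4.3956, abs=1e-4
        )

    def test_longitudinal_forward_values_match_identified_pairs(self, fixed_params):
        """Forward M_L at identified (E_L, E_T) pairs reproduces the measured
        longitudinal indentation moduli they were identified from."""
        for (E_L, E_T), M_L in [((11.1, 1.1), 7.06), ((8.0, 1.1), 5.75)]:
            c = TransverseIsotropicConstants(
                E_L, E_T, fixed_params.nu_LT, fixed_params.nu_TT, fixed_params.G_LT
            )
            assert indentation_modulus_longitudinal(
                stiffness_from_engineering(c)
            ) == pytest.approx(M_L, abs=0.03)

    def test_transverse_forward_value_matches_identified_pair(self, fixed_params):
        c = TransverseIsotropicConstants(
            11.1, 1.1, fixed_params.nu_LT, fixed_params.nu_TT, fixed_params.G_LT
        )
        assert indentation_modulus_transverse(
            stiffness_from_engineering(c)
        ) == pytest.approx(1.57, abs=0.03)

    def test_ellipticity_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c = random_admissible(rng)
            e = ellipticity(stiffness_from_engineering(c))
            assert 0.0 <= e < 1.0

    def test_monotonicity_in_own_direction(self):
        """M_L strictly increases in E_L; M_T strictly increases in E_T."""
        ELs = np.linspace(2.0, 30.0, 20)
        ETs = np.linspace(0.5, 3.0, 20)
        ML = np.array(
            [
                indentation_modulus_longitudinal(
                    stiffness_from_engineering(
                        TransverseIsotropicConstants(EL, 1.1, 0.25, 0.25, 2.51)
                    )
                )
                for EL in ELs
            ]
        )
        MT = np.array(
            [
                indentation_modulus_transverse(
                    stiffness_from_engineering(
                        TransverseIsotropicConstants(8.0, ET, 0.25, 0.25, 2.51)
                    )
                )
                for ET in ETs
            ]
        )
        assert np.all(np.diff(ML) > 0)
        assert np.all(np.diff(MT) > 0)
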