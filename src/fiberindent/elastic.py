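"""Transversely isotropic elasticity and axis-aligned indentation moduli.

The fiber wall is modelled as a transversely isotropic solid with the symmetry
(strong) axis 3 along the fiber's longitudinal direction and an isotropic
transverse plane (axes 1, 2).  Five engineering constants describe it:
``E_L`` (axial Young's modulus), ``E_T`` (transverse Young's modulus),
``nu_LT`` (axial Poisson ratio, paired with ``nu_TL`` through the symmetry
relation ``nu_TL/E_T = nu_LT/E_L``), ``nu_TT`` (in-plane Poisson ratio) and
``G_LT`` (axial shear modulus).

Indentation along the symmetry axis and perpendicular to it mixes the Voigt
stiffness components in different ways; the closed-form expressions used here
are the conical-indenter approximations of Delafargue and Ulm for transversely
isotropic half-spaces.  Voigt notation uses engineering shear strains, so the
shear compliances carry the conventional factor (S44 = 1/G_LT,
S66 = 2(1 + nu_TT)/E_T).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ellipe

__all__ = [
    "AdmissibilityError",
    "TransverseIsotropicConstants",
    "StiffnessMatrix",
    "compliance_from_engineering",
    "stiffness_from_compliance",
    "stiffness_from_engineering",
    "rotate_stiffness",
    "indentation_modulus_longitudinal",
    "indentation_modulus_transverse",
    "isotropic_indentation_modulus",
]


class AdmissibilityError(ValueError):
    """Raised when elastic constants violate thermodynamic admissibility."""


@dataclass(frozen=True)
class TransverseIsotropicConstants:
    """Engineering constants of a transversely isotropic solid (GPa / unitless).

    ``theta`` is the microfibril angle in degrees: the tilt of the cellulose
    fibril direction (material symmetry axis) away from the fiber's
    longitudinal axis.  It is carried as metadata and used only by
    :func:`rotate_stiffness`; the axis-aligned indentation moduli assume
    ``theta = 0``.
    """

    E_L: float
    E_T: float
    nu_LT: float
    nu_TT: float
    G_LT: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.E_L <= 0 or self.E_T <= 0 or self.G_LT <= 0:
            raise AdmissibilityError(
                f"moduli must be positive, got E_L={self.E_L}, E_T={self.E_T}, "
                f"G_LT={self.G_LT}"
            )
        if not 0.0 <= self.theta < 90.0:
            raise AdmissibilityError(f"theta must lie in [0, 90), got {self.theta}")

    @property
    def nu_TL(self) -> float:
        """Transverse-axial Poisson ratio from the symmetry relation."""
        return self.nu_LT * self.E_T / self.E_L

    def with_updates(self, **kwargs) -> "TransverseIsotropicConstants":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StiffnessMatrix:
    """Voigt 6x6 stiffness of a transversely isotropic solid about axis 3."""

    matrix: np.ndarray

    @property
    def C1111(self) -> float:
        return float(self.matrix[0, 0])

    @property
    def C1122(self) -> float:
        return float(self.matrix[0, 1])

    @property
    def C1133(self) -> float:
        return float(self.matrix[0, 2])

    @property
    def C3333(self) -> float:
        return float(self.matrix[2, 2])

    @property
    def C2323(self) -> float:
        return float(self.matrix[3, 3])

    @property
    def C6666(self) -> float:
        """In-plane shear stiffness, dependent: (C1111 - C1122)/2."""
        return 0.5 * (self.C1111 - self.C1122)


def _require_spd(mat: np.ndarray, what: str) -> None:
    eigs = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    if eigs.min() <= 0:
        raise AdmissibilityError(
            f"{what} is not positive definite (min eigenvalue {eigs.min():.3e}); "
            "the elastic constants are thermodynamically inadmissible"
        )


def compliance_from_engineering(constants: TransverseIsotropicConstants) -> np.ndarray:
    """Assemble the 6x6 Voigt compliance matrix (1/GPa) from engineering constants.

    S11 = S22 = 1/E_T, S33 = 1/E_L, S12 = -nu_TT/E_T, S13 = S23 = -nu_LT/E_L,
    S44 = S55 = 1/G_LT, S66 = 2(1 + nu_TT)/E_T (engineering shear strains).

    Raises :class:`AdmissibilityError` if the assembled matrix is not positive
    definite.
    """
    c = constants
    S = np.zeros((6, 6))
    S[0, 0] = S[1, 1] = 1.0 / c.E_T
    S[2, 2] = 1.0 / c.E_L
    S[0, 1] = S[1, 0] = -c.nu_TT / c.E_T
    S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = -c.nu_LT / c.E_L
    S[3, 3] = S[4, 4] = 1.0 / c.G_LT
    S[5, 5] = 2.0 * (1.0 + c.nu_TT) / c.E_T
    _require_spd(S, "compliance matrix")
    return S


def stiffness_from_compliance(S: np.ndarray) -> StiffnessMatrix:
    """Invert a Voigt compliance matrix to a :class:`StiffnessMatrix` (GPa)."""
    S = np.asarray(S, dtype=float)
    if S.shape != (6, 6):
        raise ValueError(f"expected a 6x6 matrix, got shape {S.shape}")
    if not np.allclose(S, S.T, rtol=0, atol=1e-10 * max(1.0, np.abs(S).max())):
        raise AdmissibilityError("compliance matrix must be symmetric")
    _require_spd(S, "compliance matrix")
    C = np.linalg.inv(S)
    return StiffnessMatrix(matrix=0.5 * (C + C.T))


def stiffness_from_engineering(constants: TransverseIsotropicConstants) -> StiffnessMatrix:
    """Shorthand for ``stiffness_from_compliance(compliance_from_engineering(c))``."""
    return stiffness_from_compliance(compliance_from_engineering(constants))


def _rotation_about_axis2(theta_deg: float) -> np.ndarray:
    """3x3 rotation by theta about the in-plane axis 2 (tilts axis 3 toward 1)."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _bond_matrix(a: np.ndarray) -> np.ndarray:
    """Bond stress-transformation matrix for Voigt 6x6 rotation."""
    # Voigt pair ordering: 11, 22, 33, 23, 13, 12
    pairs = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    M = np.zeros((6, 6))
    for I, (i, j) in enumerate(pairs):
        for J, (k, l) in enumerate(pairs):
            if J < 3:
                M[I, J] = a[i, k] * a[j, k]
            else:
                M[I, J] = a[i, k] * a[j, l] + a[i, l] * a[j, k]
    return M


def rotate_stiffness(C: StiffnessMatrix | np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate a Voigt stiffness by ``theta_deg`` about the in-plane axis 2.

    Sensitivity utility for exploring a nonzero microfibril angle: the result
    is generally not transversely isotropic about axis 3.  ``theta_deg = 0``
    returns the input unchanged.
    """
    mat = C.matrix if isinstance(C, StiffnessMatrix) else np.asarray(C, dtype=float)
    if theta_deg == 0.0:
        return mat.copy()
    M = _bond_matrix(_rotation_about_axis2(theta_deg))
    return M @ mat @ M.T


def _as_stiffness(C: StiffnessMatrix | TransverseIsotropicConstants) -> StiffnessMatrix:
    if isinstance(C, TransverseIsotropicConstants):
        return stiffness_from_engineering(C)
    return C


def indentation_modulus_longitudinal(
    C: StiffnessMatrix | TransverseIsotropicConstants,
) -> float:
    """Indentation modulus M_L (GPa) for indentation along the symmetry axis.

    M_L = 2 sqrt[ (C1111 C3333 - C1133^2)/C1111
                  / (1/C2323 + 2/(sqrt(C1111 C3333) + C1133)) ].
    """
    C = _as_stiffness(C)
    c11, c13, c33, c44 = C.C1111, C.C1133, C.C3333, C.C2323
    num = (c11 * c33 - c13**2) / c11
    den = 1.0 / c44 + 2.0 / (np.sqrt(c11 * c33) + c13)
    if num <= 0 or den <= 0:
        raise AdmissibilityError(
            f"longitudinal indentation modulus undefined: "
            f"(C1111*C3333 - C1133^2)/C1111 = {num:.4g}, "
            f"1/C2323 + 2/(sqrt(C1111*C3333)+C1133) = {den:.4g}"
        )
    return float(2.0 * np.sqrt(num / den))


def _surface_amplitudes(C: StiffnessMatrix) -> tuple[float, float]:
    """Green's-function amplitudes of the surface cut normal to a transverse axis.

    For indentation perpendicular to the symmetry axis the free surface
    contains one transverse axis and the symmetry axis.  ``h_axial`` is the
    compliance amplitude associated with the stiff (fiber-axis) surface
    direction and ``h_plane`` the one associated with the in-plane transverse
    direction; both reduce to 1/(pi*M) in the isotropic limit.
    """
    c11, c12, c13, c33, c44 = C.C1111, C.C1122, C.C1133, C.C3333, C.C2323
    rad = c33 / (c33 * c11 - c13**2) * (1.0 / c44 + 2.0 / (np.sqrt(c33 * c11) + c13))
    if rad <= 0:
        raise AdmissibilityError(
            f"transverse indentation modulus undefined: axial amplitude radicand "
            f"{rad:.4g} <= 0"
        )
    h_axial = np.sqrt(rad) / (2.0 * np.pi)
    h_plane = c11 / (np.pi * (c11**2 - c12**2))
    if h_plane <= 0:
        raise AdmissibilityError(
            f"transverse indentation modulus undefined: in-plane amplitude "
            f"{h_plane:.4g} <= 0 (C1111^2 <= C1122^2)"
        )
    return float(h_axial), float(h_plane)


def indentation_modulus_transverse(
    C: StiffnessMatrix | TransverseIsotropicConstants,
) -> float:
    """Indentation modulus M_T (GPa) for indentation perpendicular to the axis.

    The contact patch is elliptical; with the two principal surface compliance
    amplitudes h_axial and h_plane, the ellipticity is
    e = sqrt(1 - min(h)/max(h)) and

        M_T = 1 / (2 E(e) h_axial^{1/4} h_plane^{3/4}),

    where E(e) is the complete elliptic integral of the second kind of modulus
    e.  The dominant 3/4 weight sits on the in-plane (compliant) amplitude;
    this weighting reproduces the isotropic limit exactly and is the one
    consistent with the identified transverse moduli of pulp fibers (see
    docs/methods.md for the convention discussion).
    """
    C = _as_stiffness(C)
    h_axial, h_plane = _surface_amplitudes(C)
    lo, hi = min(h_axial, h_plane), max(h_axial, h_plane)
    e = np.sqrt(1.0 - lo / hi)
    # scipy's ellipe takes the parameter m = e^2, not the modulus e
    E_e = ellipe(e**2)
    return float(1.0 / (2.0 * E_e * h_axial**0.25 * h_plane**0.75))


def ellipticity(C: StiffnessMatrix | TransverseIsotropicConstants) -> float:
    """Degree of ellipticity e in [0, 1) of the transverse contact patch."""
    C = _as_stiffness(C)
    h_axial, h_plane = _surface_amplitudes(C)
    lo, hi = min(h_axial, h_plane), max(h_axial, h_plane)
    return float(np.sqrt(1.0 - lo / hi))


def isotropic_indentation_modulus(E: float, nu: float) -> float:
    """Plane-strain indentation modulus E/(1 - nu^2) of an isotropic solid."""
    if E <= 0:
        raise AdmissibilityError(f"E must be positive, got {E}")
    if not -1.0 < nu < 0.5:
        raise AdmissibilityError(f"nu must lie in (-1, 0.5), got {nu}")
    return E / (1.0 - nu**2)
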