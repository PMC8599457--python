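"""Creep-corrected analysis of nanoindentation force-displacement curves.

A raw per-indent record (time, force, depth) acquired under a trapezoidal load
schedule — ramp to peak, hold at peak, force-controlled unload, drift window —
is turned into an indentation modulus:

1. segment the record into approach / load / hold / unload / drift,
2. subtract the linear thermal drift estimated in the drift window,
3. compensate machine compliance,
4. fit the hold-phase creep law  z(t) = D5 + D6 t^D7,
5. fit the unloading curve      z(F) = D1 + D2 sqrt(F) + D3 F^D4,
6. observed unloading stiffness S_u = (dz/dF at F_max)^-1,
7. creep-correct it (Feng-Ngan): 1/S = 1/S_u - zdot(tau_u)/Fdot,
8. contact depth (Oliver-Pharr): z_c = z_max - eps F_max / S,
9. contact area A(z_c) from the tip geometry,
10. indentation modulus (BASh):  M = sqrt(pi) S / (2 beta sqrt(A)).

Units throughout: time s, force uN, depth nm, stiffness uN/nm, area nm^2,
modulus GPa (1 uN/nm^2 = 1000 GPa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SegmentationError",
    "FitError",
    "UnreliableStiffnessError",
    "LoadSchedule",
    "TipGeometry",
    "IndentationCurve",
    "UnloadingFit",
    "CreepFit",
    "IndentationResult",
    "segment_schedule",
    "correct_drift",
    "compensate_machine_compliance",
    "fit_unloading",
    "unloading_stiffness",
    "fit_hold_creep",
    "creep_corrected_stiffness",
    "contact_depth",
    "contact_area",
    "indentation_modulus",
    "process_curve",
]

SEGMENTS = ("approach", "load", "hold", "unload", "drift")


class SegmentationError(ValueError):
    """Record does not cover the expected load schedule."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge."""


class UnreliableStiffnessError(RuntimeError):
    """Creep dominates the unloading slope; the elastic stiffness is undefined."""


@dataclass(frozen=True)
class LoadSchedule:
    """Target load schedule of one indent.

    Defaults follow the AFM-NI protocol: 1 s ramp to peak, 10 s hold,
    force-controlled unload to 5% of peak over 1 s, 30 s drift window.
    """

    peak_uN: float = 20.0
    ramp_s: float = 1.0
    hold_s: float = 10.0
    unload_s: float = 1.0
    stop_fraction: float = 0.05
    drift_s: float = 30.0

    @property
    def unload_rate_uN_s(self) -> float:
        """Signed force rate during unload (negative)."""
        return -(1.0 - self.stop_fraction) * self.peak_uN / self.unload_s


@dataclass(frozen=True)
class TipGeometry:
    """Indenter geometry and projected-area function parameters.

    ``shape`` selects the ideal area function: a hemisphere of radius ``R_nm``
    (spherical cap, continued as a cylinder past full immersion), a four-sided
    pyramid with 45 deg faces and a spherical cap of radius ``R_nm`` at the
    apex, or a cube corner with the same cap blend.  ``beta`` is the BASh
    geometry correction (1.0 hemisphere, 1.05 pyramid/cube corner) and
    ``epsilon`` the Oliver-Pharr contact-depth factor.  A calibrated polynomial
    area function ``area_coefficients`` = (C0, C1, C2, ...) for
    A = C0 z^2 + C1 z + C2 z^(1/2) + C3 z^(1/4) + ... overrides the ideal
    geometry when provided.
    """

    shape: Literal["hemisphere", "pyramid", "cube_corner"]
    R_nm: float
    beta: float | None = None
    epsilon: float = 0.75
    area_coefficients: tuple[float, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("hemisphere", "pyramid", "cube_corner"):
            raise ValueError(f"unknown tip shape {self.shape!r}")
        if self.R_nm <= 0:
            raise ValueError(f"tip radius must be positive, got {self.R_nm}")
        if self.beta is None:
            object.__setattr__(
                self, "beta", 1.0 if self.shape == "hemisphere" else 1.05
            )

    # Equivalent-cone tangent slope tan(psi) preserving the ideal far-field
    # area law A = k z^2 (pyramid k = 4, cube corner k = 2.598).
    _FAR_FIELD_K = {"pyramid": 4.0, "cube_corner": 2.598}

    @property
    def _tan_psi(self) -> float:
        return float(np.sqrt(self._FAR_FIELD_K[self.shape] / np.pi))


# --- segmentation ----------------------------------------------------------


@dataclass
class IndentationCurve:
    """One indent: sampled time/force/depth with per-sample segment labels."""

    time_s: np.ndarray
    force_uN: np.ndarray
    depth_nm: np.ndarray
    segments: np.ndarray  # dtype '<U8', values in SEGMENTS
    schedule: LoadSchedule
    F_max_uN: float = float("nan")
    tau_u_s: float = float("nan")  # hold duration = time from hold onset to unload
    drift_rate_nm_s: float | None = None
    drift_warning: bool = False

    def mask(self, name: str) -> np.ndarray:
        return self.segments == name

    def copy(self) -> "IndentationCurve":
        return replace(
            self,
            time_s=self.time_s.copy(),
            force_uN=self.force_uN.copy(),
            depth_nm=self.depth_nm.copy(),
            segments=self.segments.copy(),
        )


def segment_schedule(
    time_s: np.ndarray,
    force_uN: np.ndarray,
    depth_nm: np.ndarray,
    schedule: LoadSchedule,
) -> IndentationCurve:
    """Label every sample of a raw record using the known load schedule.

    The ramp onset is detected from the force channel (first sustained rise
    above a noise floor); segment boundaries then follow the schedule timing.
    Raises :class:`SegmentationError` when the record ends before the unload
    completes.
    """
    t = np.asarray(time_s, dtype=float)
    F = np.asarray(force_uN, dtype=float)
    z = np.asarray(depth_nm, dtype=float)
    if not (t.shape == F.shape == z.shape) or t.ndim != 1:
        raise SegmentationError("time/force/depth must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise SegmentationError("time must be strictly increasing")

    peak = F.max()
    if peak <= 0:
        raise SegmentationError("record contains no positive force")
    threshold = 0.02 * peak
    rising = np.nonzero(F > threshold)[0]
    if rising.size == 0:
        raise SegmentationError("no ramp found above the force threshold")
    t0 = t[rising[0]]

    t_hold = t0 + schedule.ramp_s
    t_unload = t_hold + schedule.hold_s
    t_drift = t_unload + schedule.unload_s
    if t[-1] < t_drift - 0.5 / max(1.0, len(t) / (t[-1] - t[0])):
        raise SegmentationError(
            f"record ends at t={t[-1]:.3f}s before the unload completes "
            f"(expected t={t_drift:.3f}s)"
        )

    seg = np.full(t.shape, "approach", dtype="<U8")
    seg[(t >= t0) & (t < t_hold)] = "load"
    seg[(t >= t_hold) & (t < t_unload)] = "hold"
    seg[(t >= t_unload) & (t < t_drift)] = "unload"
    seg[(t >= t_drift) & (t <= t_drift + schedule.drift_s)] = "drift"
    if not (seg == "hold").any() or not (seg == "unload").any():
        raise SegmentationError("record is missing a hold or unload phase")

    # Peak force taken around the hold/unload transition, robust to noise.
    trans = (seg == "hold") | (seg == "unload")
    F_max = float(F[trans].max())
    return IndentationCurve(
        time_s=t,
        force_uN=F,
        depth_nm=z,
        segments=seg,
        schedule=schedule,
        F_max_uN=F_max,
        tau_u_s=schedule.hold_s,
    )


# --- per-stage corrections --------------------------------------------------


def correct_drift(curve: IndentationCurve) -> IndentationCurve:
    """Subtract the linear thermal drift fitted on the drift window.

    The depth rate fitted over the post-unload drift segment is removed from
    the whole depth channel.  If the segment is absent, the curve is returned
    unchanged with ``drift_warning`` set.
    """
    out = curve.copy()
    m = curve.mask("drift")
    if m.sum() < 2:
        out.drift_warning = True
        out.drift_rate_nm_s = None
        return out
    rate, _ = np.polyfit(curve.time_s[m], curve.depth_nm[m], 1)
    out.depth_nm = curve.depth_nm - rate * (curve.time_s - curve.time_s[0])
    out.drift_rate_nm_s = float(rate)
    return out


def compensate_machine_compliance(
    curve: IndentationCurve, C_m_nm_uN: float
) -> IndentationCurve:
    """Remove the machine's elastic deflection: z -> z - C_m * F.

    A negative value re-applies a previously removed compliance, so the
    operation is its own inverse.
    """
    out = curve.copy()
    out.depth_nm = curve.depth_nm - C_m_nm_uN * curve.force_uN
    return out


# --- hold-phase creep -------------------------------------------------------


@dataclass(frozen=True)
class CreepFit:
    """Power-law creep z(t) = D5 + D6 t^D7, t from hold onset (nm, s)."""

    D5: float
    D6: float
    D7: float
    residual_norm: float
    n_points: int
    no_creep: bool = False
    negative_creep: bool = False

    def depth(self, t_s: np.ndarray | float) -> np.ndarray | float:
        return self.D5 + self.D6 * np.asarray(t_s, dtype=float) ** self.D7

    def rate(self, t_s: float) -> float:
        """Creep rate zdot(t) = D6 D7 t^(D7-1) in nm/s."""
        if t_s <= 0:
            raise ValueError("creep rate defined only for t > 0")
        return self.D6 * self.D7 * t_s ** (self.D7 - 1.0)


def fit_hold_creep(curve: IndentationCurve) -> CreepFit:
    """Fit the hold-segment depth with z = D5 + D6 t^D7 (t from hold onset)."""
    m = curve.mask("hold")
    if m.sum() < 4:
        raise SegmentationError("hold segment absent or too short for a creep fit")
    t = curve.time_s[m]
    z = curve.depth_nm[m]
    t = t - t[0]
    span = float(z[-1] - z[0])
    scale = max(abs(span), 1e-9)

    def resid(p):
        D5, D6, D7 = p
        return D5 + D6 * t**D7 - z

    p0 = [float(z[0]), span / max(t[-1], 1e-9) ** 0.3, 0.3]
    sol = least_squares(
        resid,
        p0,
        bounds=([-np.inf, -np.inf, 0.01], [np.inf, np.inf, 0.99]),
        x_scale=[max(abs(z[0]), 1.0), scale, 1.0],
    )
    if not sol.success:
        raise FitError(f"creep fit did not converge: {sol.message}")
    D5, D6, D7 = sol.x
    res = float(np.linalg.norm(sol.fun))
    # D6 indistinguishable from zero at the residual scale -> no measurable creep
    no_creep = abs(D6) * t[-1] ** D7 < max(1e-6, 2.0 * res / np.sqrt(len(t)))
    return CreepFit(
        D5=float(D5),
        D6=float(D6),
        D7=float(D7),
        residual_norm=res,
        n_points=int(m.sum()),
        no_creep=bool(no_creep),
        negative_creep=bool(D6 < 0 and not no_creep),
    )


# --- unloading --------------------------------------------------------------


@dataclass(frozen=True)
class UnloadingFit:
    """Unloading branch z(F) = D1 + D2 sqrt(F) + D3 F^D4 (nm, uN)."""

    D1: float
    D2: float
    D3: float
    D4: float
    residual_norm: float
    n_points: int
    exponent_at_bound: bool = False

    def depth(self, F_uN: np.ndarray | float) -> np.ndarray | float:
        F = np.asarray(F_uN, dtype=float)
        return self.D1 + self.D2 * np.sqrt(F) + self.D3 * F**self.D4

    def compliance(self, F_uN: float) -> float:
        """dz/dF at F (nm/uN): D2/(2 sqrt(F)) + D3 D4 F^(D4-1)."""
        if F_uN <= 0:
            raise ValueError("compliance defined only for F > 0")
        return self.D2 / (2.0 * np.sqrt(F_uN)) + self.D3 * self.D4 * F_uN ** (
            self.D4 - 1.0
        )


def fit_unloading(curve: IndentationCurve, fraction: float = 0.75) -> UnloadingFit:
    """Nonlinear least-squares fit of the unloading branch adjacent to the peak.

    Only unload samples with F >= (1 - fraction) * F_max are used — by default
    the 75% of the unload next to peak force, where the fit quality matters
    most for the stiffness estimate.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    m = curve.mask("unload")
    F_max = curve.F_max_uN
    window = m & (curve.force_uN >= (1.0 - fraction) * F_max) & (curve.force_uN > 0)
    if window.sum() < 8:
        raise SegmentationError(
            f"unload window has {int(window.sum())} samples; at least 8 required"
        )
    F = curve.force_uN[window]
    z = curve.depth_nm[window]
    z_span = max(float(z.max() - z.min()), 1e-9)

    # Fit against the normalized force f = F/F_max for a well-conditioned
    # Jacobian, then convert the constants back to physical units.  The model
    # is separable (linear in D1..D3 for fixed D4), so a variable-projection
    # sweep over the exponent gives a robust start even where the sqrt and
    # power terms become collinear (D4 near 1/2); a bounded nonlinear polish
    # refines it.
    f = F / F_max

    def linear_fit(D4: float):
        X = np.column_stack([np.ones_like(f), np.sqrt(f), f**D4])
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        return coef, float(np.linalg.norm(X @ coef - z))

    grid = np.linspace(0.1, 1.0, 19)
    fits = [(D4, *linear_fit(D4)) for D4 in grid]
    D4_0, coef0, res0 = min(fits, key=lambda t: t[2])

    def resid(p):
        a1, a2, a3, D4 = p
        return a1 + a2 * np.sqrt(f) + a3 * f**D4 - z

    p0 = [coef0[0], coef0[1], coef0[2], D4_0]
    sol = least_squares(
        resid,
        p0,
        bounds=([-np.inf, -np.inf, -np.inf, 0.05], [np.inf, np.inf, np.inf, 1.0]),
        x_scale=[max(abs(z.min()), 1.0), z_span, z_span, 1.0],
        max_nfev=2000,
    )
    polished = float(np.linalg.norm(sol.fun))
    if sol.success and polished <= res0:
        a1, a2, a3, D4 = sol.x
    elif res0 <= polished or polished < 1e-3 * z_span * np.sqrt(len(z)):
        # degenerate exponent direction: the separable optimum is as good
        a1, a2, a3, D4 = (*coef0, D4_0) if res0 <= polished else tuple(sol.x)
    else:
        raise FitError(f"unloading fit did not converge: {sol.message}")
    D1, D2, D3 = a1, a2 / np.sqrt(F_max), a3 / F_max**D4
    at_bound = bool(D4 <= 0.05 + 1e-9)
    if at_bound:
        warnings.warn("unloading exponent D4 pinned at its lower bound", stacklevel=2)
    return UnloadingFit(
        D1=float(D1),
        D2=float(D2),
        D3=float(D3),
        D4=float(D4),
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_points=int(window.sum()),
        exponent_at_bound=at_bound,
    )


def unloading_stiffness(fit: UnloadingFit, F_max_uN: float) -> float:
    """Observed unloading stiffness S_u = (dz/dF at F_max)^-1 in uN/nm."""
    Q_u = fit.compliance(F_max_uN)
    if Q_u <= 0:
        raise UnreliableStiffnessError(
            f"non-positive unloading compliance dz/dF = {Q_u:.4g} nm/uN at peak; "
            "the fit is non-physical"
        )
    return 1.0 / Q_u


def creep_corrected_stiffness(
    S_u_uN_nm: float, zdot_tau_nm_s: float, Fdot_uN_s: float
) -> float:
    """Feng-Ngan elastic stiffness: 1/S = 1/S_u - zdot(tau_u)/Fdot.

    ``Fdot_uN_s`` is the signed unloading rate (negative).  Forward creep
    (zdot > 0) makes S < S_u.  Raises :class:`UnreliableStiffnessError` when
    creep dominates and 1/S would be non-positive — the regime in which the
    apparent unloading slope can even turn negative.
    """
    if S_u_uN_nm <= 0:
        raise ValueError(f"S_u must be positive, got {S_u_uN_nm}")
    if Fdot_uN_s >= 0:
        raise ValueError(f"unloading requires Fdot < 0, got {Fdot_uN_s}")
    inv_S = 1.0 / S_u_uN_nm - zdot_tau_nm_s / Fdot_uN_s
    if inv_S <= 0:
        raise UnreliableStiffnessError(
            f"creep rate {zdot_tau_nm_s:.4g} nm/s dominates the unloading slope "
            f"(1/S = {inv_S:.4g} nm/uN); stiffness is unreliable"
        )
    return 1.0 / inv_S


# --- contact depth, area, modulus ------------------------------------------


def contact_depth(
    z_max_nm: float, F_max_uN: float, S_uN_nm: float, epsilon: float = 0.75
) -> float:
    """Oliver-Pharr contact depth z_c = z_max - eps F_max / S, clipped at 0."""
    if S_uN_nm <= 0:
        raise ValueError(f"S must be positive, got {S_uN_nm}")
    z_c = z_max_nm - epsilon * F_max_uN / S_uN_nm
    if z_c < 0:
        warnings.warn(
            f"contact depth {z_c:.3g} nm negative; clipped to 0", stacklevel=2
        )
        return 0.0
    return z_c


def _spherocone_transition(R: float, tan_psi: float) -> tuple[float, float]:
    """Depth and apex offset where a spherical cap joins its tangent cone.

    For a cone of surface slope tan(psi) (radius r = (z + b) tan(psi)) capped
    by a tangent sphere of radius R, tangency occurs at z* = R (1 - sin(psi)),
    giving C1-continuous radius and projected area.
    """
    sin_psi = tan_psi / np.sqrt(1.0 + tan_psi**2)
    z_star = R * (1.0 - sin_psi)
    b = R * (1.0 - sin_psi) / sin_psi
    return z_star, b


def contact_area(tip: TipGeometry, z_c_nm: float) -> float:
    """Projected contact area A(z_c) in nm^2 for the given tip geometry.

    A calibrated polynomial area function, when present on the tip, overrides
    the ideal geometry.
    """
    if z_c_nm < 0:
        raise ValueError(f"contact depth must be >= 0, got {z_c_nm}")
    if z_c_nm == 0.0:
        return 0.0
    if tip.area_coefficients is not None:
        # Oliver-Pharr style: C0 z^2 + C1 z + C2 z^(1/2) + C3 z^(1/4) + ...
        exps = [2.0, 1.0] + [2.0 ** (-k) for k in range(1, len(tip.area_coefficients) - 1)]
        return float(
            sum(c * z_c_nm**e for c, e in zip(tip.area_coefficients, exps))
        )
    R = tip.R_nm
    if tip.shape == "hemisphere":
        if z_c_nm <= R:
            return float(np.pi * (2.0 * R * z_c_nm - z_c_nm**2))
        warnings.warn(
            f"contact depth {z_c_nm:.1f} nm exceeds hemisphere radius {R:.0f} nm; "
            "using the full cross-section pi R^2",
            stacklevel=2,
        )
        return float(np.pi * R**2)
    tan_psi = tip._tan_psi
    z_star, b = _spherocone_transition(R, tan_psi)
    if z_c_nm <= z_star:
        return float(np.pi * (2.0 * R * z_c_nm - z_c_nm**2))
    return float(np.pi * tan_psi**2 * (z_c_nm + b) ** 2)


def indentation_modulus(S_uN_nm: float, A_nm2: float, beta: float) -> float:
    """BASh relation M = sqrt(pi) S / (2 beta sqrt(A)), returned in GPa."""
    if S_uN_nm <= 0 or A_nm2 <= 0:
        raise ValueError("stiffness and area must be positive")
    # uN/nm^2 -> GPa
    return 1000.0 * np.sqrt(np.pi) * S_uN_nm / (2.0 * beta * np.sqrt(A_nm2))


# --- full pipeline ----------------------------------------------------------


@dataclass
class IndentationResult:
    """All intermediates of one processed indent."""

    S_u_uN_nm: float
    S_uN_nm: float
    creep_rate_nm_s: float
    z_max_nm: float
    z_c_nm: float
    A_nm2: float
    M_GPa: float
    drift_rate_nm_s: float | None
    unloading_fit: UnloadingFit
    creep_fit: CreepFit
    direction: str = ""
    tip_label: str = ""
    fiber_id: str = ""
    warnings: list[str] = field(default_factory=list)


def process_curve(
    curve: IndentationCurve,
    tip: TipGeometry,
    *,
    fraction: float = 0.75,
    machine_compliance_nm_uN: float = 0.0,
    creep_correction: bool = True,
    epsilon: float | None = None,
    direction: str = "",
    fiber_id: str = "",
) -> IndentationResult:
    """Run the full per-indent analysis chain on a segmented curve.

    ``creep_correction=False`` skips the Feng-Ngan step and uses the raw
    unloading stiffness (plain Oliver-Pharr), the mode of a conventional
    indenter's built-in analysis.
    """
    notes: list[str] = []
    eps = tip.epsilon if epsilon is None else epsilon

    c = correct_drift(curve)
    if c.drift_warning:
        notes.append("drift segment absent; no drift correction applied")
    if machine_compliance_nm_uN:
        c = compensate_machine_compliance(c, machine_compliance_nm_uN)

    # zero the depth channel at the surface-contact baseline so absolute
    # depth offsets in the raw record do not enter the contact depth
    approach = c.mask("approach")
    if approach.any():
        c.depth_nm = c.depth_nm - float(c.depth_nm[approach].mean())
    else:
        notes.append("no approach segment; depth baseline taken from first sample")
        c.depth_nm = c.depth_nm - float(c.depth_nm[0])

    creep = fit_hold_creep(c)
    ufit = fit_unloading(c, fraction=fraction)
    S_u = unloading_stiffness(ufit, c.F_max_uN)

    if creep_correction and not creep.no_creep:
        zdot = creep.rate(c.tau_u_s)
        S = creep_corrected_stiffness(S_u, zdot, c.schedule.unload_rate_uN_s)
    else:
        zdot = 0.0 if creep.no_creep else creep.rate(c.tau_u_s)
        S = S_u
    if creep.negative_creep:
        notes.append("negative hold-phase creep amplitude")

    # maximum penetration at peak load: the fitted hold law evaluated at the
    # hold duration, robust to sample noise and segment-boundary rounding
    z_max = float(creep.depth(c.tau_u_s))
    z_c = contact_depth(z_max, c.F_max_uN, S, eps)
    A = contact_area(tip, z_c)
    M = indentation_modulus(S, A, tip.beta)
    return IndentationResult(
        S_u_uN_nm=S_u,
        S_uN_nm=S,
        creep_rate_nm_s=zdot,
        z_max_nm=z_max,
        z_c_nm=z_c,
        A_nm2=A,
        M_GPa=M,
        drift_rate_nm_s=c.drift_rate_nm_s,
        unloading_fit=ufit,
        creep_fit=creep,
        direction=direction,
        tip_label=tip.label or tip.shape,
        fiber_id=fiber_id,
        warnings=notes,
    )
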