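"""Synthetic indentation curves and fiber populations with known ground truth.

The generator stands in for raw instrument data so the whole pipeline can be
exercised and validated without measurements.  It emulates the AFM-NI
protocol: a 1 s force ramp to 10 uN (pyramid) or 20 uN (hemisphere), a 10 s
hold at peak, a force-controlled unload to 5% of peak, and a 30 s drift
window; hold-phase power-law creep of the form D6 t^D7; linear thermal drift;
machine compliance; and independent Gaussian sample noise on force and depth.

The elastic contact law is constructed to be exactly consistent with the
processing conventions: the incremental contact stiffness is S = 2 M a with
contact radius a = sqrt(A(z_c)/pi) from the same ideal tip area function the
analysis uses, and total depth and contact depth are related through the
Oliver-Pharr epsilon relation.  For a parabolic area function this reduces in
closed form to the Hertz law F = (4/3) M sqrt(R) z^(3/2), so Hertzian
closed-form oracles remain valid at shallow depth; for the capped tips the
construction removes the cap-versus-paraboloid area bias, so that noise-free
recovery of M_true is limited only by fit precision rather than by a modelling
mismatch between generator and analyzer.

Fiber populations are drawn with lognormal per-fiber constants and lognormal
per-indent scatter, reproducing the right-skewed per-indent modulus
distributions seen in longitudinal indentation of pulp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .curves import (
    SEGMENTS,
    IndentationCurve,
    LoadSchedule,
    TipGeometry,
    contact_area,
    _spherocone_transition,
    process_curve,
)
from .elastic import (
    AdmissibilityError,
    TransverseIsotropicConstants,
    indentation_modulus_longitudinal,
    indentation_modulus_transverse,
    stiffness_from_engineering,
)
from .inversion import FixedParameters, ModulusMeasurementSet, invert_moduli

__all__ = [
    "CurveGeneratorConfig",
    "CurveGroundTruth",
    "simulate_curve",
    "PopulationConfig",
    "PopulationGroundTruth",
    "simulate_population",
    "recovery_experiment",
    "DEFAULT_HEMISPHERE",
    "DEFAULT_PYRAMID",
    "DEFAULT_CUBE_CORNER",
]

DEFAULT_HEMISPHERE = TipGeometry(shape="hemisphere", R_nm=300.0, label="hemisphere")
DEFAULT_PYRAMID = TipGeometry(shape="pyramid", R_nm=100.0, label="pyramid")
DEFAULT_CUBE_CORNER = TipGeometry(shape="cube_corner", R_nm=40.0, label="cube_corner")


@dataclass(frozen=True)
class CurveGeneratorConfig:
    """Everything that determines one synthetic indent, including the seed.

    Noise magnitudes are nominal instrument-scale defaults (the acquisition
    hardware's levels are not published) and are fully configurable.
    """

    M_true_GPa: float = 5.0
    tip: TipGeometry = DEFAULT_HEMISPHERE
    schedule: LoadSchedule = LoadSchedule()
    creep_D6_nm: float = 0.0
    creep_D7: float = 0.3
    drift_rate_nm_s: float = 0.0
    force_noise_sd_uN: float = 0.0
    depth_noise_sd_nm: float = 0.0
    machine_compliance_nm_uN: float = 0.0
    sample_hz: float = 200.0
    approach_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.schedule
        if min(s.peak_uN, s.ramp_s, s.hold_s, s.unload_s, s.drift_s) <= 0:
            raise ValueError("schedule durations and peak force must be positive")
        if not 0 < s.stop_fraction < 1:
            raise ValueError("unload stop fraction must lie in (0, 1)")
        if self.M_true_GPa <= 0:
            raise ValueError("M_true must be positive")
        if min(self.force_noise_sd_uN, self.depth_noise_sd_nm, self.sample_hz) < 0:
            raise ValueError("noise levels must be >= 0")


@dataclass
class CurveGroundTruth:
    """Generator-side truth emitted with each synthetic curve."""

    M_true_GPa: float
    S_peak_uN_nm: float
    z_el_peak_nm: float
    z_c_peak_nm: float
    creep_D6_nm: float
    creep_D7: float
    drift_rate_nm_s: float
    machine_compliance_nm_uN: float
    segments_true: np.ndarray = field(repr=False, default=None)


def _area_and_slope(tip: TipGeometry, z_c: float) -> tuple[float, float]:
    """Ideal projected area and its derivative dA/dz_c (nm^2, nm)."""
    R = tip.R_nm
    if tip.shape == "hemisphere":
        z = min(z_c, R)
        return np.pi * (2 * R * z - z * z), np.pi * (2 * R - 2 * z)
    tan_psi = tip._tan_psi
    z_star, b = _spherocone_transition(R, tan_psi)
    if z_c <= z_star:
        return np.pi * (2 * R * z_c - z_c * z_c), np.pi * (2 * R - 2 * z_c)
    return np.pi * tan_psi**2 * (z_c + b) ** 2, 2 * np.pi * tan_psi**2 * (z_c + b)


def _elastic_contact_table(
    tip: TipGeometry, M_GPa: float, F_max_uN: float, epsilon: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the self-consistent elastic contact law up to F_max.

    Returns monotone arrays (F in uN, total depth z in nm, stiffness S in
    uN/nm) parameterized by contact depth.  The governing relation,
    d F / d z_c = (S - eps F S'/S) / (1 - eps)  with  S = 2 beta M a(z_c),
    follows from dF = S dz and z = z_c + eps F / S; the BASh geometry factor
    beta enters the stiffness so that the analysis chain recovers M exactly.
    """
    M = tip.beta * M_GPa * 1e-3  # uN/nm^2, geometry-corrected

    def S_and_slope(z_c: float) -> tuple[float, float]:
        A, dA = _area_and_slope(tip, z_c)
        a = np.sqrt(A / np.pi)
        S = 2.0 * M * a
        dS = M * dA / (np.sqrt(np.pi) * np.sqrt(A))
        return S, dS

    # start on the parabolic asymptote A ~ 2 pi R z_c
    z0 = 1e-4 * tip.R_nm
    c0 = 2.0 * M * np.sqrt(2.0 * tip.R_nm) / (1.5 - epsilon)
    F0 = c0 * z0**1.5

    def rhs(z_c, y):
        S, dS = S_and_slope(z_c)
        return [(S - epsilon * y[0] * dS / S) / (1.0 - epsilon)]

    def hit_peak(z_c, y):
        return y[0] - 1.2 * F_max_uN

    hit_peak.terminal = True
    hit_peak.direction = 1
    sol = solve_ivp(
        rhs,
        (z0, 50.0 * tip.R_nm),
        [F0],
        events=hit_peak,
        max_step=tip.R_nm / 50.0,
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    if sol.t_events[0].size == 0:
        raise RuntimeError("contact integration did not reach the peak force")
    z_c = np.concatenate([[0.0], sol.t])
    F = np.concatenate([[0.0], sol.y[0]])
    S = np.array([0.0] + [S_and_slope(zc)[0] for zc in sol.t])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = z_c + np.where(S > 0, epsilon * F / S, 0.0)
    return F, z, S


def simulate_curve(
    config: CurveGeneratorConfig,
) -> tuple[IndentationCurve, CurveGroundTruth]:
    """Generate one synthetic indent and its ground truth.

    The returned curve carries generator-true segment labels; re-segmenting
    the raw channels with :func:`fiberindent.curves.segment_schedule` must
    reproduce them on clean data (a pipeline consistency check).
    """
    rng = np.random.default_rng(config.seed)
    s = config.schedule
    dt = 1.0 / config.sample_hz
    t_total = config.approach_s + s.ramp_s + s.hold_s + s.unload_s + s.drift_s
    t = np.arange(0.0, t_total + dt / 2, dt)

    t0 = config.approach_s
    t_hold = t0 + s.ramp_s
    t_unload = t_hold + s.hold_s
    t_drift = t_unload + s.unload_s

    # force schedule (force-controlled instrument: target force is realized)
    F = np.zeros_like(t)
    load = (t >= t0) & (t < t_hold)
    hold = (t >= t_hold) & (t < t_unload)
    unload = (t >= t_unload) & (t < t_drift)
    drift_seg = t >= t_drift
    F[load] = s.peak_uN * (t[load] - t0) / s.ramp_s
    F[hold] = s.peak_uN
    F[unload] = s.peak_uN + s.unload_rate_uN_s * (t[unload] - t_unload)
    F[drift_seg] = s.stop_fraction * s.peak_uN

    F_tab, z_tab, S_tab = _elastic_contact_table(
        config.tip, config.M_true_GPa, s.peak_uN, config.tip.epsilon
    )
    z_el = np.interp(F, F_tab, z_tab)
    S_peak = float(np.interp(s.peak_uN, F_tab, S_tab))
    z_el_peak = float(np.interp(s.peak_uN, F_tab, z_tab))

    # hold-phase creep, continuing through the unload with a continuous rate,
    # frozen during the drift window (negligible load)
    creep = np.zeros_like(t)
    tc = t - t_hold
    active = hold | unload
    creep[active] = config.creep_D6_nm * np.maximum(tc[active], 0.0) ** config.creep_D7
    creep_end = config.creep_D6_nm * (s.hold_s + s.unload_s) ** config.creep_D7
    creep[drift_seg] = creep_end

    z = z_el + creep
    z = z + config.drift_rate_nm_s * t
    z = z + config.machine_compliance_nm_uN * F
    if config.force_noise_sd_uN > 0:
        F = F + rng.normal(0.0, config.force_noise_sd_uN, size=F.shape)
    if config.depth_noise_sd_nm > 0:
        z = z + rng.normal(0.0, config.depth_noise_sd_nm, size=z.shape)

    seg = np.full(t.shape, "approach", dtype="<U8")
    seg[load] = "load"
    seg[hold] = "hold"
    seg[unload] = "unload"
    seg[drift_seg] = "drift"

    curve = IndentationCurve(
        time_s=t,
        force_uN=F,
        depth_nm=z,
        segments=seg,
        schedule=s,
        F_max_uN=float(F[hold | unload].max()),
        tau_u_s=s.hold_s,
    )
    z_c_peak = z_el_peak - config.tip.epsilon * s.peak_uN / S_peak
    truth = CurveGroundTruth(
        M_true_GPa=config.M_true_GPa,
        S_peak_uN_nm=S_peak,
        z_el_peak_nm=z_el_peak,
        z_c_peak_nm=z_c_peak,
        creep_D6_nm=config.creep_D6_nm,
        creep_D7=config.creep_D7,
        drift_rate_nm_s=config.drift_rate_nm_s,
        machine_compliance_nm_uN=config.machine_compliance_nm_uN,
        segments_true=seg.copy(),
    )
    return curve, truth


# --- populations ------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """Lognormal fiber population emulating the measured modulus scatter.

    Defaults mirror the study's sampling plan: a handful of fibers, tens of
    longitudinal indents and a larger transverse count, with per-fiber medians
    near the identified constants of kraft pulp walls and a right-skewed
    per-indent scatter.
    """

    n_fibers: int = 5
    E_L_median_GPa: float = 8.0
    E_L_sigma_log: float = 0.45
    E_T_median_GPa: float = 1.1
    E_T_sigma_log: float = 0.15
    fixed: FixedParameters = FixedParameters()
    indent_scatter_sigma_log: float = 0.25
    indents_per_fiber_L: int = 10
    indents_per_fiber_T: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("need at least one fiber")
        if min(self.E_L_sigma_log, self.E_T_sigma_log,
               self.indent_scatter_sigma_log) < 0:
            raise ValueError("dispersion parameters must be >= 0")


@dataclass
class PopulationGroundTruth:
    fibers: pd.DataFrame  # per-fiber E_L, E_T, M_L, M_T
    config: PopulationConfig
    n_resampled: int


def simulate_population(
    config: PopulationConfig,
) -> tuple[ModulusMeasurementSet, PopulationGroundTruth]:
    """Draw a fiber population and its per-indent modulus table.

    Per fiber, (E_L, E_T) are lognormal about the configured medians;
    inadmissible draws are rejected and redrawn (counted).  The fiber's
    forward indentation moduli then receive independent multiplicative
    lognormal per-indent scatter.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    entries: list[tuple[str, str, float]] = []
    n_resampled = 0
    for fiber in range(config.n_fibers):
        for _ in range(1000):
            E_L = config.E_L_median_GPa * np.exp(
                rng.normal(0.0, config.E_L_sigma_log)
            )
            E_T = config.E_T_median_GPa * np.exp(
                rng.normal(0.0, config.E_T_sigma_log)
            )
            try:
                c = TransverseIsotropicConstants(
                    E_L=E_L, E_T=E_T, nu_LT=config.fixed.nu_LT,
                    nu_TT=config.fixed.nu_TT, G_LT=config.fixed.G_LT,
                )
                C = stiffness_from_engineering(c)
                M_L = indentation_modulus_longitudinal(C)
                M_T = indentation_modulus_transverse(C)
                break
            except AdmissibilityError:
                n_resampled += 1
        else:
            raise RuntimeError("could not draw admissible constants")
        rows.append({"fiber": fiber, "E_L": E_L, "E_T": E_T, "M_L": M_L, "M_T": M_T})
        for _ in range(config.indents_per_fiber_L):
            m = M_L * np.exp(rng.normal(0.0, config.indent_scatter_sigma_log))
            entries.append(("L", "pyramid", float(m)))
        for _ in range(config.indents_per_fiber_T):
            m = M_T * np.exp(rng.normal(0.0, config.indent_scatter_sigma_log))
            entries.append(("T", "hemisphere", float(m)))
    measurements = ModulusMeasurementSet(entries=tuple(entries))
    truth = PopulationGroundTruth(
        fibers=pd.DataFrame(rows), config=config, n_resampled=n_resampled
    )
    return measurements, truth


# --- end-to-end recovery ----------------------------------------------------


def recovery_experiment(
    pairs: list[tuple[float, float]],
    n_per_direction: int = 3,
    fixed: FixedParameters = FixedParameters(),
    base_config: CurveGeneratorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate -> process -> summarize -> invert, for a sweep of true constants.

    For each (E_L, E_T) pair the forward indentation moduli define the ground
    truth; synthetic curves are generated per direction (pyramid tip at 10 uN
    longitudinally, hemisphere at 20 uN transversely), processed with the full
    creep-corrected pipeline, summarized by the mean, and inverted.  Returns a
    table with the true and recovered constants and relative errors; stage
    failures are counted per pair rather than raised.
    """
    base = base_config or CurveGeneratorConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for E_L_true, E_T_true in pairs:
        c = TransverseIsotropicConstants(
            E_L=E_L_true, E_T=E_T_true, nu_LT=fixed.nu_LT, nu_TT=fixed.nu_TT,
            G_LT=fixed.G_LT,
        )
        C = stiffness_from_engineering(c)
        truth_M = {
            "L": indentation_modulus_longitudinal(C),
            "T": indentation_modulus_transverse(C),
        }
        entries = []
        n_failed = 0
        for direction, tip, peak in (
            ("L", DEFAULT_PYRAMID, 10.0),
            ("T", DEFAULT_HEMISPHERE, 20.0),
        ):
            for _ in range(n_per_direction):
                cfg = replace(
                    base,
                    M_true_GPa=truth_M[direction],
                    tip=tip,
                    schedule=replace(base.schedule, peak_uN=peak),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                curve, _ = simulate_curve(cfg)
                try:
                    res = process_curve(
                        curve,
                        tip,
                        machine_compliance_nm_uN=cfg.machine_compliance_nm_uN,
                    )
                    entries.append((direction, tip.label, res.M_GPa))
                except Exception:
                    n_failed += 1
        mset = ModulusMeasurementSet(entries=tuple(entries))
        inv = invert_moduli(mset, fixed)
        rows.append(
            {
                "E_L_true": E_L_true,
                "E_T_true": E_T_true,
                "E_L_recovered": inv.E_L,
                "E_T_recovered": inv.E_T,
                "rel_err_E_L": inv.E_L / E_L_true - 1.0,
                "rel_err_E_T": inv.E_T / E_T_true - 1.0,
                "n_failed": n_failed,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["bias_E_L"] = float(df["rel_err_E_L"].mean())
    df.attrs["rmse_E_L"] = float(np.sqrt((df["rel_err_E_L"] ** 2).mean()))
    df.attrs["bias_E_T"] = float(df["rel_err_E_T"].mean())
    df.attrs["rmse_E_T"] = float(np.sqrt((df["rel_err_E_T"] ** 2).mean()))
    return df
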