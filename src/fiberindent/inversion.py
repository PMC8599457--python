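"""Inverse identification of (E_L, E_T) and the network / tensile baselines.

The forward contact model maps engineering constants to the two axis-aligned
indentation moduli (M_L, M_T).  It is not analytically invertible, so the
elastic constants are identified by quasi-Newton minimization of the residual
cost

    g(E_L, E_T | nu_LT, nu_TT, G_LT) =
        (1/n) * sqrt( sum_r (M_r^model - M_r^exp)^2 / M_r^exp ),

summed over the n = 2 indentation directions.  Two independent baselines for
the longitudinal fiber modulus are provided: inversion of the Cox shear-lag
network relation  E_sheet = (E_L_fiber / 3) * rho_sheet / rho_fiber,  and the
single-fiber tensile truss estimate  E_L = F L / (delta A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .elastic import (
    AdmissibilityError,
    TransverseIsotropicConstants,
    indentation_modulus_longitudinal,
    indentation_modulus_transverse,
    stiffness_from_engineering,
)

__all__ = [
    "FixedParameters",
    "ModulusMeasurementSet",
    "InverseResult",
    "SheetProperties",
    "FiberTensileRecord",
    "cost",
    "invert_moduli",
    "uniqueness_grid",
    "cox_invert",
    "tensile_modulus",
    "summarize_moduli",
]

#: Finite penalty returned for thermodynamically inadmissible trial constants,
#: large enough that any line search retreats but finite so BFGS stays alive.
INADMISSIBLE_PENALTY = 1e6

#: Default identification bounds (GPa): realistic ranges for pulp fiber walls.
DEFAULT_BOUNDS = ((0.5, 100.0), (0.05, 20.0))


@dataclass(frozen=True)
class FixedParameters:
    """Constants held fixed during identification (literature/assumed values)."""

    nu_LT: float = 0.25
    nu_TT: float = 0.25
    G_LT: float = 2.51
    theta: float = 0.0


@dataclass(frozen=True)
class ModulusMeasurementSet:
    """Per-indent indentation moduli grouped by direction.

    ``entries`` holds (direction, tip label, M in GPa) triples with direction
    in {"L", "T"}.  ``representative`` collapses each direction with the
    chosen statistic; the identification needs at least one entry per
    direction.
    """

    entries: tuple[tuple[str, str, float], ...]
    method: str = "mean"

    def __post_init__(self) -> None:
        if self.method not in ("mean", "median"):
            raise ValueError(f"summary method must be mean or median, got {self.method}")
        for d, _, M in self.entries:
            if d not in ("L", "T"):
                raise ValueError(f"direction must be L or T, got {d!r}")
            if M <= 0:
                raise ValueError(f"indentation moduli must be positive, got {M}")

    @classmethod
    def from_representative(
        cls, M_L: float, M_T: float, method: str = "mean"
    ) -> "ModulusMeasurementSet":
        return cls(entries=(("L", "", M_L), ("T", "", M_T)), method=method)

    def representative(self) -> dict[str, float]:
        out = {}
        for d in ("L", "T"):
            vals = [M for dd, _, M in self.entries if dd == d]
            if vals:
                out[d] = summarize_moduli(vals, self.method)
        if set(out) != {"L", "T"}:
            missing = {"L", "T"} - set(out)
            raise ValueError(
                f"inversion needs both directions; missing measurements for "
                f"{sorted(missing)}"
            )
        return out


@dataclass
class InverseResult:
    """Identified constants with optimization diagnostics."""

    E_L: float
    E_T: float
    cost: float
    iterations: int
    converged: bool
    multistart_dispersion: float
    at_bound: bool
    M_model: dict[str, float] = field(default_factory=dict)


def _forward(E_L: float, E_T: float, fixed: FixedParameters) -> dict[str, float]:
    c = TransverseIsotropicConstants(
        E_L=E_L, E_T=E_T, nu_LT=fixed.nu_LT, nu_TT=fixed.nu_TT,
        G_LT=fixed.G_LT, theta=fixed.theta,
    )
    C = stiffness_from_engineering(c)
    return {
        "L": indentation_modulus_longitudinal(C),
        "T": indentation_modulus_transverse(C),
    }


def cost(
    E_L: float,
    E_T: float,
    fixed: FixedParameters,
    measured: dict[str, float],
) -> float:
    """Residual cost g between modelled and measured indentation moduli.

    Inadmissible trial constants return the documented finite penalty rather
    than raising, so that optimizer line searches can retreat.
    """
    try:
        model = _forward(E_L, E_T, fixed)
    except (AdmissibilityError, np.linalg.LinAlgError):
        return INADMISSIBLE_PENALTY
    n = len(measured)
    total = sum(
        (model[d] - M_exp) ** 2 / M_exp for d, M_exp in measured.items()
    )
    if not np.isfinite(total):
        return INADMISSIBLE_PENALTY
    return float(np.sqrt(total) / n)


def invert_moduli(
    measured: ModulusMeasurementSet | dict[str, float],
    fixed: FixedParameters = FixedParameters(),
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    n_starts: int = 5,
) -> InverseResult:
    """Identify (E_L, E_T) by multistart BFGS minimization of the cost.

    The search runs in log-parameters (which keeps trial moduli positive and
    evens out the scale difference between E_L and E_T) from ``n_starts``
    log-spaced starting points across the bounds; the best optimum is
    returned together with the maximum pairwise distance between converged
    optima as a uniqueness diagnostic.
    """
    if isinstance(measured, ModulusMeasurementSet):
        rep = measured.representative()
    else:
        rep = dict(measured)

    (lo_L, hi_L), (lo_T, hi_T) = bounds

    def f(x: np.ndarray) -> float:
        return cost(float(np.exp(x[0])), float(np.exp(x[1])), fixed, rep)

    starts = np.column_stack(
        [
            np.linspace(np.log(lo_L), np.log(hi_L), n_starts + 2)[1:-1],
            np.linspace(np.log(lo_T), np.log(hi_T), n_starts + 2)[1:-1],
        ]
    )
    optima = []
    best = None
    for x0 in starts:
        sol = minimize(f, x0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
        if not np.isfinite(sol.fun) or sol.fun >= INADMISSIBLE_PENALTY:
            continue
        optima.append((np.exp(sol.x), sol))
        if best is None or sol.fun < best.fun:
            best = sol
    if best is None:
        raise RuntimeError(
            "no start converged to an admissible optimum; check the measured "
            "moduli and fixed parameters"
        )

    # Gauss-Newton polish on the residual vector: the square root in the cost
    # is non-smooth at a zero-residual optimum, where quasi-Newton progress
    # stalls around 1e-9; least squares on the residuals shares the minimizer
    # and drives an interpolating optimum to machine precision.
    from scipy.optimize import least_squares

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            model = _forward(float(np.exp(x[0])), float(np.exp(x[1])), fixed)
        except (AdmissibilityError, np.linalg.LinAlgError):
            return np.full(len(rep), np.sqrt(INADMISSIBLE_PENALTY))
        return np.array(
            [(model[d] - M) / np.sqrt(M) for d, M in rep.items()]
        )

    polish = least_squares(residuals, best.x, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.isfinite(polish.cost) and f(polish.x) <= best.fun:
        best.x = polish.x
        best.fun = f(polish.x)
    E = np.exp(best.x)
    pts = np.array([p for p, s in optima if s.fun < best.fun + 1e-8])
    dispersion = 0.0
    if len(pts) > 1:
        diffs = pts[:, None, :] - pts[None, :, :]
        dispersion = float(np.sqrt((diffs**2).sum(-1)).max())
    at_bound = bool(
        E[0] <= lo_L * 1.001 or E[0] >= hi_L * 0.999
        or E[1] <= lo_T * 1.001 or E[1] >= hi_T * 0.999
    )
    return InverseResult(
        E_L=float(E[0]),
        E_T=float(E[1]),
        cost=float(best.fun),
        iterations=int(best.nit),
        converged=bool(best.success or best.fun < 1e-8),
        multistart_dispersion=dispersion,
        at_bound=at_bound,
        M_model=_forward(float(E[0]), float(E[1]), fixed),
    )


@dataclass
class CostSurface:
    """Cost evaluated on an (E_L, E_T) grid, with local-minimum census."""

    E_L_grid: np.ndarray
    E_T_grid: np.ndarray
    g: np.ndarray  # shape (len(E_L_grid), len(E_T_grid))
    n_local_minima: int
    argmin: tuple[float, float]
    minimum_on_boundary: bool


def uniqueness_grid(
    measured: ModulusMeasurementSet | dict[str, float],
    fixed: FixedParameters = FixedParameters(),
    E_L_range: tuple[float, float] = (1.0, 40.0),
    E_T_range: tuple[float, float] = (0.1, 5.0),
    resolution: int = 200,
    log_spacing: bool = True,
) -> CostSurface:
    """Evaluate the cost on a grid and count strict interior local minima.

    A grid cell is a strict local minimum when its cost is strictly below all
    of its 8 neighbours.  A single interior minimum supports uniqueness of the
    identified pair within the scanned ranges.
    """
    if isinstance(measured, ModulusMeasurementSet):
        rep = measured.representative()
    else:
        rep = dict(measured)
    space = np.geomspace if log_spacing else np.linspace
    ELs = space(E_L_range[0], E_L_range[1], resolution)
    ETs = space(E_T_range[0], E_T_range[1], resolution)
    g = np.empty((resolution, resolution))
    for i, EL in enumerate(ELs):
        for j, ET in enumerate(ETs):
            g[i, j] = cost(EL, ET, fixed, rep)

    interior = g[1:-1, 1:-1]
    strict = np.ones_like(interior, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            strict &= interior < g[1 + di : resolution - 1 + di,
                                   1 + dj : resolution - 1 + dj]
    n_min = int(strict.sum())
    i0, j0 = np.unravel_index(np.argmin(g), g.shape)
    on_boundary = i0 in (0, resolution - 1) or j0 in (0, resolution - 1)
    return CostSurface(
        E_L_grid=ELs,
        E_T_grid=ETs,
        g=g,
        n_local_minima=n_min,
        argmin=(float(ELs[i0]), float(ETs[j0])),
        minimum_on_boundary=on_boundary,
    )


# --- baselines --------------------------------------------------------------


@dataclass(frozen=True)
class SheetProperties:
    """Handsheet tensile modulus and densities entering the Cox relation."""

    E_sheet_GPa: float
    rho_sheet_kg_m3: float
    rho_fiber_kg_m3: float

    def __post_init__(self) -> None:
        if self.E_sheet_GPa < 0 or self.rho_sheet_kg_m3 <= 0 or self.rho_fiber_kg_m3 <= 0:
            raise ValueError("sheet modulus must be >= 0 and densities positive")
        if self.rho_sheet_kg_m3 > self.rho_fiber_kg_m3:
            raise ValueError(
                "sheet density cannot exceed fiber density "
                f"({self.rho_sheet_kg_m3} > {self.rho_fiber_kg_m3})"
            )


def cox_invert(sheet: SheetProperties) -> float:
    """Longitudinal fiber modulus from the inverted Cox network relation.

    For an in-plane isotropic sheet of long, pin-jointed fibers,
    E_sheet = (E_L_fiber / 3) * rho_sheet / rho_fiber; inverting gives
    E_L_fiber = 3 E_sheet rho_fiber / rho_sheet (GPa).
    """
    return 3.0 * sheet.E_sheet_GPa * sheet.rho_fiber_kg_m3 / sheet.rho_sheet_kg_m3


@dataclass(frozen=True)
class FiberTensileRecord:
    """One single-fiber tensile test in SI units (N, m, m, m^2)."""

    F_N: float
    L_m: float
    delta_m: float
    A_m2: float

    def __post_init__(self) -> None:
        if min(self.F_N, self.L_m, self.delta_m, self.A_m2) <= 0:
            raise ValueError("force, span, displacement and area must be positive")


def tensile_modulus(record: FiberTensileRecord) -> float:
    """Elastic-truss longitudinal modulus E_L = F L / (delta A), in GPa."""
    E_Pa = record.F_N * record.L_m / (record.delta_m * record.A_m2)
    return E_Pa / 1e9


def summarize_moduli(values, method: str = "mean") -> float:
    """Representative modulus: arithmetic mean or sample median.

    The even-sample median is the midpoint of the two central order
    statistics.  The two statistics differ materially for skewed per-indent
    distributions, which is why both are carried through the identification.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty group of moduli")
    if method == "mean":
        return float(vals.mean())
    if method == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown summary method {method!r}")
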