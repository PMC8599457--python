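"""End-to-end batch pipeline: manifest of curves -> identified constants.

Chains curve processing, per-direction summaries (mean and median carried in
parallel, since the skewed longitudinal scatter makes them differ materially)
and the inverse identification.  Exclusion accounting is first-class: indents
whose corrected stiffness is unreliable are counted and logged, never
silently dropped, and the run fails only if no direction retains a usable
summary.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from .config import RunConfig
from .curves import LoadSchedule, process_curve, segment_schedule
from .inversion import ModulusMeasurementSet, SheetProperties, cox_invert, invert_moduli
from .io import (
    CurveIOError,
    default_schedule_for,
    read_curve_file,
    read_manifest,
    results_to_frame,
    write_results,
)

logger = logging.getLogger("fiberindent")

__all__ = ["run_full_pipeline"]


def run_full_pipeline(
    manifest_path: str | Path,
    config: RunConfig,
    out_dir: str | Path | None = None,
    sheet: SheetProperties | None = None,
    schedules: dict[str, LoadSchedule] | None = None,
) -> dict:
    """Process every curve in the manifest and identify (E_L, E_T).

    Returns a bundle with the per-indent results frame, per-direction
    summaries and an inversion per summary method, plus the Cox baseline when
    sheet properties are supplied.  When ``out_dir`` is given the bundle is
    written as ``indents.csv`` + ``summary.json`` + the resolved config.
    """
    t_start = time.perf_counter()
    manifest = read_manifest(manifest_path)
    results = []
    excluded: list[dict] = []
    for row in manifest.itertuples(index=False):
        tip_key = str(row.tip)
        if tip_key not in config.tips:
            raise CurveIOError(f"manifest references unknown tip {tip_key!r}")
        tip = config.tips[tip_key].to_geometry(label=tip_key)
        schedule = (schedules or {}).get(tip_key) or default_schedule_for(tip_key)
        try:
            raw = read_curve_file(row.file)
            curve = segment_schedule(
                raw["time_s"], raw["force_uN"], raw["depth_nm"], schedule
            )
            res = process_curve(
                curve,
                tip,
                fraction=config.processing.fraction,
                machine_compliance_nm_uN=config.processing.machine_compliance_nm_uN,
                creep_correction=config.processing.creep_correction,
                epsilon=config.processing.epsilon,
                direction=str(row.direction),
                fiber_id=str(row.fiber_id),
            )
            results.append(res)
        except Exception as exc:
            excluded.append({"file": row.file, "stage": type(exc).__name__,
                             "reason": str(exc)})
            logger.warning("excluded %s: %s", row.file, exc)
    logger.info(
        "processed %d indents, excluded %d, in %.2fs",
        len(results), len(excluded), time.perf_counter() - t_start,
    )

    frame = results_to_frame(results)
    summary: dict = {
        "config_hash": config.content_hash(),
        "n_processed": len(results),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "directions": {},
        "inversion": {},
    }
    entries = tuple((r.direction, r.tip_label, r.M_GPa) for r in results)
    have_both = {d for d, _, _ in entries} >= {"L", "T"}
    for method in config.summary_methods:
        mset = ModulusMeasurementSet(entries=entries, method=method)
        if not have_both:
            raise ValueError(
                "inversion needs indents in both directions; manifest provides "
                f"only {sorted({d for d, _, _ in entries})}"
            )
        rep = mset.representative()
        summary["directions"][method] = {"M_L_GPa": rep["L"], "M_T_GPa": rep["T"]}
        inv = invert_moduli(
            mset,
            config.fixed.to_fixed(),
            bounds=config.inversion.bounds,
            n_starts=config.inversion.n_starts,
        )
        summary["inversion"][method] = {
            "E_L_GPa": inv.E_L,
            "E_T_GPa": inv.E_T,
            "cost": inv.cost,
            "converged": inv.converged,
            "multistart_dispersion_GPa": inv.multistart_dispersion,
            "at_bound": inv.at_bound,
        }
    if sheet is not None:
        summary["cox_E_L_fiber_GPa"] = cox_invert(sheet)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(out, frame, summary)
        config.to_yaml(out / "config.resolved.yaml")
    return {"indents": frame, "summary": summary}
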