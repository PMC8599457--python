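"""Delimited-text I/O for curves, manifests and results.

Curve files are CSV/TSV with unit-suffixed headers ``time_s``, ``force_uN``,
``depth_nm`` and an optional ``segment`` column; a manifest CSV lists curve
files with their direction tag (L/T), tip tag and fiber id.  All numeric
output columns carry unit-suffixed headers.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import IndentationCurve, IndentationResult, LoadSchedule

__all__ = [
    "CurveIOError",
    "read_curve_file",
    "write_curve_file",
    "read_manifest",
    "results_to_frame",
    "write_results",
]

REQUIRED_COLUMNS = ("time_s", "force_uN", "depth_nm")
MANIFEST_COLUMNS = ("file", "direction", "tip", "fiber_id")


class CurveIOError(ValueError):
    """A curve or manifest file violates the expected dialect."""


def read_curve_file(path: str | Path) -> dict[str, np.ndarray]:
    """Read one indent record; columns are matched by header name.

    Returns a dict with the required channel arrays plus ``segment`` when
    present.  Raises :class:`CurveIOError` naming the missing column or the
    offending line for non-monotone time.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise CurveIOError(f"{path}: unparseable curve file ({exc})") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CurveIOError(f"{path}: missing required column {col!r}")
    for col in REQUIRED_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise CurveIOError(f"{path}: non-numeric value in {col!r} at line {line}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        i = int(np.nonzero(np.diff(t) <= 0)[0][0])
        # offending sample is the second of the pair; +2 for header and 1-basing
        raise CurveIOError(f"{path}: time not strictly increasing at line {i + 3}")
    out = {c: df[c].to_numpy(float) for c in REQUIRED_COLUMNS}
    if "segment" in df.columns:
        out["segment"] = df["segment"].to_numpy(str)
    return out


def write_curve_file(path: str | Path, curve: IndentationCurve) -> None:
    pd.DataFrame(
        {
            "time_s": curve.time_s,
            "force_uN": curve.force_uN,
            "depth_nm": curve.depth_nm,
            "segment": curve.segments,
        }
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the manifest CSV listing curve files with tags.

    Columns: file (path, relative to the manifest), direction (L/T), tip
    (key into the configured tip set), fiber_id.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise CurveIOError(f"{path}: manifest missing column {col!r}")
    bad = ~df["direction"].isin(["L", "T"])
    if bad.any():
        raise CurveIOError(
            f"{path}: direction must be L or T "
            f"(line {int(df.index[bad][0]) + 2})"
        )
    df["file"] = [str((path.parent / f)) for f in df["file"]]
    return df


def results_to_frame(results: list[IndentationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "fiber_id": r.fiber_id,
                "direction": r.direction,
                "tip": r.tip_label,
                "S_u_uN_nm": r.S_u_uN_nm,
                "S_uN_nm": r.S_uN_nm,
                "creep_rate_nm_s": r.creep_rate_nm_s,
                "z_max_nm": r.z_max_nm,
                "z_c_nm": r.z_c_nm,
                "A_nm2": r.A_nm2,
                "M_GPa": r.M_GPa,
                "drift_rate_nm_s": r.drift_rate_nm_s,
                "D4": r.unloading_fit.D4,
                "D7": r.creep_fit.D7,
                "warnings": ";".join(r.warnings),
            }
        )
    return pd.DataFrame(rows)


def write_results(out_dir: str | Path, frame: pd.DataFrame, summary: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out / "indents.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def default_schedule_for(tip_key: str) -> LoadSchedule:
    """Study-protocol schedule per tip: 20 uN hemisphere, 10 uN pyramid,
    100 uN cube corner."""
    peaks = {"hemisphere": 20.0, "pyramid": 10.0, "cube_corner": 100.0}
    return LoadSchedule(peak_uN=peaks.get(tip_key, 20.0))
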