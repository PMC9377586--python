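"""Readers/writers for experimental curves, probe trajectories and results.

Curves travel as CSV with a required ``displacement_mm,force_n`` header
(an ``increment`` column, as written for simulated curves, is tolerated).
Freehand probe motion reduces to a straight trajectory — a linear fit from
the probe's start to its end position with no rotation — so a curve stores
the scalar displacement magnitude along that segment, not 3D positions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import IndentationCurve
from .errors import CurveError
from .mesh import write_vtk

__all__ = [
    "ProbeTrajectory",
    "read_curve_csv",
    "write_curve_csv",
    "build_trajectory",
    "write_results",
]


@dataclass(frozen=True)
class ProbeTrajectory:
    """Straight, rotation-free probe path from ``start`` to ``end`` (mm)
    sampled uniformly at ``n_samples`` points."""

    start: np.ndarray
    end: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float))
        if self.start.shape != (3,) or self.end.shape != (3,):
            raise ValueError("start and end must be 3D points")
        if np.allclose(self.start, self.end):
            raise ValueError("start and end positions coincide")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")

    @property
    def displacement_magnitude(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def displacement_axis(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def samples(self) -> np.ndarray:
        t = np.linspace(0.0, 1.0, self.n_samples)[:, None]
        return self.start[None, :] * (1.0 - t) + self.end[None, :] * t


def build_trajectory(start, end, n_samples: int) -> ProbeTrajectory:
    """Linear fit of the probe path between its start and end positions."""
    return ProbeTrajectory(start=start, end=end, n_samples=n_samples)


def read_curve_csv(path, meta: str = "experimental") -> IndentationCurve:
    """Read a force-displacement curve from CSV.

    Requires columns ``displacement_mm`` and ``force_n``.  Rows containing
    NaN are dropped; non-monotone displacement is sorted with a warning;
    negative displacement is an error.
    """
    path = Path(path)
    if not path.exists():
        raise CurveError(f"curve file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CurveError(f"cannot parse {path}: {exc}") from exc
    missing = {"displacement_mm", "force_n"} - set(df.columns)
    if missing:
        raise CurveError(f"{path}: missing columns {sorted(missing)}")
    df = df[["displacement_mm", "force_n"]].dropna()
    if df.empty:
        raise CurveError(f"{path}: no valid samples")
    d = df["displacement_mm"].to_numpy(dtype=float)
    f = df["force_n"].to_numpy(dtype=float)
    if np.any(d < 0):
        raise CurveError(f"{path}: negative displacement values")
    if np.any(np.diff(d) < 0):
        warnings.warn(f"{path}: displacement not monotone; sorting samples")
        order = np.argsort(d, kind="stable")
        d, f = d[order], f[order]
    return IndentationCurve(d, f, meta=meta)


def write_curve_csv(curve: IndentationCurve, path) -> None:
    """Write ``increment,displacement_mm,force_n`` at 12 significant
    digits (lossless round trip at that precision)."""
    path = Path(path)
    lines = ["increment,displacement_mm,force_n"]
    for i, (d, f) in enumerate(zip(curve.displacement, curve.force)):
        lines.append(f"{i},{d:.12g},{f:.12g}")
    path.write_text("\n".join(lines) + "\n")


def _config_hash(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results(result, out_dir, config: dict | None = None) -> dict:
    """Export a simulation: curve CSV, per-increment VTK fields, and a
    JSON run manifest (material, mesh stats, config echo + hash).

    Returns the manifest dict.  ``result`` is a
    :class:`tissuecal.fem.SimulationResult`.
    """
    if result.converged_increments < 1 and result.curve.displacement.size <= 1:
        raise ValueError("empty simulation result; nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_curve_csv(result.curve, out / "curve.csv")

    from .fem import surface_fields  # local import; fem imports curves only

    for inc in range(result.n_recorded):
        vm, pressure = surface_fields(result, inc)
        write_vtk(
            result.mesh,
            out / f"fields_{inc:04d}.vtk",
            point_data={
                "displacement": result.nodal_displacements[inc],
                "von_mises": vm,
                "contact_pressure": pressure,
            },
            cell_data={"volume_ratio_J": result.element_J[inc]},
            title=f"increment {inc}",
        )

    config = dict(config or {})
    manifest = {
        "material": result.material.to_dict(),
        "contact_mode": result.contact_mode,
        "mesh": {
            "n_nodes": int(result.mesh.n_nodes),
            "n_elements": int(result.mesh.n_elements),
            "element_order": int(result.mesh.element_order),
            "volume_mm3": float(result.mesh.volume()),
        },
        "probe": {
            "face_center": [float(v) for v in result.probe.face_center],
            "face_normal": [float(v) for v in result.probe.face_normal],
            "face_half_lengths": list(result.probe.face_half_lengths),
            "displacement_axis": [float(v) for v in result.probe.displacement_axis],
            "total_displacement_mm": float(result.probe.total_displacement),
            "n_increments": int(result.probe.n_increments),
        },
        "converged_increments": int(result.converged_increments),
        "failed": bool(result.failed),
        "runtime_s": float(result.runtime_s),
        "config": config,
        "config_hash": _config_hash(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
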