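"""Verification protocols: mesh convergence and K/C1-ratio sensitivity.

Mesh convergence follows a 5% rule: a mesh is accepted once the two
next-finer meshes change the final probe reaction force by less than 5%
on average, i.e. row i's metric is ``mean_j |F_i - F_j| / F_i * 100`` over
``j in {i+1, i+2}``.  The last two rows carry no metric.  (Published
convergence tables of this kind sometimes use other averaging
conventions; only the rule above is implemented here.)

The sensitivity sweep re-runs one indentation at several K/C1 ratios and
reports the largest element volume change and the final reaction force:
larger ratios enforce incompressibility more strictly (smaller volume
change) and stiffen the response (larger force) at some runtime cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fem
from .constitutive import Material
from .errors import SolverError, TissuecalError

__all__ = ["ConvergenceRow", "ConvergenceReport", "mesh_convergence", "k_ratio_sensitivity"]


@dataclass(frozen=True)
class ConvergenceRow:
    n_nodes: int
    n_elements: int
    reaction_force: float | None
    metric: float | None  # average % difference to the next two finer meshes
    runtime_s: float | None
    failed: bool = False


@dataclass
class ConvergenceReport:
    rows: list = field(default_factory=list)
    converged_index: int | None = None
    threshold: float = 5.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_nodes": r.n_nodes,
                    "n_elements": r.n_elements,
                    "reaction_force_n": r.reaction_force,
                    "avg_percent_difference": r.metric,
                    "runtime_s": r.runtime_s,
                    "failed": r.failed,
                }
                for r in self.rows
            ]
        )


def _final_force(result: fem.SimulationResult) -> float:
    if result.failed or result.converged_increments < 1:
        raise SolverError("simulation did not complete")
    return float(result.curve.force[-1])


def mesh_convergence(
    meshes,
    mat: Material,
    probe: fem.ProbeSpec,
    *,
    threshold: float = 5.0,
    contact_mode: str = "penalty",
    runner=None,
    **solver_kwargs,
) -> ConvergenceReport:
    """Run the identical indentation on a coarse-to-fine mesh family.

    ``meshes`` must be ordered by strictly increasing element count.
    ``runner`` (default :func:`tissuecal.fem.solve_indentation`) may be
    substituted to stub the forward solves.  Failed rows are flagged and
    excluded from the metric comparisons: each row is compared with the
    next two finer non-failed rows.
    """
    meshes = list(meshes)
    if len(meshes) < 3:
        raise ValueError("mesh convergence needs at least three meshes")
    counts = [m.n_elements for m in meshes]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError("meshes must have strictly increasing element counts")
    if runner is None:
        runner = fem.solve_indentation

    forces: list = []
    runtimes: list = []
    failed: list = []
    for mesh in meshes:
        try:
            result = runner(mesh, mat, probe, contact_mode=contact_mode, **solver_kwargs)
            forces.append(_final_force(result))
            runtimes.append(getattr(result, "runtime_s", None))
            failed.append(False)
        except TissuecalError:
            forces.append(None)
            runtimes.append(None)
            failed.append(True)

    rows = []
    converged_index = None
    for i, mesh in enumerate(meshes):
        metric = None
        if not failed[i]:
            finer = [f for f in forces[i + 1 :] if f is not None][:2]
            if len(finer) == 2:
                metric = float(
                    np.mean([abs(forces[i] - fj) / forces[i] * 100.0 for fj in finer])
                )
                if converged_index is None and metric < threshold:
                    converged_index = i
        rows.append(
            ConvergenceRow(
                n_nodes=mesh.n_nodes,
                n_elements=mesh.n_elements,
                reaction_force=forces[i],
                metric=metric,
                runtime_s=runtimes[i],
                failed=failed[i],
            )
        )
    return ConvergenceReport(rows=rows, converged_index=converged_index, threshold=threshold)


def k_ratio_sensitivity(
    mesh,
    c1: float,
    ratios=(100.0, 1000.0, 10000.0),
    probe: fem.ProbeSpec | None = None,
    *,
    contact_mode: str = "penalty",
    runner=None,
    **solver_kwargs,
) -> pd.DataFrame:
    """One indentation per K/C1 ratio at fixed C1.

    Returns a DataFrame with columns ``k_ratio``,
    ``max_volume_change_pct``, ``reaction_force_n``, ``runtime_s`` and
    ``failed``.
    """
    ratios = [float(r) for r in ratios]
    if not ratios or min(ratios) <= 0:
        raise ValueError("ratios must be positive")
    if probe is None:
        raise ValueError("a ProbeSpec is required")
    if runner is None:
        runner = fem.solve_indentation

    records = []
    for ratio in ratios:
        mat = Material.coupled(c1, k_ratio=ratio)
        rec = {
            "k_ratio": ratio,
            "max_volume_change_pct": None,
            "reaction_force_n": None,
            "runtime_s": None,
            "failed": True,
        }
        try:
            result = runner(mesh, mat, probe, contact_mode=contact_mode, **solver_kwargs)
            rec["reaction_force_n"] = _final_force(result)
            rec["max_volume_change_pct"] = fem.max_volume_change(result)
            rec["runtime_s"] = getattr(result, "runtime_s", None)
            rec["failed"] = False
        except TissuecalError:
            pass
        records.append(rec)
    return pd.DataFrame(records)
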