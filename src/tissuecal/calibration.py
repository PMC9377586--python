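"""Slope-ratio inverse-FEA calibration of the Neo-Hookean coefficient.

The fitting problem has a single unknown, C1, with K slaved to it by a
fixed ratio.  Because the forward indentation problem is displacement
driven and the whole energy (including the auto-scaled contact penalty) is
homogeneous of degree one in (C1, K), the simulated reaction force — and
hence the fitted force-displacement slope — is very nearly proportional to
C1.  The calibration exploits this: each iteration divides the current C1
by the ratio of the simulated to the experimental zero-intercept
regression slopes,

    c1_new = c1 / (s_sim / s_exp),

which lands on the solution in one update for an exactly linear forward
model and in a handful of iterations otherwise.  Iterations stop when the
two slopes agree within a fractional tolerance (default 2.5%).

Before fitting, the simulated curve is cropped to the experimental
window: samples below the experimental preload force are dropped (the
probe was already loaded when recording began), displacement is re-zeroed
at the first retained sample, and samples beyond the experimental
displacement span are discarded.

A Brent root-finding baseline on the same slope mismatch is provided for
iteration-count comparisons; there every forward evaluation counts as one
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from . import fem
from .constitutive import Material
from .curves import IndentationCurve
from .errors import (
    CalibrationError,
    CurveError,
    InsufficientSimulatedDisplacementError,
)

__all__ = [
    "CalibrationState",
    "IterationRecord",
    "fit_slope_zero_intercept",
    "fit_slope",
    "crop_align",
    "update_c1",
    "calibrate",
    "calibrate_brent",
    "percent_difference",
    "fe_forward",
    "slope_sequence_forward",
]


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    c1: float
    k: float
    s_sim: float
    ratio: float


@dataclass
class CalibrationState:
    """History of one calibration run."""

    s_exp: float
    tol: float
    max_iter: int
    iterations: list = field(default_factory=list)
    converged: bool = False
    method: str = "ratio"

    @property
    def c1_trace(self) -> list:
        return [rec.c1 for rec in self.iterations]

    @property
    def final(self) -> IterationRecord:
        if not self.iterations:
            raise CalibrationError("no iterations recorded")
        return self.iterations[-1]

    @property
    def n_forward_evals(self) -> int:
        return len(self.iterations)

    def to_records(self) -> list:
        return [
            {
                "iteration": r.iteration,
                "c1_mpa": r.c1,
                "k_mpa": r.k,
                "s_sim": r.s_sim,
                "ratio": r.ratio,
            }
            for r in self.iterations
        ]


# ----------------------------------------------------------------- fits


def fit_slope_zero_intercept(curve: IndentationCurve) -> float:
    """Least-squares slope of force vs displacement through the origin,
    ``sum(d * F) / sum(d**2)`` (N/mm)."""
    d = curve.displacement
    f = curve.force
    if d.size < 2:
        raise CurveError("need at least two samples to fit a slope")
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise CurveError("all displacements are zero; slope undefined")
    return float(np.dot(d, f) / denom)


def fit_slope(curve: IndentationCurve, zero_intercept: bool = True) -> float:
    """Regression slope, optionally with a free intercept."""
    if zero_intercept:
        return fit_slope_zero_intercept(curve)
    if len(curve) < 2:
        raise CurveError("need at least two samples to fit a slope")
    slope, _ = np.polyfit(curve.displacement, curve.force, 1)
    return float(slope)


# ----------------------------------------------------------- crop/align


def crop_align(sim: IndentationCurve, exp: IndentationCurve) -> IndentationCurve:
    """Crop the simulated curve to the experimental window.

    1. drop simulated samples whose force is below ``exp.initial_force``
       (the experimental preload);
    2. re-zero displacement at the first retained sample;
    3. drop samples whose re-zeroed displacement exceeds the experimental
       displacement span.
    """
    keep = sim.force >= exp.initial_force
    if not np.any(keep):
        raise InsufficientSimulatedDisplacementError(
            f"no simulated sample reaches the experimental preload "
            f"{exp.initial_force:g} N (simulated peak {sim.peak_force:g} N); "
            "rerun the forward model with a larger total displacement"
        )
    first = int(np.argmax(keep))
    d = sim.displacement[first:] - sim.displacement[first]
    f = sim.force[first:]
    span = float(exp.displacement[-1] - exp.displacement[0])
    within = d <= span + 1e-12
    return IndentationCurve(d[within], f[within], meta=sim.meta)


def update_c1(c1: float, s_sim: float, s_exp: float) -> float:
    """Slope-ratio update: divide the current C1 by s_sim/s_exp."""
    if c1 <= 0 or s_sim <= 0 or s_exp <= 0:
        raise CalibrationError(
            f"update requires positive c1 and slopes, got c1={c1:g}, "
            f"s_sim={s_sim:g}, s_exp={s_exp:g}"
        )
    return c1 / (s_sim / s_exp)


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference, ``|a - b| / ((a + b)/2) * 100``."""
    mean = (a + b) / 2.0
    if mean == 0.0:
        raise ValueError("percent difference undefined for zero mean")
    return abs(a - b) / abs(mean) * 100.0


# ----------------------------------------------------------- main loops


def _simulated_slope(
    forward, c1: float, exp: IndentationCurve, sim_zero_intercept: bool
) -> float:
    sim = forward(c1)
    cropped = crop_align(sim, exp)
    if len(cropped) < 2:
        raise InsufficientSimulatedDisplacementError(
            "fewer than two simulated samples remain after cropping; "
            "increase the simulated displacement or the increment count"
        )
    return fit_slope(cropped, zero_intercept=sim_zero_intercept)


def calibrate(
    forward,
    exp: IndentationCurve,
    c1_init: float = 0.01,
    tol: float = 0.025,
    max_iter: int = 20,
    *,
    k_ratio: float = 1000.0,
    sim_zero_intercept: bool = True,
) -> CalibrationState:
    """Fit C1 by the slope-ratio iteration.

    ``forward`` maps a candidate C1 (MPa) to a simulated
    :class:`IndentationCurve`; ``exp`` is the experimental record.  Each
    iteration simulates, crops/aligns, fits both slopes and records the
    ratio; convergence is ``|s_sim/s_exp - 1| < tol``.  Exhausting
    ``max_iter`` yields a non-converged state rather than an exception.
    """
    if c1_init <= 0:
        raise CalibrationError("c1_init must be positive")
    s_exp = fit_slope_zero_intercept(exp)
    if s_exp <= 0:
        raise CalibrationError(f"experimental slope must be positive, got {s_exp:g}")
    state = CalibrationState(s_exp=s_exp, tol=tol, max_iter=max_iter)
    c1 = c1_init
    for it in range(1, max_iter + 1):
        try:
            s_sim = _simulated_slope(forward, c1, exp, sim_zero_intercept)
        except Exception as exc:
            raise CalibrationError(f"forward model failed at iteration {it}: {exc}") from exc
        ratio = s_sim / s_exp
        state.iterations.append(
            IterationRecord(iteration=it, c1=c1, k=k_ratio * c1, s_sim=s_sim, ratio=ratio)
        )
        if abs(ratio - 1.0) < tol:
            state.converged = True
            break
        c1 = update_c1(c1, s_sim, s_exp)
    return state


def calibrate_brent(
    forward,
    exp: IndentationCurve,
    bracket: tuple = (0.01 / 20.0, 0.01 * 20.0),
    tol: float = 0.025,
    *,
    k_ratio: float = 1000.0,
    sim_zero_intercept: bool = True,
    xtol: float = 1e-6,
    rtol: float = 1e-4,
) -> CalibrationState:
    """Brent root search on the slope mismatch ``s_sim(c1) - s_exp``.

    Every forward evaluation counts as one iteration so the count is
    directly comparable with :func:`calibrate`.  The final state is marked
    converged only if it also satisfies the slope-ratio criterion.
    """
    s_exp = fit_slope_zero_intercept(exp)
    if s_exp <= 0:
        raise CalibrationError(f"experimental slope must be positive, got {s_exp:g}")
    a, b = bracket
    if not (0 < a < b):
        raise CalibrationError(f"invalid bracket ({a:g}, {b:g})")
    state = CalibrationState(s_exp=s_exp, tol=tol, max_iter=0, method="brent")

    def mismatch(c1: float) -> float:
        s_sim = _simulated_slope(forward, c1, exp, sim_zero_intercept)
        state.iterations.append(
            IterationRecord(
                iteration=len(state.iterations) + 1,
                c1=c1,
                k=k_ratio * c1,
                s_sim=s_sim,
                ratio=s_sim / s_exp,
            )
        )
        return s_sim - s_exp

    fa, fb = mismatch(a), mismatch(b)
    if fa * fb > 0:
        raise CalibrationError(
            f"bracket ({a:g}, {b:g}) does not contain a slope-mismatch root "
            f"(f(a)={fa:g}, f(b)={fb:g})"
        )
    root = optimize.brentq(mismatch, a, b, xtol=xtol, rtol=max(rtol, 4 * np.finfo(float).eps))
    final_ratio = 1.0 + mismatch(float(root)) / s_exp
    state.converged = abs(final_ratio - 1.0) < tol
    state.max_iter = len(state.iterations)
    return state


# ------------------------------------------------------ forward models


def fe_forward(
    mesh,
    probe: fem.ProbeSpec,
    exp: IndentationCurve,
    *,
    k_ratio: float = 1000.0,
    nu_effective: float = 0.5,
    contact_mode: str = "penalty",
    sim_displacement_factor: float = 1.5,
    n_increments: int | None = None,
    **solver_kwargs,
):
    """Build a forward-model handle ``c1 -> IndentationCurve`` backed by
    the finite-element solver.

    The probe's total displacement is set to the experimental
    displacement span times ``sim_displacement_factor`` so the simulated
    curve always covers the experimental window after cropping.
    """
    total = exp.span * sim_displacement_factor
    if total <= 0:
        raise CalibrationError("experimental curve has zero displacement span")
    probe_run = replace(
        probe,
        total_displacement=total,
        n_increments=n_increments if n_increments is not None else probe.n_increments,
    )

    def forward(c1: float) -> IndentationCurve:
        mat = Material.coupled(c1, k_ratio=k_ratio, nu_effective=nu_effective)
        result = fem.solve_indentation(
            mesh, mat, probe_run, contact_mode=contact_mode, **solver_kwargs
        )
        if result.failed:
            raise CalibrationError(
                f"forward simulation failed after {result.converged_increments} "
                f"of {probe_run.n_increments} increments at c1={c1:g}"
            )
        return result.curve

    return forward


def slope_sequence_forward(slopes, d_max: float = 10.0, n: int = 11):
    """Stateful scripted forward model replaying a fixed slope sequence.

    Each call returns a straight line through the origin with the next
    slope from ``slopes`` (the last slope repeats once the script is
    exhausted), regardless of the C1 argument.  Useful for replaying a
    published per-iteration calibration record through the full loop.
    """
    slopes = [float(s) for s in slopes]
    d = np.linspace(0.0, d_max, n)
    counter = {"i": 0}

    def forward(_c1: float) -> IndentationCurve:
        s = slopes[min(counter["i"], len(slopes) - 1)]
        counter["i"] += 1
        return IndentationCurve(d, s * d, meta="simulated")

    return forward
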