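"""Force-displacement indentation curves.

A curve pairs probe displacement magnitude (mm, measured along the probe
trajectory) with probe reaction force (N).  Freehand experimental records
typically start at a nonzero preload force because the probe is already in
contact with the skin when recording begins; the first sample's force is
kept as ``initial_force`` and drives the crop-and-align rule during
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CurveError

__all__ = ["IndentationCurve"]


@dataclass(frozen=True)
class IndentationCurve:
    displacement: np.ndarray
    force: np.ndarray
    meta: str = "simulated"
    initial_force: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.ndim != 1 or f.ndim != 1 or d.size != f.size:
            raise CurveError("displacement and force must be 1-D of equal length")
        if d.size == 0:
            raise CurveError("empty curve")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise CurveError("curve contains non-finite samples")
        if np.any(np.diff(d) < 0):
            raise CurveError("displacement must be non-decreasing")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if self.initial_force is None:
            object.__setattr__(self, "initial_force", float(f[0]))

    def __len__(self) -> int:
        return self.displacement.size

    @property
    def span(self) -> float:
        """Displacement range max - min, mm."""
        return float(self.displacement[-1] - self.displacement[0])

    @property
    def peak_force(self) -> float:
        return float(np.max(self.force))

    def with_meta(self, meta: str) -> "IndentationCurve":
        return IndentationCurve(self.displacement, self.force, meta=meta)
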