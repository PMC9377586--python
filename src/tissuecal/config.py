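"""Run configuration: YAML-backed settings with CLI overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved settings for a simulation or calibration run.

    Defaults mirror the package's standard protocol: initial guess
    C1 = 0.01 MPa with K = 1000 C1, 100 displacement increments (0.01 of
    the total each), penalty contact with scale 100, slope-ratio tolerance
    2.5%, and simulated displacement 1.5x the experimental span.
    """

    # material
    c1_init: float = 0.01
    k_ratio: float = 1000.0
    nu_effective: float = 0.5
    # solver
    n_increments: int = 100
    newton_tol: float = 1e-6
    max_newton_iter: int = 25
    contact_mode: str = "penalty"
    penalty_scale: float = 100.0
    # calibration
    tol: float = 0.025
    max_iter: int = 20
    sim_displacement_factor: float = 1.5
    sim_zero_intercept: bool = True
    # probe geometry (optional; used by the CLI)
    probe: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def load(cls, path=None, overrides: dict | None = None) -> "RunConfig":
        """Build from an optional YAML file, then apply overrides (CLI
        flags win over file values; unknown keys are an error)."""
        data: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text())
            if raw is not None:
                if not isinstance(raw, dict):
                    raise ValueError(f"{path}: config must be a mapping")
                data.update(raw)
        for key, value in (overrides or {}).items():
            if value is not None:
                data[key] = value
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def material_dict(self) -> dict:
        return {
            "c1_mpa": self.c1_init,
            "k_ratio": self.k_ratio,
            "nu_effective": self.nu_effective,
        }
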