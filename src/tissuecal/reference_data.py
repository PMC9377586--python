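"""Published reference calibration records used for verification.

Two small datasets from a freehand ultrasound-probe indentation study of
cadaveric extremities, kept here as plain records so verification scripts
can recompute derived quantities from them:

* ``REGIONAL_CALIBRATIONS`` — the per-region inverse-FEA outcome for two
  donors (soft-tissue thickness at the indentation site, iterations to
  convergence, fitted C1 in MPa).  K and the effective Young's modulus
  are derived columns: ``K = 1000 * C1`` and ``E = 6 * C1`` at an
  effective Poisson ratio of 0.5.
* ``UPPER_ARM_EXAMPLE`` — the female-upper-arm worked example of the
  slope-ratio calibration: the experimental zero-intercept slope and the
  per-iteration simulated slopes from the initial guess C1 = 0.01 MPa.
"""

from __future__ import annotations

import pandas as pd

from .constitutive import effective_modulus

__all__ = ["REGIONAL_CALIBRATIONS", "UPPER_ARM_EXAMPLE", "regional_frame"]

# donor, region, soft-tissue thickness (mm), iterations, fitted C1 (MPa)
REGIONAL_CALIBRATIONS = (
    {"donor": "female", "region": "upper_arm", "thickness_mm": 18.93, "iterations": 4, "c1_mpa": 0.00358},
    {"donor": "female", "region": "lower_arm", "thickness_mm": 9.19, "iterations": 8, "c1_mpa": 0.00133},
    {"donor": "female", "region": "upper_leg", "thickness_mm": 21.17, "iterations": 2, "c1_mpa": 0.00779},
    {"donor": "female", "region": "lower_leg", "thickness_mm": 26.09, "iterations": 4, "c1_mpa": 0.00808},
    {"donor": "male", "region": "upper_arm", "thickness_mm": 38.32, "iterations": 4, "c1_mpa": 0.00342},
    {"donor": "male", "region": "lower_arm", "thickness_mm": 40.60, "iterations": 3, "c1_mpa": 0.00596},
    {"donor": "male", "region": "upper_leg", "thickness_mm": 31.49, "iterations": 3, "c1_mpa": 0.01143},
    {"donor": "male", "region": "lower_leg", "thickness_mm": 32.43, "iterations": 3, "c1_mpa": 0.00830},
)

UPPER_ARM_EXAMPLE = {
    "c1_init": 0.01,
    "experimental_slope": 1.5265,
    "simulation_slopes": (3.0807, 1.9580, 1.6454, 1.5265),
}


def regional_frame(k_ratio: float = 1000.0, nu: float = 0.5) -> pd.DataFrame:
    """The regional calibration table with derived K and effective-modulus
    columns recomputed from C1."""
    df = pd.DataFrame(REGIONAL_CALIBRATIONS)
    df["k_mpa"] = k_ratio * df["c1_mpa"]
    df["effective_modulus_mpa"] = [effective_modulus(c, nu) for c in df["c1_mpa"]]
    return df
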