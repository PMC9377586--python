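"""Uncoupled Neo-Hookean hyperelasticity for lumped soft tissue.

The strain-energy density is split into an isochoric and a volumetric part,

    psi(F) = C1 * (I1_bar - 3) + 0.5 * K * (ln J)**2

with ``C1`` the Neo-Hookean coefficient (MPa), ``K`` a bulk-modulus-like
penalty (MPa) enforcing near-incompressibility, ``J = det F`` and
``I1_bar = J**(-2/3) * tr(F^T F)`` the first invariant of the deviatoric
right Cauchy-Green tensor.  Working units are MPa / mm / N throughout.

``K`` is conventionally tied to ``C1`` by a fixed ratio (default 1000) so a
single coefficient describes the tissue; the effective Poisson ratio stored
on :class:`Material` is bookkeeping for small-strain modulus conversions
only — actual compressibility is governed by ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDeformationError

__all__ = [
    "Material",
    "DeformationState",
    "strain_energy",
    "cauchy_stress",
    "material_tangent",
    "c1_from_modulus",
    "effective_modulus",
]

_EYE = np.eye(3)


@dataclass(frozen=True)
class Material:
    """Neo-Hookean material parameters.

    Attributes
    ----------
    c1 : float
        Neo-Hookean coefficient, MPa.  Shear modulus is ``mu = 2 * c1``.
    k : float
        Bulk-modulus-like penalty, MPa.
    k_ratio : float
        Dimensionless coupling factor; ``k == k_ratio * c1`` when the
        material is built through :meth:`coupled`.
    nu_effective : float
        Effective Poisson ratio used only for modulus conversions.
    """

    c1: float
    k: float
    k_ratio: float = 1000.0
    nu_effective: float = 0.5

    def __post_init__(self) -> None:
        if not self.c1 > 0:
            raise ValueError(f"c1 must be positive, got {self.c1}")
        if not self.k_ratio > 0:
            raise ValueError(f"k_ratio must be positive, got {self.k_ratio}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")

    @classmethod
    def coupled(
        cls, c1: float, k_ratio: float = 1000.0, nu_effective: float = 0.5
    ) -> "Material":
        """Construct with ``k`` slaved to ``c1`` via ``k = k_ratio * c1``."""
        return cls(c1=c1, k=k_ratio * c1, k_ratio=k_ratio, nu_effective=nu_effective)

    @property
    def shear_modulus(self) -> float:
        return 2.0 * self.c1

    @property
    def effective_youngs_modulus(self) -> float:
        return effective_modulus(self.c1, self.nu_effective)

    def to_dict(self) -> dict:
        return {
            "c1_mpa": self.c1,
            "k_mpa": self.k,
            "k_ratio": self.k_ratio,
            "nu_effective": self.nu_effective,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Material":
        if "k_mpa" in d:
            return cls(
                c1=float(d["c1_mpa"]),
                k=float(d["k_mpa"]),
                k_ratio=float(d.get("k_ratio", float(d["k_mpa"]) / float(d["c1_mpa"]))),
                nu_effective=float(d.get("nu_effective", 0.5)),
            )
        return cls.coupled(
            c1=float(d["c1_mpa"]),
            k_ratio=float(d.get("k_ratio", 1000.0)),
            nu_effective=float(d.get("nu_effective", 0.5)),
        )


@dataclass(frozen=True)
class DeformationState:
    """Pointwise deformation described by the gradient ``F`` and derived
    invariants ``J = det F`` and ``I1_bar = J**(-2/3) tr(F^T F)``."""

    F: np.ndarray
    J: float
    I1_bar: float

    @classmethod
    def from_F(cls, F: np.ndarray) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 tensor")
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise InvalidDeformationError(f"non-positive volume ratio J={J:g}")
        I1_bar = float(J ** (-2.0 / 3.0) * np.trace(F.T @ F))
        return cls(F=F, J=J, I1_bar=I1_bar)


def _check_state(state: DeformationState) -> None:
    if state.J <= 0.0:
        raise InvalidDeformationError(f"non-positive volume ratio J={state.J:g}")


def strain_energy(state: DeformationState, mat: Material) -> float:
    """Strain-energy density (MPa) of the uncoupled Neo-Hookean law.

    Zero exactly at the undeformed state; non-negative for every admissible
    deformation because ``I1_bar >= 3`` and ``(ln J)**2 >= 0``.
    """
    _check_state(state)
    return mat.c1 * (state.I1_bar - 3.0) + 0.5 * mat.k * np.log(state.J) ** 2


def cauchy_stress(state: DeformationState, mat: Material) -> np.ndarray:
    """Cauchy stress (MPa), ``sigma = (2 C1 / J) dev(B_bar) + (K ln J / J) I``
    with ``B_bar = J**(-2/3) F F^T``."""
    _check_state(state)
    F = state.F
    J = state.J
    B_bar = J ** (-2.0 / 3.0) * (F @ F.T)
    dev_B_bar = B_bar - np.trace(B_bar) / 3.0 * _EYE
    return (2.0 * mat.c1 / J) * dev_B_bar + (mat.k * np.log(J) / J) * _EYE


def material_tangent(state: DeformationState, mat: Material) -> np.ndarray:
    """Spatial (Eulerian) elasticity tensor ``c_ijkl`` (MPa).

    This is the push-forward of the material tangent divided by ``J`` — the
    tensor entering the spatial tangent stiffness as
    ``K_ab = int (c_ijkl + delta_ik sigma_jl) dN_a/dx_j dN_b/dx_l dv``.
    It carries both minor symmetries and the major symmetry.
    """
    _check_state(state)
    F = state.F
    J = state.J
    lnJ = np.log(J)
    B = F @ F.T
    B_bar = J ** (-2.0 / 3.0) * B
    trB_bar = np.trace(B_bar)
    sigma_iso = (2.0 * mat.c1 / J) * (B_bar - trB_bar / 3.0 * _EYE)

    II = np.einsum("ij,kl->ijkl", _EYE, _EYE)
    IS = 0.5 * (
        np.einsum("ik,jl->ijkl", _EYE, _EYE) + np.einsum("il,jk->ijkl", _EYE, _EYE)
    )
    # isochoric part (Truesdell rate of Kirchhoff stress, over J)
    mu_bar = 2.0 * mat.c1 * trB_bar / 3.0  # == (2/3) C1 J^{-2/3} tr(B)
    c_iso = (2.0 / J) * mu_bar * (IS - II / 3.0) - (2.0 / 3.0) * (
        np.einsum("ij,kl->ijkl", _EYE, sigma_iso)
        + np.einsum("ij,kl->ijkl", sigma_iso, _EYE)
    )
    # volumetric part from U(J) = K/2 (ln J)^2
    c_vol = (mat.k / J) * II - 2.0 * (mat.k * lnJ / J) * IS
    return c_iso + c_vol


def c1_from_modulus(E: float, nu: float) -> float:
    """Convert a small-strain Young's modulus (MPa) to the Neo-Hookean
    coefficient via ``C1 = E / (4 (1 + nu))``."""
    if E < 0:
        raise ValueError("Young's modulus must be non-negative")
    if not (-1.0 < nu <= 0.5):
        raise ValueError("Poisson ratio must lie in (-1, 0.5]")
    return E / (4.0 * (1.0 + nu))


def effective_modulus(c1: float, nu: float = 0.5) -> float:
    """Inverse of :func:`c1_from_modulus`: ``E = 4 (1 + nu) C1`` (MPa).

    At ``nu = 0.5`` this is the familiar ``E = 6 C1`` of incompressible
    Neo-Hookean tissue, a reporting convenience rather than a measured
    property.
    """
    if c1 < 0:
        raise ValueError("c1 must be non-negative")
    return 4.0 * (1.0 + nu) * c1
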