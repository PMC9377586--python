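"""Nonlinear finite-element forward model of rigid-probe indentation.

Displacement-driven total-Lagrangian solver for the uncoupled Neo-Hookean
flesh volume: 4- or 10-node tetrahedra, Newton iteration with a consistent
spatial tangent, incremental probe advance with step cutting, and two ways
of transmitting the probe load:

``penalty``
    frictionless node-to-rigid-plane penalty contact against the flat
    rectangular probe face (gap = signed distance along the face normal,
    active only inside the footprint), with an automatic penalty stiffness
    ``k_pen = penalty_scale * c1 * h_char`` so the whole problem stays
    exactly homogeneous of degree one in (C1, K);

``prescribed_patch``
    skin nodes initially under the footprint translate rigidly with the
    probe — a simpler constraint that is exactly material-linear, useful
    for fast calibration and for the one-update convergence property of
    the slope-ratio scheme.

The reaction force reported on the curve is the component of the total
probe force along the displacement axis.  Units: mm, N, MPa.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import Material
from .curves import IndentationCurve
from .errors import ContactError, InvalidDeformationError, MeshError, SolverError
from .mesh import TetMesh

__all__ = [
    "ProbeSpec",
    "SimulationResult",
    "FEModel",
    "assemble",
    "total_strain_energy",
    "element_stresses",
    "solve_prescribed",
    "solve_indentation",
    "max_volume_change",
    "surface_fields",
]

_EYE = np.eye(3)


# ----------------------------------------------------------------- probes


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be a nonzero vector")
    return v / n


@dataclass(frozen=True)
class ProbeSpec:
    """Rigid flat rectangular probe face and its prescribed motion.

    ``face_normal`` points into the tissue; ``face_half_lengths`` are the
    two in-plane half-dimensions of the rectangular footprint (mm).  The
    face centre advances by ``total_displacement`` along
    ``displacement_axis`` in ``n_increments`` equal steps.
    """

    face_center: np.ndarray
    face_normal: np.ndarray
    face_half_lengths: tuple = (25.0, 5.0)
    displacement_axis: np.ndarray = None  # type: ignore[assignment]
    total_displacement: float = 5.0
    n_increments: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "face_center", np.asarray(self.face_center, dtype=float))
        object.__setattr__(self, "face_normal", _unit(self.face_normal, "face_normal"))
        axis = self.displacement_axis if self.displacement_axis is not None else self.face_normal
        object.__setattr__(self, "displacement_axis", _unit(axis, "displacement_axis"))
        if self.total_displacement < 0:
            raise ValueError("total_displacement must be non-negative")
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")
        h = tuple(float(v) for v in self.face_half_lengths)
        if len(h) != 2 or min(h) <= 0:
            raise ValueError("face_half_lengths must be two positive lengths")
        object.__setattr__(self, "face_half_lengths", h)

    def in_plane_axes(self) -> tuple:
        """Deterministic orthonormal in-plane axes of the probe face."""
        n = self.face_normal
        seed = _EYE[int(np.argmin(np.abs(n)))]
        t1 = np.cross(n, seed)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        return t1, t2

    def center_at(self, advance: float) -> np.ndarray:
        return self.face_center + advance * self.displacement_axis


# ------------------------------------------------------------ quadrature

_QP_A = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_QP_B = (5.0 - np.sqrt(5.0)) / 20.0
# barycentric (L0, L1, L2, L3) for the degree-2 four-point rule
_TET_QP = np.array(
    [
        [_QP_A, _QP_B, _QP_B, _QP_B],
        [_QP_B, _QP_A, _QP_B, _QP_B],
        [_QP_B, _QP_B, _QP_A, _QP_B],
        [_QP_B, _QP_B, _QP_B, _QP_A],
    ]
)
_TET_QW = np.full(4, 1.0 / 24.0)


def _shape_tet4(L: np.ndarray):
    N = L.copy()
    dN = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return N, np.broadcast_to(dN, (L.shape[0], 4, 3)).copy()


def _shape_tet10(L: np.ndarray):
    nqp = L.shape[0]
    N = np.empty((nqp, 10))
    dN = np.empty((nqp, 10, 3))
    dL = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    for i in range(4):
        N[:, i] = L[:, i] * (2.0 * L[:, i] - 1.0)
        dN[:, i, :] = (4.0 * L[:, i, None] - 1.0) * dL[i]
    from .mesh import TET10_EDGES

    for m, (a, b) in enumerate(TET10_EDGES, start=4):
        N[:, m] = 4.0 * L[:, a] * L[:, b]
        dN[:, m, :] = 4.0 * (L[:, a, None] * dL[b] + L[:, b, None] * dL[a])
    return N, dN


def _shape_table(order: int):
    N, dN = (_shape_tet4 if order == 1 else _shape_tet10)(_TET_QP)
    return N, dN, _TET_QW.copy()


# ------------------------------------------------- batched material law


def _neo_hookean_batch(F: np.ndarray, c1: float, k: float, tangent: bool):
    """Vectorized Cauchy stress and spatial tangent for a stack of
    deformation gradients ``F`` of shape (m, 3, 3)."""
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise InvalidDeformationError("element inversion: J <= 0 at a quadrature point")
    lnJ = np.log(J)
    B = np.einsum("mij,mkj->mik", F, F)
    Bbar = J[:, None, None] ** (-2.0 / 3.0) * B
    trBbar = np.trace(Bbar, axis1=1, axis2=2)
    dev = Bbar - trBbar[:, None, None] / 3.0 * _EYE
    sigma_iso = (2.0 * c1 / J)[:, None, None] * dev
    sigma = sigma_iso + (k * lnJ / J)[:, None, None] * _EYE
    if not tangent:
        return sigma, None, J
    II = np.einsum("ij,kl->ijkl", _EYE, _EYE)
    IS = 0.5 * (
        np.einsum("ik,jl->ijkl", _EYE, _EYE) + np.einsum("il,jk->ijkl", _EYE, _EYE)
    )
    mu_bar = 2.0 * c1 * trBbar / 3.0
    c = (2.0 / J * mu_bar)[:, None, None, None, None] * (IS - II / 3.0)
    c -= (2.0 / 3.0) * (
        np.einsum("ij,mkl->mijkl", _EYE, sigma_iso)
        + np.einsum("mij,kl->mijkl", sigma_iso, _EYE)
    )
    c += (k / J)[:, None, None, None, None] * II
    c -= (2.0 * k * lnJ / J)[:, None, None, None, None] * IS
    return sigma, c, J


# ----------------------------------------------------------------- model


class FEModel:
    """Precomputed assembly data for one mesh: reference shape-function
    gradients, quadrature weights, and sparse scatter indices."""

    def __init__(self, mesh: TetMesh):
        mesh.validate()
        self.mesh = mesh
        self.n_dof = 3 * mesh.n_nodes
        self.conn = mesh.elements
        ne, nn = self.conn.shape
        _, dNdxi, qw = _shape_table(mesh.element_order)
        X = mesh.nodes[self.conn]  # (ne, nn, 3)
        # dX/dxi at each quadrature point; general (possibly curved) mapping
        Jmap = np.einsum("eai,qaj->eqij", X, dNdxi)
        detJ = np.linalg.det(Jmap)
        if np.any(detJ <= 0):
            raise MeshError("non-positive mapping Jacobian at a quadrature point")
        invJ = np.linalg.inv(Jmap)
        self.gradN0 = np.einsum("qaj,eqji->eqai", dNdxi, invJ)  # (ne, nqp, nn, 3)
        self.w = qw[None, :] * detJ  # (ne, nqp) reference measure
        self.elem_vol = self.w.sum(axis=1)
        self.h_char = mesh.characteristic_length()
        edof = (3 * self.conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 3 * nn)
        self.edof = edof
        self.rows = np.repeat(edof, 3 * nn, axis=1).ravel()
        self.cols = np.tile(edof, (1, 3 * nn)).ravel()

    # -- kinematics -------------------------------------------------------
    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.conn]
        return _EYE + np.einsum("eai,eqaj->eqij", ue, self.gradN0)

    def element_volume_ratio(self, u: np.ndarray) -> np.ndarray:
        """Per-element relative volume Sum(w J)/Sum(w) — the element's
        current-to-reference volume ratio."""
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvalidDeformationError("element inversion: J <= 0")
        return (self.w * J).sum(axis=1) / self.elem_vol

    def strain_energy(self, u: np.ndarray, mat: Material) -> float:
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvalidDeformationError("element inversion: J <= 0")
        I1b = J ** (-2.0 / 3.0) * np.einsum("eqij,eqij->eq", F, F)
        psi = mat.c1 * (I1b - 3.0) + 0.5 * mat.k * np.log(J) ** 2
        return float(np.sum(self.w * psi))

    def quadrature_stresses(self, u: np.ndarray, mat: Material) -> np.ndarray:
        """Cauchy stress at every quadrature point, (ne, nqp, 3, 3)."""
        ne, nqp = self.w.shape
        F = self.deformation_gradients(u).reshape(-1, 3, 3)
        sigma, _, _ = _neo_hookean_batch(F, mat.c1, mat.k, tangent=False)
        return sigma.reshape(ne, nqp, 3, 3)

    # -- assembly ---------------------------------------------------------
    def assemble(self, u: np.ndarray, mat: Material, tangent: bool = True):
        """Internal force vector, tangent stiffness (CSR, or None), and
        per-element volume ratio at displacement ``u``."""
        ne, nqp = self.w.shape
        nn = self.conn.shape[1]
        F = self.deformation_gradients(u)
        Fr = F.reshape(-1, 3, 3)
        sigma, cmat, J = _neo_hookean_batch(Fr, mat.c1, mat.k, tangent)
        sigma = sigma.reshape(ne, nqp, 3, 3)
        Jq = J.reshape(ne, nqp)
        Finv = np.linalg.inv(Fr).reshape(ne, nqp, 3, 3)
        g = np.einsum("eqaj,eqji->eqai", self.gradN0, Finv)  # grads in current config
        wJ = self.w * Jq
        fe = np.einsum("eq,eqij,eqaj->eai", wJ, sigma, g)
        fint = np.zeros(self.n_dof)
        np.add.at(fint, self.edof, fe.reshape(ne, 3 * nn))
        Jel = (self.w * Jq).sum(axis=1) / self.elem_vol
        if not tangent:
            return fint, None, Jel
        A = cmat.reshape(ne, nqp, 3, 3, 3, 3) + np.einsum(
            "ik,eqjl->eqijkl", _EYE, sigma
        )
        # two-step contraction keeps the cost at O(ne * nqp * 81 * nn)
        T = np.einsum("eqijkl,eqaj->eqikla", A, g)
        Ke = np.einsum("eq,eqikla,eqbl->eaibk", wJ, T, g)
        K = sp.coo_matrix(
            (Ke.reshape(ne, 3 * nn, 3 * nn).ravel(), (self.rows, self.cols)),
            shape=(self.n_dof, self.n_dof),
        ).tocsr()
        return fint, K, Jel


def assemble(mesh: TetMesh, mat: Material, u: np.ndarray):
    """One-shot total-Lagrangian assembly: (internal force, tangent
    stiffness, per-element volume ratio).  The internal force is the exact
    gradient of :func:`total_strain_energy` with respect to ``u``."""
    u = np.asarray(u, dtype=float).ravel()
    model = FEModel(mesh)
    if u.size != model.n_dof:
        raise ValueError(f"u must have {model.n_dof} entries")
    if not np.all(np.isfinite(u)):
        raise ValueError("u contains non-finite entries")
    return model.assemble(u, mat, tangent=True)


def total_strain_energy(mesh: TetMesh, mat: Material, u: np.ndarray) -> float:
    """Total stored energy (N*mm) of the mesh at displacement ``u``."""
    return FEModel(mesh).strain_energy(np.asarray(u, dtype=float).ravel(), mat)


def element_stresses(mesh: TetMesh, mat: Material, u: np.ndarray) -> np.ndarray:
    """Quadrature-averaged Cauchy stress per element, (n_elements, 3, 3)."""
    model = FEModel(mesh)
    s = model.quadrature_stresses(np.asarray(u, dtype=float).ravel(), mat)
    return np.einsum("eq,eqij->eij", model.w, s) / model.elem_vol[:, None, None]


# ------------------------------------------------------------- contact


class _PenaltyContact:
    """Frictionless node-to-rigid-plane penalty contact.

    The force-gap law is quadratically smoothed over a small regularization
    depth ``eps`` so the residual is C1 at grazing contact; without it the
    Newton iteration can 2-cycle as boundary nodes flip in and out of the
    active set.  For penetration beyond ``eps`` the law is the plain linear
    penalty shifted by ``eps/2``.
    """

    def __init__(self, probe: ProbeSpec, candidates: np.ndarray, k_pen: float, eps: float):
        self.probe = probe
        self.candidates = np.asarray(candidates, dtype=np.int64)
        self.k_pen = float(k_pen)
        self.eps = float(eps)
        self.t1, self.t2 = probe.in_plane_axes()
        # footprint edges are tapered over 10% of each half-length with a
        # smoothstep weight; a sharp rectangular cut-off makes the Newton
        # residual discontinuous as surface nodes slide across the edge
        self.margins = (0.1 * probe.face_half_lengths[0], 0.1 * probe.face_half_lengths[1])

    @staticmethod
    def _smoothstep_edge(d: np.ndarray, h: float, m: float):
        """C1 taper of the footprint indicator: 1 inside |d| < h - m/2,
        0 outside |d| > h + m/2.  Returns the weight and d(weight)/d(d)."""
        t = np.clip((h - np.abs(d)) / m + 0.5, 0.0, 1.0)
        s = t * t * (3.0 - 2.0 * t)
        ds_dt = 6.0 * t * (1.0 - t)
        ds_dd = ds_dt * (-np.sign(d) / m)
        return s, ds_dd

    def _force_law(self, pen: np.ndarray):
        """Force magnitude and its derivative w.r.t. penetration."""
        k, eps = self.k_pen, self.eps
        fmag = np.where(pen >= eps, k * (pen - 0.5 * eps), k * pen**2 / (2.0 * eps))
        stiff = np.where(pen >= eps, k, k * pen / eps)
        return fmag, stiff

    def gaps(self, coords: np.ndarray, advance: float):
        """Penetration depth (positive = penetrated) and footprint mask for
        candidate nodes at the given probe advance."""
        d = coords[self.candidates] - self.probe.center_at(advance)
        pen = -(d @ self.probe.face_normal)
        h1, h2 = self.probe.face_half_lengths
        inside = (np.abs(d @ self.t1) <= h1) & (np.abs(d @ self.t2) <= h2)
        return pen, inside

    def force_and_stiffness(self, coords: np.ndarray, advance: float, n_dof: int):
        d = coords[self.candidates] - self.probe.center_at(advance)
        n = self.probe.face_normal
        pen = -(d @ n)
        d1 = d @ self.t1
        d2 = d @ self.t2
        h1, h2 = self.probe.face_half_lengths
        m1, m2 = self.margins
        s1, ds1 = self._smoothstep_edge(d1, h1, m1)
        s2, ds2 = self._smoothstep_edge(d2, h2, m2)
        w = s1 * s2
        active = (w > 0.0) & (pen > 0.0)
        fc = np.zeros(n_dof)
        nodes = self.candidates[active]
        if nodes.size == 0:
            return fc, None, 0.0, nodes, np.empty(0)
        g, gp = self._force_law(pen[active])
        wa = w[active]
        fmag = wa * g
        for i in range(3):
            fc[3 * nodes + i] = fmag * n[i]
        # consistent tangent of -f w.r.t. node position:
        #   dR/du = w g' n (x) n - g n (x) grad(w)
        dw_vec = (ds1[active] * s2[active])[:, None] * self.t1 + (
            s1[active] * ds2[active]
        )[:, None] * self.t2
        nn_outer = np.einsum("i,j->ij", n, n)
        blocks = (wa * gp)[:, None, None] * nn_outer[None, :, :] - g[
            :, None, None
        ] * np.einsum("i,aj->aij", n, dw_vec)
        rows = (3 * nodes[:, None, None] + np.arange(3)[None, :, None]).repeat(3, axis=2)
        cols = (3 * nodes[:, None, None] + np.arange(3)[None, None, :]).repeat(3, axis=1)
        Kc = sp.coo_matrix(
            (blocks.ravel(), (rows.ravel(), cols.ravel())),
            shape=(n_dof, n_dof),
        ).tocsr()
        reaction = float(np.sum(fmag) * (n @ self.probe.displacement_axis))
        return fc, Kc, reaction, nodes, fmag


# -------------------------------------------------------------- results


@dataclass
class SimulationResult:
    """Per-increment output of an indentation run.

    ``curve`` holds one sample per converged increment plus the zero
    state; field arrays are indexed the same way (index 0 = undeformed).
    """

    curve: IndentationCurve
    mesh: TetMesh
    material: Material
    probe: ProbeSpec
    contact_mode: str
    nodal_displacements: np.ndarray  # (n_rec, n_nodes, 3)
    element_J: np.ndarray  # (n_rec, n_elements)
    contact_forces: np.ndarray  # (n_rec, n_nodes, 3), probe force on tissue
    converged_increments: int
    failed: bool = False
    runtime_s: float = 0.0

    @property
    def n_recorded(self) -> int:
        return self.nodal_displacements.shape[0]


# --------------------------------------------------------------- newton


def _newton_increment(
    model: FEModel,
    mat: Material,
    u: np.ndarray,
    free: np.ndarray,
    contact: "_PenaltyContact | None",
    advance: float,
    tol: float,
    max_iter: int,
):
    """Equilibrate at a fixed probe advance / boundary state.  Mutates and
    returns ``u``; raises SolverError on non-convergence or inversion.

    A backtracking line search enforces monotone residual decrease; this
    is what keeps the semi-smooth contact iteration from 2-cycling when
    nodes flip in and out of the active set.
    """
    coords0 = model.mesh.nodes

    def residual(u_vec: np.ndarray, with_tangent: bool):
        fint, K, _ = model.assemble(u_vec, mat, tangent=with_tangent)
        r = fint
        Kc = None
        if contact is not None:
            coords = coords0 + u_vec.reshape(-1, 3)
            fc, Kc, _, _, _ = contact.force_and_stiffness(coords, advance, model.n_dof)
            r = r - fc
        if with_tangent and Kc is not None:
            K = K + Kc
        return r, K

    try:
        r, _ = residual(u, with_tangent=False)
    except InvalidDeformationError as exc:
        raise SolverError(str(exc)) from exc
    rn = float(np.linalg.norm(r[free]))
    ref = max(rn, 1e-12)
    cap = 0.5 * model.h_char

    for _ in range(max_iter):
        if rn <= tol * ref + 1e-12:
            return u
        try:
            _, K = residual(u, with_tangent=True)
        except InvalidDeformationError as exc:  # pragma: no cover - guarded below
            raise SolverError(str(exc)) from exc
        Kff = K[free][:, free].tocsc()
        du = spla.splu(Kff, permc_spec="MMD_ATA").solve(-r[free])
        if not np.all(np.isfinite(du)):
            raise SolverError("singular tangent system")
        du_max = float(np.max(np.abs(du)))
        if du_max > cap:
            # avoid overshooting into element inversion on active-set jumps
            du *= cap / du_max
        alpha = 1.0
        accepted = False
        for _ls in range(6):
            u_try = u.copy()
            u_try[free] += alpha * du
            try:
                r_try, _ = residual(u_try, with_tangent=False)
            except InvalidDeformationError:
                alpha *= 0.5
                continue
            rn_try = float(np.linalg.norm(r_try[free]))
            if rn_try < (1.0 - 1e-4 * alpha) * rn or rn_try <= tol * ref:
                u[:] = u_try
                r, rn = r_try, rn_try
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            raise SolverError("line search failed to reduce the residual")
    if rn <= tol * ref + 1e-12:
        return u
    raise SolverError(f"Newton did not converge in {max_iter} iterations")


def _advance_with_cutting(step_fn, t_from: float, t_to: float, min_frac: float):
    """Advance the load parameter from t_from to t_to, recursively halving
    the substep (down to ``min_frac`` of the span) on solver failure."""
    span = t_to - t_from
    t = t_from
    dt = span
    while t < t_to - 1e-14:
        try:
            step_fn(min(t + dt, t_to))
            t = min(t + dt, t_to)
            dt = min(2.0 * dt, t_to - t) if t < t_to else dt
        except SolverError:
            dt *= 0.5
            if dt < min_frac * span - 1e-14:
                raise


# ------------------------------------------------------- public solvers


def solve_prescribed(
    mesh: TetMesh,
    mat: Material,
    dirichlet: dict,
    n_increments: int = 1,
    *,
    newton_tol: float = 1e-6,
    max_newton_iter: int = 25,
    min_substep_frac: float = 1.0 / 64.0,
):
    """Solve with arbitrary prescribed displacement components.

    ``dirichlet`` maps ``(node, component)`` to the final prescribed value;
    values are ramped linearly over the increments.  Returns
    ``(u, fint, element_J)`` at the final state.
    """
    model = FEModel(mesh)
    items = sorted(dirichlet.items())
    bc_dofs = np.array([3 * n + c for (n, c), _ in items], dtype=np.int64)
    bc_vals = np.array([v for _, v in items], dtype=float)
    free = np.ones(model.n_dof, dtype=bool)
    free[bc_dofs] = False
    u = np.zeros(model.n_dof)

    def step(t: float) -> None:
        u_try = u.copy()
        u_try[bc_dofs] = t * bc_vals
        _newton_increment(model, mat, u_try, free, None, 0.0, newton_tol, max_newton_iter)
        u[:] = u_try

    for i in range(1, n_increments + 1):
        _advance_with_cutting(step, (i - 1) / n_increments, i / n_increments, min_substep_frac)
    fint, _, Jel = model.assemble(u, mat, tangent=False)
    return u, fint, Jel


def solve_indentation(
    mesh: TetMesh,
    mat: Material,
    probe: ProbeSpec,
    contact_mode: str = "penalty",
    *,
    newton_tol: float = 1e-6,
    max_newton_iter: int = 25,
    min_substep_frac: float = 1.0 / 64.0,
    penalty_scale: float = 100.0,
    patch_gap_tol: float | None = None,
) -> SimulationResult:
    """Displacement-driven indentation of the flesh mesh by the rigid probe.

    The bone node set is fully fixed; the probe face advances in
    ``probe.n_increments`` equal steps of ``total_displacement``.  On
    Newton failure the increment is halved down to ``min_substep_frac``
    of an increment; if that also fails a partial result is returned with
    ``failed=True`` and ``converged_increments`` recording progress.
    """
    if contact_mode not in ("penalty", "prescribed_patch"):
        raise ValueError(f"unknown contact mode {contact_mode!r}")
    t0 = time.perf_counter()
    model = FEModel(mesh)
    bone = mesh.node_sets.get("bone_fixed")
    if bone is None or bone.size == 0:
        raise MeshError("mesh has no 'bone_fixed' node set")
    skin = mesh.node_sets.get("skin_surface")
    if skin is None or skin.size == 0:
        raise MeshError("mesh has no 'skin_surface' node set")

    free = np.ones(model.n_dof, dtype=bool)
    for i in range(3):
        free[3 * bone + i] = False

    k_pen = penalty_scale * mat.c1 * model.h_char
    contact = _PenaltyContact(probe, skin, k_pen, eps=0.02 * model.h_char)
    pen0, inside0 = contact.gaps(mesh.nodes, 0.0)
    tol_touch = 1e-8 * max(1.0, model.h_char)
    if np.any(inside0 & (pen0 > tol_touch + 1e-9 * model.h_char)):
        worst = float(np.max(pen0[inside0]))
        raise ContactError(
            f"probe face starts {worst:.3g} mm inside the skin; it must begin "
            "outside or touching the surface"
        )

    patch_nodes = np.empty(0, dtype=np.int64)
    if contact_mode == "prescribed_patch":
        gap_tol = 0.25 * model.h_char if patch_gap_tol is None else patch_gap_tol
        sel = inside0 & (pen0 >= -gap_tol)
        patch_nodes = contact.candidates[sel]
        if patch_nodes.size == 0:
            raise ContactError(
                "no skin nodes within the probe footprint at first contact; "
                "check probe placement or increase patch_gap_tol"
            )
        for i in range(3):
            free[3 * patch_nodes + i] = False
        contact = None  # type: ignore[assignment]

    n_inc = probe.n_increments
    total = probe.total_displacement
    axis = probe.displacement_axis

    u = np.zeros(model.n_dof)
    disp_hist = [0.0]
    force_hist = [0.0]
    u_hist = [u.reshape(-1, 3).copy()]
    J_hist = [np.ones(model.mesh.n_elements)]
    fc_hist = [np.zeros((mesh.n_nodes, 3))]
    converged = 0
    failed = False

    def step(t: float) -> None:
        advance = t * total
        u_try = u.copy()
        if contact is None:
            for i in range(3):
                u_try[3 * patch_nodes + i] = advance * axis[i]
        _newton_increment(
            model, mat, u_try, free, contact, advance, newton_tol, max_newton_iter
        )
        u[:] = u_try

    for i in range(1, n_inc + 1):
        try:
            _advance_with_cutting(step, (i - 1) / n_inc, i / n_inc, min_substep_frac)
        except SolverError:
            failed = True
            break
        advance = (i / n_inc) * total
        fint, _, Jel = model.assemble(u, mat, tangent=False)
        fc_nodal = np.zeros((mesh.n_nodes, 3))
        if contact is not None:
            coords = mesh.nodes + u.reshape(-1, 3)
            fc, _, reaction, nodes, fmag = contact.force_and_stiffness(
                coords, advance, model.n_dof
            )
            fc_nodal = fc.reshape(-1, 3)
            force = reaction
        else:
            # reaction transmitted through the prescribed patch
            f_patch = fint.reshape(-1, 3)[patch_nodes]
            fc_nodal[patch_nodes] = f_patch
            force = float(f_patch.sum(axis=0) @ axis)
        converged = i
        disp_hist.append(advance)
        force_hist.append(force)
        u_hist.append(u.reshape(-1, 3).copy())
        J_hist.append(Jel.copy())
        fc_hist.append(fc_nodal)

    curve = IndentationCurve(
        np.asarray(disp_hist), np.asarray(force_hist), meta="simulated"
    )
    return SimulationResult(
        curve=curve,
        mesh=mesh,
        material=mat,
        probe=probe,
        contact_mode=contact_mode,
        nodal_displacements=np.asarray(u_hist),
        element_J=np.asarray(J_hist),
        contact_forces=np.asarray(fc_hist),
        converged_increments=converged,
        failed=failed,
        runtime_s=time.perf_counter() - t0,
    )


# ------------------------------------------------------ post-processing


def max_volume_change(result: SimulationResult) -> float:
    """Largest relative element volume change over all elements and
    increments, percent: ``max |J - 1| * 100``."""
    if result.converged_increments < 1:
        raise SolverError("no converged increments to evaluate")
    return float(np.max(np.abs(result.element_J - 1.0)) * 100.0)


def _nodal_average(model: FEModel, qp_values: np.ndarray) -> np.ndarray:
    """Quadrature-weighted scatter of per-qp scalars to nodes."""
    ne, nn = model.conn.shape
    num = np.zeros(model.mesh.n_nodes)
    den = np.zeros(model.mesh.n_nodes)
    wq = model.w  # (ne, nqp)
    contrib = (wq * qp_values).sum(axis=1) / nn  # equal share per element node
    wsum = wq.sum(axis=1) / nn
    for a in range(nn):
        np.add.at(num, model.conn[:, a], contrib)
        np.add.at(den, model.conn[:, a], wsum)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def surface_fields(result: SimulationResult, increment: int):
    """Von Mises (effective) stress and contact pressure maps on the skin.

    Returns two arrays of length ``n_nodes``: the nodally averaged von
    Mises stress restricted to ``skin_surface`` nodes and the contact
    pressure (normal traction magnitude over nodal tributary area), both
    zero away from the skin surface / active contact set.  ``increment``
    indexes recorded states (0 = undeformed).
    """
    if increment < 0 or increment >= result.n_recorded:
        raise IndexError(
            f"increment {increment} not recorded (0..{result.n_recorded - 1})"
        )
    mesh = result.mesh
    model = FEModel(mesh)
    u = result.nodal_displacements[increment].ravel()
    skin = mesh.node_sets["skin_surface"]
    skin_mask = np.zeros(mesh.n_nodes, dtype=bool)
    skin_mask[skin] = True

    vm_map = np.zeros(mesh.n_nodes)
    if np.any(u):
        s = model.quadrature_stresses(u, result.material)
        dev = s - np.trace(s, axis1=2, axis2=3)[..., None, None] / 3.0 * _EYE
        vm_qp = np.sqrt(1.5 * np.einsum("eqij,eqij->eq", dev, dev))
        vm_map = _nodal_average(model, vm_qp)
    vm_map[~skin_mask] = 0.0

    # nodal tributary areas on the (deformed) skin surface
    tris = mesh.surface_triangles("skin_surface")
    area = np.zeros(mesh.n_nodes)
    if tris.size:
        coords = mesh.nodes + result.nodal_displacements[increment]
        p = coords[tris[:, :3]]
        tri_area = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        share = tri_area / tris.shape[1]
        for a in range(tris.shape[1]):
            np.add.at(area, tris[:, a], share)
    fc = result.contact_forces[increment]
    fmag = np.linalg.norm(fc, axis=1)
    pressure = np.divide(fmag, area, out=np.zeros_like(fmag), where=area > 0)
    pressure[~skin_mask] = 0.0
    return vm_map, pressure
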