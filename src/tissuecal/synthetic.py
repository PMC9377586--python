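"""Phantom geometry and synthetic indentation experiments.

Real limb anatomy (CT-segmented flesh around bone) is replaced for
development and testing by an annular-cylinder phantom: a tube of flesh of
given outer radius around a rigid cylindrical bone, meshed with structured
tetrahedra.  Default dimensions put the soft-tissue thickness at about
21 mm — the scale of an adult upper leg at the indentation site — so probe
displacements of 10-30% of tissue thickness are exercisable.

Synthetic "experimental" curves come either from the finite-element model
itself or from a fast closed-form surrogate that is exactly linear in C1
(mirroring the displacement-driven FE property).  The generator emulates
two features of freehand probe records: a nonzero preload force at the
first retained sample (the probe is already pressed into the skin when
recording starts; 0.14 N by default) and additive Gaussian force noise.
Displacement is treated as exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import IndentationCurve
from .errors import MeshError
from .mesh import TET10_EDGES, TetMesh

__all__ = [
    "PhantomSpec",
    "make_limb_phantom",
    "make_box_mesh",
    "surrogate_forward",
    "synth_experiment",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Annular-cylinder limb phantom: flesh between ``bone_radius`` and
    ``outer_radius`` over axial ``length`` (mm)."""

    outer_radius: float = 33.0
    bone_radius: float = 12.0
    length: float = 60.0
    target_edge_length: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.bone_radius < self.outer_radius):
            raise ValueError("need 0 < bone_radius < outer_radius")
        if self.length <= 0 or self.target_edge_length <= 0:
            raise ValueError("length and target_edge_length must be positive")

    @property
    def thickness(self) -> float:
        return self.outer_radius - self.bone_radius


# Freudenthal 6-tet decomposition of a hexahedron along the 0-6 diagonal;
# translation-invariant, hence conforming across the structured grid.
_HEX_TETS = (
    (0, 1, 2, 6),
    (0, 2, 3, 6),
    (0, 3, 7, 6),
    (0, 7, 4, 6),
    (0, 4, 5, 6),
    (0, 5, 1, 6),
)


def _orient(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    x = nodes[tets]
    vols = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = vols < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


def _elevate_to_tet10(nodes: np.ndarray, tets: np.ndarray):
    """Insert straight mid-edge nodes (sub-parametric quadratic mesh)."""
    edge_mid: dict = {}
    coords = [nodes]
    next_id = nodes.shape[0]
    elements = np.empty((tets.shape[0], 10), dtype=np.int64)
    elements[:, :4] = tets
    new_pts = []
    for m, (a, b) in enumerate(TET10_EDGES, start=4):
        na, nb = tets[:, a], tets[:, b]
        for e in range(tets.shape[0]):
            key = (min(na[e], nb[e]), max(na[e], nb[e]))
            mid = edge_mid.get(key)
            if mid is None:
                mid = next_id
                edge_mid[key] = mid
                new_pts.append(0.5 * (nodes[key[0]] + nodes[key[1]]))
                next_id += 1
            elements[e, m] = mid
    all_nodes = np.vstack([nodes, np.asarray(new_pts)]) if new_pts else nodes
    return all_nodes, elements, edge_mid


def _propagate_sets(sets: dict, edge_mid: dict) -> dict:
    """Mid-edge nodes join a set when both parent endpoints belong."""
    out = {}
    for name, idx in sets.items():
        members = set(int(i) for i in idx)
        extra = [mid for (a, b), mid in edge_mid.items() if a in members and b in members]
        out[name] = np.asarray(sorted(members | set(extra)), dtype=np.int64)
    return out


def make_limb_phantom(
    spec: PhantomSpec, order: int = 2, divisions: tuple | None = None
) -> TetMesh:
    """Structured tetrahedral mesh of the annular flesh phantom.

    Node sets: ``bone_fixed`` on the inner cylindrical surface,
    ``skin_surface`` on the outer.  All element Jacobians are positive;
    the mesh volume approaches ``pi (R^2 - r^2) L`` as the angular
    resolution grows (chord-polygon faceting is the only defect).

    ``divisions`` overrides the edge-length heuristic with explicit
    ``(n_r, n_theta, n_z)`` counts — useful for refinement families that
    must hold the circumferential (contact-facing) resolution fixed while
    refining radially and axially.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    h = spec.target_edge_length
    if divisions is not None:
        n_r, n_theta, n_z = (int(v) for v in divisions)
        if min(n_r, n_z) < 1 or n_theta < 8:
            raise ValueError("divisions must be (n_r >= 1, n_theta >= 8, n_z >= 1)")
    else:
        n_theta = max(12, int(round(2.0 * np.pi * spec.outer_radius / h)))
        # >= 3 radial layers: the flesh annulus compresses strongly under
        # the probe and needs radial resolution to stay invertible
        n_r = max(3, int(round(spec.thickness / h)))
        n_z = max(2, int(round(spec.length / h)))
    if n_theta * n_r * n_z > 2_000_000:
        raise MeshError("target_edge_length too small for this phantom size")

    radii = np.linspace(spec.bone_radius, spec.outer_radius, n_r + 1)
    thetas = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    zs = np.linspace(0.0, spec.length, n_z + 1)

    def nid(iz: int, ir: int, it: int) -> int:
        return (iz * (n_r + 1) + ir) * n_theta + (it % n_theta)

    nodes = np.empty(((n_z + 1) * (n_r + 1) * n_theta, 3))
    for iz, z in enumerate(zs):
        for ir, r in enumerate(radii):
            base = (iz * (n_r + 1) + ir) * n_theta
            nodes[base : base + n_theta, 0] = r * np.cos(thetas)
            nodes[base : base + n_theta, 1] = r * np.sin(thetas)
            nodes[base : base + n_theta, 2] = z

    tets = []
    for iz in range(n_z):
        for ir in range(n_r):
            for it in range(n_theta):
                # hex corners: x ~ radial, y ~ angular, z ~ axial
                c = [
                    nid(iz, ir, it),
                    nid(iz, ir + 1, it),
                    nid(iz, ir + 1, it + 1),
                    nid(iz, ir, it + 1),
                    nid(iz + 1, ir, it),
                    nid(iz + 1, ir + 1, it),
                    nid(iz + 1, ir + 1, it + 1),
                    nid(iz + 1, ir, it + 1),
                ]
                for tet in _HEX_TETS:
                    tets.append([c[v] for v in tet])
    tets = _orient(nodes, np.asarray(tets, dtype=np.int64))

    inner = [nid(iz, 0, it) for iz in range(n_z + 1) for it in range(n_theta)]
    outer = [nid(iz, n_r, it) for iz in range(n_z + 1) for it in range(n_theta)]
    sets = {
        "bone_fixed": np.asarray(inner, dtype=np.int64),
        "skin_surface": np.asarray(outer, dtype=np.int64),
    }
    if order == 2:
        nodes, elements, edge_mid = _elevate_to_tet10(nodes, tets)
        sets = _propagate_sets(sets, edge_mid)
    else:
        elements = tets
    mesh = TetMesh(nodes=nodes, elements=elements, node_sets=sets)
    mesh.validate()
    return mesh


def make_box_mesh(
    lengths=(1.0, 1.0, 1.0), divisions=(2, 2, 2), order: int = 2
) -> TetMesh:
    """Structured tet mesh of a box with per-face node sets (``xmin`` ...
    ``zmax``); ``bone_fixed`` aliases ``zmin`` and ``skin_surface``
    aliases ``zmax`` so the box drops into the indentation pipeline."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    lx, ly, lz = (float(v) for v in lengths)
    nx, ny, nz = (int(v) for v in divisions)
    if min(nx, ny, nz) < 1:
        raise ValueError("divisions must be >= 1")
    xs, ys, zs = (np.linspace(0, L, n + 1) for L, n in ((lx, nx), (ly, ny), (lz, nz)))

    def nid(i: int, j: int, k: int) -> int:
        return (k * (ny + 1) + j) * (nx + 1) + i

    nodes = np.array(
        [[x, y, z] for z in zs for y in ys for x in xs], dtype=float
    )
    tets = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                c = [
                    nid(i, j, k),
                    nid(i + 1, j, k),
                    nid(i + 1, j + 1, k),
                    nid(i, j + 1, k),
                    nid(i, j, k + 1),
                    nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1),
                    nid(i, j + 1, k + 1),
                ]
                for tet in _HEX_TETS:
                    tets.append([c[v] for v in tet])
    tets = _orient(nodes, np.asarray(tets, dtype=np.int64))

    tol = 1e-12 * max(lx, ly, lz, 1.0)
    sets = {
        "xmin": np.nonzero(nodes[:, 0] < tol)[0],
        "xmax": np.nonzero(nodes[:, 0] > lx - tol)[0],
        "ymin": np.nonzero(nodes[:, 1] < tol)[0],
        "ymax": np.nonzero(nodes[:, 1] > ly - tol)[0],
        "zmin": np.nonzero(nodes[:, 2] < tol)[0],
        "zmax": np.nonzero(nodes[:, 2] > lz - tol)[0],
    }
    if order == 2:
        nodes, elements, edge_mid = _elevate_to_tet10(nodes, tets)
        sets = _propagate_sets(sets, edge_mid)
    else:
        elements = tets
    sets["bone_fixed"] = sets["zmin"]
    sets["skin_surface"] = sets["zmax"]
    mesh = TetMesh(nodes=nodes, elements=elements, node_sets=sets)
    mesh.validate()
    return mesh


# --------------------------------------------------------- experiments


def surrogate_forward(
    c1: float,
    stiffening: float = 0.05,
    d_max: float = 6.0,
    n: int = 100,
    geometry_scale: float = 300.0,
) -> IndentationCurve:
    """Closed-form stand-in for the FE forward model.

    ``F(d) = c1 * a * (d + b d^2)`` with ``a = geometry_scale`` (mm,
    lumping probe footprint and tissue geometry) and ``b = stiffening``
    (1/mm, the mild progressive stiffening of indentation curves).  The
    response is exactly linear in C1 by construction.  Defaults give
    peak forces of roughly 10 N at 6 mm for C1 = 0.005 MPa — the scale of
    the freehand indentation records the package targets.
    """
    if c1 <= 0 or d_max <= 0 or n < 2 or geometry_scale <= 0:
        raise ValueError("surrogate_forward requires positive inputs")
    if stiffening < 0:
        raise ValueError("stiffening must be non-negative")
    d = np.linspace(0.0, d_max, n)
    f = c1 * geometry_scale * (d + stiffening * d**2)
    return IndentationCurve(d, f, meta="simulated")


def synth_experiment(
    true_c1: float,
    forward=None,
    preload_force: float = 0.14,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Generate a synthetic freehand-indentation record with known truth.

    Runs ``forward(true_c1)`` (default: :func:`surrogate_forward` with its
    defaults), drops the pre-contact portion below ``preload_force``,
    re-zeroes displacement, and adds i.i.d. Gaussian force noise.
    Deterministic for a fixed ``seed``.  Returns ``(curve, truth)`` where
    ``truth`` records the generating parameters.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if forward is None:
        forward = surrogate_forward
    base = forward(true_c1)
    if preload_force > base.peak_force:
        raise ValueError(
            f"preload {preload_force:g} N exceeds the peak forward force "
            f"{base.peak_force:g} N"
        )
    keep = base.force >= preload_force
    first = int(np.argmax(keep))
    d = base.displacement[first:] - base.displacement[first]
    f = base.force[first:].copy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    curve = IndentationCurve(d, f, meta="experimental")
    truth = {
        "true_c1": float(true_c1),
        "preload_force": float(preload_force),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
    }
    return curve, truth
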