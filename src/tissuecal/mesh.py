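"""Tetrahedral volume meshes and plain-text mesh I/O.

The in-memory container is :class:`TetMesh`: linear (4-node) or quadratic
(10-node) tetrahedra with named node sets, at minimum ``bone_fixed`` (nodes
clamped to the rigid bone) and ``skin_surface`` (outer surface candidates
for probe contact).  Quadratic connectivity uses the VTK edge ordering
(4:(0,1), 5:(1,2), 6:(2,0), 7:(0,3), 8:(1,3), 9:(2,3)).

Two interchange formats are supported, both ASCII:

* Gmsh MSH — v2.2 read/write, v4.1 read.  Node sets are carried as
  physical point groups (element type 15) and/or physical surface
  triangles whose nodes join the set of that physical name.
* Legacy VTK unstructured grid — read/write.  Node sets travel as 0/1
  integer point-data masks named ``set_<name>``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MeshError

__all__ = ["TetMesh", "read_mesh", "write_mesh"]

# local mid-edge node index for each corner pair (VTK tet10 convention)
TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))
# faces of a tetrahedron: corner triple + mid-edge triple (order 2)
TET_FACES = (
    ((0, 1, 2), (4, 5, 6)),
    ((0, 1, 3), (4, 8, 7)),
    ((1, 2, 3), (5, 9, 8)),
    ((0, 2, 3), (6, 9, 7)),
)
# VTK <-> Gmsh tet10 permutation (an involution: swaps mid nodes 8 and 9)
_VTK_TO_GMSH_TET10 = (0, 1, 2, 3, 4, 5, 6, 7, 9, 8)


@dataclass
class TetMesh:
    """Tetrahedral flesh volume with named node sets.

    ``nodes`` is ``(n_nodes, 3)`` in mm; ``elements`` is ``(n_elements, 4)``
    or ``(n_elements, 10)``; ``node_sets`` maps names to sorted index
    arrays.
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise MeshError("elements must be (n, 4) or (n, 10)")
        self.node_sets = {
            name: np.unique(np.asarray(idx, dtype=np.int64))
            for name, idx in self.node_sets.items()
        }

    # ------------------------------------------------------------- topology
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def element_order(self) -> int:
        return 1 if self.elements.shape[1] == 4 else 2

    @property
    def corners(self) -> np.ndarray:
        """Corner (vertex) connectivity, (n_elements, 4)."""
        return self.elements[:, :4]

    def signed_corner_volumes(self) -> np.ndarray:
        x = self.nodes[self.corners]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def volume(self) -> float:
        return float(np.sum(self.signed_corner_volumes()))

    def characteristic_length(self) -> float:
        """Edge-length scale of a regular tetrahedron with the mean element
        volume (used, e.g., to scale the contact penalty)."""
        vbar = self.volume() / self.n_elements
        return float((6.0 * np.sqrt(2.0) * vbar) ** (1.0 / 3.0))

    def validate(self) -> None:
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=0) >= self.n_nodes:
            raise MeshError("element connectivity references invalid node indices")
        vols = self.signed_corner_volumes()
        if np.any(vols <= 0):
            raise MeshError(
                f"{int(np.sum(vols <= 0))} elements have non-positive reference volume"
            )
        for name, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise MeshError(f"node set {name!r} references invalid node indices")
        bone = self.node_sets.get("bone_fixed")
        skin = self.node_sets.get("skin_surface")
        if bone is not None and skin is not None and np.intersect1d(bone, skin).size:
            raise MeshError("bone_fixed and skin_surface node sets overlap")

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one element.

        Returns ``(n_faces, 3)`` corner triples for linear meshes or
        ``(n_faces, 6)`` corner+mid-edge index rows for quadratic ones.
        """
        n_face_nodes = 3 if self.element_order == 1 else 6
        seen: dict = {}
        for elem in self.elements:
            for corners, mids in TET_FACES:
                tri = tuple(int(elem[c]) for c in corners)
                key = tuple(sorted(tri))
                if self.element_order == 2:
                    row = tri + tuple(int(elem[m]) for m in mids)
                else:
                    row = tri
                if key in seen:
                    seen[key] = None
                else:
                    seen[key] = row
        rows = [r for r in seen.values() if r is not None]
        if not rows:
            return np.empty((0, n_face_nodes), dtype=np.int64)
        return np.asarray(rows, dtype=np.int64)

    def surface_triangles(self, set_name: str) -> np.ndarray:
        """Boundary faces whose nodes all belong to the named node set."""
        faces = self.boundary_faces()
        members = np.zeros(self.n_nodes, dtype=bool)
        members[self.node_sets[set_name]] = True
        keep = members[faces].all(axis=1)
        return faces[keep]


# ---------------------------------------------------------------- Gmsh MSH


def _write_msh2(mesh: TetMesh, path: Path) -> None:
    buf = io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    set_names = sorted(mesh.node_sets)
    buf.write("$PhysicalNames\n")
    buf.write(f"{len(set_names) + 1}\n")
    buf.write('3 1 "flesh"\n')
    for i, name in enumerate(set_names):
        buf.write(f'0 {i + 2} "{name}"\n')
    buf.write("$EndPhysicalNames\n")
    buf.write("$Nodes\n")
    buf.write(f"{mesh.n_nodes}\n")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        buf.write(f"{i} {x:.16g} {y:.16g} {z:.16g}\n")
    buf.write("$EndNodes\n")
    n_points = sum(len(mesh.node_sets[n]) for n in set_names)
    buf.write("$Elements\n")
    buf.write(f"{mesh.n_elements + n_points}\n")
    eid = 1
    etype = 4 if mesh.element_order == 1 else 11
    for elem in mesh.elements:
        conn = elem if mesh.element_order == 1 else elem[list(_VTK_TO_GMSH_TET10)]
        nodes = " ".join(str(int(n) + 1) for n in conn)
        buf.write(f"{eid} {etype} 2 1 1 {nodes}\n")
        eid += 1
    for i, name in enumerate(set_names):
        for node in mesh.node_sets[name]:
            buf.write(f"{eid} 15 2 {i + 2} {i + 2} {int(node) + 1}\n")
            eid += 1
    buf.write("$EndElements\n")
    path.write_text(buf.getvalue())


def _read_sections(text: str) -> dict:
    sections: dict = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                body.append(lines[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1
    return sections


def _read_msh(path: Path) -> TetMesh:
    text = path.read_text()
    sections = _read_sections(text)
    if "MeshFormat" not in sections or "Nodes" not in sections:
        raise MeshError(f"{path}: not a Gmsh MSH file")
    version = float(sections["MeshFormat"][0].split()[0])
    phys_names: dict = {}
    if "PhysicalNames" in sections:
        for line in sections["PhysicalNames"][1:]:
            parts = line.split(maxsplit=2)
            if len(parts) == 3:
                phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')
    if version >= 4.0:
        return _read_msh4(sections, phys_names)
    return _read_msh2(sections, phys_names)


def _finish_mesh(coords, tets, set_nodes) -> TetMesh:
    if not tets:
        raise MeshError("no tetrahedral elements found")
    widths = {len(t) for t in tets}
    if len(widths) != 1:
        raise MeshError("mixed linear/quadratic tetrahedra are not supported")
    elements = np.asarray(tets, dtype=np.int64)
    if elements.shape[1] == 10:
        elements = elements[:, list(_VTK_TO_GMSH_TET10)]  # gmsh -> vtk ordering
    node_sets = {name: np.asarray(sorted(idx), dtype=np.int64) for name, idx in set_nodes.items()}
    return TetMesh(nodes=np.asarray(coords, dtype=float), elements=elements, node_sets=node_sets)


def _read_msh2(sections: dict, phys_names: dict) -> TetMesh:
    node_lines = sections["Nodes"]
    n_nodes = int(node_lines[0])
    tag_to_idx: dict = {}
    coords = np.empty((n_nodes, 3))
    for i, line in enumerate(node_lines[1 : n_nodes + 1]):
        parts = line.split()
        tag_to_idx[int(parts[0])] = i
        coords[i] = [float(v) for v in parts[1:4]]
    tets = []
    set_nodes: dict = {}
    for line in sections.get("Elements", ["0"])[1:]:
        parts = [int(v) for v in line.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3] if ntags >= 1 else -1
        conn = [tag_to_idx[t] for t in parts[3 + ntags :]]
        if etype in (4, 11):
            tets.append(conn)
        elif etype in (15, 1, 2, 9, 8):  # points, lines, triangles -> node sets
            name = phys_names.get((0, phys)) or phys_names.get((2, phys)) or phys_names.get((1, phys))
            if name is not None:
                set_nodes.setdefault(name, set()).update(conn)
    return _finish_mesh(coords, tets, set_nodes)


def _read_msh4(sections: dict, phys_names: dict) -> TetMesh:
    # map (dim, entity tag) -> physical name via $Entities
    entity_phys: dict = {}
    if "Entities" in sections:
        tokens = " ".join(sections["Entities"]).split()
        pos = 0
        counts = [int(tokens[pos + d]) for d in range(4)]
        pos += 4
        for dim, count in enumerate(counts):
            for _ in range(count):
                tag = int(tokens[pos])
                pos += 1 + (3 if dim == 0 else 6)  # coords / bbox
                n_phys = int(tokens[pos])
                pos += 1
                phys = [int(tokens[pos + i]) for i in range(n_phys)]
                pos += n_phys
                if dim > 0:
                    n_bound = int(tokens[pos])
                    pos += 1 + n_bound
                for p in phys:
                    if (dim, abs(p)) in phys_names:
                        entity_phys[(dim, tag)] = phys_names[(dim, abs(p))]
    node_tokens = " ".join(sections["Nodes"]).split()
    pos = 0
    n_blocks, n_nodes = int(node_tokens[0]), int(node_tokens[1])
    pos = 4
    tag_to_idx: dict = {}
    coords = np.empty((n_nodes, 3))
    idx = 0
    for _ in range(n_blocks):
        n_in_block = int(node_tokens[pos + 3])
        pos += 4
        tags = [int(node_tokens[pos + i]) for i in range(n_in_block)]
        pos += n_in_block
        for tag in tags:
            tag_to_idx[tag] = idx
            coords[idx] = [float(node_tokens[pos + i]) for i in range(3)]
            pos += 3
            idx += 1
    elem_tokens = " ".join(sections["Elements"]).split()
    pos = 4
    n_blocks = int(elem_tokens[0])
    n_per_type = {15: 1, 1: 2, 2: 3, 8: 3, 9: 6, 4: 4, 11: 10}
    tets = []
    set_nodes: dict = {}
    for _ in range(n_blocks):
        dim, tag, etype, n_in_block = (int(elem_tokens[pos + i]) for i in range(4))
        pos += 4
        if etype not in n_per_type:
            raise MeshError(f"unsupported MSH element type {etype}")
        width = n_per_type[etype]
        for _ in range(n_in_block):
            conn = [tag_to_idx[int(t)] for t in elem_tokens[pos + 1 : pos + 1 + width]]
            pos += 1 + width
            if etype in (4, 11):
                tets.append(conn)
            else:
                name = entity_phys.get((dim, tag))
                if name is not None:
                    set_nodes.setdefault(name, set()).update(conn)
    return _finish_mesh(coords, tets, set_nodes)


# ------------------------------------------------------------- legacy VTK


def write_vtk(
    mesh: TetMesh,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    title: str = "tissuecal mesh",
) -> None:
    """Write a legacy ASCII VTK unstructured grid.

    Node sets are emitted as integer point-data masks named ``set_<name>``;
    extra ``point_data`` (scalars ``(n,)`` or vectors ``(n, 3)``) and
    ``cell_data`` scalars are appended verbatim.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(f"{title}\n")
    buf.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} double\n")
    for x, y, z in mesh.nodes:
        buf.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
    width = mesh.elements.shape[1]
    buf.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (width + 1)}\n")
    for elem in mesh.elements:
        buf.write(f"{width} " + " ".join(str(int(n)) for n in elem) + "\n")
    buf.write(f"CELL_TYPES {mesh.n_elements}\n")
    ctype = 10 if width == 4 else 24
    buf.write("\n".join([str(ctype)] * mesh.n_elements) + "\n")

    buf.write(f"POINT_DATA {mesh.n_nodes}\n")
    for name in sorted(mesh.node_sets):
        mask = np.zeros(mesh.n_nodes, dtype=int)
        mask[mesh.node_sets[name]] = 1
        buf.write(f"SCALARS set_{name} int 1\nLOOKUP_TABLE default\n")
        buf.write("\n".join(str(v) for v in mask) + "\n")
    for name, values in (point_data or {}).items():
        values = np.asarray(values)
        if values.ndim == 2 and values.shape[1] == 3:
            buf.write(f"VECTORS {name} double\n")
            for row in values:
                buf.write(f"{row[0]:.12g} {row[1]:.12g} {row[2]:.12g}\n")
        else:
            buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            buf.write("\n".join(f"{v:.12g}" for v in values) + "\n")
    if cell_data:
        buf.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, values in cell_data.items():
            buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            buf.write("\n".join(f"{v:.12g}" for v in np.asarray(values)) + "\n")
    path.write_text(buf.getvalue())


def _read_vtk(path: Path) -> TetMesh:
    tokens = path.read_text().split("\n")
    # tokenize, skipping the two header lines and comments
    flat: list[str] = []
    for line in tokens[2:]:
        flat.extend(line.split())
    pos = 0

    def expect(keyword: str) -> None:
        nonlocal pos
        while pos < len(flat) and flat[pos].upper() != keyword:
            pos += 1
        if pos >= len(flat):
            raise MeshError(f"{path}: VTK keyword {keyword} not found")
        pos += 1

    expect("POINTS")
    n_nodes = int(flat[pos]); pos += 2  # count, dtype
    coords = np.array(flat[pos : pos + 3 * n_nodes], dtype=float).reshape(n_nodes, 3)
    pos += 3 * n_nodes
    expect("CELLS")
    n_cells = int(flat[pos]); total = int(flat[pos + 1]); pos += 2
    cell_tokens = np.array(flat[pos : pos + total], dtype=np.int64)
    pos += total
    expect("CELL_TYPES")
    n_types = int(flat[pos]); pos += 1
    types = np.array(flat[pos : pos + n_types], dtype=int)
    pos += n_types
    width = {10: 4, 24: 10}.get(int(types[0])) if n_types else None
    if width is None or not np.all(types == types[0]):
        raise MeshError(f"{path}: only homogeneous tet4/tet10 grids are supported")
    cells = cell_tokens.reshape(n_cells, width + 1)
    if not np.all(cells[:, 0] == width):
        raise MeshError(f"{path}: inconsistent cell widths")
    elements = cells[:, 1:]
    node_sets: dict = {}
    # optional point-data masks
    while pos < len(flat):
        if flat[pos].upper() == "SCALARS" and flat[pos + 1].startswith("set_"):
            name = flat[pos + 1][4:]
            pos += 3  # SCALARS name type
            if pos < len(flat) and flat[pos].isdigit():
                pos += 1  # optional numComp
            if pos < len(flat) and flat[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            mask = np.array(flat[pos : pos + n_nodes], dtype=float)
            pos += n_nodes
            node_sets[name] = np.nonzero(mask > 0.5)[0]
        else:
            pos += 1
    return TetMesh(nodes=coords, elements=elements, node_sets=node_sets)


# ------------------------------------------------------------- dispatchers


def read_mesh(path) -> TetMesh:
    """Read a tetrahedral mesh from a Gmsh ``.msh`` (v2.2 or v4.1 ASCII) or
    legacy ``.vtk`` file, inferring the format from the suffix (falling back
    to content sniffing)."""
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".msh":
        return _read_msh(path)
    if suffix == ".vtk":
        return _read_vtk(path)
    head = path.read_text(errors="ignore")[:200]
    if head.startswith("$MeshFormat"):
        return _read_msh(path)
    if head.startswith("# vtk"):
        return _read_vtk(path)
    raise MeshError(f"cannot determine mesh format of {path}")


def write_mesh(mesh: TetMesh, path) -> None:
    """Write ``mesh`` as Gmsh MSH v2.2 (``.msh``) or legacy VTK (``.vtk``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".msh":
        _write_msh2(mesh, path)
    elif suffix == ".vtk":
        write_vtk(mesh, path)
    else:
        raise MeshError(f"unsupported mesh format: {path}")
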