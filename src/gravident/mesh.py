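"""Tetrahedral meshes, displacement fields and per-element large-deformation kinematics.

All quantities are SI internally (metres, pascals, kg m^-3).  File readers
convert 1-based node indices to the 0-based internal convention and apply
unit conversion at the boundary (CSV displacement files default to mm,
meshes default to metres).
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TetMesh",
    "DisplacementField",
    "ElementKinematics",
    "InvertedElementError",
    "read_mesh",
    "read_displacement_field",
    "write_vtk",
    "write_displacement_csv",
    "element_kinematics",
]

#: faces of a tet4 element, in local vertex indices
_TET_FACES = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))


class InvertedElementError(ValueError):
    """An element has non-positive volume that a single vertex swap cannot fix."""


@dataclass
class TetMesh:
    """A 4-node tetrahedral mesh in the reference configuration.

    Parameters
    ----------
    nodes : (n, 3) float array
        Node coordinates in metres.
    elements : (m, 4) int array
        0-based connectivity.  Orientation is fixed at construction so every
        element has positive reference volume.
    density : float
        Tissue density in kg m^-3.
    """

    nodes: np.ndarray
    elements: np.ndarray
    density: float = 1040.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (m, 4) tet4 connectivity")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("connectivity refers to nonexistent nodes")
        self._fix_orientation()

    # -- construction helpers -------------------------------------------------

    def _fix_orientation(self):
        """Reorder vertices of negatively oriented elements (single swap)."""
        vol6 = self._signed_volumes6()
        bad = np.flatnonzero(vol6 <= 0)
        if bad.size:
            zero = bad[vol6[bad] == 0]
            if zero.size:
                raise InvertedElementError(
                    f"degenerate (zero-volume) elements: {zero[:10].tolist()}"
                )
            # swapping any vertex pair flips the sign; use the last two
            self.elements[bad[:, None], [2, 3]] = self.elements[bad[:, None], [3, 2]]
            if np.any(self._signed_volumes6() <= 0):
                raise InvertedElementError("vertex swap failed to fix orientation")
        self._cache.clear()

    def _signed_volumes6(self) -> np.ndarray:
        x = self.nodes[self.elements]  # (m, 4, 3)
        edges = x[:, 1:] - x[:, :1]  # (m, 3, 3) rows are edge vectors
        return np.linalg.det(edges)

    # -- derived geometry (cached) --------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def volumes(self) -> np.ndarray:
        """(m,) reference element volumes V0, m^3."""
        if "volumes" not in self._cache:
            self._cache["volumes"] = self._signed_volumes6() / 6.0
        return self._cache["volumes"]

    @property
    def shape_gradients(self) -> np.ndarray:
        """(m, 4, 3) reference gradients of the linear shape functions dN_a/dX."""
        if "shape_gradients" not in self._cache:
            x = self.nodes[self.elements]
            edges = x[:, 1:] - x[:, :1]  # row a-1 is X_a - X_0
            dinv = np.linalg.inv(edges)  # (m, 3, 3); columns map to local coords
            g = np.empty((self.n_elements, 4, 3))
            g[:, 1:, :] = np.swapaxes(dinv, 1, 2)
            g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
            self._cache["shape_gradients"] = g
        return self._cache["shape_gradients"]

    @property
    def boundary_faces(self) -> np.ndarray:
        """(k, 3) node triples of faces belonging to exactly one element."""
        if "boundary_faces" not in self._cache:
            faces = self.elements[:, _TET_FACES].reshape(-1, 3)
            key = np.sort(faces, axis=1)
            _, idx, counts = np.unique(
                key, axis=0, return_index=True, return_counts=True
            )
            self._cache["boundary_faces"] = faces[idx[counts == 1]]
        return self._cache["boundary_faces"]

    @property
    def boundary_nodes(self) -> np.ndarray:
        """Sorted array of node indices lying on the mesh boundary."""
        if "boundary_nodes" not in self._cache:
            self._cache["boundary_nodes"] = np.unique(self.boundary_faces)
        return self._cache["boundary_nodes"]

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """(m, 3, 3) deformation gradient F = I + du/dX per element.

        Exact for affine displacement fields (constant-strain elements).
        """
        ue = u[self.elements]  # (m, 4, 3)
        gradu = np.einsum("eai,eaj->eij", ue, self.shape_gradients)
        return gradu + np.eye(3)


@dataclass
class DisplacementField:
    """Per-node displacement vectors in metres, aligned with a mesh's node order."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("values must be (n, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement field contains non-finite components")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max_magnitude(self) -> float:
        """Largest nodal displacement-vector magnitude (m)."""
        if len(self.values) == 0:
            return 0.0
        return float(np.linalg.norm(self.values, axis=1).max())


@dataclass
class ElementKinematics:
    """Kinematic state of one element under a displacement field."""

    F: np.ndarray  # 3x3 deformation gradient
    J: float  # det F
    V0: float  # reference volume, m^3
    ref_shape_gradients: np.ndarray  # (4, 3) dN/dX


def element_kinematics(
    mesh: TetMesh, disp: DisplacementField, element_index: int
) -> ElementKinematics:
    """Deformation gradient, Jacobian and reference volume of one element.

    Raises
    ------
    ValueError
        If det F <= 0 (non-physical state), naming the element.
    """
    F = mesh.deformation_gradients(disp.values)[element_index]
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise ValueError(f"element {element_index}: J = {J:.3e} <= 0")
    return ElementKinematics(
        F=F,
        J=J,
        V0=float(mesh.volumes[element_index]),
        ref_shape_gradients=mesh.shape_gradients[element_index],
    )


# ---------------------------------------------------------------------------
# mesh readers
# ---------------------------------------------------------------------------


def read_mesh(
    path, format_hint: str | None = None, density: float = 1040.0, units: str = "m"
) -> TetMesh:
    """Read a tet4 mesh from Gmsh .msh (v2/v4 ASCII), legacy VTK, or minimal FEBio .feb.

    Node coordinates are scaled to metres according to ``units`` ("m" or "mm").
    Non-tet4 volume cells cause an error; lower-dimensional cells are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or _sniff_format(path)
    if fmt == "msh":
        nodes, elements = _read_gmsh(path)
    elif fmt == "vtk":
        nodes, elements, _ = _read_vtk(path)
    elif fmt == "feb":
        nodes, elements, units = _read_feb(path, units)
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r}")
    nodes = nodes * _unit_scale(units)
    return TetMesh(nodes=nodes, elements=elements, density=density)


def _unit_scale(units: str) -> float:
    try:
        return {"m": 1.0, "mm": 1e-3, "um": 1e-6}[units]
    except KeyError:
        raise ValueError(f"unknown unit {units!r}") from None


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".msh", ".vtk", ".feb"}:
        return suffix[1:]
    head = path.read_bytes()[:256].lstrip()
    if head.startswith(b"$MeshFormat"):
        return "msh"
    if head.startswith(b"# vtk"):
        return "vtk"
    if head.startswith(b"<?xml") or head.startswith(b"<febio"):
        return "feb"
    raise ValueError(f"cannot determine mesh format of {path}")


def _read_gmsh(path: Path):
    text = path.read_text()
    m = re.search(r"\$MeshFormat\s+([\d.]+)\s+(\d+)", text)
    if not m:
        raise ValueError("not a Gmsh .msh file (missing $MeshFormat)")
    if m.group(2) != "0":
        raise ValueError("binary Gmsh files are not supported")
    version = float(m.group(1))
    nodes_block = _gmsh_section(text, "Nodes")
    elems_block = _gmsh_section(text, "Elements")
    if version >= 4.0:
        return _parse_gmsh4(nodes_block, elems_block)
    return _parse_gmsh2(nodes_block, elems_block)


def _gmsh_section(text: str, name: str) -> list[str]:
    m = re.search(rf"\${name}\s*\n(.*?)\$End{name}", text, re.S)
    if not m:
        raise ValueError(f"Gmsh file has no ${name} section")
    return m.group(1).strip().splitlines()


def _parse_gmsh2(nodes_block, elems_block):
    n = int(nodes_block[0])
    ids = np.empty(n, dtype=np.int64)
    coords = np.empty((n, 3))
    for i, line in enumerate(nodes_block[1 : n + 1]):
        parts = line.split()
        ids[i] = int(parts[0])
        coords[i] = [float(v) for v in parts[1:4]]
    remap = {nid: i for i, nid in enumerate(ids)}
    tets = []
    ne = int(elems_block[0])
    for line in elems_block[1 : ne + 1]:
        parts = [int(v) for v in line.split()]
        etype = parts[1]
        if etype == 4:  # tet4
            ntags = parts[2]
            tets.append([remap[v] for v in parts[3 + ntags : 7 + ntags]])
        elif etype in (5, 6, 7, 11, 17):  # other volume cells
            raise ValueError(f"non-tet4 volume element (gmsh type {etype}) present")
    if not tets:
        raise ValueError("no tet4 elements found")
    return coords, np.asarray(tets, dtype=np.int64)


def _parse_gmsh4(nodes_block, elems_block):
    # $Nodes: numEntityBlocks numNodes minTag maxTag, then per-block header
    # (dim, tag, parametric, numNodesInBlock), tag lines, coordinate lines.
    header = nodes_block[0].split()
    n_blocks, n_nodes = int(header[0]), int(header[1])
    ids = []
    coords = []
    pos = 1
    for _ in range(n_blocks):
        bn = int(nodes_block[pos].split()[3])
        pos += 1
        ids.extend(int(nodes_block[pos + i]) for i in range(bn))
        pos += bn
        for i in range(bn):
            coords.append([float(v) for v in nodes_block[pos + i].split()[:3]])
        pos += bn
    if len(ids) != n_nodes:
        raise ValueError("Gmsh v4 $Nodes block is inconsistent")
    remap = {nid: i for i, nid in enumerate(ids)}
    header = elems_block[0].split()
    n_blocks = int(header[0])
    pos = 1
    tets = []
    for _ in range(n_blocks):
        dim, _tag, etype, bn = (int(v) for v in elems_block[pos].split())
        pos += 1
        if etype == 4:
            for i in range(bn):
                parts = [int(v) for v in elems_block[pos + i].split()]
                tets.append([remap[v] for v in parts[1:5]])
        elif dim == 3:
            raise ValueError(f"non-tet4 volume element (gmsh type {etype}) present")
        pos += bn
    if not tets:
        raise ValueError("no tet4 elements found")
    return np.asarray(coords), np.asarray(tets, dtype=np.int64)


def _read_vtk(path: Path):
    """Legacy ASCII VTK unstructured grid; returns nodes, tets, point vectors (or None)."""
    tokens = _VTKTokens(path.read_text())
    if "vtk" not in tokens.header.lower():
        raise ValueError("not a legacy VTK file")
    points = None
    cells = None
    cell_types = None
    vectors = None
    while True:
        word = tokens.next_word()
        if word is None:
            break
        w = word.upper()
        if w == "DATASET":
            kind = tokens.next_word().upper()
            if kind != "UNSTRUCTURED_GRID":
                raise ValueError(f"unsupported VTK dataset {kind}")
        elif w == "POINTS":
            n = int(tokens.next_word())
            tokens.next_word()  # dtype
            points = tokens.take_floats(3 * n).reshape(n, 3)
        elif w == "CELLS":
            n = int(tokens.next_word())
            total = int(tokens.next_word())
            raw = tokens.take_ints(total)
            cells = []
            i = 0
            for _ in range(n):
                k = raw[i]
                cells.append(raw[i + 1 : i + 1 + k])
                i += 1 + k
        elif w == "CELL_TYPES":
            n = int(tokens.next_word())
            cell_types = tokens.take_ints(n)
        elif w == "POINT_DATA":
            tokens.next_word()
        elif w == "VECTORS":
            tokens.next_word()  # name
            tokens.next_word()  # dtype
            if points is None:
                raise ValueError("VECTORS before POINTS in VTK file")
            vectors = tokens.take_floats(3 * len(points)).reshape(-1, 3)
    if points is None:
        raise ValueError("VTK file has no POINTS")
    tets = None
    if cells is not None:
        if cell_types is None or len(cell_types) != len(cells):
            raise ValueError("VTK CELLS/CELL_TYPES mismatch")
        keep = [c for c, t in zip(cells, cell_types) if t == 10]
        bad = [t for t in cell_types if t not in (10, 1, 3, 5)]
        if bad:
            raise ValueError(f"non-tet4 volume cells in VTK file (types {sorted(set(bad))})")
        if keep:
            tets = np.asarray(keep, dtype=np.int64)
    return points, tets, vectors


class _VTKTokens:
    def __init__(self, text: str):
        lines = text.splitlines()
        self.header = lines[0] if lines else ""
        if len(lines) > 2 and lines[2].strip().upper() == "BINARY":
            raise ValueError("binary VTK files are not supported")
        self._words = "\n".join(lines[2:]).split()
        self._i = 0

    def next_word(self):
        if self._i >= len(self._words):
            return None
        w = self._words[self._i]
        self._i += 1
        return w

    def take_floats(self, n) -> np.ndarray:
        out = np.array(self._words[self._i : self._i + n], dtype=np.float64)
        if len(out) != n:
            raise ValueError("truncated VTK file")
        self._i += n
        return out

    def take_ints(self, n) -> np.ndarray:
        out = np.array(self._words[self._i : self._i + n], dtype=np.int64)
        if len(out) != n:
            raise ValueError("truncated VTK file")
        self._i += n
        return out


def _read_feb(path: Path, units: str):
    """Minimal FEBio .feb dialect: <Nodes> and tet4 <Elements> only."""
    root = ET.parse(path).getroot()
    nodes_el = root.find(".//Nodes")
    if nodes_el is None:
        raise ValueError(".feb file has no <Nodes> section")
    ids = []
    coords = []
    for node in nodes_el.findall("node"):
        ids.append(int(node.get("id")))
        coords.append([float(v) for v in node.text.split(",")])
    remap = {nid: i for i, nid in enumerate(ids)}
    tets = []
    for elems in root.findall(".//Elements"):
        etype = (elems.get("type") or "").lower()
        if etype and etype != "tet4":
            raise ValueError(f"non-tet4 elements (type {etype!r}) present in .feb file")
        for el in elems.findall("elem"):
            conn = [remap[int(v)] for v in el.text.split(",")]
            if len(conn) != 4:
                raise ValueError("non-tet4 connectivity in .feb file")
            tets.append(conn)
    if not tets:
        raise ValueError("no tet4 elements found in .feb file")
    # FEBio files conventionally carry mm; honour an explicit length unit tag
    unit_el = root.find(".//Units")
    if unit_el is not None and unit_el.text:
        if "mm" in unit_el.text.lower():
            units = "mm"
        elif unit_el.text.strip().lower() in ("m", "si"):
            units = "m"
    return np.asarray(coords), np.asarray(tets, dtype=np.int64), units


# ---------------------------------------------------------------------------
# displacement field I/O
# ---------------------------------------------------------------------------


def read_displacement_field(
    path, mesh: TetMesh, units: str | None = None
) -> DisplacementField:
    """Read a per-node displacement field (CSV ``node,ux,uy,uz``, VTK point data,
    or a MAT-file) aligned to ``mesh``.

    CSV and MAT files default to millimetres (MRI convention); VTK point data
    defaults to metres.  Pass ``units`` explicitly to override.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        values = _read_disp_csv(path, mesh.n_nodes)
        scale = _unit_scale(units or "mm")
    elif suffix == ".vtk":
        _, _, vectors = _read_vtk(path)
        if vectors is None:
            raise ValueError("VTK file carries no point-data VECTORS")
        values = vectors
        scale = _unit_scale(units or "m")
    elif suffix == ".mat":
        values = _read_disp_mat(path, mesh.n_nodes)
        scale = _unit_scale(units or "mm")
    else:
        raise ValueError(f"unsupported displacement format {suffix!r}")
    if len(values) != mesh.n_nodes:
        raise ValueError(
            f"displacement record count {len(values)} != mesh node count {mesh.n_nodes}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("displacement field contains NaN/inf components")
    return DisplacementField(values=values * scale)


def _read_disp_csv(path: Path, n_nodes: int) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip().lower().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    cols = {name.strip(): i for i, name in enumerate(header)}
    if not {"ux", "uy", "uz"} <= set(cols):
        raise ValueError("CSV header must contain node,ux,uy,uz")
    values = np.full((n_nodes, 3), np.nan)
    if "node" in cols:
        idx = data[:, cols["node"]].astype(np.int64) - 1  # files are 1-based
    else:
        idx = np.arange(len(data))
    values[idx, 0] = data[:, cols["ux"]]
    values[idx, 1] = data[:, cols["uy"]]
    values[idx, 2] = data[:, cols["uz"]]
    return values


def _read_disp_mat(path: Path, n_nodes: int) -> np.ndarray:
    """Best-effort reader for MATLAB displacement deposits.

    Looks for the first (n, 3) or (3, n) floating array matching the node
    count; raises a clear error for unsupported layouts.
    """
    from scipy.io import loadmat

    try:
        contents = loadmat(path)
    except NotImplementedError as exc:  # v7.3 files are HDF5
        raise ValueError(
            "MAT-file is v7.3 (HDF5); convert it or supply CSV/VTK instead"
        ) from exc
    for key, arr in contents.items():
        if key.startswith("__") or not isinstance(arr, np.ndarray):
            continue
        a = np.asarray(arr, dtype=np.float64) if arr.dtype.kind == "f" else None
        if a is None:
            continue
        if a.shape == (n_nodes, 3):
            return a
        if a.shape == (3, n_nodes):
            return a.T
    raise ValueError(
        "unsupported MAT layout: no floating array of shape (n_nodes, 3) found"
    )


# ---------------------------------------------------------------------------
# writers (legacy ASCII VTK, CSV)
# ---------------------------------------------------------------------------


def write_vtk(path, mesh: TetMesh, point_vectors: dict[str, np.ndarray] | None = None):
    """Write the mesh (and optional per-node vector fields) as legacy ASCII VTK."""
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\ngravident mesh\nASCII\n")
    buf.write("DATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} double\n")
    for p in mesh.nodes:
        buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    buf.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
    for e in mesh.elements:
        buf.write(f"4 {e[0]} {e[1]} {e[2]} {e[3]}\n")
    buf.write(f"CELL_TYPES {mesh.n_elements}\n")
    buf.write("\n".join(["10"] * mesh.n_elements) + "\n")
    if point_vectors:
        buf.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, vec in point_vectors.items():
            buf.write(f"VECTORS {name} double\n")
            for v in np.asarray(vec):
                buf.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
    Path(path).write_text(buf.getvalue())


def write_displacement_csv(path, disp: DisplacementField, units: str = "mm"):
    """Write a displacement field as ``node,ux,uy,uz`` CSV (1-based node ids)."""
    scale = 1.0 / _unit_scale(units)
    with open(path, "w") as fh:
        fh.write("node,ux,uy,uz\n")
        for i, v in enumerate(disp.values, start=1):
            fh.write(f"{i},{v[0] * scale:.17g},{v[1] * scale:.17g},{v[2] * scale:.17g}\n")
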