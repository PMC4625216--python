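"""Triangle-mesh data model, file I/O and discrete differential geometry.

All downstream shape analysis runs on closed, genus-0, consistently
oriented triangle meshes representing subcortical structure boundaries.
Coordinates are in millimetres; areas in mm^2; volumes in mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriangleMesh",
    "CorrespondedSurface",
    "VertexScalarMap",
    "MeshInvariantError",
    "load_mesh",
    "save_mesh",
    "save_mesh_with_scalars",
    "load_mesh_with_scalars",
    "vertex_areas",
    "face_areas",
    "vertex_normals",
    "mean_curvature",
    "enclosed_volume",
]


class MeshInvariantError(ValueError):
    """A mesh violates a structural invariant (openness, genus, orientation...)."""


@dataclass
class TriangleMesh:
    """A closed oriented triangle mesh for one subcortical structure.

    Parameters
    ----------
    structure_id : str
        Name of the structure the surface bounds (e.g. ``"left_thalamus"``).
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    faces : (F, 3) int array
        0-based vertex index triples, counter-clockwise seen from outside.
    """

    structure_id: str
    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- topology -----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def directed_edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def undirected_edges(self) -> np.ndarray:
        de = self.directed_edges()
        return np.unique(np.sort(de, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.undirected_edges()) + self.n_faces

    def is_consistently_oriented(self) -> bool:
        """Every directed edge occurs exactly once, paired with its reverse."""
        de = self.directed_edges()
        uniq, counts = np.unique(de, axis=0, return_counts=True)
        if np.any(counts != 1):
            return False
        rev = uniq[:, ::-1]
        key = uniq[:, 0] * (self.n_vertices + 1) + uniq[:, 1]
        rkey = rev[:, 0] * (self.n_vertices + 1) + rev[:, 1]
        return bool(np.all(np.isin(rkey, key)))

    def validate(self) -> "TriangleMesh":
        """Check closed-manifold, genus-0, orientation and non-degeneracy.

        Raises
        ------
        MeshInvariantError
            Naming the first failed check.
        """
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise MeshInvariantError("face index out of range")
        de = self.directed_edges()
        ue = np.sort(de, axis=1)
        uniq, counts = np.unique(ue, axis=0, return_counts=True)
        if np.any(counts == 1):
            raise MeshInvariantError("open edge: boundary edge present, surface is not closed")
        if np.any(counts > 2):
            raise MeshInvariantError("non-manifold edge shared by more than 2 faces")
        chi = self.n_vertices - len(uniq) + self.n_faces
        if chi != 2:
            raise MeshInvariantError(f"genus != 0: Euler characteristic {chi} != 2")
        if not self.is_consistently_oriented():
            raise MeshInvariantError("inconsistent face orientation")
        if np.any(face_areas(self) <= 0.0):
            raise MeshInvariantError("zero-area face")
        if self.signed_volume() < 0:
            raise MeshInvariantError("inward orientation: signed volume is negative")
        return self

    def signed_volume(self) -> float:
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.structure_id, self.vertices.copy(), self.faces.copy())

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class CorrespondedSurface:
    """A subject mesh in implicit vertex correspondence with a template.

    Vertex ``i`` of ``mesh`` matches vertex ``i`` of the template named by
    ``template_id``; the face list must be identical to the template's.
    """

    mesh: TriangleMesh
    template_id: str

    def check_against(self, template: TriangleMesh) -> "CorrespondedSurface":
        if self.mesh.n_vertices != template.n_vertices or not np.array_equal(
            self.mesh.faces, template.faces
        ):
            raise MeshInvariantError("correspondence broken: face list differs from template")
        return self


@dataclass
class VertexScalarMap:
    """One real value per template vertex (RD, logJD, t, q, importance...)."""

    structure_id: str
    values: np.ndarray
    name: str = "scalar"
    flags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# I/O: PLY / OBJ via trimesh, VTK legacy polydata written and parsed here
# (POINT_DATA scalar overlays are a VTK-only feature in this package).
# ---------------------------------------------------------------------------

_FORMATS = ("ply", "obj", "vtk")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def load_mesh(path, fmt: str | None = None, structure_id: str | None = None,
              validate: bool = True) -> TriangleMesh:
    """Load a triangle mesh from PLY, OBJ or legacy VTK polydata.

    The loaded surface is validated as a closed, genus-0, outward-oriented
    mesh unless ``validate=False``.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        mesh, _ = load_mesh_with_scalars(path, structure_id=structure_id, validate=validate)
        return mesh
    tm = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"{path}: could not parse a triangle mesh from {fmt} file")
    name = structure_id or str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    mesh = TriangleMesh(name, np.asarray(tm.vertices, float), np.asarray(tm.faces))
    return mesh.validate() if validate else mesh


def save_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as PLY (binary little-endian), OBJ or legacy VTK."""
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        save_mesh_with_scalars(mesh, [], path)
        return
    mesh.to_trimesh().export(str(path), file_type=fmt)


def save_mesh_with_scalars(mesh: TriangleMesh, overlays, path) -> None:
    """Write legacy VTK ASCII polydata with named POINT_DATA scalar overlays.

    Round-tripping through :func:`load_mesh_with_scalars` recovers
    coordinates and scalar values to better than 1e-6.
    """
    overlays = list(overlays)
    for ov in overlays:
        if len(ov) != mesh.n_vertices:
            raise MeshInvariantError(
                f"overlay {ov.name!r} has {len(ov)} values for {mesh.n_vertices} vertices"
            )
    lines = [
        "# vtk DataFile Version 3.0",
        f"subshape surface {mesh.structure_id}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{c:.12g}" for c in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    if overlays:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for ov in overlays:
            safe = ov.name.replace(" ", "_")
            lines.append(f"SCALARS {safe} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.12g}" for v in ov.values]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_mesh_with_scalars(path, structure_id: str | None = None, validate: bool = True):
    """Parse legacy VTK ASCII polydata; returns (mesh, {name: VertexScalarMap})."""
    with open(path) as fh:
        tokens = fh.read().split()
    name = structure_id or str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]

    def _find(kw: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i].upper() == kw:
                return i
        return -1

    ip = _find("POINTS")
    if ip < 0:
        raise ValueError(f"{path}: no POINTS section; not legacy VTK polydata")
    nv = int(tokens[ip + 1])
    verts = np.array(tokens[ip + 3 : ip + 3 + 3 * nv], dtype=float).reshape(nv, 3)
    ipoly = _find("POLYGONS")
    if ipoly < 0:
        raise ValueError(f"{path}: no POLYGONS section")
    nf, sz = int(tokens[ipoly + 1]), int(tokens[ipoly + 2])
    raw = np.array(tokens[ipoly + 3 : ipoly + 3 + sz], dtype=np.int64)
    if np.any(raw.reshape(nf, -1)[:, 0] != 3):
        raise ValueError(f"{path}: non-triangular polygon present")
    faces = raw.reshape(nf, 4)[:, 1:]
    mesh = TriangleMesh(name, verts, faces)
    if validate:
        mesh.validate()
    overlays: dict[str, VertexScalarMap] = {}
    pos = _find("POINT_DATA")
    while pos >= 0:
        pos = _find("SCALARS", pos + 1)
        if pos < 0:
            break
        sname = tokens[pos + 1]
        # skip SCALARS name type [ncomp] + LOOKUP_TABLE default
        j = pos + 3
        if tokens[j].isdigit():
            j += 1
        if tokens[j].upper() == "LOOKUP_TABLE":
            j += 2
        vals = np.array(tokens[j : j + nv], dtype=float)
        overlays[sname] = VertexScalarMap(name, vals, sname)
    return mesh, overlays


# ---------------------------------------------------------------------------
# Differential geometry
# ---------------------------------------------------------------------------

def face_areas(mesh: TriangleMesh) -> np.ndarray:
    t = mesh.vertices[mesh.faces]
    return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)


def vertex_areas(mesh: TriangleMesh) -> VertexScalarMap:
    """Barycentric vertex areas: one third of incident face areas (mm^2).

    The total over vertices equals the total surface area exactly (up to
    floating-point summation order).
    """
    fa = face_areas(mesh)
    va = np.zeros(mesh.n_vertices)
    np.add.at(va, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return VertexScalarMap(mesh.structure_id, va, "vertex_area")


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted outward unit vertex normals."""
    t = mesh.vertices[mesh.faces]
    fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # 2*area*unit normal
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


def _adjacency_lists(mesh: TriangleMesh):
    nbr: list[set] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        nbr[a].update((b, c)); nbr[b].update((a, c)); nbr[c].update((a, b))
    return nbr


def mean_curvature(mesh: TriangleMesh) -> VertexScalarMap:
    """Discrete mean curvature (1/mm) via the cotangent Laplacian.

    Uses the mean-curvature-normal operator K(x_i) = (1/2A_i) * sum_j
    (cot a_ij + cot b_ij)(x_i - x_j) with A_i the mixed Voronoi area
    (Voronoi for non-obtuse triangles, T/2 at the obtuse corner and T/4
    elsewhere otherwise); H_i = |K|/2 signed by its projection on the
    outward normal, so a convex sphere of radius r gives +1/r.  Vertices
    with a degenerate (near-zero-area) one-ring are flagged and filled
    with the average of their neighbours.
    """
    v, f = mesh.vertices, mesh.faces
    V = mesh.n_vertices
    K = np.zeros_like(v)
    va = np.zeros(V)
    fa = face_areas(mesh)
    cots = np.empty((len(f), 3))
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        u1 = v[i] - v[o]
        u2 = v[j] - v[o]
        cross = np.linalg.norm(np.cross(u1, u2), axis=1)
        cross[cross < 1e-300] = 1e-300
        w = np.einsum("ij,ij->i", u1, u2) / cross  # cot of angle at o
        cots[:, k] = w
        np.add.at(K, i, w[:, None] * (v[i] - v[j]))
        np.add.at(K, j, w[:, None] * (v[j] - v[i]))
    obtuse_corner = np.where(cots.min(axis=1) < 0, np.argmin(cots, axis=1), -1)
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        l2 = np.einsum("ij,ij->i", v[i] - v[j], v[i] - v[j])
        vor = l2 * cots[:, k] / 8.0
        # obtuse triangles: T/2 to the obtuse corner, T/4 to the others
        ok = obtuse_corner < 0
        for idx in (i, j):
            contrib = np.where(ok, vor, 0.0)
            np.add.at(va, idx, contrib)
    if (obtuse_corner >= 0).any():
        bad = np.flatnonzero(obtuse_corner >= 0)
        for t in bad:
            for corner in range(3):
                # corner index k stores the vertex opposite edge k: vertex f[t, k]
                share = 0.5 if corner == ((obtuse_corner[t] + 2) % 3) else 0.25
                va[f[t, corner]] += share * fa[t]
    degenerate = va < 1e-12 * max(va.max(), 1e-30)
    safe_va = np.where(degenerate, 1.0, va)
    K = K / (2.0 * safe_va[:, None])
    n = vertex_normals(mesh)
    mag = np.linalg.norm(K, axis=1)
    sign = np.sign(np.einsum("ij,ij->i", K, n))
    sign[sign == 0] = 1.0
    H = 0.5 * mag * sign
    if degenerate.any():
        nbr = _adjacency_lists(mesh)
        for idx in np.flatnonzero(degenerate):
            good = [j for j in nbr[idx] if not degenerate[j]]
            H[idx] = float(np.mean(H[good])) if good else 0.0
    flags = np.zeros(V, dtype=bool)
    flags[degenerate] = True
    return VertexScalarMap(mesh.structure_id, H, "mean_curvature", flags=flags)


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem.

    Requires a closed, consistently oriented mesh; invariant under rigid
    motion. The absolute value is returned.
    """
    if not mesh.is_consistently_oriented():
        raise MeshInvariantError("inconsistent face orientation")
    return abs(mesh.signed_volume())
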