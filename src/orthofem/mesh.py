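"""Region-tagged tetrahedral meshing of the synthetic anatomy.

The volume mesh is built as a structured O-grid around the tooth axis:
rings of nodes at each axial level, placed exactly on the tooth surface,
the PDL outer (socket) surface, and graded through the bone to the block
walls.  Ring-to-ring hexahedral cells are split into six tetrahedra with
globally consistent face diagonals, and each tetrahedron is tagged by
analytic classification of its centroid (tooth / PDL / cortical /
cancellous), so elements conform to the tooth-PDL and PDL-bone interfaces
along the root where the stress samples are taken.  Cells whose centroid
falls outside every tissue (air around the crown) are discarded.

Also provided: simple box meshes (the standard 5/6-tet cube decompositions)
used for solver verification, quadratic (10-node) element promotion by
edge-midpoint insertion, mesh-quality metrics, and VTK-legacy / Abaqus-inp
export for inspection in third-party tools.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anatomy import AnatomyModel, Region, REGION_NAMES

__all__ = [
    "VolumeMesh",
    "MeshQualityReport",
    "tetrahedralize",
    "box_mesh",
    "to_quadratic",
    "mesh_quality",
    "tet_volumes",
    "boundary_faces",
    "write_vtk",
    "read_vtk",
    "write_inp",
    "MeshingError",
]


class MeshingError(RuntimeError):
    pass


#: 6-tet decomposition of a hexahedron around the 0-6 main diagonal.  Face
#: diagonals induced by this split are consistent between structured
#: neighbours (verified in tests via conformity of shared faces).
_HEX_TO_TETS = np.array(
    [
        [0, 1, 2, 6],
        [0, 2, 3, 6],
        [0, 3, 7, 6],
        [0, 7, 4, 6],
        [0, 4, 5, 6],
        [0, 5, 1, 6],
    ]
)

#: prism (A,B,C,A',B',C') split compatible with the hex split above
_PRISM_TO_TETS = np.array([[0, 1, 2, 5], [0, 1, 5, 4], [0, 4, 5, 3]])

#: 5-tet decomposition of a cube (alternating parity needed between cells)
_HEX_TO_TETS_5 = np.array(
    [[0, 1, 3, 4], [1, 2, 3, 6], [1, 4, 5, 6], [3, 4, 6, 7], [1, 3, 4, 6]]
)


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with per-element tissue tags and boundary node sets.

    nodes : (n, 3) float, mm.  elements : (m, 4) or (m, 10) int.
    region : (m,) int codes from :class:`orthofem.anatomy.Region`.
    node_sets : named boundary sets (fixed_base, bracket_nodes, palatal_patch).
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    order: int = 1
    target_edge: float = 1.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_elements(self) -> np.ndarray:
        return self.elements[:, :4]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.corner_elements())

    def centroids(self) -> np.ndarray:
        return self.nodes[self.corner_elements()].mean(axis=1)

    def region_counts(self) -> dict[str, int]:
        return {
            REGION_NAMES[code]: int(np.sum(self.region == code))
            for code in np.unique(self.region)
        }

    def validate(self) -> None:
        vols = self.volumes()
        if not np.all(vols > 0):
            raise MeshingError(f"{np.sum(vols <= 0)} elements have non-positive volume")
        used = np.unique(self.elements)
        if len(used) != self.n_nodes:
            raise MeshingError("mesh contains unreferenced nodes")
        if len(self.region) != self.n_elements:
            raise MeshingError("region tags do not cover all elements")


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of 4-node tetrahedra (positive for correct orientation)."""
    p = nodes[tets]
    e = p[:, 1:] - p[:, :1]
    return np.linalg.det(e) / 6.0


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    v = tet_volumes(nodes, tets)
    flip = v < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


# -- structured anatomy mesher ------------------------------------------------


def _semiaxes(model: AnatomyModel, z: float) -> tuple[float, float]:
    cfg = model.config
    if z >= 0:
        a, b = cfg.crown_semiaxes(np.array(min(z, cfg.crown_height)))
    elif z >= -cfg.root_length:
        a, b = cfg.root_semiaxes(np.array(z))
    else:
        a, b = cfg.root_semiaxes(np.array(-cfg.root_length))
    return float(a), float(b)


def _z_levels(model: AnatomyModel, target_edge: float) -> np.ndarray:
    cfg = model.config
    L, t, H, bz = cfg.root_length, cfg.pdl_thickness, cfg.crown_height, cfg.bone_block[2]
    crown = np.linspace(H, 0.0, max(3, int(np.ceil(H / (1.6 * target_edge))) + 1))
    root = np.linspace(0.0, -L, max(7, int(np.ceil(L / target_edge)) + 1))[1:]
    cap = np.array([-L - t])
    # pose-aware bottom: the lowest tooth-frame level must map to the block floor
    tz = model.pose.translation[2]
    rzz = model.pose.rotation[2, 2]
    z_bot = (-bz - tz) / rzz
    below = np.linspace(-L - t, z_bot, max(4, int(np.ceil((abs(z_bot) - L - t) / (1.8 * target_edge))) + 1))[1:]
    return np.concatenate([crown, root, cap, below])


def tetrahedralize(model: AnatomyModel, target_edge: float = 0.9, order: int = 1) -> VolumeMesh:
    """Mesh the synthetic anatomy into region-tagged tetrahedra.

    Parameters
    ----------
    model
        Generated anatomy (its pose is honoured: tooth, PDL and socket move
        together, the bone block stays fixed).
    target_edge
        Requested characteristic edge length, mm.  Element count scales
        roughly with volume / target_edge**3.
    order
        1 for 4-node linear tetrahedra, 2 for 10-node quadratic.
    """
    if target_edge <= 0:
        raise MeshingError("target_edge must be > 0")
    if order not in (1, 2):
        raise MeshingError("order must be 1 or 2")
    cfg = model.config
    pose = model.pose
    hx, hy, bz = cfg.bone_block[0] / 2, cfg.bone_block[1] / 2, cfg.bone_block[2]
    t = cfg.pdl_thickness

    # circumferential resolution from the cervical perimeter
    ac, bc = cfg.root_semiaxes(np.array(0.0))
    perimeter = np.pi * (float(ac) + float(bc))
    n_theta = max(12, int(np.ceil(perimeter / target_edge)))
    theta = (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)
    dirs2 = np.column_stack([np.cos(theta), np.sin(theta)])

    n_tooth = max(2, int(round(float(ac) / target_edge)))
    tooth_fracs = np.linspace(1.0 / n_tooth, 1.0, n_tooth)
    n_bone = max(3, int(round((min(hx, hy) - float(bc)) / (1.5 * target_edge))))
    bone_fracs = (np.arange(1, n_bone + 1) / n_bone) ** 1.3

    z_levels = _z_levels(model, target_edge)
    n_lvl = len(z_levels)
    n_stations = n_tooth + 1 + n_bone  # tooth rings + pdl ring + bone rings
    level_size = 1 + n_stations * n_theta

    axis_xy = pose.apply(np.zeros(3))[:2]
    rw = model.wall_radius(axis_xy, dirs2)

    nodes = np.empty((n_lvl * level_size, 3))
    for k, z in enumerate(z_levels):
        a, b = _semiaxes(model, z)
        base = k * level_size
        ring_tf = np.empty((n_stations, n_theta, 3))
        for s, f in enumerate(tooth_fracs):
            ring_tf[s] = np.column_stack(
                [f * a * dirs2[:, 0] * 1.0, f * b * dirs2[:, 1], np.full(n_theta, z)]
            )
        ring_tf[n_tooth] = np.column_stack(
            [(a + t) * dirs2[:, 0], (b + t) * dirs2[:, 1], np.full(n_theta, z)]
        )
        axis_node = pose.apply(np.array([0.0, 0.0, z]))
        inner_world = pose.apply(ring_tf.reshape(-1, 3)).reshape(n_stations, n_theta, 3)
        zw = float(np.clip(axis_node[2], -bz, 0.0))
        wall = np.column_stack([axis_xy + dirs2 * rw[:, None], np.full(n_theta, zw)])
        pdl_world = inner_world[n_tooth]
        for j, g in enumerate(bone_fracs):
            inner_world[n_tooth + 1 + j] = (1 - g) * pdl_world + g * wall
        nodes[base] = axis_node
        nodes[base + 1 : base + level_size] = inner_world.reshape(-1, 3)

    # snap the bottom level to the block floor and wall rings onto the walls
    bottom = slice((n_lvl - 1) * level_size, n_lvl * level_size)
    nodes[bottom, 2] = -bz
    for k in range(n_lvl):
        base = k * level_size
        wall_ids = base + 1 + (n_stations - 1) * n_theta + np.arange(n_theta)
        if nodes[base, 2] <= 1e-9:  # below the crest only
            nodes[wall_ids, 2] = np.clip(nodes[wall_ids, 2], -bz, 0.0)

    def ring_id(k: int, s: int, i: int) -> int:
        return k * level_size + 1 + s * n_theta + (i % n_theta)

    tets = []
    for k in range(n_lvl - 1):
        ax0, ax1 = k * level_size, (k + 1) * level_size
        for i in range(n_theta):
            j = i + 1
            # wedge: axis to first ring; split compatible with hex inner faces
            A, B, C = ax0, ring_id(k, 0, i), ring_id(k, 0, j)
            Ap, Bp, Cp = ax1, ring_id(k + 1, 0, i), ring_id(k + 1, 0, j)
            tets.append([A, B, C, Cp])
            tets.append([A, B, Cp, Bp])
            tets.append([A, Bp, Cp, Ap])
        for s in range(n_stations - 1):
            for i in range(n_theta):
                j = i + 1
                hexa = [
                    ring_id(k, s, i), ring_id(k, s, j), ring_id(k, s + 1, j), ring_id(k, s + 1, i),
                    ring_id(k + 1, s, i), ring_id(k + 1, s, j), ring_id(k + 1, s + 1, j), ring_id(k + 1, s + 1, i),
                ]
                for tet in _HEX_TO_TETS:
                    tets.append([hexa[v] for v in tet])
    tets = np.asarray(tets, dtype=np.int64)

    centroids = nodes[tets].mean(axis=1)
    tags = model.classify(centroids)
    keep = tags != Region.OUTSIDE
    tets, tags = tets[keep], tags[keep]
    _seal_pdl_shell(tets, tags)

    # degenerate slivers can appear where rings collapse near the apex axis
    vols = np.abs(tet_volumes(nodes, tets))
    ok = vols > 1e-10
    tets, tags = tets[ok], tags[ok]
    tets = _orient_positive(nodes, tets)

    # compact node numbering
    used, inverse = np.unique(tets, return_inverse=True)
    tets = inverse.reshape(tets.shape)
    nodes = nodes[used]

    mesh = VolumeMesh(nodes=nodes, elements=tets, region=tags, order=1, target_edge=target_edge)
    _attach_node_sets(mesh, model)
    mesh.validate()
    if order == 2:
        mesh = to_quadratic(mesh)
    return mesh


def _seal_pdl_shell(tets: np.ndarray, tags: np.ndarray) -> None:
    """Retag boundary-straddling elements so the PDL fully separates
    tooth from bone.

    Centroid classification is exact on the structured interfaces along the
    root, but cells at the apex cap and the cervical rim can straddle the
    thin ligament and end up coupling a root-surface node directly to a
    bone element, which would short-circuit the soft PDL with a stiff load
    path.  Any tooth element sharing a node with bone (or vice versa) is
    reassigned to the ligament; physically these collars at the alveolar
    crest and apex are soft tissue.  Modifies `tags` in place.
    """
    bone = (tags == Region.CORTICAL) | (tags == Region.CANCELLOUS)
    for _ in range(4):  # each pass shrinks tooth/bone sets; terminates early
        tooth_nodes = np.unique(tets[tags == Region.TOOTH])
        bone_nodes = np.unique(tets[bone])
        shared = np.intersect1d(tooth_nodes, bone_nodes, assume_unique=True)
        if len(shared) == 0:
            return
        touches = np.isin(tets, shared).any(axis=1)
        tags[touches & (tags == Region.TOOTH)] = Region.PDL
        tags[touches & bone] = Region.PDL
        bone = (tags == Region.CORTICAL) | (tags == Region.CANCELLOUS)
    raise MeshingError("could not separate tooth from bone with a PDL layer")


def _attach_node_sets(mesh: VolumeMesh, model: AnatomyModel) -> None:
    cfg = model.config
    hx, bz = cfg.bone_block[0] / 2, cfg.bone_block[2]
    tol = 1e-6
    x, z = mesh.nodes[:, 0], mesh.nodes[:, 2]
    # mesial and distal cut faces plus the block floor (superior surface of
    # the model, which is apical in the maxilla)
    fixed = np.flatnonzero((np.abs(np.abs(x) - hx) < tol) | (np.abs(z + bz) < tol))
    if len(fixed) == 0:
        raise MeshingError("no boundary nodes found for the fixed set")

    tooth_nodes = np.unique(mesh.corner_elements()[mesh.region == Region.TOOTH])
    zb = cfg.bracket_height_fraction * cfg.crown_height
    _, bbuc = cfg.crown_semiaxes(np.array(zb))
    attach = model.pose.apply(np.array([0.0, float(bbuc), zb]))
    d = np.linalg.norm(mesh.nodes[tooth_nodes] - attach, axis=1)
    n_pick = min(6, max(3, len(tooth_nodes)))
    bracket = tooth_nodes[np.argsort(d)[:n_pick]]

    crown = tooth_nodes[mesh.nodes[tooth_nodes, 2] > 0.05 * cfg.crown_height]
    palatal = crown[mesh.nodes[crown, 1] < 0]
    mesh.node_sets = {
        "fixed_base": fixed,
        "bracket_nodes": bracket,
        "palatal_patch": palatal,
    }


# -- box meshes for solver verification ---------------------------------------


def box_mesh(
    lengths: tuple[float, float, float],
    divisions: tuple[int, int, int],
    decomposition: int = 6,
    region: int = Region.TOOTH,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VolumeMesh:
    """Structured tetrahedral mesh of a rectangular block.

    `decomposition` 6 uses the consistent 6-tet hex split; 5 uses the
    parity-alternating 5-tet split.  Used for patch, bar and cantilever
    verification problems.
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexa = [
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ]
                if decomposition == 6:
                    pattern = _HEX_TO_TETS
                elif decomposition == 5:
                    if (i + j + k) % 2 == 1:  # mirror for face conformity
                        hexa = [hexa[1], hexa[0], hexa[3], hexa[2], hexa[5], hexa[4], hexa[7], hexa[6]]
                    pattern = _HEX_TO_TETS_5
                else:
                    raise MeshingError("decomposition must be 5 or 6")
                for tet in pattern:
                    tets.append([hexa[v] for v in tet])
    tets = _orient_positive(nodes, np.asarray(tets, dtype=np.int64))
    mesh = VolumeMesh(
        nodes=nodes,
        elements=tets,
        region=np.full(len(tets), region, dtype=np.int32),
        target_edge=float(min(lx / nx, ly / ny, lz / nz)),
    )
    mesh.validate()
    return mesh


# -- quadratic promotion ------------------------------------------------------

#: VTK quadratic-tet edge ordering: node 4+e lies on edge _TET_EDGES[e]
TET_EDGES = np.array([[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]])


def to_quadratic(mesh: VolumeMesh) -> VolumeMesh:
    """Promote 4-node tets to 10-node by inserting shared edge midpoints."""
    if mesh.order != 1:
        raise MeshingError("mesh is already quadratic")
    tets = mesh.elements
    edges = tets[:, TET_EDGES]  # (m, 6, 2)
    edges_sorted = np.sort(edges.reshape(-1, 2), axis=1)
    uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    midpoints = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    mid_ids = mesh.n_nodes + inverse.reshape(len(tets), 6)
    elements = np.hstack([tets, mid_ids])
    nodes = np.vstack([mesh.nodes, midpoints])

    # propagate node sets: a midpoint joins a set when both ends belong
    node_sets = dict(mesh.node_sets)
    for name, ids in mesh.node_sets.items():
        members = np.isin(uniq, ids).all(axis=1)
        extra = mesh.n_nodes + np.flatnonzero(members)
        node_sets[name] = np.concatenate([ids, extra])
    return VolumeMesh(
        nodes=nodes,
        elements=elements,
        region=mesh.region.copy(),
        node_sets=node_sets,
        order=2,
        target_edge=mesh.target_edge,
    )


# -- quality ------------------------------------------------------------------


@dataclass(frozen=True)
class MeshQualityReport:
    n_elements: int
    n_nodes: int
    min_volume: float
    total_volume: float
    min_aspect: float
    mean_aspect: float
    max_aspect: float
    min_dihedral_deg: float
    region_counts: dict[str, int]
    flagged: np.ndarray  # element ids with aspect ratio above threshold
    aspect_threshold: float


def mesh_quality(mesh: VolumeMesh, aspect_threshold: float = 15.0) -> MeshQualityReport:
    """Aspect ratio (longest edge / inradius, normalised so a regular tet
    scores 1), minimum dihedral angle, volumes and per-region counts."""
    tets = mesh.corner_elements()
    p = mesh.nodes[tets]
    vols = tet_volumes(mesh.nodes, tets)

    edge_vecs = p[:, TET_EDGES[:, 1]] - p[:, TET_EDGES[:, 0]]
    edge_len = np.linalg.norm(edge_vecs, axis=2)
    longest = edge_len.max(axis=1)

    # inradius = 3V / total face area
    faces = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    areas = np.zeros(len(tets))
    normals = np.empty((len(tets), 4, 3))
    for fi, (a, b, c) in enumerate(faces):
        n = np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a])
        normals[:, fi] = n
        areas += 0.5 * np.linalg.norm(n, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inradius = 3.0 * np.abs(vols) / areas
        aspect = longest / (2.0 * np.sqrt(6.0) * inradius)
    aspect = np.where(np.isfinite(aspect), aspect, np.inf)

    # dihedral angle across each edge = angle between the two faces not
    # containing it; outward normals n1, n2 give cos(dihedral) = -n1.n2
    opposite_faces = {tuple(sorted(e)): [] for e in TET_EDGES}
    for fi, f in enumerate(faces):
        fset = set(f)
        for e in TET_EDGES:
            if set(e) <= fset:
                opposite_faces[tuple(sorted(e))].append(fi)
    min_dihedral = np.full(len(tets), np.inf)
    unit = normals / np.maximum(np.linalg.norm(normals, axis=2, keepdims=True), 1e-300)
    for e, (f1, f2) in opposite_faces.items():
        cosang = -np.einsum("ij,ij->i", unit[:, f1], unit[:, f2])
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        min_dihedral = np.minimum(min_dihedral, ang)

    flagged = np.flatnonzero(aspect > aspect_threshold)
    return MeshQualityReport(
        n_elements=mesh.n_elements,
        n_nodes=mesh.n_nodes,
        min_volume=float(vols.min()),
        total_volume=float(np.abs(vols).sum()),
        min_aspect=float(aspect.min()),
        mean_aspect=float(np.mean(aspect[np.isfinite(aspect)])),
        max_aspect=float(aspect.max()),
        min_dihedral_deg=float(min_dihedral.min()),
        region_counts=mesh.region_counts(),
        flagged=flagged,
        aspect_threshold=aspect_threshold,
    )


def boundary_faces(mesh: VolumeMesh) -> np.ndarray:
    """Corner triangles appearing in exactly one element (the free surface)."""
    faces = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    tris = mesh.corner_elements()[:, faces].reshape(-1, 3)
    key = np.sort(tris, axis=1)
    _, index, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return tris[index[counts == 1]]


# -- I/O ----------------------------------------------------------------------

_VTK_CELL_TYPE = {1: 10, 2: 24}  # linear / quadratic tetrahedron


def write_vtk(
    mesh: VolumeMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a legacy-ASCII VTK unstructured grid with region tags."""
    nn = mesh.elements.shape[1]
    out = io.StringIO()
    out.write("# vtk DataFile Version 3.0\northofem mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
    out.write(f"POINTS {mesh.n_nodes} double\n")
    np.savetxt(out, mesh.nodes, fmt="%.9g")
    out.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (nn + 1)}\n")
    cells = np.hstack([np.full((mesh.n_elements, 1), nn), mesh.elements])
    np.savetxt(out, cells, fmt="%d")
    out.write(f"CELL_TYPES {mesh.n_elements}\n")
    np.savetxt(out, np.full(mesh.n_elements, _VTK_CELL_TYPE[mesh.order]), fmt="%d")

    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region)
    out.write(f"CELL_DATA {mesh.n_elements}\n")
    for name, values in cell_data.items():
        values = np.asarray(values)
        if values.ndim == 1:
            fmt = "%d" if np.issubdtype(values.dtype, np.integer) else "%.9g"
            kind = "int" if np.issubdtype(values.dtype, np.integer) else "double"
            out.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            np.savetxt(out, values, fmt=fmt)
        else:
            out.write(f"VECTORS {name} double\n")
            np.savetxt(out, values, fmt="%.9g")
    if point_data:
        out.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, values in point_data.items():
            values = np.asarray(values)
            if values.ndim == 1:
                out.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            else:
                out.write(f"VECTORS {name} double\n")
            np.savetxt(out, values, fmt="%.9g")
    Path(path).write_text(out.getvalue())


def read_vtk(path: str | Path) -> VolumeMesh:
    """Read a legacy-ASCII VTK unstructured grid written by :func:`write_vtk`."""
    tokens = Path(path).read_text().split()
    it = iter(range(len(tokens)))

    def find(word: str) -> int:
        for i, tok in enumerate(tokens):
            if tok == word:
                return i
        raise ValueError(f"VTK token {word!r} not found")

    i = find("POINTS")
    n_pts = int(tokens[i + 1])
    start = i + 3
    nodes = np.array(tokens[start : start + 3 * n_pts], dtype=float).reshape(n_pts, 3)

    i = find("CELLS")
    n_cells, total = int(tokens[i + 1]), int(tokens[i + 2])
    raw = np.array(tokens[i + 3 : i + 3 + total], dtype=np.int64)
    nn = int(raw[0])
    cells = raw.reshape(n_cells, nn + 1)[:, 1:]

    region = np.full(n_cells, Region.TOOTH, dtype=np.int32)
    for i, tok in enumerate(tokens):
        if tok == "SCALARS" and tokens[i + 1] == "region":
            start = i + 6  # SCALARS name type 1 LOOKUP_TABLE default
            region = np.array(tokens[start : start + n_cells], dtype=np.int32)
            break
    order = 1 if nn == 4 else 2
    return VolumeMesh(nodes=nodes, elements=cells, region=region, order=order)


_INP_ELEMENT = {1: "C3D4", 2: "C3D10"}
#: VTK -> Abaqus quadratic-tet node permutation (Abaqus expects edge nodes
#: in the order 01, 12, 20, 03, 13, 23; identical to the VTK layout)
_VTK_TO_ABAQUS = np.arange(10)


def write_inp(mesh: VolumeMesh, path: str | Path) -> None:
    """Export nodes/elements/element-sets in Abaqus .inp form for cross-checks."""
    lines = ["*HEADING", "orthofem export", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")
    elems = mesh.elements if mesh.order == 1 else mesh.elements[:, _VTK_TO_ABAQUS]
    lines.append(f"*ELEMENT, TYPE={_INP_ELEMENT[mesh.order]}")
    for i, conn in enumerate(elems, start=1):
        lines.append(f"{i}, " + ", ".join(str(c + 1) for c in conn))
    for code in np.unique(mesh.region):
        ids = np.flatnonzero(mesh.region == code) + 1
        lines.append(f"*ELSET, ELSET={REGION_NAMES[int(code)].upper()}")
        for chunk in np.array_split(ids, max(1, len(ids) // 12)):
            lines.append(", ".join(map(str, chunk)))
    Path(path).write_text("\n".join(lines) + "\n")
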