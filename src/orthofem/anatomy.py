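"""Parametric stand-in anatomy for a maxillary canine retraction segment.

Patient imaging (CT segmentations, scanned dental casts) is not available,
so the geometry every downstream stage consumes is generated parametrically:

* canine root: tapered cone with elliptical cross-section (mesiodistal
  semi-axis `cervical_radius`, buccolingual axis scaled by `ellipse_ratio`),
  flat apex;
* crown: capped elliptical frustum above the cervix;
* periodontal ligament (PDL): constant-thickness shell offset from the root,
  closed by an apical cap;
* alveolar bone: rectangular block whose socket is the PDL outer surface,
  with a cortical shell of constant thickness around a cancellous core;
* a bracket attachment point on the buccal crown surface, a temporary
  skeletal anchorage device (TAD) point distal to the canine, and the three
  root landmarks C1D, C2D (distal surface, 1/3 and 2/3 of root length from
  the cervix) and C1M (mesial surface, 1/3).

Coordinate convention (the model frame): x mesial(-)/distal(+),
y buccal(+)/palatal(-), z apical(-)/coronal(+); origin at the cervical
center of the canine; units mm.  Positive tooth movement is distal.

The tooth (with its PDL and socket) carries a rigid pose so that a study
can advance it between periods while the bone block stays fixed in space.
All region membership tests are analytic, which lets the mesher tag
elements exactly and keeps every stage deterministic.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .movement import RigidTransform

__all__ = [
    "AnatomyConfig",
    "AnatomyModel",
    "LandmarkSet",
    "Region",
    "REGION_NAMES",
    "build_model",
    "export_stl",
    "import_stl",
    "StlParseError",
]


class Region:
    """Integer region codes used throughout meshing and assembly."""

    OUTSIDE = 0
    TOOTH = 1
    PDL = 2
    CORTICAL = 3
    CANCELLOUS = 4
    BRACKET = 5


REGION_NAMES = {
    Region.OUTSIDE: "outside",
    Region.TOOTH: "tooth",
    Region.PDL: "pdl",
    Region.CORTICAL: "cortical",
    Region.CANCELLOUS: "cancellous",
    Region.BRACKET: "bracket",
}


class ConfigurationError(ValueError):
    pass


class StlParseError(ValueError):
    """Malformed STL input; carries the byte offset of the defect."""

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


@dataclass(frozen=True)
class AnatomyConfig:
    """Dimensions of the synthetic segment.

    Defaults are chosen at the scale of an adult maxillary canine; none of
    them reproduces a particular patient's anatomy, and all are free
    parameters of the study.
    """

    root_length: float = 15.0  # mm, cervix to apex
    crown_height: float = 10.0  # mm, cervix to cusp
    cervical_radius: float = 3.0  # mm, mesiodistal semi-axis at the cervix
    root_apical_radius: float = 0.6  # mm, semi-axis at the (flat) apex
    ellipse_ratio: float = 1.25  # buccolingual / mesiodistal semi-axis
    crown_flare: float = 0.2  # fractional widening of the crown at the cusp
    pdl_thickness: float = 0.25  # mm
    bone_block: tuple[float, float, float] = (20.0, 14.0, 20.0)  # mm (x, y, z)
    cortical_shell_thickness: float = 1.5  # mm
    bracket_offset: float = 3.5  # mm, from the buccal crown surface
    bracket_height_fraction: float = 0.45  # of crown height, above the cervix
    tad_position: tuple[float, float, float] = (9.0, 2.0, -6.0)  # mm, model frame
    random_seed: int = 0
    surface_resolution: int = 48  # circumferential facets of export surfaces

    def __post_init__(self) -> None:
        lengths = {
            "root_length": self.root_length,
            "crown_height": self.crown_height,
            "cervical_radius": self.cervical_radius,
            "root_apical_radius": self.root_apical_radius,
            "pdl_thickness": self.pdl_thickness,
            "cortical_shell_thickness": self.cortical_shell_thickness,
            "bracket_offset": self.bracket_offset,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        if any(d <= 0 for d in self.bone_block):
            raise ConfigurationError(f"bone_block dimensions must be > 0, got {self.bone_block}")
        if self.pdl_thickness >= 0.5 * self.cervical_radius:
            raise ConfigurationError(
                "pdl_thickness must be small relative to cervical_radius "
                f"(got {self.pdl_thickness} vs {self.cervical_radius})"
            )
        if self.root_apical_radius >= self.cervical_radius:
            raise ConfigurationError("root must taper: apical radius < cervical radius")
        if self.tad_position[0] <= self.cervical_radius:
            raise ConfigurationError("tad_position must lie distal to the canine (x > cervical radius)")
        if self.surface_resolution < 12:
            raise ConfigurationError("surface_resolution must be >= 12")
        socket = self.cervical_radius * self.ellipse_ratio + self.pdl_thickness
        if socket + self.cortical_shell_thickness >= min(self.bone_block[0], self.bone_block[1]) / 2:
            raise ConfigurationError("bone_block too small to house the socket plus cortical shell")

    # -- radius profiles in the tooth frame ---------------------------------

    def root_semiaxes(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mesiodistal/buccolingual semi-axes of the root at height z in [-L, 0]."""
        z = np.asarray(z, dtype=float)
        f = 1.0 + z / self.root_length
        a = self.root_apical_radius + (self.cervical_radius - self.root_apical_radius) * f
        return a, a * self.ellipse_ratio

    def crown_semiaxes(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Semi-axes of the crown frustum at height z in [0, H]."""
        z = np.asarray(z, dtype=float)
        a = self.cervical_radius * (1.0 + self.crown_flare * z / self.crown_height)
        return a, a * self.ellipse_ratio


@dataclass(frozen=True)
class LandmarkSet:
    """The three canine-root measurement points (model/world frame, mm)."""

    C1D: np.ndarray  # distal surface, 1/3 of root length from the cervix
    C2D: np.ndarray  # distal surface, 2/3
    C1M: np.ndarray  # mesial surface, 1/3

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"C1D": self.C1D, "C2D": self.C2D, "C1M": self.C1M}

    def as_array(self) -> np.ndarray:
        return np.stack([self.C1D, self.C2D, self.C1M])


@dataclass(frozen=True)
class AnatomyModel:
    """Generated anatomy: surfaces, attachment points, landmarks, pose.

    `pose` maps the tooth frame into the model frame; bone-block extents are
    fixed in the model frame.  Surfaces are closed triangulations intended
    for export/inspection; the mesher works from the analytic geometry.
    """

    config: AnatomyConfig
    pose: RigidTransform
    surfaces: dict[str, trimesh.Trimesh]
    landmark_set: LandmarkSet
    bracket_point: np.ndarray
    tad_point: np.ndarray
    palatal_reference_patch: np.ndarray
    declared_facet_counts: dict[str, int]

    # -- frames --------------------------------------------------------------

    def to_tooth_frame(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.pose.translation) @ self.pose.rotation

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return self.pose.apply(points)

    # -- analytic region membership ------------------------------------------

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Region code for each point (model frame). Vectorized."""
        cfg = self.config
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tf = self.to_tooth_frame(pts)
        x, y, z = tf[:, 0], tf[:, 1], tf[:, 2]
        out = np.full(len(pts), Region.OUTSIDE, dtype=np.int32)

        L, t, H = cfg.root_length, cfg.pdl_thickness, cfg.crown_height

        crown = (z >= 0) & (z <= H)
        if crown.any():
            a, b = cfg.crown_semiaxes(np.clip(z[crown], 0, H))
            inside = (x[crown] / a) ** 2 + (y[crown] / b) ** 2 <= 1.0
            out[np.flatnonzero(crown)[inside]] = Region.TOOTH

        root = (z < 0) & (z >= -L)
        if root.any():
            idx = np.flatnonzero(root)
            a, b = cfg.root_semiaxes(z[idx])
            s_tooth = (x[idx] / a) ** 2 + (y[idx] / b) ** 2
            s_pdl = (x[idx] / (a + t)) ** 2 + (y[idx] / (b + t)) ** 2
            out[idx[s_tooth <= 1.0]] = Region.TOOTH
            out[idx[(s_tooth > 1.0) & (s_pdl <= 1.0)]] = Region.PDL

        cap = (z < -L) & (z >= -L - t)
        if cap.any():
            idx = np.flatnonzero(cap)
            frac = np.clip((z[idx] + L) / t, -1.0, 0.0)  # 0 at apex, -1 at cap bottom
            s = np.sqrt(np.maximum(0.0, 1.0 - frac**2))
            ra, rb = cfg.root_semiaxes(np.array(-L))
            a = np.maximum((ra + t) * s, 1e-9)
            b = np.maximum((rb + t) * s, 1e-9)
            inside = (x[idx] / a) ** 2 + (y[idx] / b) ** 2 <= 1.0
            out[idx[inside]] = Region.PDL

        # bone block is fixed in the model frame
        hx, hy, bz = cfg.bone_block[0] / 2, cfg.bone_block[1] / 2, cfg.bone_block[2]
        xw, yw, zw = pts[:, 0], pts[:, 1], pts[:, 2]
        in_block = (
            (out == Region.OUTSIDE)
            & (np.abs(xw) <= hx)
            & (np.abs(yw) <= hy)
            & (zw <= 0.0)
            & (zw >= -bz)
        )
        if in_block.any():
            idx = np.flatnonzero(in_block)
            cst = cfg.cortical_shell_thickness
            near_shell = (
                (hx - np.abs(xw[idx]) < cst)
                | (hy - np.abs(yw[idx]) < cst)
                | (zw[idx] < -bz + cst)
                | (zw[idx] > -cst)
            )
            out[idx] = np.where(near_shell, Region.CORTICAL, Region.CANCELLOUS)
        return out

    def wall_radius(self, axis_xy: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Distance from the tooth axis to the bone-block side walls.

        `directions`: (n, 2) unit vectors in the model xy-plane.
        """
        return _wall_radius(self.config, axis_xy, directions)

    def with_pose(self, pose: RigidTransform) -> "AnatomyModel":
        """Rebuild the model with the tooth (and its PDL/socket) re-posed."""
        return build_model(self.config, pose=pose)


def _wall_radius(config: AnatomyConfig, axis_xy: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Ray distance from `axis_xy` to the block's rectangular side walls."""
    hx, hy = config.bone_block[0] / 2, config.bone_block[1] / 2
    x0, y0 = axis_xy
    d = np.atleast_2d(directions)
    with np.errstate(divide="ignore"):
        tx = np.where(d[:, 0] > 0, (hx - x0) / d[:, 0], np.where(d[:, 0] < 0, (-hx - x0) / d[:, 0], np.inf))
        ty = np.where(d[:, 1] > 0, (hy - y0) / d[:, 1], np.where(d[:, 1] < 0, (-hy - y0) / d[:, 1], np.inf))
    r = np.minimum(tx, ty)
    if not np.all(np.isfinite(r) & (r > 0)):
        raise ConfigurationError("tooth axis lies outside the bone block")
    return r


# -- surface construction -----------------------------------------------------


def _ring(a: float, b: float, z: float, theta: np.ndarray) -> np.ndarray:
    return np.column_stack([a * np.cos(theta), b * np.sin(theta), np.full_like(theta, z)])


def _tube_faces(n_rings: int, n_theta: int, offset: int = 0, flip: bool = False) -> np.ndarray:
    """Triangulate consecutive rings of n_theta vertices into a closed tube strip."""
    faces = []
    for k in range(n_rings - 1):
        r0, r1 = offset + k * n_theta, offset + (k + 1) * n_theta
        for i in range(n_theta):
            j = (i + 1) % n_theta
            faces.append([r0 + i, r0 + j, r1 + j])
            faces.append([r0 + i, r1 + j, r1 + i])
    faces = np.asarray(faces, dtype=np.int64)
    return faces[:, ::-1] if flip else faces


def _fan_faces(center: int, ring_start: int, n_theta: int, flip: bool = False) -> np.ndarray:
    faces = []
    for i in range(n_theta):
        j = (i + 1) % n_theta
        faces.append([center, ring_start + i, ring_start + j])
    faces = np.asarray(faces, dtype=np.int64)
    return faces[:, ::-1] if flip else faces


def _annulus_faces(inner_start: int, outer_start: int, n_theta: int, flip: bool = False) -> np.ndarray:
    faces = []
    for i in range(n_theta):
        j = (i + 1) % n_theta
        faces.append([inner_start + i, outer_start + j, outer_start + i])
        faces.append([inner_start + i, inner_start + j, outer_start + j])
    faces = np.asarray(faces, dtype=np.int64)
    return faces[:, ::-1] if flip else faces


def _close_mesh(vertices: np.ndarray, faces: np.ndarray, jitter: float, rng: np.random.Generator) -> trimesh.Trimesh:
    verts = vertices.copy()
    if jitter > 0:
        verts = verts + rng.uniform(-jitter, jitter, size=verts.shape)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return mesh


def _build_tooth_surface(cfg: AnatomyConfig, theta: np.ndarray, nz_root: int, nz_crown: int):
    """Closed tooth surface: apex cap + root cone + crown frustum + cusp cap."""
    n = len(theta)
    z_root = np.linspace(-cfg.root_length, 0.0, nz_root)
    z_crown = np.linspace(0.0, cfg.crown_height, nz_crown)[1:]
    rings = []
    for z in z_root:
        a, b = cfg.root_semiaxes(np.array(z))
        rings.append(_ring(float(a), float(b), float(z), theta))
    for z in z_crown:
        a, b = cfg.crown_semiaxes(np.array(z))
        rings.append(_ring(float(a), float(b), float(z), theta))
    verts = np.vstack(rings)
    faces = [_tube_faces(len(rings), n)]
    apex = len(verts)
    verts = np.vstack([verts, [[0.0, 0.0, -cfg.root_length]]])
    faces.append(_fan_faces(apex, 0, n, flip=True))
    cusp = len(verts)
    verts = np.vstack([verts, [[0.0, 0.0, cfg.crown_height]]])
    faces.append(_fan_faces(cusp, (len(rings) - 1) * n, n))
    return verts, np.vstack(faces)


def _build_pdl_surface(cfg: AnatomyConfig, theta: np.ndarray, nz: int):
    """Closed PDL shell: root (inner) + offset socket (outer) + cervical rim + caps."""
    n = len(theta)
    t = cfg.pdl_thickness
    z_levels = np.linspace(-cfg.root_length, 0.0, nz)
    inner = []
    outer = []
    for z in z_levels:
        a, b = cfg.root_semiaxes(np.array(z))
        inner.append(_ring(float(a), float(b), float(z), theta))
        outer.append(_ring(float(a) + t, float(b) + t, float(z), theta))
    verts = np.vstack(inner + outer)
    n_in = nz * n
    faces = [
        _tube_faces(nz, n, offset=0, flip=True),  # inner surface faces inward
        _tube_faces(nz, n, offset=n_in),
        _annulus_faces(inner_start=(nz - 1) * n, outer_start=n_in + (nz - 1) * n, n_theta=n),
    ]
    apex_in = len(verts)
    verts = np.vstack([verts, [[0.0, 0.0, -cfg.root_length]]])
    faces.append(_fan_faces(apex_in, 0, n))
    apex_out = len(verts)
    verts = np.vstack([verts, [[0.0, 0.0, -cfg.root_length - t]]])
    faces.append(_fan_faces(apex_out, n_in, n, flip=True))
    return verts, np.vstack(faces)


def _build_bone_surface(cfg: AnatomyConfig, pose: RigidTransform, theta: np.ndarray, nz: int):
    """Closed bone block with the socket carved out of the top face.

    The outer side wall is the prism through the wall intersection points of
    the n_theta circumferential directions, so wall vertices lie exactly on
    the block's rectangular faces.
    """
    n = len(theta)
    t = cfg.pdl_thickness
    hx, hy, bz = cfg.bone_block[0] / 2, cfg.bone_block[1] / 2, cfg.bone_block[2]
    # socket surface = PDL outer, posed into the model frame
    z_levels = np.linspace(-cfg.root_length, 0.0, nz)
    socket = []
    for z in z_levels:
        a, b = cfg.root_semiaxes(np.array(z))
        socket.append(pose.apply(_ring(float(a) + t, float(b) + t, float(z), theta)))
    verts = np.vstack(socket)
    faces = [_tube_faces(nz, n, flip=True)]
    apex = len(verts)
    verts = np.vstack([verts, pose.apply(np.array([0.0, 0.0, -cfg.root_length - t]))[None, :]])
    faces.append(_fan_faces(apex, 0, n))

    axis_xy = pose.apply(np.zeros(3))[:2]
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    rw = _wall_radius(cfg, axis_xy, dirs)
    wall_xy = axis_xy + dirs * rw[:, None]
    top_wall = len(verts)
    verts = np.vstack([verts, np.column_stack([wall_xy, np.zeros(n)])])
    # top annulus between socket rim (last socket ring) and the wall ring
    rim_start = (nz - 1) * n
    faces.append(_annulus_faces(inner_start=rim_start, outer_start=top_wall, n_theta=n))
    bot_wall = len(verts)
    verts = np.vstack([verts, np.column_stack([wall_xy, np.full(n, -bz)])])
    for i in range(n):
        j = (i + 1) % n
        faces.append(np.array([[top_wall + i, bot_wall + j, top_wall + j],
                               [top_wall + i, bot_wall + i, bot_wall + j]]))
    bot_center = len(verts)
    verts = np.vstack([verts, [[axis_xy[0], axis_xy[1], -bz]]])
    faces.append(_fan_faces(bot_center, bot_wall, n, flip=True))
    return verts, np.vstack(faces)


def build_model(config: AnatomyConfig, pose: RigidTransform | None = None) -> AnatomyModel:
    """Generate the synthetic anatomy.

    Deterministic for a given (config, pose): `random_seed` drives only a
    sub-micrometre jitter of the export-surface vertices, emulating scanner
    noise without moving any interface by more than 0.5 um.
    """
    pose = pose or RigidTransform.identity()
    rng = np.random.default_rng(config.random_seed)
    n = config.surface_resolution
    theta = (np.arange(n) + 0.5) * (2 * np.pi / n)

    nz_root = max(8, n // 4)
    nz_crown = max(5, n // 8)
    jitter = 5e-4  # mm

    tooth_v, tooth_f = _build_tooth_surface(config, theta, nz_root, nz_crown)
    pdl_v, pdl_f = _build_pdl_surface(config, theta, nz_root)
    bone_v, bone_f = _build_bone_surface(config, pose, theta, nz_root)

    surfaces = {
        "tooth": _close_mesh(pose.apply(tooth_v), tooth_f, jitter, rng),
        "pdl": _close_mesh(pose.apply(pdl_v), pdl_f, jitter, rng),
        "bone": _close_mesh(bone_v, bone_f, jitter, rng),
    }
    declared = {name: len(mesh.faces) for name, mesh in surfaces.items()}

    L = config.root_length
    a1, _ = config.root_semiaxes(np.array(-L / 3.0))
    a2, _ = config.root_semiaxes(np.array(-2.0 * L / 3.0))
    landmarks = LandmarkSet(
        C1D=pose.apply(np.array([float(a1), 0.0, -L / 3.0])),
        C2D=pose.apply(np.array([float(a2), 0.0, -2.0 * L / 3.0])),
        C1M=pose.apply(np.array([-float(a1), 0.0, -L / 3.0])),
    )

    zb = config.bracket_height_fraction * config.crown_height
    _, bb = config.crown_semiaxes(np.array(zb))
    bracket = pose.apply(np.array([0.0, float(bb) + config.bracket_offset, zb]))

    # palatal patch: crown-surface points on the palatal side (y < 0), a
    # stable reference for serial superimposition
    z_patch = np.linspace(0.15, 0.85, 5) * config.crown_height
    th_patch = np.linspace(-2.6, -0.6, 7)
    patch = []
    for z in z_patch:
        a, b = config.crown_semiaxes(np.array(z))
        patch.append(np.column_stack([
            float(a) * np.cos(th_patch), float(b) * np.sin(th_patch), np.full_like(th_patch, z)
        ]))
    palatal = pose.apply(np.vstack(patch))

    return AnatomyModel(
        config=config,
        pose=pose,
        surfaces=surfaces,
        landmark_set=landmarks,
        bracket_point=bracket,
        tad_point=np.asarray(config.tad_position, dtype=float),
        palatal_reference_patch=palatal,
        declared_facet_counts=declared,
    )


# -- STL I/O ------------------------------------------------------------------


def export_stl(model: AnatomyModel, directory: str | Path, binary: bool = True) -> dict[str, Path]:
    """Write one STL per region surface plus a JSON sidecar of key points.

    Returns the mapping region -> written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    ext = "stl"
    for name, mesh in model.surfaces.items():
        path = directory / f"{name}.{ext}"
        mesh.export(path, file_type="stl" if binary else "stl_ascii")
        written[name] = path
    sidecar = {
        "landmarks": {k: v.tolist() for k, v in model.landmark_set.as_dict().items()},
        "bracket_point": model.bracket_point.tolist(),
        "tad_point": model.tad_point.tolist(),
    }
    (directory / "points.json").write_text(json.dumps(sidecar, indent=2))
    written["points"] = directory / "points.json"
    return written


def _validate_binary_stl(path: Path) -> None:
    data = path.read_bytes()
    if len(data) >= 5 and data[:5] == b"solid" and b"facet" in data[:1024]:
        return  # ASCII STL; leave detailed parsing to trimesh
    if len(data) < 84:
        raise StlParseError("binary STL truncated before facet count", byte_offset=len(data))
    (n_facets,) = struct.unpack("<I", data[80:84])
    expected = 84 + 50 * n_facets
    if len(data) != expected:
        raise StlParseError(
            f"binary STL declares {n_facets} facets ({expected} bytes) but file has {len(data)}",
            byte_offset=min(len(data), expected),
        )


def import_stl(path: str | Path) -> trimesh.Trimesh:
    """Load a single STL surface, validating binary framing first."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_binary_stl(path)
    mesh = trimesh.load_mesh(path, file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise StlParseError("STL contained no facets", byte_offset=0)
    return mesh
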