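"""Procedural 3D virtual cotton plant.

Builds a parameterized plant — main stem of 20 segments, straight fruiting
branches on nodes 5-20, petioles and leaf blades of three shape classes
(ovate / 3-lobed / 5-lobed at 20/55/25% of the canopy) — as triangle
meshes in millimetres, z up, with every leaf labelled by canopy layer
(lower 0-50 cm, middle 50-90 cm, upper 90-130 cm by attachment height).

Leaf blade outlines are star-shaped polar curves scaled exactly to the
target planform (windward) area, so the fan triangulation from the origin
is always valid:

    ovate       r(phi) = R (1 + 0.55 cos phi)        (egg curve)
    three_lobed r(phi) = R (1 + 0.40 cos 3 phi)
    five_lobed  r(phi) = R (1 + 0.35 cos 5 phi)

The petiole joins the outline at phi = pi (the basal sinus).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "LeafTemplate",
    "PlantSpec",
    "Leaf",
    "PlantModel",
    "LEAF_KINDS",
    "PAPER_LEAF_AREAS",
    "make_leaf_template",
    "allocate_leaf_kinds",
    "generate_plant",
    "assign_layers",
    "export_mesh",
    "mesh_area",
]

LEAF_KINDS = ("ovate", "three_lobed", "five_lobed")

#: windward (planform) areas of the three leaf classes, mm^2
PAPER_LEAF_AREAS = {"ovate": 4206.25, "three_lobed": 7859.10, "five_lobed": 9823.00}

_LOBE_PARAMS = {"ovate": (1, 0.55), "three_lobed": (3, 0.40), "five_lobed": (5, 0.35)}

LAYER_NAMES_3 = ("lower", "middle", "upper")


def shoelace_area(outline) -> float:
    """Signed-magnitude polygon area of a closed 2D outline (shoelace)."""
    p = np.asarray(outline, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class LeafTemplate:
    """Flat 2D leaf blade outline at exact target area, petiole attachment
    on the outline."""

    kind: str
    outline: np.ndarray        # (n, 2), mm, implicitly closed
    target_area: float         # mm^2
    attach_point: np.ndarray   # (2,), on the outline

    def to_mesh(self) -> trimesh.Trimesh:
        """Fan-triangulate from the origin (interior by construction)."""
        n = len(self.outline)
        verts = np.zeros((n + 1, 3))
        verts[1:, :2] = self.outline
        faces = np.array([[0, 1 + i, 1 + (i + 1) % n] for i in range(n)])
        return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def make_leaf_template(kind: str, target_area: float, n_points: int = 128) -> LeafTemplate:
    """Leaf outline of the given shape class scaled to ``target_area`` mm^2.

    The shape family is fixed per class; only the overall scale changes,
    so the polygon area equals the target exactly (up to round-off).
    """
    if kind not in LEAF_KINDS:
        raise ValueError(f"unknown leaf kind {kind!r}; expected one of {LEAF_KINDS}")
    if not target_area > 0:
        raise ValueError("target_area must be positive")
    k, amp = _LOBE_PARAMS[kind]
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = 1.0 + amp * np.cos(k * phi)
    outline = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    scale = np.sqrt(target_area / shoelace_area(outline))
    outline *= scale
    i_attach = int(np.argmin(np.abs(phi - np.pi)))
    return LeafTemplate(kind=kind, outline=outline, target_area=float(target_area),
                        attach_point=outline[i_attach].copy())


def allocate_leaf_kinds(n: int, fractions: dict) -> dict:
    """Integer leaf counts per kind by largest-remainder rounding.

    Realized counts differ from n * fraction by less than 1.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    kinds = [k for k in LEAF_KINDS if k in fractions]
    quotas = np.array([n * fractions[k] for k in kinds])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return dict(zip(kinds, (int(c) for c in counts)))


@dataclass
class PlantSpec:
    """Phenotypic parameters of the virtual plant (lengths in the units noted)."""

    height: float = 130.0                       # cm
    n_stem_segments: int = 20
    fruiting_node_range: tuple = (5, 20)        # inclusive stem node indices
    leaf_type_fractions: dict = field(default_factory=lambda: {
        "ovate": 0.20, "three_lobed": 0.55, "five_lobed": 0.25})
    leaf_areas: dict = field(default_factory=lambda: dict(PAPER_LEAF_AREAS))  # mm^2
    layer_bounds: tuple = (0.0, 50.0, 90.0, 130.0)  # cm
    leaves_per_branch: int = 3
    n_leaves: int | None = None                 # override total (spread over branches)
    branch_length_base: float = 260.0           # mm, at the lowest fruiting node
    branch_length_top: float = 130.0            # mm, at the top node
    branch_radius: float = 4.0                  # mm
    stem_radius: float = 8.0                    # mm
    petiole_length_mean: float = 60.0           # mm
    petiole_length_sd: float = 8.0              # mm
    petiole_radius: float = 1.5                 # mm
    petiole_pitch_deg: float = -5.0             # droop below horizontal
    blade_tilt_sd_deg: float = 5.0              # random tilt of the blade plane
    azimuth_step_deg: float = 137.5             # alternate-spiral phyllotaxy
    azimuth_jitter_deg: float = 10.0
    leaf_outline_points: int = 128              # blade outline resolution
    rng_seed: int = 0

    def __post_init__(self):
        if abs(sum(self.leaf_type_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("leaf_type_fractions must sum to 1")
        if not all(b < a for b, a in zip(self.layer_bounds, self.layer_bounds[1:])):
            raise ValueError("layer_bounds must be strictly increasing")
        lo, hi = self.fruiting_node_range
        if not (1 <= lo <= hi <= self.n_stem_segments):
            raise ValueError("fruiting_node_range outside [1, n_stem_segments]")
        if self.branch_length_base <= 0 or self.branch_length_top <= 0:
            raise ValueError("branch lengths must be positive")


@dataclass
class Leaf:
    mesh: trimesh.Trimesh
    kind: str
    layer_id: str
    attach_point: np.ndarray   # (3,), mm
    stem_node: int

    @property
    def attach_height(self) -> float:
        """Attachment height above the root, mm."""
        return float(self.attach_point[2])


@dataclass
class PlantModel:
    stem_mesh: trimesh.Trimesh
    branch_meshes: list
    petiole_meshes: list
    leaves: list
    root_position: np.ndarray
    spec: PlantSpec

    def all_meshes(self):
        return ([self.stem_mesh] + self.branch_meshes + self.petiole_meshes
                + [lf.mesh for lf in self.leaves])

    def leaf_meshes(self):
        return [lf.mesh for lf in self.leaves]

    @property
    def bounding_box_height(self) -> float:
        """z extent of the whole plant, mm."""
        vs = np.vstack([m.vertices for m in self.all_meshes()])
        return float(vs[:, 2].max() - vs[:, 2].min())


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_axis(axis, a):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return trimesh.transformations.rotation_matrix(a, axis)[:3, :3]


def _cylinder(p0, p1, radius, sections=10) -> trimesh.Trimesh:
    """Straight cylinder between two 3D points (deterministic mesh)."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    vec = p1 - p0
    length = np.linalg.norm(vec)
    if length <= 0:
        raise ValueError("zero-length cylinder (infeasible geometry)")
    mesh = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    mesh.apply_translation([0, 0, length / 2.0])
    # rotate +z onto vec
    z = np.array([0.0, 0.0, 1.0])
    d = vec / length
    v = np.cross(z, d)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if d[2] > 0 else _rot_axis([1, 0, 0], np.pi)
    else:
        rot = _rot_axis(v, np.arccos(np.clip(np.dot(z, d), -1, 1)))
    mesh.vertices = mesh.vertices @ rot.T + p0
    return mesh


def _layer_label(height_mm: float, bounds_cm) -> str:
    """Half-open [lo, hi) intervals by attachment height; top interval closed."""
    b = np.asarray(bounds_cm, float) * 10.0  # cm -> mm
    if height_mm < b[0] or height_mm > b[-1]:
        raise ValueError(f"attachment height {height_mm} mm outside layer bounds {bounds_cm} cm")
    idx = min(int(np.searchsorted(b, height_mm, side="right")) - 1, len(b) - 2)
    names = LAYER_NAMES_3 if len(b) == 4 else tuple(f"band_{i}" for i in range(len(b) - 1))
    return names[idx]


def generate_plant(spec: PlantSpec) -> PlantModel:
    """Generate the full plant model; deterministic for a fixed ``rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    h_mm = spec.height * 10.0
    seg = h_mm / spec.n_stem_segments
    stem = _cylinder([0, 0, 0], [0, 0, h_mm], spec.stem_radius, sections=12)

    lo, hi = spec.fruiting_node_range
    nodes = list(range(lo, hi + 1))
    n_branches = len(nodes)

    # leaf schedule: per-branch counts, then kind assignment by largest remainder
    if spec.n_leaves is None:
        per_branch = [spec.leaves_per_branch] * n_branches
    else:
        # spread the requested total evenly along the stem
        host = np.floor(np.arange(spec.n_leaves) * n_branches
                        / spec.n_leaves).astype(int)
        per_branch = np.bincount(host, minlength=n_branches).tolist()
    n_total = sum(per_branch)
    counts = allocate_leaf_kinds(n_total, spec.leaf_type_fractions)
    kind_pool = [k for k in LEAF_KINDS for _ in range(counts.get(k, 0))]
    kind_pool = [kind_pool[i] for i in rng.permutation(n_total)]

    templates = {k: make_leaf_template(k, spec.leaf_areas[k],
                                       n_points=spec.leaf_outline_points)
                 for k in LEAF_KINDS}

    branches, petioles, leaves = [], [], []
    i_leaf = 0
    for i, node in enumerate(nodes):
        z = (node - 0.5) * seg  # branch inserted mid-segment, below the stem tip
        t = i / max(n_branches - 1, 1)
        length = spec.branch_length_base * (1 - t) + spec.branch_length_top * t
        azim = np.deg2rad(spec.azimuth_step_deg * i
                          + rng.uniform(-spec.azimuth_jitter_deg, spec.azimuth_jitter_deg))
        d = np.array([np.cos(azim), np.sin(azim), 0.0])
        p0 = d * spec.stem_radius + [0, 0, z]
        p1 = p0 + d * length
        branches.append(_cylinder(p0, p1, spec.branch_radius))

        n_lv = per_branch[i]
        for j in range(1, n_lv + 1):
            # equal internode spacing along the branch
            base = p0 + d * (length * j / n_lv)
            pet_az = azim + np.deg2rad(rng.uniform(-60.0, 60.0))
            pitch = np.deg2rad(spec.petiole_pitch_deg + rng.uniform(-3.0, 3.0))
            pd = np.array([np.cos(pet_az) * np.cos(pitch),
                           np.sin(pet_az) * np.cos(pitch),
                           np.sin(pitch)])
            plen = max(rng.normal(spec.petiole_length_mean, spec.petiole_length_sd), 5.0)
            tip = base + pd * plen
            petioles.append(_cylinder(base, tip, spec.petiole_radius, sections=8))

            kind = kind_pool[i_leaf]
            i_leaf += 1
            tpl = templates[kind]
            blade = tpl.to_mesh()
            # orient: outline +x axis (away from the basal attachment) along
            # the petiole azimuth, then a small random tilt of the blade plane
            rot = _rot_z(pet_az)
            tilt_axis = np.array([np.cos(pet_az + np.pi / 2),
                                  np.sin(pet_az + np.pi / 2), 0.0])
            tilt = np.deg2rad(rng.normal(0.0, spec.blade_tilt_sd_deg))
            rot = _rot_axis(tilt_axis, tilt) @ rot
            attach3 = rot @ np.array([tpl.attach_point[0], tpl.attach_point[1], 0.0])
            blade.vertices = blade.vertices @ rot.T + (tip - attach3)
            leaves.append(Leaf(mesh=blade, kind=kind,
                               layer_id=_layer_label(tip[2], spec.layer_bounds),
                               attach_point=tip.copy(), stem_node=node))

    return PlantModel(stem_mesh=stem, branch_meshes=branches,
                      petiole_meshes=petioles, leaves=leaves,
                      root_position=np.zeros(3), spec=spec)


def assign_layers(plant: PlantModel, layer_bounds) -> PlantModel:
    """Re-label every leaf by its attachment height (bounds in cm).

    Intervals are half-open [lo, hi); the top interval is closed.  A leaf
    attached outside [min, max] raises ``ValueError``.
    """
    b = tuple(layer_bounds)
    if not all(x < y for x, y in zip(b, b[1:])):
        raise ValueError("layer bounds must be strictly increasing")
    for lf in plant.leaves:
        lf.layer_id = _layer_label(lf.attach_height, b)
    return plant


def mesh_area(mesh) -> float:
    """Total triangle area of a mesh (mm^2 for plant meshes)."""
    if isinstance(mesh, trimesh.Trimesh):
        v, fcs = mesh.vertices, mesh.faces
    else:
        v, fcs = mesh
        v, fcs = np.asarray(v, float), np.asarray(fcs)
    cross = np.cross(v[fcs[:, 1]] - v[fcs[:, 0]], v[fcs[:, 2]] - v[fcs[:, 0]])
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    if area == 0.0:
        warnings.warn("degenerate mesh: total area is zero")
    return float(area)


def export_mesh(plant_or_mesh, path, file_format: str | None = None):
    """Export a plant (all parts concatenated) or a single mesh as STL/OBJ."""
    if isinstance(plant_or_mesh, PlantModel):
        mesh = trimesh.util.concatenate(plant_or_mesh.all_meshes())
    else:
        mesh = plant_or_mesh
    path = str(path)
    if file_format is None:
        file_format = path.rsplit(".", 1)[-1].lower()
    if file_format.lower() not in ("stl", "obj"):
        raise ValueError(f"unsupported mesh format {file_format!r}")
    mesh.export(path, file_type=file_format.lower())
    return path
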