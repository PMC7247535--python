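"""Planar mass-spring-damper mesh construction.

A planar multibody brain model lives in one anatomic plane (coronal,
sagittal or axial).  Brain tissue is lumped into point masses placed on a
square grid clipped to a closed outline (default: an ellipse standing in
for the brain cross-section).  Springs connect 4-neighbourhood grid
adjacencies; a ring of massless skull nodes on the outline drives the
model kinematically, each tethered to its nearest brain node by a single
spring.  Triads of adjacent brain nodes form triangular elements on which
finite strain is evaluated.

Units: metres, kilograms, newtons per metre.  Coordinates are 2-D
Cartesian with the origin at the outline centre; positive rotation is
counterclockwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

PLANE_IDS = ("coronal", "sagittal", "axial")

#: Placeholder spring stiffness (N/m) assigned before calibration; the
#: midpoint-ish value of the 2000-70000 N/m search range on a log scale.
DEFAULT_STIFFNESS = 12_000.0


class MeshError(ValueError):
    """Base class for mesh construction/validation failures."""


class DegenerateMeshError(MeshError):
    """Raised when the outline admits fewer than 4 interior brain nodes."""


class MeshFormatError(MeshError):
    """Raised when a mesh file is malformed; message names the offending field."""


@dataclass(frozen=True)
class PlaneSpec:
    """Geometry and inertia specification for one anatomic plane.

    Parameters
    ----------
    plane_id:
        One of ``coronal``, ``sagittal``, ``axial``.
    semi_axes:
        Ellipse semi-axes (a, b) in metres.  Ignored when ``outline`` is
        given.
    grid_spacing:
        Square-grid spacing for brain-node placement, metres.
    total_mass:
        Total brain mass lumped into the plane, kg.
    n_skull_nodes:
        Number of kinematically driven skull nodes, equally spaced by arc
        length along the outline.
    outline:
        Optional (n, 2) closed polyline overriding the ellipse.
    """

    plane_id: str
    semi_axes: tuple[float, float] = (0.07, 0.065)
    grid_spacing: float = 0.0265
    total_mass: float = 1.0
    n_skull_nodes: int = 8
    outline: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.plane_id not in PLANE_IDS:
            raise MeshError(f"unknown plane_id {self.plane_id!r}")
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise MeshError("semi_axes must be positive")
        if self.grid_spacing <= 0:
            raise MeshError("grid_spacing must be positive")
        if self.total_mass <= 0:
            raise MeshError("total_mass must be positive")
        if self.n_skull_nodes < 3:
            raise MeshError("n_skull_nodes must be >= 3")

    def outline_polygon(self, n_points: int = 256) -> Polygon:
        """Return the outline as a shapely polygon (ellipse discretised)."""
        if self.outline is not None:
            return Polygon(self.outline)
        t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
        a, b = self.semi_axes
        return Polygon(np.column_stack([a * np.cos(t), b * np.sin(t)]))


# Per-plane defaults.  Semi-axes are parametric placeholders (the source
# anatomy is proprietary); spacing is tuned so that 19-20 brain nodes fall
# inside each outline, matching the coarse-element count the model targets.
DEFAULT_PLANE_SPECS: dict[str, PlaneSpec] = {
    "coronal": PlaneSpec("coronal", semi_axes=(0.070, 0.065), grid_spacing=0.0265),
    "sagittal": PlaneSpec("sagittal", semi_axes=(0.085, 0.065), grid_spacing=0.0295),
    "axial": PlaneSpec("axial", semi_axes=(0.085, 0.070), grid_spacing=0.0305),
}


@dataclass
class Node:
    id: int
    role: str  # "brain" | "skull"
    ref_position: np.ndarray  # shape (2,), metres
    mass: float | None = None  # kg; None for skull nodes (kinematically driven)


@dataclass
class Spring:
    id: int
    node_a: int
    node_b: int
    stiffness: float  # N/m
    rest_length: float  # m, equals reference separation (zero pre-strain)


@dataclass
class TriangleElement:
    id: int
    vertices: tuple[int, int, int]  # brain node ids, counterclockwise
    ref_side_lengths: np.ndarray  # (3,)
    ref_area: float


@dataclass
class PlanarMesh:
    """A full planar multibody model: nodes, springs and strain triangles."""

    spec: PlaneSpec
    nodes: list[Node]
    springs: list[Spring]
    triangles: list[TriangleElement]

    # -- cached array views -------------------------------------------------
    @property
    def brain_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.role == "brain"]

    @property
    def skull_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.role == "skull"]

    @property
    def brain_ids(self) -> np.ndarray:
        return np.array([n.id for n in self.brain_nodes], dtype=int)

    @property
    def skull_ids(self) -> np.ndarray:
        return np.array([n.id for n in self.skull_nodes], dtype=int)

    @property
    def brain_positions(self) -> np.ndarray:
        return np.array([n.ref_position for n in self.brain_nodes], dtype=float)

    @property
    def skull_positions(self) -> np.ndarray:
        return np.array([n.ref_position for n in self.skull_nodes], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([n.mass for n in self.brain_nodes], dtype=float)

    @property
    def n_brain(self) -> int:
        return len(self.brain_nodes)

    @property
    def centroid(self) -> np.ndarray:
        return mesh_centroid(self)

    @property
    def subdomains(self) -> dict[int, list[int]]:
        """Map brain-node id -> incident spring ids."""
        out: dict[int, list[int]] = {n.id: [] for n in self.brain_nodes}
        for s in self.springs:
            for end in (s.node_a, s.node_b):
                if end in out:
                    out[end].append(s.id)
        return out

    def node_by_id(self, node_id: int) -> Node:
        return self.nodes[node_id]

    def spring_by_id(self, spring_id: int) -> Spring:
        return self.springs[spring_id]

    def set_stiffness(self, values: Mapping[int, float] | np.ndarray) -> None:
        """Assign spring stiffnesses from a spring-id map or dense array."""
        if isinstance(values, Mapping):
            items = values.items()
        else:
            items = enumerate(np.asarray(values, dtype=float))
        for sid, k in items:
            if k <= 0:
                raise MeshError(f"stiffness for spring {sid} must be > 0, got {k}")
            self.springs[sid].stiffness = float(k)

    def copy(self) -> "PlanarMesh":
        return PlanarMesh(
            spec=self.spec,
            nodes=[Node(n.id, n.role, n.ref_position.copy(), n.mass) for n in self.nodes],
            springs=[Spring(s.id, s.node_a, s.node_b, s.stiffness, s.rest_length) for s in self.springs],
            triangles=[
                TriangleElement(t.id, t.vertices, t.ref_side_lengths.copy(), t.ref_area)
                for t in self.triangles
            ],
        )

    def validate(self, strict: bool = True) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure.

        With ``strict=False`` the per-node spring-count and connectivity
        checks are skipped, which permits hand-built toy meshes (e.g. a
        single mass on a spring) used for dynamics verification.
        """
        ids = [n.id for n in self.nodes]
        if ids != list(range(len(self.nodes))):
            raise MeshError("node ids must be 0..n-1 in order")
        total = sum(n.mass for n in self.brain_nodes)
        if abs(total - self.spec.total_mass) > 1e-9:
            raise MeshError(
                f"brain-node masses sum to {total}, expected {self.spec.total_mass}"
            )
        brain = {n.id for n in self.brain_nodes}
        seen_pairs = set()
        for s in self.springs:
            if s.stiffness <= 0:
                raise MeshError(f"spring {s.id}: stiffness must be > 0")
            pair = frozenset((s.node_a, s.node_b))
            if pair in seen_pairs:
                raise MeshError(f"duplicate spring between {s.node_a} and {s.node_b}")
            seen_pairs.add(pair)
            ra = self.nodes[s.node_a].ref_position
            rb = self.nodes[s.node_b].ref_position
            if abs(np.linalg.norm(rb - ra) - s.rest_length) > 1e-9:
                raise MeshError(f"spring {s.id}: rest_length != reference separation")
        for t in self.triangles:
            if len(set(t.vertices)) != 3:
                raise MeshError(f"triangle {t.id}: vertices not distinct")
            if any(v not in brain for v in t.vertices):
                raise MeshError(f"triangle {t.id}: vertex is not a brain node")
            if t.ref_area <= 1e-8:
                raise MeshError(f"triangle {t.id}: reference area too small")
            if _signed_area(*(self.nodes[v].ref_position for v in t.vertices)) <= 0:
                raise MeshError(f"triangle {t.id}: orientation not counterclockwise")
        for n in self.skull_nodes:
            cnt = sum(1 for s in self.springs if n.id in (s.node_a, s.node_b))
            if cnt != 1:
                raise MeshError(f"skull node {n.id} has {cnt} springs, expected 1")
        if not strict:
            return
        bb = [(s.node_a, s.node_b) for s in self.springs if s.node_a in brain and s.node_b in brain]
        deg = {i: 0 for i in brain}
        for a, b in bb:
            deg[a] += 1
            deg[b] += 1
        for i, d in deg.items():
            if not 1 <= d <= 4:
                raise MeshError(f"brain node {i} has {d} brain-brain springs (expected 1-4)")
        if not _connected(brain, bb):
            raise MeshError("brain-brain spring graph is not connected")


def _signed_area(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    u, v = p1 - p0, p2 - p0
    return 0.5 * float(u[0] * v[1] - u[1] * v[0])


def _connected(nodes: set[int], edges: Iterable[tuple[int, int]]) -> bool:
    adj: dict[int, list[int]] = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    if not nodes:
        return True
    stack = [next(iter(nodes))]
    seen = set(stack)
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == nodes


def build_mesh(spec: PlaneSpec, stiffness: float = DEFAULT_STIFFNESS) -> PlanarMesh:
    """Construct the planar mesh for ``spec``.

    Brain nodes are grid points strictly inside the outline; each carries
    the mass of its Voronoi cell clipped to the outline (so the node
    masses tile the outline and sum exactly to ``total_mass``).  Springs
    connect 4-neighbourhood adjacencies; skull nodes are equally spaced
    on the outline, each tethered to its nearest brain node.  Every full
    interior grid cell is split into two counterclockwise triangles and
    each three-cornered boundary cell contributes one.
    """
    poly = spec.outline_polygon()
    h = spec.grid_spacing
    minx, miny, maxx, maxy = poly.bounds
    i_lo, i_hi = int(np.floor(minx / h)) - 1, int(np.ceil(maxx / h)) + 1
    j_lo, j_hi = int(np.floor(miny / h)) - 1, int(np.ceil(maxy / h)) + 1

    grid_index: dict[tuple[int, int], int] = {}
    nodes: list[Node] = []
    # Nodes sit at cell centres: ((i + 1/2) h, (j + 1/2) h).
    for j in range(j_lo, j_hi + 1):
        for i in range(i_lo, i_hi + 1):
            p = np.array([(i + 0.5) * h, (j + 0.5) * h])
            if poly.contains(Point(p)):
                grid_index[(i, j)] = len(nodes)
                nodes.append(Node(len(nodes), "brain", p))
    n_brain = len(nodes)
    if n_brain < 4:
        raise DegenerateMeshError(
            f"only {n_brain} brain nodes fit inside the outline (need >= 4)"
        )

    # Voronoi cell areas clipped to the outline -> node masses.
    pts = MultiPoint([Point(n.ref_position) for n in nodes])
    cells = voronoi_diagram(pts, envelope=poly.buffer(4 * h))
    areas = np.zeros(n_brain)
    for cell in cells.geoms:
        for k, n in enumerate(nodes):
            if cell.contains(Point(n.ref_position)):
                areas[k] = cell.intersection(poly).area
                break
    if np.any(areas <= 0):
        raise MeshError("failed to assign a Voronoi cell area to every brain node")
    masses = spec.total_mass * areas / areas.sum()
    for n, m in zip(nodes, masses):
        n.mass = float(m)

    # Brain-brain springs: 4-neighbourhood grid adjacency.
    springs: list[Spring] = []

    def _add_spring(a: int, b: int) -> None:
        ra, rb = nodes[a].ref_position, nodes[b].ref_position
        springs.append(Spring(len(springs), a, b, stiffness, float(np.linalg.norm(rb - ra))))

    for (i, j), a in grid_index.items():
        for di, dj in ((1, 0), (0, 1)):
            b = grid_index.get((i + di, j + dj))
            if b is not None:
                _add_spring(a, b)

    # Skull nodes equally spaced by arc length; one spring each to the
    # nearest brain node.
    ring = poly.exterior
    brain_xy = np.array([n.ref_position for n in nodes])
    for k in range(spec.n_skull_nodes):
        pt = ring.interpolate(ring.length * k / spec.n_skull_nodes)
        p = np.array([pt.x, pt.y])
        node = Node(len(nodes), "skull", p)
        nodes.append(node)
        nearest = int(np.argmin(np.linalg.norm(brain_xy - p, axis=1)))
        _add_spring(nearest, node.id)

    # Triangles from grid cells.
    triangles: list[TriangleElement] = []

    def _add_triangle(v: tuple[int, int, int]) -> None:
        p = [nodes[x].ref_position for x in v]
        if _signed_area(*p) < 0:
            v = (v[0], v[2], v[1])
            p = [nodes[x].ref_position for x in v]
        sides = np.array(
            [
                np.linalg.norm(p[1] - p[0]),
                np.linalg.norm(p[2] - p[1]),
                np.linalg.norm(p[0] - p[2]),
            ]
        )
        triangles.append(TriangleElement(len(triangles), v, sides, _signed_area(*p)))

    for (i, j) in list(grid_index):
        corners = [(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)]
        present = [c for c in corners if c in grid_index]
        if len(present) == 4:
            a, b, c, d = (grid_index[c] for c in corners)
            _add_triangle((a, b, c))
            _add_triangle((a, c, d))
        elif len(present) == 3:
            _add_triangle(tuple(grid_index[c] for c in present))

    mesh = PlanarMesh(spec=spec, nodes=nodes, springs=springs, triangles=triangles)
    mesh.validate()
    return mesh


def mesh_centroid(mesh: PlanarMesh) -> np.ndarray:
    """Mass-weighted centroid of the brain nodes (the rotation centre)."""
    m = mesh.masses
    return (m[:, None] * mesh.brain_positions).sum(axis=0) / m.sum()


# ---------------------------------------------------------------------------
# Mesh file I/O (JSON sections: spec, nodes, springs, triangles)
# ---------------------------------------------------------------------------

def write_mesh(mesh: PlanarMesh, path: str | Path) -> None:
    spec = mesh.spec
    doc = {
        "spec": {
            "plane_id": spec.plane_id,
            "semi_axes": list(spec.semi_axes),
            "grid_spacing": spec.grid_spacing,
            "total_mass": spec.total_mass,
            "n_skull_nodes": spec.n_skull_nodes,
            "outline": [list(p) for p in spec.outline] if spec.outline else None,
        },
        "nodes": [
            [n.id, n.role, float(n.ref_position[0]), float(n.ref_position[1]), n.mass]
            for n in mesh.nodes
        ],
        "springs": [
            [s.id, s.node_a, s.node_b, s.stiffness, s.rest_length] for s in mesh.springs
        ],
        "triangles": [[t.id, *t.vertices] for t in mesh.triangles],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_mesh(path: str | Path) -> PlanarMesh:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MeshFormatError(f"not valid JSON: {exc}") from exc
    for block in ("spec", "nodes", "springs", "triangles"):
        if block not in doc:
            raise MeshFormatError(f"missing required block {block!r}")
    sd = doc["spec"]
    try:
        spec = PlaneSpec(
            plane_id=sd["plane_id"],
            semi_axes=tuple(sd["semi_axes"]),
            grid_spacing=sd["grid_spacing"],
            total_mass=sd["total_mass"],
            n_skull_nodes=sd["n_skull_nodes"],
            outline=tuple(tuple(p) for p in sd["outline"]) if sd.get("outline") else None,
        )
    except KeyError as exc:
        raise MeshFormatError(f"spec block missing field {exc.args[0]!r}") from exc
    nodes = []
    for row in doc["nodes"]:
        try:
            nid, role, x, y, mass = row
        except ValueError as exc:
            raise MeshFormatError(f"nodes row {row!r} malformed") from exc
        nodes.append(Node(nid, role, np.array([x, y], dtype=float), mass))
    springs = []
    for row in doc["springs"]:
        try:
            sid, a, b, k, L0 = row
        except ValueError as exc:
            raise MeshFormatError(f"springs row {row!r} malformed") from exc
        springs.append(Spring(sid, a, b, float(k), float(L0)))
    triangles = []
    for row in doc["triangles"]:
        try:
            tid, v0, v1, v2 = row
        except ValueError as exc:
            raise MeshFormatError(f"triangles row {row!r} malformed") from exc
        p = [nodes[v].ref_position for v in (v0, v1, v2)]
        sides = np.array(
            [
                np.linalg.norm(p[1] - p[0]),
                np.linalg.norm(p[2] - p[1]),
                np.linalg.norm(p[0] - p[2]),
            ]
        )
        triangles.append(TriangleElement(tid, (v0, v1, v2), sides, _signed_area(*p)))
    mesh = PlanarMesh(spec=spec, nodes=nodes, springs=springs, triangles=triangles)
    mesh.validate()
    return mesh
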