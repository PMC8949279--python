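"""Tetrahedral meshes: container, structured generators, quality checks.

Two programmatic fixtures cover everything the solver needs:

* a structured bar (each hexahedral cell split into six tetrahedra with the
  Kuhn scheme, so orientations are consistent), used for oracle tests and
  one-dimensional wave benchmarks;
* an ellipsoid approximating a cranium, built by radially mapping a
  structured cube mesh onto the unit ball and scaling by the semi-axes.  A
  surface shell on the impact-facing side can be tagged as an elastic
  "frontal_layer" (simplified skull); the interior is brain material.

Node sets carried by every mesh: ``contact_candidates`` (surface nodes that
may touch the obstacle), ``measurement_point`` (exactly one node — the
occipital point where acceleration is recorded) and optionally
``frontal_layer`` / ``fixed``.  Indexing is 0-based internally; format
writers convert at the boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "MeshGenerationError",
    "generate_bar_mesh",
    "generate_ellipsoid_mesh",
    "read_mesh",
    "write_mesh",
]

#: Material tag conventions used by the generators.
TAG_BULK = 1
TAG_FRONTAL_LAYER = 2

#: Generation-time quality gate: longest_edge^3 / (6*sqrt(2)*V), 1 for the
#: regular tetrahedron.  Degenerate slivers score in the thousands; stretched
#: structured bar cells legitimately reach ~100, hence the permissive default.
DEFAULT_MAX_ASPECT = 200.0


class MeshGenerationError(RuntimeError):
    """Raised when a requested mesh cannot be generated."""


@dataclass
class Mesh:
    """Tetrahedral mesh with named node sets and per-element material tags."""

    nodes: np.ndarray                      # (N, 3) float, metres
    tets: np.ndarray                       # (E, 4) int, positively oriented
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_tags: np.ndarray | None = None  # (E,) int

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.element_tags is None:
            self.element_tags = np.full(len(self.tets), TAG_BULK, dtype=np.int64)
        else:
            self.element_tags = np.asarray(self.element_tags, dtype=np.int64)
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}

    # -- basic queries -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def element_volumes(self) -> np.ndarray:
        """Signed volumes det([p1-p0, p2-p0, p3-p0]) / 6 per element."""
        p = self.nodes[self.tets]
        e = p[:, 1:] - p[:, :1]
        return np.linalg.det(e) / 6.0

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def edge_lengths(self) -> np.ndarray:
        """(E, 6) lengths of the six edges of each tetrahedron."""
        p = self.nodes[self.tets]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        return np.stack([np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in pairs], axis=1)

    def aspect_ratios(self) -> np.ndarray:
        """longest_edge^3 / (6*sqrt(2)*V); equals 1 for a regular tet."""
        V = self.element_volumes()
        lmax = self.edge_lengths().max(axis=1)
        return lmax**3 / (6.0 * np.sqrt(2.0) * V)

    def surface_faces(self) -> np.ndarray:
        """(F, 3) boundary triangles (faces owned by exactly one tet)."""
        faces = self.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def measurement_node(self) -> int:
        (idx,) = self.node_sets["measurement_point"]
        return int(idx)

    def copy(self) -> "Mesh":
        return Mesh(
            self.nodes.copy(),
            self.tets.copy(),
            {k: v.copy() for k, v in self.node_sets.items()},
            self.element_tags.copy(),
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (E, 4)")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= self.n_nodes):
            raise ValueError("connectivity index out of range")
        if len(self.element_tags) != self.n_elements:
            raise ValueError("element_tags length mismatch")
        for name, ids in self.node_sets.items():
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise ValueError(f"node set {name!r} references a node out of range")
        if "measurement_point" in self.node_sets and len(self.node_sets["measurement_point"]) != 1:
            raise ValueError("measurement_point set must contain exactly one node")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"element {bad} has non-positive volume {vols[bad]:.3e}")


# -- structured bar --------------------------------------------------------

def _kuhn_tets_for_cell(corner_ids: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Six positively oriented tetrahedra for one hexahedral cell.

    ``corner_ids`` indexes the 8 corners by bit pattern (ix, iy, iz).  Each
    permutation of the axes gives one simplex along the main diagonal; odd
    permutations get two vertices swapped to restore positive orientation.
    """
    tets = []
    for perm in itertools.permutations(range(3)):
        bits = [0, 0, 0]
        path = [tuple(bits)]
        for axis in perm:
            bits[axis] = 1
            path.append(tuple(bits))
        ids = [corner_ids[b[0], b[1], b[2]] for b in path]
        # parity of permutation: count inversions
        inversions = sum(
            1 for i in range(3) for j in range(i + 1, 3) if perm[i] > perm[j]
        )
        if inversions % 2 == 1:
            ids[2], ids[3] = ids[3], ids[2]
        tets.append(tuple(int(i) for i in ids))
    return tets


def _structured_tets(nx: int, ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-cube structured grid: normalised coords in [0,1]^3 and tets."""
    xs = np.linspace(0.0, 1.0, nx + 1)
    ys = np.linspace(0.0, 1.0, ny + 1)
    zs = np.linspace(0.0, 1.0, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    nid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corners = nid[i : i + 2, j : j + 2, k : k + 2]
                tets.extend(_kuhn_tets_for_cell(corners))
    return nodes, np.asarray(tets, dtype=np.int64)


def generate_bar_mesh(
    length: float,
    width: float,
    height: float,
    divisions: tuple[int, int, int],
    max_aspect: float = DEFAULT_MAX_ASPECT,
) -> Mesh:
    """Structured tetrahedral bar on [0,L] x [0,W] x [0,H].

    Node sets: ``contact_candidates`` is the face at x = 0 (minimum axial
    coordinate), ``measurement_point`` the node nearest the centre of the
    opposite face.  Generation is deterministic for fixed arguments.
    """
    if length <= 0 or width <= 0 or height <= 0:
        raise ValueError("bar dimensions must be positive")
    nx, ny, nz = (int(d) for d in divisions)
    if nx < 1 or ny < 1 or nz < 1:
        raise ValueError("division counts must be >= 1")
    nodes, tets = _structured_tets(nx, ny, nz)
    nodes = nodes * np.array([length, width, height])
    contact = np.flatnonzero(np.isclose(nodes[:, 0], 0.0))
    target = np.array([length, width / 2.0, height / 2.0])
    meas = int(np.argmin(np.linalg.norm(nodes - target, axis=1)))
    mesh = Mesh(
        nodes,
        tets,
        node_sets={
            "contact_candidates": contact,
            "measurement_point": np.array([meas]),
        },
    )
    mesh.validate()
    _check_quality(mesh, max_aspect)
    return mesh


# -- ellipsoid -------------------------------------------------------------

def _division_triple(target_element_count: int) -> tuple[int, int, int]:
    """Near-cubic division triple with 6*nx*ny*nz closest to the target."""
    prod_target = target_element_count / 6.0
    n0 = max(1, round(prod_target ** (1.0 / 3.0)))
    best = None
    for triple in itertools.product(range(max(1, n0 - 2), n0 + 3), repeat=3):
        count = 6 * triple[0] * triple[1] * triple[2]
        err = abs(count - target_element_count)
        spread = max(triple) - min(triple)
        cand = (err, spread, triple)
        if best is None or cand < best:
            best = cand
    err, _, triple = best
    if err > 0.25 * target_element_count:
        raise MeshGenerationError(
            f"cannot reach element count {target_element_count} within 25% with a "
            f"structured grid (closest: {6 * triple[0] * triple[1] * triple[2]})"
        )
    return tuple(sorted(triple, reverse=True))


def generate_ellipsoid_mesh(
    semi_axes: tuple[float, float, float],
    target_element_count: int,
    frontal_layer_thickness: float = 0.0,
    impact_direction: tuple[float, float, float] = (-1.0, 0.0, 0.0),
    max_aspect: float = DEFAULT_MAX_ASPECT,
) -> Mesh:
    """Solid ellipsoid mesh via the radial cube-to-ball map.

    A structured cube grid on [-1,1]^3 is split into tetrahedra and every
    node p mapped to p * max|p_i| / |p| (the cube surface lands on the unit
    sphere), then scaled by the semi-axes.  Elements whose centroid lies
    within ``frontal_layer_thickness`` of the surface on the impact-facing
    side are tagged as the elastic frontal (skull) layer.

    ``measurement_point`` is the surface node nearest the pole opposite the
    impact-facing pole (the occipital point); ``contact_candidates`` are the
    surface nodes on the impact-facing half.
    """
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    if target_element_count < 100:
        raise ValueError("target_element_count must be >= 100")
    if frontal_layer_thickness < 0:
        raise ValueError("frontal_layer_thickness must be non-negative")
    if frontal_layer_thickness >= min(a, b, c):
        raise ValueError("frontal layer thickness must be smaller than the smallest semi-axis")
    d_hat = np.asarray(impact_direction, dtype=float)
    nrm = np.linalg.norm(d_hat)
    if nrm == 0:
        raise ValueError("impact_direction must be non-zero")
    d_hat = d_hat / nrm

    nx, ny, nz = _division_triple(target_element_count)
    nodes01, tets = _structured_tets(nx, ny, nz)
    cube = 2.0 * nodes01 - 1.0  # [-1, 1]^3
    # smooth cube-to-ball ("spherified cube") map: the cube surface lands on
    # the unit sphere with far less cell distortion than radial projection
    x, y, z = cube[:, 0], cube[:, 1], cube[:, 2]
    ball = np.stack(
        [
            x * np.sqrt(1 - y**2 / 2 - z**2 / 2 + y**2 * z**2 / 3),
            y * np.sqrt(1 - z**2 / 2 - x**2 / 2 + z**2 * x**2 / 3),
            z * np.sqrt(1 - x**2 / 2 - y**2 / 2 + x**2 * y**2 / 3),
        ],
        axis=1,
    )
    nodes = ball * np.array([a, b, c])

    mesh = Mesh(nodes, tets)
    vols = mesh.element_volumes()
    if np.any(vols <= 0):
        raise MeshGenerationError(
            f"radial map inverted {int(np.sum(vols <= 0))} elements; refine the grid"
        )

    # frontal layer: distance to the surface measured along the ray from the
    # centre, front half only
    centroids = nodes[tets].mean(axis=1)
    rho = np.linalg.norm(centroids / np.array([a, b, c]), axis=1)
    rho = np.clip(rho, 1e-12, None)
    dist_to_surface = np.linalg.norm(centroids, axis=1) * (1.0 / rho - 1.0)
    front = centroids @ d_hat > 0
    tags = np.full(len(tets), TAG_BULK, dtype=np.int64)
    if frontal_layer_thickness > 0:
        tags[front & (dist_to_surface <= frontal_layer_thickness)] = TAG_FRONTAL_LAYER
    mesh.element_tags = tags

    surf_nodes = np.unique(mesh.surface_faces())
    front_nodes = surf_nodes[nodes[surf_nodes] @ d_hat > 0]
    # pole opposite the impact direction, on the ellipsoid surface: the ray
    # t*(-d_hat) meets the surface at t = 1/|d_hat / semi_axes|
    occipital_pole = -d_hat / np.linalg.norm(d_hat / np.array([a, b, c]))
    meas = int(surf_nodes[np.argmin(np.linalg.norm(nodes[surf_nodes] - occipital_pole, axis=1))])

    mesh.node_sets = {
        "contact_candidates": front_nodes,
        "measurement_point": np.array([meas]),
    }
    if frontal_layer_thickness > 0:
        mesh.node_sets["frontal_layer"] = np.unique(tets[tags == TAG_FRONTAL_LAYER])
    mesh.validate()
    _check_quality(mesh, max_aspect)
    return mesh


def _check_quality(mesh: Mesh, max_aspect: float) -> None:
    worst = float(mesh.aspect_ratios().max())
    if worst > max_aspect:
        raise MeshGenerationError(
            f"mesh quality gate failed: worst aspect ratio {worst:.2f} > {max_aspect}"
        )


# -- I/O dispatch ----------------------------------------------------------

def read_mesh(path, fmt: str | None = None) -> Mesh:
    """Read a mesh from Gmsh MSH 4.1 ("msh") or VTU XML ("vtu")."""
    from . import formats

    fmt = fmt or _infer_format(path)
    if fmt == "msh":
        return formats.read_msh(path)
    if fmt == "vtu":
        return formats.read_vtu(path)
    raise ValueError(f"unknown mesh format {fmt!r} (expected 'msh' or 'vtu')")


def write_mesh(mesh: Mesh, path, fmt: str | None = None) -> None:
    from . import formats

    fmt = fmt or _infer_format(path)
    if fmt == "msh":
        formats.write_msh(mesh, path)
    elif fmt == "vtu":
        formats.write_vtu(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (expected 'msh' or 'vtu')")


def _infer_format(path) -> str:
    s = str(path)
    if s.endswith(".msh"):
        return "msh"
    if s.endswith(".vtu"):
        return "vtu"
    raise ValueError(f"cannot infer mesh format from {s!r}")
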