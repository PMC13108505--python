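"""Spherical cortical geometry: meshes, regular SHT grids, parcellation, mappings.

Each cortical hemisphere is represented as a triangulated mesh on the unit
sphere (the inflated-surface convention) together with a physical radius in
millimetres.  The pseudospectral machinery operates on a separate *regular*
grid (Gauss--Legendre colatitudes x equispaced longitudes) on which spherical
harmonic transforms are exact for band-limited fields; mesh vertices are
related to grid nodes by nearest-neighbour assignment on the sphere.

Source ordering convention used throughout the package:
``[hemisphere-0 grid nodes, hemisphere-1 grid nodes, subcortical nodes]``,
with grid nodes flattened colatitude-major (the longitude index varies
fastest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Hemisphere",
    "SphericalBrain",
    "RegularSphericalGrid",
    "VertexToGridMap",
    "build_regular_grid",
    "map_mesh_to_grid",
    "vertex_areas",
    "region_average",
    "grid_region_labels",
    "icosphere",
    "read_mesh",
    "write_mesh",
    "read_labels",
    "write_labels",
    "read_parcellation",
    "write_parcellation",
]


@dataclass
class Hemisphere:
    """A single-hemisphere unit-sphere mesh with per-vertex region labels."""

    vertices: np.ndarray  # (n, 3) unit vectors
    triangles: np.ndarray  # (m, 3) int
    labels: np.ndarray  # (n,) int region ids

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        norms = np.linalg.norm(self.vertices, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("mesh vertices must lie on the unit sphere (|v| = 1)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")
        if len(self.labels) != len(self.vertices):
            raise ValueError("one region label per vertex required")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class SphericalBrain:
    """Two unit-sphere hemispheres, subcortical point nodes and a parcellation.

    Parameters
    ----------
    hemispheres:
        ``(left, right)`` :class:`Hemisphere` meshes.
    radius_mm:
        Physical sphere radius used for areas, distances and the local
        coupling kernel.  Default 100 mm.
    subcortical_regions:
        Region ids of subcortical point nodes, in source order.
    subcortical_positions_mm:
        ``(k, 3)`` positions of the subcortical nodes in millimetres.
    parcellation:
        Table with columns ``region_id, name, hemisphere, is_cortical``.
    """

    hemispheres: tuple[Hemisphere, Hemisphere]
    radius_mm: float = 100.0
    subcortical_regions: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    subcortical_positions_mm: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3))
    )
    parcellation: pd.DataFrame | None = None
    # 3D centres of the two hemisphere spheres; cortical positions in mm are
    # centre + radius_mm * unit vertex.  Defaults place both at the origin.
    hemisphere_centers_mm: np.ndarray = field(default_factory=lambda: np.zeros((2, 3)))

    def __post_init__(self) -> None:
        self.subcortical_regions = np.asarray(self.subcortical_regions, dtype=int)
        self.subcortical_positions_mm = np.asarray(
            self.subcortical_positions_mm, dtype=float
        ).reshape(-1, 3)
        if len(self.subcortical_regions) != len(self.subcortical_positions_mm):
            raise ValueError("subcortical regions and positions must align")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    @property
    def n_regions(self) -> int:
        if self.parcellation is not None:
            return len(self.parcellation)
        labels = np.concatenate(
            [h.labels for h in self.hemispheres] + [self.subcortical_regions]
        )
        return int(labels.max()) + 1 if labels.size else 0

    @property
    def n_subcortical(self) -> int:
        return len(self.subcortical_regions)


@dataclass
class RegularSphericalGrid:
    """Quadrature grid on which degree-``lmax`` SHTs are exact.

    Colatitudes are the ``lmax + 1`` Gauss--Legendre nodes mapped through
    ``theta = arccos(x)`` (sorted increasing in ``(0, pi)``); longitudes are
    ``2 lmax + 2`` equispaced points in ``[0, 2 pi)``.  Nodes are flattened
    colatitude-major.
    """

    lmax: int
    colatitudes: np.ndarray
    longitudes: np.ndarray
    colatitude_weights: np.ndarray  # Gauss-Legendre weights (in cos(theta))

    @property
    def n_colat(self) -> int:
        return len(self.colatitudes)

    @property
    def n_lon(self) -> int:
        return len(self.longitudes)

    @property
    def n_nodes(self) -> int:
        return self.n_colat * self.n_lon

    def node_angles(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (theta, phi) for every grid node."""
        th = np.repeat(self.colatitudes, self.n_lon)
        ph = np.tile(self.longitudes, self.n_colat)
        return th, ph

    def unit_vectors(self) -> np.ndarray:
        th, ph = self.node_angles()
        return np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )

    def quadrature_weights(self) -> np.ndarray:
        """Per-node solid-angle quadrature weights (sum to 4 pi)."""
        w = np.repeat(self.colatitude_weights, self.n_lon)
        return w * (2.0 * np.pi / self.n_lon)


@dataclass
class VertexToGridMap:
    """Nearest-grid-node assignment for every mesh vertex (one hemisphere)."""

    forward: np.ndarray  # (n_mesh,) grid-node index per mesh vertex
    n_grid: int

    def inverse(self) -> list[np.ndarray]:
        """Grid node -> array of mesh vertex indices mapped to it."""
        order = np.argsort(self.forward, kind="stable")
        sorted_fwd = self.forward[order]
        bounds = np.searchsorted(sorted_fwd, np.arange(self.n_grid + 1))
        return [order[bounds[i] : bounds[i + 1]] for i in range(self.n_grid)]


def build_regular_grid(max_degree: int) -> RegularSphericalGrid:
    """Build the Gauss--Legendre x equispaced grid for degree-``max_degree`` SHTs.

    The Gauss--Legendre rule with ``L + 1`` nodes integrates polynomials in
    ``cos(theta)`` up to degree ``2L + 1`` exactly, and ``2L + 2`` equispaced
    longitudes resolve Fourier orders up to ``2L``; together these make the
    forward transform of any band-limited (degree <= L) field exact.
    """
    if not isinstance(max_degree, (int, np.integer)) or max_degree < 2:
        raise ValueError("max_degree must be an integer >= 2")
    x, w = np.polynomial.legendre.leggauss(max_degree + 1)
    theta = np.arccos(x)[::-1].copy()  # increasing in (0, pi)
    weights = w[::-1].copy()
    n_lon = 2 * max_degree + 2
    phi = np.arange(n_lon) * (2.0 * np.pi / n_lon)
    return RegularSphericalGrid(
        lmax=int(max_degree),
        colatitudes=theta,
        longitudes=phi,
        colatitude_weights=weights,
    )


def map_mesh_to_grid(
    vertices: np.ndarray | Hemisphere, grid: RegularSphericalGrid
) -> VertexToGridMap:
    """Assign each mesh vertex to its nearest regular-grid node.

    Nearness is great-circle distance on the unit sphere, i.e. the node with
    the largest dot product; ties resolve to the smallest grid-node index
    (``argmax`` returns the first maximum).
    """
    if isinstance(vertices, Hemisphere):
        vertices = vertices.vertices
    vertices = np.asarray(vertices, dtype=float)
    if vertices.size == 0:
        raise ValueError("empty mesh")
    nodes = grid.unit_vectors()
    fwd = np.empty(len(vertices), dtype=int)
    chunk = 2048
    for start in range(0, len(vertices), chunk):
        block = vertices[start : start + chunk]
        # clip keeps acos-free comparison stable; argmax dot == min great-circle
        fwd[start : start + len(block)] = np.argmax(block @ nodes.T, axis=1)
    return VertexToGridMap(forward=fwd, n_grid=grid.n_nodes)


def vertex_areas(
    vertices: np.ndarray | Hemisphere,
    triangles: np.ndarray | None = None,
    radius_mm: float = 1.0,
) -> np.ndarray:
    """Per-vertex area in mm^2: one third of each incident triangle's area.

    Triangle areas are flat (chordal) areas of the mesh scaled to the physical
    radius; the total over vertices equals the total mesh surface area exactly.
    """
    if isinstance(vertices, Hemisphere):
        triangles = vertices.triangles
        verts = vertices.vertices
    else:
        verts = np.asarray(vertices, dtype=float)
    tris = np.asarray(triangles, dtype=int)
    p = verts[tris] * radius_mm  # (m, 3, 3)
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(len(verts))
    for corner in range(3):
        np.add.at(areas, tris[:, corner], tri_area / 3.0)
    return areas


def region_average(
    values: np.ndarray, labels: np.ndarray, n_regions: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-region mean of a per-source field.

    Returns ``(means, present)`` of length ``n_regions``; ``means`` is NaN and
    ``present`` False for regions with no sources.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("field and labels must have equal length")
    counts = np.bincount(labels, minlength=n_regions).astype(float)
    sums = np.bincount(labels, weights=values, minlength=n_regions)
    present = counts > 0
    means = np.full(n_regions, np.nan)
    means[present] = sums[present] / counts[present]
    return means, present


def grid_region_labels(
    hemi: Hemisphere, grid: RegularSphericalGrid, mapping: VertexToGridMap
) -> np.ndarray:
    """Region label per grid node: majority vote of the mesh vertices mapped
    to it (ties -> smallest region id); empty nodes take the label of the
    nearest mesh vertex."""
    out = np.empty(grid.n_nodes, dtype=int)
    inv = mapping.inverse()
    empty_nodes = []
    for g, members in enumerate(inv):
        if len(members) == 0:
            empty_nodes.append(g)
            continue
        lab = hemi.labels[members]
        ids, counts = np.unique(lab, return_counts=True)
        out[g] = ids[np.argmax(counts)]  # unique() sorts ids: first max = smallest id
    if empty_nodes:
        nodes = grid.unit_vectors()[empty_nodes]
        nearest = np.argmax(nodes @ hemi.vertices.T, axis=1)
        out[empty_nodes] = hemi.labels[nearest]
    return out


# ---------------------------------------------------------------------------
# Icosphere construction (deterministic refinement of the icosahedron)
# ---------------------------------------------------------------------------


def icosphere(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Subdivided icosahedron projected onto the unit sphere.

    Level ``L`` has ``10 * 4**L + 2`` vertices and ``20 * 4**L`` triangles.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    for _ in range(level):
        verts_list = list(verts)
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            idx = midpoint_cache.get(key)
            if idx is None:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                verts_list.append(m)
                idx = len(verts_list) - 1
                midpoint_cache[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=int)
    return verts, faces


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def write_mesh(path, vertices: np.ndarray, triangles: np.ndarray) -> None:
    """ASCII mesh: header line ``nv nt``, then vertex and triangle blocks."""
    with open(path, "w") as fh:
        fh.write(f"{len(vertices)} {len(triangles)}\n")
        for v in vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for tri in triangles:
            fh.write(f"{tri[0]} {tri[1]} {tri[2]}\n")


def read_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        nv, nt = (int(tok) for tok in fh.readline().split())
        data = np.loadtxt(fh, max_rows=nv).reshape(nv, 3)
        tris = np.loadtxt(fh, dtype=int, max_rows=nt).reshape(nt, 3)
    return data, tris


def write_labels(path, labels: np.ndarray) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def read_labels(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).reshape(-1)


def write_parcellation(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
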