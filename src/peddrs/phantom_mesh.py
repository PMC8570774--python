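"""Synthetic tetrahedral phantoms for luminescence-tomography studies.

A phantom is a tetrahedral mesh over a box, with per-tetrahedron tissue
labels (mapping to optical properties) and an embedded ground-truth
emission source.  Real studies segment and mesh an animal atlas; the
reconstruction mathematics is mesh-agnostic, so structured box phantoms
with embedded organ-like regions exercise the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TetMesh",
    "OpticalProperties",
    "Sphere",
    "Cube",
    "Cylinder",
    "Ellipsoid",
    "SourceGeometry",
    "TISSUE_OPTICS",
    "build_structured_tet_mesh",
    "assign_regions",
    "true_source_nodes",
    "fractional_node_set_volume",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical parameters of one tissue at the imaging wavelength.

    Parameters
    ----------
    mu_a
        Absorption coefficient, mm^-1.
    mu_s_prime
        Reduced scattering coefficient mu_s' = (1 - g) * mu_s, mm^-1.
    g
        Scattering anisotropy factor (mean cosine), dimensionless.
    """

    mu_a: float
    mu_s_prime: float
    g: float

    def __post_init__(self) -> None:
        if not self.mu_a > 0:
            raise ValueError(f"mu_a must be > 0, got {self.mu_a}")
        if not self.mu_s_prime > 0:
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not (0 <= self.g < 1):
            raise ValueError(f"g must be in [0, 1), got {self.g}")


#: Optical parameters of mouse tissues at 630 nm (mu_a, mu_s', g in mm^-1, -).
TISSUE_OPTICS: dict[str, OpticalProperties] = {
    "Muscle": OpticalProperties(0.016, 0.510, 0.90),
    "Heart": OpticalProperties(0.011, 1.053, 0.86),
    "Stomach": OpticalProperties(0.002, 1.525, 0.90),
    "Liver": OpticalProperties(0.065, 0.723, 0.90),
    "Kidney": OpticalProperties(0.012, 2.472, 0.90),
    "Lung": OpticalProperties(0.036, 2.246, 0.90),
}


# ---------------------------------------------------------------------------
# geometric primitives (region predicates / source shapes)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Shape:
    center: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of which ``points`` (n, 3) lie strictly inside."""
        raise NotImplementedError


@dataclass(frozen=True)
class Sphere(_Shape):
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d2 = np.sum((np.atleast_2d(points) - np.asarray(self.center)) ** 2, axis=1)
        return d2 < self.radius**2


@dataclass(frozen=True)
class Cube(_Shape):
    side: float

    def __post_init__(self) -> None:
        if not self.side > 0:
            raise ValueError("side must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.abs(np.atleast_2d(points) - np.asarray(self.center))
        return np.all(d < self.side / 2.0, axis=1)


@dataclass(frozen=True)
class Cylinder(_Shape):
    """Circular cylinder with axis along z."""

    radius: float
    height: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.height > 0):
            raise ValueError("radius and height must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - np.asarray(self.center)
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        return (r2 < self.radius**2) & (np.abs(p[:, 2]) < self.height / 2.0)


@dataclass(frozen=True)
class Ellipsoid(_Shape):
    """Axis-aligned ellipsoid with semi-axes (a, b, c)."""

    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = (np.atleast_2d(points) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.sum(p**2, axis=1) < 1.0


#: Any of the four supported source shapes.
SourceGeometry = Sphere | Cube | Cylinder | Ellipsoid


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------


@dataclass
class TetMesh:
    """Conforming tetrahedral mesh with per-tet tissue labels.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array
        Node coordinates in mm.
    tets : (n_tets, 4) int array
        Node indices of each tetrahedron (positively oriented).
    boundary_faces : (n_faces, 3) int array
        Triangles on the exterior surface.
    region_label : (n_tets,) object array of str
        Tissue name of each tetrahedron.
    spacing : float
        Characteristic edge length (grid spacing for structured meshes), mm.
    """

    nodes: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    region_label: np.ndarray
    spacing: float = 1.0
    _volumes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed-volume magnitudes of all tets (mm^3), cached."""
        if self._volumes is None:
            p = self.nodes[self.tets]
            v = np.einsum(
                "ij,ij->i",
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                p[:, 3] - p[:, 0],
            ) / 6.0
            self._volumes = np.abs(v)
        return self._volumes

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def boundary_node_indices(self) -> np.ndarray:
        """Sorted indices of nodes lying on the exterior surface."""
        return np.unique(self.boundary_faces)

    def validate(self) -> None:
        if self.tets.min() < 0 or self.tets.max() >= self.n_nodes:
            raise ValueError("tet index out of range")
        if np.any(self.tet_volumes() <= 0):
            raise ValueError("degenerate (zero-volume) tetrahedron")
        if len(self.region_label) != self.n_tets:
            raise ValueError("one region label per tet required")


# Kuhn decomposition of the unit hexahedron into 6 tets: all share the main
# diagonal (0,0,0)-(1,1,1), so adjacent cells conform without parity flips.
_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ]
)
# local corner k has offsets (k&1, (k>>1)&1, (k>>2)&1)


def _face_census(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All distinct triangular faces and their incidence counts."""
    faces = np.vstack(
        [
            tets[:, [0, 1, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 3]],
            tets[:, [1, 2, 3]],
        ]
    )
    faces = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return uniq, counts


def build_structured_tet_mesh(
    extent: tuple[float, float, float],
    spacing: float,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    default_tissue: str = "Muscle",
) -> TetMesh:
    """Tetrahedralize the box ``origin + [0, extent]`` on a uniform grid.

    Each grid cell is split into 6 tets sharing the cell's main diagonal
    (Kuhn split), which is conforming across cells.  ``extent`` is snapped
    to an integer number of cells; each dimension must span >= 2 cells.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    extent = tuple(float(e) for e in extent)
    ncells = [int(round(e / spacing)) for e in extent]
    for e, nc in zip(extent, ncells):
        if nc < 1 or abs(nc * spacing - e) > 1e-9 * max(1.0, e):
            raise ValueError(
                f"extent {extent} is not an integer multiple of spacing {spacing}"
            )
        if e < 2 * spacing - 1e-12:
            raise ValueError("each extent dimension must be >= 2*spacing")
    nx, ny, nz = (nc + 1 for nc in ncells)

    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    ii, jj, kk = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    corners = np.empty((len(ii), 8), dtype=np.int64)
    for c in range(8):
        corners[:, c] = nid(ii + (c & 1), jj + ((c >> 1) & 1), kk + ((c >> 2) & 1))
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)

    # orient positively
    p = nodes[tets]
    signed = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = signed < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    uniq, counts = _face_census(tets)
    boundary_faces = uniq[counts == 1]

    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        boundary_faces=boundary_faces,
        region_label=np.array([default_tissue] * len(tets), dtype=object),
        spacing=spacing,
    )
    mesh.validate()
    return mesh


def assign_regions(
    mesh: TetMesh,
    regions: list[tuple[SourceGeometry, str]],
    default_tissue: str = "Muscle",
    optics: dict[str, OpticalProperties] | None = None,
) -> TetMesh:
    """Label each tet by the last region whose shape contains its centroid.

    Tissue names are validated against ``optics`` (default: the built-in
    tissue table).  Returns ``mesh`` with ``region_label`` replaced.
    """
    table = TISSUE_OPTICS if optics is None else optics
    for _, name in list(regions) + [(None, default_tissue)]:
        if name not in table:
            raise ValueError(f"unknown tissue name {name!r}")
    labels = np.array([default_tissue] * mesh.n_tets, dtype=object)
    centroids = mesh.tet_centroids()
    for shape, name in regions:
        labels[shape.contains(centroids)] = name
    mesh.region_label = labels
    return mesh


def fractional_node_set_volume(mesh: TetMesh, node_set: np.ndarray) -> float:
    """Volume attributed to a node set by fractional vertex counting.

    A tet with k of its 4 vertices in the set contributes k/4 of its
    volume, so sets smaller than one cell are not quantized to zero.
    """
    member = np.zeros(mesh.n_nodes, dtype=bool)
    member[np.asarray(node_set, dtype=np.int64)] = True
    k = member[mesh.tets].sum(axis=1)
    return float(np.sum(mesh.tet_volumes() * (k / 4.0)))


def true_source_nodes(
    mesh: TetMesh, src: SourceGeometry
) -> tuple[np.ndarray, np.ndarray, float]:
    """Ground-truth node set of an embedded source.

    Returns ``(T, indicator, V_T)``: sorted indices of nodes strictly
    inside the source geometry, the 0/1 indicator over all mesh nodes,
    and the fractional-vertex-count volume of the set (mm^3).

    Raises if no node falls inside (source below mesh resolution).
    """
    inside = src.contains(mesh.nodes)
    T = np.flatnonzero(inside)
    if len(T) == 0:
        raise ValueError(
            "source smaller than mesh resolution; refine spacing"
        )
    indicator = inside.astype(float)
    return T, indicator, fractional_node_set_volume(mesh, T)
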