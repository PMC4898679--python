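"""Triangulated-surface and per-vertex scalar containers.

The two types here carry all surface geometry through the pipeline:
:class:`TriSurface` holds pial / white / outer-hull meshes (world
coordinates in mm, RAS) and :class:`ScalarMap` holds one value per vertex
(local gyrification index, vertex area, thickness, t statistics, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh


@dataclass
class TriSurface:
    """A triangulated surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions in mm (RAS world coordinates).
    triangles : (F, 3) int array
        Vertex index triples, consistently oriented.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals, dtype=np.float64)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self, edges: np.ndarray | None = None) -> np.ndarray:
        if edges is None:
            edges = self.edges()
        d = self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def adjacency(self, weighted: bool = True) -> sp.csr_matrix:
        """Sparse symmetric vertex adjacency; weights are edge lengths (mm)."""
        e = self.edges()
        w = self.edge_lengths(e) if weighted else np.ones(len(e))
        n = self.n_vertices
        m = sp.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
        return (m + m.T).tocsr()

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.triangles)

    # -- validation ---------------------------------------------------------

    def validate(self, require_closed: bool = True) -> None:
        """Check manifoldness / orientation / non-degeneracy; raise on failure."""
        tm = self.to_trimesh()
        if not tm.is_winding_consistent:
            raise ValueError("mesh is not consistently oriented")
        if require_closed and not tm.is_watertight:
            raise ValueError("mesh is not closed (watertight)")
        if np.any(self.triangle_areas() <= 0):
            raise ValueError("mesh has degenerate (zero-area) triangles")

    # -- interop ------------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriSurface":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.triangles.copy())


@dataclass
class ScalarMap:
    """One real value per surface vertex, with named units.

    Units are informational ("" for dimensionless lGI, "mm^2" for area,
    "mm" for thickness / depth, "1/mm" for curvature).
    """

    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return len(self.values)

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"ScalarMap {self.name!r} contains non-finite values")


def icosphere(subdivisions: int = 4, radius: float = 1.0) -> TriSurface:
    """Icosphere mesh; exactly mirror-symmetric about the x = 0 plane."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface.from_trimesh(m)
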