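"""Synthetic diffusion-tensor phantoms with planted fiber bundles.

Each bundle is a tube of configurable radius around a parametric centerline
(straight segment or circular arc, the latter emulating short U-shaped
cortico-cortical fibers). Voxels inside a bundle carry an anisotropic tensor
whose principal eigenvector follows the local centerline tangent; everywhere
else the field is near-isotropic background whose FA sits below the tracking
threshold by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..tracts import LOWER_TRI_ORDER, TensorVolume, tensor_metrics

logger = logging.getLogger(__name__)


@dataclass
class BundleSpec:
    """A planted fiber bundle.

    ``kind`` is ``"straight"`` (centerline from ``start`` to ``end``) or
    ``"u_shaped"`` (circular arc: ``arc_center``/``arc_radius`` in the plane
    spanned by ``arc_u``/``arc_v``, swept from ``arc_deg[0]`` to
    ``arc_deg[1]``). ``eigenvalues`` are (lambda1, lambda2, lambda3) in
    mm^2/s, sorted descending.
    """

    kind: str = "straight"
    start: tuple = (0.0, 0.0, 0.0)
    end: tuple = (0.0, 0.0, 60.0)
    arc_center: tuple = (0.0, 0.0, 0.0)
    arc_radius: float = 8.0
    arc_u: tuple = (1.0, 0.0, 0.0)
    arc_v: tuple = (0.0, 0.0, 1.0)
    arc_deg: tuple = (0.0, 180.0)
    cross_section_radius: float = 3.0
    eigenvalues: tuple = (1.7e-3, 0.2e-3, 0.2e-3)

    def __post_init__(self) -> None:
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if self.kind not in ("straight", "u_shaped"):
            raise ValueError(f"unknown bundle kind {self.kind!r}")

    def centerline(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        """Densely sampled centerline points and unit tangents."""
        if self.kind == "straight":
            p0 = np.asarray(self.start, float)
            p1 = np.asarray(self.end, float)
            length = np.linalg.norm(p1 - p0)
            n = max(int(np.ceil(length / spacing)) + 1, 2)
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts = p0 + t * (p1 - p0)
            tans = np.tile((p1 - p0) / length, (n, 1))
            return pts, tans
        c = np.asarray(self.arc_center, float)
        u = np.asarray(self.arc_u, float)
        u = u / np.linalg.norm(u)
        v = np.asarray(self.arc_v, float)
        v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
        a0, a1 = np.deg2rad(self.arc_deg)
        length = abs(a1 - a0) * self.arc_radius
        n = max(int(np.ceil(length / spacing)) + 1, 2)
        phi = np.linspace(a0, a1, n)
        pts = c + self.arc_radius * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
        tans = np.sign(a1 - a0) * (-np.sin(phi)[:, None] * u + np.cos(phi)[:, None] * v)
        return pts, tans

    def arc_length(self) -> float:
        """Analytic centerline length in mm."""
        if self.kind == "straight":
            return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))
        a0, a1 = np.deg2rad(self.arc_deg)
        return float(abs(a1 - a0) * self.arc_radius)

    def membership(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(inside mask, unit tangents) for world points.

        The tube is bounded by the endpoint planes (no spherical end caps),
        so the planted solid has exactly the centerline's axial extent.
        """
        p = np.asarray(points, float)
        if self.kind == "straight":
            p0 = np.asarray(self.start, float)
            p1 = np.asarray(self.end, float)
            axis = p1 - p0
            length = np.linalg.norm(axis)
            u = axis / length
            t = (p - p0) @ u
            perp = np.linalg.norm(p - p0 - t[:, None] * u, axis=1)
            inside = (t >= 0) & (t <= length) & (perp <= self.cross_section_radius)
            tangents = np.tile(u, (len(p), 1))
            return inside, tangents
        c = np.asarray(self.arc_center, float)
        u = np.asarray(self.arc_u, float)
        u = u / np.linalg.norm(u)
        v = np.asarray(self.arc_v, float)
        v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
        nrm = np.cross(u, v)
        rel = p - c
        x, y, z = rel @ u, rel @ v, rel @ nrm
        a0, a1 = np.deg2rad(self.arc_deg)
        sweep = a1 - a0
        phi = np.arctan2(y, x)
        dphi = np.mod(np.sign(sweep) * (phi - a0), 2.0 * np.pi)
        in_arc = dphi <= abs(sweep)
        rho = np.hypot(x, y)
        dist = np.hypot(rho - self.arc_radius, z)
        inside = in_arc & (dist <= self.cross_section_radius)
        tangents = np.sign(sweep) * (
            -np.sin(phi)[:, None] * u + np.cos(phi)[:, None] * v
        )
        return inside, tangents


def _tensor_from_tangent(tangents: np.ndarray, eigenvalues: tuple) -> np.ndarray:
    """(N, 6) lower-tri tensors with principal axis along each tangent."""
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    # orthonormal complement via a stable reference axis
    ref = np.where(np.abs(t[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    e2 = np.cross(t, ref)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(t, e2)
    l1, l2, l3 = eigenvalues
    full = (
        l1 * np.einsum("ni,nj->nij", t, t)
        + l2 * np.einsum("ni,nj->nij", e2, e2)
        + l3 * np.einsum("ni,nj->nij", e3, e3)
    )
    out = np.empty((len(t), 6))
    for c, (i, j) in enumerate(LOWER_TRI_ORDER):
        out[:, c] = full[:, i, j]
    return out


def generate_tensor_volume(
    shape: tuple,
    voxel_size: float,
    bundles: list[BundleSpec],
    background_eigenvalues: tuple = (0.7e-3, 0.7e-3, 0.7e-3),
    origin: tuple | None = None,
    fa_threshold: float = 0.2,
) -> TensorVolume:
    """Build a tensor phantom with planted bundles on isotropic background.

    ``origin`` is the world position of voxel (0,0,0); by default the grid is
    centred on the world origin. When bundles overlap, the earlier bundle in
    the list takes precedence (logged). Raises if the background FA is not
    below ``fa_threshold`` (the phantom invariant the tracker relies on).
    """
    shape = tuple(int(s) for s in shape)
    bg = np.sort(np.asarray(background_eigenvalues, float))[::-1]
    bg_fa = tensor_metrics(bg)[0]
    if not bg_fa < fa_threshold:
        raise ValueError(
            f"background FA {bg_fa:.3f} not below tracking threshold {fa_threshold}"
        )
    if origin is None:
        origin = -(np.array(shape) - 1) * voxel_size / 2.0
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = origin

    data = np.zeros(shape + (6,))
    bg6 = np.zeros(6)
    for c, (i, j) in enumerate(LOWER_TRI_ORDER):
        if i == j:
            bg6[c] = bg[i]
    data[...] = bg6

    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * voxel_size + origin
    claimed = np.zeros(len(centers), dtype=bool)
    lo = np.asarray(origin)
    hi = lo + (np.array(shape) - 1) * voxel_size
    for bi, b in enumerate(bundles):
        pts, _ = b.centerline(spacing=voxel_size)
        if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
            raise ValueError(f"bundle {bi} centerline leaves the volume bounds")
        inside, tans = b.membership(centers)
        overlap = inside & claimed
        if np.any(overlap):
            logger.info(
                "bundle %d overlaps %d voxels already claimed; earlier bundle wins",
                bi,
                int(overlap.sum()),
            )
        take = inside & ~claimed
        if np.any(take):
            t6 = _tensor_from_tangent(tans[take], b.eigenvalues)
            flat = data.reshape(-1, 6)
            flat[take] = t6
            claimed |= take
    return TensorVolume(data, affine)
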