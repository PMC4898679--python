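"""Synthetic folded cortical surfaces.

A "cortex" here is an icosphere whose radius is perturbed by concentric
sinusoidal ripples confined to a circular patch around a chosen direction:

    r(theta) = R + A * w(theta) * cos(2 pi f theta)

where ``theta`` is the angular distance from the patch centre, ``A`` the fold
amplitude (mm), ``f`` the fold frequency (cycles per radian) and ``w`` a
smooth cosine-squared taper that is 1 at the patch centre and 0 outside the
patch. The ripples are rings, so the folded region is a surface of
revolution about the patch axis; this keeps an exact 1-D quadrature oracle
available for its area. The white surface is the pial offset inward along
vertex normals by a fixed thickness.

Amplitude differences between subjects/groups stand in for inter-individual
variation in cortical folding; higher amplitude means more buried cortex and
a higher local gyrification index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geometry import TriSurface, icosphere


@dataclass
class FoldSpec:
    """Parameters of a synthetic folded surface.

    Attributes
    ----------
    base_radius : float
        Sphere radius in mm.
    fold_amplitude : float
        Peak ripple amplitude in mm (>= 0).
    fold_frequency : float
        Ripple frequency in cycles per radian of angular distance.
    patch_center : (3,) array
        Unit direction of the patch centre.
    patch_width : float
        Angular radius of the folded patch, radians, in (0, pi).
    subdivision_level : int
        Icosphere subdivision level (>= 2).
    thickness : float
        Inward white-surface offset in mm.
    roughness_mm : float
        SD of seeded per-vertex radial jitter (0 disables it).
    """

    base_radius: float = 50.0
    fold_amplitude: float = 5.0
    fold_frequency: float = 3.0
    patch_center: tuple = (1.0, 0.0, 0.0)
    patch_width: float = 0.5
    subdivision_level: int = 4
    thickness: float = 2.5
    roughness_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.fold_amplitude < 0:
            raise ValueError("fold_amplitude must be >= 0")
        if self.subdivision_level < 2:
            raise ValueError("subdivision_level must be >= 2")
        if not (0 < self.patch_width < np.pi):
            raise ValueError("patch_width must be in (0, pi)")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")


def radial_profile(theta: np.ndarray, spec: FoldSpec) -> np.ndarray:
    """Radius as a function of angular distance from the patch centre."""
    theta = np.asarray(theta, dtype=np.float64)
    w = np.where(
        theta < spec.patch_width,
        np.cos(0.5 * np.pi * theta / spec.patch_width) ** 2,
        0.0,
    )
    return spec.base_radius + spec.fold_amplitude * w * np.cos(
        2.0 * np.pi * spec.fold_frequency * theta
    )


def generate_folded_surface(spec: FoldSpec, seed: int = 0) -> tuple[TriSurface, TriSurface]:
    """Generate (pial, white) surfaces for a :class:`FoldSpec`.

    Deterministic for a fixed spec and seed. Raises ``ValueError`` when the
    requested folds cannot be represented without self-intersection or
    aliasing at the chosen subdivision level.
    """
    sphere = icosphere(subdivisions=spec.subdivision_level, radius=1.0)
    units = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1, keepdims=True)

    center = np.asarray(spec.patch_center, dtype=np.float64)
    center = center / np.linalg.norm(center)
    theta = np.arccos(np.clip(units @ center, -1.0, 1.0))

    # aliasing guard: need several edges per ripple wavelength
    if spec.fold_amplitude > 0 and spec.fold_frequency > 0:
        mean_edge_rad = float(
            np.mean(TriSurface(units, sphere.triangles).edge_lengths())
        )
        wavelength_rad = 1.0 / spec.fold_frequency
        if wavelength_rad < 4.0 * mean_edge_rad:
            raise ValueError(
                "fold_frequency too high for subdivision level "
                f"(wavelength {wavelength_rad:.3f} rad < 4 mesh edges "
                f"{4 * mean_edge_rad:.3f} rad); increase subdivision_level"
            )

    r = radial_profile(theta, spec)
    if spec.roughness_mm > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, spec.roughness_mm, size=r.shape)
    if np.any(r <= spec.thickness):
        raise ValueError("fold amplitude too large: surface folds through the origin")

    pial = TriSurface(units * r[:, None], sphere.triangles)

    normals = pial.vertex_normals()
    # curvature-limited inward offset: where folds curve tightly (troughs and
    # crests) the offset is capped below the local radius of curvature so the
    # white surface cannot fold through itself (cortex likewise thins toward
    # sulcal fundi)
    from ..morphometry import compute_mean_curvature

    h = np.abs(compute_mean_curvature(pial).values)
    with np.errstate(divide="ignore"):
        cap = np.where(h > 0, 0.3 / h, np.inf)
    offset = np.minimum(spec.thickness, cap)
    white = TriSurface(pial.vertices - offset[:, None] * normals, pial.triangles)

    # reject inward offsets that flip triangles (thickness exceeding the local
    # radius of curvature of a fold => self-intersecting white surface)
    if _has_flipped_triangles(pial, white):
        raise ValueError(
            "white surface self-intersects: fold amplitude/frequency too large "
            "for the requested thickness"
        )
    return pial, white


def _has_flipped_triangles(pial: TriSurface, white: TriSurface) -> bool:
    def tri_normals(s: TriSurface) -> np.ndarray:
        p = s.vertices[s.triangles]
        return np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    dots = np.einsum("ij,ij->i", tri_normals(pial), tri_normals(white))
    return bool(np.any(dots <= 0))
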