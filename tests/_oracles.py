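"""Independent oracles used by the test suite.

These deliberately use different algorithms (and, where possible, different
libraries) from the implementation they check: qhull-based convex hulls for
the dip statistic, 1-D quadrature of the parametric fold profile for
surface areas, and a 2-D rolling-ball closing of the meridian cross-section
for the outer-hull profile of the (axisymmetric) folded fixtures.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from gyriconn.synth.surfaces import FoldSpec, radial_profile


# ---------------------------------------------------------------------------
# dip statistic brute force (per candidate modal point, qhull hulls)


def dip_brute_force(sample: np.ndarray) -> float:
    x = np.sort(np.asarray(sample, float).ravel())
    n = len(x)
    xu, counts = np.unique(x, return_counts=True)
    J = len(xu)
    if J == 1:
        return 1.0 / (2.0 * n)
    cum = np.cumsum(counts)
    fr = cum / n
    fl = (cum - counts) / n

    def gcm_dev(m):
        if m == 0:
            return 0.0
        pts = np.column_stack([xu[: m + 1], fl[: m + 1]])
        if m == 1:
            g = fl[: m + 1]
        else:
            cap = np.array([[xu[0], 2.0], [xu[m], 2.0]])
            h = ConvexHull(np.vstack([pts, cap]))
            vid = sorted(v for v in h.vertices if v <= m)
            g = np.interp(xu[: m + 1], xu[vid], fl[vid])
        return float(np.max(fr[:m] - g[:m]))

    def lcm_dev(m):
        if m == J - 1:
            return 0.0
        pts = np.column_stack([xu[m:], fr[m:]])
        if len(pts) == 2:
            g = fr[m:]
        else:
            cap = np.array([[xu[m], -2.0], [xu[J - 1], -2.0]])
            h = ConvexHull(np.vstack([pts, cap]))
            vid = sorted(v for v in h.vertices if v < len(pts))
            g = np.interp(xu[m:], pts[vid, 0], pts[vid, 1])
        return float(np.max(g[1:] - fl[m + 1 :]))

    d = min(max(gcm_dev(m), lcm_dev(m)) for m in range(J)) / 2.0
    return max(d, 1.0 / (2.0 * n))


# ---------------------------------------------------------------------------
# parametric fold-surface areas (surface of revolution about the patch axis)


def folded_area_parametric(
    spec: FoldSpec, theta_max: float = np.pi, n: int = 40000
) -> float:
    """Exact (quadrature) area of the folded pial surface for theta <=
    theta_max, using the surface-of-revolution element
    dA = r * sqrt(r^2 + r'^2) * sin(theta) dtheta dphi."""
    theta = np.linspace(0.0, theta_max, n)
    r = radial_profile(theta, spec)
    dr = np.gradient(r, theta)
    integrand = r * np.sqrt(r**2 + dr**2) * np.sin(theta)
    return float(2.0 * np.pi * np.trapezoid(integrand, theta))


def hull_profile_2d(
    spec: FoldSpec,
    closing_diameter: float,
    grid_mm: float = 0.2,
    n_theta: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Outer-hull radial profile rho(theta) by 2-D rolling-ball closing.

    The folded surface is axisymmetric about the patch axis, so the 3-D
    morphological closing reduces (to first order in ball/sphere radius
    ratio) to a disc closing of the meridian cross-section. Computed on a
    fine 2-D Cartesian raster with EDT-based dilation/erosion.
    """
    rmax = spec.base_radius + spec.fold_amplitude + closing_diameter + 4.0
    # model the full meridian plane (mirrored across the axis) so the
    # morphological operations behave correctly at the patch centre
    u = np.arange(-rmax, rmax, grid_mm)  # signed distance from axis
    v = np.arange(-rmax, rmax, grid_mm)  # along axis
    U, V = np.meshgrid(u, v, indexing="ij")
    rr = np.hypot(U, V)
    th = np.arctan2(np.abs(U), V)  # angle from +axis
    inside = rr <= radial_profile(th, spec)
    ball = closing_diameter / 2.0
    if ball > 0:
        d_out = ndimage.distance_transform_edt(~inside, sampling=grid_mm)
        dil = inside | (d_out <= ball)
        d_in = ndimage.distance_transform_edt(dil, sampling=grid_mm)
        closed = (d_in >= ball + 0.5 * grid_mm) | inside
    else:
        closed = inside
    thetas = np.linspace(1e-4, np.pi - 1e-4, n_theta)
    rho = np.empty(n_theta)
    rs = np.arange(0.0, rmax, grid_mm / 2.0)
    for i, t in enumerate(thetas):
        uu = np.clip((rs * np.sin(t) + rmax) / grid_mm, 0, len(u) - 1).astype(int)
        vv = np.clip((rs * np.cos(t) + rmax) / grid_mm, 0, len(v) - 1).astype(int)
        occ = closed[uu, vv]
        rho[i] = rs[np.max(np.flatnonzero(occ))] if occ.any() else 0.0
    return thetas, rho


def lgi_center_oracle(
    spec: FoldSpec, closing_diameter: float, geodesic_radius: float
) -> float:
    """Parametric lGI at the patch centre: buried pial area over hull-cap
    area inside the hull geodesic disc of the given radius."""
    from scipy.signal import savgol_filter

    thetas, rho = hull_profile_2d(spec, closing_diameter)
    # the ray-sampled profile is radially quantized; smooth over a window
    # much shorter than the fold wavelength before differentiating
    rho = savgol_filter(rho, window_length=31, polyorder=3)
    drho = np.gradient(rho, thetas)
    ds = np.sqrt(rho**2 + drho**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(thetas))])
    if geodesic_radius >= s[-1]:
        raise ValueError("geodesic radius exceeds hull extent")
    theta_b = float(np.interp(geodesic_radius, s, thetas))
    mask = thetas <= theta_b
    hull_cap = 2.0 * np.pi * np.trapezoid(
        (rho * ds * np.sin(thetas))[mask], thetas[mask]
    )
    pial_cap = folded_area_parametric(spec, theta_max=theta_b)
    return pial_cap / hull_cap
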