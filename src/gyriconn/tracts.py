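"""Deterministic streamline tractography on diffusion-tensor volumes.

Implements the classic tensor-line algorithm: seeds on a uniform grid at the
data resolution (one per voxel with FA above threshold), bidirectional Euler
integration along the principal eigenvector of the component-wise
cubic-spline-interpolated tensor field, stopping on low FA, sharp turning
angles, or leaving the volume, with a minimum-length filter. Also provides
tensor-derived scalar metrics (FA/MD/AD/RD), surface-ROI voxelization,
endpoint-based tract dissection, and along-streamline metric summaries.

World coordinates are mm (RAS); voxel indices are 0-based. Tensors are
stored with their frame aligned to world axes, so the affine is expected to
be rotation-free (scaling + translation), as holds for the synthetic world.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: index order of the 6 unique tensor components (lower-triangular,
#: row-major): dxx, dxy, dyy, dxz, dyz, dzz
LOWER_TRI_ORDER = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


def tensor_metrics(eigenvalues: np.ndarray) -> tuple[np.ndarray, ...]:
    """FA, MD, AD, RD from sorted eigenvalues.

    ``eigenvalues`` has shape (..., 3) with lambda1 >= lambda2 >= lambda3 >= 0.
    AD is the axial (parallel) diffusivity lambda1; RD the radial
    (perpendicular) diffusivity (lambda2 + lambda3)/2. All-zero tensors give
    NaN FA (flagged for exclusion from tracking).
    """
    ev = np.asarray(eigenvalues, dtype=np.float64)
    if ev.shape[-1] != 3:
        raise ValueError("eigenvalues must have shape (..., 3)")
    if np.any(ev < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(ev, axis=-1) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = 0.5 * (ev[..., 1] + ev[..., 2])
    num = np.sqrt(((ev - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, np.nan)
    return fa, md, ad, rd


@dataclass
class TensorVolume:
    """Voxel grid of symmetric diffusion tensors plus a voxel->world affine.

    ``data`` has shape (X, Y, Z, 6) in lower-triangular order
    (dxx, dxy, dyy, dxz, dyz, dzz), units mm^2/s.
    """

    data: np.ndarray
    affine: np.ndarray

    _eigcache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError("data must be (X, Y, Z, 6)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def as_matrices(self) -> np.ndarray:
        """Full (X, Y, Z, 3, 3) symmetric tensor array."""
        out = np.empty(self.shape + (3, 3))
        for c, (i, j) in enumerate(LOWER_TRI_ORDER):
            out[..., i, j] = self.data[..., c]
            out[..., j, i] = self.data[..., c]
        return out

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached voxel-wise (eigenvalues desc (X,Y,Z,3), eigenvectors (X,Y,Z,3,3))."""
        if self._eigcache is None:
            w, v = np.linalg.eigh(self.as_matrices())
            # eigh returns ascending; flip to descending
            w = w[..., ::-1]
            v = v[..., ::-1]
            self._eigcache = (w, v)
        return self._eigcache

    def fa_volume(self) -> np.ndarray:
        """Voxel-wise FA from tensor invariants (no eigendecomposition)."""
        d = self.data
        xx, xy, yy, xz, yz, zz = (d[..., c] for c in range(6))
        md = (xx + yy + zz) / 3.0
        norm2 = xx**2 + yy**2 + zz**2 + 2.0 * (xy**2 + xz**2 + yz**2)
        dev2 = norm2 - 3.0 * md**2
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * np.clip(dev2, 0.0, None) / norm2)
        return np.where(norm2 > 0, fa, 0.0)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class VoxelMask:
    """Boolean grid aligned with a :class:`TensorVolume` (shared affine)."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class StreamlineSet:
    """Streamline polylines in world mm plus per-streamline summaries."""

    lines: list
    affine: np.ndarray | None = None
    metrics: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.lines)

    def lengths(self) -> np.ndarray:
        """Polyline arc lengths in mm."""
        return np.array(
            [np.linalg.norm(np.diff(l, axis=0), axis=1).sum() for l in self.lines]
        )

    def endpoints(self) -> np.ndarray:
        """(N, 2, 3) array of first and last points."""
        if not self.lines:
            return np.empty((0, 2, 3))
        return np.stack([[l[0], l[-1]] for l in self.lines])

    def subset(self, idx: np.ndarray) -> "StreamlineSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub_metrics = {k: np.asarray(v)[idx] for k, v in self.metrics.items()}
        return StreamlineSet(
            [self.lines[i] for i in idx], affine=self.affine, metrics=sub_metrics
        )


class _TensorInterpolator:
    """Component-wise spline interpolation of the tensor field.

    ``log_euclidean=True`` interpolates the matrix logarithm instead
    (positive-definiteness preserving; slower, an option rather than the
    default because the reference method interpolates components).
    """

    def __init__(self, vol: TensorVolume, order: int = 3, log_euclidean: bool = False):
        self.vol = vol
        self.order = order
        self.log_euclidean = log_euclidean
        data = vol.data
        if log_euclidean:
            w, v = np.linalg.eigh(vol.as_matrices())
            logw = np.log(np.clip(w, 1e-12, None))
            logm = np.einsum("...ij,...j,...kj->...ik", v, logw, v)
            data = np.empty_like(vol.data)
            for c, (i, j) in enumerate(LOWER_TRI_ORDER):
                data[..., c] = logm[..., i, j]
        if order > 1:
            self._coeffs = [
                ndimage.spline_filter(data[..., c], order=order, mode="nearest")
                for c in range(6)
            ]
        else:
            self._coeffs = [data[..., c] for c in range(6)]

    def tensors_at(self, vox: np.ndarray) -> np.ndarray:
        """(N, 3, 3) tensors at continuous voxel coordinates (N, 3)."""
        coords = vox.T
        comp = np.stack(
            [
                ndimage.map_coordinates(
                    c, coords, order=self.order, prefilter=False, mode="nearest"
                )
                for c in self._coeffs
            ],
            axis=-1,
        )
        out = np.empty((len(vox), 3, 3))
        for c, (i, j) in enumerate(LOWER_TRI_ORDER):
            out[:, i, j] = comp[:, c]
            out[:, j, i] = comp[:, c]
        if self.log_euclidean:
            w, v = np.linalg.eigh(out)
            out = np.einsum("nij,nj,nkj->nik", v, np.exp(w), v)
        return out

    def fa_dir_at(self, vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """FA and principal eigenvector at continuous voxel coordinates."""
        t = self.tensors_at(vox)
        w, v = np.linalg.eigh(t)
        ev = np.clip(w[:, ::-1], 0.0, None)
        fa, _, _, _ = tensor_metrics(ev)
        return np.nan_to_num(fa, nan=0.0), v[:, :, 2]


def track_whole_volume(
    vol: TensorVolume,
    fa_threshold: float = 0.2,
    angle_max_deg: float = 35.0,
    step_mm: float = 1.0,
    min_len_mm: float = 20.0,
    max_len_mm: float = 400.0,
    interp_order: int = 3,
    log_euclidean: bool = False,
    seeds_per_voxel: int = 1,
) -> StreamlineSet:
    """Whole-volume deterministic tractography.

    One seed per voxel centre with FA >= ``fa_threshold``; bidirectional
    Euler propagation with ``step_mm`` steps along the sign-aligned principal
    eigenvector of the cubic-interpolated tensor; stops where the voxel-wise
    FA map drops below threshold at the candidate point, the turning angle
    between consecutive steps exceeds ``angle_max_deg``, or the streamline
    leaves the volume. Streamlines shorter than ``min_len_mm`` are discarded.
    """
    fa_vox = vol.fa_volume()
    seed_idx = np.argwhere(fa_vox >= fa_threshold)
    if len(seed_idx) == 0:
        warnings.warn("no seed voxels with FA above threshold; empty streamline set")
        return StreamlineSet([], affine=vol.affine)

    interp = _TensorInterpolator(vol, order=interp_order, log_euclidean=log_euclidean)
    if seeds_per_voxel > 1:
        # fixed sub-voxel offsets (deterministic; tracking itself has no RNG)
        offs = np.random.default_rng(0).uniform(-0.5, 0.5, size=(seeds_per_voxel, 3))
        offs[0] = 0.0
        seed_idx = (seed_idx[:, None, :] + offs[None]).reshape(-1, 3)
    seeds_world = vol.voxel_to_world(seed_idx)
    scale = vol.voxel_size()  # rotation-free affine: world step -> voxel step

    def to_vox(pts_world: np.ndarray) -> np.ndarray:
        return vol.world_to_voxel(pts_world)

    shape = np.array(vol.shape, float)

    fa0, d0 = interp.fa_dir_at(to_vox(seeds_world))

    max_steps = int(np.ceil(max_len_mm / step_mm)) + 1
    cos_max = np.cos(np.deg2rad(angle_max_deg))

    def propagate(init_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = len(seeds_world)
        pts = np.full((n, max_steps, 3), np.nan)
        pts[:, 0] = seeds_world
        n_pts = np.ones(n, dtype=int)
        pos = seeds_world.copy()
        d_prev = init_dir.copy()
        active = np.ones(n, dtype=bool)
        for step in range(1, max_steps):
            ia = np.flatnonzero(active)
            if len(ia) == 0:
                break
            vox = to_vox(pos[ia])
            _, d = interp.fa_dir_at(vox)
            dots = np.einsum("ij,ij->i", d, d_prev[ia])
            d = np.where(dots[:, None] < 0, -d, d)
            cosang = np.abs(dots)
            ok = cosang >= cos_max
            cand = pos[ia] + step_mm * d
            cvox = to_vox(cand)
            inside = np.all((cvox >= 0) & (cvox <= shape - 1), axis=1)
            ok &= inside
            if np.any(ok):
                nearest = np.round(cvox[ok]).astype(int)
                fa_c = np.zeros(len(ia))
                fa_c[ok] = fa_vox[tuple(nearest.T)]
                ok &= fa_c >= fa_threshold
            acc = ia[ok]
            active[ia[~ok]] = False
            if len(acc):
                pos[acc] = cand[ok]
                d_prev[acc] = d[ok]
                pts[acc, step] = cand[ok]
                n_pts[acc] += 1
        return pts, n_pts

    fwd_pts, fwd_n = propagate(d0)
    bwd_pts, bwd_n = propagate(-d0)

    lines = []
    for i in range(len(seeds_world)):
        back = bwd_pts[i, 1 : bwd_n[i]][::-1]
        line = np.vstack([back, fwd_pts[i, : fwd_n[i]]])
        if (len(line) - 1) * step_mm >= min_len_mm:
            lines.append(np.ascontiguousarray(line))
    return StreamlineSet(lines, affine=vol.affine)


def voxelize_surface_roi(
    vertex_set: np.ndarray,
    surface,
    affine: np.ndarray,
    grid_shape: tuple,
    band_voxels: float = 1.0,
) -> VoxelMask:
    """Rasterize a surface-vertex ROI into a voxel mask.

    Marks voxels whose centres lie within ``band_voxels`` voxels (Euclidean,
    in voxel units) of any ROI vertex mapped through the affine. The band
    absorbs surface/volume discretization gaps.
    """
    if np.abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is not invertible")
    pts = np.asarray(surface.vertices)[np.asarray(vertex_set, dtype=int)]
    inv = np.linalg.inv(affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    mask = np.zeros(grid_shape, dtype=bool)
    ijk = np.round(vox).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.array(grid_shape)), axis=1)
    if not np.any(ok):
        warnings.warn("ROI lies entirely outside the voxel grid; empty mask")
        return VoxelMask(mask, affine)
    mask[tuple(ijk[ok].T)] = True
    if band_voxels > 0:
        dist = ndimage.distance_transform_edt(~mask)
        mask = dist <= band_voxels
    return VoxelMask(mask, affine)


def dissect_by_endpoints(streams: StreamlineSet, mask: VoxelMask) -> StreamlineSet:
    """Keep streamlines with >= 1 endpoint inside the mask.

    Streamlines that merely pass through the mask mid-course are excluded.
    Idempotent; output is always a subset of the input.
    """
    if streams.count == 0 or mask.count() == 0:
        return StreamlineSet([], affine=streams.affine)
    ends = streams.endpoints().reshape(-1, 3)
    inv = np.linalg.inv(mask.affine)
    vox = np.round(ends @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.array(mask.mask.shape)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    inside = np.zeros(len(ends), dtype=bool)
    inside[ok] = mask.mask[tuple(vox[ok].T)]
    keep = inside.reshape(-1, 2).any(axis=1)
    return streams.subset(keep)


def streamline_mean_metrics(
    streams: StreamlineSet, vol: TensorVolume, interp_order: int = 3
) -> dict:
    """Per-streamline and set-level mean FA / MD / AD / RD.

    Metrics are sampled at every streamline point from the interpolated
    tensor field and averaged along each streamline; the subject-level
    summary is the unweighted mean across streamlines. Points outside the
    volume are excluded (and counted in the log). Empty sets give NaN
    summaries.
    """
    names = ("fa", "md", "ad", "rd")
    if streams.count == 0:
        return {f"mean_{k}": float("nan") for k in names} | {"n_streamlines": 0}
    interp = _TensorInterpolator(vol, order=interp_order)
    pts = np.vstack(streams.lines)
    ids = np.repeat(np.arange(streams.count), [len(l) for l in streams.lines])
    vox = vol.world_to_voxel(pts)
    shape = np.array(vol.shape, float)
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("streamline_mean_metrics: %d points outside volume excluded", n_out)
    t = interp.tensors_at(vox[inside])
    w = np.clip(np.linalg.eigh(t)[0][:, ::-1], 0.0, None)
    fa, md, ad, rd = tensor_metrics(w)
    per_line = {}
    counts = np.bincount(ids[inside], minlength=streams.count).astype(float)
    with np.errstate(invalid="ignore"):
        for name, vals in zip(names, (fa, md, ad, rd)):
            sums = np.bincount(ids[inside], weights=vals, minlength=streams.count)
            per_line[name] = sums / counts
    streams.metrics.update(per_line)
    out = {f"mean_{k}": float(np.nanmean(v)) for k, v in per_line.items()}
    out["n_streamlines"] = streams.count
    return out
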