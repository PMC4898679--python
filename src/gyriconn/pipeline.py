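"""End-to-end synthetic cohort analysis.

Orchestrates: cohort generation -> per-subject folded surfaces and
morphometry (lGI, thickness, depth, curvature) -> smoothing -> vertex GLM
with RFT cluster correction -> cluster ROI and mirrored control ROI ->
per-subject tensor phantoms and tractography -> endpoint dissection ->
pooled length distribution (dip, mixture, short/long split) -> per-subject
summaries -> group and coupling statistics.

All randomness flows from the single top-level seed (per-subject child
seeds via ``numpy.random.SeedSequence``); a fixed config + seed is
bit-reproducible at the report level. Stage outputs can be cached in a
working directory keyed by a hash of the relevant config section.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import ScalarMap, TriSurface
from . import morphometry as morpho
from . import vertexstats as vstats
from . import tracts
from . import lengths as lengths_mod
from . import coupling
from .synth import BundleSpec, CohortSpec, FoldSpec, generate_folded_surface
from .synth.phantom import generate_tensor_volume

logger = logging.getLogger(__name__)

METRICS = ("fa", "md", "ad", "rd")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters (defaults are the synthetic study
    conditions; see docs/methods.md for rationale)."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)

    # surface geometry
    base_radius: float = 50.0  # mm
    fold_frequency: float = 3.0  # cycles/radian
    fold_amplitude_base: float = 5.0  # mm at the mean lGI
    fold_amplitude_per_lgi: float = 5.0  # mm amplitude per lGI unit
    patch_center: tuple = (1.0, 0.0, 0.0)
    patch_width: float = 0.5  # radians
    subdivision_level: int = 4
    thickness: float = 2.5  # mm
    roughness_mm: float = 0.05  # per-vertex radial jitter (inter-individual noise)

    # morphometry
    closing_diameter: float = 15.0  # mm
    hull_pitch: float = 2.0  # mm
    hull_mc_step: int = 2  # marching-cubes decimation for per-subject hulls
    lgi_radius: float = 25.0  # mm
    smoothing_fwhm: float = 12.0  # mm (~3.6 mesh edges at subdivision 4)

    # vertex statistics
    cluster_forming_p: float = 0.001
    cluster_alpha: float = 0.05

    # phantom + tracking
    volume_shape: tuple = (64, 64, 64)
    voxel_size: float = 2.0  # mm
    n_u_fibers: int = 10
    u_arc_radius_range: tuple = (6.8, 9.2)  # mm -> U lengths ~21-29 mm
    u_cross_radius: float = 2.2  # mm
    long_lengths: tuple = (55.0, 62.0, 70.0)  # mm
    long_cross_radius: float = 2.5  # mm
    long_tilt: float = 0.35
    bundle_rd: float = 0.55e-3  # lambda2 = lambda3, mm^2/s
    background_eigenvalue: float = 0.7e-3
    fa_threshold: float = 0.2
    angle_max_deg: float = 35.0
    step_mm: float = 1.0
    min_len_mm: float = 20.0
    roi_band_voxels: float = 1.5

    # length mixture
    k_range: tuple = (1, 2, 3, 4)
    cv_splits: int = 3
    cv_gain_threshold: float = 0.01
    upper_len_mm: float = 150.0
    max_pooled_lengths: int = 2000  # dip/mixture subsample size
    dip_n_boot: int = 1000  # Monte-Carlo null replicates for the dip p

    # coupling statistics
    alpha: float = 0.05
    n_comparisons: int = 8

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Audit trail of a pipeline run."""

    config: dict
    config_hash: str
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# bundle template


def build_bundle_templates(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    """Fixed per-cohort bundle geometry (positions shared across subjects).

    Primary-hemisphere U-fibers cluster under the folded patch; one long
    straight bundle projects inward (tilted off the mirror plane). The
    control hemisphere carries the x-mirrored geometry with the long bundle
    tilted the opposite way so the two never meet.
    """
    c = np.asarray(cfg.patch_center, float)
    c = c / np.linalg.norm(c)
    r_end = cfg.base_radius - 1.0

    def orthobasis(d):
        ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(d, e1)

    golden = np.pi * (3.0 - np.sqrt(5.0))
    lo_r, hi_r = cfg.u_arc_radius_range
    u_list = []
    e1, e2 = orthobasis(c)
    for i in range(cfg.n_u_fibers):
        # golden-angle placement keeps fibers spread (limits tube overlap);
        # small seeded jitter decorrelates the exact positions
        frac = (i + 0.5) / cfg.n_u_fibers
        ang = (0.10 + 0.24 * frac) + rng.uniform(-0.02, 0.02)
        azi = i * golden + rng.uniform(-0.1, 0.1)
        ci = np.cos(ang) * c + np.sin(ang) * (np.cos(azi) * e1 + np.sin(azi) * e2)
        arc_r = lo_r + (hi_r - lo_r) * ((i * 7) % cfg.n_u_fibers) / max(cfg.n_u_fibers - 1, 1)
        delta = np.arcsin(arc_r / r_end)
        e1i, e2i = orthobasis(ci)
        psi = rng.uniform(0.0, np.pi)
        axis = np.cos(psi) * e1i + np.sin(psi) * e2i
        tang = np.cross(axis, ci)
        d1 = np.cos(delta) * ci + np.sin(delta) * tang
        d2 = np.cos(delta) * ci - np.sin(delta) * tang
        p1, p2 = r_end * d1, r_end * d2
        mid = 0.5 * (p1 + p2)
        arc_rr = float(np.linalg.norm(p1 - mid))
        u_vec = (p1 - mid) / arc_rr
        u_list.append(
            dict(
                kind="u_shaped",
                arc_center=tuple(mid),
                arc_radius=arc_rr,
                arc_u=tuple(u_vec),
                arc_v=tuple(-ci),  # dips inward
                arc_deg=(0.0, 180.0),
                cross_section_radius=cfg.u_cross_radius,
            )
        )

    long_list = []
    n_long = len(cfg.long_lengths)
    for j, L in enumerate(cfg.long_lengths):
        azi = 2.0 * np.pi * j / n_long
        # attach outside the U-fiber ring (but inside the folded patch)
        start_dir = np.cos(0.42) * c + np.sin(0.42) * (np.cos(azi) * e1 + np.sin(azi) * e2)
        tilt_vec = np.array([0.0, 0.25 * np.sin(azi + 1.0), cfg.long_tilt + 0.1 * j])
        d_long = -start_dir + tilt_vec
        d_long /= np.linalg.norm(d_long)
        start = r_end * start_dir
        long_list.append(
            dict(
                kind="straight",
                start=tuple(start),
                end=tuple(start + L * d_long),
                cross_section_radius=cfg.long_cross_radius,
            )
        )

    def mirror(b: dict, flip_z: bool = False) -> dict:
        out = dict(b)
        for key in ("start", "end", "arc_center", "arc_u", "arc_v"):
            if key in out:
                v = np.asarray(out[key], float)
                v[0] *= -1
                if flip_z:
                    v[2] *= -1
                out[key] = tuple(v)
        return out

    return {
        "short_primary": u_list,
        "long_primary": long_list,
        "short_control": [mirror(b) for b in u_list],
        "long_control": [mirror(b, flip_z=True) for b in long_list],
    }


# ---------------------------------------------------------------------------
# per-subject stages


def subject_surfaces(
    cfg: PipelineConfig, lgi_latent: float, seed: int
) -> tuple[TriSurface, TriSurface]:
    amp = cfg.fold_amplitude_base + cfg.fold_amplitude_per_lgi * (
        lgi_latent - cfg.cohort.lgi_mean
    )
    amp = max(amp, 0.2)
    spec = FoldSpec(
        base_radius=cfg.base_radius,
        fold_amplitude=amp,
        fold_frequency=cfg.fold_frequency,
        patch_center=cfg.patch_center,
        patch_width=cfg.patch_width,
        subdivision_level=cfg.subdivision_level,
        thickness=cfg.thickness,
        roughness_mm=cfg.roughness_mm,
    )
    return generate_folded_surface(spec, seed=seed)


def subject_morphometry(cfg: PipelineConfig, pial: TriSurface, white: TriSurface) -> dict:
    hull = morpho.compute_outer_hull(
        pial,
        closing_diameter=cfg.closing_diameter,
        pitch=cfg.hull_pitch,
        mc_step=cfg.hull_mc_step,
    )
    lgi = morpho.compute_lgi(pial, hull, radius=cfg.lgi_radius)
    thick = morpho.compute_thickness(white, pial)
    depth = morpho.compute_sulcal_depth(pial, hull)
    curv = morpho.compute_mean_curvature(pial)
    return {"pial": pial, "hull": hull, "lgi": lgi, "ct": thick, "sulc": depth, "curv": curv}


def subject_tensor_volume(
    cfg: PipelineConfig,
    templates: dict,
    ad_short: float,
    ad_long: float,
    ad_short_ctrl: float,
    ad_long_ctrl: float,
) -> tracts.TensorVolume:
    rd = cfg.bundle_rd
    bundles = []
    # long bundles take precedence where tubes touch (they are the skeleton;
    # clipped U-fibers shorter than the minimum length are simply dropped)
    for role, ad in (
        ("long_primary", ad_long),
        ("short_primary", ad_short),
        ("long_control", ad_long_ctrl),
        ("short_control", ad_short_ctrl),
    ):
        l1 = max(ad, rd + 1e-6)
        for b in templates[role]:
            bundles.append(BundleSpec(eigenvalues=(l1, rd, rd), **b))
    bg = (cfg.background_eigenvalue,) * 3
    return generate_tensor_volume(
        cfg.volume_shape, cfg.voxel_size, bundles, background_eigenvalues=bg
    )


def cluster_mean(
    map_values: np.ndarray,
    areas: np.ndarray,
    vertices: np.ndarray,
    area_weighted: bool = True,
) -> float:
    """Mean of a per-vertex map over a cluster (area-weighted by default,
    robust to nonuniform meshing; plain vertex mean as option)."""
    v = np.asarray(vertices, int)
    if not area_weighted:
        return float(np.mean(map_values[v]))
    return float(np.average(map_values[v], weights=areas[v]))


def summarize_subject(
    morpho_maps: dict,
    cluster_vertices: np.ndarray,
    streams_by_class: dict,
    vol: tracts.TensorVolume,
    subject_row: pd.Series,
) -> dict:
    """Assemble one SubjectSummary row from per-subject artifacts.

    ``streams_by_class`` maps class names (e.g. "short", "long",
    "short_ctrl") to dissected StreamlineSets; metric summaries are NaN
    with a zero count for empty classes.
    """
    areas = morpho.vertex_area(morpho_maps["pial"]).values
    row = {
        "subject": subject_row["subject"],
        "group": int(subject_row["group"]),
        "center": int(subject_row["center"]),
        "age": float(subject_row["age"]),
        "fsiq": float(subject_row["fsiq"]),
        "lgi": cluster_mean(morpho_maps["lgi"].values, areas, cluster_vertices),
        "ct": cluster_mean(morpho_maps["ct"].values, areas, cluster_vertices),
        "sulc": cluster_mean(morpho_maps["sulc"].values, areas, cluster_vertices),
        "curv": cluster_mean(morpho_maps["curv"].values, areas, cluster_vertices),
    }
    for cls, streams in streams_by_class.items():
        summ = tracts.streamline_mean_metrics(streams, vol)
        for m in METRICS:
            row[f"{m}_{cls}"] = summ[f"mean_{m}"]
        row[f"n_{cls}"] = summ["n_streamlines"]
    return row


# ---------------------------------------------------------------------------
# cohort-level statistics


def analyze_cohort_table(table: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Group, moderation, SURE and partial-correlation analyses on a
    SubjectSummary table (returns a JSON-serializable dict)."""
    out = {}
    metric_cols = [f"{m}_{c}" for c in ("short", "long") for m in METRICS]
    glm = coupling.fit_group_glm(table, metric_cols)
    thr = coupling.bonferroni_threshold(cfg.alpha, cfg.n_comparisons)
    out["bonferroni_threshold"] = thr
    out["group_glm"] = {
        m: {
            "F": float(glm.loc[m, "F"]),
            "p": float(glm.loc[m, "p"]),
            "significant_corrected": bool(glm.loc[m, "p"] < thr),
        }
        for m in metric_cols
    }

    for resp, pred, tag in (
        ("ad_short", "lgi", "ad_short_on_lgi"),
        ("lgi", "ad_short", "lgi_on_ad_short"),
        ("ad_long", "lgi", "ad_long_on_lgi"),
    ):
        mod = coupling.fit_moderation_glm(table, resp, pred)
        out[f"moderation_{tag}"] = {
            t: {"beta": float(mod.loc[t, "beta"]), "F": float(mod.loc[t, "F"]), "p": float(mod.loc[t, "p"])}
            for t in ("group", "predictor", "group_x_predictor")
        }

    # SURE: (1) group effect on lGI vs on AD; (2) lGI->AD vs AD->lGI
    sub = table[["lgi", "ad_short", "group", "center"]].dropna()
    zl = coupling.zscore(sub["lgi"].to_numpy())
    za = coupling.zscore(sub["ad_short"].to_numpy())
    g = sub["group"].to_numpy(float)
    cen = sub["center"].to_numpy(float)
    ones = np.ones(len(sub))
    X_gc = np.column_stack([ones, g, cen])
    r1 = coupling.sure_fit(zl, X_gc, za, X_gc, ["const", "group", "center"], ["const", "group", "center"])
    chi2_g, p_g = coupling.sure_compare(r1, "group", "group")
    Xl = np.column_stack([ones, zl, g, cen])
    Xa = np.column_stack([ones, za, g, cen])
    r2 = coupling.sure_fit(
        za, Xl, zl, Xa, ["const", "predictor", "group", "center"], ["const", "predictor", "group", "center"]
    )
    chi2_c, p_c = coupling.sure_compare(r2, "predictor", "predictor")
    out["sure"] = {
        "group_lgi_vs_group_ad": {"chi2": chi2_g, "p": p_g},
        "lgi_to_ad_vs_ad_to_lgi": {"chi2": chi2_c, "p": p_c},
    }

    pcs = {}
    for cov in ("ct", "sulc", "curv"):
        subc = table[["lgi", "ad_short", cov]].dropna()
        r, p = coupling.partial_correlation(
            subc["lgi"].to_numpy(), subc["ad_short"].to_numpy(), subc[cov].to_numpy()
        )
        pcs[cov] = {"r_par": r, "p": p}
    subr = table[["lgi", "ad_short"]].dropna()
    r0, p0 = coupling.partial_correlation(subr["lgi"].to_numpy(), subr["ad_short"].to_numpy())
    out["correlation_lgi_ad_short"] = {"r": r0, "p": p0}
    out["partial_correlations"] = pcs

    ctrl_cols = [f"{m}_{c}" for c in ("short_ctrl", "long_ctrl") for m in METRICS]
    have = [c for c in ctrl_cols if c in table.columns]
    if have:
        glm_c = coupling.fit_group_glm(table, have)
        out["control_group_glm"] = {
            m: {"F": float(glm_c.loc[m, "F"]), "p": float(glm_c.loc[m, "p"])}
            for m in have
        }
    return out


# ---------------------------------------------------------------------------
# full run


def _morpho_cache_key(cfg: PipelineConfig) -> str:
    fields = [
        "seed", "base_radius", "fold_frequency", "fold_amplitude_base",
        "fold_amplitude_per_lgi", "patch_center", "patch_width",
        "subdivision_level", "thickness", "roughness_mm", "closing_diameter",
        "hull_pitch", "hull_mc_step", "lgi_radius",
    ]
    blob = json.dumps(
        {f: getattr(cfg, f) for f in fields} | {"cohort": asdict(cfg.cohort)},
        sort_keys=True, default=str,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    cfg: PipelineConfig, progress: bool = False, workdir: str | None = None
) -> tuple[dict, RunManifest]:
    """Execute the full synthetic analysis; returns (report, manifest).

    The report is a JSON-serializable dict with the significant clusters,
    length-distribution results and all coupling statistics. With no
    significant lGI cluster the run completes with an empty ROI branch
    (vertex statistics only). When ``workdir`` is given, the morphometry
    stage (the expensive one) is cached there keyed by a hash of the
    relevant config section, making re-runs resumable.
    """
    manifest = RunManifest(config=asdict(cfg), config_hash=cfg.config_hash())
    logger.info("pipeline run %s config: %s", cfg.config_hash(), json.dumps(asdict(cfg), default=str))
    t_all = time.time()
    report: dict = {"seed": cfg.seed}

    # --- cohort -----------------------------------------------------------
    t0 = time.time()
    spec = dataclasses.replace(cfg.cohort, seed=cfg.seed)
    from .synth import generate_cohort

    cohort = generate_cohort(spec)
    n = len(cohort)
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(n + 2)
    rng_geom = np.random.default_rng(child[n])
    rng_ctrl = np.random.default_rng(child[n + 1])
    ctrl_short = spec.ad_mean_control + rng_ctrl.normal(0.0, spec.noise_sd_ad, n)
    ctrl_long = spec.ad_mean_control_long + rng_ctrl.normal(0.0, spec.noise_sd_ad_long, n)
    manifest.timings["cohort"] = time.time() - t0

    # --- morphometry ------------------------------------------------------
    t0 = time.time()
    cache_path = None
    if workdir is not None:
        import os

        os.makedirs(workdir, exist_ok=True)
        cache_path = os.path.join(workdir, f"morpho_{_morpho_cache_key(cfg)}.npz")
    maps_by_subject = []
    if cache_path is not None and os.path.exists(cache_path):
        arr = np.load(cache_path)
        tris = arr["triangles"]
        for i in range(n):
            pial = TriSurface(arr["vertices"][i], tris)
            maps_by_subject.append(
                {
                    "pial": pial,
                    "lgi": ScalarMap(arr["lgi"][i], name="lgi"),
                    "ct": ScalarMap(arr["ct"][i], units="mm", name="thickness"),
                    "sulc": ScalarMap(arr["sulc"][i], units="mm", name="sulc"),
                    "curv": ScalarMap(arr["curv"][i], units="1/mm", name="curv"),
                }
            )
        manifest.warnings.append("morphometry loaded from cache")
    else:
        for i in range(n):
            pial, white = subject_surfaces(
                cfg,
                float(cohort["lgi"].iloc[i]),
                seed=int(child[i].generate_state(1)[0] % 2**31),
            )
            maps_by_subject.append(subject_morphometry(cfg, pial, white))
            if progress and (i + 1) % 10 == 0:
                logger.info("morphometry %d/%d", i + 1, n)
        if cache_path is not None:
            np.savez_compressed(
                cache_path,
                triangles=maps_by_subject[0]["pial"].triangles,
                vertices=np.stack([m["pial"].vertices for m in maps_by_subject]),
                lgi=np.stack([m["lgi"].values for m in maps_by_subject]),
                ct=np.stack([m["ct"].values for m in maps_by_subject]),
                sulc=np.stack([m["sulc"].values for m in maps_by_subject]),
                curv=np.stack([m["curv"].values for m in maps_by_subject]),
            )
            manifest.outputs["morphometry_cache"] = cache_path
    lgi_stack = np.asarray([m["lgi"].values for m in maps_by_subject])
    manifest.timings["morphometry"] = time.time() - t0

    # --- vertex statistics ------------------------------------------------
    t0 = time.time()
    surf0 = maps_by_subject[0]["pial"]
    smooth_op = morpho.smoothing_operator(surf0, cfg.smoothing_fwhm)
    smoothed = lgi_stack if smooth_op is None else lgi_stack @ smooth_op.T.toarray()
    X, _ = vstats.build_design(
        cohort["group"].to_numpy(), cohort["center"].to_numpy(),
        cohort["age"].to_numpy(), cohort["fsiq"].to_numpy(),
    )
    glm = vstats.fit_vertex_glm(smoothed, X)
    clusters = vstats.rft_cluster_correct(
        glm.tmap, glm.residuals, surf0, glm.df,
        cluster_forming_p=cfg.cluster_forming_p, cluster_alpha=cfg.cluster_alpha,
    )
    report["clusters"] = [
        {
            "n_vertices": int(len(c.vertices)),
            "peak_t": c.peak_t,
            "p": c.p,
            "area_mm2": c.area_mm2,
            "sign": c.sign,
        }
        for c in clusters
    ]
    manifest.timings["vertex_stats"] = time.time() - t0

    if not clusters:
        manifest.warnings.append("no significant lGI cluster; ROI branch skipped")
        report["status"] = "no_significant_cluster"
        manifest.timings["total"] = time.time() - t_all
        return report, manifest

    primary = max(clusters, key=lambda c: c.resels)
    roi = vstats.extract_cluster_roi(primary, surf0)
    # correspondence lives on the underlying (symmetric) sphere topology;
    # folded coordinates themselves are not mirror-symmetric
    unit_sphere = TriSurface(
        surf0.vertices / np.linalg.norm(surf0.vertices, axis=1, keepdims=True),
        surf0.triangles,
    )
    corr = vstats.mirror_correspondence(unit_sphere, axis=0)
    roi_ctrl = vstats.mirror_cluster(roi, corr)
    report["roi"] = {"n_vertices": int(len(roi)), "n_vertices_control": int(len(roi_ctrl))}

    # --- tractography per subject ----------------------------------------
    t0 = time.time()
    templates = build_bundle_templates(cfg, rng_geom)
    per_subject_streams = []
    pooled = []
    vols = []
    for i in range(n):
        vol = subject_tensor_volume(
            cfg,
            templates,
            float(cohort["ad_short"].iloc[i]),
            float(cohort["ad_long"].iloc[i]),
            float(ctrl_short[i]),
            float(ctrl_long[i]),
        )
        streams = tracts.track_whole_volume(
            vol,
            fa_threshold=cfg.fa_threshold,
            angle_max_deg=cfg.angle_max_deg,
            step_mm=cfg.step_mm,
            min_len_mm=cfg.min_len_mm,
        )
        pial = maps_by_subject[i]["pial"]
        mask = tracts.voxelize_surface_roi(
            roi, pial, vol.affine, cfg.volume_shape, band_voxels=cfg.roi_band_voxels
        )
        mask_c = tracts.voxelize_surface_roi(
            roi_ctrl, pial, vol.affine, cfg.volume_shape, band_voxels=cfg.roi_band_voxels
        )
        prim = tracts.dissect_by_endpoints(streams, mask)
        ctrl = tracts.dissect_by_endpoints(streams, mask_c)
        per_subject_streams.append((prim, ctrl))
        vols.append(vol)
        pooled.append(prim.lengths())
        if progress and (i + 1) % 10 == 0:
            logger.info("tractography %d/%d", i + 1, n)
    manifest.timings["tractography"] = time.time() - t0

    # --- length distribution ---------------------------------------------
    t0 = time.time()
    pooled_all = np.concatenate(pooled)
    rng_len = np.random.default_rng(cfg.seed + 17)
    if len(pooled_all) > cfg.max_pooled_lengths:
        sub_lengths = rng_len.choice(pooled_all, cfg.max_pooled_lengths, replace=False)
    else:
        sub_lengths = pooled_all
    # polyline lengths are quantized to the step size; dither by half a step
    # so the mixture sees the underlying continuous length distribution
    sub_lengths = sub_lengths + rng_len.uniform(
        -0.5 * cfg.step_mm, 0.5 * cfg.step_mm, size=len(sub_lengths)
    )
    dip = lengths_mod.dip_statistic(sub_lengths)
    dip_p = lengths_mod.dip_pvalue(
        dip, len(sub_lengths), n_boot=cfg.dip_n_boot, seed=cfg.seed + 18
    )
    k, cv_scores = lengths_mod.select_k_crossval(
        sub_lengths,
        cfg.k_range,
        seed=cfg.seed + 19,
        n_splits=cfg.cv_splits,
        gain_threshold=cfg.cv_gain_threshold,
    )
    model = lengths_mod.fit_gmm_em(sub_lengths, max(k, 2), seed=cfg.seed + 20)
    cutoffs = lengths_mod.class_cutoffs(model)
    cutoff = float(cutoffs[0])
    report["lengths"] = {
        "n_pooled": int(len(pooled_all)),
        "dip": float(dip),
        "dip_p": float(dip_p),
        "k_selected": int(k),
        "cv_scores": {str(kk): float(v) for kk, v in cv_scores.items()},
        "mixture": {
            "weights": model.weights.tolist(),
            "means": model.means.tolist(),
            "sds": model.sds.tolist(),
        },
        "cutoffs_mm": cutoffs.tolist(),
        "split_cutoff_mm": cutoff,
    }
    manifest.timings["length_mixture"] = time.time() - t0

    # --- subject summaries -------------------------------------------------
    t0 = time.time()
    rows = []
    for i in range(n):
        prim, ctrl = per_subject_streams[i]
        sp = lengths_mod.split_short_long(prim, cutoff, cfg.upper_len_mm)
        sc = lengths_mod.split_short_long(ctrl, cutoff, cfg.upper_len_mm)
        rows.append(
            summarize_subject(
                maps_by_subject[i],
                roi,
                {
                    "short": sp.short,
                    "long": sp.long,
                    "short_ctrl": sc.short,
                    "long_ctrl": sc.long,
                },
                vols[i],
                cohort.iloc[i],
            )
        )
    summary = pd.DataFrame(rows)
    manifest.timings["summaries"] = time.time() - t0

    # --- statistics --------------------------------------------------------
    t0 = time.time()
    report["statistics"] = analyze_cohort_table(summary, cfg)
    counts = {
        cls: summary[f"n_{cls}"].to_numpy()
        for cls in ("short", "long", "short_ctrl", "long_ctrl")
    }
    from scipy import stats as sps

    g1 = (summary["group"] == 1).to_numpy()
    count_tests = {}
    for cls, v in counts.items():
        if np.var(v) == 0:  # identical counts: trivially no group difference
            count_tests[cls] = {"t": 0.0, "p": 1.0}
        else:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.ttest_ind(v[g1], v[~g1])
            t_val = float(res.statistic) if np.isfinite(res.statistic) else 0.0
            p_val = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
            count_tests[cls] = {"t": t_val, "p": p_val}
    report["streamline_count_tests"] = count_tests
    manifest.timings["statistics"] = time.time() - t0
    manifest.timings["total"] = time.time() - t_all
    report["status"] = "ok"
    report["summary_table"] = summary.to_dict(orient="list")
    return report, manifest
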