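"""Synthetic two-group, two-centre cohorts with planted coupling.

The generator draws per-subject scalar summaries mimicking a case-control
imaging study: a mean local gyrification index (lGI) inside a cortical
cluster, with a group offset, and a short-tract axial diffusivity (AD)
that is linearly coupled to the subject's realized lGI plus a small direct
group effect -- so group differences in AD flow mostly *through*
gyrification, with diffusivity SDs and group means matching published
case-control values (short-tract AD approx 1.10 vs 1.08 x10^-3 mm^2/s,
SD approx 0.04 x10^-3). Age and full-scale IQ are drawn matched between
groups; centre effects are sum-to-zero.

Group coding: 1 = cases (ASD-like), 0 = controls. All randomness flows from
``CohortSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CohortSpec:
    """Cohort generator parameters (units in field names / docstring).

    The AD defaults are calibrated so that the total group difference
    (direct + through-lGI coupling) is ~0.023e-3 mm^2/s against a
    within-group SD of 0.04e-3 -- the effect size implied by the target
    case-control study's short-tract AD means and F statistic.
    """

    n_group1: int = 51  # cases
    n_group2: int = 48  # controls
    lgi_mean: float = 1.30  # control mean lGI in cluster (dimensionless)
    group_lgi_delta: float = 0.135  # case - control lGI offset
    noise_sd_lgi: float = 0.12
    ad_mean_control: float = 1.08e-3  # mm^2/s, short tracts
    coupling_slope: float = 0.018e-3 / 0.135  # (mm^2/s) per lGI unit
    group_ad_delta: float = 0.005e-3  # direct group effect on AD, mm^2/s
    noise_sd_ad: float = 0.0367e-3  # residual AD noise, mm^2/s
    ad_mean_control_long: float = 1.14e-3  # long tracts: no lGI coupling
    group_ad_delta_long: float = 0.005e-3
    noise_sd_ad_long: float = 0.035e-3
    center_lgi_effect: float = 0.02  # centre 1 minus centre 0, lGI units
    center_ad_effect: float = 0.003e-3  # same, mm^2/s
    center_proportions: tuple = (0.515, 0.485)  # fraction at centre 0, per group
    age_range: tuple = (18.0, 43.0)  # years
    fsiq_range: tuple = (77.0, 137.0)  # WASI points
    ct_mean: float = 2.5  # mean cortical thickness, mm
    ct_lgi_slope: float = 0.1  # mm per lGI unit (mild shared structure)
    noise_sd_ct: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 <= 0 or self.n_group2 <= 0:
            raise ValueError("group sizes must be positive")
        if min(self.noise_sd_lgi, self.noise_sd_ad, self.noise_sd_ad_long) < 0:
            raise ValueError("noise SDs must be >= 0")
        for p in self.center_proportions:
            if not 0 <= p <= 1:
                raise ValueError("center proportions must lie in [0, 1]")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the per-subject scalar cohort table.

    Returns a DataFrame with one row per subject: ``group`` (0/1),
    ``center`` (0/1), ``age`` (years), ``fsiq``, ``lgi`` (dimensionless),
    ``ad_short`` / ``ad_long`` (mm^2/s) and ``ct`` (mm). Deterministic for a
    fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_group1 + spec.n_group2
    group = np.concatenate([np.ones(spec.n_group1, int), np.zeros(spec.n_group2, int)])

    center = np.zeros(n, int)
    offset = 0
    for g, ng in ((1, spec.n_group1), (0, spec.n_group2)):
        p0 = spec.center_proportions[0 if g == 1 else 1]
        n0 = int(round(p0 * ng))
        center[offset + n0 : offset + ng] = 1
        offset += ng

    # age / FSIQ matched between groups by construction
    age = rng.uniform(*spec.age_range, size=n)
    fsiq = np.clip(rng.normal(113.0, 12.0, size=n), *spec.fsiq_range)

    c = center - 0.5  # sum-to-zero centre coding keeps group means interpretable
    lgi = (
        spec.lgi_mean
        + spec.group_lgi_delta * group
        + spec.center_lgi_effect * c
        + rng.normal(0.0, spec.noise_sd_lgi, size=n)
    )
    ad_short = (
        spec.ad_mean_control
        - spec.coupling_slope * spec.lgi_mean
        + spec.coupling_slope * lgi
        + spec.group_ad_delta * group
        + spec.center_ad_effect * c
        + rng.normal(0.0, spec.noise_sd_ad, size=n)
    )
    ad_long = (
        spec.ad_mean_control_long
        + spec.group_ad_delta_long * group
        + spec.center_ad_effect * c
        + rng.normal(0.0, spec.noise_sd_ad_long, size=n)
    )
    ct = (
        spec.ct_mean
        + spec.ct_lgi_slope * (lgi - spec.lgi_mean)
        + rng.normal(0.0, spec.noise_sd_ct, size=n)
    )
    return pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(n)],
            "group": group,
            "center": center,
            "age": age,
            "fsiq": fsiq,
            "lgi": lgi,
            "ad_short": ad_short,
            "ad_long": ad_long,
            "ct": ct,
        }
    )
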