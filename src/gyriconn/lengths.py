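"""Tract-length distribution analysis: multimodality, mixtures, classes.

Streamline length samples pooled across subjects are tested for
multimodality with Hartigan's dip statistic, modeled with 1-D Gaussian
mixtures fitted by EM, with the number of components chosen by split-half
cross-validation (smallest k whose held-out log-likelihood gain from one
more component is negligible). Adjacent-component density crossings give
the length cut-offs that split tracts into short- and long-distance
classes (boundary semantics: short = [min, cutoff), long = [cutoff,
upper]).
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hartigan's dip


def _prefix_hull_deviation(x: np.ndarray, y_lo: np.ndarray, y_hi: np.ndarray) -> np.ndarray:
    """Running max deviation of step targets above prefix convex minorants.

    For each m, the greatest convex minorant of the constraint points
    (x_j, y_lo_j), j <= m, is fitted; dev[m] is the maximum of
    y_hi_i - gcm(x_i) over i < m. Incremental monotone-chain hull with
    re-scans of re-hulled spans; deviations only grow as the hull tightens.
    """
    J = len(x)
    dev = np.zeros(J)
    hull = [0]
    cur = 0.0
    for m in range(1, J):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b when slope(a,b) >= slope(b,m): b is not on the lower hull
            if (y_lo[b] - y_lo[a]) * (x[m] - x[b]) >= (y_lo[m] - y_lo[b]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        h = hull[-1]
        if m - h >= 1:
            span = np.arange(h, m)
            g = y_lo[h] + (y_lo[m] - y_lo[h]) * (x[span] - x[h]) / (x[m] - x[h])
            cur = max(cur, float(np.max(y_hi[span] - g)))
        dev[m] = cur
        hull.append(m)
    return dev


def dip_statistic(sample: np.ndarray) -> float:
    """Hartigan-Hartigan dip: minimax distance between the empirical CDF
    and the closest unimodal CDF.

    Computed from greatest-convex-minorant / least-concave-majorant fits on
    either side of every candidate modal point; the dip is half the best
    achievable max deviation, floored at the minimum attainable value
    1/(2n). Values lie in (0, 0.25]; requires n >= 4. Invariant under
    strictly monotone transformations of the sample.
    """
    x = np.sort(np.asarray(sample, dtype=np.float64).ravel())
    n = len(x)
    if n < 4:
        raise ValueError("dip statistic requires n >= 4")
    xu, counts = np.unique(x, return_counts=True)
    J = len(xu)
    if J == 1:
        return 1.0 / (2.0 * n)
    cum = np.cumsum(counts)
    f_right = cum / n
    f_left = (cum - counts) / n

    dev_l = _prefix_hull_deviation(xu, f_left, f_right)
    # right side by reflection: x -> -x reversed, F -> 1 - F
    dev_r = _prefix_hull_deviation(
        -xu[::-1], (1.0 - f_right)[::-1], (1.0 - f_left)[::-1]
    )[::-1]
    d = float(np.min(np.maximum(dev_l, dev_r))) / 2.0
    return max(d, 1.0 / (2.0 * n))


def dip_pvalue(
    dip: float,
    n: int,
    n_boot: int = 2000,
    seed: int = 0,
    null_dips: np.ndarray | None = None,
) -> float:
    """Monte-Carlo dip p-value against the uniform null.

    ``null_dips`` may carry a precomputed null table for sample size ``n``
    (useful when calibrating over many replicates); otherwise ``n_boot``
    uniform samples are drawn with the given seed. Deterministic for fixed
    inputs.
    """
    if null_dips is None:
        if n_boot < 1000:
            raise ValueError("n_boot must be >= 1000")
        null_dips = dip_null_table(n, n_boot, seed)
    null_dips = np.asarray(null_dips)
    return float((1.0 + np.sum(null_dips >= dip)) / (len(null_dips) + 1.0))


def dip_null_table(n: int, n_boot: int, seed: int = 0) -> np.ndarray:
    """Null distribution of the dip for uniform samples of size n."""
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])


# ---------------------------------------------------------------------------
# Gaussian mixtures (1-D, EM)


@dataclass
class MixtureModel:
    """A k-component 1-D Gaussian mixture (components sorted by mean)."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("mixture SDs must be positive")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("component means must be sorted ascending")

    @property
    def k(self) -> int:
        return len(self.weights)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        comp = stats.norm.pdf(x[..., None], self.means, self.sds)
        return comp @ self.weights

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        z = (x[..., None] - self.means) / self.sds
        logs = (
            -0.5 * z**2
            - np.log(self.sds)
            - 0.5 * np.log(2.0 * np.pi)
            + np.log(self.weights)
        )
        m = logs.max(axis=-1, keepdims=True)
        return (m + np.log(np.exp(logs - m).sum(axis=-1, keepdims=True))).squeeze(-1)


class _ComponentCollapse(RuntimeError):
    pass


def _kmeans_1d(x: np.ndarray, k: int, rng: np.random.Generator, iters: int = 15) -> np.ndarray:
    """Seeded quantile-initialized Lloyd iterations; returns k centers."""
    q = (np.arange(k) + rng.uniform(0.25, 0.75, size=k)) / k
    centers = np.quantile(x, np.sort(q))
    for _ in range(iters):
        lab = np.abs(x[:, None] - centers).argmin(axis=1)
        for j in range(k):
            if np.any(lab == j):
                centers[j] = x[lab == j].mean()
    return np.sort(centers)


def _em_once(
    x: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = len(x)
    scale = max(float(np.std(x)), 1e-12)
    mu = _kmeans_1d(x, k, rng)
    sd = np.full(k, scale / max(k, 2))
    w = np.full(k, 1.0 / k)
    log_2pi = np.log(2.0 * np.pi)
    ll_old = -np.inf
    for it in range(max_iter):
        z = (x[:, None] - mu) / sd
        logs = -0.5 * z**2 - np.log(sd) - 0.5 * log_2pi + np.log(w)
        m = logs.max(axis=1, keepdims=True)
        lse = m + np.log(np.exp(logs - m).sum(axis=1, keepdims=True))
        ll = float(lse.sum())
        # EM guarantees a non-decreasing likelihood (up to the tiny variance
        # regularization); a real decrease is a bug
        assert ll >= ll_old - 1e-6 * max(1.0, abs(ll_old)), "EM log-likelihood decreased"
        resp = np.exp(logs - lse)
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise _ComponentCollapse("empty component")
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        # variance regularization guards against collapse onto repeated values
        sd = np.sqrt(var + (1e-3 * scale) ** 2)
        if it > 0 and (ll - ll_old) < tol * abs(ll_old):
            ll_old = ll
            break
        ll_old = ll
    return w, mu, sd, ll_old


def fit_gmm_em(
    sample: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureModel:
    """Fit a k-component Gaussian mixture by EM.

    Best of ``n_restarts`` seeded k-means-style initializations by final
    log-likelihood; collapsing components trigger a fresh restart (an error
    if every restart collapses). Requires n > 10 k.
    """
    x = np.asarray(sample, float).ravel()
    if len(x) <= 10 * k:
        raise ValueError("need n > 10 * k observations")
    rng = np.random.default_rng(seed)
    best = None
    failures = 0
    attempts = 0
    while attempts < n_restarts:
        attempts += 1
        try:
            w, mu, sd, ll = _em_once(x, k, rng, tol, max_iter)
        except _ComponentCollapse:
            failures += 1
            if failures >= 3 * n_restarts:
                raise RuntimeError(
                    f"EM failed: components collapsed in {failures} restarts"
                )
            attempts -= 1  # retry with fresh initialization
            continue
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll)
    w, mu, sd, ll = best
    order = np.argsort(mu)
    return MixtureModel(w[order], mu[order], sd[order], ll)


def select_k_crossval(
    sample: np.ndarray,
    k_range: tuple = (1, 2, 3, 4),
    seed: int = 0,
    n_splits: int = 5,
    gain_threshold: float = 0.01,
    n_restarts: int = 3,
) -> tuple[int, dict]:
    """Split-half cross-validated component count selection.

    For each k, the mean held-out per-point log-likelihood over
    ``n_splits`` random half/half splits is computed; the chosen k is the
    smallest whose relative held-out gain from moving to k+1 falls below
    ``gain_threshold`` (1% by default) -- the parsimony reading of
    "no considerable increase in likelihood". Returns (k, per-k scores).
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    x = np.asarray(sample, float).ravel()
    rng = np.random.default_rng(seed)
    scores = {k: [] for k in ks}
    for s in range(n_splits):
        perm = rng.permutation(len(x))
        half = len(x) // 2
        train, test = x[perm[:half]], x[perm[half:]]
        for k in ks:
            model = fit_gmm_em(train, k, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
            scores[k].append(float(np.mean(model.log_pdf(test))))
    mean_scores = {k: float(np.mean(v)) for k, v in scores.items()}
    chosen = ks[-1]
    for a, b in zip(ks[:-1], ks[1:]):
        gain = (mean_scores[b] - mean_scores[a]) / abs(mean_scores[a])
        if gain < gain_threshold:
            chosen = a
            break
    return chosen, mean_scores


# ---------------------------------------------------------------------------
# class cut-offs and short/long split


def class_cutoffs(model: MixtureModel) -> np.ndarray:
    """Boundaries between adjacent components (k-1 sorted values, mm).

    Each boundary is the point between two adjacent means where the
    weighted component densities cross (pairwise posterior responsibility
    0.5). When the densities do not cross between the means (one component
    dominating throughout), the point minimizing the absolute
    log-density-ratio is used instead (logged).
    """
    if model.k < 2:
        raise ValueError("cutoffs require k >= 2 components")
    bounds = []
    for i in range(model.k - 1):
        w1, m1, s1 = model.weights[i], model.means[i], model.sds[i]
        w2, m2, s2 = model.weights[i + 1], model.means[i + 1], model.sds[i + 1]

        def logratio(x):
            return (
                np.log(w1 / s1)
                - 0.5 * ((x - m1) / s1) ** 2
                - np.log(w2 / s2)
                + 0.5 * ((x - m2) / s2) ** 2
            )

        # quadratic coefficients of logratio(x) = 0
        a = 0.5 * (1.0 / s2**2 - 1.0 / s1**2)
        b = m1 / s1**2 - m2 / s2**2
        c = (
            np.log(w1 / s1)
            - np.log(w2 / s2)
            - 0.5 * (m1 / s1) ** 2
            + 0.5 * (m2 / s2) ** 2
        )
        roots = np.roots([a, b, c]) if abs(a) > 1e-300 else np.array([-c / b])
        roots = roots[np.isreal(roots)].real if len(roots) else roots
        inside = roots[(roots > m1) & (roots < m2)] if len(roots) else roots
        if len(inside):
            bounds.append(float(inside.min()))
        else:
            logger.info(
                "no density crossing between components %d and %d; using the "
                "minimum-|log ratio| point",
                i,
                i + 1,
            )
            grid = np.linspace(m1, m2, 2001)
            bounds.append(float(grid[np.argmin(np.abs(logratio(grid)))]))
    return np.array(sorted(bounds))


SplitResult = namedtuple("SplitResult", ["short", "long", "n_excluded"])


def split_short_long(streams, cutoff_mm: float, upper_mm: float = 150.0) -> SplitResult:
    """Partition a streamline set into short and long classes by length.

    short: length < cutoff; long: cutoff <= length <= upper; streamlines
    above ``upper_mm`` are excluded (their count is returned). The
    partition below ``upper_mm`` is exhaustive and disjoint.
    """
    lengths = streams.lengths()
    short = streams.subset(lengths < cutoff_mm)
    longs = streams.subset((lengths >= cutoff_mm) & (lengths <= upper_mm))
    n_excl = int(np.sum(lengths > upper_mm))
    return SplitResult(short, longs, n_excl)
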