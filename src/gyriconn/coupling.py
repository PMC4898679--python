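"""Structure-connectivity coupling statistics on subject summary tables.

Group comparisons of tract metrics (per-metric GLMs with group, centre,
age and FSIQ; Bonferroni control over the tract-class x metric family),
moderation models linking gyrification and diffusivity in both directions
(DTI ~ group + lGI + group x lGI + centre, and the reverse), seemingly
unrelated regression (SURE) with cross-equation chi-square tests of
coefficient equality, and partial correlations controlling for other
cortical features.

lGI and diffusivity are z-standardized before the moderation and SURE
models so that cross-equation coefficients share a scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Corrected per-test error rate alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = []
        r = 0
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            rj = np.linalg.matrix_rank(arr[:, : j + 1])
            if rj == r:
                bad.append(str(name))
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_group_glm(
    table: pd.DataFrame,
    metrics: list[str],
    group_col: str = "group",
    center_col: str | None = "center",
    covariates: tuple = ("age", "fsiq"),
) -> pd.DataFrame:
    """Per-metric GLM for the group effect, covarying centre/age/FSIQ.

    Returns a DataFrame with the group F (df = 1), its p-value, group
    coefficient, and the n used per metric (rows with missing metric values
    are dropped from that model only). ``center_col=None`` and
    ``covariates=()`` reduce the model to intercept + group.
    """
    rows = []
    for m in metrics:
        cols = [m, group_col] + ([center_col] if center_col else []) + list(covariates)
        sub = table[cols].dropna()
        X = pd.DataFrame({"intercept": 1.0, "group": sub[group_col].astype(float)})
        if center_col:
            X["center"] = sub[center_col].astype(float)
        for c in covariates:
            X[c] = sub[c].astype(float)
        _check_full_rank(X)
        fit = sm.OLS(sub[m].astype(float).to_numpy(), X.to_numpy()).fit()
        t_g = fit.tvalues[1]
        rows.append(
            {
                "metric": m,
                "n": int(fit.nobs),
                "beta_group": fit.params[1],
                "F": t_g**2,
                "p": fit.pvalues[1],
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def fit_moderation_glm(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    group_col: str = "group",
    center_col: str = "center",
    standardize: bool = True,
    covariates: tuple = (),
) -> pd.DataFrame:
    """Moderation model: response ~ group + predictor + group x predictor + centre.

    The predictor (and response, when ``standardize``) is z-scored before
    the interaction is formed, so main effects are interpretable at the
    mean. ``covariates`` names optional extra columns (e.g. age, FSIQ).
    Returns per-term coefficient, F (df = 1) and p.
    """
    sub = table[[response, predictor, group_col, center_col, *covariates]].dropna()
    y = sub[response].astype(float).to_numpy()
    x = sub[predictor].astype(float).to_numpy()
    if standardize:
        if np.std(y) == 0 or np.std(x) == 0:
            raise ValueError("constant response or predictor")
        y = (y - y.mean()) / y.std()
        x = (x - x.mean()) / x.std()
    g = sub[group_col].astype(float).to_numpy()
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "group": g,
            "predictor": x,
            "group_x_predictor": g * x,
            "center": sub[center_col].astype(float).to_numpy(),
        }
    )
    for c in covariates:
        X[c] = sub[c].astype(float).to_numpy()
    _check_full_rank(X)
    fit = sm.OLS(y, X.to_numpy()).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))):
        raise ValueError("degenerate fit: residual variance is (numerically) zero")
    out = pd.DataFrame(
        {
            "term": X.columns,
            "beta": fit.params,
            "F": fit.tvalues**2,
            "p": fit.pvalues,
        }
    ).set_index("term")
    out.attrs["n"] = int(fit.nobs)
    return out


# ---------------------------------------------------------------------------
# seemingly unrelated regression


@dataclass
class SureResult:
    """Two-equation SURE fit (feasible GLS with cross-equation covariance)."""

    params: list[np.ndarray]
    cov_params: np.ndarray  # joint covariance of stacked coefficients
    sigma: np.ndarray  # 2x2 residual covariance
    names: list[list[str]]
    n: int

    def param_index(self, eq: int, name: str) -> int:
        offset = sum(len(p) for p in self.params[:eq])
        return offset + self.names[eq].index(name)


def sure_fit(
    y1: np.ndarray,
    X1: np.ndarray,
    y2: np.ndarray,
    X2: np.ndarray,
    names1: list[str] | None = None,
    names2: list[str] | None = None,
    n_iter: int = 1,
) -> SureResult:
    """Feasible GLS estimation of a two-equation SURE system.

    Equations share observations (rows are the same subjects). Residual
    covariance is estimated from per-equation OLS and the stacked system is
    re-estimated by GLS (optionally iterated). With identical regressor
    matrices the GLS estimates coincide with per-equation OLS (the
    classical degeneracy), but the joint covariance still carries the
    cross-equation correlation needed for coefficient comparisons.
    """
    y1 = np.asarray(y1, float).ravel()
    y2 = np.asarray(y2, float).ravel()
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    n = len(y1)
    if len(y2) != n or X1.shape[0] != n or X2.shape[0] != n:
        raise ValueError("equations must share observations")
    p1, p2 = X1.shape[1], X2.shape[1]
    names1 = names1 or [f"eq1_b{j}" for j in range(p1)]
    names2 = names2 or [f"eq2_b{j}" for j in range(p2)]

    b1 = np.linalg.lstsq(X1, y1, rcond=None)[0]
    b2 = np.linalg.lstsq(X2, y2, rcond=None)[0]
    for _ in range(max(n_iter, 1)):
        e = np.column_stack([y1 - X1 @ b1, y2 - X2 @ b2])
        sigma = e.T @ e / n
        if np.linalg.det(sigma) <= 1e-300:
            raise ValueError("singular residual covariance")
        w = np.linalg.inv(sigma)
        # stacked GLS with Omega^-1 = W kron I_n
        A11 = w[0, 0] * X1.T @ X1
        A12 = w[0, 1] * X1.T @ X2
        A22 = w[1, 1] * X2.T @ X2
        A = np.block([[A11, A12], [A12.T, A22]])
        b = np.concatenate(
            [
                w[0, 0] * X1.T @ y1 + w[0, 1] * X1.T @ y2,
                w[0, 1] * X2.T @ y1 + w[1, 1] * X2.T @ y2,
            ]
        )
        sol = np.linalg.solve(A, b)
        b1, b2 = sol[:p1], sol[p1:]
    cov = np.linalg.inv(A)
    return SureResult(
        params=[b1, b2], cov_params=cov, sigma=sigma, names=[names1, names2], n=n
    )


def sure_compare(result: SureResult, name1: str, name2: str) -> tuple[float, float]:
    """Chi-square (df = 1) test of equality of a coefficient across equations.

    Tests H0: beta_eq1[name1] = beta_eq2[name2] via the Wald statistic on
    the joint GLS covariance (equivalent to comparing the systems with the
    coefficient constrained equal versus free).
    """
    i = result.param_index(0, name1)
    j = result.param_index(1, name2)
    diff = result.params[0][result.names[0].index(name1)] - result.params[1][
        result.names[1].index(name2)
    ]
    var = (
        result.cov_params[i, i]
        + result.cov_params[j, j]
        - 2.0 * result.cov_params[i, j]
    )
    chi2 = float(diff**2 / var)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial correlation of x and y given covariates, with its p-value.

    Residualizes both variables on the covariates (plus intercept) and
    correlates the residuals; p comes from the t transform with
    n - k - 2 degrees of freedom. With no covariates this is the Pearson
    correlation.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.asarray(covariates, float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        Z = np.column_stack([np.ones(n), covariates])
        k = covariates.shape[1]
    if n <= k + 3:
        raise ValueError("need n > n_covariates + 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float((rx * ry).sum() / denom)
    df = n - k - 2
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) >= 1.0:
        return r_c, 0.0
    t = r_c * np.sqrt(df / (1.0 - r_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def zscore(v: np.ndarray) -> np.ndarray:
    """z-standardize a vector (population SD)."""
    v = np.asarray(v, float)
    s = v.std()
    if s == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / s
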