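"""Two-sample MR estimators and sensitivity statistics on harmonized pairs.

All estimators consume aligned per-variant (beta_x, se_x, beta_y, se_y)
marginal effects.  The causal effect theta is reported per 1-SD higher
exposure; for binary outcomes it is a log odds ratio.  The battery:

* Wald ratio — single instrument, ``theta = beta_y / beta_x`` with the
  first-order delta SE ``|se_y / beta_x|``.
* IVW — weighted regression of beta_y on beta_x through the origin with
  weights ``1/se_y^2``; fixed-effect for <=3 instruments, multiplicative
  random effects (SE inflated by ``max(1, sqrt(Q/df))``) for >3, under
  the ``"auto"`` rule.
* Correlated-instrument IVW — generalised least squares with residual
  covariance ``Omega_jk = se_yj se_yk r_jk`` from a reference LD matrix.
* MR-Egger — weighted regression with a free intercept; the intercept
  tests directional pleiotropy, the slope estimates the causal effect.
* MR-PRESSO — simulation-based residual-sum-of-squares global test for
  pleiotropy, per-instrument outlier flagging and a distortion test.
* Contamination mixture — profile likelihood over a grid of candidate
  causal effects, each instrument classed valid or invalid.

Heterogeneity is summarised by Cochran's Q and I^2.  All p-values are
two-sided normal unless the method dictates otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "HeterogeneityStats",
    "PleiotropyStats",
    "PressoResult",
    "ConmixResult",
    "InsufficientInstrumentsError",
    "UndefinedEstimateError",
    "wald_ratio",
    "ivw",
    "ivw_correlated",
    "egger",
    "presso",
    "conmix",
    "select_primary",
]

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Raised when an estimator is given fewer instruments than it supports."""


class UndefinedEstimateError(ZeroDivisionError):
    """Raised when the estimate is undefined (e.g. all exposure effects zero)."""


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate with its 95% CI."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        """exp(theta); meaningful for binary outcomes."""
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q across per-instrument estimates, with I^2."""

    q: float
    df: int
    p_q: float
    i2: float


@dataclass(frozen=True)
class PleiotropyStats:
    """MR-Egger intercept test for directional pleiotropy."""

    egger_intercept: float
    se: float
    p_intercept: float


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion tests."""

    rss_obs: float
    p_global: float
    outliers: tuple[int, ...]
    p_distortion: float | None
    n_sim: int
    seed: int
    theta_raw: float
    theta_outlier_corrected: float | None


@dataclass(frozen=True)
class ConmixResult:
    """Contamination-mixture estimate with the valid-instrument set."""

    estimate: MREstimate
    valid: tuple[int, ...]
    theta_grid: np.ndarray = field(repr=False)
    profile_loglik: np.ndarray = field(repr=False)


def _as_arrays(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = pairs["beta_x"].to_numpy(dtype=float)
    sx = pairs["se_x"].to_numpy(dtype=float)
    by = pairs["beta_y"].to_numpy(dtype=float)
    sy = pairs["se_y"].to_numpy(dtype=float)
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("standard errors must be positive")
    return bx, sx, by, sy


def _normal_estimate(method: str, theta: float, se: float, n: int) -> MREstimate:
    z = theta / se
    p = 2 * stats.norm.sf(abs(z))
    return MREstimate(
        method=method, theta=float(theta), se=float(se),
        ci_low=float(theta - Z95 * se), ci_high=float(theta + Z95 * se),
        pvalue=float(max(p, np.finfo(float).tiny)), n_snps=n,
    )


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument causal estimate ``beta_y / beta_x``.

    The default SE is the first-order delta approximation ``|se_y/beta_x|``,
    which ignores exposure-side uncertainty; ``second_order=True`` adds the
    ``beta_y^2 se_x^2 / beta_x^4`` term.
    """
    if beta_x == 0:
        raise UndefinedEstimateError("Wald ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    if second_order:
        se = np.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    else:
        se = abs(se_y / beta_x)
    return _normal_estimate("wald", theta, se, 1)


def ivw(pairs: pd.DataFrame, mode: str = "auto") -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate with Cochran-Q heterogeneity.

    Weighted regression of beta_y on beta_x through the origin, weights
    ``1/se_y^2``.  ``mode="auto"`` uses a fixed-effect model for <=3
    instruments and multiplicative random effects for >3; the latter
    scales the SE by ``max(1, sqrt(Q/df))``.
    """
    if mode not in ("auto", "fixed", "mre"):
        raise ValueError(f"unknown mode {mode!r}")
    bx, _, by, sy = _as_arrays(pairs)
    k = len(bx)
    if k < 1:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    if np.all(bx == 0):
        raise UndefinedEstimateError("all exposure effects are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    df = k - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0

    if mode == "auto":
        mode = "fixed" if k <= 3 else "mre"
    if mode == "mre" and df > 0:
        se = se_fixed * max(1.0, np.sqrt(q / df))
        method = "ivw_mre"
    else:
        se = se_fixed
        method = "ivw_fixed"
    est = _normal_estimate(method, theta, se, k)
    het = HeterogeneityStats(q=q, df=df, p_q=p_q, i2=float(i2))
    return est, het


def ivw_correlated(
    pairs: pd.DataFrame,
    ld_sub: np.ndarray,
    ridge: float = 1e-6,
) -> MREstimate:
    """IVW accounting for instrument correlation.

    Generalised weighted regression through the origin with residual
    covariance ``Omega = diag(se_y) R diag(se_y)`` where R is the LD
    correlation submatrix for the instruments, in their row order.  If the
    smallest eigenvalue of Omega is below 1e-8, ``ridge`` is added to its
    diagonal before solving.
    """
    bx, _, by, sy = _as_arrays(pairs)
    k = len(bx)
    ld_sub = np.asarray(ld_sub, dtype=float)
    if ld_sub.shape != (k, k):
        raise ValueError("LD submatrix shape does not match instrument count")
    omega = np.outer(sy, sy) * ld_sub
    if np.linalg.eigvalsh(omega).min() < 1e-8:
        omega = omega + ridge * np.eye(k)
    try:
        oinv_bx = np.linalg.solve(omega, bx)
        oinv_by = np.linalg.solve(omega, by)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"instrument covariance singular after ridge {ridge}: {e}"
        )
    denom = float(bx @ oinv_bx)
    if denom <= 0:
        raise UndefinedEstimateError("non-positive GLS denominator")
    theta = float(bx @ oinv_by) / denom
    se = denom ** -0.5
    return _normal_estimate("ivw_correlated", theta, se, k)


def egger(pairs: pd.DataFrame) -> tuple[MREstimate, PleiotropyStats]:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy test.

    Instruments are first oriented so every beta_x >= 0 (flipping the pair's
    signs jointly), since Egger is not invariant to allele orientation.
    Weighted least squares with weights ``1/se_y^2``; SEs use multiplicative
    over-dispersion with df = k - 2, truncated below at 1.
    """
    bx, _, by, sy = _as_arrays(pairs)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (k - 2))
    cov = phi * np.linalg.inv(xtwx)
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    est = _normal_estimate("egger_slope", slope, se_slope, k)
    z_i = inter / se_inter
    pleio = PleiotropyStats(
        egger_intercept=float(inter), se=float(se_inter),
        p_intercept=float(2 * stats.norm.sf(abs(z_i))),
    )
    return est, pleio


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorised."""
    num = np.sum(w * bx * by)
    den = np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def presso(
    pairs: pd.DataFrame,
    n_sim: int = 1000,
    alpha_outlier: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO pleiotropy residual-sum and outlier test.

    Global test: the observed weighted RSS of leave-one-out IVW predictions
    is compared with its parametric-bootstrap distribution — each replicate
    redraws (beta_x, beta_y) from normals centred on the observed beta_x and
    on the leave-one-out prediction ``theta_(-j) beta_xj``.  The Monte-Carlo
    p has resolution 1/(n_sim+1).  Per-instrument outlier p-values use the
    analogous per-observation comparison, Bonferroni-corrected by the number
    of instruments.  When outliers are found, the distortion test compares
    the outlier-corrected estimate with the distribution of estimates after
    removing equally many instruments at random.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    k = len(bx)
    if k < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 instruments")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2
    theta_loo = _loo_thetas(bx, by, w)
    obs_contrib = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_contrib))

    # parametric bootstrap under the no-pleiotropy model
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    w_row = w[None, :]
    num = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True)
    den = np.sum(w_row * bx_sim**2, axis=1, keepdims=True)
    theta_loo_sim = (num - w_row * bx_sim * by_sim) / (den - w_row * bx_sim**2)
    contrib_sim = w_row * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = contrib_sim.sum(axis=1)
    p_global = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    p_outlier = (1 + np.sum(contrib_sim >= obs_contrib[None, :], axis=0)) / (1 + n_sim)
    outliers = tuple(int(i) for i in np.nonzero(p_outlier * k < alpha_outlier)[0])

    theta_raw = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    theta_corr = None
    p_distortion = None
    if outliers and len(outliers) < k - 1:
        keep = np.setdiff1d(np.arange(k), outliers)
        theta_corr = float(
            np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(w[keep] * bx[keep] ** 2)
        )
        d_obs = (theta_corr - theta_raw) / abs(theta_raw) if theta_raw != 0 else np.inf
        n_out = len(outliers)
        d_null = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            kp = np.setdiff1d(np.arange(k), drop)
            t = np.sum(w[kp] * bx[kp] * by[kp]) / np.sum(w[kp] * bx[kp] ** 2)
            d_null[s] = (t - theta_raw) / abs(theta_raw) if theta_raw != 0 else np.inf
        p_distortion = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_sim))

    return PressoResult(
        rss_obs=rss_obs, p_global=p_global, outliers=outliers,
        p_distortion=p_distortion, n_sim=n_sim, seed=seed,
        theta_raw=theta_raw, theta_outlier_corrected=theta_corr,
    )


def conmix(
    pairs: pd.DataFrame,
    psi: float | None = None,
    theta_grid: np.ndarray | None = None,
    n_grid: int = 2001,
) -> ConmixResult:
    """Contamination-mixture causal estimate.

    Each instrument's ratio estimate ``theta_j = beta_yj/beta_xj`` (SE
    ``se_yj/|beta_xj|``) is modelled as either valid — N(theta, se_j^2) —
    or invalid — N(0, se_j^2 + psi^2) — and the profile log-likelihood,
    taking the better class per instrument, is maximised over a grid of
    candidate effects.  The 95% CI inverts the likelihood-ratio test at
    the chi-square(1) 0.95 quantile; the reported SE is the CI half-width
    divided by 1.96.

    ``psi`` defaults to 1.5x the SD of the ratio estimates; the default
    grid spans their range widened by 3x the largest SE, with ``n_grid``
    points.
    """
    bx, _, by, sy = _as_arrays(pairs)
    if len(bx) < 2:
        raise InsufficientInstrumentsError("contamination mixture needs >=2 instruments")
    if np.any(bx == 0):
        raise UndefinedEstimateError("zero exposure effect among instruments")
    theta_j = by / bx
    se_j = sy / np.abs(bx)
    if psi is None:
        psi = 1.5 * float(np.std(theta_j, ddof=1)) if len(theta_j) > 1 else 1.0
        psi = max(psi, 1e-6)
    if psi <= 0:
        raise ValueError("psi must be positive")
    if theta_grid is None:
        pad = 3 * float(se_j.max())
        theta_grid = np.linspace(theta_j.min() - pad, theta_j.max() + pad, n_grid)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("empty theta grid")

    diff = theta_j[None, :] - theta_grid[:, None]
    ll_valid = stats.norm.logpdf(diff, scale=se_j[None, :])
    ll_invalid = stats.norm.logpdf(theta_j, scale=np.sqrt(se_j**2 + psi**2))
    profile = np.sum(np.maximum(ll_valid, ll_invalid[None, :]), axis=1)
    i_max = int(np.argmax(profile))
    theta_hat = float(theta_grid[i_max])
    valid = tuple(int(j) for j in np.nonzero(ll_valid[i_max] >= ll_invalid)[0])

    crit = stats.chi2.ppf(0.95, 1)
    in_ci = 2 * (profile[i_max] - profile) <= crit
    ci_low = float(theta_grid[in_ci].min())
    ci_high = float(theta_grid[in_ci].max())
    se = max((ci_high - ci_low) / (2 * Z95), 1e-12)
    p = float(2 * stats.norm.sf(abs(theta_hat) / se))
    est = MREstimate(
        method="conmix", theta=theta_hat, se=float(se),
        ci_low=ci_low, ci_high=ci_high, pvalue=max(p, np.finfo(float).tiny),
        n_snps=len(bx),
    )
    return ConmixResult(estimate=est, valid=valid,
                        theta_grid=theta_grid, profile_loglik=profile)


def select_primary(pairs: pd.DataFrame) -> tuple[MREstimate, HeterogeneityStats | None]:
    """Primary-analysis dispatch: Wald ratio for one instrument, else auto IVW."""
    if len(pairs) == 0:
        raise InsufficientInstrumentsError("no instruments")
    if len(pairs) == 1:
        row = pairs.iloc[0]
        return wald_ratio(row["beta_x"], row["se_x"], row["beta_y"], row["se_y"]), None
    return ivw(pairs, mode="auto")
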