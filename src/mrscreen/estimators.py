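"""Causal-effect estimators for two-sample summary-data MR.

All estimators take harmonized instruments (per-SNP exposure effect in SD
units, outcome effect in log-odds, with standard errors) and return the
causal log-odds of the outcome per SD increase in the exposure, together
with an OR_SD transform (exp of the effect with a normal-theory CI).

Methods
-------
wald_ratio
    Single-SNP estimate beta_outcome / beta_exposure, first- or second-order
    delta-method SE.
ivw_fe
    Fixed-effects inverse-variance-weighted mean of per-SNP Wald ratios;
    algebraically the WLS slope of beta_outcome on beta_exposure through the
    origin with weights 1/se_outcome^2 (when first-order ratio SEs are used).
max_likelihood
    Profile-likelihood estimate under a bivariate-normal measurement model:
    observed (beta_x, beta_y) are independent normals around (gamma_j,
    theta*gamma_j) with known SEs; the per-SNP nuisance means are profiled
    out analytically, leaving the concentrated log-likelihood
    l(theta) = -1/2 * sum (beta_y - theta*beta_x)^2 / (se_y^2 + theta^2 se_x^2),
    maximized by Newton iteration; the SE comes from the observed information.
weighted_median
    Weighted median of the per-SNP ratios (consistent when valid instruments
    carry a majority of the weight), SE by seeded parametric bootstrap.
weighted_mode
    Mode of a weighted Gaussian-kernel density over the per-SNP ratios
    (consistent when the largest homogeneous cluster is valid), SE by
    parametric bootstrap.
egger
    Weighted regression of outcome on exposure effects *with* an intercept
    after orienting every SNP to a positive exposure effect; a non-zero
    intercept estimates directional (unbalanced horizontal) pleiotropy.

P-values are two-sided normal throughout, the summary-data MR convention;
with very few SNPs this is mildly anti-conservative relative to a t
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .gwas_io import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "EggerResult",
    "EstimationError",
    "ConvergenceError",
    "SingularDesignError",
    "wald_ratio",
    "ivw_fe",
    "max_likelihood",
    "weighted_median",
    "weighted_mode",
    "egger",
    "to_or_scale",
]

METHODS = ("wald", "ivw_fe", "mle", "weighted_median", "weighted_mode", "egger_slope")


class EstimationError(ValueError):
    """Invalid input to an estimator (empty set, zero exposure effect, ...)."""


class ConvergenceError(EstimationError):
    """Optimizer failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class SingularDesignError(EstimationError):
    """Regression design has no leverage (all exposure effects equal)."""


def to_or_scale(
    theta: float, se: float, level: float = 0.95
) -> tuple[float, float, float, float]:
    """(or_sd, ci_low, ci_high, pvalue) for a log-scale effect and its SE."""
    if se <= 0:
        raise EstimationError(f"se must be positive, got {se}")
    if not 0 < level < 1:
        raise EstimationError(f"level must be in (0,1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    or_sd = math.exp(theta)
    ci_low = math.exp(theta - z * se)
    ci_high = math.exp(theta + z * se)
    pvalue = 2.0 * stats.norm.sf(abs(theta) / se)
    return or_sd, ci_low, ci_high, float(pvalue)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate: log-odds per SD, with OR_SD and 95% CI."""

    method: str
    theta: float
    se: float
    n_snps: int
    or_sd: float
    ci_low: float
    ci_high: float
    pvalue: float
    level: float = 0.95


def _make_estimate(
    method: str, theta: float, se: float, n_snps: int, level: float = 0.95
) -> MREstimate:
    or_sd, lo, hi, p = to_or_scale(theta, se, level)
    return MREstimate(
        method=method, theta=float(theta), se=float(se), n_snps=int(n_snps),
        or_sd=or_sd, ci_low=lo, ci_high=hi, pvalue=p, level=level,
    )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the directional-pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float

    @property
    def n_snps(self) -> int:
        return self.slope.n_snps


# ---------------------------------------------------------------------------
# array-level core (used by the model layer and the public wrappers)
# ---------------------------------------------------------------------------

def _unpack(insts: Sequence[HarmonizedInstrument]):
    kept = [i for i in insts if getattr(i, "kept", True)]
    if not kept:
        raise EstimationError("no usable instruments (all dropped or empty input)")
    bx = np.array([i.beta_exposure for i in kept], dtype=float)
    sx = np.array([i.se_exposure for i in kept], dtype=float)
    by = np.array([i.beta_outcome for i in kept], dtype=float)
    sy = np.array([i.se_outcome for i in kept], dtype=float)
    return bx, sx, by, sy


def _ratio_se(bx, sx, by, sy, se_order: str) -> np.ndarray:
    if se_order == "first":
        return sy / np.abs(bx)
    if se_order == "second":
        return np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    raise EstimationError(f"se_order must be 'first' or 'second', got {se_order!r}")


def _check_nonzero_bx(bx: np.ndarray) -> None:
    if np.any(bx == 0):
        raise EstimationError("beta_exposure = 0: Wald ratio undefined")


def _wald_arrays(bx, sx, by, sy, se_order="first", level=0.95) -> MREstimate:
    _check_nonzero_bx(np.atleast_1d(bx))
    theta = by / bx
    se = _ratio_se(bx, sx, by, sy, se_order)
    return _make_estimate("wald", float(theta), float(se), 1, level)


def _ivw_arrays(bx, sx, by, sy, se_order="first", level=0.95) -> MREstimate:
    _check_nonzero_bx(bx)
    theta_j = by / bx
    w = 1.0 / _ratio_se(bx, sx, by, sy, se_order) ** 2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return _make_estimate("ivw_fe", theta, se, len(bx), level)


def _profile_score(theta, bx, sx, by, sy) -> float:
    r = by - theta * bx
    v = sy**2 + theta**2 * sx**2
    return float(np.sum(bx * r / v + theta * sx**2 * r**2 / v**2))


def _mle_arrays(bx, sx, by, sy, tol=1e-8, maxiter=200, level=0.95) -> MREstimate:
    if len(bx) < 2:
        raise EstimationError("max_likelihood requires >= 2 instruments")
    _check_nonzero_bx(bx)
    # start from the IVW point estimate
    theta = float(np.sum(by * bx / sy**2) / np.sum(bx**2 / sy**2))
    trace = [theta]
    scale = max(1.0, abs(theta))
    converged = False
    for _ in range(maxiter):
        h = 1e-6 * max(1.0, abs(theta))
        s = _profile_score(theta, bx, sx, by, sy)
        ds = (
            _profile_score(theta + h, bx, sx, by, sy)
            - _profile_score(theta - h, bx, sx, by, sy)
        ) / (2 * h)
        if ds >= 0:  # not locally concave; fall back to damped score step
            step = s * 1e-2
        else:
            step = -s / ds
        # trust-region style damping keeps Newton from overshooting
        step = float(np.clip(step, -10 * scale, 10 * scale))
        theta += step
        trace.append(theta)
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"profile-likelihood Newton failed to converge in {maxiter} iterations",
            trace,
        )
    h = 1e-5 * max(1.0, abs(theta))
    info = -(
        _profile_score(theta + h, bx, sx, by, sy)
        - _profile_score(theta - h, bx, sx, by, sy)
    ) / (2 * h)
    if info <= 0:
        raise ConvergenceError("observed information not positive at the optimum", trace)
    se = info**-0.5
    return _make_estimate("mle", theta, se, len(bx), level)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    # standardized cumulative weight at each order statistic
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        est[b] = point_fn(bxb, byb)
    return float(np.std(est, ddof=1))


def _wm_point(bx, by, sy) -> float:
    ratios = by / bx
    weights = bx**2 / sy**2  # 1 / first-order ratio variance
    return _weighted_median_point(ratios, weights)


def _weighted_median_arrays(
    bx, sx, by, sy, n_boot=1000, seed=0, level=0.95
) -> MREstimate:
    if len(bx) < 3:
        raise EstimationError("weighted_median requires >= 3 instruments")
    _check_nonzero_bx(bx)
    theta = _wm_point(bx, by, sy)
    se = _bootstrap_se(
        lambda bxb, byb: _wm_point(bxb, byb, sy), bx, sx, by, sy, n_boot, seed
    )
    return _make_estimate("weighted_median", theta, se, len(bx), level)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    k = len(ratios)
    s = float(np.std(ratios, ddof=1)) if k > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) * 1.4826
    if s > 0 and mad > 0:
        spread = min(s, mad)
    elif s > 0:
        spread = s
    elif mad > 0:
        spread = mad
    else:
        return 0.0
    return phi * 0.9 * spread * k ** (-1 / 5)


def _mode_point(bx, by, sy, phi, n_grid=2048, refine=True) -> float:
    ratios = by / bx
    weights = bx**2 / sy**2
    weights = weights / np.sum(weights)
    h = _mode_bandwidth(ratios, phi)
    if h == 0.0:  # degenerate spread: every ratio identical
        return float(ratios[0])

    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, n_grid)

    def neg_density(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - ratios[None, :]) / h
        return -np.sum(weights[None, :] * np.exp(-0.5 * z**2), axis=1)

    dens = -neg_density(grid)
    i = int(np.argmax(dens))
    if not refine:
        return float(grid[i])
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda x: float(neg_density(x)[0]), bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def _weighted_mode_arrays(
    bx, sx, by, sy, phi=1.0, n_boot=1000, seed=0, level=0.95
) -> MREstimate:
    if len(bx) < 3:
        raise EstimationError("weighted_mode requires >= 3 instruments")
    if phi <= 0:
        raise EstimationError(f"phi must be positive, got {phi}")
    _check_nonzero_bx(bx)
    theta = _mode_point(bx, by, sy, phi)
    se = _bootstrap_se(
        lambda bxb, byb: _mode_point(bxb, byb, sy, phi, n_grid=512, refine=False),
        bx, sx, by, sy, n_boot, seed,
    )
    return _make_estimate("weighted_mode", theta, se, len(bx), level)


def _egger_arrays(bx, sx, by, sy, level=0.95) -> EggerResult:
    if len(bx) < 3:
        raise EstimationError("egger requires >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)  # orient to positive exposure effect
    bxo, byo = bx * sign, by * sign
    if np.ptp(bxo) == 0:
        raise SingularDesignError(
            "all exposure effects identical after orientation; no regression leverage"
        )
    w = 1.0 / sy**2
    X = sm.add_constant(bxo)
    fit = sm.WLS(byo, X, weights=w).fit()
    # fixed-effect covariance (X'WX)^-1, consistent with the IVW-FE weighting;
    # no residual-variance rescaling (see methods note)
    se = np.sqrt(np.diag(fit.normalized_cov_params))
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    slope_est = _make_estimate("egger_slope", slope, float(se[1]), len(bx), level)
    ipval = 2.0 * stats.norm.sf(abs(intercept) / se[0])
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=float(se[0]),
        intercept_pvalue=float(ipval),
    )


# ---------------------------------------------------------------------------
# public wrappers over harmonized-instrument lists
# ---------------------------------------------------------------------------

def wald_ratio(
    inst: HarmonizedInstrument, se_order: str = "first", level: float = 0.95
) -> MREstimate:
    """Single-SNP causal estimate beta_outcome / beta_exposure."""
    return _wald_arrays(
        np.float64(inst.beta_exposure), np.float64(inst.se_exposure),
        np.float64(inst.beta_outcome), np.float64(inst.se_outcome),
        se_order, level,
    )


def ivw_fe(
    insts: Sequence[HarmonizedInstrument],
    se_order: str = "first",
    level: float = 0.95,
) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate over >= 1 instrument."""
    return _ivw_arrays(*_unpack(insts), se_order, level)


def max_likelihood(
    insts: Sequence[HarmonizedInstrument],
    tol: float = 1e-8,
    maxiter: int = 200,
    level: float = 0.95,
) -> MREstimate:
    """Profile-likelihood estimate under the bivariate measurement model."""
    return _mle_arrays(*_unpack(insts), tol=tol, maxiter=maxiter, level=level)


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> MREstimate:
    """Weighted-median estimate; SE from a seeded parametric bootstrap."""
    return _weighted_median_arrays(*_unpack(insts), n_boot=n_boot, seed=seed, level=level)


def weighted_mode(
    insts: Sequence[HarmonizedInstrument],
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> MREstimate:
    """Weighted mode-based estimate; SE from a seeded parametric bootstrap."""
    return _weighted_mode_arrays(
        *_unpack(insts), phi=phi, n_boot=n_boot, seed=seed, level=level
    )


def egger(
    insts: Sequence[HarmonizedInstrument], level: float = 0.95
) -> EggerResult:
    """MR-Egger regression: pleiotropy-adjusted slope and intercept test."""
    return _egger_arrays(*_unpack(insts), level=level)
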