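"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-SNP effect pairs (gamma_j on the exposure, Gamma_j on
the outcome, with standard errors), each estimator pools the per-SNP Wald
ratios Gamma_j / gamma_j into a single causal estimate under different
assumptions about pleiotropy:

* ``ivw`` — inverse-variance-weighted regression of Gamma on gamma through
  the origin; consistent when every instrument is valid.  The headline
  flavor uses multiplicative random effects (the standard-error scale is
  inflated by sqrt(Q / (n-1)) when the heterogeneity statistic Q exceeds
  its degrees of freedom).
* ``mr_egger`` — the same regression with an intercept; the slope is robust
  to directional pleiotropy under the InSIDE assumption and the intercept
  estimates the average pleiotropic effect.
* ``weighted_median`` — consistent when instruments carrying at least half
  the weight are valid; SE by parametric bootstrap.
* ``mode_estimate`` — simple and weighted mode of the kernel-smoothed ratio
  distribution (ZEMPA: the largest cluster of agreeing ratios is assumed
  valid); SE by parametric bootstrap.
* ``mvmr_ivw`` — multivariable IVW regressing outcome effects on K exposure
  columns jointly, giving each exposure's direct effect conditional on the
  others; this is the adjusted mediator->outcome step of a two-step
  mediation design.

Confidence intervals are normal-approximation beta +/- 1.96 se throughout.
P-values are two-sided normal except for MR-Egger, which uses a t
distribution with n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrument, usable_instruments

logger = logging.getLogger("mrmediate")

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: Number of evaluation points for the mode estimator's density grid.
MODE_GRID_POINTS = 512


class EstimationError(ValueError):
    """Estimator preconditions violated (too few instruments, zero exposure beta...)."""


class CollinearityError(EstimationError):
    """Multivariable design matrix is numerically rank deficient."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate: outcome SD per exposure SD."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        beta: float,
        se: float,
        n_snp: int,
        df: Optional[int] = None,
    ) -> "MREstimate":
        """Normal-CI estimate; p-value from t with ``df`` when given, else normal."""
        if df is not None:
            p = 2.0 * stats.t.sf(abs(beta / se), df) if se > 0 else 1.0
        else:
            p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else 1.0
        p = min(max(float(p), 1e-300), 1.0)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            pvalue=p,
            n_snp=int(n_snp),
        )


def _arrays(instruments: Iterable[HarmonizedInstrument]):
    use = usable_instruments(instruments)
    bx = np.array([h.beta_exp for h in use])
    sx = np.array([h.se_exp for h in use])
    by = np.array([h.beta_out for h in use])
    sy = np.array([h.se_out for h in use])
    return use, bx, sx, by, sy


def wald_ratio(h: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta_out / beta_exp.

    First-order delta SE is se_out / |beta_exp|; the second-order variant
    adds the exposure-uncertainty term beta_out^2 se_exp^2 / beta_exp^4.
    """
    if h.beta_exp == 0:
        raise EstimationError("wald_ratio undefined for beta_exp = 0")
    beta = h.beta_out / h.beta_exp
    if second_order:
        var = h.se_out**2 / h.beta_exp**2 + h.beta_out**2 * h.se_exp**2 / h.beta_exp**4
        se = math.sqrt(var)
    else:
        se = h.se_out / abs(h.beta_exp)
    return MREstimate.from_beta_se("wald", beta, se, 1)


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    re_mode: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of Gamma on gamma through the origin.

    Closed form beta = sum(w gamma Gamma) / sum(w gamma^2) with w = 1/se_out^2.
    ``re_mode='fixed'`` uses se = 1/sqrt(sum(gamma^2/se_out^2));
    ``'multiplicative_random'`` inflates it by max(1, sqrt(Q/(n-1))).
    A single instrument always uses the fixed form.
    """
    use, bx, _, by, sy = _arrays(instruments)
    n = len(use)
    if n == 0:
        raise EstimationError("ivw requires at least one usable instrument")
    if re_mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown re_mode {re_mode!r}")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = 1.0 / math.sqrt(denom)
    method = "ivw_fixed"
    if re_mode == "multiplicative_random":
        if n == 1:
            logger.debug("ivw: single instrument, falling back to fixed-effect SE")
        else:
            q = float(np.sum(w * (by - beta * bx) ** 2))
            se *= max(1.0, math.sqrt(q / (n - 1)))
            method = "ivw_mre"
    return MREstimate.from_beta_se(method, beta, se, n)


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: WLS of Gamma on gamma with an intercept.

    Instruments are first oriented so every gamma_j > 0 (flip both members
    of a pair with negative gamma).  Returns (slope, intercept); SEs carry
    multiplicative random-effects scaling max(1, sqrt(RSS_w/(n-2))) and
    p-values use a t distribution with n-2 df.
    """
    use, bx, _, by, sy = _arrays(instruments)
    n = len(use)
    if n < 3:
        raise EstimationError("mr_egger requires at least 3 usable instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (n - 2)))
    cov = np.linalg.inv(xtwx)
    se_int, se_slope = scale * np.sqrt(np.diag(cov))
    slope = MREstimate.from_beta_se("egger_slope", coef[1], se_slope, n, df=n - 2)
    intercept = MREstimate.from_beta_se("egger_intercept", coef[0], se_int, n, df=n - 2)
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted empirical-CDF median with linear interpolation at 0.5.

    Standardized cumulative weights s_j = (cum_j - w_j/2) / sum(w), then
    interpolate the sorted values at s = 0.5.
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, v))


def _ratio_weights(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Per-SNP Wald ratios and inverse first-order-variance weights."""
    ratios = by / bx
    weights = bx**2 / sy**2  # 1 / (se_out^2 / beta_exp^2)
    return ratios, weights


def _parametric_resamples(
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
):
    """Draw (n_boot, n) exposure/outcome betas from their sampling distributions."""
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    return bxs, bys


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent when valid instruments carry >= 50% of the inverse-variance
    weight.  The bootstrap resamples every (gamma_j, Gamma_j) from
    independent normals at their standard errors, seeded for bit-for-bit
    reproducibility.
    """
    use, bx, sx, by, sy = _arrays(instruments)
    n = len(use)
    if n < 3:
        raise EstimationError("weighted_median requires at least 3 usable instruments")
    ratios, weights = _ratio_weights(bx, by, sy)
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    bxs, bys = _parametric_resamples(bx, sx, by, sy, n_boot, rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r, w = _ratio_weights(bxs[i], bys[i], sy)
        boots[i] = _weighted_median(r, w)
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se("weighted_median", beta, se, n)


def mode_bandwidth(ratios: np.ndarray, phi: float = 1.0) -> float:
    """Silverman-style bandwidth 0.9 min(sd, IQR/1.349) n^(-1/5), scaled by phi."""
    sd = float(np.std(ratios, ddof=1))
    q75, q25 = np.percentile(ratios, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-0.2)


def _kde_argmax(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    """Argmax of the weighted Gaussian KDE on a fixed grid spanning +/- 3 bandwidths."""
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, MODE_GRID_POINTS)
    dens = np.sum(
        weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
        axis=1,
    )
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    instruments: Sequence[HarmonizedInstrument],
    variant: str = "simple",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimator: argmax of the kernel-smoothed ratio density.

    ``variant='simple'`` weights every ratio equally; ``'weighted'`` weights
    by inverse ratio variance.  When all ratios coincide the bandwidth is
    zero and that common ratio is returned directly (the bootstrap SE is
    still computed).
    """
    if variant not in ("simple", "weighted"):
        raise ValueError(f"unknown mode variant {variant!r}")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    use, bx, sx, by, sy = _arrays(instruments)
    n = len(use)
    if n < 3:
        raise EstimationError("mode_estimate requires at least 3 usable instruments")

    def point(bxv, byv):
        ratios, ivw_w = _ratio_weights(bxv, byv, sy)
        w = ivw_w / ivw_w.sum() if variant == "weighted" else np.full(n, 1.0 / n)
        h = mode_bandwidth(ratios, phi)
        if h <= 0:
            return float(ratios[0])
        return _kde_argmax(ratios, w, h)

    beta = point(bx, by)
    h_used = mode_bandwidth(by / bx, phi)
    logger.debug("mode_estimate(%s): bandwidth %.6g (phi=%g)", variant, h_used, phi)
    rng = np.random.default_rng(seed)
    bxs, bys = _parametric_resamples(bx, sx, by, sy, n_boot, rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = point(bxs[i], bys[i])
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se(f"{variant}_mode", beta, se, n)


def mvmr_ivw(
    beta_exposures: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    exposure_names: Optional[Sequence[str]] = None,
    re_mode: str = "multiplicative_random",
    cond_max: float = 1e8,
) -> list[MREstimate]:
    """Multivariable IVW: WLS of outcome effects on K exposure-effect columns.

    ``beta_exposures`` is an (n_snp, K) matrix of per-SNP effects on the K
    exposures; the regression has no intercept and weights 1/se_out^2.
    Returns one estimate per exposure (each exposure's effect conditional on
    the others).  Raises on n_snp <= K or a numerically collinear design.
    """
    X = np.atleast_2d(np.asarray(beta_exposures, dtype=float))
    y = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    n, k = X.shape
    if n <= k:
        raise EstimationError(f"mvmr_ivw needs more SNPs ({n}) than exposures ({k})")
    if np.any(sy <= 0):
        raise EstimationError("outcome SEs must be strictly positive")
    w = 1.0 / sy**2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.cond(Xw) > cond_max:
        raise CollinearityError("exposure-effect columns are numerically collinear")
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    scale = 1.0
    if re_mode == "multiplicative_random" and n > k:
        resid = y - X @ coef
        rss_w = float(np.sum(w * resid**2))
        scale = max(1.0, math.sqrt(rss_w / (n - k)))
    names = list(exposure_names) if exposure_names else [f"x{i}" for i in range(k)]
    ses = scale * np.sqrt(np.diag(cov))
    return [
        MREstimate.from_beta_se("mvmr_ivw", coef[i], ses[i], n) for i in range(k)
    ]
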