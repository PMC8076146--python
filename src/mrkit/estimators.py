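"""Univariable MR estimators: Wald ratio, IVW, weighted median, MR-Egger.

All estimators consume a :class:`~mrkit.summary_data.HarmonizedSet` and report
the causal effect of the exposure on the outcome per unit of the exposure
(log-odds per log-odds when both traits are binary), with normal-theory
confidence intervals and an odds-ratio transform.

The IVW estimate is the inverse-variance-weighted combination of per-SNP Wald
ratios, equivalent to weighted least squares of outcome betas on exposure
betas through the origin with weights 1/se_out^2. Heterogeneity among per-SNP
estimates is measured by Cochran's Q and I^2; "random effects" is the
multiplicative model that inflates standard errors by sqrt(Q/df) when Q
exceeds its degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .summary_data import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are violated."""


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds (beta) scale.

    ``or_`` and its bounds are the exponentiated beta-scale quantities.
    """

    method: str
    beta: float
    se: float
    n_snps: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    pvalue: float = np.nan
    or_: float = np.nan
    or_low: float = np.nan
    or_high: float = np.nan

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se
        if np.isnan(self.pvalue):
            z = self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)
            self.pvalue = float(2 * stats.norm.sf(abs(z)))


@dataclass
class HetStats:
    """Cochran's Q heterogeneity statistic and the derived I^2 percentage."""

    Q: float
    df: int
    I2: float


@dataclass
class EggerEstimate:
    """MR-Egger regression: pleiotropy-corrected slope plus intercept test.

    The intercept estimates the average directional pleiotropic effect; an
    intercept distinguishable from zero flags directional pleiotropy.
    """

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    het: HetStats


def _het_stats(Q: float, df: int) -> HetStats:
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HetStats(Q=float(Q), df=int(df), I2=float(i2))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP causal estimate: ratio of outcome to exposure beta.

    The first-order delta-method SE, se_out/|beta_exp|, ignores the sampling
    error of the exposure beta — adequate when instruments are strong.
    """
    if beta_exp == 0:
        raise EstimationError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return to_or(MREstimate(method="wald_ratio", beta=beta, se=se, n_snps=1))


def ivw(h: HarmonizedSet, re_mode: str = "multiplicative_random") -> tuple[MREstimate, HetStats]:
    """Inverse-variance-weighted estimate with Cochran's Q / I^2.

    Weighted regression through the origin of beta_out on beta_exp with
    weights 1/se_out^2. Under ``multiplicative_random`` (the default, and the
    usual headline model) the fixed-effect SE is inflated by
    max(1, sqrt(Q/df)); a single-SNP set falls back to fixed with a warning.
    """
    if re_mode not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown re_mode {re_mode!r}")
    j = len(h)
    if j == 0:
        raise EstimationError("ivw requires at least one SNP")
    bx, _, by, sy = h.arrays()
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = j - 1
    het = _het_stats(q, df) if df >= 1 else HetStats(Q=0.0, df=0, I2=0.0)

    se = se_fixed
    method = "ivw_fixed"
    if re_mode == "multiplicative_random":
        if j == 1:
            logger.warning("ivw: single SNP — random-effects falls back to fixed")
        else:
            se = se_fixed * max(1.0, np.sqrt(q / df))
            method = "ivw_random"
    est = to_or(MREstimate(method=method, beta=beta, se=float(se), n_snps=j))
    return est, het


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median of per-SNP Wald ratios; bootstrap standard error.

    The estimator is the weighted 50th percentile of the sorted ratios
    (linear interpolation of ratio against centred normalised cumulative
    weight), consistent when valid instruments carry at least half the total
    weight. The SE is the SD of the estimate over parametric-bootstrap
    replicates redrawing both exposure and outcome betas from normals centred
    on the observed values.
    """
    j = len(h)
    if j < 3:
        raise EstimationError("weighted_median requires at least 3 SNPs")
    if seed is None:
        raise EstimationError("weighted_median requires an explicit RNG seed")
    bx, sx, by, sy = h.arrays()
    beta = _weighted_median_point(bx, by, sy)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    boots = np.array([_weighted_median_point(bx_star[b], by_star[b], sy)
                      for b in range(n_boot)])
    se = float(boots.std(ddof=1))
    return to_or(MREstimate(method="weighted_median", beta=float(beta), se=se, n_snps=j))


def _weighted_median_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    """Interpolated weighted 50th percentile of the Wald ratios."""
    ratios = by / bx
    w = (np.abs(bx) / sy) ** 2  # inverse of the delta-method ratio variance
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def mr_egger(h: HarmonizedSet, re_mode: str = "multiplicative_random") -> EggerEstimate:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    The slope is a causal estimate robust to directional pleiotropy under the
    InSIDE assumption; the intercept estimates the average direct (pleiotropic)
    effect and its p-value is the standard pleiotropy test. Requires the
    harmonised set to be oriented to non-negative exposure betas.
    """
    if re_mode not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown re_mode {re_mode!r}")
    j = len(h)
    if j < 3:
        raise EstimationError("mr_egger requires at least 3 SNPs")
    bx, _, by, sy = h.arrays()
    if (bx < 0).any():
        raise EstimationError(
            "mr_egger requires non-negative exposure betas; apply orient_positive_exposure first")
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(sw[:, None] * x, sw * by, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])

    resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    df = j - 2
    het = _het_stats(q, df)
    xtwx_inv = np.linalg.inv(x.T @ (w[:, None] * x))
    se_int, se_slope = np.sqrt(np.diag(xtwx_inv))
    if re_mode == "multiplicative_random":
        infl = max(1.0, np.sqrt(q / df))
        se_int, se_slope = se_int * infl, se_slope * infl

    slope_est = to_or(MREstimate(method="egger_slope", beta=slope, se=float(se_slope), n_snps=j))
    p_int = float(2 * stats.norm.sf(abs(intercept / se_int)))
    return EggerEstimate(slope=slope_est, intercept=intercept,
                         intercept_se=float(se_int), intercept_p=p_int, het=het)


def to_or(e: MREstimate) -> MREstimate:
    """Fill the odds-ratio fields by exponentiating the beta-scale estimate."""
    return replace(e, or_=float(np.exp(e.beta)),
                   or_low=float(np.exp(e.ci_low)), or_high=float(np.exp(e.ci_high)))
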