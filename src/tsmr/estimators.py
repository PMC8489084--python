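"""Causal-effect estimators for two-sample summary-data MR.

All estimators consume a :class:`~tsmr.summary_data.HarmonizedDataset` and
return a :class:`MrEstimate` on the log-odds scale with the odds ratio and
its 95% CI attached.

The per-variant building block is the Wald ratio ``r_i = beta_out / beta_exp``
with first-order (delta-method) standard error ``se_out / |beta_exp|``.
The inverse-variance-weighted (IVW) estimate is the precision-weighted mean
of the ratios — equivalently a weighted regression of outcome on exposure
betas through the origin — and assumes every instrument is valid.  The
weighted median tolerates up to half the weight coming from invalid
instruments; MR-Egger frees the intercept, whose distance from zero measures
average directional pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_data import HarmonizedDataset, HarmonizedRecord

__all__ = [
    "MrEstimate",
    "EggerInterceptResult",
    "EstimatorError",
    "Z_95",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
]

#: 97.5% normal quantile used for all 95% confidence intervals
Z_95 = 1.959964


class EstimatorError(ValueError):
    """Raised when a dataset cannot support the requested estimator."""


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate: log-odds per SD of exposure, with OR scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    exposure_name: str = ""
    outcome_name: str = ""

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z_95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z_95 * self.se))


@dataclass(frozen=True)
class EggerInterceptResult:
    """MR-Egger intercept: average directional pleiotropy on the log-odds scale."""

    intercept: float
    se: float
    pvalue: float


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _make_estimate(
    method: str, beta: float, se: float, n_snp: int, data: HarmonizedDataset,
    pvalue: float | None = None,
) -> MrEstimate:
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pvalue=_normal_p(beta, se) if pvalue is None else float(pvalue),
        n_snp=n_snp,
        exposure_name=data.exposure_name,
        outcome_name=data.outcome_name,
    )


def wald_ratio(record: HarmonizedRecord,
               exposure_name: str = "", outcome_name: str = "") -> MrEstimate:
    """Single-variant causal estimate ``beta_out / beta_exp``.

    The SE is the first-order delta approximation ``se_out / |beta_exp|``,
    which ignores sampling error in the exposure beta.
    """
    if record.beta_exposure == 0:
        raise EstimatorError(f"{record.rsid}: zero exposure beta, ratio undefined")
    beta = record.beta_outcome / record.beta_exposure
    se = record.se_outcome / abs(record.beta_exposure)
    return MrEstimate(
        method="wald_ratio",
        beta=beta,
        se=se,
        pvalue=_normal_p(beta, se),
        n_snp=1,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )


def _ratio_weights(data: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and first-order inverse-variance weights."""
    bx, _, by, sy = data.arrays()
    if np.any(bx == 0):
        bad = [r.rsid for r in data if r.beta_exposure == 0]
        raise EstimatorError(f"zero exposure beta for {bad}; ratios undefined")
    return by / bx, bx**2 / sy**2


def _ivw_beta_q(data: HarmonizedDataset) -> tuple[float, float, float]:
    """(IVW beta, fixed-effect SE, Cochran's Q) shared by ivw and diagnostics."""
    r, w = _ratio_weights(data)
    beta = float(np.sum(w * r) / np.sum(w))
    se_fe = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    return beta, se_fe, q


def ivw(
    data: HarmonizedDataset, mode: str = "multiplicative_random"
) -> MrEstimate:
    """Inverse-variance-weighted estimate over all instruments.

    The point estimate is identical in both modes; ``multiplicative_random``
    (the default) inflates the fixed-effect SE by ``sqrt(Q / (k - 1))`` when
    Cochran's Q exceeds its degrees of freedom, and never deflates it.
    With a single instrument the estimate degrades to the Wald ratio.
    """
    if mode not in {"fixed", "multiplicative_random"}:
        raise ValueError(f"unknown IVW mode {mode!r}")
    k = len(data)
    if k == 0:
        raise EstimatorError("empty dataset")
    if k == 1:
        est = wald_ratio(data.records[0], data.exposure_name, data.outcome_name)
        return MrEstimate(
            method=f"ivw_{'fe' if mode == 'fixed' else 'mre'}",
            beta=est.beta, se=est.se, pvalue=est.pvalue, n_snp=1,
            exposure_name=data.exposure_name, outcome_name=data.outcome_name,
        )
    beta, se_fe, q = _ivw_beta_q(data)
    if mode == "fixed":
        return _make_estimate("ivw_fe", beta, se_fe, k, data)
    inflation = max(1.0, np.sqrt(q / (k - 1)))
    return _make_estimate("ivw_mre", beta, se_fe * inflation, k, data)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` under ``weights``.

    Sort ratios ascending, place each at the midpoint of its normalized
    weight interval, and linearly interpolate the ratio at cumulative
    weight 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(
    data: HarmonizedDataset, n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The estimate is the inverse-variance-weight median of the per-SNP Wald
    ratios and remains consistent while valid instruments carry more than
    half the total weight.  The SE is the standard deviation of the estimate
    across ``n_boot`` parametric resamples of every beta from a normal with
    its reported mean and SE; ``seed`` makes it reproducible.
    """
    k = len(data)
    if k < 3:
        raise EstimatorError(f"weighted median needs >= 3 instruments, got {k}")
    if n_boot < 2:
        raise EstimatorError(f"n_boot must be >= 2, got {n_boot}")
    bx, sx, by, sy = data.arrays()
    ratios, weights = _ratio_weights(data)
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        r = by_star[b] / bx_star[b]
        w = bx_star[b] ** 2 / sy**2
        estimates[b] = _weighted_median_point(r, w)
    se = float(np.std(estimates, ddof=1))
    return _make_estimate("weighted_median", point, se, k, data)


def _egger_fit(
    data: HarmonizedDataset, with_intercept: bool = True
) -> tuple[np.ndarray, np.ndarray, int]:
    """Weighted least squares of beta_out on beta_exp, weights 1/se_out^2.

    Returns (coefficients, standard errors, residual df).  Coefficients are
    ordered (intercept, slope) when the intercept is included, else (slope,).
    SEs carry the usual residual scale ``sqrt(RSS_w / df)``.
    """
    bx, _, by, sy = data.arrays()
    k = len(bx)
    w = 1.0 / sy**2
    if with_intercept:
        X = np.column_stack([np.ones(k), bx])
    else:
        X = bx[:, None]
    p = X.shape[1]
    A = (X.T * w) @ X
    if np.linalg.matrix_rank(A) < p:
        raise EstimatorError(
            "degenerate design: exposure betas are collinear with the intercept"
        )
    coef = np.linalg.solve(A, (X.T * w) @ by)
    resid = by - X @ coef
    df = k - p
    sigma = np.sqrt(np.sum(w * resid**2) / df) if df > 0 else 0.0
    se = np.sqrt(np.diag(np.linalg.inv(A))) * sigma
    return coef, se, df


def egger(data: HarmonizedDataset) -> tuple[MrEstimate, EggerInterceptResult]:
    """MR-Egger regression: pleiotropy-robust slope plus intercept test.

    Weighted least squares of outcome betas on exposure betas with a free
    intercept, weights ``1/se_out^2``.  The slope estimates the causal
    effect under the InSIDE assumption; the intercept estimates average
    directional pleiotropy, and its two-sided p-value (t distribution with
    k - 2 df, matching the usual least-squares inference at these small
    instrument counts) is the pleiotropy test.
    """
    k = len(data)
    if k < 3:
        raise EstimatorError(f"MR-Egger needs >= 3 instruments, got {k}")
    coef, se, df = _egger_fit(data, with_intercept=True)
    (a, b), (se_a, se_b) = coef, se
    p_slope = float(2.0 * stats.t.sf(abs(b) / se_b, df))
    p_int = float(2.0 * stats.t.sf(abs(a) / se_a, df))
    slope = _make_estimate("egger_slope", b, se_b, k, data, pvalue=p_slope)
    intercept = EggerInterceptResult(
        intercept=float(a), se=float(se_a), pvalue=p_int
    )
    return slope, intercept
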