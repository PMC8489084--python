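"""Heterogeneity, pleiotropy and outlier diagnostics.

Cochran's Q measures whether the per-variant Wald ratios scatter around the
pooled IVW estimate more than their sampling errors allow; funnel-plot
coordinates expose the same information visually.  The leave-one-out table
probes whether any single instrument drives the pooled estimate.  MR-PRESSO
tests global pleiotropy via a simulated null distribution of the weighted
residual sum of squares, flags individual outlying instruments and, when it
finds any, re-estimates the effect without them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EstimatorError,
    MrEstimate,
    _ivw_beta_q,
    ivw,
    wald_ratio,
)
from .summary_data import HarmonizedDataset

__all__ = [
    "HeterogeneityResult",
    "LeaveOneOutRow",
    "PressoResult",
    "cochran_q",
    "single_snp_table",
    "leave_one_out",
    "mr_presso",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square df and upper-tail p-value."""

    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class LeaveOneOutRow:
    dropped_rsid: str
    estimate: MrEstimate


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global test, per-variant outlier tests and corrected estimate."""

    rss_obs: float
    global_pvalue: float
    outlier_rsids: list[str]
    per_snp_pvalues: dict[str, float]
    outlier_threshold: float
    corrected_estimate: MrEstimate | None = None
    distortion_pvalue: float | None = None


def cochran_q(data: HarmonizedDataset) -> HeterogeneityResult:
    """Cochran's Q over the Wald ratios, chi-square(k-1) under homogeneity.

    Uses the same ratios and first-order weights as the IVW estimator, so
    Q = 0 exactly when all ratios coincide.
    """
    k = len(data)
    if k < 2:
        raise EstimatorError(f"Cochran's Q needs >= 2 instruments, got {k}")
    _, _, q = _ivw_beta_q(data)
    df = k - 1
    return HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def single_snp_table(data: HarmonizedDataset) -> pd.DataFrame:
    """Per-variant Wald ratios with SE and precision (funnel-plot coordinates).

    Columns: rsid, ratio, ratio_se, precision (= 1/SE).  A funnel plot is
    ratio on x against precision on y; asymmetry suggests directional
    pleiotropy.
    """
    if len(data) < 1:
        raise EstimatorError("empty dataset")
    rows = []
    for rec in data:
        est = wald_ratio(rec)
        rows.append(
            {
                "rsid": rec.rsid,
                "ratio": est.beta,
                "ratio_se": est.se,
                "precision": 1.0 / est.se,
            }
        )
    return pd.DataFrame(rows)


def leave_one_out(
    data: HarmonizedDataset, mode: str = "multiplicative_random"
) -> list[LeaveOneOutRow]:
    """IVW re-estimated k times, each time excluding one instrument.

    A pooled estimate that swings when one variant is removed points to that
    variant being pleiotropic or outlying.  Row order follows the dataset.
    """
    if len(data) < 3:
        raise EstimatorError(f"leave-one-out needs >= 3 instruments, got {len(data)}")
    return [
        LeaveOneOutRow(dropped_rsid=r.rsid, estimate=ivw(data.drop(r.rsid), mode=mode))
        for r in data
    ]


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over which index is left out.

    With regression-scale weights ``w = 1/se_out^2`` the IVW slope is
    ``sum(w x y) / sum(w x^2)``; dropping index i subtracts its term from
    both sums.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
    distortion_test: bool = False,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier flags, corrected estimate.

    The observed statistic is the weighted residual sum of squares
    ``RSS = sum_i (beta_out_i - bhat_(-i) * beta_exp_i)^2 / se_out_i^2``
    where ``bhat_(-i)`` is the IVW slope excluding variant i.  Its null
    distribution is built from ``n_sim`` parametric simulations that redraw
    both betas from their reported sampling distributions under the
    no-pleiotropy model, giving an add-one simulation p-value (never zero).
    Per-variant residuals are compared with their own simulated
    distributions; variants below ``outlier_alpha / k`` (Bonferroni) are
    flagged and the IVW estimate is recomputed without them.

    The optional distortion test compares the raw-vs-corrected shift with
    the shift from removing equally many randomly chosen variants.
    Identical ``seed``/``n_sim`` give bit-identical results.
    """
    k = len(data)
    if k < 4:
        raise EstimatorError(f"MR-PRESSO needs >= 4 instruments, got {k}")
    if n_sim < 100:
        raise EstimatorError(f"n_sim must be >= 100, got {n_sim}")
    bx, sx, by, sy = data.arrays()
    w = 1.0 / sy**2

    loo_beta = _loo_ivw_betas(bx, by, w)
    resid_obs = w * (by - loo_beta * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    # expected outcome effects under the no-pleiotropy null, per leave-one-out slope
    by_star = rng.normal(loo_beta * bx, sy, size=(n_sim, k))
    loo_star = _loo_ivw_betas(bx_star, by_star, np.broadcast_to(w, (n_sim, k)))
    resid_star = w * (by_star - loo_star * bx_star) ** 2
    rss_star = np.sum(resid_star, axis=1)

    global_pvalue = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(resid_star >= resid_obs, axis=0)) / (n_sim + 1)
    threshold = outlier_alpha / k
    flagged = [data.records[i].rsid for i in np.flatnonzero(per_snp_p < threshold)]
    per_snp = {r.rsid: float(p) for r, p in zip(data.records, per_snp_p)}

    corrected = None
    distortion_pvalue = None
    if flagged:
        keep = [r.rsid for r in data if r.rsid not in flagged]
        if len(keep) >= 2:
            corrected = ivw(data.subset(keep))
            if distortion_test:
                raw_beta = ivw(data).beta
                observed_shift = raw_beta - corrected.beta
                n_out = len(flagged)
                keep_idx = np.array(
                    [i for i, r in enumerate(data.records) if r.rsid in keep]
                )
                shifts = np.empty(n_sim)
                for s in range(n_sim):
                    removed = rng.choice(keep_idx, size=n_out, replace=False)
                    mask = np.ones(k, dtype=bool)
                    mask[removed] = False
                    sub_beta = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(
                        w[mask] * bx[mask] ** 2
                    )
                    shifts[s] = raw_beta - sub_beta
                distortion_pvalue = float(
                    (1 + np.sum(np.abs(shifts) >= abs(observed_shift))) / (n_sim + 1)
                )
    return PressoResult(
        rss_obs=rss_obs,
        global_pvalue=global_pvalue,
        outlier_rsids=flagged,
        per_snp_pvalues=per_snp,
        outlier_threshold=threshold,
        corrected_estimate=corrected,
        distortion_pvalue=distortion_pvalue,
    )
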