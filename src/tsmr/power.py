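"""Statistical power for MR with a binary outcome, and its inversion.

Implements the standard non-centrality-parameter approximation for a
two-stage instrumental-variable analysis of a case/control outcome (the
routine behind the mRnd web calculator).  With case fraction ``K`` and an
alternative-hypothesis odds ratio ``OR`` per SD of exposure, the attenuated
mean shift is

    b = K * (OR / (1 + K*(OR - 1)) - 1)

its variance ``v = (K*(1-K) - b^2) / (N * R2)`` where ``R2`` is the
variance of the exposure explained by the instruments, and the test
statistic is non-central chi-square with 1 df and NCP ``b^2 / v``.
``find_detectable_or`` inverts the calculation to the smallest odds ratio
detectable at a target power.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "PowerResult", "PowerError", "power_binary", "find_detectable_or"]


class PowerError(ValueError):
    """Raised for degenerate power-calculation regimes."""


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a binary-outcome MR power calculation.

    n_total/n_cases: outcome-study sample size and case count; r2: variance
    of the exposure explained by the instruments, in (0,1); alpha: two-sided
    significance level; or_alt: alternative-hypothesis OR per SD of exposure.
    """

    n_total: int
    n_cases: int
    r2: float
    alpha: float = 0.05
    or_alt: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.n_cases < self.n_total):
            raise PowerError(
                f"need 0 < n_cases < n_total, got {self.n_cases}/{self.n_total}"
            )
        if not (0.0 < self.r2 < 1.0):
            raise PowerError(f"r2 must be in (0, 1), got {self.r2}")
        if not (0.0 < self.alpha < 1.0):
            raise PowerError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (self.or_alt > 0):
            raise PowerError(f"or_alt must be > 0, got {self.or_alt}")


@dataclass(frozen=True)
class PowerResult:
    power: float
    ncp: float


def _ncp(spec: PowerSpec) -> float:
    k = spec.n_cases / spec.n_total
    b = k * (spec.or_alt / (1.0 + k * (spec.or_alt - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b * b) / (spec.n_total * spec.r2)
    if v <= 0:
        raise PowerError(
            f"variance term non-positive (K={k:.3f}, OR={spec.or_alt:.3f}): "
            "the attenuated effect exceeds the binomial variance bound; "
            "no power is defined in this regime"
        )
    return b * b / v


def power_binary(spec: PowerSpec) -> PowerResult:
    """Power of the two-sided Wald/chi-square test at ``spec.alpha``.

    Equals ``alpha`` exactly at ``or_alt = 1`` and grows monotonically with
    sample size, instrument R2 and effect size.
    """
    ncp = _ncp(spec)
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    power = float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else spec.alpha
    return PowerResult(power=power, ncp=float(ncp))


def _power_at(n_total: int, n_cases: int, r2: float, alpha: float, or_alt: float) -> float:
    return power_binary(
        PowerSpec(n_total=n_total, n_cases=n_cases, r2=r2, alpha=alpha, or_alt=or_alt)
    ).power


def find_detectable_or(
    n_total: int,
    n_cases: int,
    r2: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    protective: bool = False,
    tol: float = 1e-6,
) -> float:
    """Smallest odds ratio detectable at ``target_power``.

    Bisects over OR > 1 (power is monotone increasing there); with
    ``protective=True`` the mirrored bracket OR < 1 is searched instead.
    The upper bracket is capped where the variance term of the NCP formula
    turns non-positive, beyond which power is undefined.
    """
    if not (alpha < target_power < 1.0):
        raise PowerError(
            f"target_power must be in (alpha, 1), got {target_power} (alpha={alpha})"
        )

    def power_of(or_alt: float) -> float:
        return _power_at(n_total, n_cases, r2, alpha, or_alt)

    if protective:
        lo, hi = 1e-6, 1.0 - 1e-6  # power decreasing in OR on (0, 1)
        p_lo = power_of(lo)
        if p_lo < target_power:
            raise PowerError(
                f"target power {target_power} unreachable: power at OR={lo} is {p_lo:.4f}"
            )
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if power_of(mid) >= target_power:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lo, hi = 1.0 + 1e-6, 50.0
    while True:  # shrink past the regime where the variance term is negative
        try:
            p_hi = power_of(hi)
            break
        except PowerError:
            hi *= 0.95
            if hi <= lo:
                raise PowerError("no valid OR bracket above 1") from None
    if p_hi < target_power:
        raise PowerError(
            f"target power {target_power} unreachable: power spans "
            f"[{power_of(lo):.4f}, {p_hi:.4f}] on OR in [{lo:.3f}, {hi:.3f}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_of(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
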