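"""Simulation of two-sample GWAS summary statistics with known ground truth.

The generator mimics the asymptotic two-sample setup: a set of independent
instruments with fixed true effects ``gamma_i`` on the exposure, a causal
effect ``b`` of the exposure on the (log-odds of the) outcome, and optional
per-variant direct (pleiotropic) effects ``alpha_i`` that bypass the
exposure.  Observed betas are the truth plus Gaussian sampling noise with
the configured standard errors, exactly the model under which the IVW,
weighted-median and Egger estimators are derived.

Instrument effects (and cosmetic EAFs/alleles) are realized once per
configuration from ``config.seed``; only the sampling noise varies with the
per-call seed, so Monte-Carlo replicates isolate sampling variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .summary_data import SnpAssociation

__all__ = [
    "SimulationConfig",
    "SimulatedStudyPair",
    "SimulationTruth",
    "simulate_pair",
    "table1_like_config",
    "load_config",
]

_PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise levels for one simulated study pair.

    ``instrument_effects`` is either an explicit per-SNP list or a
    ``(low, high)`` range to draw from uniformly (once per config).
    ``se_exposure`` / ``se_outcome`` are scalars or per-SNP lists.
    ``n_outliers`` variants get an extra ``outlier_shift`` added to their
    true outcome effect, planting detectable pleiotropic outliers.
    """

    n_snp: int
    true_beta: float = 0.0
    instrument_effects: Sequence[float] | tuple[float, float] = (0.02, 0.1)
    se_exposure: float | Sequence[float] = 0.003
    se_outcome: float | Sequence[float] = 0.03
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError(f"n_snp must be >= 1, got {self.n_snp}")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not (0 <= self.n_outliers < self.n_snp):
            raise ValueError("need 0 <= n_outliers < n_snp")
        for se in (self._se_array("se_exposure"), self._se_array("se_outcome")):
            if np.any(se <= 0):
                raise ValueError("all standard errors must be > 0")
        if (
            not self._effects_are_range()
            and len(tuple(self.instrument_effects)) != self.n_snp
        ):
            raise ValueError(
                "explicit instrument_effects must have length n_snp"
            )

    def _effects_are_range(self) -> bool:
        eff = tuple(self.instrument_effects)
        return len(eff) == 2 and self.n_snp != 2

    def _se_array(self, which: str) -> np.ndarray:
        value = getattr(self, which)
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_snp,))
        return np.array(arr)


@dataclass(frozen=True)
class SimulationTruth:
    """Per-variant ground truth recorded alongside the observed statistics."""

    true_beta: float
    instrument_effects: np.ndarray
    direct_effects: np.ndarray
    outlier_indices: np.ndarray


@dataclass(frozen=True)
class SimulatedStudyPair:
    exposure: list[SnpAssociation]
    outcome: list[SnpAssociation]
    truth: SimulationTruth


def _realize_instruments(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instrument effects, EAFs and outlier indices — fixed given config.seed."""
    rng = np.random.default_rng(config.seed)
    if config._effects_are_range():
        lo, hi = config.instrument_effects
        gamma = rng.uniform(lo, hi, size=config.n_snp)
    else:
        gamma = np.asarray(tuple(config.instrument_effects), dtype=float)
        rng.uniform(0, 1, size=config.n_snp)  # keep stream position stable
    eaf = rng.uniform(0.1, 0.9, size=config.n_snp)
    outliers = rng.choice(config.n_snp, size=config.n_outliers, replace=False)
    return gamma, eaf, np.sort(outliers)


def simulate_pair(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedStudyPair:
    """Draw one two-sample summary-statistic dataset from ``config``.

    ``seed`` overrides the noise seed for Monte-Carlo replication; the
    instrument effects, EAFs and planted-outlier positions stay those
    implied by ``config.seed``.  Identical (config, seed) gives bit-identical
    output.  P-values are computed from the simulated z-scores.
    """
    gamma, eaf, outlier_idx = _realize_instruments(config)
    se_exp = config._se_array("se_exposure")
    se_out = config._se_array("se_outcome")

    noise_rng = np.random.default_rng(config.seed if seed is None else seed)
    alpha = np.zeros(config.n_snp)
    if config.pleiotropy_mode == "balanced":
        alpha = noise_rng.normal(0.0, config.pleiotropy_sd, size=config.n_snp)
    elif config.pleiotropy_mode == "directional":
        alpha = noise_rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=config.n_snp
        )
    gamma_outcome = config.true_beta * gamma + alpha
    gamma_outcome = gamma_outcome.copy()
    gamma_outcome[outlier_idx] += config.outlier_shift

    beta_exp = noise_rng.normal(gamma, se_exp)
    beta_out = noise_rng.normal(gamma_outcome, se_out)

    def _assoc(beta: np.ndarray, se: np.ndarray) -> list[SnpAssociation]:
        out = []
        for i in range(config.n_snp):
            z = beta[i] / se[i]
            p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 5e-324, 1.0))
            out.append(
                SnpAssociation(
                    rsid=f"sim{i + 1:04d}",
                    effect_allele="A",
                    other_allele="G",
                    eaf=float(eaf[i]),
                    beta=float(beta[i]),
                    se=float(se[i]),
                    pvalue=p,
                    chrom=str(i % 22 + 1),
                    nearby_gene="synthetic",
                )
            )
        return out

    with warnings.catch_warnings():
        # simulated p-values are exact normal tails by construction; the
        # round-trip soft check is redundant noise here
        warnings.simplefilter("ignore")
        exposure = _assoc(beta_exp, se_exp)
        outcome = _assoc(beta_out, se_out)
    truth = SimulationTruth(
        true_beta=config.true_beta,
        instrument_effects=gamma,
        direct_effects=alpha + np.where(
            np.isin(np.arange(config.n_snp), outlier_idx), config.outlier_shift, 0.0
        ),
        outlier_indices=outlier_idx,
    )
    return SimulatedStudyPair(exposure=exposure, outcome=outcome, truth=truth)


# per-exposure Table-1-scale instrument effects and standard errors
_TABLE1_SCALES = {
    "25ohd": {
        "effects": (0.089, 0.036, 0.031, 0.026, 0.017, 0.017),
        "se_exposure": (0.002, 0.002, 0.002, 0.003, 0.002, 0.003),
        "se_outcome": (0.029, 0.033, 0.027, 0.035, 0.028, 0.034),
    },
    "calcium": {
        "effects": (0.071, 0.018, 0.018, 0.018, 0.017, 0.022, 0.027),
        "se_exposure": (0.004, 0.003, 0.003, 0.003, 0.003, 0.004, 0.005),
        "se_outcome": (0.039, 0.028, 0.028, 0.030, 0.028, 0.037, 0.046),
    },
    "pth": {
        "effects": (0.070, 0.030, 0.040, 0.020, 0.030),
        "se_exposure": (0.003, 0.003, 0.003, 0.003, 0.004),
        "se_outcome": (0.030, 0.030, 0.030, 0.029, 0.039),
    },
}


def table1_like_config(
    exposure_name: str,
    true_beta: float = 0.0,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """A config matching the published instrument sets' precision regime.

    Instrument counts, effect sizes and both studies' standard errors equal
    those of the named bundled exposure (``25OHD``, ``calcium`` or ``PTH``);
    the causal effect and any pleiotropy are free parameters.  Useful for
    studying estimator behaviour at exactly the reproduced analysis' scale.
    """
    key = exposure_name.strip().lower().replace("-", "").replace("s25ohd", "25ohd")
    if key not in _TABLE1_SCALES:
        raise KeyError(
            f"unknown exposure {exposure_name!r}; valid: ['25OHD', 'calcium', 'PTH']"
        )
    scale = _TABLE1_SCALES[key]
    params = dict(
        n_snp=len(scale["effects"]),
        true_beta=true_beta,
        instrument_effects=scale["effects"],
        se_exposure=scale["se_exposure"],
        se_outcome=scale["se_outcome"],
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML key-value file.

    Keys mirror the dataclass fields; unknown keys raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; valid: {sorted(valid)}")
    return SimulationConfig(**raw)
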