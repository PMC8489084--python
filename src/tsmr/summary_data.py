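"""Summary-statistic data model, I/O, instrument filtering and harmonization.

The unit of analysis is a genetic variant's association with a trait in one
GWAS: effect allele, other allele, effect-allele frequency, beta, SE and
p-value (:class:`SnpAssociation`).  Pairing the exposure-study and
outcome-study associations of the same variant on a common effect allele
yields a :class:`HarmonizedRecord`; a set of those is a
:class:`HarmonizedDataset`, the input every causal estimator consumes.

Bundled with the package are the instrument sets for three exposures —
serum 25-hydroxyvitamin D (6 SNPs), serum calcium (7 SNPs) and serum
parathyroid hormone (5 SNPs) — together with their associations with
coronary artery disease in a diabetic population, available through
:func:`load_fixture`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpAssociation",
    "HarmonizedRecord",
    "HarmonizedDataset",
    "SummaryDataError",
    "read_summary_table",
    "write_summary_table",
    "significance_filter",
    "harmonize",
    "load_fixture",
    "FIXTURE_NAMES",
]

logger = logging.getLogger(__name__)

#: canonical column order of the summary-statistics TSV dialect
CANONICAL_COLUMNS = (
    "rsid",
    "chrom",
    "gene",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryDataError(ValueError):
    """Raised for malformed summary-statistic inputs."""


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary statistics in one study.

    ``beta`` is in SD units for a quantitative exposure and log-odds for a
    binary outcome.  ``eaf`` may be ``None`` when the source does not report
    an effect-allele frequency (common for outcome studies).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    chrom: str = ""
    nearby_gene: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise SummaryDataError("rsid must be non-empty")
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(
                f"{self.rsid}: effect allele equals other allele ({self.effect_allele})"
            )
        if not (self.se > 0):
            raise SummaryDataError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SummaryDataError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise SummaryDataError(
                f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]"
            )
        self._check_pvalue_consistency()

    def _check_pvalue_consistency(self) -> None:
        # soft check: the reported p and |beta/se| should imply comparable
        # normal z-scores; warn, never fail.  Compared on the z scale rather
        # than the p scale because rounding published betas/SEs to a few
        # decimals shifts extreme p-values by many orders of magnitude while
        # moving z only modestly; a factor-2 z discrepancy still catches
        # wrong-column and wrong-unit errors.
        z_implied = abs(self.beta / self.se)
        z_reported = float(stats.norm.isf(self.pvalue / 2.0))
        if not math.isfinite(z_reported):  # p underflowed; nothing to compare
            return
        if max(z_implied, z_reported) < 1.0:
            return
        lo, hi = sorted([max(z_implied, 1e-3), max(z_reported, 1e-3)])
        if hi / lo > 2.0:
            warnings.warn(
                f"{self.rsid}: reported p={self.pvalue:.3g} (z~{z_reported:.2f}) "
                f"is inconsistent with |beta/se|={z_implied:.2f}",
                stacklevel=3,
            )

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is ambiguous."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass(frozen=True)
class HarmonizedRecord:
    """Paired exposure/outcome effects of one variant on a common effect allele."""

    rsid: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (self.se_exposure > 0 and self.se_outcome > 0):
            raise SummaryDataError(f"{self.rsid}: standard errors must be > 0")


@dataclass
class HarmonizedDataset:
    """Ordered collection of harmonized exposure/outcome records."""

    exposure_name: str
    outcome_name: str
    records: list[HarmonizedRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            dup = sorted({r for r in rsids if rsids.count(r) > 1})
            raise SummaryDataError(f"duplicate rsids in dataset: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HarmonizedRecord]:
        return iter(self.records)

    def drop(self, rsid: str) -> "HarmonizedDataset":
        """Return a copy without the named variant."""
        if rsid not in {r.rsid for r in self.records}:
            raise KeyError(rsid)
        return HarmonizedDataset(
            self.exposure_name,
            self.outcome_name,
            [r for r in self.records if r.rsid != rsid],
        )

    def subset(self, rsids: Iterable[str]) -> "HarmonizedDataset":
        keep = set(rsids)
        return HarmonizedDataset(
            self.exposure_name,
            self.outcome_name,
            [r for r in self.records if r.rsid in keep],
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) as arrays."""
        bx = np.array([r.beta_exposure for r in self.records], dtype=float)
        sx = np.array([r.se_exposure for r in self.records], dtype=float)
        by = np.array([r.beta_outcome for r in self.records], dtype=float)
        sy = np.array([r.se_outcome for r in self.records], dtype=float)
        return bx, sx, by, sy

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "effect_allele": [r.effect_allele for r in self.records],
                "beta_exposure": [r.beta_exposure for r in self.records],
                "se_exposure": [r.se_exposure for r in self.records],
                "beta_outcome": [r.beta_outcome for r in self.records],
                "se_outcome": [r.se_outcome for r in self.records],
                "eaf_exposure": [r.eaf_exposure for r in self.records],
                "flipped": [r.flipped for r in self.records],
                "palindromic": [r.palindromic for r in self.records],
            }
        )


def read_summary_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read a tab-separated summary-statistics table.

    ``dialect`` maps canonical field names (``rsid``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, optionally
    ``chrom`` and ``gene``) to the column names actually present in the file.
    Scientific notation is accepted; ``NA`` / empty EAF is allowed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    colmap = {name: name for name in CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)
    required = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue")
    for canonical in required:
        if colmap[canonical] not in table.columns:
            raise SummaryDataError(
                f"{path.name}: required column {colmap[canonical]!r} "
                f"(for field {canonical!r}) not found; "
                f"available: {list(table.columns)}"
            )

    def _num(raw: str, fieldname: str, line: int, optional: bool = False) -> float | None:
        raw = raw.strip()
        if optional and raw.upper() in {"", "NA", "NAN", "."}:
            return None
        try:
            value = float(raw)
        except ValueError:
            raise SummaryDataError(
                f"{path.name} line {line}: cannot parse {fieldname}={raw!r} as a number"
            ) from None
        if fieldname == "pvalue" and value == 0.0 and not raw.lstrip("+").startswith(("0", ".", "-")):
            # printed p like 4.74E-343 underflows double precision; clamp to
            # the smallest positive float rather than reject the row
            value = 5e-324
        return value

    records: list[SnpAssociation] = []
    for idx, row in table.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            rec = SnpAssociation(
                rsid=row[colmap["rsid"]].strip(),
                effect_allele=row[colmap["effect_allele"]].strip().upper(),
                other_allele=row[colmap["other_allele"]].strip().upper(),
                eaf=_num(row[colmap["eaf"]], "eaf", line, optional=True),
                beta=_num(row[colmap["beta"]], "beta", line),
                se=_num(row[colmap["se"]], "se", line),
                pvalue=_num(row[colmap["pvalue"]], "pvalue", line),
                chrom=str(row[colmap["chrom"]]).strip() if colmap["chrom"] in table.columns else "",
                nearby_gene=str(row[colmap["gene"]]).strip() if colmap["gene"] in table.columns else "",
            )
        except SummaryDataError as exc:
            raise SummaryDataError(f"{path.name} line {line}: {exc}") from None
        records.append(rec)
    return records


def write_summary_table(assocs: Sequence[SnpAssociation], path: str | Path) -> None:
    """Write associations as a canonical TSV at full float precision."""
    rows = []
    for a in assocs:
        rows.append(
            {
                "rsid": a.rsid,
                "chrom": a.chrom,
                "gene": a.nearby_gene,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "eaf": "NA" if a.eaf is None else repr(a.eaf),
                "beta": repr(a.beta),
                "se": repr(a.se),
                "pvalue": repr(a.pvalue),
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def significance_filter(
    assocs: Sequence[SnpAssociation], threshold: float = 5e-8
) -> list[SnpAssociation]:
    """Keep associations with p strictly below ``threshold`` (default 5e-8).

    Enforces the instrument-relevance assumption: only genome-wide
    significant variants qualify as instruments.  Order is preserved.
    """
    if not (0.0 < threshold < 1.0) and threshold != 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return [a for a in assocs if a.pvalue < threshold]


def _alleles_match(exp: SnpAssociation, out: SnpAssociation) -> str:
    """Classify the allele configuration of an exposure/outcome pair.

    Returns one of ``same``, ``swapped``, ``same_strandflip``,
    ``swapped_strandflip`` or ``irreconcilable``.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea, oa):
        return "same"
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return "swapped"
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (out.effect_allele, out.other_allele) == (cea, coa):
        return "same_strandflip"
    if (out.effect_allele, out.other_allele) == (coa, cea):
        return "swapped_strandflip"
    return "irreconcilable"


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindromic_eaf_window: float = 0.08,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    reorient_positive_exposure: bool = False,
) -> HarmonizedDataset:
    """Align outcome effects onto the exposure study's effect alleles.

    Variants are inner-joined on rsid.  When the outcome study reports the
    opposite allele as its effect allele, the outcome beta is negated and its
    EAF complemented (``flipped=True``).  Strand complements are resolved
    before giving up.  Palindromic variants (A/T, C/G) whose exposure EAF
    lies within ``palindromic_eaf_window`` of 0.5 are dropped as strand-
    ambiguous; irreconcilable allele pairs are dropped.  Both drop reasons
    are logged per variant.

    ``reorient_positive_exposure`` re-signs each record so that the exposure
    beta is non-negative; off by default so published datasets keep their
    printed orientation (the Egger intercept is not invariant to it).
    """
    out_by_rsid = {a.rsid: a for a in outcome}
    shared = [a for a in exposure if a.rsid in out_by_rsid]
    if not shared:
        raise SummaryDataError(
            "no shared rsids between exposure and outcome studies"
        )

    records: list[HarmonizedRecord] = []
    for exp in shared:
        out = out_by_rsid[exp.rsid]
        palindromic = exp.is_palindromic
        if palindromic:
            eaf = exp.eaf if exp.eaf is not None else 0.5
            if abs(min(eaf, 1.0 - eaf) - 0.5) <= palindromic_eaf_window:
                logger.info(
                    "dropping %s: palindromic with EAF %.3f too close to 0.5",
                    exp.rsid,
                    eaf,
                )
                continue

        config = _alleles_match(exp, out)
        if config == "irreconcilable":
            logger.info(
                "dropping %s: alleles %s/%s vs %s/%s cannot be reconciled",
                exp.rsid,
                exp.effect_allele,
                exp.other_allele,
                out.effect_allele,
                out.other_allele,
            )
            continue
        if config.endswith("strandflip"):
            logger.info("%s: resolved by strand complement (%s)", exp.rsid, config)
        flipped = config.startswith("swapped")
        beta_out = -out.beta if flipped else out.beta

        rec = HarmonizedRecord(
            rsid=exp.rsid,
            effect_allele=exp.effect_allele,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=beta_out,
            se_outcome=out.se,
            eaf_exposure=exp.eaf,
            flipped=flipped,
            palindromic=palindromic,
        )
        if reorient_positive_exposure and rec.beta_exposure < 0:
            rec = replace(
                rec,
                beta_exposure=-rec.beta_exposure,
                beta_outcome=-rec.beta_outcome,
                eaf_exposure=None
                if rec.eaf_exposure is None
                else 1.0 - rec.eaf_exposure,
            )
        records.append(rec)
    return HarmonizedDataset(exposure_name, outcome_name, records)


_FIXTURES = {
    "25ohd": ("s25ohd", "S-25OHD"),
    "calcium": ("calcium", "S-Ca"),
    "pth": ("pth", "S-PTH"),
}

FIXTURE_NAMES = ("25OHD", "calcium", "PTH")

_OUTCOME_LABEL = "CAD in diabetes"


def _fixture_path(basename: str) -> Path:
    return Path(resources.files("tsmr") / "tables" / basename)


def load_fixture(exposure_name: str) -> HarmonizedDataset:
    """Load a bundled, pre-harmonized instrument set by exposure name.

    Valid names (case-insensitive): ``25OHD`` (serum 25-hydroxyvitamin D,
    6 SNPs), ``calcium`` (7 SNPs), ``PTH`` (parathyroid hormone, 5 SNPs).
    The outcome study in all three is coronary artery disease among
    individuals with diabetes.  Values are stored exactly as published;
    effect alleles already agree between studies, so harmonization is an
    identity pass.
    """
    key = exposure_name.strip().lower().replace("-", "").replace("s25ohd", "25ohd")
    if key not in _FIXTURES:
        raise KeyError(
            f"unknown exposure {exposure_name!r}; valid names: {list(FIXTURE_NAMES)}"
        )
    stem, label = _FIXTURES[key]
    exposure = read_summary_table(_fixture_path(f"{stem}_exposure.tsv"))
    outcome = read_summary_table(_fixture_path(f"{stem}_outcome.tsv"))
    return harmonize(
        exposure,
        outcome,
        exposure_name=label,
        outcome_name=_OUTCOME_LABEL,
    )
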