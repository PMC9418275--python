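"""GWAS summary-statistic quality control and allele handling.

QC filters applied to each disorder's summary statistics before scoring:
strand-ambiguous SNPs (allele pair A/T or C/G, whose strand cannot be
resolved from alleles alone), insertions/deletions, variants inside the MHC
locus (extreme LD), and variants absent from the target reference panel.
For case/control GWAS the effective sample size is
``floor(4 * N_case * N_control / (N_case + N_control))``, the balanced-design
equivalent N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: chr6:25-35 Mb (GRCh37, 1-based inclusive) — conventional MHC exclusion window.
MHC_REGION = ("6", 25_000_000, 35_000_000)

CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "effect",
    "p_value",
]

DEFAULT_COLUMN_MAP = {
    "SNP": "variant_id",
    "CHR": "chromosome",
    "BP": "position",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "effect",
    "OR": "effect",
    "P": "p_value",
}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One GWAS variant: alleles plus effect estimate on the beta scale."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    effect: float
    p_value: float

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: identical alleles")
        if self.position < 1:
            raise ValidationError(f"{self.variant_id}: position must be >= 1")
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"{self.variant_id}: p_value outside (0, 1]")


@dataclass
class QcReport:
    """Per-stage removal counts; ``n_output = n_input - sum(removals)``."""

    n_input: int = 0
    n_removed_malformed: int = 0
    n_removed_ambiguous: int = 0
    n_removed_indel: int = 0
    n_removed_mhc: int = 0
    n_removed_unmatched: int = 0
    n_output: int = 0
    log: list[str] = field(default_factory=list)

    def check(self) -> None:
        removed = (
            self.n_removed_malformed
            + self.n_removed_ambiguous
            + self.n_removed_indel
            + self.n_removed_mhc
            + self.n_removed_unmatched
        )
        if self.n_output != self.n_input - removed:
            raise AssertionError("QcReport counts are inconsistent")

    def to_text(self) -> str:
        lines = [
            f"n_input: {self.n_input}",
            f"n_removed_malformed: {self.n_removed_malformed}",
            f"n_removed_ambiguous: {self.n_removed_ambiguous}",
            f"n_removed_indel: {self.n_removed_indel}",
            f"n_removed_mhc: {self.n_removed_mhc}",
            f"n_removed_unmatched: {self.n_removed_unmatched}",
            f"n_output: {self.n_output}",
        ]
        lines += [f"log: {entry}" for entry in self.log]
        return "\n".join(lines) + "\n"


def is_indel(effect_allele: str, other_allele: str) -> bool:
    return not (
        effect_allele in VALID_ALLELES and other_allele in VALID_ALLELES
    )


def is_strand_ambiguous(effect_allele: str, other_allele: str) -> bool:
    return frozenset((effect_allele, other_allele)) in AMBIGUOUS_PAIRS


def filter_sumstats(
    sumstats: pd.DataFrame,
    reference_variant_ids=None,
    mhc_region: tuple[str, int, int] = MHC_REGION,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the QC filters; returns (surviving rows, report).

    ``sumstats`` uses the canonical column names (see ``read_sumstats``).
    Each removed row is counted once, at the first rule it violates, in the
    order: malformed, ambiguous, INDEL, MHC, unmatched against
    ``reference_variant_ids`` (skipped when the reference is None).
    Malformed rows (equal alleles, non-positive position, p outside (0, 1])
    are rejected per-row and itemized in the report log.
    """
    df = sumstats.copy()
    report = QcReport(n_input=len(df))

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    pos = pd.to_numeric(df["position"], errors="coerce")
    pval = pd.to_numeric(df["p_value"], errors="coerce")
    eff = pd.to_numeric(df["effect"], errors="coerce")

    malformed = (
        (ea == oa)
        | ~(pos >= 1)
        | ~((pval > 0) & (pval <= 1))
        | eff.isna()
        | df["variant_id"].isna()
    )
    for vid in df.loc[malformed, "variant_id"].fillna("<missing id>"):
        report.log.append(f"malformed row rejected: {vid}")
    report.n_removed_malformed = int(malformed.sum())
    keep = ~malformed

    ambiguous = keep & np.array(
        [
            is_strand_ambiguous(a, b) if not is_indel(a, b) else False
            for a, b in zip(ea, oa)
        ],
        dtype=bool,
    )
    report.n_removed_ambiguous = int(ambiguous.sum())
    keep &= ~ambiguous

    indel = keep & np.array([is_indel(a, b) for a, b in zip(ea, oa)], dtype=bool)
    report.n_removed_indel = int(indel.sum())
    keep &= ~indel

    chrom, start, end = mhc_region
    in_mhc = keep & (
        (df["chromosome"].astype(str).str.replace("chr", "", regex=False) == str(chrom))
        & (pos >= start)
        & (pos <= end)
    )
    report.n_removed_mhc = int(in_mhc.sum())
    keep &= ~in_mhc

    if reference_variant_ids is not None:
        ref = set(map(str, reference_variant_ids))
        unmatched = keep & ~df["variant_id"].astype(str).isin(ref)
        report.n_removed_unmatched = int(unmatched.sum())
        keep &= ~unmatched

    out = df.loc[keep].copy()
    out["effect_allele"] = ea[keep]
    out["other_allele"] = oa[keep]
    report.n_output = len(out)
    report.check()
    return out, report


def align_alleles(
    effect_allele: str,
    other_allele: str,
    effect: float,
    target_effect_allele: str,
    target_other_allele: str,
) -> tuple[float | None, str]:
    """Express ``effect`` relative to the target's effect allele.

    Returns ``(aligned_effect, status)`` with status one of ``match``
    (identical orientation), ``flip`` (alleles swapped: sign negated),
    ``complement`` / ``complement_flip`` (opposite strand), or ``mismatch``
    (allele sets irreconcilable; aligned_effect is None).  Assumes ambiguous
    pairs were already removed, so strand flips are unambiguous.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    tea, toa = target_effect_allele.upper(), target_other_allele.upper()
    if (ea, oa) == (tea, toa):
        return effect, "match"
    if (ea, oa) == (toa, tea):
        return -effect, "flip"
    if ea in COMPLEMENT and oa in COMPLEMENT:
        cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
        if (cea, coa) == (tea, toa):
            return effect, "complement"
        if (cea, coa) == (toa, tea):
            return -effect, "complement_flip"
    return None, "mismatch"


def effective_sample_size(n_case: int, n_control: int) -> int:
    """Balanced-design equivalent N for a case/control GWAS (floored)."""
    if n_case < 1 or n_control < 1:
        raise ValidationError("case and control counts must be >= 1")
    return math.floor(4 * n_case * n_control / (n_case + n_control))


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    effect_is_or: bool = False,
) -> pd.DataFrame:
    """Read whitespace/tab-delimited summary statistics with a header row.

    ``column_map`` maps file column names to the canonical names; defaults
    cover the common SNP/CHR/BP/A1/A2/BETA|OR/P layout.  When
    ``effect_is_or`` the effect column is log-transformed to the beta scale.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"summary statistics missing columns: {missing}")
    df = df[CANONICAL_COLUMNS]
    if effect_is_or:
        orr = pd.to_numeric(df["effect"], errors="coerce")
        if (orr <= 0).any():
            raise ValidationError("odds ratios must be positive for log transform")
        df["effect"] = np.log(orr)
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_qc_report(report: QcReport, path: str | Path) -> None:
    Path(path).write_text(report.to_text())
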