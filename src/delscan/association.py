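"""Allelic case-control association scan with Bonferroni threshold.

Per SNP, alleles are tallied into a 2x2 (case/control x alt/ref) table
and tested with the 1-df Pearson chi-square on allele counts — the
basic allelic test a case/control association run reports by default —
with no continuity correction and no covariates.  Monomorphic sites
(a zero margin) are assigned statistic 0, p = 1 and flagged.  The
genome-wide threshold is Bonferroni: -log10(alpha / number of variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import SampleSpec
from .variants import VariantRecord


@dataclass
class AlleleTable:
    """2x2 allele counts: rows (case, control), columns (alt, ref)."""

    case_alt: int
    case_ref: int
    control_alt: int
    control_ref: int

    def __post_init__(self) -> None:
        if min(self.case_alt, self.case_ref, self.control_alt, self.control_ref) < 0:
            raise ValueError("allele counts must be >= 0")

    @property
    def total(self) -> int:
        return self.case_alt + self.case_ref + self.control_alt + self.control_ref

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.case_alt, self.case_ref], [self.control_alt, self.control_ref]]
        )


@dataclass
class AssociationResult:
    chrom: str
    pos: int
    snp_id: str
    chi_square: float
    p_value: float
    neg_log10_p: float
    monomorphic: bool = False
    case_alt_freq: float = float("nan")
    control_alt_freq: float = float("nan")


def allele_table(variant: VariantRecord, samples: list[SampleSpec]) -> AlleleTable:
    """Tally alleles by phenotype; missing genotypes contribute nothing."""
    if len(variant.genotypes) != len(samples):
        raise ValueError("genotype vector and sample list differ in length")
    counts = {"case_alt": 0, "case_ref": 0, "control_alt": 0, "control_ref": 0}
    for gt, s in zip(variant.genotypes, samples):
        if gt is None:
            continue
        if any(a not in (0, 1) for a in gt):
            raise ValueError(f"variant {variant.vid} is not biallelic")
        grp = "case" if s.is_case else "control"
        alt = gt[0] + gt[1]
        counts[f"{grp}_alt"] += alt
        counts[f"{grp}_ref"] += 2 - alt
    return AlleleTable(**counts)


def allelic_chi_square(table: AlleleTable) -> tuple[float, float, bool]:
    """Pearson 1-df chi-square on the 2x2 allele table.

    Returns (statistic, p, monomorphic_flag).  No continuity correction;
    a zero margin yields (0, 1, True).
    """
    if table.total <= 0:
        raise ValueError("empty allele table")
    a, b = table.case_alt, table.case_ref
    c, d = table.control_alt, table.control_ref
    n = table.total
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0, True
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p, False


def bonferroni_threshold(n_variants: int, alpha: float = 0.05) -> float:
    """Genome-wide significance on the -log10 scale: -log10(alpha/n)."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_variants))


def associate(
    variant: VariantRecord, samples: list[SampleSpec]
) -> AssociationResult:
    table = allele_table(variant, samples)
    stat, p, mono = allelic_chi_square(table)
    ca = table.case_alt + table.case_ref
    co = table.control_alt + table.control_ref
    return AssociationResult(
        chrom=variant.chrom,
        pos=variant.pos,
        snp_id=variant.vid,
        chi_square=stat,
        p_value=p,
        neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
        monomorphic=mono,
        case_alt_freq=table.case_alt / ca if ca else float("nan"),
        control_alt_freq=table.control_alt / co if co else float("nan"),
    )


def scan(
    variants: list[VariantRecord], samples: list[SampleSpec]
) -> list[AssociationResult]:
    """Allelic test at every variant, in input order."""
    return [associate(v, samples) for v in variants]


@dataclass
class SignificantRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_snps: int
    peak_neg_log10_p: float


def significant_regions(
    results: list[AssociationResult],
    threshold: float,
    merge_gap: int = 10_000,
) -> list[SignificantRegion]:
    """Maximal runs of significant SNPs, merging runs <= merge_gap apart."""
    positions = [(r.chrom, r.pos) for r in results]
    if positions != sorted(positions):
        raise ValueError("results must be sorted by (chrom, pos)")
    regions: list[SignificantRegion] = []
    for r in results:
        if r.neg_log10_p < threshold:
            continue
        last = regions[-1] if regions else None
        if last is not None and last.chrom == r.chrom and r.pos - last.end <= merge_gap:
            last.end = r.pos
            last.n_snps += 1
            last.peak_neg_log10_p = max(last.peak_neg_log10_p, r.neg_log10_p)
        else:
            regions.append(
                SignificantRegion(r.chrom, r.pos, r.pos, 1, r.neg_log10_p)
            )
    return regions
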