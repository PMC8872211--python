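"""Cohort simulation: deletion genotypes and linked SNPs.

Emulates the study's cross design: cases (light-yellow plumage, LY) are
homozygous for the deletion allele, controls (dark-red, DR) are
heterozygous or homozygous wildtype.  SNPs are planted around the
deletion with linkage disequilibrium that decays exponentially with
distance, so a case-control scan recovers a significant region around
the causal edit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reference import HaplotypeEdit, ReferenceRegion
from .variants import VariantRecord

CASE_PHENOTYPE = "LY"
CONTROL_PHENOTYPE = "DR"

GT_WT = "wt/wt"
GT_HET = "wt/del"
GT_HOM = "del/del"


@dataclass
class SampleSpec:
    """One bird: phenotype, deletion genotype, and haplotype flags."""

    sample_id: str
    phenotype: str  # "DR" or "LY"
    del_genotype: str  # "wt/wt", "wt/del", "del/del"
    # which of the two haplotypes carries the deletion allele
    hap_is_del: tuple[bool, bool] = field(default=(False, False))

    def __post_init__(self) -> None:
        if self.phenotype not in (CASE_PHENOTYPE, CONTROL_PHENOTYPE):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.del_genotype not in (GT_WT, GT_HET, GT_HOM):
            raise ValueError(f"unknown deletion genotype {self.del_genotype!r}")
        expected = {GT_WT: 0, GT_HET: 1, GT_HOM: 2}[self.del_genotype]
        if sum(self.hap_is_del) != expected:
            object.__setattr__(
                self,
                "hap_is_del",
                (True, expected == 2) if expected else (False, False),
            )

    @property
    def is_case(self) -> bool:
        return self.phenotype == CASE_PHENOTYPE

    @property
    def n_del_alleles(self) -> int:
        return int(self.hap_is_del[0]) + int(self.hap_is_del[1])


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    het_fraction_controls: float = 0.5,
    seed: int = 0,
) -> list[SampleSpec]:
    """Draw a case-control cohort under the recessive-deletion model.

    Every case is del/del; each control is wt/del with probability
    ``het_fraction_controls`` and wt/wt otherwise.  Deterministic for a
    fixed seed.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("cohort sizes must be >= 1")
    if not 0.0 <= het_fraction_controls <= 1.0:
        raise ValueError("het_fraction_controls must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples: list[SampleSpec] = []
    for i in range(n_cases):
        samples.append(
            SampleSpec(f"LY{i + 1:03d}", CASE_PHENOTYPE, GT_HOM, (True, True))
        )
    het = rng.random(n_controls) < het_fraction_controls
    for i in range(n_controls):
        gt = GT_HET if het[i] else GT_WT
        samples.append(
            SampleSpec(f"DR{i + 1:03d}", CONTROL_PHENOTYPE, gt, (het[i], False))
        )
    return samples


def _distance_to_edit(pos: int, edit: HaplotypeEdit) -> int:
    """bp distance from a position to the deleted interval (0 if adjacent)."""
    if pos < edit.del_start:
        return edit.del_start - pos - 1
    if pos >= edit.del_end:
        return pos - edit.del_end
    raise ValueError("position inside the deleted interval")


def plant_linked_snps(
    ref: ReferenceRegion,
    causal_edit: HaplotypeEdit,
    samples: list[SampleSpec],
    n_snps: int,
    r2_at_zero: float = 1.0,
    decay_bp: float = 20_000.0,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> list[VariantRecord]:
    """Plant biallelic SNPs in linkage with the deletion allele.

    Each SNP at distance d from the deleted interval is assigned a target
    r-squared of ``r2_at_zero * exp(-d / decay_bp)`` with the deletion.
    Per-haplotype alleles are drawn by the copy model: with probability
    r = sqrt(r2) the SNP allele copies the haplotype's deletion indicator,
    otherwise it is an independent Bernoulli draw at the deletion-allele
    frequency, which makes the realised correlation approximately r.
    Positions falling inside the deleted interval are rejected and
    redrawn.  Genotypes are set missing independently at ``missing_rate``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0.0 <= r2_at_zero <= 1.0:
        raise ValueError("r2_at_zero must be in [0, 1]")
    rng = np.random.default_rng(seed)

    deleted = range(causal_edit.del_start, causal_edit.del_end)
    positions: set[int] = set()
    while len(positions) < n_snps:
        pos = int(rng.integers(ref.offset, ref.end + 1))
        if pos in deleted:
            continue
        positions.add(pos)
    sorted_pos = sorted(positions)

    # pooled deletion-allele frequency over the cohort's haplotypes
    n_hap = 2 * len(samples)
    p_del = sum(s.n_del_alleles for s in samples) / n_hap if n_hap else 0.0
    p_del = min(max(p_del, 0.01), 0.99)  # guard degenerate pools

    bases = "ACGT"
    variants: list[VariantRecord] = []
    for pos in sorted_pos:
        d = _distance_to_edit(pos, causal_edit)
        r = math.sqrt(r2_at_zero * math.exp(-d / decay_bp))
        ref_base = ref.sequence[ref.index(pos)]
        alt_base = rng.choice([b for b in bases if b != ref_base])
        genotypes: list[tuple[int, int] | None] = []
        for s in samples:
            alleles = []
            for hap_del in s.hap_is_del:
                if rng.random() < r:
                    alleles.append(int(hap_del))
                else:
                    alleles.append(int(rng.random() < p_del))
            if rng.random() < missing_rate:
                genotypes.append(None)
            else:
                genotypes.append((alleles[0], alleles[1]))
        variants.append(
            VariantRecord(
                chrom=ref.name,
                pos=pos,
                ref=ref_base,
                alt=str(alt_base),
                qual=100.0,
                info={},
                genotypes=genotypes,
            )
        )
    return variants
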