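"""In-silico PCR genotyping and the three-locus plumage rule engine.

A diagnostic primer pair flanking the deletion yields a long product
from the wildtype allele and a short one from the deletion allele, so a
sample's band pattern reads out its deletion genotype directly.  The
rule engine combines the SOX10 upstream deletion with the autosomal
dominant-white locus (PMEL17, alleles I > i) and the Z-linked silver
locus (SLC45A2, alleles S, N; hens are hemizygous ZW) to predict
plumage colour, encoding the cross's observed combinations: males
carrying I are white; del/del females are light yellow (LY); females
with at least one wildtype SOX10 allele and the I/i, N/W combination
are dark red (DR); everything else is left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reads import revcomp

PHENO_WHITE = "white"
PHENO_DR = "DR"
PHENO_LY = "LY"
PHENO_OTHER = "other"

_ACGT = set("ACGT")


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{name} primer shorter than 15 nt")
            if not set(p) <= _ACGT:
                raise ValueError(f"{name} primer contains non-ACGT characters")


# the study's diagnostic pair flanking the deletion
DIAGNOSTIC_PRIMERS = PrimerPair(
    forward="TTTGCTCCCAACCCCTCATC",
    reverse="AGCCATCGGAAAAGAAGCCA",
)


@dataclass
class Amplicon:
    allele: str  # haplotype label, e.g. "wt" or "del"
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("length does not equal sequence length")


def _find_all(hay: str, needle: str) -> list[int]:
    hits, i = [], hay.find(needle)
    while i >= 0:
        hits.append(i)
        i = hay.find(needle, i + 1)
    return hits


def predict_amplicons(
    haplotypes: dict[str, str],
    primers: PrimerPair,
    max_len: int = 20_000,
) -> dict[str, Amplicon | None]:
    """Exact-match PCR prediction per haplotype.

    A product requires exactly one forward site and one reverse-complement
    reverse site, in order, with product length <= max_len; otherwise the
    haplotype yields no product (None), never an exception.
    """
    rev_site = revcomp(primers.reverse)
    out: dict[str, Amplicon | None] = {}
    for label, seq in haplotypes.items():
        f_hits = _find_all(seq, primers.forward)
        r_hits = _find_all(seq, rev_site)
        if len(f_hits) != 1 or len(r_hits) != 1:
            out[label] = None
            continue
        f, r = f_hits[0], r_hits[0]
        end = r + len(rev_site)  # product is inclusive of both primer sites
        if end <= f or end - f > max_len:
            out[label] = None
            continue
        product = seq[f:end]
        out[label] = Amplicon(allele=label, length=len(product), sequence=product)
    return out


def genotype_from_products(
    product_lengths: list[int],
    wt_length: int,
    del_length: int,
    tolerance: int = 50,
) -> str | None:
    """Deletion genotype from a sample's band sizes.

    Bands are classified against the two predicted lengths (+- tolerance);
    both classes -> wt/del, only the short class -> del/del, only the
    long class -> wt/wt, nothing classifiable -> no-call (None).
    """
    has_wt = any(abs(x - wt_length) <= tolerance for x in product_lengths)
    has_del = any(abs(x - del_length) <= tolerance for x in product_lengths)
    if has_wt and has_del:
        return "wt/del"
    if has_del:
        return "del/del"
    if has_wt:
        return "wt/wt"
    return None


@dataclass
class ConcordanceReport:
    n_samples: int
    n_consistent: int
    violators: list[str]

    @property
    def concordance(self) -> float | None:
        if self.n_samples == 0:
            return None
        return self.n_consistent / self.n_samples


def recessive_concordance(
    genotypes: dict[str, str | None],
    phenotypes: dict[str, str],
) -> ConcordanceReport:
    """Fraction of samples consistent with phenotype LY <=> del/del."""
    violators = []
    n = 0
    for sid, gt in genotypes.items():
        if sid not in phenotypes:
            raise KeyError(f"no phenotype for sample {sid}")
        n += 1
        is_case = phenotypes[sid] == "LY"
        if (gt == "del/del") != is_case:
            violators.append(sid)
    return ConcordanceReport(
        n_samples=n, n_consistent=n - len(violators), violators=sorted(violators)
    )


_SOX10 = {"wt/wt", "wt/del", "del/del"}
_PMEL = {"I/I", "I/i", "i/i"}
_SLC_MALE = {"S/S", "S/N", "N/N"}
_SLC_FEMALE = {"S/W", "N/W"}


@dataclass(frozen=True)
class PlumageGenotype:
    """Three-locus genotype; hens (ZW) are hemizygous at SLC45A2."""

    sox10: str
    pmel17: str
    slc45a2: str
    sex: str  # "male" or "female"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.sox10 not in _SOX10:
            raise ValueError(f"unknown SOX10 genotype {self.sox10!r}")
        if self.pmel17 not in _PMEL:
            raise ValueError(f"unknown PMEL17 genotype {self.pmel17!r}")
        valid = _SLC_MALE if self.sex == "male" else _SLC_FEMALE
        if self.slc45a2 not in valid:
            raise ValueError(
                f"SLC45A2 genotype {self.slc45a2!r} invalid for {self.sex} "
                f"(hens carry a single Z allele)"
            )


def predict_plumage(g: PlumageGenotype) -> str:
    """Plumage phenotype from the three-locus rule table.

    Males carrying at least one dominant-white I allele are white (the
    cross's males are all I/i).  Females: deletion homozygotes are LY;
    carriers of at least one wildtype SOX10 allele with the cross's DR
    combination (I/i at PMEL17, N/W at SLC45A2) are DR.  Combinations
    outside the enumerated table are reported as "other" rather than
    guessed.
    """
    if g.sex == "male":
        return PHENO_WHITE if "I" in g.pmel17 else PHENO_OTHER
    if g.sox10 == "del/del":
        return PHENO_LY
    if g.pmel17 == "I/i" and g.slc45a2 == "N/W":
        return PHENO_DR
    return PHENO_OTHER
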