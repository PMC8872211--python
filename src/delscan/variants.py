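"""Biallelic SNP records and simulation of caller annotations.

A :class:`VariantRecord` carries the six annotation fields the hard
filters act on (QUAL, QD, FS, MQ, MQRankSum, ReadPosRankSum — the last
two may be absent, as they are at sites without heterozygotes) plus
per-sample diploid genotypes with missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# annotation keys carried in the INFO dict
ANNOTATIONS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    info: dict[str, float] = field(default_factory=dict)
    # one entry per sample: (a0, a1) allele indices, or None if missing
    genotypes: list[tuple[int, int] | None] = field(default_factory=list)
    vid: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.qual < 0:
            raise ValueError("QUAL must be >= 0")
        if not self.vid:
            self.vid = f"{self.chrom}:{self.pos}"

    @property
    def call_rate(self) -> float:
        if not self.genotypes:
            raise ValueError("variant has no genotypes")
        called = sum(g is not None for g in self.genotypes)
        return called / len(self.genotypes)

    def copy(self) -> "VariantRecord":
        return replace(self, info=dict(self.info), genotypes=list(self.genotypes))


# Distributions used to dress simulated variants with caller annotations.
# "good" draws clear every hard threshold with margin; each failure mode
# pushes exactly one annotation across its printed threshold.
_GOOD = {
    "QUAL": (60.0, 1500.0),
    "QD": (8.0, 35.0),
    "FS": (0.0, 20.0),
    "MQ": (50.0, 60.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
}
_BAD = {
    "QUAL": (0.0, 30.0),
    "QD": (0.0, 5.0),
    "FS": (60.0, 300.0),
    "MQ": (0.0, 40.0),
    "MQRankSum": (-30.0, -12.5),
    "ReadPosRankSum": (-20.0, -8.0),
}


def annotate_variants(
    variants: list[VariantRecord],
    fail_rate: float = 0.15,
    absent_ranksum_rate: float = 0.05,
    seed: int = 0,
) -> list[VariantRecord]:
    """Attach QUAL/QD/FS/MQ/rank-sum annotations to simulated variants.

    Each variant independently is a clean call with probability
    ``1 - fail_rate``; otherwise one annotation, chosen uniformly, is
    drawn from its failing range.  Rank-sum annotations are dropped
    (absent) at ``absent_ranksum_rate``, emulating sites without
    heterozygous carriers.  Returns new records; input is not modified.
    """
    rng = np.random.default_rng(seed)
    keys = list(_GOOD)
    out = []
    for v in variants:
        nv = v.copy()
        vals = {k: float(rng.uniform(*_GOOD[k])) for k in keys}
        if rng.random() < fail_rate:
            k = keys[int(rng.integers(len(keys)))]
            vals[k] = float(rng.uniform(*_BAD[k]))
        nv.qual = vals.pop("QUAL")
        for k in ("MQRankSum", "ReadPosRankSum"):
            if rng.random() < absent_ranksum_rate:
                vals.pop(k)
        nv.info = vals
        out.append(nv)
    return out
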