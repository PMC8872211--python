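"""SNP quality filters: six hard thresholds, SNP-cluster rule, call rate.

A variant survives the hard filters iff

    QUAL > 30.0 and QD > 5.0 and FS < 60.0 and MQ > 40.0
    and MQRankSum > -12.5 and ReadPosRankSum > -8.0

with all inequalities strict.  Rank-sum annotations are undefined at
sites without heterozygous carriers; an absent MQRankSum or
ReadPosRankSum does not fail its rule.  The cluster rule removes every
SNP belonging to a window of ``window`` bp (inclusive span: positions p,
q cluster when |p - q| <= window - 1) containing at least ``min_count``
SNPs.  The call-rate rule keeps variants genotyped in at least
``min_rate`` of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variants import VariantRecord

HARD_FILTER_DEFAULTS = {
    "QUAL": 30.0,
    "QD": 5.0,
    "FS": 60.0,
    "MQ": 40.0,
    "MQRankSum": -12.5,
    "ReadPosRankSum": -8.0,
}

# rule labels in the order they are checked; the first failure wins
RULE_LABELS = (
    "LowQual",
    "LowQD",
    "HighFS",
    "LowMQ",
    "LowMQRankSum",
    "LowReadPosRankSum",
)
MALFORMED_LABEL = "MalformedAnnotation"
PASS_LABEL = "PASS"


@dataclass
class FilterReport:
    """Per-variant verdicts plus counts per rule."""

    verdicts: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def tally(self, verdict: str) -> None:
        self.verdicts.append(verdict)
        self.counts[verdict] = self.counts.get(verdict, 0) + 1

    @property
    def n_input(self) -> int:
        return len(self.verdicts)

    @property
    def n_pass(self) -> int:
        return self.counts.get(PASS_LABEL, 0)


def _as_float(value) -> float:
    v = float(value)
    if v != v:  # NaN is malformed, not absent
        raise ValueError("NaN annotation")
    return v


def hard_filter_verdict(
    variant: VariantRecord, thresholds: dict[str, float] | None = None
) -> str:
    """Label for one variant: PASS, the first failing rule, or malformed."""
    t = dict(HARD_FILTER_DEFAULTS)
    if thresholds:
        t.update(thresholds)
    try:
        if not _as_float(variant.qual) > t["QUAL"]:
            return "LowQual"
        info = variant.info
        if "QD" not in info or not _as_float(info["QD"]) > t["QD"]:
            return "LowQD" if "QD" in info else MALFORMED_LABEL
        if "FS" not in info or not _as_float(info["FS"]) < t["FS"]:
            return "HighFS" if "FS" in info else MALFORMED_LABEL
        if "MQ" not in info or not _as_float(info["MQ"]) > t["MQ"]:
            return "LowMQ" if "MQ" in info else MALFORMED_LABEL
        # rank sums: absent is acceptable (undefined, not bad)
        if "MQRankSum" in info and not _as_float(info["MQRankSum"]) > t["MQRankSum"]:
            return "LowMQRankSum"
        if "ReadPosRankSum" in info and not (
            _as_float(info["ReadPosRankSum"]) > t["ReadPosRankSum"]
        ):
            return "LowReadPosRankSum"
    except (TypeError, ValueError):
        return MALFORMED_LABEL
    return PASS_LABEL


def apply_hard_filters(
    variants: list[VariantRecord], thresholds: dict[str, float] | None = None
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the six hard thresholds; return survivors and a report."""
    report = FilterReport()
    survivors = []
    for v in variants:
        verdict = hard_filter_verdict(v, thresholds)
        report.tally(verdict)
        if verdict == PASS_LABEL:
            survivors.append(v)
    return survivors, report


def remove_clustered_snps(
    variants: list[VariantRecord], window: int = 10, min_count: int = 3
) -> list[VariantRecord]:
    """Drop every SNP lying in any ``window`` bp span holding >= min_count SNPs.

    Input must be sorted by (chrom, pos).  A window of 10 bp spans 10
    bases inclusive, so positions p and q co-cluster when
    ``|p - q| <= window - 1``.
    """
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chrom, pos); sort first")
    n = len(variants)
    drop = [False] * n
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and variants[j + 1].chrom == variants[i].chrom
            and variants[j + 1].pos - variants[i].pos <= window - 1
        ):
            j += 1
        if j - i + 1 >= min_count:
            for k in range(i, j + 1):
                drop[k] = True
        i += 1
    return [v for v, d in zip(variants, drop) if not d]


def apply_call_rate_filter(
    variants: list[VariantRecord], min_rate: float = 0.8
) -> list[VariantRecord]:
    """Keep variants genotyped in at least ``min_rate`` of samples."""
    out = []
    for v in variants:
        if not v.genotypes:
            raise ValueError(f"variant {v.vid} has zero samples")
        if v.call_rate >= min_rate:
            out.append(v)
    return out


def run_filter_pipeline(
    variants: list[VariantRecord],
    thresholds: dict[str, float] | None = None,
    window: int = 10,
    min_count: int = 3,
    min_rate: float = 0.8,
) -> tuple[list[VariantRecord], FilterReport]:
    """Hard filters, then cluster rule, then call rate (the study's order)."""
    survivors, report = apply_hard_filters(variants, thresholds)
    survivors = remove_clustered_snps(survivors, window=window, min_count=min_count)
    survivors = apply_call_rate_filter(survivors, min_rate=min_rate)
    return survivors, report
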