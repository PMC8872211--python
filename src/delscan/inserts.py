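"""Apparent insert-size profiling and discordant-pair SV typing.

A deletion lying between a pair's mates inflates the apparent insert
(reference span) by deletion length minus junction-insertion length, so
deletion-homozygous samples show a discordant-long mode far above the
fragment distribution while wildtype samples stay within it.  The
classifier contrasts the discordant-long fraction between case and
control pools and estimates the net deletion size from the median
discordant insert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reads import AlignmentRecord

SV_DELETION = "DELETION"
SV_DUPLICATION = "DUPLICATION"
SV_NONE = "NONE"


@dataclass
class InsertProfile:
    """Absolute apparent insert sizes of pairs whose span hits a region."""

    group: str
    sizes: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.sizes)

    @property
    def median(self) -> float:
        return float(np.median(self.sizes)) if self.sizes else float("nan")

    @property
    def mad(self) -> float:
        if not self.sizes:
            return float("nan")
        arr = np.asarray(self.sizes, dtype=float)
        return float(np.median(np.abs(arr - np.median(arr))))

    @property
    def max(self) -> int:
        return max(self.sizes) if self.sizes else 0


@dataclass
class SVCall:
    sv_type: str  # DELETION, DUPLICATION or NONE
    net_size_estimate: int
    support: int

    def __post_init__(self) -> None:
        if self.sv_type == SV_NONE and self.net_size_estimate > 0:
            raise ValueError("net_size_estimate must be 0 when no SV is called")


def extract_apparent_inserts(
    records: list[AlignmentRecord],
    region_start: int,
    region_end: int,
    group: str = "",
    samples: set[str] | None = None,
) -> InsertProfile:
    """One absolute insert per pair whose outer span intersects the region.

    Pairs are counted once via their leftmost mate (positive TLEN); both
    mates must be mapped on the same reference.
    """
    sizes: list[int] = []
    for rec in records:
        if rec.is_unmapped or not rec.mate_mapped or rec.apparent_insert <= 0:
            continue
        if samples is not None and rec.sample_id not in samples:
            continue
        span_start = rec.pos
        span_end = rec.pos + rec.apparent_insert - 1
        if span_end >= region_start and span_start <= region_end:
            sizes.append(rec.apparent_insert)
    return InsertProfile(group=group, sizes=sizes)


def discordant_long_cutoff(frag_mean: float, frag_sd: float, z: float = 5.0) -> float:
    return frag_mean + z * frag_sd


def classify_sv(
    case_profile: InsertProfile,
    control_profile: InsertProfile,
    frag_mean: float,
    frag_sd: float,
    discordant_z: float = 5.0,
    min_support: int = 3,
    fraction_margin: float = 0.05,
) -> SVCall:
    """Call DELETION/DUPLICATION/NONE from the two pools' insert profiles.

    DELETION: the case pool's discordant-long fraction exceeds the
    control pool's by ``fraction_margin`` with at least ``min_support``
    supporting pairs; the net size estimate is
    median(discordant sizes) - frag_mean (the junction insertion is not
    subtracted — it is invisible to insert sizes).  DUPLICATION is the
    mirrored contrast on discordant-short pairs (a directional flag
    only).  Anything else is NONE.
    """
    for name, prof in (("case", case_profile), ("control", control_profile)):
        if prof.n == 0:
            raise ValueError(f"empty insert profile for {name} group")
    long_cut = discordant_long_cutoff(frag_mean, frag_sd, discordant_z)
    short_cut = max(0.0, frag_mean - discordant_z * frag_sd)

    case_long = [s for s in case_profile.sizes if s > long_cut]
    ctrl_long = [s for s in control_profile.sizes if s > long_cut]
    f_case = len(case_long) / case_profile.n
    f_ctrl = len(ctrl_long) / control_profile.n
    if f_case - f_ctrl > fraction_margin and len(case_long) >= min_support:
        net = int(round(float(np.median(case_long)) - frag_mean))
        return SVCall(SV_DELETION, net, len(case_long))

    case_short = [s for s in case_profile.sizes if s < short_cut]
    ctrl_short = [s for s in control_profile.sizes if s < short_cut]
    f_case_s = len(case_short) / case_profile.n
    f_ctrl_s = len(ctrl_short) / control_profile.n
    if f_case_s - f_ctrl_s > fraction_margin and len(case_short) >= min_support:
        net = int(round(frag_mean - float(np.median(case_short))))
        return SVCall(SV_DUPLICATION, max(net, 1), len(case_short))
    return SVCall(SV_NONE, 0, 0)


def per_sample_discordance(
    records: list[AlignmentRecord],
    region_start: int,
    region_end: int,
    frag_mean: float,
    frag_sd: float,
    discordant_z: float = 5.0,
) -> dict[str, int]:
    """Count discordant-long pairs per sample over a region.

    Useful for separating deletion homozygotes (about twice the count)
    from heterozygotes at matched coverage.
    """
    cut = discordant_long_cutoff(frag_mean, frag_sd, discordant_z)
    counts: dict[str, int] = {}
    for rec in records:
        if rec.is_unmapped or not rec.mate_mapped or rec.apparent_insert <= 0:
            continue
        span_end = rec.pos + rec.apparent_insert - 1
        if span_end < region_start or rec.pos > region_end:
            continue
        if rec.apparent_insert > cut:
            counts[rec.sample_id] = counts.get(rec.sample_id, 0) + 1
    return counts
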