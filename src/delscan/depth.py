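"""Pooled per-base depth and log depth-ratio scanning.

Depth at a base counts mapped, non-clipped read bases covering it,
summed over a pool of samples.  The contrast between two pools is the
per-base log2 ratio (with a pseudocount guarding zero depth inside a
homozygous deletion); candidate copy-number segments are maximal runs
where the smoothed absolute ratio clears a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .reads import AlignmentRecord
from .reference import ReferenceRegion


@dataclass
class DepthTrack:
    region_name: str
    start: int  # genome coordinate of depth[0]
    depth_a: np.ndarray
    depth_b: np.ndarray
    pool_a: int
    pool_b: int

    def __post_init__(self) -> None:
        if len(self.depth_a) != len(self.depth_b):
            raise ValueError("depth arrays must have equal length")


@dataclass
class CandidateSegment:
    start: int  # 1-based inclusive genome coords
    end: int
    mean_log_ratio: float
    direction: str  # "A>B" or "B>A"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def pooled_depth(
    records: list[AlignmentRecord],
    region: ReferenceRegion,
    samples: set[str] | None = None,
) -> np.ndarray:
    """Per-base depth over the region for a pool of samples.

    Soft-clipped bases do not contribute (they are unaligned sequence).
    ``samples=None`` pools every record.
    """
    n = len(region)
    diff = np.zeros(n + 1, dtype=np.int64)
    lo, hi = region.offset, region.end
    for rec in records:
        if rec.is_unmapped:
            continue
        if samples is not None and rec.sample_id not in samples:
            continue
        s = max(rec.pos, lo)
        e = min(rec.end, hi)
        if e < s:
            continue
        diff[s - lo] += 1
        diff[e - lo + 1] -= 1
    return np.cumsum(diff[:-1])


def log_depth_ratio(
    depth_a: np.ndarray,
    depth_b: np.ndarray,
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> np.ndarray:
    """Per-base log2((A + pc) / (B + pc)), optionally mean-normalized.

    With ``normalize`` each array is rescaled to the common (grand mean)
    depth first, so unequal pool coverages cancel.
    """
    a = np.asarray(depth_a, dtype=float)
    b = np.asarray(depth_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("depth arrays must have equal length")
    if pseudocount <= 0 and (np.any(a == 0) or np.any(b == 0)):
        raise ValueError("pseudocount must be > 0 when any depth is zero")
    if normalize:
        ma, mb = a.mean(), b.mean()
        if ma > 0 and mb > 0:
            target = 0.5 * (ma + mb)
            a = a * (target / ma)
            b = b * (target / mb)
    return np.log2((a + pseudocount) / (b + pseudocount))


def call_candidate_segments(
    ratio: np.ndarray,
    start: int,
    threshold: float = 1.0,
    min_len: int = 500,
    smooth_window: int = 201,
) -> list[CandidateSegment]:
    """Maximal runs of smoothed |log-ratio| >= threshold, >= min_len long.

    ``start`` is the genome coordinate of ratio[0]; smoothing is a
    centered moving mean.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if len(ratio) == 0:
        return []
    smooth = uniform_filter1d(
        np.asarray(ratio, dtype=float), size=smooth_window, mode="nearest"
    )
    above = np.abs(smooth) >= threshold
    segments: list[CandidateSegment] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):  # [s, e) index runs
        if e - s < min_len:
            continue
        mean_ratio = float(smooth[s:e].mean())
        segments.append(
            CandidateSegment(
                start=start + int(s),
                end=start + int(e) - 1,
                mean_log_ratio=mean_ratio,
                direction="A>B" if mean_ratio > 0 else "B>A",
            )
        )
    return segments
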