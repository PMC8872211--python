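"""Breakpoint resolution from soft-clipped reads.

At a deletion junction, reads anchored on the left flank carry the
post-junction sequence as a right soft clip ending exactly at the first
deleted base; reads anchored on the right flank carry the pre-junction
sequence as a left clip starting exactly at the first retained base.
Clustering clip edges, voting a junction consensus from the clipped
sequences, and anchoring the consensus flanks back onto the reference
recovers the breakpoints and any non-templated inserted sequence at
base resolution — the in-silico analogue of sequencing a junction PCR
product and aligning it to the genome.

Conventions: the reported deletion length is ``del_end - del_start``
(the deleted bases are [del_start, del_end)); with micro-homology at the
junction the deletion is placed leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reads import AlignmentRecord
from .reference import ReferenceRegion

SIDE_RIGHT_CLIP = "right"  # read anchored left of the junction, clip extends right
SIDE_LEFT_CLIP = "left"  # read anchored right of the junction, clip extends left

DEFAULT_MIN_CLIP = 20
DEFAULT_MIN_SUPPORT = 2


@dataclass
class ClipCluster:
    """Soft clips sharing one reference edge position and side.

    ``edge`` is the junction coordinate implied by the clips: for
    right-clipped reads the first reference base past the mapped span
    (i.e. the first deleted base); for left-clipped reads the leftmost
    mapped base (the first retained base after the deletion).
    """

    edge: int
    side: str
    clipped_seqs: list[str] = field(default_factory=list)
    clipped_quals: list[str] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.clipped_seqs)


@dataclass
class BreakpointCall:
    del_start: int
    del_end: int
    inserted_seq: str
    support: int

    def __post_init__(self) -> None:
        if self.del_end < self.del_start:
            raise ValueError("del_end < del_start")

    @property
    def deletion_length(self) -> int:
        return self.del_end - self.del_start


class BreakpointNoCall(RuntimeError):
    """Raised when junction evidence cannot be resolved to a unique call."""


def collect_clip_clusters(
    records: list[AlignmentRecord],
    segment_start: int,
    segment_end: int,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[ClipCluster]:
    """Cluster soft clips by (edge position, side) within a segment.

    Clips shorter than ``min_clip`` are ignored; clusters with fewer
    than ``min_support`` reads are dropped.  Returned sorted by support
    (descending), then edge.
    """
    buckets: dict[tuple[int, str], ClipCluster] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        if rec.right_clip >= min_clip:
            edge = rec.end + 1
            if segment_start <= edge <= segment_end:
                cl = buckets.setdefault(
                    (edge, SIDE_RIGHT_CLIP), ClipCluster(edge, SIDE_RIGHT_CLIP)
                )
                start = rec.left_clip + rec.mapped_len
                cl.clipped_seqs.append(rec.seq[start:])
                cl.clipped_quals.append(rec.qual[start:])
        if rec.left_clip >= min_clip:
            edge = rec.pos
            if segment_start <= edge <= segment_end:
                cl = buckets.setdefault(
                    (edge, SIDE_LEFT_CLIP), ClipCluster(edge, SIDE_LEFT_CLIP)
                )
                cl.clipped_seqs.append(rec.seq[: rec.left_clip])
                cl.clipped_quals.append(rec.qual[: rec.left_clip])
    clusters = [c for c in buckets.values() if c.support >= min_support]
    clusters.sort(key=lambda c: (-c.support, c.edge))
    return clusters


# column votes: {column: {base: [count, summed_quality]}}
_Votes = dict[int, dict[str, list[int]]]


def _add_votes(votes: _Votes, seq: str, qual: str, start_col: int) -> None:
    for i, (b, q) in enumerate(zip(seq, qual)):
        entry = votes.setdefault(start_col + i, {}).setdefault(b, [0, 0])
        entry[0] += 1
        entry[1] += ord(q) - 33


def _consensus(votes: _Votes) -> tuple[str, int]:
    """Per-column majority (ties: summed quality, then lexicographic).

    Returns (consensus string, first column index).
    """
    if not votes:
        return "", 0
    cols = sorted(votes)
    out = []
    for c in cols:
        best = min(votes[c].items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
        out.append(best[0])
    return "".join(out), cols[0]


@dataclass
class _MergedJunction:
    """Voted junction in left-edge columns: col 0 = first base past lc.edge."""

    consensus: str
    first_col: int
    shift: int  # column of the right cluster's edge == apparent insertion length


def _registration_shift(
    cons: str,
    ref_extension: str,
    max_shift: int,
    min_compare: int = 8,
    min_identity: float = 0.9,
) -> int | None:
    """Smallest s such that cons[s:] matches ref_extension well.

    ``cons`` is a clip-side consensus read outwards from a junction edge
    and ``ref_extension`` the reference read outwards from the opposite
    edge; the returned s is the number of leading non-templated
    (inserted) bases.  None when no registration clears the identity bar.
    """
    for s in range(0, min(max_shift, len(cons) - min_compare) + 1):
        seg = cons[s:]
        n = min(len(seg), len(ref_extension))
        if n < min_compare:
            break
        matches = sum(a == b for a, b in zip(seg[:n], ref_extension[:n]))
        if matches / n >= min_identity:
            return s
    return None


def _merge_junction(
    left_cluster: ClipCluster,
    right_cluster: ClipCluster,
    reference: ReferenceRegion | None = None,
    max_insert_search: int = 200,
    min_overlap: int = 15,
) -> _MergedJunction:
    votes_a: _Votes = {}
    for seq, qual in zip(left_cluster.clipped_seqs, left_cluster.clipped_quals):
        _add_votes(votes_a, seq, qual, 0)
    cons_a, a0 = _consensus(votes_a)  # a0 == 0

    # right-cluster clips end just before that cluster's edge
    votes_b: _Votes = {}
    for seq, qual in zip(right_cluster.clipped_seqs, right_cluster.clipped_quals):
        _add_votes(votes_b, seq, qual, -len(seq))
    cons_b, b0 = _consensus(votes_b)

    # The shift s places B's column 0 (the first retained base after the
    # deletion) at A's column s, so the true shift equals the
    # junction-insertion length.
    best_s: int | None = None
    if reference is not None:
        # Register each side's extension against the reference at the
        # opposite cluster edge (the clip extensions themselves overlap
        # only across the insertion, which may be tiny or empty).
        ref_right = reference.subseq(
            right_cluster.edge,
            min(reference.end, right_cluster.edge + len(cons_a)),
        )
        s_a = _registration_shift(cons_a, ref_right, max_insert_search)
        ref_left_rev = reference.subseq(
            max(reference.offset, left_cluster.edge - len(cons_b)),
            left_cluster.edge - 1,
        )[::-1]
        s_b = _registration_shift(cons_b[::-1], ref_left_rev, max_insert_search)
        if s_a is not None and s_b is not None:
            best_s = s_a if s_a == s_b else min(s_a, s_b)
        else:
            best_s = s_a if s_a is not None else s_b
    if best_s is None:
        # reference-free fallback: best ungapped overlap of the two sides
        best_score = float("-inf")
        for s in range(-max_insert_search, max_insert_search + 1):
            lo = max(a0, b0 + s)
            hi = min(a0 + len(cons_a), b0 + s + len(cons_b))
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            matches = sum(
                1 for c in range(lo, hi) if cons_a[c - a0] == cons_b[c - s - b0]
            )
            score = matches - 2 * (overlap - matches)
            if score > best_score:
                best_score, best_s = score, s
    if best_s is None:
        raise BreakpointNoCall(
            "junction sides could not be registered (no reference anchor "
            "and no usable overlap)"
        )

    merged: _Votes = {}
    for src, off in ((votes_a, 0), (votes_b, best_s)):
        for col, d in src.items():
            for b, (n, q) in d.items():
                entry = merged.setdefault(col + off, {}).setdefault(b, [0, 0])
                entry[0] += n
                entry[1] += q

    # Trim thinly covered outer columns: only the longest clips reach
    # them, so a single sequencing error there would corrupt the voted
    # flank.  Coverage rises monotonically towards the junction, hence
    # trimming from both ends is safe.
    support = min(left_cluster.support, right_cluster.support)
    min_cov = min(3, support)
    cols = sorted(merged)
    cov = {c: sum(e[0] for e in merged[c].values()) for c in cols}
    while cols and cov[cols[0]] < min_cov:
        merged.pop(cols.pop(0))
    while cols and cov[cols[-1]] < min_cov:
        merged.pop(cols.pop())
    if not merged:
        raise BreakpointNoCall("no junction column with sufficient coverage")

    cons, first = _consensus(merged)
    return _MergedJunction(consensus=cons, first_col=first, shift=best_s)


def junction_consensus(
    left_cluster: ClipCluster,
    right_cluster: ClipCluster,
    reference: ReferenceRegion | None = None,
    max_insert_search: int = 200,
    min_overlap: int = 15,
) -> str:
    """Majority-vote consensus across the junction from both clip sides.

    ``left_cluster`` holds right-clipped reads (anchored left of the
    junction); ``right_cluster`` holds left-clipped reads.  Each
    cluster's clips are stacked at their shared edge and voted per
    column; the two extensions are merged at the ungapped offset that
    best aligns them.  The result reads: reference bases left of the
    junction (as far as the clips reach), any inserted bases, then
    reference bases after the junction.
    """
    if left_cluster.side == right_cluster.side:
        raise ValueError("need one cluster per junction side")
    if left_cluster.side != SIDE_RIGHT_CLIP:
        left_cluster, right_cluster = right_cluster, left_cluster
    if not left_cluster.clipped_seqs or not right_cluster.clipped_seqs:
        raise ValueError("both clusters must be non-empty")
    return _merge_junction(
        left_cluster, right_cluster, reference, max_insert_search, min_overlap
    ).consensus


def resolve_breakpoints(
    consensus: str,
    reference: ReferenceRegion,
    search_window: tuple[int, int] | None = None,
    min_anchor: int = DEFAULT_MIN_CLIP,
    support: int = 0,
) -> BreakpointCall:
    """Anchor a junction consensus to the reference and read off breakpoints.

    The consensus's first and last ``min_anchor`` bases must each match
    the reference exactly and uniquely (within ``search_window``, genome
    coordinates, if given); the matches are then extended maximally
    inwards.  The unanchored middle is the inserted sequence; overlap of
    the two extensions (junction micro-homology) is resolved by leftmost
    placement of the deletion.
    """
    if len(consensus) < 2 * min_anchor:
        raise BreakpointNoCall(
            f"consensus of {len(consensus)} bp is shorter than two "
            f"{min_anchor} bp anchors"
        )
    seq = reference.sequence
    if search_window is not None:
        w_lo = reference.index(max(search_window[0], reference.offset))
        w_hi = reference.index(min(search_window[1], reference.end)) + 1
    else:
        w_lo, w_hi = 0, len(seq)
    hay = seq[w_lo:w_hi]

    def unique_find(probe: str, what: str) -> int:
        first = hay.find(probe)
        if first < 0:
            raise BreakpointNoCall(f"{what} anchor not found in search window")
        if hay.find(probe, first + 1) >= 0:
            raise BreakpointNoCall(f"{what} anchor is not unique in search window")
        return w_lo + first

    left_at = unique_find(consensus[:min_anchor], "left flank")
    right_at = unique_find(consensus[-min_anchor:], "right flank")

    # extend the left match rightwards along the consensus
    left_ext = min_anchor
    while (
        left_ext < len(consensus)
        and left_at + left_ext < len(seq)
        and seq[left_at + left_ext] == consensus[left_ext]
    ):
        left_ext += 1
    # extend the right match leftwards
    right_ext = min_anchor
    while (
        right_ext < len(consensus)
        and right_at + min_anchor - right_ext - 1 >= 0
        and seq[right_at + min_anchor - right_ext - 1]
        == consensus[len(consensus) - right_ext - 1]
    ):
        right_ext += 1

    overlap = left_ext + right_ext - len(consensus)
    if overlap > 0:  # junction micro-homology: place the deletion leftmost
        left_ext -= overlap
    inserted = consensus[left_ext : len(consensus) - right_ext]

    del_start = reference.offset + left_at + left_ext
    del_end = reference.offset + (right_at + min_anchor - right_ext)
    if del_end < del_start:
        raise BreakpointNoCall("flank anchors are inconsistent (right before left)")
    return BreakpointCall(
        del_start=del_start,
        del_end=del_end,
        inserted_seq=inserted,
        support=support,
    )


def resolve_deletion(
    records: list[AlignmentRecord],
    reference: ReferenceRegion,
    segment_start: int,
    segment_end: int,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_support: int = DEFAULT_MIN_SUPPORT,
    flank: int = 300,
) -> BreakpointCall:
    """Full split-read chain: clusters -> consensus -> breakpoint call.

    Takes the best-supported cluster on each junction side within the
    segment, votes the junction, then pads the voted consensus with
    reference flanks at its column bounds (the mapped portions of the
    supporting reads match the reference there by construction) so both
    anchors have full length even when individual clips are short.
    """
    clusters = collect_clip_clusters(
        records, segment_start, segment_end, min_clip, min_support
    )
    lefts = [c for c in clusters if c.side == SIDE_RIGHT_CLIP]
    rights = [c for c in clusters if c.side == SIDE_LEFT_CLIP]
    if not lefts or not rights:
        raise BreakpointNoCall(
            f"need clip clusters on both junction sides, found "
            f"{len(lefts)} left / {len(rights)} right"
        )
    lc, rc = lefts[0], rights[0]
    merged = _merge_junction(lc, rc, reference)
    # column -> coordinate: cols < 0 are reference left of lc.edge;
    # cols >= shift are reference from rc.edge on
    last_col = merged.first_col + len(merged.consensus) - 1
    left_ref_end = lc.edge + merged.first_col - 1  # base before first voted col
    right_ref_start = rc.edge + (last_col - merged.shift) + 1
    lf_start = max(reference.offset, left_ref_end - flank + 1)
    rf_end = min(reference.end, right_ref_start + flank - 1)
    left_flank = (
        reference.subseq(lf_start, left_ref_end) if left_ref_end >= lf_start else ""
    )
    right_flank = (
        reference.subseq(right_ref_start, rf_end) if rf_end >= right_ref_start else ""
    )
    consensus = left_flank + merged.consensus + right_flank
    support = min(lc.support, rc.support)
    window = (lf_start, rf_end)
    return resolve_breakpoints(
        consensus, reference, search_window=window, support=support
    )
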