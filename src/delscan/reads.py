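"""Paired-end read simulation and exact coordinate-projection alignment.

Reads are simulated from sample haplotypes with a normal fragment-size
distribution, uniform substitution noise and constant base qualities.
No heuristic aligner is involved: each read's alignment on the reference
is obtained by projecting its haplotype interval through the
:class:`~delscan.reference.CoordinateMap`.  A read falling entirely
within a mapped block projects to an ungapped record; a read crossing
the deletion junction is anchored on its longer mapped side and
soft-clipped at the junction; a read without a sufficient anchor
(default 20 bp) on either side is flagged unmapped.

The apparent insert size follows TLEN semantics: the signed
outermost-coordinate span of the pair on the reference, positive for the
leftmost mate.  A pair whose mates flank the deletion therefore shows an
apparent insert inflated by (deletion length - insertion length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SampleSpec
from .reference import CoordinateMap

DEFAULT_MIN_ANCHOR = 20
DEFAULT_QUALITY = 30  # constant Phred quality for simulated bases

_COMP = bytes.maketrans(b"ACGT", b"TGCA")
_BASE_ORDS = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class ReadPair:
    """A simulated pair with its truth placement on the haplotype.

    ``read1``/``read2`` sequences are in sequencing orientation (read2 is
    the reverse-complement of the fragment's 3' end).
    """

    name: str
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str
    true_haplotype: int  # 0 or 1: which haplotype of the sample
    true_fragment_start: int  # 1-based on the haplotype
    true_fragment_length: int

    def __post_init__(self) -> None:
        if len(self.read1_seq) > self.true_fragment_length:
            raise ValueError("read length exceeds fragment length")
        if len(self.read1_qual) != len(self.read1_seq) or len(
            self.read2_qual
        ) != len(self.read2_seq):
            raise ValueError("quality string length mismatch")


@dataclass
class AlignmentRecord:
    """A projected read alignment (SAM-like, 1-based leftmost position).

    ``seq``/``qual`` are stored in reference orientation, so the layout
    along the record is always left_clip | mapped | right_clip.
    """

    query_name: str
    ref_name: str
    pos: int  # 1-based leftmost mapped position (0 if unmapped)
    mapped_len: int
    left_clip: int
    right_clip: int
    is_reverse: bool
    is_read1: bool
    mate_pos: int
    apparent_insert: int  # signed TLEN; 0 if either mate unmapped
    proper_pair: bool
    mate_mapped: bool
    is_unmapped: bool
    seq: str
    qual: str
    sample_id: str = ""

    @property
    def read_len(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        """1-based rightmost mapped position (inclusive)."""
        return self.pos + self.mapped_len - 1

    @property
    def cigar(self) -> str:
        if self.is_unmapped:
            return "*"
        parts = []
        if self.left_clip:
            parts.append(f"{self.left_clip}S")
        parts.append(f"{self.mapped_len}M")
        if self.right_clip:
            parts.append(f"{self.right_clip}S")
        return "".join(parts)


def project_read(
    cmap: CoordinateMap,
    hap_start: int,
    read_len: int,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> tuple[int, int, int, int] | None:
    """Project a haplotype interval onto the reference.

    Returns (pos, mapped_len, left_clip, right_clip) or None if the read
    has no mapped anchor of at least ``min_anchor`` bases on either side
    of the junction.
    """
    s = hap_start
    e = hap_start + read_len - 1
    if s < 1 or e > cmap.hap_length:
        raise ValueError("read interval outside haplotype")
    left_len, ins_len = cmap.left_len, cmap.ins_len
    block2_start = left_len + ins_len + 1

    n_left = max(0, min(e, left_len) - s + 1)
    n_right = max(0, e - max(s, block2_start) + 1)

    if n_left == read_len:
        return (cmap.offset + s - 1, read_len, 0, 0)
    if n_right == read_len:
        return (cmap.edit.del_end + (s - block2_start), read_len, 0, 0)

    # junction-crossing read: anchor on the longer mapped side
    anchor_left = n_left >= min_anchor
    anchor_right = n_right >= min_anchor
    if anchor_left and (n_left >= n_right or not anchor_right):
        return (cmap.offset + s - 1, n_left, 0, read_len - n_left)
    if anchor_right:
        h2 = max(s, block2_start)
        pos = cmap.edit.del_end + (h2 - block2_start)
        return (pos, n_right, read_len - n_right, 0)
    return None


def project_alignment(
    cmap: CoordinateMap,
    pair: ReadPair,
    ref_name: str = "chr1",
    sample_id: str = "",
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Project both mates of a pair and fill in mate/TLEN fields."""
    rl1 = len(pair.read1_seq)
    rl2 = len(pair.read2_seq)
    s1 = pair.true_fragment_start
    s2 = pair.true_fragment_start + pair.true_fragment_length - rl2
    p1 = project_read(cmap, s1, rl1, min_anchor)
    p2 = project_read(cmap, s2, rl2, min_anchor)

    def make(proj, is_read1, seq_ref, qual, mate_proj):
        unmapped = proj is None
        pos, mlen, lc, rc = proj if proj else (0, 0, 0, 0)
        mate_unmapped = mate_proj is None
        mate_pos = mate_proj[0] if mate_proj else pos
        if unmapped and mate_proj:
            pos = mate_proj[0]  # unmapped mate placed at its mate
        return AlignmentRecord(
            query_name=pair.name,
            ref_name=ref_name,
            pos=pos,
            mapped_len=mlen,
            left_clip=lc,
            right_clip=rc,
            is_reverse=not is_read1,
            is_read1=is_read1,
            mate_pos=mate_pos,
            apparent_insert=0,
            proper_pair=False,
            mate_mapped=not mate_unmapped,
            is_unmapped=unmapped,
            seq=seq_ref,
            qual=qual,
            sample_id=sample_id,
        )

    seq1_ref = pair.read1_seq
    seq2_ref = revcomp(pair.read2_seq)
    r1 = make(p1, True, seq1_ref, pair.read1_qual, p2)
    r2 = make(p2, False, seq2_ref, pair.read2_qual[::-1], p1)

    if p1 is not None and p2 is not None:
        leftmost = min(r1.pos, r2.pos)
        outer_end = max(r1.end, r2.end)
        span = outer_end - leftmost + 1
        if r1.pos <= r2.pos:  # tie -> read1 carries the positive sign
            r1.apparent_insert, r2.apparent_insert = span, -span
        else:
            r1.apparent_insert, r2.apparent_insert = -span, span
        r1.proper_pair = r2.proper_pair = True
    return r1, r2


def simulate_read_pairs(
    sample: SampleSpec,
    haplotypes: tuple[str, str],
    cmaps: tuple[CoordinateMap, CoordinateMap],
    coverage: float = 5.0,
    read_len: int = 150,
    frag_mean: float = 500.0,
    frag_sd: float = 50.0,
    error_rate: float = 0.001,
    seed: int = 0,
    ref_name: str = "chr1",
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> tuple[list[ReadPair], list[AlignmentRecord]]:
    """Simulate paired reads from a sample's two haplotypes.

    The number of pairs is coverage * region_length / (2 * read_len),
    where region_length is the reference length (so coverage is stated
    on the reference scale).  Fragment lengths are normal(frag_mean,
    frag_sd), resampled while shorter than the read or longer than the
    haplotype.  Substitution errors are uniform at ``error_rate``;
    qualities are constant Q30.  The returned truth alignments come from
    coordinate projection, not a heuristic aligner.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if frag_mean < read_len:
        raise ValueError("frag_mean must be >= read_len")
    rng = np.random.default_rng(seed)
    region_length = cmaps[0].ref_length
    n_pairs = int(round(coverage * region_length / (2 * read_len)))
    hap_lens = np.array([len(haplotypes[0]), len(haplotypes[1])])

    hap_idx = rng.integers(0, 2, size=n_pairs)
    frags = np.rint(rng.normal(frag_mean, frag_sd, size=n_pairs)).astype(int)
    max_len = hap_lens[hap_idx]
    bad = (frags < read_len) | (frags > max_len)
    while bad.any():
        frags[bad] = np.rint(
            rng.normal(frag_mean, frag_sd, size=int(bad.sum()))
        ).astype(int)
        bad = (frags < read_len) | (frags > max_len)
    starts = (rng.random(n_pairs) * (max_len - frags + 1)).astype(int) + 1

    # fragment-forward slices (reference orientation)
    seqs1 = []
    seqs2 = []
    for i in range(n_pairs):
        h = haplotypes[hap_idx[i]]
        s = starts[i] - 1
        seqs1.append(bytearray(h[s : s + read_len], "ascii"))
        fe = s + frags[i]
        seqs2.append(bytearray(h[fe - read_len : fe], "ascii"))

    # uniform substitution noise, batched over all bases
    total_bases = 2 * n_pairs * read_len
    n_err = rng.binomial(total_bases, error_rate)
    if n_err:
        flat = rng.integers(0, total_bases, size=n_err)
        subs = rng.integers(1, 4, size=n_err)  # offset to a different base
        for f, off in zip(flat, subs):
            mate, rem = divmod(int(f), 2 * read_len)
            which, j = divmod(rem, read_len)
            target = seqs1[mate] if which == 0 else seqs2[mate]
            cur = _BASE_ORDS.tolist().index(target[j])
            target[j] = _BASE_ORDS[(cur + int(off)) % 4]

    qual = chr(DEFAULT_QUALITY + 33) * read_len
    pairs: list[ReadPair] = []
    records: list[AlignmentRecord] = []
    for i in range(n_pairs):
        seq1 = seqs1[i].decode("ascii")
        seq2_ref = seqs2[i].decode("ascii")
        pair = ReadPair(
            name=f"{sample.sample_id}:{i}",
            read1_seq=seq1,
            read1_qual=qual,
            read2_seq=revcomp(seq2_ref),
            read2_qual=qual,
            true_haplotype=int(hap_idx[i]),
            true_fragment_start=int(starts[i]),
            true_fragment_length=int(frags[i]),
        )
        r1, r2 = project_alignment(
            cmaps[hap_idx[i]], pair, ref_name, sample.sample_id, min_anchor
        )
        pairs.append(pair)
        records.extend((r1, r2))
    return pairs, records
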