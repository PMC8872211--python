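"""Reference regions, deletion-with-insertion alleles and coordinate maps.

All coordinates are 1-based and inclusive, expressed on the genome scale:
a :class:`ReferenceRegion` carries an ``offset`` (the genome coordinate of
its first base) so that printed chromosome coordinates in the tens of
megabases can be used on a short synthetic sequence.

The one deliberate exception is the deletion-length convention of
:class:`HaplotypeEdit`: the reported length of a deletion is
``del_end - del_start``, i.e. the deleted bases are the half-open interval
``[del_start, del_end)`` and ``del_end`` itself survives in the haplotype.
This is the convention under which breakpoints 51,035,106 / 51,042,744
yield a 7638 bp deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = b"ACGT"
_ALPHABET = set("ACGT")


def _check_acgt(seq: str, what: str) -> None:
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class ReferenceRegion:
    """A named uppercase ACGT sequence anchored at a genome coordinate."""

    name: str
    offset: int  # genome coordinate (1-based) of the first base
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("reference sequence must be non-empty")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        _check_acgt(self.sequence, "reference sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        """Genome coordinate of the last base (inclusive)."""
        return self.offset + len(self.sequence) - 1

    def index(self, pos: int) -> int:
        """0-based index into ``sequence`` of genome position ``pos``."""
        if not self.offset <= pos <= self.end:
            raise ValueError(
                f"position {pos} outside region {self.name}:{self.offset}-{self.end}"
            )
        return pos - self.offset

    def subseq(self, start: int, end: int) -> str:
        """Sequence of the inclusive genome interval [start, end]."""
        if end < start:
            raise ValueError("end < start")
        return self.sequence[self.index(start) : self.index(end) + 1]

    def with_sequence(self, sequence: str) -> "ReferenceRegion":
        return ReferenceRegion(self.name, self.offset, sequence)


@dataclass(frozen=True)
class HaplotypeEdit:
    """A deletion allele, possibly with a non-templated junction insertion.

    Deleted bases are ``[del_start, del_end)``; the reported deletion
    length is ``del_end - del_start``.  ``del_end == del_start`` with an
    empty insertion is the identity edit.
    """

    del_start: int
    del_end: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.del_end < self.del_start:
            raise ValueError("del_end must be >= del_start")
        if self.del_start < 1:
            raise ValueError("del_start must be >= 1")
        _check_acgt(self.inserted_seq, "inserted_seq")

    @property
    def length(self) -> int:
        """Reported deletion length (bp)."""
        return self.del_end - self.del_start

    @property
    def is_identity(self) -> bool:
        return self.length == 0 and not self.inserted_seq


IDENTITY_EDIT = HaplotypeEdit(del_start=1, del_end=1, inserted_seq="")


@dataclass(frozen=True)
class CoordinateMap:
    """Bidirectional map between haplotype and reference coordinates.

    The haplotype consists of a left block (reference up to the junction),
    the inserted sequence (unmapped), and a right block (reference from
    ``del_end`` on).  Haplotype positions are 1-based; position 1
    corresponds to genome position ``offset`` when the left block is
    non-empty.
    """

    offset: int
    ref_length: int
    edit: HaplotypeEdit

    # derived block geometry, filled in __post_init__
    left_len: int = field(init=False)
    ins_len: int = field(init=False)
    hap_length: int = field(init=False)

    def __post_init__(self) -> None:
        ref_end = self.offset + self.ref_length - 1
        e = self.edit
        if not e.is_identity:
            if e.del_start < self.offset or e.del_end > ref_end + 1:
                raise ValueError(
                    f"edit [{e.del_start},{e.del_end}) outside region "
                    f"{self.offset}-{ref_end}"
                )
        left = (e.del_start - self.offset) if not e.is_identity else self.ref_length
        object.__setattr__(self, "left_len", left)
        object.__setattr__(self, "ins_len", len(e.inserted_seq))
        object.__setattr__(
            self, "hap_length", self.ref_length - (0 if e.is_identity else e.length) + self.ins_len
        )

    @property
    def junction_hap_pos(self) -> int:
        """Last haplotype position of the left block (0 if it is empty)."""
        return self.left_len

    def hap_to_ref(self, hap_pos: int) -> int | None:
        """Genome position of haplotype position, None inside the insertion."""
        if not 1 <= hap_pos <= self.hap_length:
            raise ValueError(f"haplotype position {hap_pos} out of range")
        if hap_pos <= self.left_len:
            return self.offset + hap_pos - 1
        if hap_pos <= self.left_len + self.ins_len:
            return None
        return self.edit.del_end + (hap_pos - self.left_len - self.ins_len - 1)

    def ref_to_hap(self, ref_pos: int) -> int | None:
        """Haplotype position of genome position, None inside the deletion."""
        ref_end = self.offset + self.ref_length - 1
        if not self.offset <= ref_pos <= ref_end:
            raise ValueError(f"reference position {ref_pos} out of range")
        if self.edit.is_identity or ref_pos < self.edit.del_start:
            return ref_pos - self.offset + 1
        if ref_pos < self.edit.del_end:
            return None
        return self.left_len + self.ins_len + (ref_pos - self.edit.del_end + 1)


def build_reference(
    length: int,
    offset: int = 1,
    gc: float = 0.42,
    seed: int = 0,
    name: str = "chr1",
) -> ReferenceRegion:
    """Draw a random reference sequence with the requested GC content.

    Bases are i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2,
    so for long sequences the realised GC fraction is binomially
    concentrated around ``gc``.  Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at, cg = (1.0 - gc) / 2.0, gc / 2.0
    idx = rng.choice(4, size=length, p=[at, cg, cg, at])  # A C G T
    seq = np.frombuffer(_BASES, dtype=np.uint8)[idx].tobytes().decode("ascii")
    return ReferenceRegion(name=name, offset=offset, sequence=seq)


def apply_edit(ref: ReferenceRegion, edit: HaplotypeEdit) -> tuple[str, CoordinateMap]:
    """Apply a deletion-with-insertion allele to a reference region.

    Returns the haplotype sequence and the coordinate map between
    haplotype and reference positions.
    """
    if not edit.is_identity and not (
        ref.offset <= edit.del_start and edit.del_end <= ref.end + 1
    ):
        raise ValueError(
            f"edit [{edit.del_start},{edit.del_end}) outside region "
            f"{ref.name}:{ref.offset}-{ref.end}"
        )
    cmap = CoordinateMap(offset=ref.offset, ref_length=len(ref), edit=edit)
    if edit.is_identity:
        return ref.sequence, cmap
    i, j = edit.del_start - ref.offset, edit.del_end - ref.offset
    hap = ref.sequence[:i] + edit.inserted_seq + ref.sequence[j:]
    assert len(hap) == cmap.hap_length
    return hap, cmap


def identity_map(ref: ReferenceRegion) -> CoordinateMap:
    """Coordinate map of the unedited (wildtype) haplotype."""
    return CoordinateMap(
        offset=ref.offset,
        ref_length=len(ref),
        edit=HaplotypeEdit(ref.offset, ref.offset, ""),
    )


def guard_junction(ref: ReferenceRegion, edit: HaplotypeEdit) -> ReferenceRegion:
    """Make the planted edit's representation canonical (leftmost-unique).

    A deletion-with-insertion has several equivalent spellings when the
    insertion's first (last) base equals the first (last) deleted base —
    micro-homology.  So that a planted edit is recoverable exactly as
    specified, the adjacent deleted reference bases are swapped to a
    different base where needed.  Only bases inside the deleted interval
    are touched, so every haplotype carrying the edit is unchanged.
    """
    if edit.is_identity:
        return ref
    seq = bytearray(ref.sequence, "ascii")
    first_del = ref.index(edit.del_start)
    last_del = ref.index(edit.del_end - 1)
    forbidden: dict[int, set[str]] = {}
    if edit.inserted_seq:
        forbidden.setdefault(first_del, set()).add(edit.inserted_seq[0])
        forbidden.setdefault(last_del, set()).add(edit.inserted_seq[-1])
    else:
        if edit.del_end <= ref.end:
            forbidden.setdefault(first_del, set()).add(
                ref.sequence[ref.index(edit.del_end)]
            )
        if edit.del_start > ref.offset:
            forbidden.setdefault(last_del, set()).add(
                ref.sequence[ref.index(edit.del_start - 1)]
            )
    for i, bad in forbidden.items():
        if chr(seq[i]) in bad:
            seq[i] = ord(next(b for b in "ACGT" if b not in bad))
    return ref.with_sequence(seq.decode("ascii"))


def plant_sites(ref: ReferenceRegion, sites: dict[int, str]) -> ReferenceRegion:
    """Overwrite the reference with fixed subsequences at genome positions.

    Used to place exact primer-binding sites (or any motif) at printed
    coordinates before haplotypes are derived.
    """
    seq = bytearray(ref.sequence, "ascii")
    for start, motif in sites.items():
        _check_acgt(motif, "planted motif")
        i = ref.index(start)
        if i + len(motif) > len(seq):
            raise ValueError(f"motif at {start} extends past region end")
        seq[i : i + len(motif)] = motif.encode("ascii")
    return ref.with_sequence(seq.decode("ascii"))
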