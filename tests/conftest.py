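"""Shared fixtures: a compact study region carrying the causal edit.

The full-scale geometry (200 kb) is only used where a check explicitly
needs it; most tests run on a 40 kb window around the deletion so the
suite stays fast while every coordinate matches the printed ones.
"""

from __future__ import annotations

import pytest

from delscan.cohort import SampleSpec, simulate_cohort
from delscan.diagnostics import DIAGNOSTIC_PRIMERS
from delscan.pipeline import PRIMER_FORWARD_START, PRIMER_REGION_END
from delscan.reads import revcomp, simulate_read_pairs
from delscan.reference import (
    HaplotypeEdit,
    apply_edit,
    build_reference,
    guard_junction,
    identity_map,
    plant_sites,
)

DEL_START = 51_035_106
DEL_END = 51_042_744
INSERTED = "GGTGCGGTGA"


@pytest.fixture(scope="session")
def causal_edit() -> HaplotypeEdit:
    return HaplotypeEdit(DEL_START, DEL_END, INSERTED)


@pytest.fixture(scope="session")
def small_ref(causal_edit):
    """40 kb reference around the deletion, primer sites planted."""
    ref = build_reference(40_000, offset=51_020_000, gc=0.42, seed=101)
    ref = plant_sites(
        ref,
        {
            PRIMER_FORWARD_START: DIAGNOSTIC_PRIMERS.forward,
            PRIMER_REGION_END
            - len(DIAGNOSTIC_PRIMERS.reverse)
            + 1: revcomp(DIAGNOSTIC_PRIMERS.reverse),
        },
    )
    return guard_junction(ref, causal_edit)


@pytest.fixture(scope="session")
def haplotypes(small_ref, causal_edit):
    """(wt_seq, wt_map, del_seq, del_map) on the small reference."""
    del_seq, del_map = apply_edit(small_ref, causal_edit)
    return small_ref.sequence, identity_map(small_ref), del_seq, del_map


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(39, 40, het_fraction_controls=0.5, seed=2)


def make_sample(genotype: str, sid: str = "S1") -> SampleSpec:
    pheno = "LY" if genotype == "del/del" else "DR"
    flags = {
        "wt/wt": (False, False),
        "wt/del": (True, False),
        "del/del": (True, True),
    }[genotype]
    return SampleSpec(sid, pheno, genotype, flags)


def simulate_sample_reads(
    genotype: str,
    haps,
    coverage: float = 5.0,
    seed: int = 0,
    sid: str = "S1",
    **kwargs,
):
    """Reads + truth alignments for one sample on the small reference."""
    wt_seq, wt_map, del_seq, del_map = haps
    sample = make_sample(genotype, sid)
    pick = lambda flag: (del_seq, del_map) if flag else (wt_seq, wt_map)  # noqa: E731
    h0, m0 = pick(sample.hap_is_del[0])
    h1, m1 = pick(sample.hap_is_del[1])
    return sample, *simulate_read_pairs(
        sample, (h0, h1), (m0, m1), coverage=coverage, seed=seed, **kwargs
    )
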