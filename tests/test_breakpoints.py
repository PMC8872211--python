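"""Clip clustering, junction consensus voting, breakpoint resolution."""

import numpy as np
import pytest

from delscan.breakpoints import (
    BreakpointNoCall,
    ClipCluster,
    SIDE_LEFT_CLIP,
    SIDE_RIGHT_CLIP,
    collect_clip_clusters,
    junction_consensus,
    resolve_breakpoints,
    resolve_deletion,
)
from delscan.reference import (
    HaplotypeEdit,
    apply_edit,
    build_reference,
    guard_junction,
)

from conftest import DEL_END, DEL_START, INSERTED, simulate_sample_reads
from test_depth import simple_record


class TestCollectClipClusters:
    def test_no_clipped_reads_no_clusters(self):
        recs = [simple_record(1000), simple_record(2000)]
        assert collect_clip_clusters(recs, 1, 10_000) == []

    def test_short_clips_ignored(self):
        rec = simple_record(1000, mapped=140, right_clip=10)
        assert collect_clip_clusters([rec], 1, 10_000, min_clip=20) == []

    def test_deletion_sample_yields_two_dominant_clusters(self, haplotypes):
        _, _, recs = simulate_sample_reads("del/del", haplotypes, coverage=20, seed=17)
        clusters = collect_clip_clusters(recs, DEL_START - 5000, DEL_END + 5000)
        sides = {(c.side, c.edge) for c in clusters}
        assert (SIDE_RIGHT_CLIP, DEL_START) in sides
        assert (SIDE_LEFT_CLIP, DEL_END) in sides
        # the two junction clusters dominate every other cluster
        by_support = sorted(clusters, key=lambda c: -c.support)[:2]
        assert {(c.side, c.edge) for c in by_support} == sides


def cluster_from(seqs, side, edge):
    return ClipCluster(
        edge=edge, side=side,
        clipped_seqs=list(seqs), clipped_quals=["I" * len(s) for s in seqs],
    )


class TestJunctionConsensus:
    def test_identical_clips_vote_themselves(self):
        # a large insertion makes the two sides overlap without a reference
        ins = "ACGTTGCAAGGCTTACGGATCCATGCAA"  # 28 bp, non-periodic
        right_ref = "GGGGGCCCCCAAAAATTTTT"
        left_ref = "TTTTTAAAAACCCCCGGGGG"
        lc = cluster_from([ins + right_ref] * 5, SIDE_RIGHT_CLIP, 1000)
        rc = cluster_from([left_ref + ins] * 5, SIDE_LEFT_CLIP, 2000)
        cons = junction_consensus(lc, rc)
        assert ins in cons
        assert cons == left_ref + ins + right_ref

    def test_single_substitution_outvoted(self):
        ins = "ACGTTGCAAGGCTTACGGATCCATGCAA"
        right_ref = "GGGGGCCCCCAAAAATTTTT"
        left_ref = "TTTTTAAAAACCCCCGGGGG"
        reads = [ins + right_ref] * 9 + ["T" + (ins + right_ref)[1:]]
        lc = cluster_from(reads, SIDE_RIGHT_CLIP, 1000)
        rc = cluster_from([left_ref + ins] * 10, SIDE_LEFT_CLIP, 2000)
        assert junction_consensus(lc, rc) == left_ref + ins + right_ref

    def test_same_side_clusters_rejected(self):
        a = cluster_from(["A" * 30], SIDE_RIGHT_CLIP, 100)
        b = cluster_from(["C" * 30], SIDE_RIGHT_CLIP, 200)
        with pytest.raises(ValueError):
            junction_consensus(a, b)


class TestResolveBreakpoints:
    def test_planted_consensus_recovers_printed_coordinates(self, small_ref):
        cons = (
            small_ref.subseq(DEL_START - 60, DEL_START - 1)
            + INSERTED
            + small_ref.subseq(DEL_END, DEL_END + 59)
        )
        call = resolve_breakpoints(cons, small_ref)
        assert (call.del_start, call.del_end) == (DEL_START, DEL_END)
        assert call.deletion_length == 7638
        assert call.inserted_seq == INSERTED

    def test_empty_insertion_recovered_as_empty(self):
        ref = build_reference(5000, offset=1, seed=51)
        edit = HaplotypeEdit(2000, 2400, "")
        ref = guard_junction(ref, edit)
        cons = ref.subseq(1950, 1999) + ref.subseq(2400, 2449)
        call = resolve_breakpoints(cons, ref)
        assert (call.del_start, call.del_end, call.inserted_seq) == (2000, 2400, "")

    def test_unanchorable_flank_is_a_no_call(self):
        ref = build_reference(5000, offset=1, seed=52)
        with pytest.raises(BreakpointNoCall):
            resolve_breakpoints("T" * 40 + "A" * 40, ref)

    def test_repeated_flank_is_ambiguous(self):
        seq = ("ACGTA" * 12) + "GGGGGGGGGGCCCCCCCCCCGGCATTACGA" * 3
        ref = build_reference(2000, offset=1, seed=53)
        repeated = ref.with_sequence(ref.sequence[:500] + seq[:60] + ref.sequence[560:1000] + seq[:60] + ref.sequence[1060:])
        with pytest.raises(BreakpointNoCall, match="unique"):
            resolve_breakpoints(seq[:60] + "A" * 40, repeated)


class TestResolveDeletion:
    def test_full_chain_recovers_planted_edit(self, small_ref, haplotypes):
        _, _, recs = simulate_sample_reads("del/del", haplotypes, coverage=20, seed=18)
        call = resolve_deletion(recs, small_ref, DEL_START - 5000, DEL_END + 5000)
        assert (call.del_start, call.del_end) == (DEL_START, DEL_END)
        assert call.deletion_length == 7638
        assert call.inserted_seq == INSERTED
        assert call.support >= 2

    def test_no_junction_reads_is_a_no_call(self, small_ref, haplotypes):
        _, _, recs = simulate_sample_reads("wt/wt", haplotypes, coverage=20, seed=19)
        with pytest.raises(BreakpointNoCall):
            resolve_deletion(recs, small_ref, DEL_START - 5000, DEL_END + 5000)

    @pytest.mark.parametrize("error_rate", [0.0, 0.001])
    def test_random_edits_recovered_exactly(self, error_rate):
        """Planted deletions (200-2000 bp, 0-20 bp insert) on toy
        references are recovered at base resolution."""
        rng = np.random.default_rng(57)
        n_exact = 0
        n_edits = 15
        for i in range(n_edits):
            ref = build_reference(12_000, offset=1, seed=600 + i)
            del_len = int(rng.integers(200, 2001))
            ins_len = int(rng.integers(0, 21))
            start = int(rng.integers(3000, 9000 - del_len))
            ins = "".join(rng.choice(list("ACGT"), size=ins_len))
            edit = HaplotypeEdit(start, start + del_len, ins)
            ref = guard_junction(ref, edit)
            hap, cmap = apply_edit(ref, edit)
            from delscan.cohort import SampleSpec
            from delscan.reads import simulate_read_pairs

            sample = SampleSpec("s", "LY", "del/del", (True, True))
            coverage = 20 if error_rate == 0.0 else 30
            _, recs = simulate_read_pairs(
                sample, (hap, hap), (cmap, cmap), coverage=coverage,
                error_rate=error_rate, seed=700 + i,
            )
            call = resolve_deletion(recs, ref, 1, 12_000)
            if (
                call.del_start == start
                and call.del_end == start + del_len
                and call.inserted_seq == ins
            ):
                n_exact += 1
        if error_rate == 0.0:
            assert n_exact == n_edits
        else:
            assert n_exact >= n_edits - 1  # >= 95% under sequencing noise

    def test_consistent_with_insert_size_estimate(self, small_ref, haplotypes):
        """deletion_length equals net insert-size estimate + insertion
        length within median sampling error."""
        from delscan.inserts import classify_sv, extract_apparent_inserts

        case_recs, ctrl_recs = [], []
        for i in range(5):
            _, _, r = simulate_sample_reads(
                "del/del", haplotypes, coverage=5, seed=800 + i, sid=f"c{i}"
            )
            case_recs.extend(r)
            _, _, r = simulate_sample_reads(
                "wt/wt", haplotypes, coverage=5, seed=900 + i, sid=f"k{i}"
            )
            ctrl_recs.extend(r)
        call = resolve_deletion(case_recs, small_ref, DEL_START - 5000, DEL_END + 5000)
        cp = extract_apparent_inserts(case_recs, DEL_START, DEL_END, "case")
        kp = extract_apparent_inserts(ctrl_recs, DEL_START, DEL_END, "ctrl")
        sv = classify_sv(cp, kp, 500, 50)
        n = sv.support
        tol = 2 * 50 / np.sqrt(n)
        assert abs(
            call.deletion_length - (sv.net_size_estimate + len(call.inserted_seq))
        ) <= max(tol, 5)
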