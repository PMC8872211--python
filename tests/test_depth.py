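"""Pooled depth, log ratio track, and candidate-segment calling."""

import numpy as np
import pytest

from delscan.depth import call_candidate_segments, log_depth_ratio, pooled_depth
from delscan.reads import AlignmentRecord
from delscan.reference import ReferenceRegion, build_reference

from conftest import DEL_END, DEL_START, simulate_sample_reads


def simple_record(pos, mapped=150, sample="s1", left_clip=0, right_clip=0):
    return AlignmentRecord(
        query_name="q", ref_name="chr1", pos=pos, mapped_len=mapped,
        left_clip=left_clip, right_clip=right_clip, is_reverse=False,
        is_read1=True, mate_pos=pos, apparent_insert=500, proper_pair=True,
        mate_mapped=True, is_unmapped=False, seq="A" * (mapped + left_clip + right_clip),
        qual="I" * (mapped + left_clip + right_clip), sample_id=sample,
    )


@pytest.fixture
def flat_region():
    return ReferenceRegion("chr1", 1, "A" * 400)


class TestPooledDepth:
    def test_single_read_covers_its_span(self, flat_region):
        depth = pooled_depth([simple_record(101)], flat_region)
        assert depth[99] == 0 and depth[100] == 1 and depth[249] == 1
        assert depth[250] == 0
        assert depth.sum() == 150

    def test_overlapping_reads_stack(self, flat_region):
        depth = pooled_depth([simple_record(101), simple_record(151)], flat_region)
        assert depth[140] == 1 and depth[160] == 2 and depth[260] == 1

    def test_soft_clipped_bases_do_not_count(self, flat_region):
        depth = pooled_depth(
            [simple_record(101, mapped=100, right_clip=50)], flat_region
        )
        assert depth.sum() == 100

    def test_depth_conservation(self, small_ref, haplotypes):
        _, _, recs = simulate_sample_reads("wt/wt", haplotypes, coverage=2, seed=6)
        depth = pooled_depth(recs, small_ref)
        mapped_bases = sum(r.mapped_len for r in recs if not r.is_unmapped)
        assert depth.sum() == mapped_bases

    def test_pool_of_ten_samples_at_5x(self, small_ref, haplotypes):
        recs = []
        for i in range(10):
            _, _, r = simulate_sample_reads(
                "wt/wt", haplotypes, coverage=5, seed=100 + i, sid=f"s{i}"
            )
            recs.extend(r)
        depth = pooled_depth(recs, small_ref, {f"s{i}" for i in range(10)})
        interior = depth[1000:-1000]
        assert abs(float(interior.mean()) - 50.0) <= 2.0

    def test_deletion_depth_signature(self, small_ref, haplotypes):
        """del/del depth is 0 inside the deletion; wt/del is half flanking."""
        lo = DEL_START - small_ref.offset
        hi = DEL_END - small_ref.offset
        _, _, hom = simulate_sample_reads("del/del", haplotypes, coverage=5, seed=7)
        d_hom = pooled_depth(hom, small_ref)
        inner = d_hom[lo + 200 : hi - 200]
        assert inner.max() == 0
        _, _, het = simulate_sample_reads("wt/del", haplotypes, coverage=8, seed=8)
        d_het = pooled_depth(het, small_ref)
        inside = float(d_het[lo + 200 : hi - 200].mean())
        flank = float(np.concatenate([d_het[1000:lo - 200], d_het[hi + 200:-1000]]).mean())
        assert inside == pytest.approx(flank / 2, rel=0.2)


class TestLogDepthRatio:
    def test_equal_depths_give_zero(self):
        d = np.full(100, 7.0)
        assert np.allclose(log_depth_ratio(d, d.copy()), 0.0)

    def test_swap_negates_exactly(self):
        rng = np.random.default_rng(43)
        a, b = rng.poisson(20, 500).astype(float), rng.poisson(30, 500).astype(float)
        assert np.allclose(
            log_depth_ratio(a, b), -log_depth_ratio(b, a), atol=1e-12
        )

    def test_normalization_cancels_scale(self):
        rng = np.random.default_rng(47)
        a, b = rng.poisson(20, 500).astype(float), rng.poisson(20, 500).astype(float)
        base = log_depth_ratio(a, b, pseudocount=0.5)
        doubled = log_depth_ratio(2 * a, 2 * b, pseudocount=0.5)
        assert np.allclose(base, doubled, atol=0.1)

    def test_zero_pseudocount_with_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            log_depth_ratio(np.zeros(10), np.ones(10), pseudocount=0.0)


class TestCandidateSegments:
    def test_flat_track_yields_nothing(self):
        assert call_candidate_segments(np.zeros(5000), 1) == []

    def test_threshold_above_max_yields_nothing(self):
        track = np.concatenate([np.zeros(1000), np.full(1000, 2.0), np.zeros(1000)])
        assert call_candidate_segments(track, 1, threshold=5.0) == []

    def test_clean_step_recovered_with_direction(self):
        track = np.concatenate([np.zeros(2000), np.full(1500, -3.0), np.zeros(2000)])
        segs = call_candidate_segments(track, 1, threshold=1.0, min_len=500)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.direction == "B>A"
        # smoothing blurs edges by at most half the window
        assert abs(seg.start - 2001) <= 101 and abs(seg.end - 3500) <= 101

    def test_simulated_deletion_segment_overlaps_truth(self, small_ref, haplotypes):
        """Control-vs-case ratio over the deletion: one A>B segment with
        high Jaccard overlap against the planted interval."""
        case_recs, ctrl_recs = [], []
        for i in range(5):
            _, _, r = simulate_sample_reads(
                "del/del", haplotypes, coverage=5, seed=200 + i, sid=f"ly{i}"
            )
            case_recs.extend(r)
            genotype = "wt/del" if i % 2 else "wt/wt"
            _, _, r = simulate_sample_reads(
                genotype, haplotypes, coverage=5, seed=300 + i, sid=f"dr{i}"
            )
            ctrl_recs.extend(r)
        d_case = pooled_depth(case_recs, small_ref)
        d_ctrl = pooled_depth(ctrl_recs, small_ref)
        ratio = log_depth_ratio(d_ctrl, d_case)
        segs = call_candidate_segments(ratio, small_ref.offset)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.direction == "A>B"
        inter = min(seg.end, DEL_END - 1) - max(seg.start, DEL_START) + 1
        union = max(seg.end, DEL_END - 1) - min(seg.start, DEL_START) + 1
        assert inter / union >= 0.8
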