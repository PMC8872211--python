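"""Hard filters, SNP-cluster rule and call-rate filter."""

import numpy as np
import pytest

from delscan.filters import (
    MALFORMED_LABEL,
    PASS_LABEL,
    apply_call_rate_filter,
    apply_hard_filters,
    hard_filter_verdict,
    remove_clustered_snps,
)
from delscan.variants import VariantRecord, annotate_variants


def make_variant(pos=100, qual=100.0, info=None, genotypes=None, chrom="chr1"):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="C",
        qual=qual,
        info=dict(
            {"QD": 20.0, "FS": 1.0, "MQ": 55.0, "MQRankSum": 0.0,
             "ReadPosRankSum": 0.0},
            **(info or {}),
        ),
        genotypes=genotypes if genotypes is not None else [(0, 1)],
    )


class TestHardFilters:
    @pytest.mark.parametrize(
        "qual,info,expected",
        [
            (29.9, {}, "LowQual"),
            (30.0, {}, "LowQual"),  # strict inequality: QUAL > 30.0
            (30.01, {}, PASS_LABEL),
            (100.0, {"QD": 5.0}, "LowQD"),
            (100.0, {"FS": 60.0}, "HighFS"),
            (100.0, {"MQ": 40.0}, "LowMQ"),
            (100.0, {"MQRankSum": -12.5}, "LowMQRankSum"),
            (100.0, {"ReadPosRankSum": -8.0}, "LowReadPosRankSum"),
            (100.0, {"ReadPosRankSum": -7.99}, PASS_LABEL),
        ],
    )
    def test_threshold_boundaries(self, qual, info, expected):
        assert hard_filter_verdict(make_variant(qual=qual, info=info)) == expected

    def test_absent_rank_sums_do_not_fail(self):
        v = make_variant()
        del v.info["MQRankSum"], v.info["ReadPosRankSum"]
        assert hard_filter_verdict(v) == PASS_LABEL

    def test_malformed_annotation_gets_distinct_label(self):
        v = make_variant(info={"MQ": float("nan")})
        assert hard_filter_verdict(v) == MALFORMED_LABEL
        v2 = make_variant(info={"QD": "not-a-number"})
        assert hard_filter_verdict(v2) == MALFORMED_LABEL

    def test_survivors_equal_brute_force_predicates(self):
        base = [make_variant(pos=p) for p in range(1, 2001)]
        variants = annotate_variants(base, fail_rate=0.4, seed=13)
        survivors, report = apply_hard_filters(variants)

        def brute(v):
            i = v.info
            return (
                v.qual > 30.0
                and i["QD"] > 5.0
                and i["FS"] < 60.0
                and i["MQ"] > 40.0
                and i.get("MQRankSum", 0.0) > -12.5
                and i.get("ReadPosRankSum", 0.0) > -8.0
            )

        assert [v.vid for v in survivors] == [v.vid for v in variants if brute(v)]
        assert sum(report.counts.values()) == len(variants)

    def test_idempotent(self):
        variants = annotate_variants(
            [make_variant(pos=p) for p in range(1, 500)], fail_rate=0.3, seed=1
        )
        once, _ = apply_hard_filters(variants)
        twice, rep = apply_hard_filters(once)
        assert [v.vid for v in twice] == [v.vid for v in once]
        assert rep.n_pass == len(once)


class TestClusterRule:
    def _positions(self, variants):
        return [v.pos for v in variants]

    def test_three_in_ten_bp_all_removed(self):
        vs = [make_variant(pos=p) for p in (100, 105, 109)]
        assert remove_clustered_snps(vs) == []

    def test_spread_positions_retained(self):
        vs = [make_variant(pos=p) for p in (100, 105, 120)]
        assert self._positions(remove_clustered_snps(vs)) == [100, 105, 120]

    def test_single_snp_retained(self):
        vs = [make_variant(pos=42)]
        assert self._positions(remove_clustered_snps(vs)) == [42]

    def test_window_is_inclusive_span(self):
        # 100 and 109 are 10 bases apart inclusive: clustered with 104
        vs = [make_variant(pos=p) for p in (100, 104, 109)]
        assert remove_clustered_snps(vs) == []
        # 100..110 spans 11 bases: no 10 bp window holds all three
        vs = [make_variant(pos=p) for p in (100, 104, 110)]
        assert self._positions(remove_clustered_snps(vs)) == [100, 104, 110]

    def test_unsorted_input_raises(self):
        vs = [make_variant(pos=200), make_variant(pos=100)]
        with pytest.raises(ValueError, match="sort"):
            remove_clustered_snps(vs)

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(17)
        positions = np.unique(rng.integers(1, 3000, size=400))
        vs = [make_variant(pos=int(p)) for p in positions]
        got = self._positions(remove_clustered_snps(vs, window=10, min_count=3))

        drop = set()
        pos = list(positions)
        for w in range(1, 3001):
            inside = [p for p in pos if w <= p <= w + 9]
            if len(inside) >= 3:
                drop.update(inside)
        assert got == [p for p in pos if p not in drop]

    def test_idempotent(self):
        rng = np.random.default_rng(19)
        vs = [make_variant(pos=int(p)) for p in np.unique(rng.integers(1, 500, 80))]
        once = remove_clustered_snps(vs)
        assert remove_clustered_snps(once) == once


class TestCallRateFilter:
    def _with_called(self, n_called, n_total, pos=100):
        gts = [(0, 1)] * n_called + [None] * (n_total - n_called)
        return make_variant(pos=pos, genotypes=gts)

    def test_just_below_study_threshold_removed(self):
        # 63/79 = 0.797 < 0.8
        assert apply_call_rate_filter([self._with_called(63, 79)]) == []

    def test_just_above_study_threshold_retained(self):
        # 64/79 = 0.810 >= 0.8
        assert len(apply_call_rate_filter([self._with_called(64, 79)])) == 1

    def test_fully_called_retained(self):
        assert len(apply_call_rate_filter([self._with_called(10, 10)])) == 1

    def test_zero_samples_raise(self):
        with pytest.raises(ValueError):
            apply_call_rate_filter([make_variant(genotypes=[])])

    def test_order_independent_with_hard_filters(self):
        base = [
            self._with_called(n % 12, 12, pos=100 * n) for n in range(1, 100)
        ]
        variants = annotate_variants(base, fail_rate=0.3, seed=23)
        a, _ = apply_hard_filters(apply_call_rate_filter(variants))
        b = apply_call_rate_filter(apply_hard_filters(variants)[0])
        assert [v.vid for v in a] == [v.vid for v in b]
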