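"""Allelic chi-square association, Bonferroni threshold, region calling."""

import numpy as np
import pytest
from scipy import stats

from delscan.association import (
    AlleleTable,
    AssociationResult,
    allele_table,
    allelic_chi_square,
    bonferroni_threshold,
    scan,
    significant_regions,
)
from delscan.cohort import plant_linked_snps, simulate_cohort
from delscan.reference import HaplotypeEdit, build_reference
from delscan.variants import VariantRecord

from conftest import make_sample


def variant_with_genotypes(genotypes, pos=100):
    return VariantRecord("chr1", pos, "A", "C", 100.0, {}, list(genotypes))


class TestAlleleTable:
    def test_complete_separation(self):
        samples = [make_sample("del/del", "c1"), make_sample("del/del", "c2"),
                   make_sample("wt/wt", "k1"), make_sample("wt/wt", "k2")]
        v = variant_with_genotypes([(1, 1), (1, 1), (0, 0), (0, 0)])
        t = allele_table(v, samples)
        assert (t.case_alt, t.case_ref, t.control_alt, t.control_ref) == (4, 0, 0, 4)

    def test_single_het_each(self):
        samples = [make_sample("del/del", "c1"), make_sample("wt/wt", "k1")]
        v = variant_with_genotypes([(0, 1), (0, 1)])
        t = allele_table(v, samples)
        assert (t.case_alt, t.case_ref, t.control_alt, t.control_ref) == (1, 1, 1, 1)

    def test_missing_genotypes_excluded_and_counts_match_brute_force(self):
        rng = np.random.default_rng(29)
        samples = [
            make_sample("del/del" if i < 50 else "wt/wt", f"s{i}")
            for i in range(100)
        ]
        gts = [
            None if rng.random() < 0.1 else (int(rng.integers(2)), int(rng.integers(2)))
            for _ in range(100)
        ]
        t = allele_table(variant_with_genotypes(gts), samples)
        alt_case = sum(sum(g) for g, s in zip(gts, samples) if g and s.is_case)
        called_case = sum(1 for g, s in zip(gts, samples) if g and s.is_case)
        assert t.case_alt == alt_case
        assert t.case_alt + t.case_ref == 2 * called_case

    def test_multiallelic_rejected(self):
        samples = [make_sample("del/del", "c1")]
        with pytest.raises(ValueError, match="biallelic"):
            allele_table(variant_with_genotypes([(0, 2)]), samples)


class TestAllelicChiSquare:
    def test_balanced_table_is_null(self):
        stat, p, mono = allelic_chi_square(AlleleTable(1, 1, 1, 1))
        assert stat == 0.0 and p == 1.0 and not mono

    def test_complete_separation_equals_total(self):
        # with complete separation the Pearson statistic equals N
        stat, p, _ = allelic_chi_square(AlleleTable(78, 0, 0, 80))
        assert stat == pytest.approx(158.0)
        assert p < 1e-35

    def test_monomorphic_margin_flagged(self):
        stat, p, mono = allelic_chi_square(AlleleTable(0, 78, 0, 80))
        assert (stat, p, mono) == (0.0, 1.0, True)

    def test_agrees_with_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(500):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            stat, p, _ = allelic_chi_square(AlleleTable(a, b, c, d))
            n = a + b + c + d
            expected = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert stat == pytest.approx(expected, abs=1e-10)
            assert p == pytest.approx(float(stats.chi2.sf(expected, 1)), abs=1e-12)

    def test_monotone_in_frequency_difference(self):
        # fixed margins 2x80: statistic grows with |case - control| alt counts
        prev = -1.0
        for a in range(40, 81):
            stat, _, _ = allelic_chi_square(AlleleTable(a, 80 - a, 80 - a, a))
            assert stat >= prev
            prev = stat


class TestBonferroni:
    def test_study_scale_threshold(self):
        assert round(bonferroni_threshold(16_745_104, 0.05), 2) == 8.52

    def test_single_test(self):
        assert bonferroni_threshold(1, 0.05) == pytest.approx(1.3010, abs=1e-4)

    def test_thousand_tests(self):
        assert bonferroni_threshold(1000, 0.05) == pytest.approx(4.3010, abs=1e-4)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


def result(pos, nlp, chrom="chr1"):
    p = 10.0 ** (-nlp)
    return AssociationResult(chrom, pos, f"{chrom}:{pos}", 0.0, p, nlp)


class TestSignificantRegions:
    def test_empty_when_nothing_significant(self):
        assert significant_regions([result(1, 2.0), result(5, 3.0)], 8.0) == []

    def test_nearby_hits_merge(self):
        regions = significant_regions(
            [result(1000, 9.0), result(2000, 10.0)], 8.0, merge_gap=10_000
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1000, 2000)
        assert regions[0].peak_neg_log10_p == 10.0

    def test_distant_hits_stay_separate(self):
        regions = significant_regions(
            [result(1000, 9.0), result(50_000, 9.0)], 8.0, merge_gap=10_000
        )
        assert len(regions) == 2

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError):
            significant_regions([result(500, 9.0), result(100, 9.0)], 8.0)

    def test_perfect_ld_snp_recovers_causal_region(self):
        """A fully linked SNP in the study cohort clears the threshold for
        a million tests (complete separation gives chi-square about 158)."""
        ref = build_reference(60_000, offset=51_010_000, seed=41)
        edit = HaplotypeEdit(51_035_106, 51_042_744, "GGTGCGGTGA")
        samples = simulate_cohort(39, 40, 0.0, seed=2)  # controls all wt/wt
        variants = plant_linked_snps(
            ref, edit, samples, n_snps=50, r2_at_zero=1.0, decay_bp=1e12,
            missing_rate=0.0, seed=3,
        )
        results = scan(variants, samples)
        thr = bonferroni_threshold(10**6, 0.05)
        regions = significant_regions(results, thr, merge_gap=60_000)
        assert len(regions) == 1
        assert all(r.neg_log10_p >= 30 for r in results)
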