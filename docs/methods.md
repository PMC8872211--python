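# Methods

## The problem and the model

A recessive plumage phenotype (light yellow, LY) segregates against
dark red (DR) in hens of a Rhode Island Red × White Leghorn cross. The
causal allele is modelled as a deletion-with-insertion haplotype edit on
chromosome 1: the bases in the half-open interval
[`del_start`, `del_end`) = [51,035,106, 51,042,744) are removed and the
10 nt sequence `GGTGCGGTGA` is inserted at the junction. Under this
convention the reported deletion length is `del_end − del_start` =
7,638 bp, consistent with the printed breakpoints; the inclusive-count
alternative (7,639) is rejected. Phenotype follows a strictly recessive
model at this locus: LY ⟺ del/del.

All coordinates are 1-based and inclusive. A reference region carries an
`offset` (genome coordinate of its first base) so that printed
multi-megabase coordinates can be used on a short synthetic sequence.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions as defaults:

| parameter | default | why |
|---|---|---|
| region length / anchor | 200 kb at offset 50,935,000 | spans the reported significant region (50.93–51.12 Mb) |
| cohort | 39 LY cases, 40 DR controls | the sequenced cohort sizes |
| control heterozygote fraction | 0.5 | controls are het or wildtype; the split is not reported, so an even split is assumed (configurable) |
| coverage / read length | 5X, 2×150 bp | the study's sequencing design |
| fragment model | normal(500, 50), resampled below the read length | the library's fragment distribution is not reported; 500/50 keeps wildtype apparent inserts well below the 1 kb control bound while a deletion-spanning pair lands near 8.1 kb |
| substitution error / base quality | 0.1%, constant Q30 | uniform noise only; quality trimming is out of scope |
| linked SNPs | 400 sites, r² decaying as exp(−d/20 kb) from 1.0 | produces the LD-driven significant region around the deletion |
| genotype missingness | 2% | exercises the call-rate filter |
| annotation failure rate | 15% | exercises each hard filter |

SNP–deletion linkage uses a copy model: each haplotype's SNP allele
copies the haplotype's deletion indicator with probability r = √r² and
is otherwise an independent Bernoulli draw at the pooled deletion-allele
frequency, giving realised correlation ≈ r (verified: realised r² at one
decay length is exp(−1) ± sampling error).

Truth alignments come from coordinate projection, not a heuristic
aligner: a read inside a mapped block projects to an ungapped record; a
read crossing the junction is anchored on its longer mapped side
(minimum anchor 20 bp) with the remainder soft-clipped exactly at the
junction; a read with no 20 bp anchor on either side is flagged
unmapped. The apparent insert is the signed outer reference span of the
pair (TLEN semantics). Consequences of this idealisation: no mapping
ambiguity, no chimeric or mismapped reads, no indel errors, no PCR
duplicates, no GC-coverage bias. Passing tests therefore demonstrate the
statistical logic of each stage under clean mapping, not robustness to
real aligner artefacts.

Because a deletion-with-insertion has several equivalent spellings when
an insertion end matches the adjacent deleted base (junction
micro-homology), planted edits are made canonical: the generator swaps
the first/last *deleted* reference base where needed
(`guard_junction`), touching only bases absent from every edited
haplotype. Breakpoint calls use leftmost placement, so canonical truth
and call coincide; on real data the reported representation would be the
leftmost-normalised one.

## Stage-specific choices

**Filters.** All six inequalities are strict, exactly as specified.
Absent MQRankSum/ReadPosRankSum pass their rules (the annotation is
undefined without heterozygous carriers, not bad); absent QD/FS/MQ or
non-numeric values are rejected with a distinct `MalformedAnnotation`
label. The cluster rule removes every SNP in any 10 bp inclusive window
(|p − q| ≤ 9) holding ≥ 3 SNPs; threshold and window are configurable
because the source wording ("more than 3 … all 3") is ambiguous. The
pipeline order is hard filters → cluster rule → call rate; the hard and
call-rate filters commute.

**Association.** The allelic 1-df Pearson chi-square on the 2×2 allele
table, no continuity correction, missing genotypes excluded — the
default case/control test of standard GWAS toolkits, matching a
Manhattan plot of unadjusted p-values. Monomorphic sites get statistic
0, p = 1 and a flag rather than an exception. The Bonferroni threshold
is reported at full precision; comparison against the printed 8.52 uses
two-decimal rounding.

**Depth ratio.** Depth counts mapped, non-clipped bases. Pools are
mean-normalised before the ratio (pool coverages need not match);
pseudocount 1.0 guards the zero depth of a del/del pool inside the
deletion. Smoothing is a 201 bp centred moving mean; segments need
|log2 ratio| ≥ 1 (two-fold) over ≥ 500 bp. None of these are reported
by the study; they are desk-scale defaults and all configurable.

**Insert sizes.** Discordant-long means apparent insert >
frag_mean + 5·frag_sd. A DELETION call needs the case pool's
discordant fraction to exceed the control's by 0.05 with ≥ 3 supporting
pairs; the net size estimate is median(discordant) − frag_mean, which
targets deletion length minus insertion length (7,628), not the
deletion length itself — the junction insertion is invisible to insert
sizes. Duplications are flagged from the mirrored discordant-short
contrast only.

**Breakpoints.** Soft clips ≥ 20 bp are clustered by (edge, side);
clusters need ≥ 2 reads. Each side's clips are stacked at their shared
edge and voted per column (majority count, ties by summed base quality,
then lexicographic). The two sides are registered by aligning each
side's extension against the reference at the *opposite* cluster edge
(≥ 90% identity over ≥ 8 bases, smallest shift wins) — the two clip
extensions themselves overlap only across the insertion, which may be
empty; a reference-free overlap merge is the fallback. Outer consensus
columns covered by fewer than min(3, support) reads are trimmed before
anchoring, because a single sequencing error in a one-read column would
otherwise break the exact-match flank extension. The final consensus is
padded with reference flanks at its column bounds and anchored by its
first/last 20 bases, which must match the reference uniquely inside the
search window; maximal inward extension determines the breakpoints, the
unanchored middle is the inserted sequence, and extension overlap
(micro-homology) is resolved leftmost. Failure to anchor uniquely is a
no-call (`BreakpointNoCall`), never a guess.

**Diagnostics.** In-silico PCR uses exact primer matching (the study
reports a clean diagnostic assay); a haplotype yields a product only for
exactly one forward and one reverse-complement site in order within
20 kb. Band classes are the two predicted lengths ± 50 bp. The plumage
rule engine encodes the enumerated combinations (males carrying the
dominant-white I allele are white; del/del females are LY; females with
a wildtype SOX10 allele, I/i and N/W are DR) and routes everything else
to `other` rather than interpolating — the source's F1 allele table
contains apparent typos (I/I where an F1 should be I/i), so only the
printed combinations are asserted.

**Pipeline.** One master seed derives per-stage seeds as
SeedSequence(master, stage_index) mod 2³¹ (stage 1000+i for sample i's
reads), so stages re-run in isolation reproduce the full run exactly.
Config is a flat YAML-loadable dataclass; CLI flags override config.

## Problem sizes in tests and acceptance

The statistical checks run at the following sizes, chosen to give the
stated tolerances comfortable sampling margins: filter-oracle
equivalence on 10,000 annotated variants; chi-square vs textbook formula
on 500 random tables (1e-10); type-I error on 10,000 null sites in the
39/40 cohort (band [0.04, 0.06], ~4.5 binomial s.d.); net deletion-size
estimator over 20 seeded runs of 10-sample 5X pools on a 60 kb region
(|mean − 7,628| ≤ 25 bp; the per-seed median has s.e. ≈ 11 bp); random
breakpoint recovery on 15 toy edits per error rate. The full 79-sample
5X default run over 200 kb completes in well under a minute.

## Known limitations

- The generator's clean-mapping idealisation (above) means pipeline
  performance on real BAMs depends on upstream aligner behaviour the
  tests do not model; the loaders accept standard SAM/VCF so real data
  can be substituted.
- `classify_sv` handles deletion vs duplication direction only; no
  inversions or translocations, and no split-read duplication typing.
- Exact primer matching only; primer mismatch tolerance, Tm and dimer
  thermodynamics are out of scope.
- The null-calibration check treats the chi-square approximation as
  adequate for MAF ≥ 0.2 at n = 158 alleles; rare-variant tests would
  need exact methods.
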