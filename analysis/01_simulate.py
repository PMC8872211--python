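"""Simulate the study: 39 deletion-homozygous light-yellow (LY) hens and
40 dark-red (DR) controls, 5X paired-end reads over a 200 kb region
carrying the 7638 bp deletion with its 10 bp junction insertion.

Writes the reference, the two haplotypes, the sample sheet and the
annotated SNP table under results/sim/.
"""

import numpy as np

from delscan import io as dio
from delscan.depth import pooled_depth

from common import load_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    data = load_study(args.seed)
    out = outdir("sim")

    dio.write_reference(data.ref, out / "reference.fa")
    dio.write_fasta(
        {"wt": data.wt_hap, "del": data.del_hap},
        out / "haplotypes.fa", offset=data.ref.offset,
    )
    dio.write_sample_sheet(data.samples, out / "samples.tsv")
    dio.write_vcf(
        data.variants, data.sample_ids, out / "variants.vcf",
        chrom_len=data.ref.end,
    )

    n_cases = sum(s.is_case for s in data.samples)
    n_het = sum(s.del_genotype == "wt/del" for s in data.samples)
    depth = pooled_depth(data.records, data.ref)
    mean_depth = float(np.mean(depth[1000:-1000])) / len(data.samples)
    print(f"cohort: {n_cases} LY del/del cases, "
          f"{len(data.samples) - n_cases} DR controls ({n_het} heterozygous)")
    print(f"region: {data.ref.name}:{data.ref.offset}-{data.ref.end} "
          f"({len(data.ref):,} bp), edit removes {data.edit.length} bp and "
          f"inserts {len(data.edit.inserted_seq)} bp")
    print(f"reads: {len(data.records) // 2:,} pairs, "
          f"mean per-sample depth {mean_depth:.2f}X")
    print(f"variants: {len(data.variants)} annotated SNPs -> {out}")


if __name__ == "__main__":
    main()
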