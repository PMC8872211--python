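"""Apply the SNP quality chain — six hard thresholds, the 3-SNPs-in-10-bp
cluster rule, and the 0.8 call-rate rule — and report what each rule
removed.  Writes the verdict table and the filtered VCF to results/filter/.
"""

from delscan import io as dio
from delscan.filters import run_filter_pipeline

from common import load_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    data = load_study(args.seed)
    out = outdir("filter")

    survivors, report = run_filter_pipeline(data.variants)
    dio.write_filter_report(report, out / "filter_report.tsv")
    dio.write_vcf(
        survivors, data.sample_ids, out / "variants.filtered.vcf",
        chrom_len=data.ref.end,
    )

    print(f"input variants: {report.n_input}")
    for rule, count in sorted(report.counts.items()):
        print(f"  {rule:<22s}{count}")
    print(f"after cluster + call-rate rules: {len(survivors)} variants "
          f"({len(survivors) / report.n_input:.1%} retained) -> {out}")


if __name__ == "__main__":
    main()
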