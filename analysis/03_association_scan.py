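"""Case-control allelic chi-square scan over the filtered SNPs with the
Bonferroni threshold, reporting the significant region around the
deletion.  Writes the association table and a Manhattan-style plot.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from delscan import io as dio
from delscan.association import bonferroni_threshold, scan, significant_regions
from delscan.filters import run_filter_pipeline

from common import load_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    data = load_study(args.seed)
    out = outdir("assoc")

    survivors, _ = run_filter_pipeline(data.variants)
    results = scan(survivors, data.samples)
    threshold = bonferroni_threshold(len(survivors))
    regions = significant_regions(results, threshold)
    dio.write_association_tsv(results, out / "assoc.tsv")

    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.scatter([r.pos / 1e6 for r in results],
               [r.neg_log10_p for r in results], s=8, c="steelblue")
    ax.axhline(threshold, color="firebrick", ls="--",
               label=f"Bonferroni {threshold:.2f}")
    ax.axvspan(data.edit.del_start / 1e6, data.edit.del_end / 1e6,
               color="gold", alpha=0.4, label="planted deletion")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "manhattan.png", dpi=150)

    print(f"tested {len(results)} SNPs; threshold -log10(0.05/n) = "
          f"{threshold:.3f}")
    for r in regions:
        print(f"significant region {r.chrom}:{r.start:,}-{r.end:,} "
              f"({r.n_snps} SNPs, peak {r.peak_neg_log10_p:.1f})")
    hit = any(
        r.start - 20_000 <= data.edit.del_start <= r.end + 20_000
        for r in regions
    )
    print("deletion lies within/adjacent to a significant region:" , hit)


if __name__ == "__main__":
    main()
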