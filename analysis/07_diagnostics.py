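"""In-silico diagnostic PCR across the deletion, genotype every bird from
its band sizes, test concordance with the recessive model (LY iff
del/del), and tabulate the three-locus plumage rule engine.
Writes the genotype table and rule table to results/diagnostics/.
"""

import pandas as pd

from delscan.diagnostics import (
    PlumageGenotype,
    genotype_from_products,
    predict_amplicons,
    predict_plumage,
    recessive_concordance,
)

from common import load_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    data = load_study(args.seed)
    out = outdir("diagnostics")

    amps = predict_amplicons(
        {"wt": data.wt_hap, "del": data.del_hap}, data.primers
    )
    wt_len, del_len = amps["wt"].length, amps["del"].length
    print(f"predicted products: wildtype {wt_len} bp, deletion {del_len} bp")

    rows = []
    genotypes = {}
    for s in data.samples:
        alleles = {"del" if f else "wt" for f in s.hap_is_del}
        lengths = [amps[a].length for a in alleles if amps[a]]
        gt = genotype_from_products(lengths, wt_len, del_len)
        genotypes[s.sample_id] = gt
        rows.append({"sample_id": s.sample_id, "phenotype": s.phenotype,
                     "bands": ",".join(str(x) for x in sorted(lengths)),
                     "genotype": gt})
    pd.DataFrame(rows).to_csv(out / "pcr_genotypes.tsv", sep="\t", index=False)

    conc = recessive_concordance(
        genotypes, {s.sample_id: s.phenotype for s in data.samples}
    )
    print(f"recessive-model concordance: {conc.concordance:.3f} "
          f"({conc.n_consistent}/{conc.n_samples}); violators: "
          f"{conc.violators or 'none'}")

    rule_rows = []
    for sox10 in ("wt/wt", "wt/del", "del/del"):
        for pmel in ("I/I", "I/i", "i/i"):
            for sex, slcs in (("male", ("S/S", "S/N", "N/N")),
                              ("female", ("S/W", "N/W"))):
                for slc in slcs:
                    g = PlumageGenotype(sox10, pmel, slc, sex)
                    rule_rows.append({"sox10": sox10, "pmel17": pmel,
                                      "slc45a2": slc, "sex": sex,
                                      "plumage": predict_plumage(g)})
    rules = pd.DataFrame(rule_rows)
    rules.to_csv(out / "plumage_rules.tsv", sep="\t", index=False)
    print("plumage rule table:",
          {k: int(v) for k, v in rules["plumage"].value_counts().items()})


if __name__ == "__main__":
    main()
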