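"""Contrast apparent insert sizes between the phenotype pools over the
candidate segment and classify the structural variant: junction-spanning
LY pairs show apparent inserts above 7 kb while DR wildtype pairs stay
inside the fragment distribution.  Writes histograms, the SV call and a
figure to results/inserts/.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from delscan import io as dio
from delscan.depth import call_candidate_segments, log_depth_ratio, pooled_depth
from delscan.inserts import classify_sv, extract_apparent_inserts

from common import load_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    data = load_study(args.seed)
    cfg = data.cfg
    out = outdir("inserts")

    case_pool = set(sorted(s.sample_id for s in data.samples if s.is_case)[: cfg.pool_size])
    ctrl_pool = set(sorted(s.sample_id for s in data.samples if not s.is_case)[: cfg.pool_size])
    ratio = log_depth_ratio(
        pooled_depth(data.records, data.ref, ctrl_pool),
        pooled_depth(data.records, data.ref, case_pool),
        cfg.pseudocount,
    )
    segments = call_candidate_segments(
        ratio, data.ref.offset, cfg.segment_threshold, cfg.segment_min_len,
        cfg.smooth_window,
    )
    seg = max(segments, key=lambda s: s.length)

    case_prof = extract_apparent_inserts(
        data.records, seg.start, seg.end, "LY", case_pool
    )
    ctrl_prof = extract_apparent_inserts(
        data.records, seg.start, seg.end, "DR", ctrl_pool
    )
    call = classify_sv(case_prof, ctrl_prof, cfg.frag_mean, cfg.frag_sd,
                       cfg.discordant_z)
    dio.write_insert_histogram(case_prof, out / "inserts_LY.tsv")
    dio.write_insert_histogram(ctrl_prof, out / "inserts_DR.tsv")
    dio.write_sv_call(call, out / "sv_call.json")

    fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
    for ax, prof, title in ((axes[0], ctrl_prof, "DR pool"),
                            (axes[1], case_prof, "LY pool")):
        ax.scatter(range(prof.n), sorted(prof.sizes), s=4)
        ax.set_title(title)
        ax.set_ylabel("apparent insert (bp)")
        ax.axhline(1000, color="grey", ls=":")
    fig.tight_layout()
    fig.savefig(out / "insert_sizes.png", dpi=150)

    print(f"candidate segment {seg.start:,}-{seg.end:,}")
    print(f"LY pool: {case_prof.n} pairs, median {case_prof.median:.0f}, "
          f"max {case_prof.max}")
    print(f"DR pool: {ctrl_prof.n} pairs, median {ctrl_prof.median:.0f}, "
          f"max {ctrl_prof.max}")
    print(f"call: {call.sv_type}, net size estimate "
          f"{call.net_size_estimate} bp from {call.support} discordant pairs")


if __name__ == "__main__":
    main()
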