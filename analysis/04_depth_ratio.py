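"""Pool ten birds per phenotype, compute per-base depth and the log2
depth ratio (DR over LY), and call candidate copy-number segments.
A deletion carried by all LY birds shows as a strongly positive ratio.
Writes the segment BED, the ratio track and a figure to results/depth/.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from delscan import io as dio
from delscan.depth import call_candidate_segments, log_depth_ratio, pooled_depth

from common import load_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    data = load_study(args.seed)
    cfg = data.cfg
    out = outdir("depth")

    case_pool = {s.sample_id for s in data.samples if s.is_case}
    ctrl_pool = {s.sample_id for s in data.samples if not s.is_case}
    case_pool = set(sorted(case_pool)[: cfg.pool_size])
    ctrl_pool = set(sorted(ctrl_pool)[: cfg.pool_size])
    d_ctrl = pooled_depth(data.records, data.ref, ctrl_pool)
    d_case = pooled_depth(data.records, data.ref, case_pool)
    ratio = log_depth_ratio(d_ctrl, d_case, cfg.pseudocount)
    segments = call_candidate_segments(
        ratio, data.ref.offset, cfg.segment_threshold, cfg.segment_min_len,
        cfg.smooth_window,
    )
    dio.write_bed(segments, data.ref.name, out / "segments.bed")
    # bedGraph of the smoothed track at 50 bp resolution keeps the file small
    coarse = ratio[: len(ratio) // 50 * 50].reshape(-1, 50).mean(axis=1)
    dio.write_bedgraph(
        np.round(coarse, 3), data.ref.name, data.ref.offset, out / "ratio.bedgraph"
    )

    x = (np.arange(len(ratio)) + data.ref.offset) / 1e6
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(x[::25], ratio[::25], lw=0.5, color="grey")
    ax.axvspan(data.edit.del_start / 1e6, data.edit.del_end / 1e6,
               color="gold", alpha=0.4, label="planted deletion")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("log2 depth ratio (DR/LY)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "depth_ratio.png", dpi=150)

    print(f"pools: {len(ctrl_pool)} DR vs {len(case_pool)} LY birds")
    for seg in segments:
        print(f"candidate segment {seg.start:,}-{seg.end:,} "
              f"({seg.length:,} bp, {seg.direction}, "
              f"mean log-ratio {seg.mean_log_ratio:.2f})")
    if segments:
        best = max(segments, key=lambda s: s.length)
        inter = min(best.end, data.edit.del_end - 1) - max(
            best.start, data.edit.del_start) + 1
        union = max(best.end, data.edit.del_end - 1) - min(
            best.start, data.edit.del_start) + 1
        print(f"Jaccard overlap with the planted deletion: {inter / union:.3f}")


if __name__ == "__main__":
    main()
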