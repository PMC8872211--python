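"""End-to-end orchestration: simulate -> filter -> associate -> depth ->
inserts -> breakpoints -> diagnostics, as one reproducible, seeded run.

A single master seed deterministically derives per-stage seeds
(``stage_seed``: SeedSequence over (master, stage index)), so any stage
can be re-run in isolation and two runs with the same configuration are
identical apart from the report timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .association import bonferroni_threshold, scan, significant_regions
from .breakpoints import resolve_deletion
from .cohort import plant_linked_snps, simulate_cohort
from .depth import call_candidate_segments, log_depth_ratio, pooled_depth
from .diagnostics import (
    DIAGNOSTIC_PRIMERS,
    PrimerPair,
    genotype_from_products,
    predict_amplicons,
    recessive_concordance,
)
from .filters import run_filter_pipeline
from .inserts import classify_sv, extract_apparent_inserts
from .reads import simulate_read_pairs
from .reference import (
    HaplotypeEdit,
    apply_edit,
    build_reference,
    guard_junction,
    identity_map,
    plant_sites,
)
from .variants import annotate_variants

log = logging.getLogger("delscan")

# printed coordinates of the study's diagnostic PCR region
PRIMER_FORWARD_START = 51_034_587
PRIMER_REGION_END = 51_043_419


@dataclass
class RunConfig:
    """Study-condition defaults: the cross's cohort, a 200 kb region
    anchored to the printed coordinates, the 7638 bp deletion with its
    10 bp junction insertion, and 5X paired 150 bp reads."""

    seed: int = 1
    out_dir: str = "runs/default"
    # region geometry
    region_name: str = "chr1"
    region_length: int = 200_000
    region_offset: int = 50_935_000
    gc: float = 0.42
    # causal edit
    del_start: int = 51_035_106
    del_end: int = 51_042_744
    inserted_seq: str = "GGTGCGGTGA"
    # cohort
    n_cases: int = 39
    n_controls: int = 40
    het_fraction_controls: float = 0.5
    # linked SNPs
    n_snps: int = 400
    r2_at_zero: float = 1.0
    decay_bp: float = 20_000.0
    missing_rate: float = 0.02
    annotation_fail_rate: float = 0.15
    # sequencing
    coverage: float = 5.0
    read_len: int = 150
    frag_mean: float = 500.0
    frag_sd: float = 50.0
    error_rate: float = 0.001
    # filters
    cluster_window: int = 10
    cluster_min_count: int = 3
    min_call_rate: float = 0.8
    # association
    alpha: float = 0.05
    merge_gap: int = 10_000
    # depth scan
    pool_size: int = 10
    pseudocount: float = 1.0
    smooth_window: int = 201
    segment_threshold: float = 1.0
    segment_min_len: int = 500
    # insert / breakpoint
    discordant_z: float = 5.0
    min_clip: int = 20
    min_support: int = 2
    # diagnostics
    primer_forward: str = DIAGNOSTIC_PRIMERS.forward
    primer_reverse: str = DIAGNOSTIC_PRIMERS.reverse
    write_reads: bool = False  # FASTQ/SAM output is bulky; off by default

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(master), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(cfg: RunConfig) -> list[str]:
    """All invariant violations in the configuration, empty iff valid."""
    v: list[str] = []
    if cfg.n_cases < 1:
        v.append("n_cases must be >= 1")
    if cfg.n_controls < 1:
        v.append("n_controls must be >= 1")
    if not 0 <= cfg.het_fraction_controls <= 1:
        v.append("het_fraction_controls must be in [0, 1]")
    if cfg.region_length < 1000:
        v.append("region_length must be >= 1000")
    if not 0 < cfg.gc < 1:
        v.append("gc must be in (0, 1)")
    if cfg.coverage <= 0:
        v.append("coverage must be > 0")
    if cfg.frag_mean < cfg.read_len:
        v.append("frag_mean must be >= read_len")
    if cfg.del_end < cfg.del_start:
        v.append("del_end must be >= del_start")
    region_end = cfg.region_offset + cfg.region_length - 1
    if not (cfg.region_offset <= cfg.del_start and cfg.del_end <= region_end):
        v.append("edit must lie inside the region")
    if cfg.n_snps < 1:
        v.append("n_snps must be >= 1")
    if not 0 <= cfg.r2_at_zero <= 1:
        v.append("r2_at_zero must be in [0, 1]")
    if not 0 < cfg.min_call_rate <= 1:
        v.append("min_call_rate must be in (0, 1]")
    if cfg.pool_size < 1:
        v.append("pool_size must be >= 1")
    if cfg.pool_size > min(cfg.n_cases, cfg.n_controls):
        v.append("pool_size cannot exceed the smaller cohort")
    if cfg.pseudocount <= 0:
        v.append("pseudocount must be > 0")
    return v


@dataclass
class StudyData:
    """Everything the seeded simulation produces, held in memory."""

    cfg: RunConfig
    ref: object  # ReferenceRegion
    edit: HaplotypeEdit
    primers: PrimerPair
    wt_hap: str
    del_hap: str
    wt_map: object
    del_map: object
    samples: list
    pairs: list
    records: list
    variants: list

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def simulate_study(cfg: RunConfig, keep_pairs: bool = True) -> StudyData:
    """Deterministically derive the whole synthetic study from cfg.seed.

    Reference with planted primer sites and a canonical (junction-
    guarded) edit, cohort, per-sample reads with projected truth
    alignments, and annotated SNPs in linkage with the deletion.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    edit = HaplotypeEdit(cfg.del_start, cfg.del_end, cfg.inserted_seq)
    primers = PrimerPair(cfg.primer_forward, cfg.primer_reverse)
    ref = build_reference(
        cfg.region_length, cfg.region_offset, cfg.gc, stage_seed(cfg.seed, 0),
        name=cfg.region_name,
    )
    from .reads import revcomp

    ref = plant_sites(
        ref,
        {
            PRIMER_FORWARD_START: primers.forward,
            PRIMER_REGION_END - len(primers.reverse) + 1: revcomp(primers.reverse),
        },
    )
    ref = guard_junction(ref, edit)
    wt_hap, wt_map = ref.sequence, identity_map(ref)
    del_hap, del_map = apply_edit(ref, edit)

    samples = simulate_cohort(
        cfg.n_cases, cfg.n_controls, cfg.het_fraction_controls,
        stage_seed(cfg.seed, 1),
    )
    haps = {False: (wt_hap, wt_map), True: (del_hap, del_map)}
    all_records: list = []
    all_pairs: list = []
    for i, s in enumerate(samples):
        h = (haps[s.hap_is_del[0]][0], haps[s.hap_is_del[1]][0])
        m = (haps[s.hap_is_del[0]][1], haps[s.hap_is_del[1]][1])
        pairs, recs = simulate_read_pairs(
            s, h, m,
            coverage=cfg.coverage, read_len=cfg.read_len,
            frag_mean=cfg.frag_mean, frag_sd=cfg.frag_sd,
            error_rate=cfg.error_rate, seed=stage_seed(cfg.seed, 1000 + i),
            ref_name=ref.name,
        )
        all_records.extend(recs)
        if keep_pairs:
            all_pairs.extend(pairs)

    truth_snps = plant_linked_snps(
        ref, edit, samples, cfg.n_snps, cfg.r2_at_zero, cfg.decay_bp,
        cfg.missing_rate, stage_seed(cfg.seed, 2),
    )
    variants = annotate_variants(
        truth_snps, fail_rate=cfg.annotation_fail_rate, seed=stage_seed(cfg.seed, 3)
    )
    return StudyData(
        cfg=cfg, ref=ref, edit=edit, primers=primers,
        wt_hap=wt_hap, del_hap=del_hap, wt_map=wt_map, del_map=del_map,
        samples=samples, pairs=all_pairs, records=all_records,
        variants=variants,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage, write outputs under cfg.out_dir, return report."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    # --- stage 0-1: reference, haplotypes, cohort, reads, variants -----
    log.info("stage simulate: building reference, cohort and reads")
    data = simulate_study(cfg, keep_pairs=cfg.write_reads)
    ref, edit, primers = data.ref, data.edit, data.primers
    wt_hap, del_hap = data.wt_hap, data.del_hap
    samples, all_records, variants = data.samples, data.records, data.variants
    dio.write_reference(ref, out / "reference.fa")
    dio.write_fasta(
        {"wt": wt_hap, "del": del_hap}, out / "haplotypes.fa", offset=ref.offset
    )
    dio.write_sample_sheet(samples, out / "samples.tsv")
    n_pairs = len(all_records) // 2
    log.info("stage simulate: %d samples, %d read pairs", len(samples), n_pairs)
    if cfg.write_reads:
        dio.write_fastq(data.pairs, out / "reads")
        dio.write_sam(all_records, ref, out / "alignments.sam")
    report["stages"]["simulate"] = {
        "n_samples": len(samples),
        "n_read_pairs": n_pairs,
    }

    # --- stage 2: variant filtering ------------------------------------
    sample_ids = [s.sample_id for s in samples]
    dio.write_vcf(variants, sample_ids, out / "variants.vcf", chrom_len=ref.end)
    survivors, filt_report = run_filter_pipeline(
        variants,
        window=cfg.cluster_window,
        min_count=cfg.cluster_min_count,
        min_rate=cfg.min_call_rate,
    )
    dio.write_vcf(survivors, sample_ids, out / "variants.filtered.vcf", chrom_len=ref.end)
    dio.write_filter_report(filt_report, out / "filter_report.tsv")
    log.info(
        "stage filter: %d of %d variants pass", len(survivors), len(variants)
    )
    report["stages"]["filter"] = {
        "n_input": filt_report.n_input,
        "n_hard_pass": filt_report.n_pass,
        "n_surviving": len(survivors),
        "counts": filt_report.counts,
    }

    # --- stage 3: association ------------------------------------------
    results = scan(survivors, samples)
    threshold = bonferroni_threshold(len(survivors), cfg.alpha)
    regions = significant_regions(results, threshold, cfg.merge_gap)
    dio.write_association_tsv(results, out / "assoc.tsv")
    log.info(
        "stage assoc: threshold %.3f, %d significant region(s)",
        threshold, len(regions),
    )
    report["stages"]["assoc"] = {
        "n_tested": len(results),
        "threshold_neg_log10": threshold,
        "regions": [
            {"start": r.start, "end": r.end, "n_snps": r.n_snps,
             "peak": r.peak_neg_log10_p}
            for r in regions
        ],
    }

    # --- stage 4: pooled depth ratio -----------------------------------
    case_pool = {s.sample_id for s in samples if s.is_case}
    ctrl_pool = {s.sample_id for s in samples if not s.is_case}
    case_pool = set(sorted(case_pool)[: cfg.pool_size])
    ctrl_pool = set(sorted(ctrl_pool)[: cfg.pool_size])
    depth_ctrl = pooled_depth(all_records, ref, ctrl_pool)  # group A: controls (DR)
    depth_case = pooled_depth(all_records, ref, case_pool)  # group B: cases (LY)
    ratio = log_depth_ratio(depth_ctrl, depth_case, cfg.pseudocount)
    segments = call_candidate_segments(
        ratio, ref.offset, cfg.segment_threshold, cfg.segment_min_len,
        cfg.smooth_window,
    )
    dio.write_bed(segments, ref.name, out / "depth_segments.bed")
    report["stages"]["depthscan"] = {
        "pool_sizes": [len(ctrl_pool), len(case_pool)],
        "segments": [
            {"start": s.start, "end": s.end, "mean_log_ratio": s.mean_log_ratio,
             "direction": s.direction}
            for s in segments
        ],
    }
    if not segments:
        raise RuntimeError("stage depthscan failed: no candidate segment found")
    candidate = max(segments, key=lambda s: s.length)
    log.info(
        "stage depthscan: candidate segment %d-%d (%s)",
        candidate.start, candidate.end, candidate.direction,
    )

    # --- stage 5: insert sizes -----------------------------------------
    case_profile = extract_apparent_inserts(
        all_records, candidate.start, candidate.end, "LY", case_pool
    )
    ctrl_profile = extract_apparent_inserts(
        all_records, candidate.start, candidate.end, "DR", ctrl_pool
    )
    sv_call = classify_sv(
        case_profile, ctrl_profile, cfg.frag_mean, cfg.frag_sd, cfg.discordant_z
    )
    dio.write_insert_histogram(case_profile, out / "inserts_LY.tsv")
    dio.write_insert_histogram(ctrl_profile, out / "inserts_DR.tsv")
    dio.write_sv_call(sv_call, out / "sv_call.json")
    log.info(
        "stage insertscan: %s net %d bp (support %d)",
        sv_call.sv_type, sv_call.net_size_estimate, sv_call.support,
    )
    report["stages"]["insertscan"] = {
        "type": sv_call.sv_type,
        "net_size_estimate": sv_call.net_size_estimate,
        "support": sv_call.support,
        "case_max_insert": case_profile.max,
        "control_max_insert": ctrl_profile.max,
    }

    # --- stage 6: breakpoints ------------------------------------------
    margin = int(4 * cfg.frag_mean)
    case_records = [r for r in all_records if r.sample_id in case_pool]
    bp_call = resolve_deletion(
        case_records, ref,
        max(ref.offset, candidate.start - margin),
        min(ref.end, candidate.end + margin),
        min_clip=cfg.min_clip, min_support=cfg.min_support,
    )
    dio.write_breakpoint_call(bp_call, out / "breakpoint.json")
    dio.write_breakpoint_vcf(bp_call, ref, out / "breakpoint.vcf")
    log.info(
        "stage breakpoint: del %d-%d (%d bp), insertion %r",
        bp_call.del_start, bp_call.del_end, bp_call.deletion_length,
        bp_call.inserted_seq,
    )
    report["stages"]["breakpoint"] = {
        "del_start": bp_call.del_start,
        "del_end": bp_call.del_end,
        "deletion_length": bp_call.deletion_length,
        "inserted_seq": bp_call.inserted_seq,
        "support": bp_call.support,
    }

    # --- stage 7: diagnostics ------------------------------------------
    amps = predict_amplicons({"wt": wt_hap, "del": del_hap}, primers)
    wt_len = amps["wt"].length if amps["wt"] else 0
    del_len = amps["del"].length if amps["del"] else 0
    genotypes = {}
    for s in samples:
        labels = {"wt", "del"} & {
            ("del" if flag else "wt") for flag in s.hap_is_del
        }
        lengths = [amps[lab].length for lab in labels if amps[lab]]
        genotypes[s.sample_id] = genotype_from_products(lengths, wt_len, del_len)
    phenos = {s.sample_id: s.phenotype for s in samples}
    conc = recessive_concordance(genotypes, phenos)
    report["stages"]["diagnostics"] = {
        "wt_product_bp": wt_len,
        "del_product_bp": del_len,
        "concordance": conc.concordance,
        "violators": conc.violators,
    }
    log.info(
        "stage diagnostics: products wt=%d bp del=%d bp, concordance %.3f",
        wt_len, del_len, conc.concordance if conc.concordance is not None else -1,
    )

    report["timestamp"] = datetime.datetime.now().isoformat()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
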