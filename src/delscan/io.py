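"""File-format round trips: FASTA, FASTQ, SAM, VCF and TSV tables.

Genome anchoring: a reference region written to FASTA carries its
offset in the description (``offset=<n>``), and SAM/VCF records use
genome coordinates directly (the SAM header length is the region end so
positions stay in range).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .breakpoints import BreakpointCall
from .cohort import SampleSpec
from .depth import CandidateSegment
from .filters import FilterReport
from .inserts import InsertProfile, SVCall
from .reads import AlignmentRecord, ReadPair
from .reference import ReferenceRegion
from .variants import ANNOTATIONS, VariantRecord


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | Path, offset: int = 1) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=f"offset={offset}")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_reference(region: ReferenceRegion, path: str | Path) -> None:
    write_fasta({region.name: region.sequence}, path, offset=region.offset)


def read_reference(path: str | Path) -> ReferenceRegion:
    rec = next(SeqIO.parse(str(path), "fasta"))
    offset = 1
    for token in rec.description.split():
        if token.startswith("offset="):
            offset = int(token.split("=", 1)[1])
    return ReferenceRegion(name=rec.id, offset=offset, sequence=str(rec.seq).upper())


# ---------------------------------------------------------------- FASTQ

def write_fastq(pairs: list[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write mate files ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``."""
    prefix = Path(prefix)
    paths = (
        prefix.with_name(prefix.name + "_R1.fastq"),
        prefix.with_name(prefix.name + "_R2.fastq"),
    )
    for path, mate in zip(paths, (1, 2)):
        records = []
        for p in pairs:
            seq = p.read1_seq if mate == 1 else p.read2_seq
            qual = p.read1_qual if mate == 1 else p.read2_qual
            rec = SeqRecord(Seq(seq), id=p.name, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")
    return paths


# ------------------------------------------------------------------ SAM

def _sam_header(region: ReferenceRegion, sample_ids: list[str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": region.name, "LN": region.end}],
        "RG": [{"ID": sid, "SM": sid} for sid in sample_ids],
    }


def write_sam(
    records: list[AlignmentRecord], region: ReferenceRegion, path: str | Path
) -> None:
    sample_ids = sorted({r.sample_id for r in records if r.sample_id})
    header = pysam.AlignmentHeader.from_dict(_sam_header(region, sample_ids))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.query_name
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            flag = 0x1  # paired
            flag |= 0x2 if rec.proper_pair else 0
            flag |= 0x4 if rec.is_unmapped else 0
            flag |= 0 if rec.mate_mapped else 0x8
            flag |= 0x10 if rec.is_reverse else 0
            flag |= 0x20 if rec.is_read1 else 0  # mate (read2) is reverse
            flag |= 0x40 if rec.is_read1 else 0x80
            a.flag = flag
            a.reference_id = 0 if not rec.is_unmapped else -1
            a.reference_start = rec.pos - 1 if rec.pos else -1
            if not rec.is_unmapped:
                cig = []
                if rec.left_clip:
                    cig.append((4, rec.left_clip))
                cig.append((0, rec.mapped_len))
                if rec.right_clip:
                    cig.append((4, rec.right_clip))
                a.cigartuples = cig
                a.mapping_quality = 60
            a.next_reference_id = 0 if rec.mate_mapped else -1
            a.next_reference_start = rec.mate_pos - 1 if rec.mate_pos else -1
            a.template_length = rec.apparent_insert
            if rec.sample_id:
                a.set_tag("RG", rec.sample_id)
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam.fetch(until_eof=True):
            left = right = 0
            mapped = 0
            if a.cigartuples:
                for i, (op, n) in enumerate(a.cigartuples):
                    if op == 4:
                        if i == 0:
                            left = n
                        else:
                            right = n
                    elif op == 0:
                        mapped = n
            out.append(
                AlignmentRecord(
                    query_name=a.query_name,
                    ref_name=a.reference_name or "",
                    pos=(a.reference_start + 1) if a.reference_start >= 0 else 0,
                    mapped_len=mapped,
                    left_clip=left,
                    right_clip=right,
                    is_reverse=a.is_reverse,
                    is_read1=a.is_read1,
                    mate_pos=(a.next_reference_start + 1)
                    if a.next_reference_start >= 0
                    else 0,
                    apparent_insert=a.template_length,
                    proper_pair=a.is_proper_pair,
                    mate_mapped=not a.mate_is_unmapped,
                    is_unmapped=a.is_unmapped,
                    seq=a.query_sequence or "",
                    qual="".join(chr(q + 33) for q in (a.query_qualities or [])),
                    sample_id=a.get_tag("RG") if a.has_tag("RG") else "",
                )
            )
    return out


# ------------------------------------------------------------------ VCF

def _vcf_header(chrom: str, chrom_len: int, sample_ids: list[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={chrom},length={chrom_len}>")
    for key in ANNOTATIONS:
        h.add_line(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="{key} annotation">'
        )
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in sample_ids:
        h.add_sample(sid)
    return h


def write_vcf(
    variants: list[VariantRecord],
    sample_ids: list[str],
    path: str | Path,
    chrom_len: int | None = None,
) -> None:
    if not variants:
        raise ValueError("no variants to write")
    chrom = variants[0].chrom
    length = chrom_len or max(v.pos for v in variants) + 1
    header = _vcf_header(chrom, length, sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref, v.alt),
                id=v.vid,
                qual=v.qual,
            )
            for key, val in v.info.items():
                rec.info[key] = float(val)
            for sid, gt in zip(sample_ids, v.genotypes):
                rec.samples[sid]["GT"] = gt if gt is not None else (None, None)
            out.write(rec)


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    variants: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf.fetch():
            if len(rec.alts or ()) != 1:
                raise ValueError(f"variant at {rec.pos} is not biallelic")
            info = {k: float(rec.info[k]) for k in ANNOTATIONS if k in rec.info}
            gts: list[tuple[int, int] | None] = []
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    gts.append(None)
                else:
                    gts.append((int(gt[0]), int(gt[1])))
            variants.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    qual=rec.qual if rec.qual is not None else 0.0,
                    info=info,
                    genotypes=gts,
                    vid=rec.id or "",
                )
            )
    return variants, sample_ids


def write_breakpoint_vcf(
    call: BreakpointCall, region: ReferenceRegion, path: str | Path
) -> None:
    """Symbolic-allele record for a resolved deletion (SVTYPE=DEL)."""
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={region.name},length={region.end}>")
    h.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    h.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    h.add_line(
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description='
        '"Non-templated junction insertion">'
    )
    h.add_line('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Read support">')
    with pysam.VariantFile(str(path), "w", header=h) as out:
        anchor = region.subseq(call.del_start - 1, call.del_start - 1)
        rec = out.new_record(
            contig=region.name,
            start=call.del_start - 2,  # base before the deletion, 0-based
            stop=call.del_end - 1,
            alleles=(anchor, "<DEL>"),
        )
        rec.info["SVTYPE"] = "DEL"
        rec.info["SVLEN"] = -call.deletion_length
        if call.inserted_seq:
            rec.info["INSSEQ"] = call.inserted_seq
        rec.info["SUPPORT"] = call.support
        out.write(rec)


# --------------------------------------------------------------- tables

def write_sample_sheet(samples: list[SampleSpec], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "phenotype": [s.phenotype for s in samples],
            "del_genotype": [s.del_genotype for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleSpec(r.sample_id, r.phenotype, r.del_genotype)
        for r in df.itertuples(index=False)
    ]


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    rows = sorted(report.counts.items())
    pd.DataFrame(rows, columns=["verdict", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_association_tsv(results, path: str | Path) -> None:
    """plink ``.assoc``-style columns: CHR SNP BP A1 F_A F_U A2 CHISQ P."""
    pd.DataFrame(
        {
            "CHR": [r.chrom for r in results],
            "SNP": [r.snp_id for r in results],
            "BP": [r.pos for r in results],
            "F_A": [r.case_alt_freq for r in results],
            "F_U": [r.control_alt_freq for r in results],
            "CHISQ": [r.chi_square for r in results],
            "P": [r.p_value for r in results],
            "NEG_LOG10_P": [r.neg_log10_p for r in results],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bed(segments: list[CandidateSegment], chrom: str, path: str | Path) -> None:
    """Segments as BED (0-based half-open on output)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{chrom}\t{seg.start - 1}\t{seg.end}\t{seg.direction}\t"
                f"{seg.mean_log_ratio:.4f}\n"
            )


def write_bedgraph(values, chrom: str, start: int, path: str | Path) -> None:
    """A per-base track as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                fh.write(
                    f"{chrom}\t{start - 1 + run_start}\t{start - 1 + i}\t"
                    f"{float(values[run_start]):.4f}\n"
                )
                run_start = i


def write_insert_histogram(profile: InsertProfile, path: str | Path) -> None:
    sizes = pd.Series(profile.sizes, name="count")
    tab = sizes.value_counts().sort_index()
    tab.rename_axis("insert_size").reset_index().to_csv(path, sep="\t", index=False)


def write_sv_call(call: SVCall, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "type": call.sv_type,
                "net_size_estimate": call.net_size_estimate,
                "support": call.support,
            },
            fh,
            indent=2,
        )


def write_breakpoint_call(call: BreakpointCall, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "del_start": call.del_start,
                "del_end": call.del_end,
                "inserted_seq": call.inserted_seq,
                "deletion_length": call.deletion_length,
                "support": call.support,
            },
            fh,
            indent=2,
        )
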