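"""Readers and writers for the pipeline's file formats.

Dialects:

* SNVs — VCF 4.2, sites-only, with INFO fields ``TNC`` (the 5'-ref-3'
  reference trinucleotide) and ``C96`` (96-context class index).
* SVs — BEDPE, 0-based half-open, ten standard columns followed by named
  extra columns (``discordant_pairs split_reads soft_clip normal_evidence
  region_coverage sv_type microhomology_len near_centromere near_telomere``);
  the header line starts with ``#``.
* CN segments — TSV with a header; ``start``/``end`` are 1-based inclusive
  in the file and converted to 0-based half-open internally.
* Reads — FASTQ (gzip-transparent on read).
* Genome build — TSV ``chrom length [cen_start cen_end]`` (1-based inclusive
  centromere interval in the file).

Everything downstream works on the 0-based half-open internal convention.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable, List, Optional

import pandas as pd
import pysam

from .errors import CoordinateError, FileFormatError, ValidationError
from .model import (
    HEAD,
    TAIL,
    Breakend,
    CNSegment,
    GenomeBuild,
    NUCLEOTIDES,
    SomaticSNV,
    SVCall,
)

log = logging.getLogger(__name__)

STRAND_TO_ORIENT = {"+": HEAD, "-": TAIL, "−": TAIL}
ORIENT_TO_STRAND = {HEAD: "+", TAIL: "-"}

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]
BEDPE_EXTRAS = [
    "discordant_pairs", "split_reads", "soft_clip",
    "normal_evidence", "region_coverage",
    "sv_type", "microhomology_len", "near_centromere", "near_telomere",
]

CN_COLUMNS = ["chrom", "start", "end", "total_cn", "major_allele_fraction",
              "mean_baf", "mean_logr", "state"]


# ---------------------------------------------------------------------------
# SNV VCF

def read_snv_vcf(path, genome: GenomeBuild) -> List[SomaticSNV]:
    """Read biallelic somatic SNVs from a VCF.

    Multiallelic records are split into one SNV per single-base ALT; non-SNV
    alleles (indels, symbolic) are skipped with a logged count.  A record on
    a chromosome absent from ``genome`` raises :class:`CoordinateError`.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise FileFormatError(f"cannot parse VCF {path}: {exc}") from exc
    snvs = []
    n_skipped = 0
    with vf:
        for rec in vf:
            if rec.chrom not in genome:
                raise CoordinateError(
                    f"VCF record {rec.chrom}:{rec.pos} on chromosome absent from genome build"
                )
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                    n_skipped += 1
                    continue
                def info_field(key):
                    # undeclared INFO keys make pysam raise rather than miss
                    try:
                        value = rec.info.get(key)
                    except (KeyError, ValueError):
                        return None
                    return value[0] if isinstance(value, tuple) else value

                tnc = info_field("TNC")
                c96 = info_field("C96")
                snvs.append(
                    SomaticSNV(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,  # VCF 1-based -> internal 0-based
                        ref_base=ref,
                        alt_base=alt,
                        context5=tnc[0] if tnc else None,
                        context3=tnc[2] if tnc else None,
                        class96=int(c96) if c96 is not None else None,
                    )
                )
    if n_skipped:
        log.info("read_snv_vcf: skipped %d non-SNV allele(s) in %s", n_skipped, path)
    return snvs


def write_snv_vcf(path, snvs: Iterable[SomaticSNV], genome: GenomeBuild):
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom in genome.chrom_names:
        header.contigs.add(chrom, length=genome.chrom_lengths[chrom])
    header.add_line('##INFO=<ID=TNC,Number=1,Type=String,Description="Reference trinucleotide context">')
    header.add_line('##INFO=<ID=C96,Number=1,Type=Integer,Description="96-context class index">')
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vf:
        for snv in sorted(snvs, key=lambda s: (genome.chrom_index(s.chrom), s.pos)):
            rec = vf.new_record(contig=snv.chrom, start=snv.pos, stop=snv.pos + 1,
                                alleles=(snv.ref_base, snv.alt_base))
            if snv.context5 is not None and snv.context3 is not None:
                rec.info["TNC"] = snv.context5 + snv.ref_base + snv.context3
            if snv.class96 is not None:
                rec.info["C96"] = snv.class96
            vf.write(rec)


# ---------------------------------------------------------------------------
# SV BEDPE

def _parse_flag(value):
    return str(value) in ("1", "True", "true")


def read_sv_bedpe(path, genome: GenomeBuild) -> List[SVCall]:
    """Read SV calls from a BEDPE with named extra columns.

    Strands are mapped '+' -> head, '-' -> tail; breakends are canonicalized
    to genome order.  Missing evidence columns default to 0 with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas raises various types
        raise FileFormatError(f"cannot parse BEDPE {path}: {exc}") from exc
    df.columns = [c.lstrip("#") for c in df.columns]
    missing_std = [c for c in BEDPE_COLUMNS if c not in df.columns]
    if missing_std:
        raise FileFormatError(f"BEDPE {path} missing standard columns {missing_std}")
    for col in ("discordant_pairs", "split_reads", "soft_clip", "normal_evidence", "region_coverage"):
        if col not in df.columns:
            log.warning("read_sv_bedpe: column %s absent in %s, defaulting to 0", col, path)
            df[col] = "0"
    svs = []
    for idx, row in df.iterrows():
        for chrom_col in ("chrom1", "chrom2"):
            if row[chrom_col] not in genome:
                raise CoordinateError(
                    f"BEDPE row {idx}: chromosome {row[chrom_col]!r} absent from genome build"
                )
        for strand_col in ("strand1", "strand2"):
            if row[strand_col] not in STRAND_TO_ORIENT:
                raise FileFormatError(
                    f"BEDPE row {idx}: strand {row[strand_col]!r} not in {{+,-}}"
                )
        bnd1 = Breakend(row["chrom1"], int(row["start1"]), STRAND_TO_ORIENT[row["strand1"]])
        bnd2 = Breakend(row["chrom2"], int(row["start2"]), STRAND_TO_ORIENT[row["strand2"]])
        sv = SVCall(
            bnd1=bnd1,
            bnd2=bnd2,
            evidence={
                "discordant_pairs": int(row["discordant_pairs"]),
                "split_reads": int(row["split_reads"]),
                "soft_clip": int(row["soft_clip"]),
            },
            normal_evidence=int(row["normal_evidence"]),
            region_coverage=float(row["region_coverage"]),
            sv_type=(row["sv_type"] or None) if "sv_type" in df.columns and row.get("sv_type", ".") != "." else None,
            microhomology_len=(int(row["microhomology_len"])
                               if "microhomology_len" in df.columns and row["microhomology_len"] not in (".", "")
                               else None),
            near_centromere=_parse_flag(row["near_centromere"]) if "near_centromere" in df.columns else False,
            near_telomere=_parse_flag(row["near_telomere"]) if "near_telomere" in df.columns else False,
            name=row["name"],
        )
        svs.append(sv.canonicalized(genome))
    return svs


def write_sv_bedpe(path, svs: Iterable[SVCall]):
    rows = []
    for sv in svs:
        rows.append({
            "chrom1": sv.bnd1.chrom, "start1": sv.bnd1.pos, "end1": sv.bnd1.pos + 1,
            "chrom2": sv.bnd2.chrom, "start2": sv.bnd2.pos, "end2": sv.bnd2.pos + 1,
            "name": sv.name, "score": ".",
            "strand1": ORIENT_TO_STRAND[sv.bnd1.orient],
            "strand2": ORIENT_TO_STRAND[sv.bnd2.orient],
            "discordant_pairs": sv.evidence.get("discordant_pairs", 0),
            "split_reads": sv.evidence.get("split_reads", 0),
            "soft_clip": sv.evidence.get("soft_clip", 0),
            "normal_evidence": sv.normal_evidence,
            "region_coverage": sv.region_coverage,
            "sv_type": sv.sv_type if sv.sv_type is not None else ".",
            "microhomology_len": sv.microhomology_len if sv.microhomology_len is not None else ".",
            "near_centromere": int(sv.near_centromere),
            "near_telomere": int(sv.near_telomere),
        })
    df = pd.DataFrame(rows, columns=BEDPE_COLUMNS + BEDPE_EXTRAS)
    df = df.rename(columns={"chrom1": "#chrom1"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CN segment TSV

def read_cn_segments(path, genome: GenomeBuild) -> dict:
    """Read allele-specific CN segments from a TSV (1-based inclusive).

    Returns ``{chrom: [CNSegment]}`` sorted by start; overlapping segments on
    one chromosome raise :class:`ValidationError` naming both rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise FileFormatError(f"cannot parse CN TSV {path}: {exc}") from exc
    for col in ("chrom", "start", "end", "total_cn"):
        if col not in df.columns:
            raise FileFormatError(f"CN TSV {path} missing column {col!r}")
    per_chrom = {}
    row_of = {}
    for idx, row in df.iterrows():
        chrom = row["chrom"]
        if chrom not in genome:
            raise CoordinateError(f"CN row {idx}: chromosome {chrom!r} absent from genome build")
        total_cn = int(row["total_cn"])
        if total_cn < 0:
            raise ValidationError(f"CN row {idx}: negative total_cn")

        def opt_float(col):
            v = row.get(col, "")
            return float(v) if col in df.columns and v not in ("", ".") else None

        seg = CNSegment(
            chrom=chrom,
            start=int(row["start"]) - 1,   # 1-based inclusive -> half-open
            end=int(row["end"]),
            total_cn=total_cn,
            major_allele_fraction=opt_float("major_allele_fraction"),
            mean_baf=opt_float("mean_baf"),
            mean_logr=opt_float("mean_logr"),
            state=(row["state"] or None) if "state" in df.columns and row.get("state", ".") not in (".", "") else None,
        )
        per_chrom.setdefault(chrom, []).append(seg)
        row_of[id(seg)] = idx
    for chrom, segs in per_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"CN segments overlap: rows {row_of[id(a)]} and {row_of[id(b)]} "
                    f"({chrom}:{a.start + 1}-{a.end} vs {chrom}:{b.start + 1}-{b.end})"
                )
    return per_chrom


def write_cn_segments(path, per_chrom: dict, genome: Optional[GenomeBuild] = None):
    order = (genome.chrom_names if genome is not None else sorted(per_chrom))
    rows = []
    for chrom in order:
        for seg in per_chrom.get(chrom, []):
            rows.append({
                "chrom": seg.chrom,
                "start": seg.start + 1,  # half-open -> 1-based inclusive
                "end": seg.end,
                "total_cn": seg.total_cn,
                "major_allele_fraction": seg.major_allele_fraction if seg.major_allele_fraction is not None else ".",
                "mean_baf": seg.mean_baf if seg.mean_baf is not None else ".",
                "mean_logr": seg.mean_logr if seg.mean_logr is not None else ".",
                "state": seg.state if seg.state is not None else ".",
            })
    pd.DataFrame(rows, columns=CN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq_sequences(path):
    """Yield read sequences from a FASTQ (plain or gzipped)."""
    with pysam.FastxFile(os.fspath(path)) as fh:
        for entry in fh:
            yield entry.sequence


def write_fastq(path, reads, name_prefix="read"):
    """Write an iterable of sequences as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{name_prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Genome build table and truth labels

def read_genome_table(path) -> GenomeBuild:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    if "chrom" not in df.columns or "length" not in df.columns:
        raise FileFormatError(f"genome table {path} needs 'chrom' and 'length' columns")
    names = tuple(df["chrom"])
    lengths = {r["chrom"]: int(r["length"]) for _, r in df.iterrows()}
    cen = {}
    if "cen_start" in df.columns and "cen_end" in df.columns:
        for _, r in df.iterrows():
            if r["cen_start"] not in ("", ".") and r["cen_end"] not in ("", "."):
                cen[r["chrom"]] = (int(r["cen_start"]) - 1, int(r["cen_end"]))
    return GenomeBuild(names, lengths, cen or None)


def write_genome_table(path, genome: GenomeBuild):
    rows = []
    for chrom in genome.chrom_names:
        cen = (genome.centromeres or {}).get(chrom)
        rows.append({
            "chrom": chrom,
            "length": genome.chrom_lengths[chrom],
            "cen_start": cen[0] + 1 if cen else ".",
            "cen_end": cen[1] if cen else ".",
        })
    pd.DataFrame(rows, columns=["chrom", "length", "cen_start", "cen_end"]).to_csv(
        path, sep="\t", index=False)


def write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
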