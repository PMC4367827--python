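"""Readers/writers for FASTA, FASTQ, SAM, BED and GFF3.

All coordinates are 0-based half-open internally; GFF3 converts at the
boundary (1-based closed on disk, phase column preserved).  Sequences are
uppercased on input with a warning when mixed case is seen.  SAM support is
the subset needed for the Alignment contract (header, strand FLAG, CIGAR
M/I/D, NM tag) so an external mapper can stand in for the internal one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .mapping import Alignment
from .simulate import ReadSet


def _upper(seq: str, name: str, path) -> str:
    if not seq.isupper():
        warnings.warn(f"{path}: lowercase bases in {name!r} uppercased")
        seq = seq.upper()
    return seq


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = _upper(str(rec.seq), rec.id, path)
    return out


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> ReadSet:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.description.split()[0] if rec.description else rec.id)
        seqs.append(_upper(str(rec.seq), rec.id, path))
    read_len = len(seqs[0]) if seqs else 0
    paired = any(i.endswith("/1") for i in ids[:2])
    return ReadSet(ids=ids, seqs=seqs, read_len=read_len, paired=paired)


def write_fastq(path, reads: ReadSet) -> None:
    # constant 'I' placeholder qualities; no quality-aware logic downstream
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# SAM

_OP2CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CODE2OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def write_sam(path, alignments: list[Alignment], ref_lengths: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": L} for n, L in ref_lengths.items()],
    }
    names = list(ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = aln.read_id
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_id = names.index(aln.ref_id)
            seg.reference_start = aln.ref_start
            seg.mapping_quality = aln.mapq
            seg.cigartuples = [(_OP2CODE[op], n) for op, n in aln.cigar]
            seg.query_sequence = aln.seq
            seg.set_tag("NM", aln.nm)
            fh.write(seg)


def read_sam(path) -> tuple[list[Alignment], dict[str, int]]:
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        ref_lengths = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            if seg.is_unmapped:
                continue
            cigar = [(_CODE2OP[c], n) for c, n in seg.cigartuples if c in _CODE2OP]
            alignments.append(
                Alignment(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    ref_start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=cigar,
                    mapq=seg.mapping_quality,
                    nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    seq=seg.query_sequence or "",
                )
            )
    return alignments, ref_lengths


# ---------------------------------------------------------------------------
# BED

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: len(df.columns)] + [
        f"extra{i}" for i in range(max(0, len(df.columns) - 6))
    ]
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffRecord:
    """One GFF3 feature, 0-based half-open; ``phase`` is None or 0/1/2."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: int | None
    attrs: dict[str, str] = field(default_factory=dict)


def read_gff3(path) -> list[GffRecord]:
    out: list[GffRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 record: expected 9 columns"
                )
            try:
                f = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record: {exc}")
            out.append(
                GffRecord(
                    seqid=f.seqid,
                    source=f.source,
                    type=f.featuretype,
                    start=f.start - 1,
                    end=f.end,
                    score=f.score,
                    strand=f.strand,
                    phase=None if f.frame in (".", None) else int(f.frame),
                    attrs={k: v[0] if isinstance(v, list) else v for k, v in f.attributes.items()},
                )
            )
    return out


def write_gff3(path, records: list[GffRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(f"{k}={v}" for k, v in r.attrs.items()) or "."
            phase = "." if r.phase is None else str(r.phase)
            fh.write(
                f"{r.seqid}\t{r.source}\t{r.type}\t{r.start + 1}\t{r.end}\t"
                f"{r.score}\t{r.strand}\t{phase}\t{attrs}\n"
            )


def truth_to_gff3(truth, seqid: str = "ref") -> list[GffRecord]:
    """Planted gene structure as GFF3 records (CDS rows carry phase)."""
    type_map = {
        "gene": "gene",
        "exon": "CDS",
        "intron": "intron",
        "utr5": "five_prime_UTR",
        "utr3": "three_prime_UTR",
    }
    out: list[GffRecord] = []
    for f in truth.features:
        if f.type not in type_map:
            continue
        phase = f.attrs.get("phase") if f.type == "exon" else None
        out.append(
            GffRecord(
                seqid=seqid,
                source="bactrokit",
                type=type_map[f.type],
                start=f.start,
                end=f.end,
                score=".",
                strand="+",
                phase=phase,
                attrs={"ID": f"{f.name}.{f.type}.{f.start}", "Parent": f.name},
            )
        )
    return out
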