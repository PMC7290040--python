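"""Readers and writers for the standard formats the toolkit touches.

All internal coordinates are 0-based half-open; conversions to and from the
1-based conventions of GTF and SAM happen only here, at the format boundary.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A malformed input file."""


@dataclass(frozen=True)
class CircRecord:
    """One circRNA as a genomic interval.

    ``start`` is the 0-based acceptor-side boundary, ``end`` the 0-based
    exclusive donor-side boundary; the back-splice junction joins end-1
    back to start.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    circ_id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid circRNA interval [{self.start}, {self.end}) for {self.circ_id!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.circ_id:
            object.__setattr__(
                self, "circ_id", f"{self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start


class GenomeSequence(dict):
    """Mapping of chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    def add(self, name: str, seq: str, strict: bool = True) -> None:
        if not name:
            raise FormatError("empty sequence name")
        if name in self:
            raise FormatError(f"duplicate sequence name {name!r}")
        seq = seq.upper()
        bad = set(seq) - VALID_ALPHABET
        if bad:
            if strict:
                raise FormatError(
                    f"sequence {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            seq = re.sub(f"[^{''.join(sorted(VALID_ALPHABET))}]", "N", seq)
        self[name] = seq


@dataclass(frozen=True)
class Exon:
    gene_id: str
    transcript_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class AnnotationSet:
    """Genes and exons, with introns derived per transcript.

    Introns are exactly the gaps between consecutive sorted exons of one
    transcript; a single-exon transcript has none.
    """

    genes: list[Gene] = field(default_factory=list)
    exons: list[Exon] = field(default_factory=list)

    def transcripts(self) -> dict[str, list[Exon]]:
        by_tx: dict[str, list[Exon]] = {}
        for ex in self.exons:
            by_tx.setdefault(ex.transcript_id, []).append(ex)
        for tx_id, exs in by_tx.items():
            exs.sort(key=lambda e: e.start)
            for a, b in zip(exs, exs[1:]):
                if b.start < a.end:
                    raise FormatError(
                        f"overlapping exons in transcript {tx_id!r}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
        return by_tx

    def introns(self) -> list[Exon]:
        """Per-transcript gaps between consecutive exons, as Exon-shaped spans."""
        out = []
        for tx_id, exs in self.transcripts().items():
            for a, b in zip(exs, exs[1:]):
                if b.start > a.end:
                    out.append(
                        Exon(a.gene_id, tx_id, a.chrom, a.end, b.start, a.strand)
                    )
        return out


@dataclass(frozen=True)
class AlignedSegment:
    """One read alignment: reference span in 0-based half-open coordinates."""

    read_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    is_mapped: bool = True

    def __post_init__(self):
        if self.is_mapped:
            if not self.ref_name:
                raise ValueError("mapped segment with empty reference name")
            if not self.ref_start < self.ref_end:
                raise ValueError(
                    f"mapped segment with empty span [{self.ref_start}, {self.ref_end})"
                )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[CircRecord]:
    """Read a BED3+ file of circRNAs.

    BED is natively 0-based half-open, so coordinates pass through unchanged.
    A missing name column synthesizes ``chrom:start-end``; a missing strand
    column yields ``.``. Duplicate explicit ids are an error.
    """
    records: list[CircRecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from e
            if not 0 <= start < end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            rec = CircRecord(chrom, start, end, strand, name)
            if rec.circ_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate id {rec.circ_id!r}")
            seen_ids.add(rec.circ_id)
            records.append(rec)
    return records


def write_bed(records: Iterable[CircRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, strict: bool = True) -> GenomeSequence:
    """Read a FASTA file; names are the header token before the first space."""
    genome = GenomeSequence()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(rec.id, str(rec.seq), strict=strict)
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF3

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF_ATTR = re.compile(r"(\w+)=([^;]*)")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    if "=" in attr_field and '"' not in attr_field:
        return dict(_GFF_ATTR.findall(attr_field))
    return dict(_GTF_ATTR.findall(attr_field))


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read gene/exon features from GTF (attribute pairs) or GFF3 (Parent=).

    GTF/GFF 1-based inclusive spans become 0-based half-open internally.
    Only gene and exon features are consumed; for GFF3 exons the Parent
    attribute supplies the transcript id (gene id falls back to the
    transcript id when absent).
    """
    genes: list[Gene] = []
    exons: list[Exon] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attr_field = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from e
            attrs = _parse_attributes(attr_field)
            if feature == "gene":
                gene_id = attrs.get("gene_id") or attrs.get("ID")
                if not gene_id:
                    raise FormatError(f"{path}:{lineno}: gene without gene_id/ID")
                genes.append(Gene(gene_id, chrom, strand, start, end))
            else:
                tx_id = attrs.get("transcript_id") or attrs.get("Parent")
                if not tx_id:
                    raise FormatError(
                        f"{path}:{lineno}: exon without transcript_id/Parent"
                    )
                gene_id = attrs.get("gene_id") or tx_id
                exons.append(Exon(gene_id, tx_id, chrom, start, end, strand))
    annot = AnnotationSet(genes, exons)
    annot.transcripts()  # validates exon sorting/overlap per transcript
    return annot


def write_gtf(annot: AnnotationSet, path: str | Path) -> None:
    """Write genes and exons back out as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in annot.genes:
            fh.write(
                f"{g.chrom}\tcirckit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
        for e in annot.exons:
            fh.write(
                f"{e.chrom}\tcirckit\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                f'gene_id "{e.gene_id}"; transcript_id "{e.transcript_id}";\n'
            )


# ---------------------------------------------------------------------------
# SAM


def read_sam(path: str | Path) -> list[AlignedSegment]:
    """Read a SAM file into AlignedSegments via pysam.

    The reference span is POS-1 plus the reference-consuming CIGAR length
    (M/D/N/=/X); insertions and clips never extend it. Unmapped records
    (flag 0x4) come back with ``is_mapped=False`` and no span.
    """
    segments: list[AlignedSegment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                segments.append(
                    AlignedSegment(aln.query_name, "", -1, -1, is_mapped=False)
                )
                continue
            if aln.cigartuples is None:
                raise FormatError(
                    f"{path}: mapped record {aln.query_name!r} with CIGAR '*'"
                )
            segments.append(
                AlignedSegment(
                    aln.query_name,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                )
            )
    return segments


def cigar_reference_length(cigar: str) -> int:
    """Reference-consumed length of a CIGAR string (sum of M/D/N/=/X runs)."""
    if cigar == "*":
        raise FormatError("CIGAR '*' has no reference length")
    total = 0
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        if op in "MDN=X":
            total += int(n)
    return total


def write_csv(rows: Iterable[dict], path: str | Path, columns: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row[c] for c in columns})
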