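"""Self-consistent synthetic fixtures: genome, annotation, circRNAs of every
junction category, and Ribo-seq alignments with planted truth.

The generator emulates the inputs of the translation-evidence pipeline at
desk scale: a small random genome with multi-exon genes and intergenic
space, an extra rRNA contig excluded from the annotation, circRNAs
engineered so each of the seven junction categories is realized, and three
SAM files (reads vs rRNA, vs linear genome, vs doubled junction
references). Translated circRNAs are planted with enough surviving
junction-spanning reads to clear the calling threshold; decoys either fall
short of it or have their junction reads removed by the rRNA/linear
subtraction filter. Identical configurations produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .classify import CATEGORIES
from .io_formats import (
    AlignedSegment,
    AnnotationSet,
    CircRecord,
    Exon,
    Gene,
    GenomeSequence,
    write_bed,
    write_fasta,
    write_gtf,
)
from .junction_ref import JunctionRef, build_junction_ref, write_junction_fasta
from .stemloop import reverse_complement

RRNA_CHROM = "rRNA"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10000
    n_genes: int = 2  # per chromosome
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 200
    intergenic_gap: int = 1500
    n_circ_per_category: int = 5
    read_length: int = 30  # ribosome-protected fragments are ~30 nt
    min_overhang: int = 5
    n_junction_reads_per_translated: int = 5
    n_decoy_reads: int = 50  # pure rRNA reads, and again pure linear reads
    planted_stem_repeat_length: int = 20
    rrna_length: int = 2000

    def gene_length(self) -> int:
        return (
            self.exons_per_gene * self.exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeSequence
    annotation: AnnotationSet
    circs: list[CircRecord]
    truth: pd.DataFrame  # circ_id, label, translated, stem_planted
    read_ids: list[str]
    rrna_aln: list[AlignedSegment]
    linear_aln: list[AlignedSegment]
    junction_aln: list[AlignedSegment]
    junction_refs: list[JunctionRef] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_genome_annotation(
    cfg: SimConfig,
) -> tuple[GenomeSequence, AnnotationSet, pd.DataFrame]:
    """Random genome plus gene models, and a truth table of every interval.

    Genes with ``exons_per_gene`` exons are laid out left to right with
    intergenic gaps; the rRNA contig carries no annotation.
    """
    rng = np.random.default_rng(cfg.seed)
    needed = cfg.intergenic_gap + cfg.n_genes * (cfg.gene_length() + cfg.intergenic_gap)
    if needed > cfg.chrom_length:
        raise ValueError(
            f"genes do not fit: need {needed} nt per chromosome, have {cfg.chrom_length}"
        )
    genome = GenomeSequence()
    genes: list[Gene] = []
    exons: list[Exon] = []
    truth_rows = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        genome.add(chrom, _random_seq(rng, cfg.chrom_length))
        pos = cfg.intergenic_gap
        prev_end = 0
        for gi in range(cfg.n_genes):
            gene_id = f"gene_{chrom}_{gi}"
            tx_id = f"tx_{chrom}_{gi}"
            strand = "+" if (gi % 2 == 0) else "-"
            truth_rows.append((chrom, prev_end, pos, "intergenic", "", "", -1))
            gstart = pos
            for ei in range(cfg.exons_per_gene):
                estart = pos
                eend = estart + cfg.exon_length
                exons.append(Exon(gene_id, tx_id, chrom, estart, eend, strand))
                truth_rows.append((chrom, estart, eend, "exon", gene_id, tx_id, ei))
                pos = eend
                if ei < cfg.exons_per_gene - 1:
                    truth_rows.append(
                        (chrom, pos, pos + cfg.intron_length, "intron", gene_id, tx_id, ei)
                    )
                    pos += cfg.intron_length
            genes.append(Gene(gene_id, chrom, strand, gstart, pos))
            prev_end = pos
            pos += cfg.intergenic_gap
        truth_rows.append((chrom, prev_end, cfg.chrom_length, "intergenic", "", "", -1))
    genome.add(RRNA_CHROM, _random_seq(rng, cfg.rrna_length))
    annot = AnnotationSet(genes, exons)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "kind", "gene_id", "transcript_id", "index"],
    )
    # generator self-checks: every annotated interval lies inside its chromosome
    assert (truth["end"] <= cfg.chrom_length).all() and (truth["start"] >= 0).all()
    return genome, annot, truth


def _plant_stem_repeat(
    genome: GenomeSequence, circ: CircRecord, k: int, rng: np.random.Generator
) -> None:
    """Write a reverse-complement repeat of length k into the two flanks,
    30 nt away from each boundary, so the flanks can pair into a stem.

    Each motif copy is padded with N barriers: N never scores as a match,
    so the optimal local alignment between the flanks is exactly the
    planted repeat rather than a chance extension through its neighborhood.
    """
    motif = _random_seq(rng, k)
    pad = "N" * 6
    up_block = pad + motif + pad
    down_block = pad + reverse_complement(motif) + pad
    seq = genome[circ.chrom]
    up_start = circ.start - 30 - len(up_block)
    down_start = circ.end + 30
    if up_start < 0 or down_start + len(down_block) > len(seq):
        raise ValueError(f"{circ.circ_id}: no room to plant stem repeat")
    # upstream carries the motif; downstream carries its reverse complement,
    # so revcomp(upstream flank) realigns to the downstream flank exactly.
    genome[circ.chrom] = (
        seq[:up_start]
        + up_block
        + seq[up_start + len(up_block) : down_start]
        + down_block
        + seq[down_start + len(down_block) :]
    )


def simulate_circrnas(
    cfg: SimConfig,
    genome: GenomeSequence,
    annot: AnnotationSet,
    truth_intervals: pd.DataFrame,
) -> tuple[list[CircRecord], pd.DataFrame]:
    """circRNAs of every category, with truth labels and planted stem repeats.

    The first intergenic circRNA gets a reverse-complement repeat planted
    in its flanks (its flanks sit in empty intergenic space, so the plant
    cannot collide with any other engineered feature). Coordinates are
    engineered from the interval truth table so ``classify_all`` must
    recover the labels exactly.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    by_tx = annot.transcripts()
    tx_ids = sorted(by_tx)
    if cfg.exons_per_gene < 2:
        raise ValueError("category different_exon impossible: need >= 2 exons per gene")
    gaps = truth_intervals.query("kind == 'intergenic' and end - start >= 400")
    if gaps.empty:
        raise ValueError("category intergenic impossible: no intergenic gap >= 400 nt")
    circs: list[CircRecord] = []
    truth_rows = []
    min_len = 2 * cfg.read_length  # keep every circle longer than a read
    for n in range(cfg.n_circ_per_category):
        tx_id = tx_ids[n % len(tx_ids)]
        exs = by_tx[tx_id]
        gene = next(g for g in annot.genes if g.gene_id == exs[0].gene_id)
        chrom = exs[0].chrom
        e0, e1 = exs[0], exs[1]
        i0_start, i0_end = e0.end, e1.start  # first intron
        jitter = int(rng.integers(0, 20))
        coords = {
            "same_exon": (e0.start + 5 + jitter, e0.start + 5 + jitter + max(min_len, 100)),
            "different_exon": (e0.start + 10 + jitter, e1.end - 10 - jitter),
            "intron_exon": (i0_start + 10 + jitter, e1.end - 10 - jitter),
            "intron": (i0_start + 10 + jitter, i0_end - 10 - jitter),
            "intron_intergenic": (i0_start + 10 + jitter, gene.end + 60 + jitter),
            "exon_intergenic": (e0.start + 10 + jitter, gene.end + 60 + jitter),
        }
        gap = gaps.iloc[n % len(gaps)]
        gap_mid = int(gap.start) + (int(gap.end) - int(gap.start)) // 2
        coords["intergenic"] = (
            gap_mid - 60 - jitter,
            gap_mid + 60 + jitter,
        )
        for label in CATEGORIES:
            start, end = coords[label]
            if end - start < min_len:
                raise ValueError(f"category {label} impossible under this geometry")
            circ = CircRecord(
                chrom, start, end, "+" if n % 2 == 0 else "-", f"circ_{label}_{n}"
            )
            circs.append(circ)
            plant = n == 0 and label == "intergenic"
            if plant:
                _plant_stem_repeat(genome, circ, cfg.planted_stem_repeat_length, rng)
            truth_rows.append(
                {"circ_id": circ.circ_id, "label": label, "stem_planted": plant}
            )
    truth = pd.DataFrame(truth_rows)
    return circs, truth


def simulate_ribo_reads(
    cfg: SimConfig,
    circs: list[CircRecord],
    truth: pd.DataFrame,
    genome: GenomeSequence,
) -> tuple[list[str], list[AlignedSegment], list[AlignedSegment], list[AlignedSegment], set[str], list[JunctionRef]]:
    """Reads and their three alignment sets, with a planted translated truth.

    Alternating circRNAs are designated translated and receive
    ``n_junction_reads_per_translated`` surviving junction-spanning
    alignments. Decoys alternate between two flavors: 2 surviving spanning
    reads (below threshold) and >= 3 spanning reads that the subtraction
    filter removes because they also map to rRNA or the linear genome.
    Background reads map only to rRNA or only to the linear genome.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    refs = [build_junction_ref(c, genome) for c in circs]
    ref_by_id = {r.circ_id: r for r in refs}
    L_read, ovh = cfg.read_length, cfg.min_overhang
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"read_{counter:05d}"

    read_ids: list[str] = []
    rrna_aln: list[AlignedSegment] = []
    linear_aln: list[AlignedSegment] = []
    junction_aln: list[AlignedSegment] = []
    translated_truth: set[str] = set()

    def spanning_start(L: int) -> int:
        lo, hi = L + ovh - L_read, L - ovh
        return int(rng.integers(lo, hi + 1))

    for idx, circ in enumerate(circs):
        ref = ref_by_id[circ.circ_id]
        L = ref.junction_offset
        if idx % 2 == 0:
            translated_truth.add(circ.circ_id)
            for _ in range(cfg.n_junction_reads_per_translated):
                rid = next_id()
                read_ids.append(rid)
                s = spanning_start(L)
                junction_aln.append(AlignedSegment(rid, circ.circ_id, s, s + L_read))
            # one extra surviving read that does NOT span (no overhang) —
            # must not change the call
            rid = next_id()
            read_ids.append(rid)
            junction_aln.append(AlignedSegment(rid, circ.circ_id, 2, 2 + L_read))
            # surviving reads show up unmapped in the subtraction SAMs
            for rid2 in read_ids[-(cfg.n_junction_reads_per_translated + 1):]:
                rrna_aln.append(AlignedSegment(rid2, "", -1, -1, is_mapped=False))
                linear_aln.append(AlignedSegment(rid2, "", -1, -1, is_mapped=False))
        elif idx % 4 == 1:
            # decoy A: only 2 surviving spanning reads
            for _ in range(2):
                rid = next_id()
                read_ids.append(rid)
                s = spanning_start(L)
                junction_aln.append(AlignedSegment(rid, circ.circ_id, s, s + L_read))
        else:
            # decoy B: plenty of spanning reads, all filtered out upstream
            for k in range(max(3, cfg.n_junction_reads_per_translated)):
                rid = next_id()
                read_ids.append(rid)
                s = spanning_start(L)
                junction_aln.append(AlignedSegment(rid, circ.circ_id, s, s + L_read))
                pos = int(rng.integers(0, cfg.rrna_length - L_read))
                if k % 2 == 0:
                    rrna_aln.append(AlignedSegment(rid, RRNA_CHROM, pos, pos + L_read))
                else:
                    linear_aln.append(AlignedSegment(rid, "chr1", pos, pos + L_read))

    for _ in range(cfg.n_decoy_reads):  # pure rRNA contamination
        rid = next_id()
        read_ids.append(rid)
        pos = int(rng.integers(0, cfg.rrna_length - L_read))
        rrna_aln.append(AlignedSegment(rid, RRNA_CHROM, pos, pos + L_read))
    for _ in range(cfg.n_decoy_reads):  # pure linear-transcript reads
        rid = next_id()
        read_ids.append(rid)
        pos = int(rng.integers(0, cfg.chrom_length - L_read))
        linear_aln.append(AlignedSegment(rid, "chr1", pos, pos + L_read))

    # generator postcondition: planted translated circRNAs really do have
    # enough surviving spanning alignments
    for seg in junction_aln:
        ref = ref_by_id[seg.ref_name]
        assert 0 <= seg.ref_start and seg.ref_end <= len(ref.sequence)
    return read_ids, rrna_aln, linear_aln, junction_aln, translated_truth, refs


def simulate_all(cfg: SimConfig) -> SimResult:
    genome, annot, intervals = simulate_genome_annotation(cfg)
    circs, circ_truth = simulate_circrnas(cfg, genome, annot, intervals)
    read_ids, rrna_aln, linear_aln, junction_aln, translated, refs = simulate_ribo_reads(
        cfg, circs, circ_truth, genome
    )
    truth = circ_truth.assign(
        translated=circ_truth["circ_id"].isin(translated)
    )
    return SimResult(
        config=cfg,
        genome=genome,
        annotation=annot,
        circs=circs,
        truth=truth,
        read_ids=read_ids,
        rrna_aln=rrna_aln,
        linear_aln=linear_aln,
        junction_aln=junction_aln,
        junction_refs=refs,
    )


def _write_sam(
    path: Path,
    segments: list[AlignedSegment],
    ref_lengths: dict[str, int],
    genome_like: dict[str, str],
    read_length: int,
) -> None:
    """Write alignments as SAM with pure-match CIGARs and real sequences."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = seg.read_id
            if seg.is_mapped:
                a.reference_name = seg.ref_name
                a.reference_start = seg.ref_start
                a.cigarstring = f"{seg.ref_end - seg.ref_start}M"
                a.query_sequence = genome_like[seg.ref_name][seg.ref_start : seg.ref_end]
                a.mapping_quality = 60
                a.flag = 0
            else:
                a.flag = 4
                a.query_sequence = "N" * read_length
            out.write(a)


def write_fixture_tree(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set to disk; returns the path of each file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = {name: out / fname for name, fname in [
        ("genome", "genome.fa"), ("gtf", "annotation.gtf"), ("bed", "circ.bed"),
        ("reads", "reads.ids"), ("rrna_sam", "rrna.sam"),
        ("linear_sam", "linear.sam"), ("junction_sam", "junction.sam"),
        ("junction_fasta", "junction_ref.fa"), ("truth", "truth.csv"),
    ]}
    write_fasta(result.genome, paths["genome"])
    write_gtf(result.annotation, paths["gtf"])
    write_bed(result.circs, paths["bed"])
    paths["reads"].write_text("".join(rid + "\n" for rid in result.read_ids))
    genome_lengths = {name: len(seq) for name, seq in result.genome.items()}
    _write_sam(paths["rrna_sam"], result.rrna_aln,
               {RRNA_CHROM: genome_lengths[RRNA_CHROM]}, result.genome, cfg.read_length)
    _write_sam(paths["linear_sam"], result.linear_aln,
               {n: l for n, l in genome_lengths.items() if n != RRNA_CHROM},
               result.genome, cfg.read_length)
    doubled = {r.circ_id: r.sequence for r in result.junction_refs}
    _write_sam(paths["junction_sam"], result.junction_aln,
               {r.circ_id: len(r.sequence) for r in result.junction_refs},
               doubled, cfg.read_length)
    write_junction_fasta(result.junction_refs, paths["junction_fasta"])
    result.truth.to_csv(paths["truth"], index=False)
    return paths
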