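"""Doubled pseudo-circular reference construction.

A linear aligner cannot place a read across the back-splice junction of a
circRNA, because the junction sequence does not exist in the genome. The
standard trick is to copy the full circRNA sequence and concatenate it to
itself: the doubled sequence contains every circular substring of length
<= L, and the junction lies exactly between positions L-1 and L.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from .io_formats import CircRecord, GenomeSequence, write_fasta
from .stemloop import reverse_complement

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JunctionRef:
    """A circRNA sequence doubled end-to-end.

    ``junction_offset`` equals the circRNA length L: the back-splice
    junction of the simulated circle sits between indices L-1 and L of the
    doubled sequence.
    """

    circ_id: str
    sequence: str
    junction_offset: int
    source: CircRecord

    def __post_init__(self):
        L = self.junction_offset
        if len(self.sequence) != 2 * L or self.sequence[:L] != self.sequence[L:]:
            raise ValueError(f"{self.circ_id}: sequence is not an exact doubling")


def extract_circ_sequence(circ: CircRecord, genome: GenomeSequence) -> str:
    """Genomic substring of the circRNA, 5'->3' on the transcribed strand.

    Minus-strand circRNAs are reverse-complemented because Ribo-seq reads
    derive from the RNA molecule, not the genome's plus strand.
    """
    if circ.chrom not in genome:
        raise KeyError(f"{circ.circ_id}: chromosome {circ.chrom!r} not in genome")
    chrom_seq = genome[circ.chrom]
    if circ.end > len(chrom_seq):
        raise ValueError(
            f"{circ.circ_id}: interval [{circ.start}, {circ.end}) exceeds "
            f"{circ.chrom} length {len(chrom_seq)}"
        )
    seq = chrom_seq[circ.start : circ.end]
    if circ.strand == "-":
        seq = reverse_complement(seq)
    return seq


def build_junction_ref(circ: CircRecord, genome: GenomeSequence) -> JunctionRef:
    """Double the circRNA sequence; the junction offset is the circle length."""
    seq = extract_circ_sequence(circ, genome)
    return JunctionRef(circ.circ_id, seq + seq, len(seq), circ)


def circular_window(circ_seq: str, start: int, width: int) -> str:
    """Wraparound substring of a circle, for cross-checking doubled windows."""
    L = len(circ_seq)
    return "".join(circ_seq[(start + i) % L] for i in range(width))


def write_junction_fasta(refs: list[JunctionRef], path: str | Path) -> None:
    """Write doubled references as FASTA, one record per circRNA.

    Whitespace in ids would split the FASTA header token, so it is replaced
    with underscores (logged).
    """
    if not refs:
        raise ValueError("no junction references to write")
    out: dict[str, str] = {}
    for ref in refs:
        safe_id = re.sub(r"\s+", "_", ref.circ_id)
        if safe_id != ref.circ_id:
            log.warning("sanitized id %r -> %r for FASTA header", ref.circ_id, safe_id)
        if safe_id in out:
            raise ValueError(f"duplicate junction reference id {safe_id!r}")
        out[safe_id] = ref.sequence
    write_fasta(out, path)
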