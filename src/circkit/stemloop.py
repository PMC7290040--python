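"""Flanking stem-loop detection by local alignment.

Reverse-complementary repeats in the sequences flanking a circRNA can base
pair into a stem, bringing the splice sites together and promoting
circularization. For each circRNA we extract an upstream and a downstream
flank, reverse-complement the upstream one, and locally align it against
the downstream flank (Smith-Waterman with affine gaps). A strong hit means
the two flanks can form a stem with the circle as the loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .io_formats import CircRecord, GenomeSequence, write_csv

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; other characters are an error."""
    if set(seq) - set("ACGTN"):
        raise ValueError(f"non-ACGTN characters in sequence: {set(seq) - set('ACGTN')}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like defaults; a length-k gap costs gap_open + k * gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class StemLoopHit:
    """Best local alignment between revcomp(upstream flank) and downstream flank.

    Spans are 0-based half-open within the two aligned strings as fed to the
    aligner (the upstream one already reverse-complemented). Aligned strings
    are gapped with '-' and have equal length; identity is matched columns
    over aligned columns. A score of 0 means no positive-scoring local
    alignment exists and all other fields are empty.
    """

    score: int = 0
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0
    aligned_a: str = ""
    aligned_b: str = ""

    @property
    def identity(self) -> float:
        cols = len(self.aligned_a)
        if cols == 0:
            return 0.0
        matches = sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x not in "-N"
        )
        return matches / cols


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> StemLoopHit:
    """Affine-gap Smith-Waterman returning one maximal local alignment.

    Ties on the maximal score are broken by the smaller end position in
    ``a``, then in ``b``. 'N' never scores as a match.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return StemLoopHit()
    NEG = float("-inf")
    go, ge = scheme.gap_open, scheme.gap_extend
    # H: best local score ending at (i, j); E ends with a gap in b (consumes
    # a[i]); F ends with a gap in a (consumes b[j]). 1-based on sequences.
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + go + ge, E[i - 1][j] + ge)
            F[i][j] = max(H[i][j - 1] + go + ge, F[i][j - 1] + ge)
            s = (
                scheme.match
                if ai == b[j - 1] and ai != "N"
                else scheme.mismatch
            )
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, best_i, best_j = h, i, j
    if best == 0:
        return StemLoopHit()

    # Traceback from the best H cell, tracking which matrix we are in.
    i, j, state = best_i, best_j, "H"
    aligned_a: list[str] = []
    aligned_b: list[str] = []
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            s = (
                scheme.match
                if a[i - 1] == b[j - 1] and a[i - 1] != "N"
                else scheme.mismatch
            )
            if h == H[i - 1][j - 1] + s:
                aligned_a.append(a[i - 1])
                aligned_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aligned_a.append(a[i - 1])
            aligned_b.append("-")
            came_from_h = E[i][j] == H[i - 1][j] + go + ge
            i -= 1
            if came_from_h:
                state = "H"
        else:  # F
            aligned_a.append("-")
            aligned_b.append(b[j - 1])
            came_from_h = F[i][j] == H[i][j - 1] + go + ge
            j -= 1
            if came_from_h:
                state = "H"
    return StemLoopHit(
        score=best,
        a_start=i,
        a_end=best_i,
        b_start=j,
        b_end=best_j,
        aligned_a="".join(reversed(aligned_a)),
        aligned_b="".join(reversed(aligned_b)),
    )


def extract_flanks(
    circ: CircRecord, genome: GenomeSequence, flank: int
) -> tuple[str, str]:
    """Genomic plus-strand flanks: ``flank`` nt upstream of start and
    downstream of end, truncated at chromosome boundaries."""
    if flank < 1:
        raise ValueError("flank length must be >= 1")
    chrom_seq = genome[circ.chrom]
    up = chrom_seq[max(0, circ.start - flank) : circ.start]
    down = chrom_seq[circ.end : circ.end + flank]
    if len(up) < flank or len(down) < flank:
        log.info(
            "%s: flanks truncated at chromosome edge (up=%d, down=%d)",
            circ.circ_id,
            len(up),
            len(down),
        )
    return up, down


def stem_ring_hit(
    circ: CircRecord,
    genome: GenomeSequence,
    flank: int = 200,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> StemLoopHit:
    """Align revcomp(upstream flank) against the downstream flank."""
    up, down = extract_flanks(circ, genome, flank)
    return smith_waterman(reverse_complement(up), down, scheme)


def stem_ring_scan(
    circs: list[CircRecord],
    genome: GenomeSequence,
    flank: int = 200,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    out_path: str | Path | None = None,
) -> list[dict]:
    """One best hit per circRNA, in input order; optionally written as CSV.

    Upstream alignment coordinates are reported within the
    reverse-complemented upstream flank, matching the aligned strings.
    """
    rows = []
    for circ in circs:
        hit = stem_ring_hit(circ, genome, flank, scheme)
        rows.append(
            {
                "circ_id": circ.circ_id,
                "chrom": circ.chrom,
                "start": circ.start,
                "end": circ.end,
                "strand": circ.strand,
                "up_aln_start": hit.a_start,
                "up_aln_end": hit.a_end,
                "down_aln_start": hit.b_start,
                "down_aln_end": hit.b_end,
                "score": hit.score,
                "identity": round(hit.identity, 6),
                "aligned_up": hit.aligned_a,
                "aligned_down": hit.aligned_b,
            }
        )
    if out_path is not None:
        write_csv(rows, out_path, list(rows[0].keys()) if rows else STEM_COLUMNS)
    return rows


STEM_COLUMNS = [
    "circ_id",
    "chrom",
    "start",
    "end",
    "strand",
    "up_aln_start",
    "up_aln_end",
    "down_aln_start",
    "down_aln_end",
    "score",
    "identity",
    "aligned_up",
    "aligned_down",
]
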