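"""Seven-way junction-position classification of circRNAs.

Each back-splice junction end falls in an exon, an intron, or intergenic
space; the ordered pair of contexts assigns one of seven categories:
same_exon, different_exon, intron_exon, intron, intron_intergenic,
exon_intergenic, intergenic. Context lookup ignores annotation strand
(the categories are purely positional); classification is total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AnnotationSet, CircRecord, write_csv

log = logging.getLogger(__name__)

CATEGORIES = (
    "same_exon",
    "different_exon",
    "intron_exon",
    "intron",
    "intron_intergenic",
    "exon_intergenic",
    "intergenic",
)

# Figure-legend aliases seen in the wild for the same seven labels.
CATEGORY_ALIASES = {
    "same_exon": "same_exon_circ",
    "different_exon": "diff_exon_circ",
    "intron_exon": "exon_intron_circ",
    "intron": "intron_circ",
    "intron_intergenic": "interg_intron_circ",
    "exon_intergenic": "interg_exon_circ",
    "intergenic": "interg_circ",
}


@dataclass(frozen=True)
class BoundaryContext:
    position: int
    context: str  # exon | intron | intergenic
    gene_id: str | None = None
    transcript_id: str | None = None
    exon_index: int | None = None


class AnnotationIndex:
    """Interval trees over exons and gene spans for fast context lookup."""

    def __init__(self, annot: AnnotationSet):
        self.exon_trees: dict[str, IntervalTree] = {}
        self.gene_trees: dict[str, IntervalTree] = {}
        by_tx = annot.transcripts()
        tx_n_exons = {tx: len(exs) for tx, exs in by_tx.items()}
        for tx_id, exs in by_tx.items():
            for idx, ex in enumerate(exs):
                tree = self.exon_trees.setdefault(ex.chrom, IntervalTree())
                tree[ex.start : ex.end] = (
                    ex.gene_id,
                    tx_id,
                    idx,
                    tx_n_exons[tx_id],
                )
        for g in annot.genes:
            tree = self.gene_trees.setdefault(g.chrom, IntervalTree())
            tree[g.start : g.end] = g.gene_id

    def locate(self, pos: int, chrom: str) -> BoundaryContext:
        """Exon wins over intron; among exon hits the transcript with most
        exons, then lexicographic transcript_id, breaks ties. An unknown
        chromosome is intergenic."""
        if chrom not in self.gene_trees and chrom not in self.exon_trees:
            log.debug("chromosome %r not annotated; %d treated as intergenic", chrom, pos)
            return BoundaryContext(pos, "intergenic")
        exon_hits = sorted(
            self.exon_trees.get(chrom, IntervalTree())[pos],
            key=lambda iv: (-iv.data[3], iv.data[1]),
        )
        if exon_hits:
            gene_id, tx_id, idx, _ = exon_hits[0].data
            return BoundaryContext(pos, "exon", gene_id, tx_id, idx)
        gene_hits = sorted(
            self.gene_trees.get(chrom, IntervalTree())[pos], key=lambda iv: iv.data
        )
        if gene_hits:
            return BoundaryContext(pos, "intron", gene_hits[0].data)
        return BoundaryContext(pos, "intergenic")


def locate_boundary(pos: int, chrom: str, annot: AnnotationSet | AnnotationIndex) -> BoundaryContext:
    index = annot if isinstance(annot, AnnotationIndex) else AnnotationIndex(annot)
    return index.locate(pos, chrom)


def classify_circ(
    circ: CircRecord, annot: AnnotationSet | AnnotationIndex
) -> tuple[str, BoundaryContext, BoundaryContext]:
    """Category of one circRNA from the contexts of its two junction ends.

    The two boundary positions are the first and last base inside the
    circle (start and end-1), so both lookups are inside the interval.
    The pair is unordered: which end is exonic does not change the label.
    """
    index = annot if isinstance(annot, AnnotationIndex) else AnnotationIndex(annot)
    left = index.locate(circ.start, circ.chrom)
    right = index.locate(circ.end - 1, circ.chrom)
    pair = frozenset((left.context, right.context))
    if pair == {"exon"}:
        same = (
            left.transcript_id == right.transcript_id
            and left.exon_index == right.exon_index
        )
        label = "same_exon" if same else "different_exon"
    elif pair == {"exon", "intron"}:
        label = "intron_exon"
    elif pair == {"intron"}:
        label = "intron"
    elif pair == {"intron", "intergenic"}:
        label = "intron_intergenic"
    elif pair == {"exon", "intergenic"}:
        label = "exon_intergenic"
    else:
        label = "intergenic"
    return label, left, right


def classify_all(
    circs: list[CircRecord],
    annot: AnnotationSet | AnnotationIndex,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """One row per circRNA; totality holds by construction."""
    index = annot if isinstance(annot, AnnotationIndex) else AnnotationIndex(annot)
    rows = []
    for circ in circs:
        label, left, right = classify_circ(circ, index)
        rows.append(
            {
                "circ_id": circ.circ_id,
                "label": label,
                "chrom": circ.chrom,
                "start": circ.start,
                "end": circ.end,
                "strand": circ.strand,
                "length": circ.length(),
                "gene_id_start": left.gene_id or "",
                "gene_id_end": right.gene_id or "",
            }
        )
    columns = [
        "circ_id", "label", "chrom", "start", "end", "strand", "length",
        "gene_id_start", "gene_id_end",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if out_path is not None:
        write_csv(rows, out_path, columns)
    return df


def classification_density(
    table: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_bins: int = 100,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Counts of circRNA midpoints per equal-width bin, chromosome and label.

    Bins are half-open-right, so a midpoint on an internal edge falls in the
    bin to its right; total counts equal the number of circRNAs.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    missing = set(table["chrom"]) - set(chrom_lengths)
    if missing:
        raise KeyError(f"chromosomes missing from chrom_lengths: {sorted(missing)}")
    rows = []
    for chrom, chrom_df in table.groupby("chrom", sort=True):
        edges = np.linspace(0, chrom_lengths[chrom], n_bins + 1)
        mids = (chrom_df["start"].to_numpy() + chrom_df["end"].to_numpy()) // 2
        idx = np.clip(np.searchsorted(edges, mids, side="right") - 1, 0, n_bins - 1)
        for (b, label), count in (
            pd.DataFrame({"bin": idx, "label": chrom_df["label"].to_numpy()})
            .value_counts(["bin", "label"])
            .sort_index()
            .items()
        ):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": int(edges[b]),
                    "bin_end": int(edges[b + 1]),
                    "label": label,
                    "count": int(count),
                }
            )
    columns = ["chrom", "bin_start", "bin_end", "label", "count"]
    df = pd.DataFrame(rows, columns=columns)
    if out_path is not None:
        write_csv(rows, out_path, columns)
    return df
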