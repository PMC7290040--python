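# Methods

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)`. BED is native
to this convention; GTF/GFF (1-based inclusive) and SAM (1-based POS) are
converted at the format boundary and nowhere else. Histogram bins, genome
windows, and density bins are uniformly half-open-right, so a value exactly
on an internal edge belongs to the bin on its right. A circRNA's two
junction positions are the first and last base *inside* the circle
(`start` and `end − 1`); both lookups therefore land inside the interval and
are stable under the half-open convention.

## Doubled pseudo-circular references

The back-splice junction sequence is absent from the genome, so each
circRNA sequence *S* is concatenated to itself. The doubled string `S·S`
contains every circular substring of length ≤ |S|, and the junction lies
between indices |S|−1 and |S| (`junction_offset = |S|`). Minus-strand
circRNAs are reverse-complemented before doubling because Ribo-seq reads
derive from the transcribed RNA, not the genome's plus strand. The doubled
reference is the contiguous *genomic* interval: for multi-exon circRNAs the
introns are **not** spliced out. This is a documented limitation — junction
reads of a spliced exonic circRNA whose BSJ-proximal sequence differs from
the genomic interval may be missed. A read aligning more than once to one
doubled reference (guaranteed for circles shorter than the read) is counted
once per distinct read id, never per alignment record.

## Translation calling

1. **Subtraction filter.** Every read with *any* mapped alignment record
   (primary, secondary, or supplementary) in the rRNA SAM or the linear SAM
   is removed; only never-mapped reads survive. When a read maps to both,
   the removal is attributed to rRNA. The module is aligner-agnostic: it
   consumes SAM files, whatever produced them, and accepts any combination
   of linear references (genome, transcriptome, or both) — their union is
   subtracted.
2. **Junction spanning.** An alignment spans the junction iff
   `ref_start ≤ L − h` and `ref_end ≥ L + h` with min-overhang `h = 5` nt by
   default. The overhang guards against 1-nt-overlap alignment noise on
   ~30 nt reads while remaining permissive; it is a flag on every entry
   point.
3. **Call.** `translated ⟺ junction_reads ≥ 3` (configurable). The mapping
   table is sorted by junction reads descending, ties broken by id.

## Classification

Context lookup uses interval trees over exons and gene spans. Exon wins
over intron when transcripts disagree; among overlapping exon hits the
transcript with the most exons, then the lexicographically smallest
transcript id, is chosen — the convention of exon-centric circRNA
classifiers, where a junction at an annotated exon boundary is an exonic
back-splice. `same_exon` requires the same transcript *and* the same exon
ordinal; two exonic ends in different genes are `different_exon` (the
categories are feature-typed, not gene-typed; both gene ids are carried in
the output for scrutiny). Annotation strand is ignored for context lookup
— the categories are positional — and circRNA strand is passed through.
Unknown chromosomes classify as intergenic (logged). Density tables count
one midpoint per circRNA so totals conserve exactly; `n_bins` equal-width
bins per chromosome.

The seven labels also circulate under figure-style aliases
(`interg_exon_circ` for `exon_intergenic`, etc.); the mapping lives in
`classify.CATEGORY_ALIASES`.

## Splice signals

Reported as `upstream/downstream` 2-mers on the transcribed strand: for a
plus-strand circRNA these are `genome[start−2:start]` and
`genome[end:end+2]`; for minus-strand the two plus-strand flanks are
reverse-complemented and swapped. Pair order and strand handling are a fixed
package convention (documented rather than inferred — reported signal sets
in the literature do not state theirs). Flanks that run off a chromosome end
are padded with `N`. GC windows use a non-N denominator; an all-N window is
undefined (NaN), not zero, so assembly gaps are not painted AT-rich.

## Stem-loop search

Flanks of 200 nt (default) are taken in genomic plus-strand orientation on
both sides; the upstream flank is reverse-complemented and locally aligned
against the downstream flank with a hand-written affine-gap Smith–Waterman
(Gotoh recurrences, full traceback). The strand choice is immaterial here:
the revcomp-vs-direct comparison is symmetric under strand for this
purpose. Scheme defaults are BLASTN-like (match +2, mismatch −3, gap open
−5, gap extend −2); a length-*k* gap costs `open + k·extend`, and `N` never
scores as a match. Ties on the optimal score are broken toward the smaller
end position in the first sequence, then the second, giving a deterministic
single best hit per circRNA (no sub-optimal hits — one CSV row each). No
score threshold is imposed; raw scores and identities are reported and
thresholding is left to the user. The kernel is validated against an
exhaustive alignment-path enumeration oracle on short pairs and against
Bio.Align.PairwiseAligner scores on longer ones; flank-scale problems
(200×200) take ~10 ms in pure Python, which is the intended scale.

## Simulator

`simulate` emulates the study conditions end to end, at desk scale:

| parameter | default | rationale |
| --- | --- | --- |
| chromosomes × length | 2 × 10 kb | smallest geometry hosting all categories |
| genes per chromosome | 2 (3 exons × 300 nt, introns 200 nt, gaps 1500 nt) | every context realizable with room for flanks |
| circRNAs per category | 5 (35 total) | every label exercised repeatedly |
| read length | 30 nt | ribosome-protected fragment regime (< 50 nt) |
| junction reads per translated circRNA | 5 | comfortably above the 3-read threshold |
| decoy reads | 50 rRNA + 50 linear | exercises the subtraction filter |
| stem repeat | 20 nt | well above chance local-alignment scores |

Alternating circRNAs are planted translated; decoys alternate between "2
surviving junction reads" (below threshold) and "≥ 3 junction reads that
also map to rRNA or the linear genome" (removed by the filter). CIGARs are
pure-match so span arithmetic is transparent (the CIGAR parser is exercised
separately with I/D/N/S operations). The rRNA reference is one extra contig
excluded from the annotation. The planted stem repeat is padded with `N`
barriers so the optimal local alignment is exactly the planted repeat — `N`
cannot score a match, so chance extensions through the repeat's random
neighborhood are suppressed and exact-identity recovery is well-defined.
Everything derives from one integer seed; identical configurations produce
byte-identical files.

What the simulator does *not* emulate — and hence what green tests do not
show about real data: sequencing errors and quality scores, rolling-circle
multi-copy reads, spliced circRNA isoforms, soft-clipped or indel-containing
junction alignments from real aligners, ribosome dwell-time structure, and
realistic genome composition (repeats, GC heterogeneity). Recovery rates of
1.0 on these fixtures validate the bookkeeping, not performance on noisy
libraries.

## Visualization

Plot correctness is asserted on the data layers (circular coverage, codon
positions, density and signal tables), never on pixels. Circular coverage
projects doubled-reference alignments modulo L (an alignment covers circular
position p when it covers p or p + L), clipping alignment length at L so
mass is conserved. Codon marks scan the doubled string at starts < L, which
natively captures wraparound ATG/TAA/TAG/TGA codons. The mapping plot
anchors the junction at angle 0 and proceeds clockwise 5′→3′; the overview
exposes bin width rather than a kernel bandwidth for the density ring.

## Degenerate inputs and numerical choices

Empty circRNA sets yield header-only tables and are an error only where an
output would be meaningless (an empty junction-reference FASTA, an empty
plot). Empty strings score 0 in the aligner with an empty hit. Splice-signal
fractions normalize to 1 within 1e−9 on non-empty input. Thresholds and
overhangs below 1 are rejected rather than clamped. BED ids are synthesized
as `chrom:start-end` when absent; duplicate explicit ids are an error at
parse time.
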