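"""Translation evidence for circRNAs from ribosome profiling.

A translated circRNA must carry ribosomes across its back-splice junction,
so junction-spanning Ribo-seq reads are the diagnostic signal. Because
ribosome-protected fragments are short (~30 nt), a read that happens to
align across the junction may equally well come from rRNA contamination or
from a linear transcript with similar sequence. The procedure therefore:

1. removes every read that aligns anywhere on the rRNA reference or the
   linear genome/transcriptome (the subtraction filter);
2. counts, per circRNA, the distinct surviving reads whose alignment to the
   doubled junction reference crosses the junction with a minimum overhang
   on both sides;
3. calls a circRNA translated when that count reaches the threshold
   (default 3 junction-spanning reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io_formats import AlignedSegment, write_csv
from .junction_ref import JunctionRef

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 3
DEFAULT_MIN_OVERHANG = 5


@dataclass
class ReadFilterResult:
    """Outcome of the rRNA/linear subtraction filter.

    A read mapped in both inputs is attributed to rRNA (removal reasons are
    mutually exclusive; rRNA takes precedence).
    """

    kept_ids: set[str] = field(default_factory=set)
    removed_rrna: int = 0
    removed_linear: int = 0


@dataclass(frozen=True)
class TranslationCall:
    circ_id: str
    junction_reads: int
    translated: bool


def subtract_mapped_reads(
    all_read_ids: set[str],
    rrna_aln: list[AlignedSegment],
    linear_aln: list[AlignedSegment],
) -> ReadFilterResult:
    """Keep only reads with no mapping to rRNA or linear references.

    Any alignment record counts, primary or not: the filter removes reads
    that *can* be aligned anywhere linear. Alignment read ids outside the
    universe are logged and ignored.
    """
    rrna_mapped = {seg.read_id for seg in rrna_aln if seg.is_mapped}
    linear_mapped = {seg.read_id for seg in linear_aln if seg.is_mapped}
    unknown = (rrna_mapped | linear_mapped) - all_read_ids
    if unknown:
        log.warning("%d aligned read ids not in the read universe; ignored", len(unknown))
    rrna_mapped &= all_read_ids
    linear_mapped &= all_read_ids
    kept = all_read_ids - rrna_mapped - linear_mapped
    return ReadFilterResult(
        kept_ids=kept,
        removed_rrna=len(rrna_mapped),
        removed_linear=len(linear_mapped - rrna_mapped),
    )


def spans_junction(
    seg: AlignedSegment, junction_offset: int, min_overhang: int = DEFAULT_MIN_OVERHANG
) -> bool:
    """True iff the alignment crosses the junction with >= min_overhang nt
    on each side: ref_start <= offset - overhang and ref_end >= offset + overhang."""
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if not seg.is_mapped:
        return False
    return (
        seg.ref_start <= junction_offset - min_overhang
        and seg.ref_end >= junction_offset + min_overhang
    )


def count_junction_reads(
    refs: list[JunctionRef],
    junction_aln: list[AlignedSegment],
    kept: ReadFilterResult,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> pd.DataFrame:
    """Per circRNA, the number of distinct kept reads spanning its junction.

    A read with several spanning alignments to one doubled reference counts
    once — the doubling itself guarantees duplicate internal placements.
    Alignments to unknown reference names are logged and skipped.
    """
    offsets = {ref.circ_id: ref.junction_offset for ref in refs}
    spanning: dict[str, set[str]] = {circ_id: set() for circ_id in offsets}
    for seg in junction_aln:
        if not seg.is_mapped:
            continue
        if seg.ref_name not in offsets:
            log.warning("alignment to unknown reference %r skipped", seg.ref_name)
            continue
        if seg.read_id not in kept.kept_ids:
            continue
        if spans_junction(seg, offsets[seg.ref_name], min_overhang):
            spanning[seg.ref_name].add(seg.read_id)
    return pd.DataFrame(
        {
            "circ_id": list(offsets),
            "junction_reads": [len(spanning[c]) for c in offsets],
        }
    )


def call_translation(
    counts: pd.DataFrame, threshold: int = DEFAULT_THRESHOLD
) -> list[TranslationCall]:
    """Label each circRNA translated iff junction_reads >= threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return [
        TranslationCall(row.circ_id, int(row.junction_reads),
                        int(row.junction_reads) >= threshold)
        for row in counts.itertuples(index=False)
    ]


def mapping_table(
    calls: list[TranslationCall],
    counts: pd.DataFrame,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Combine calls and counts into one table, sorted by junction_reads
    descending then circ_id; optionally written as CSV."""
    count_ids = set(counts["circ_id"])
    call_ids = {c.circ_id for c in calls}
    if count_ids != call_ids:
        raise ValueError(
            f"id mismatch between calls and counts: {sorted(count_ids ^ call_ids)}"
        )
    df = pd.DataFrame(
        [
            {"circ_id": c.circ_id, "junction_reads": c.junction_reads,
             "translated": c.translated}
            for c in calls
        ],
        columns=["circ_id", "junction_reads", "translated"],
    )
    df = df.sort_values(
        ["junction_reads", "circ_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if out_path is not None:
        write_csv(
            df.to_dict("records"), out_path, ["circ_id", "junction_reads", "translated"]
        )
    return df
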