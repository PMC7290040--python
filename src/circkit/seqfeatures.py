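"""Meta-features over circRNA sets: splice signals, length and chromosome
distributions, and windowed GC content.

The splice signal is the dinucleotide pair immediately flanking the
back-splice site, reported as "upstream/downstream" on the transcribed
strand (canonical spliceosomal introns give AG upstream / GT downstream of
the circle on the genome). Histogram bins and genome windows are uniformly
half-open-right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io_formats import CircRecord, GenomeSequence, write_csv
from .stemloop import reverse_complement


@dataclass(frozen=True)
class SpliceSignal:
    circ_id: str
    upstream_dinuc: str
    downstream_dinuc: str

    @property
    def signal(self) -> str:
        return f"{self.upstream_dinuc}/{self.downstream_dinuc}"


def _padded_slice(seq: str, start: int, end: int) -> str:
    """Substring padded with N where the window leaves the chromosome."""
    left_pad = max(0, -start)
    right_pad = max(0, end - len(seq))
    return "N" * left_pad + seq[max(0, start) : min(len(seq), end)] + "N" * right_pad


def splice_signal(circ: CircRecord, genome: GenomeSequence) -> SpliceSignal:
    """Two bases on each side of the back-splice site, on the transcribed strand.

    Plus strand: upstream = genome[start-2:start], downstream =
    genome[end:end+2]. Minus strand: the transcript's upstream flank is the
    plus-strand downstream flank reverse-complemented, and vice versa.
    Flanks beyond the chromosome ends are padded with N.
    """
    seq = genome[circ.chrom]
    before = _padded_slice(seq, circ.start - 2, circ.start)
    after = _padded_slice(seq, circ.end, circ.end + 2)
    if circ.strand == "-":
        return SpliceSignal(circ.circ_id, reverse_complement(after), reverse_complement(before))
    return SpliceSignal(circ.circ_id, before, after)


def splice_signal_counts(
    circs: list[CircRecord],
    genome: GenomeSequence,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Signal frequency table sorted by count descending then signal."""
    signals = [splice_signal(c, genome).signal for c in circs]
    if not signals:
        df = pd.DataFrame(columns=["signal", "count", "fraction"])
    else:
        counts = pd.Series(signals).value_counts()
        df = pd.DataFrame(
            {
                "signal": counts.index,
                "count": counts.to_numpy(),
                "fraction": counts.to_numpy() / len(signals),
            }
        ).sort_values(["count", "signal"], ascending=[False, True], ignore_index=True)
    if out_path is not None:
        write_csv(df.to_dict("records"), out_path, ["signal", "count", "fraction"])
    return df


def length_distribution(
    circs: list[CircRecord],
    bin_width: int = 200,
    classification: pd.DataFrame | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Histogram of circRNA lengths in [k*w, (k+1)*w) bins.

    With a classification table (from ``classify_all``) the histogram is
    additionally split per category label.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    labels = (
        dict(zip(classification["circ_id"], classification["label"]))
        if classification is not None
        else {}
    )
    rows: dict[tuple[int, str], int] = {}
    for c in circs:
        key = (c.length() // bin_width, labels.get(c.circ_id, "all"))
        rows[key] = rows.get(key, 0) + 1
    out = [
        {
            "bin_start": k * bin_width,
            "bin_end": (k + 1) * bin_width,
            "label": label,
            "count": n,
        }
        for (k, label), n in sorted(rows.items())
    ]
    columns = ["bin_start", "bin_end", "label", "count"]
    df = pd.DataFrame(out, columns=columns)
    if out_path is not None:
        write_csv(out, out_path, columns)
    return df


def _natural_key(name: str) -> list:
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


def chromosome_distribution(
    circs: list[CircRecord], out_path: str | Path | None = None
) -> pd.DataFrame:
    """circRNA counts per chromosome, naturally sorted (chr2 before chr10)."""
    counts: dict[str, int] = {}
    for c in circs:
        counts[c.chrom] = counts.get(c.chrom, 0) + 1
    rows = [
        {"chrom": chrom, "count": counts[chrom]}
        for chrom in sorted(counts, key=_natural_key)
    ]
    df = pd.DataFrame(rows, columns=["chrom", "count"])
    if out_path is not None:
        write_csv(rows, out_path, ["chrom", "count"])
    return df


def gc_windows(
    genome: GenomeSequence,
    window: int = 10000,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """GC fraction over non-N bases in tiling windows per chromosome.

    Windows never cross chromosomes; the last window may be short. An
    all-N window has undefined GC (NaN), not zero — assembly gaps are not
    AT-rich.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for chrom, seq in genome.items():
        for start in range(0, len(seq), window):
            chunk = seq[start : start + window]
            acgt = len(chunk) - chunk.count("N")
            gc = (chunk.count("G") + chunk.count("C")) / acgt if acgt else float("nan")
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": start,
                    "window_end": min(start + window, len(seq)),
                    "gc_fraction": gc,
                }
            )
    columns = ["chrom", "window_start", "window_end", "gc_fraction"]
    df = pd.DataFrame(rows, columns=columns)
    if out_path is not None:
        write_csv(rows, out_path, columns)
    return df


def write_gc_bedgraph(gc_track: pd.DataFrame, path: str | Path) -> None:
    """bedGraph export of the GC track for genome browsers (NaN rows skipped)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="GC content"\n')
        for row in gc_track.itertuples(index=False):
            if row.gc_fraction == row.gc_fraction:  # skip NaN
                fh.write(
                    f"{row.chrom}\t{row.window_start}\t{row.window_end}\t"
                    f"{row.gc_fraction:.4f}\n"
                )
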