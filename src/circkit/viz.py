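"""Plot-data layers and thin matplotlib renderings.

All numeric layers (circular coverage, codon positions, classification
density, signal counts) are computed here or in other modules and tested as
tables; rendering consumes them unchanged. The circular mapping plot
anchors the back-splice junction at angle 0 and proceeds clockwise 5'->3'.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io_formats import AlignedSegment
from .junction_ref import JunctionRef
from .ribo_translation import ReadFilterResult

START_CODON = "ATG"
STOP_CODONS = ("TAA", "TAG", "TGA")


def circular_coverage(
    ref: JunctionRef,
    junction_aln: list[AlignedSegment],
    kept: ReadFilterResult,
) -> np.ndarray:
    """Per-position read coverage over the circle [0, L).

    A doubled-reference alignment covers circular position p when it covers
    p or p + L; an alignment longer than the circle covers every position
    once. Total mass equals the sum of min(aligned length, L).
    """
    L = ref.junction_offset
    cov = np.zeros(L, dtype=int)
    for seg in junction_aln:
        if not seg.is_mapped or seg.ref_name != ref.circ_id:
            continue
        if seg.read_id not in kept.kept_ids:
            continue
        length = min(seg.ref_end - seg.ref_start, L)
        for i in range(length):
            cov[(seg.ref_start + i) % L] += 1
    return cov


def find_codons(circ_seq: str) -> tuple[list[int], list[int]]:
    """Circular positions (all frames, wraparound included) of start and
    stop codons. Scans the doubled string restricted to starts < L."""
    L = len(circ_seq)
    doubled = circ_seq + circ_seq
    starts = [i for i in range(L) if doubled[i : i + 3] == START_CODON]
    stops = [i for i in range(L) if doubled[i : i + 3] in STOP_CODONS]
    return starts, stops


def _require_columns(table: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def render_mapping_plot(
    ref: JunctionRef,
    junction_aln: list[AlignedSegment],
    kept: ReadFilterResult,
    path: str | Path,
    zoom: tuple[int, int] | None = None,
) -> None:
    """Ring diagram of reads on one circRNA: coverage ring, read arcs,
    start/stop codon ticks, junction marked at angle 0.

    ``zoom = (lo, hi)`` with lo < 0 < hi restricts the drawn arc to circular
    offsets [lo, hi) around the junction.
    """
    L = ref.junction_offset
    cov = circular_coverage(ref, junction_aln, kept)
    starts, stops = find_codons(ref.sequence[:L])
    if zoom is None:
        visible = np.ones(L, dtype=bool)
    else:
        lo, hi = zoom
        if not lo < 0 < hi:
            raise ValueError("zoom interval must contain the junction (offset 0)")
        signed = (np.arange(L) + L // 2) % L - L // 2  # offset from junction
        visible = (signed >= lo) & (signed < hi)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    angles = np.linspace(0, 2 * np.pi, L, endpoint=False)
    ax.scatter(angles[visible], np.full(visible.sum(), 1.0),
               c=cov[visible], cmap="coolwarm", s=4)
    rows = [
        seg for seg in junction_aln
        if seg.is_mapped and seg.ref_name == ref.circ_id and seg.read_id in kept.kept_ids
    ]
    for k, seg in enumerate(rows):
        arc = np.linspace(seg.ref_start, seg.ref_end - 1, 50) % L
        ax.plot(2 * np.pi * arc / L, np.full(50, 0.9 - 0.02 * (k % 20)),
                color="green", lw=0.8)
    for p in starts:
        ax.plot([2 * np.pi * p / L], [1.05], marker="^", color="blue", ms=4)
    for p in stops:
        ax.plot([2 * np.pi * p / L], [1.05], marker="v", color="red", ms=4)
    ax.plot([0, 0], [0.8, 1.1], color="black", lw=2)  # the back-splice junction
    ax.set_rticks([])
    ax.set_xticks([])
    ax.set_title(f"{ref.circ_id} (L={L} nt, {len(rows)} reads)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_overview(
    classification: pd.DataFrame,
    gc_track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Genome-wide ring: circRNA positions/lengths by category, GC heat ring."""
    _require_columns(classification, ["chrom", "start", "end", "label", "length"],
                     "classification table")
    _require_columns(gc_track, ["chrom", "window_start", "gc_fraction"], "GC track")
    if classification.empty:
        raise ValueError("no circRNAs to draw")
    chroms = sorted(chrom_lengths)
    total = sum(chrom_lengths[c] for c in chroms)
    offset = {}
    acc = 0
    for c in chroms:
        offset[c] = acc
        acc += chrom_lengths[c]
    to_angle = lambda chrom, pos: 2 * np.pi * (offset[chrom] + pos) / total
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    labels = sorted(classification["label"].unique())
    cmap = plt.get_cmap("tab10")
    for li, label in enumerate(labels):
        sub = classification[classification["label"] == label]
        ang = [to_angle(r.chrom, (r.start + r.end) // 2) for r in sub.itertuples()]
        rad = 1.0 + 0.3 * sub["length"].to_numpy() / max(classification["length"].max(), 1)
        ax.scatter(ang, rad, s=8, color=cmap(li % 10), label=label)
    gc = gc_track.dropna(subset=["gc_fraction"])
    ax.scatter(
        [to_angle(r.chrom, r.window_start) for r in gc.itertuples()],
        np.full(len(gc), 0.8),
        c=gc["gc_fraction"], cmap="Reds", s=6, marker="s",
    )
    ax.set_rticks([])
    ax.set_xticks([])
    ax.legend(loc="center", fontsize=6)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_class_density(density: pd.DataFrame, path: str | Path) -> None:
    """Per-chromosome density profiles of each circRNA category."""
    _require_columns(density, ["chrom", "bin_start", "label", "count"], "density table")
    if density.empty:
        raise ValueError("empty density table")
    chroms = sorted(density["chrom"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2.2 * len(chroms)),
                             squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = density[density["chrom"] == chrom]
        for label, group in sub.groupby("label"):
            ax.plot(group["bin_start"], group["count"], label=label, lw=1)
        ax.set_ylabel(chrom)
    axes.ravel()[0].legend(fontsize=6, ncol=4)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_signal_hist(signal_counts: pd.DataFrame, path: str | Path,
                       top: int = 15) -> None:
    """Histogram of the most frequent splice-signal dinucleotide pairs."""
    _require_columns(signal_counts, ["signal", "count"], "signal table")
    if signal_counts.empty:
        raise ValueError("empty signal table")
    sub = signal_counts.head(top)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(sub["signal"], sub["count"], color="steelblue")
    ax.set_xlabel("splice signal (upstream/downstream)")
    ax.set_ylabel("circRNA count")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
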