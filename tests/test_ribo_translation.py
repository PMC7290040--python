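import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circkit.io_formats import AlignedSegment, CircRecord
from circkit.junction_ref import JunctionRef
from circkit.ribo_translation import (
    ReadFilterResult,
    call_translation,
    count_junction_reads,
    mapping_table,
    spans_junction,
    subtract_mapped_reads,
)


def seg(rid, ref, start, end):
    return AlignedSegment(rid, ref, start, end)


def make_ref(circ_id="circA", L=100):
    circ = CircRecord("chr1", 0, L, "+", circ_id)
    return JunctionRef(circ_id, "A" * (2 * L), L, circ)


class TestSubtraction:
    def test_union_removed(self):
        res = subtract_mapped_reads(
            {"r1", "r2", "r3"}, [seg("r1", "rRNA", 0, 30)], [seg("r2", "chr1", 0, 30)]
        )
        assert res.kept_ids == {"r3"}
        assert (res.removed_rrna, res.removed_linear) == (1, 1)

    def test_empty_inputs_keep_universe(self):
        res = subtract_mapped_reads({"a", "b"}, [], [])
        assert res.kept_ids == {"a", "b"}

    def test_rrna_precedence_when_mapped_in_both(self):
        res = subtract_mapped_reads(
            {"r1"}, [seg("r1", "rRNA", 0, 30)], [seg("r1", "chr1", 0, 30)]
        )
        assert (res.removed_rrna, res.removed_linear) == (1, 0)

    def test_unknown_alignment_ids_ignored(self):
        res = subtract_mapped_reads({"r1"}, [seg("ghost", "rRNA", 0, 30)], [])
        assert res.kept_ids == {"r1"} and res.removed_rrna == 0

    def test_unmapped_records_do_not_remove(self):
        unmapped = AlignedSegment("r1", "", -1, -1, is_mapped=False)
        res = subtract_mapped_reads({"r1"}, [unmapped], [unmapped])
        assert res.kept_ids == {"r1"}


class TestSpansJunction:
    @pytest.mark.parametrize(
        "span,overhang,expected",
        [
            ((90, 110), 5, True),
            ((96, 130), 5, False),  # only 4 nt left of the junction
            ((70, 104), 5, False),  # only 4 nt right
            ((95, 105), 5, True),  # exactly the minimum both sides
            ((99, 101), 1, True),  # minimal 1-nt overhang
            ((100, 130), 1, False),  # starts at the junction: no left overhang
        ],
    )
    def test_overhang_inequality(self, span, overhang, expected):
        s = seg("r", "circA", *span)
        assert spans_junction(s, 100, overhang) is expected

    def test_invalid_overhang_rejected(self):
        with pytest.raises(ValueError):
            spans_junction(seg("r", "c", 0, 50), 100, 0)


class TestCounting:
    def test_enumeration_oracle_mixed_alignments(self):
        # 2 spanning kept + 4 non-spanning + 1 spanning-but-filtered -> 2
        ref = make_ref()
        aln = [
            seg("k1", "circA", 90, 120),
            seg("k2", "circA", 80, 110),
            seg("k3", "circA", 0, 30),
            seg("k4", "circA", 10, 40),
            seg("k5", "circA", 120, 150),
            seg("k6", "circA", 96, 126),  # insufficient left overhang
            seg("f1", "circA", 90, 120),  # filtered upstream
        ]
        kept = ReadFilterResult(kept_ids={"k1", "k2", "k3", "k4", "k5", "k6"})
        counts = count_junction_reads([ref], aln, kept, min_overhang=5)
        assert counts.set_index("circ_id")["junction_reads"]["circA"] == 2

    def test_multimapping_read_counts_once(self):
        ref = make_ref()
        aln = [seg("r1", "circA", 90, 120), seg("r1", "circA", 95, 125)]
        kept = ReadFilterResult(kept_ids={"r1"})
        counts = count_junction_reads([ref], aln, kept)
        assert counts["junction_reads"].tolist() == [1]

    def test_unknown_reference_skipped(self):
        ref = make_ref()
        aln = [seg("r1", "nope", 90, 120)]
        counts = count_junction_reads([ref], aln, ReadFilterResult(kept_ids={"r1"}))
        assert counts["junction_reads"].tolist() == [0]

    def test_matches_brute_force_scan_on_simulation(self, sim):
        kept = subtract_mapped_reads(set(sim.read_ids), sim.rrna_aln, sim.linear_aln)
        counts = count_junction_reads(sim.junction_refs, sim.junction_aln, kept)
        offsets = {r.circ_id: r.junction_offset for r in sim.junction_refs}
        # independent brute-force (read x alignment) scan
        expected = {}
        for ref_id, offset in offsets.items():
            readset = set()
            for s in sim.junction_aln:
                if (
                    s.is_mapped
                    and s.ref_name == ref_id
                    and s.read_id in kept.kept_ids
                    and s.ref_start <= offset - 5
                    and s.ref_end >= offset + 5
                ):
                    readset.add(s.read_id)
            expected[ref_id] = len(readset)
        got = dict(zip(counts["circ_id"], counts["junction_reads"]))
        assert got == expected

    def test_monotone_in_added_spanning_read(self, sim):
        kept = subtract_mapped_reads(set(sim.read_ids), sim.rrna_aln, sim.linear_aln)
        base = count_junction_reads(sim.junction_refs, sim.junction_aln, kept)
        ref = sim.junction_refs[0]
        L = ref.junction_offset
        extra = seg("brand_new_read", ref.circ_id, L - 15, L + 15)
        kept.kept_ids.add("brand_new_read")
        more = count_junction_reads(sim.junction_refs, sim.junction_aln + [extra], kept)
        b = dict(zip(base["circ_id"], base["junction_reads"]))
        m = dict(zip(more["circ_id"], more["junction_reads"]))
        assert m[ref.circ_id] == b[ref.circ_id] + 1
        assert all(m[c] >= b[c] for c in b)


class TestCalling:
    def test_threshold_three(self):
        counts = pd.DataFrame(
            {"circ_id": ["A", "B", "C"], "junction_reads": [3, 2, 0]}
        )
        calls = {c.circ_id: c.translated for c in call_translation(counts)}
        assert calls == {"A": True, "B": False, "C": False}

    def test_zero_reads_never_translated(self):
        counts = pd.DataFrame({"circ_id": ["A"], "junction_reads": [0]})
        assert not call_translation(counts, threshold=1)[0].translated

    def test_monotone_in_count(self):
        counts = pd.DataFrame({"circ_id": ["A"], "junction_reads": [100]})
        assert call_translation(counts)[0].translated

    def test_translated_set_shrinks_with_threshold(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            {"circ_id": [f"c{i}" for i in range(30)],
             "junction_reads": rng.integers(0, 10, 30)}
        )
        prev = None
        for threshold in range(1, 12):
            now = {c.circ_id for c in call_translation(counts, threshold) if c.translated}
            if prev is not None:
                assert now <= prev
            prev = now

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_translation(pd.DataFrame({"circ_id": [], "junction_reads": []}), 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        reads=st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=15),
        t1=st.integers(min_value=1, max_value=10),
        t2=st.integers(min_value=1, max_value=10),
    )
    def test_translated_set_monotone_in_threshold_property(self, reads, t1, t2):
        lo, hi = sorted((t1, t2))
        counts = pd.DataFrame(
            {"circ_id": [f"c{i}" for i in range(len(reads))], "junction_reads": reads}
        )
        at_lo = {c.circ_id for c in call_translation(counts, lo) if c.translated}
        at_hi = {c.circ_id for c in call_translation(counts, hi) if c.translated}
        assert at_hi <= at_lo


@settings(derandomize=True, max_examples=100)
@given(
    start=st.integers(min_value=0, max_value=200),
    length=st.integers(min_value=1, max_value=100),
    offset=st.integers(min_value=10, max_value=150),
    overhang=st.integers(min_value=1, max_value=20),
)
def test_spans_junction_equivalent_to_circular_overlap_property(
    start, length, offset, overhang
):
    """Spanning holds exactly when the alignment covers the closed window
    of ``overhang`` bases on each side of the junction."""
    s = seg("r", "c", start, start + length)
    window = set(range(offset - overhang, offset + overhang))
    covered = set(range(start, start + length))
    assert spans_junction(s, offset, overhang) == (window <= covered)


class TestMappingTable:
    def test_sorted_by_count_then_id(self, tmp_path):
        counts = pd.DataFrame(
            {"circ_id": ["B", "A", "C"], "junction_reads": [0, 3, 3]}
        )
        calls = call_translation(counts)
        out = tmp_path / "table.csv"
        df = mapping_table(calls, counts, out)
        assert df["circ_id"].tolist() == ["A", "C", "B"]
        assert out.read_text().splitlines()[0] == "circ_id,junction_reads,translated"

    def test_empty_gives_header_only(self, tmp_path):
        counts = pd.DataFrame({"circ_id": [], "junction_reads": []})
        out = tmp_path / "table.csv"
        mapping_table([], counts, out)
        assert out.read_text().strip() == "circ_id,junction_reads,translated"

    def test_id_mismatch_rejected(self):
        counts = pd.DataFrame({"circ_id": ["A"], "junction_reads": [1]})
        calls = call_translation(
            pd.DataFrame({"circ_id": ["B"], "junction_reads": [1]})
        )
        with pytest.raises(ValueError, match="mismatch"):
            mapping_table(calls, counts)
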