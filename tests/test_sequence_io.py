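"""Read preprocessing: merging, trimming, filtering, collapsing."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from premirseq.sequence_io import (
    CollapsedRead, InvalidSequenceError, MergeFailure, SeqRead, collapse,
    length_select, merge_pair, quality_filter, read_fastq, revcomp,
    trim_adapters, write_fastq,
)

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMergePair:
    def test_error_free_reconstruction(self):
        rng = random.Random(1)
        template = _rand_seq(rng, 120)
        fwd = SeqRead("r/1", template[:75], [40] * 75)
        rev = SeqRead("r/2", revcomp(template[-75:]), [40] * 75)
        merged = merge_pair(fwd, rev)
        assert merged.seq == template

    def test_no_valid_overlap_fails(self):
        rng = random.Random(2)
        fwd = SeqRead("a", "ACGTACGTACGTACGTACGT", [40] * 20)
        rev = SeqRead("b", _rand_seq(rng, 20), [40] * 20)
        out = merge_pair(fwd, rev, min_overlap=15)
        assert isinstance(out, MergeFailure)

    def test_higher_quality_base_wins_at_mismatch(self):
        """Planted overlap mismatches resolve to the higher-phred base."""
        rng = random.Random(3)
        for _ in range(200):
            template = _rand_seq(rng, 100)
            cut = rng.randrange(40, 60)
            overlap = rng.randrange(20, 35)
            fwd_seq = template[:cut + overlap]
            rev_tpl = list(template[cut:])
            pos = rng.randrange(overlap)  # mismatch inside the overlap
            truth = fwd_seq[cut + pos]
            alt = rng.choice([b for b in "ACGT" if b != truth])
            rev_tpl[pos] = alt
            fwd = SeqRead("f", fwd_seq, [40] * len(fwd_seq))
            rev = SeqRead("r", revcomp("".join(rev_tpl)), [20] * len(rev_tpl))
            merged = merge_pair(fwd, rev)
            assert not isinstance(merged, MergeFailure)
            assert merged.seq == template
            assert merged.qual[cut + pos] == 40

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(InvalidSequenceError):
            merge_pair(
                SeqRead("a", "ACGTXACGTACGT", [40] * 13),
                SeqRead("b", "ACGTACGTACGTA", [40] * 13),
            )


class TestTrimAdapters:
    def test_full_adapter_removal(self):
        insert = "ACGTACGTACGT"
        r = trim_adapters(SeqRead("r", insert + ADAPTER3, [40] * (12 + len(ADAPTER3))),
                          ADAPTER3, ADAPTER5)
        assert r.seq == insert
        assert len(r.qual) == len(r.seq)

    def test_no_adapter_is_identity(self):
        r = SeqRead("r", "ACGTACGTACGTACGTACGT", [40] * 20)
        assert trim_adapters(r, ADAPTER3, ADAPTER5).seq == r.seq

    @pytest.mark.parametrize("has5,has3,partial3", [
        (True, True, False), (True, False, False),
        (False, True, False), (False, True, True),
    ])
    def test_planted_adapters_recovered(self, has5, has3, partial3):
        rng = random.Random(7)
        for _ in range(125):
            insert = _rand_seq(rng, rng.randrange(40, 120))
            seq = insert
            if has5:
                seq = ADAPTER5 + seq
            if has3:
                a3 = ADAPTER3[:rng.randrange(8, len(ADAPTER3))] if partial3 else ADAPTER3
                tail = "" if partial3 else _rand_seq(rng, 5)
                seq = seq + a3 + tail
            out = trim_adapters(SeqRead("r", seq, [40] * len(seq)), ADAPTER3, ADAPTER5)
            assert out.seq == insert

    def test_trim_to_empty_marks_read(self):
        out = trim_adapters(
            SeqRead("r", ADAPTER5 + ADAPTER3, [40] * (len(ADAPTER5) + len(ADAPTER3))),
            ADAPTER3, ADAPTER5,
        )
        assert out.seq == ""


class TestFilters:
    def test_quality_filter_matches_brute_force(self):
        rng = random.Random(11)
        reads = [
            SeqRead(f"r{i}", _rand_seq(rng, 50),
                    [rng.randrange(2, 41) for _ in range(50)])
            for i in range(300)
        ]
        kept = quality_filter(reads, 30)
        expected = [r for r in reads if sum(r.qual) / 50 >= 30]
        assert kept == expected

    def test_high_and_low_quality_boundaries(self):
        hi = SeqRead("hi", "ACGT" * 10, [40] * 40)
        lo = SeqRead("lo", "ACGT" * 10, [20] * 40)
        assert quality_filter([hi, lo], 30) == [hi]

    def test_n_rich_reads_dropped(self):
        r = SeqRead("n", "N" * 10 + "ACGT" * 10, [40] * 50)
        assert quality_filter([r], 30) == []

    @pytest.mark.parametrize("n,kept", [(39, False), (40, True), (241, True), (242, False)])
    def test_length_window_closed(self, n, kept):
        r = SeqRead("r", "A" * n, [40] * n)
        assert (length_select([r], 40, 241) == [r]) is kept

    def test_filters_idempotent(self):
        rng = random.Random(13)
        reads = []
        for i in range(100):
            n = rng.randrange(20, 300)
            reads.append(SeqRead(f"r{i}", _rand_seq(rng, n),
                                 [rng.randrange(20, 41)] * n))
        once = quality_filter(length_select(reads, 40, 241), 30)
        twice = quality_filter(length_select(once, 40, 241), 30)
        assert once == twice


class TestCollapse:
    def test_simple_counts(self):
        out = collapse(["AAA", "AAA", "CCC"])
        assert {(c.seq, c.count) for c in out} == {("AAA", 2), ("CCC", 1)}

    def test_empty_input(self):
        assert collapse([]) == []

    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=8), max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_count_conservation(self, seqs):
        out = collapse(seqs)
        assert sum(c.count for c in out) == len(seqs)
        assert len({c.seq for c in out}) == len(out)


def test_fastq_round_trip(tmp_path):
    reads = [SeqRead("a", "ACGT", [2, 40, 30, 33]), SeqRead("b", "GGGC", [35] * 4)]
    p = tmp_path / "x.fastq"
    write_fastq(reads, p)
    back = list(read_fastq(p))
    assert [(r.id, r.seq, r.qual) for r in back] == [(r.id, r.seq, r.qual) for r in reads]
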