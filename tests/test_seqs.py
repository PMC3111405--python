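"""Symbolic/numeric conversion, FASTA I/O and windowing."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucperiod import (
    NPS_DINUCLEOTIDES,
    FastaFormatError,
    IndicatorSequence,
    SymbolSet,
    SymbolicFragment,
    indicator,
    indicator_to_fragment,
    perfect_periodic,
    read_fasta,
    windows,
)


class TestReadFasta:
    def test_single_record(self, write_fasta):
        frags = list(read_fasta(write_fasta([("a", "AATT")])))
        assert len(frags) == 1
        assert frags[0].seq_id == "a"
        assert frags[0].N == 4
        assert (frags[0].start, frags[0].end) == (0, 4)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert list(read_fasta(path)) == []

    def test_two_records_in_order(self, write_fasta):
        frags = list(read_fasta(write_fasta([("one", "ACGT"), ("two", "TTTT")])))
        assert [f.seq_id for f in frags] == ["one", "two"]

    def test_uppercases(self, write_fasta):
        (frag,) = read_fasta(write_fasta([("a", "acgt")]))
        assert frag.symbols == "ACGT"

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "in.fasta.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(">a\nAACC\n")
        (frag,) = read_fasta(path)
        assert frag.symbols == "AACC"

    def test_malformed_raises(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("AACC\nGGTT\n")
        with pytest.raises(FastaFormatError):
            list(read_fasta(path))


class TestWindows:
    @pytest.mark.parametrize(
        "N,width,step,expected",
        [(152, 150, 1, 3), (150, 150, 1, 1), (100, 150, 1, 0), (10, 4, 3, 3)],
    )
    def test_window_count(self, N, width, step, expected):
        frag = SymbolicFragment("c", "A" * N)
        assert len(list(windows(frag, width, step))) == expected

    def test_coordinates_offset_by_parent(self):
        frag = SymbolicFragment("c", "ACGTACGT", start=100)
        ws = list(windows(frag, 4, 2))
        assert [(w.start, w.end) for w in ws] == [(100, 104), (102, 106), (104, 108)]
        assert ws[1].symbols == "GTAC"

    def test_invalid_args(self):
        frag = SymbolicFragment("c", "ACGT")
        with pytest.raises(ValueError):
            list(windows(frag, 1, 1))
        with pytest.raises(ValueError):
            list(windows(frag, 2, 0))


class TestIndicator:
    def test_nps_example(self):
        x = indicator(SymbolicFragment("a", "AATA"), NPS_DINUCLEOTIDES)
        assert x.values.tolist() == [1, 0, 1, 0]

    def test_no_matches(self):
        x = indicator(SymbolicFragment("a", "CCCC"), NPS_DINUCLEOTIDES)
        assert x.values.tolist() == [0, 0, 0, 0]

    def test_overlapping_matches(self):
        x = indicator(SymbolicFragment("a", "AAAA"), SymbolSet(("AA",)))
        assert x.values.tolist() == [1, 1, 1, 0]

    def test_ambiguity_never_matches(self):
        x = indicator(SymbolicFragment("a", "ANAA"), NPS_DINUCLEOTIDES)
        assert x.values.tolist() == [0, 0, 1, 0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=2, max_size=60), st.integers(0, 6))
    def test_sum_matches_brute_force_count(self, seq, set_choice):
        sets = [
            SymbolSet(("AA", "TT", "TA")),
            SymbolSet(("AA",)),
            SymbolSet(("AC", "GT")),
            SymbolSet(("ACG",)),
            SymbolSet(("A", "T")),
            SymbolSet(("TATA",)),
            SymbolSet(("CG", "GC")),
        ]
        sset = sets[set_choice]
        x = indicator(SymbolicFragment("h", seq), sset)
        brute = sum(
            1
            for n in range(len(seq) - sset.k + 1)
            if seq[n : n + sset.k] in sset.members
        )
        assert x.count() == brute

    def test_fragment_shorter_than_k(self):
        x = indicator(SymbolicFragment("a", "A"), NPS_DINUCLEOTIDES)
        assert x.values.tolist() == [0]


class TestPerfectPeriodic:
    @pytest.mark.parametrize("n0", [0, 9])
    def test_150_10(self, n0):
        x = perfect_periodic(150, 10, n0)
        assert x.count() == 15
        assert np.flatnonzero(x.values).tolist() == list(range(n0, 150, 10))

    def test_short_fragment(self):
        x = perfect_periodic(5, 10, 0) if False else None
        with pytest.raises(ValueError):
            perfect_periodic(5, 10, 0)  # p > N

    def test_single_event(self):
        x = perfect_periodic(5, 5, 0)
        assert x.values.tolist() == [1, 0, 0, 0, 0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 40), st.integers(2, 30), st.integers(0, 29))
    def test_ones_count_formula(self, N, p, n0):
        if not (0 <= n0 < p <= N):
            return
        x = perfect_periodic(N, p, n0)
        assert x.count() == int(np.ceil((N - n0) / p))

    def test_invalid_phase(self):
        with pytest.raises(ValueError):
            perfect_periodic(150, 10, 10)


class TestSymbolSet:
    def test_nps_is_reverse_complement_closed(self):
        assert NPS_DINUCLEOTIDES.is_reverse_complement_closed()

    def test_general_set_union(self):
        s = SymbolSet(("AC",))
        assert not s.is_reverse_complement_closed()
        assert set(s.with_reverse_complement().members) == {"AC", "GT"}

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            SymbolSet(("AA", "TTT"))


class TestBackConversion:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=80))
    def test_round_trip(self, bits):
        x = IndicatorSequence(np.array(bits, dtype=np.uint8))
        frag = indicator_to_fragment(x)
        back = indicator(frag, NPS_DINUCLEOTIDES)
        assert back.values[: x.N].tolist() == bits
        assert back.values[x.N] == 0  # trailing position of the extra base

    def test_coordinate_invariant(self):
        frag = SymbolicFragment("a", "ACGT", start=10)
        assert frag.end == 14
        with pytest.raises(ValueError):
            SymbolicFragment("a", "ACGT", start=0, end=5)
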