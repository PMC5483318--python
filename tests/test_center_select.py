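import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dict_occurrences, dict_similarity_scores

from starmsa.seqio import Dataset, Sequence
from starmsa.center_select import (
    MAX_CODE,
    SEGMENT_BITS,
    TABLE_SIZE,
    build_occurrence_table,
    encode_segment,
    segment_codes,
    select_center,
    similarity_scores,
)
from conftest import random_dataset


def make_dataset(*seqs: str) -> Dataset:
    return Dataset([Sequence(id=f"s{i}", residues=s) for i, s in enumerate(seqs)])


class TestEncodeSegment:
    @pytest.mark.parametrize(
        "segment,code",
        [
            ("ATCGCGAT", 7905),  # published worked example
            ("AAAAAAAA", 0),
            ("CCCCCCCC", 65535),
            ("GGGGGGGG", 43690),  # 0b10 x 8 = 0xAAAA
        ],
    )
    def test_known_codes(self, segment, code):
        assert encode_segment(segment) == code

    def test_prose_mapping_differs(self):
        # the alternative mapping stated in running text gives 7089, not 7905
        assert encode_segment("ATCGCGAT", mapping="prose") == 7089

    def test_wrong_length(self):
        with pytest.raises(ValueError, match="8 characters"):
            encode_segment("ACGT")

    def test_bad_character(self):
        with pytest.raises(ValueError, match="'N'"):
            encode_segment("ACGTNACG")

    @given(st.text(alphabet="ACGT", min_size=8, max_size=8))
    def test_codes_in_range_and_injective_vs_oracle(self, seg):
        code = encode_segment(seg)
        assert 0 <= code <= MAX_CODE
        # independent recomputation from the character map
        table = {"A": "00", "T": "01", "G": "10", "C": "11"}
        assert code == int("".join(table[ch] for ch in seg), 2)

    def test_bit_width_constants(self):
        assert SEGMENT_BITS == 16
        assert TABLE_SIZE == 65536


class TestSegmentCodes:
    def test_repeated_segment(self):
        codes = segment_codes("ATCGCGATATCGCGAT")
        assert codes.tolist() == [7905, 7905]

    def test_remainder_dropped(self):
        assert len(segment_codes("ATCGCGATAT")) == 1

    def test_too_short(self):
        assert segment_codes("ACGTACG").tolist() == []

    def test_skip_ambiguous_drops_tainted_segment(self):
        rec = Sequence(id="a", residues="ACATACGT" + "ATCGCGAT", ambiguous_positions=(2,))
        codes = segment_codes(rec, skip_ambiguous=True)
        assert codes.tolist() == [7905]


class TestOccurrenceTable:
    def test_two_identical_sequences(self):
        occ = build_occurrence_table(make_dataset("ATCGCGAT", "ATCGCGAT"))
        assert occ.counts[7905] == 2

    def test_per_sequence_dedup(self):
        occ = build_occurrence_table(make_dataset("ATCGCGATATCGCGAT"))
        assert occ.counts[7905] == 1

    def test_all_short_sequences(self):
        occ = build_occurrence_table(make_dataset("ACG", "T"))
        assert occ.counts.sum() == 0

    def test_counts_bounded_by_n(self, rng):
        data = random_dataset(rng, 30, 120, min_len=8)
        occ = build_occurrence_table(data)
        assert occ.counts.max() <= data.n


class TestSimilarityScores:
    def test_worked_scores(self):
        data = make_dataset("ATCGCGAT", "ATCGCGAT", "AAAAAAAA")
        occ = build_occurrence_table(data)
        assert similarity_scores(data, occ) == [2, 2, 1]

    def test_single_sequence_distinct_segments(self, rng):
        seq = "ATCGCGAT" + "AAAAAAAA" + "CCCCCCCC"
        data = make_dataset(seq)
        occ = build_occurrence_table(data)
        assert similarity_scores(data, occ) == [3]

    def test_short_sequence_scores_zero(self):
        data = make_dataset("ACGT", "ATCGCGAT", "ATCGCGAT")
        occ = build_occurrence_table(data)
        assert similarity_scores(data, occ)[0] == 0

    def test_exclude_self_subtracts_listed_segments(self):
        data = make_dataset("ATCGCGATATCGCGAT", "ATCGCGAT")
        occ = build_occurrence_table(data)
        inc = similarity_scores(data, occ, include_self=True)
        exc = similarity_scores(data, occ, include_self=False)
        assert inc == [4, 2]
        assert exc == [2, 1]


class TestSelectCenter:
    def test_tie_breaks_to_smallest_index(self):
        assert select_center(make_dataset("ATCGCGAT", "ATCGCGAT", "AAAAAAAA")) == 0

    def test_all_identical(self):
        assert select_center(make_dataset("ACGTACGT", "ACGTACGT", "ACGTACGT")) == 0

    def test_pair_beats_singleton(self):
        assert select_center(make_dataset("ATCGCGAT", "GGGGGGGG", "GGGGGGGG")) == 1

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_center(make_dataset("ACGTACGT"))


class TestOracleEquivalence:
    """Bitmap table/scores must agree exactly with the dictionary oracle."""

    def test_random_datasets(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 51))
            data = random_dataset(rng, n, 200, min_len=1)
            seqs = [r.residues for r in data]
            occ = build_occurrence_table(data)

            oracle_occ = dict_occurrences(seqs)
            assert occ.counts.sum() == sum(oracle_occ.values())
            for seg_text, count in oracle_occ.items():
                assert occ.counts[encode_segment(seg_text)] == count

            assert similarity_scores(data, occ) == dict_similarity_scores(seqs)

    def test_linear_operation_count(self, rng):
        data = random_dataset(rng, 40, 160, min_len=8)
        total_segments = sum(len(r) // 8 for r in data)
        occ = build_occurrence_table(data)
        similarity_scores(data, occ)
        assert occ.total_ops <= 2 * total_segments


class TestPermutationCovariance:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_permuting_order_permutes_scores(self, seed):
        rng = np.random.default_rng(seed)
        data = random_dataset(rng, int(rng.integers(2, 12)), 60, min_len=8)
        perm = rng.permutation(data.n)
        permuted = Dataset([data[int(i)] for i in perm])

        occ1 = build_occurrence_table(data)
        occ2 = build_occurrence_table(permuted)
        ss1 = similarity_scores(data, occ1)
        ss2 = similarity_scores(permuted, occ2)
        assert ss2 == [ss1[int(i)] for i in perm]

        if ss1.count(max(ss1)) == 1:
            c1 = select_center(data)
            c2 = select_center(permuted)
            assert permuted[c2].id == data[c1].id
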