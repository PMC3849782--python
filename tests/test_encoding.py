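"""Weighted k-mer encoding: counting, normalization, embedding, distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fuzzyfam as ff
from fuzzyfam.encoding import AmbiguityError, embed

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_strategy = st.text(alphabet=AA, min_size=1, max_size=50)


def naive_count(seq, n):
    out = {}
    for i in range(len(seq) - n + 1):
        out[seq[i:i + n]] = out.get(seq[i:i + n], 0) + 1
    return out


class TestCountNpeptides:
    @pytest.mark.parametrize("seq,n,expected", [
        ("AAAC", 1, {"A": 3, "C": 1}),
        ("ACDE", 2, {"AC": 1, "CD": 1, "DE": 1}),
        ("AC", 3, {}),
    ])
    def test_window_counts(self, seq, n, expected):
        assert ff.count_npeptides(ff.SequenceRecord("s", seq), n) == expected

    def test_ambiguous_windows_skipped_or_error(self):
        rec = ff.SequenceRecord("s", "AXCD")
        counts = ff.count_npeptides(rec, 2)
        assert counts == {"CD": 1}  # AX and XC windows skipped
        with pytest.raises(AmbiguityError, match="position 2"):
            ff.count_npeptides(rec, 2, policy="error")

    @given(seq=seq_strategy, n=st.integers(1, 4))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_naive_enumeration(self, seq, n):
        rec = ff.SequenceRecord("s", seq)
        assert ff.count_npeptides(rec, n) == naive_count(seq, n)


class TestNormalizeBlock:
    @pytest.mark.parametrize("counts,n,expected", [
        ({"A": 3, "C": 1}, 1, {"A": 7.5, "C": 2.5}),
        ({"AC": 1, "CD": 1, "DE": 1}, 2, {k: 100 / 3 for k in ("AC", "CD", "DE")}),
        ({}, 4, {}),
    ])
    def test_weighted_frequencies(self, counts, n, expected):
        got = ff.normalize_block(counts, n)
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    @given(seq=seq_strategy, n=st.integers(1, 4))
    @settings(max_examples=150, deadline=None)
    def test_block_sums_to_weight(self, seq, n):
        """Non-empty length-n blocks always sum to exactly 10**n."""
        block = ff.normalize_block(
            ff.count_npeptides(ff.SequenceRecord("s", seq), n), n)
        if block:
            assert sum(block.values()) == pytest.approx(10 ** n, abs=1e-9)


class TestEncodeSequence:
    def test_domain_counts_weighted(self):
        rec = ff.SequenceRecord("s", "AAAC")
        hits = [ff.DomainHit("s", "CXC", 0.1), ff.DomainHit("s", "CXC", 0.2),
                ff.DomainHit("s", "PF-B", 0.3), ff.DomainHit("other", "CXC", 0.1)]
        vec = ff.encode_sequence(rec, hits)
        assert vec.domain_block == {"CXC": 200.0, "PF-B": 100.0}
        assert vec.blocks[3] == pytest.approx({"AAA": 500.0, "AAC": 500.0})

    def test_no_hits_empty_domain_block(self):
        vec = ff.encode_sequence(ff.SequenceRecord("s", "AAAC"))
        assert vec.domain_block == {}

    def test_weight_ladder_dominance(self):
        """Total mass of the n=4 block dominates n=1 by three decades."""
        vec = ff.encode_sequence(ff.SequenceRecord("s", "ACDEFGHIKL"))
        assert sum(vec.blocks[4].values()) == pytest.approx(
            1000 * sum(vec.blocks[1].values()))


class TestFeatureMatrix:
    def test_symmetric_composition(self):
        recs = [ff.SequenceRecord("x", "AC"), ff.SequenceRecord("y", "CA")]
        space, vecs = ff.build_feature_matrix(recs)
        for v in vecs:
            assert v.blocks[1] == pytest.approx({"A": 5.0, "C": 5.0})
        assert ("1", "A") not in space.index  # keys are (block, kmer) pairs
        assert (1, "A") in space.index

    def test_identical_sequences_identical_vectors(self):
        recs = [ff.SequenceRecord("x", "ACDE"), ff.SequenceRecord("y", "ACDE")]
        space, vecs = ff.build_feature_matrix(recs)
        X = embed(space, vecs).toarray()
        assert np.allclose(X[0], X[1])

    def test_adding_record_preserves_existing_values(self):
        r1 = [ff.SequenceRecord("x", "ACDE"), ff.SequenceRecord("y", "MKVL")]
        _, v1 = ff.build_feature_matrix(r1)
        _, v2 = ff.build_feature_matrix(r1 + [ff.SequenceRecord("z", "WWWW")])
        assert v1[0].blocks == v2[0].blocks

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError):
            ff.build_feature_matrix([ff.SequenceRecord("x", "ACDE")])


class TestDissimilarityMatrix:
    def test_identical_vectors_zero_distance(self):
        recs = [ff.SequenceRecord("x", "ACDE"), ff.SequenceRecord("y", "ACDE")]
        D = ff.dissimilarity_matrix(*ff.build_feature_matrix(recs))
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_single_letter_distance(self):
        # 1-mer blocks {A:10} vs {C:10}: euclidean sqrt(100+100),
        # plus identical contributions cancel in every other block
        recs = [ff.SequenceRecord("x", "A"), ff.SequenceRecord("y", "C")]
        cfg = ff.EncoderConfig(peptide_lengths=(1,))
        space, vecs = ff.build_feature_matrix(recs, config=cfg)
        D = ff.dissimilarity_matrix(space, vecs)
        assert D.values[0, 1] == pytest.approx(math.sqrt(200), rel=1e-9)

    def test_symmetry_and_zero_diagonal(self, family_set):
        *_, D = family_set
        assert np.allclose(D.values, D.values.T, atol=1e-12)
        assert np.all(np.diag(D.values) == 0)

    def test_permutation_equivariance(self):
        recs = [ff.SequenceRecord(c, c * 5 + "ACDE") for c in "WKY"]
        D1 = ff.dissimilarity_matrix(*ff.build_feature_matrix(recs))
        D2 = ff.dissimilarity_matrix(*ff.build_feature_matrix(recs[::-1]))
        assert np.allclose(D1.values, D2.values[::-1, ::-1])

    def test_manhattan_option(self):
        recs = [ff.SequenceRecord("x", "A"), ff.SequenceRecord("y", "C")]
        cfg = ff.EncoderConfig(peptide_lengths=(1,))
        space, vecs = ff.build_feature_matrix(recs, config=cfg)
        D = ff.dissimilarity_matrix(space, vecs, metric="manhattan")
        assert D.values[0, 1] == pytest.approx(20.0)
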