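import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_mmi_vector
from seqppi.alphabet import RESIDUES
from seqppi.mmi_features import (
    MMIEncoder,
    count_kgrams,
    enumerate_types,
    mi2,
    mi3,
    mmi_feature_names,
    mmi_pair,
    mmi_vector,
    pseudo_frequency,
)

codes_list = st.lists(st.integers(0, 6), min_size=3, max_size=300)


class TestEnumerateTypes:
    @pytest.mark.parametrize("k,expected", [(1, 7), (2, 28), (3, 84)])
    def test_counts(self, k, expected):
        types = enumerate_types(k)
        assert len(types) == expected
        assert types == sorted(types)  # frozen lexicographic order
        assert all(t == tuple(sorted(t)) for t in types)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            enumerate_types(4)


class TestCountKgrams:
    def test_two_gram_on_homotriple(self):
        counts = count_kgrams([0, 0, 0], 2)
        assert counts[(0, 0)] == 2
        assert sum(counts.values()) == 2

    def test_three_gram_windows_share_sorted_type(self):
        counts = count_kgrams([0, 1, 2, 0], 3)
        assert counts[(0, 1, 2)] == 2
        assert sum(counts.values()) == 2

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter than window"):
            count_kgrams([5], 2)

    @settings(deadline=None)
    @given(codes_list, st.integers(1, 3))
    def test_counts_sum_to_window_count(self, codes, k):
        counts = count_kgrams(codes, k)
        assert sum(counts.values()) == len(codes) - k + 1

    @settings(deadline=None)
    @given(codes_list)
    def test_within_window_order_is_irrelevant(self, codes):
        # typing by unordered multiset: reversing the sequence preserves
        # the multiset of window types
        assert count_kgrams(codes, 3) == count_kgrams(codes[::-1], 3)
        assert count_kgrams(codes, 2) == count_kgrams(codes[::-1], 2)


class TestPseudoFrequency:
    @pytest.mark.parametrize(
        "count,windows,expected",
        [(4, 4, 1.0), (2, 4, 0.6), (0, 9, 0.1)],
    )
    def test_values(self, count, windows, expected):
        assert pseudo_frequency(count, windows) == pytest.approx(expected)

    def test_negative_windows_raise(self):
        with pytest.raises(ValueError):
            pseudo_frequency(0, -1)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_always_in_unit_interval(self, count, windows):
        if count > windows:
            count, windows = windows, count
        f = pseudo_frequency(count, windows)
        assert 0 < f <= 1


class TestMITerms:
    def test_mi2_unity_inputs(self):
        assert mi2(1.0, 1.0, 1.0) == 0.0

    def test_mi2_independence_factorization(self):
        assert mi2(0.12, 0.4, 0.3) == pytest.approx(0.0, abs=1e-15)

    def test_mi2_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mi2(0.0, 0.5, 0.5)

    def test_homopolymer_present_type_mi_terms_zero(self):
        # for the all-C0 types every frequency ratio is 1, so the MI and
        # entropy terms vanish exactly; types with absent categories keep
        # pseudocount ratios != 1 and need not vanish
        v = mmi_vector("A" * 10)
        assert v[0] == pytest.approx(0.0, abs=1e-15)  # mi3 (C0,C0,C0)
        assert v[84] == pytest.approx(0.0, abs=1e-15)  # mi2 (C0,C0)

    def test_mi3_matches_oracle_on_short_sequence(self):
        got = mmi_vector("ACDA")
        expected = oracle_mmi_vector("ACDA")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_mi3_finite_when_three_gram_count_zero(self):
        v = mmi_vector("AAAAACCCCC")  # most 3-gram types absent
        assert np.isfinite(v).all()

    def test_role_average_mode_differs_but_is_finite(self):
        seq = "ACDEFGHIKL" * 3
        v_avg = mmi_vector(seq, role_mode="average")
        assert np.isfinite(v_avg).all()
        with pytest.raises(ValueError):
            mmi_vector(seq, role_mode="bogus")


class TestMMIVector:
    def test_length_and_finiteness(self, random_sequence):
        v = mmi_vector(random_sequence(80))
        assert v.shape == (119,)
        assert np.isfinite(v).all()

    def test_homopolymer_frequency_tail(self):
        v = mmi_vector("A" * 10)
        expected_tail = [1.0] + [1 / 11] * 6
        assert v[112:] == pytest.approx(expected_tail, abs=1e-15)

    def test_deterministic(self, random_sequence):
        seq = random_sequence(120)
        assert np.array_equal(mmi_vector(seq), mmi_vector(seq))

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            mmi_vector("AC")

    def test_oracle_equivalence_on_random_sequences(self, rng, random_sequence):
        for _ in range(200):
            seq = random_sequence(int(rng.integers(3, 61)))
            assert mmi_vector(seq) == pytest.approx(
                oracle_mmi_vector(seq), abs=1e-12
            ), seq

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet=RESIDUES, min_size=3, max_size=2000))
    def test_entries_finite_for_any_sequence(self, seq):
        v = mmi_vector(seq)
        assert np.isfinite(v).all()
        assert ((v[112:] > 0) & (v[112:] <= 1)).all()


class TestPairAndEncoder:
    def test_pair_is_concatenation(self, random_sequence):
        a, b = random_sequence(60), random_sequence(90)
        pair = mmi_pair(a, b)
        assert pair.shape == (238,)
        assert np.array_equal(pair[:119], mmi_vector(a))
        assert np.array_equal(pair[119:], mmi_vector(b))
        swapped = mmi_pair(b, a)
        assert np.array_equal(swapped, np.concatenate([pair[119:], pair[:119]]))

    def test_encoder_transform_and_names(self, random_sequence):
        seqs = [random_sequence(50) for _ in range(4)]
        enc = MMIEncoder().fit(seqs)
        X = enc.transform(seqs)
        assert X.shape == (4, 119)
        names = enc.get_feature_names_out()
        assert len(names) == 119
        assert names[0] == "mi3_C0C0C0"
        assert names[84] == "mi2_C0C0"
        assert names[-1] == "f_C6"
        assert len(set(names)) == 119

    def test_encoder_params_round_trip(self):
        enc = MMIEncoder(role_mode="average")
        assert MMIEncoder(**enc.get_params()).role_mode == "average"


def test_feature_names_match_vector_layout():
    names = mmi_feature_names()
    assert len(names) == 119
    assert sum(n.startswith("mi3_") for n in names) == 84
    assert sum(n.startswith("mi2_") for n in names) == 28
    assert sum(n.startswith("f_") for n in names) == 7
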