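import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aavec import AlphabetConfig, ProteinSequence
from aavec.encoding import (
    content_ratios,
    delta,
    delta_closed_form,
    encode,
    position_ratios,
    tally,
    transition_probabilities,
    verify_delta_identity,
)
from aavec.fixtures import random_sequence

ALPHABET = AlphabetConfig()
L, A = ALPHABET.index("L"), ALPHABET.index("A")

residue_strings = st.text(alphabet=ALPHABET.residue_order, min_size=2, max_size=400)


def seq(residues: str) -> ProteinSequence:
    return ProteinSequence("test", residues)


class TestTally:
    def test_llal_hand_enumeration(self):
        # residues L L A L -> pairs LL, LA, AL; positions of L: 1,2,4; of A: 3
        c = tally(seq("LLAL"), ALPHABET)
        assert c.occurrence_counts[L] == 3
        assert c.occurrence_counts[A] == 1
        assert c.occurrence_counts.sum() == 4
        assert c.pair_counts[L, L] == 1
        assert c.pair_counts[L, A] == 1
        assert c.pair_counts[A, L] == 1
        assert c.pair_counts.sum() == 3
        assert c.position_sums[L] == 1 + 2 + 4
        assert c.position_sums[A] == 3
        assert c.first_residue_index == L
        assert c.last_residue_index == L

    def test_smallest_legal_input(self):
        c = tally(seq("AA"), ALPHABET)
        assert c.occurrence_counts[A] == 2
        assert c.pair_counts[A, A] == 1
        assert c.position_sums[A] == 3

    @given(residue_strings)
    @settings(max_examples=200, deadline=None)
    def test_count_identities(self, residues):
        s = seq(residues)
        c = tally(s, ALPHABET)
        n = s.length
        assert c.occurrence_counts.sum() == n
        assert c.pair_counts.sum() == n - 1
        assert c.position_sums.sum() == n * (n + 1) // 2

    @given(residue_strings)
    @settings(max_examples=200, deadline=None)
    def test_pair_count_marginals_exact(self, residues):
        # row sums: n_i, minus one for the last residue's row;
        # column sums: n_j, minus one for the first residue's column
        s = seq(residues)
        c = tally(s, ALPHABET)
        expected_rows = c.occurrence_counts.copy()
        expected_rows[c.last_residue_index] -= 1
        assert (c.pair_counts.sum(axis=1) == expected_rows).all()
        expected_cols = c.occurrence_counts.copy()
        expected_cols[c.first_residue_index] -= 1
        assert (c.pair_counts.sum(axis=0) == expected_cols).all()


class TestTransitionProbabilities:
    def test_llal_hand_application(self):
        # L ends the sequence, so its denominator is n_L - 1 = 2
        p = transition_probabilities(tally(seq("LLAL"), ALPHABET)).reshape(20, 20)
        assert p[L, L] == 0.5
        assert p[L, A] == 0.5
        assert p[A, L] == 1.0
        assert np.count_nonzero(p) == 3

    def test_absent_residue_row_is_zero(self):
        p = transition_probabilities(tally(seq("LLAL"), ALPHABET)).reshape(20, 20)
        W = ALPHABET.index("W")
        assert (p[W] == 0).all()

    def test_aa_last_residue_branch(self):
        p = transition_probabilities(tally(seq("AA"), ALPHABET)).reshape(20, 20)
        assert p[A, A] == 1.0

    def test_last_residue_occurs_once_row_is_zero(self):
        # W occurs once, at the end: numerator and denominator both 0
        p = transition_probabilities(tally(seq("AAW"), ALPHABET)).reshape(20, 20)
        W = ALPHABET.index("W")
        assert (p[W] == 0).all()

    @given(residue_strings)
    @settings(max_examples=200, deadline=None)
    def test_rows_sum_to_one_or_zero(self, residues):
        c = tally(seq(residues), ALPHABET)
        p = transition_probabilities(c).reshape(20, 20)
        sums = p.sum(axis=1)
        denom = c.occurrence_counts.copy()
        denom[c.last_residue_index] -= 1
        defined = denom > 0
        assert np.abs(sums[defined] - 1.0).max() <= 1e-12
        assert (sums[~defined] == 0).all()
        assert (p >= 0).all() and (p <= 1).all()


class TestRatioBlocks:
    def test_content_llal(self):
        c = content_ratios(tally(seq("LLAL"), ALPHABET))
        assert c[L] == 0.75
        assert c[A] == 0.25
        assert c.sum() == 1.0

    def test_position_llal(self):
        d = position_ratios(tally(seq("LLAL"), ALPHABET))
        assert d[L] == 0.7
        assert d[A] == 0.3

    def test_homopolymer(self):
        c = content_ratios(tally(seq("GGGGG"), ALPHABET))
        d = position_ratios(tally(seq("GGGGG"), ALPHABET))
        G = ALPHABET.index("G")
        assert c[G] == 1.0
        assert d[G] == 1.0

    @given(residue_strings)
    @settings(max_examples=200, deadline=None)
    def test_both_blocks_normalised(self, residues):
        c = tally(seq(residues), ALPHABET)
        assert abs(content_ratios(c).sum() - 1.0) <= 1e-12
        assert abs(position_ratios(c).sum() - 1.0) <= 1e-12


class TestEncode:
    def test_llal_full_vector(self):
        v = encode(seq("LLAL"), ALPHABET)
        assert v.dimension == 440
        assert v.blocks == ("P", "C", "D")
        # exactly the seven hand-derived nonzero entries
        expected = {
            ("P", L, L): 0.5,
            ("P", L, A): 0.5,
            ("P", A, L): 1.0,
            ("C", L, None): 0.75,
            ("C", A, None): 0.25,
            ("D", L, None): 0.7,
            ("D", A, None): 0.3,
        }
        assert np.count_nonzero(v.values) == 7
        for (block, i, j), val in expected.items():
            got = v.block(block)[i, j] if block == "P" else v.block(block)[i]
            assert got == val

    def test_single_block_projection(self):
        v = encode(seq("LLAL"), ALPHABET, blocks={"C"})
        np.testing.assert_array_equal(
            v.values, content_ratios(tally(seq("LLAL"), ALPHABET))
        )
        assert v.dimension == 20

    @pytest.mark.parametrize(
        "blocks,dim", [("PCD", 440), ("P", 400), ("CD", 40), ("D", 20)]
    )
    def test_block_dimensions(self, blocks, dim):
        assert encode(seq("LLAL"), ALPHABET, blocks=set(blocks)).dimension == dim

    def test_block_order_preserved_regardless_of_selection_order(self):
        a = encode(seq("LLAL"), ALPHABET, blocks=["D", "C"])
        b = encode(seq("LLAL"), ALPHABET, blocks=["C", "D"])
        assert a.blocks == b.blocks == ("C", "D")
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_block_selection_rejected(self):
        with pytest.raises(ValueError):
            encode(seq("LLAL"), ALPHABET, blocks=set())

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError):
            encode(seq("LLAL"), ALPHABET, blocks={"Q"})

    def test_encoding_ignores_label(self):
        a = encode(ProteinSequence("x", "LLAL"), ALPHABET)
        b = encode(ProteinSequence("y", "LLAL"), ALPHABET)
        np.testing.assert_array_equal(a.values, b.values)

    def test_identical_tallies_give_identical_vectors(self):
        # distinct strings with equal occurrence, pair, and position tallies
        a = encode(seq("AACCAC"), ALPHABET)
        b = encode(seq("ACAACC"), ALPHABET)
        assert "AACCAC" != "ACAACC"
        np.testing.assert_array_equal(a.values, b.values)

    @given(residue_strings)
    @settings(max_examples=100, deadline=None)
    def test_all_entries_in_unit_interval(self, residues):
        v = encode(seq(residues), ALPHABET)
        assert np.isfinite(v.values).all()
        assert (v.values >= 0).all() and (v.values <= 1).all()


class TestDeltaIdentity:
    def test_llal_direct_sum(self):
        v = encode(seq("LLAL"), ALPHABET)
        assert delta(v, L) == pytest.approx(0.75 * 0.5 + 0.25 * 1.0, abs=1e-15)

    def test_llal_closed_form_first_residue_branch(self):
        # L is both first and last residue: C_L - 1/N + P_{L,L}/N
        v = encode(seq("LLAL"), ALPHABET)
        assert delta_closed_form(v, L) == pytest.approx(
            0.75 - 0.25 + 0.5 / 4, abs=1e-15
        )
        assert delta(v, L) == pytest.approx(0.625, abs=1e-15)

    def test_absent_residue(self):
        v = encode(seq("LLAL"), ALPHABET)
        W = ALPHABET.index("W")
        assert delta(v, W) == 0.0
        assert delta_closed_form(v, W) == 0.0

    def test_out_of_range_index_rejected(self):
        v = encode(seq("LLAL"), ALPHABET)
        with pytest.raises(ValueError):
            delta(v, 20)
        with pytest.raises(ValueError):
            delta(v, -1)

    def test_requires_p_and_c_blocks(self):
        v = encode(seq("LLAL"), ALPHABET, blocks={"C", "D"})
        with pytest.raises(ValueError):
            delta(v, 0)

    def test_last_residue_occurs_once_reduced_form(self):
        # last residue W unique -> its transition row is zero and the
        # identity reduces to C_j (minus 1/N on the first-residue column)
        s = seq("AALAW")
        assert verify_delta_identity(s, ALPHABET).max() <= 1e-12
        v = encode(s, ALPHABET)
        W = ALPHABET.index("W")
        assert (v.block("P")[W] == 0).all()
        assert delta(v, A) == pytest.approx(v.block("C")[A] - 1 / 5, abs=1e-15)
        assert delta(v, L) == pytest.approx(v.block("C")[L], abs=1e-15)

    @given(residue_strings)
    @settings(max_examples=200, deadline=None)
    def test_identity_holds_for_random_sequences(self, residues):
        assert verify_delta_identity(seq(residues), ALPHABET).max() <= 1e-12

    def test_identity_holds_for_long_sequences(self, rng):
        for n in (1000, 5000):
            s = random_sequence(rng, n, ALPHABET)
            assert verify_delta_identity(s, ALPHABET).max() <= 1e-12
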