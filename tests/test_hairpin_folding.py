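"""Folding backends, MFEI, dinucleotide shuffling and the randomization test."""

import itertools
import random

import pytest

from premirseq.hairpin_folding import (
    MIN_HAIRPIN_LOOP, PAIR_ENERGY, FoldError, UndefinedMFEIError,
    count_terminal_loops, dinucleotide_counts, dinucleotide_shuffle, fold,
    gc_percent, mfei, pairs_from_dotbracket, randomization_p, score_structure,
)


def _can_pair(a, b):
    return (a, b) in PAIR_ENERGY


def all_nested_structures(s, i, j):
    """Exhaustive enumeration of pseudoknot-free structures on s[i..j]
    (independent oracle for the builtin DP)."""
    if j - i < MIN_HAIRPIN_LOOP + 1:
        yield frozenset()
        return
    yield from all_nested_structures(s, i + 1, j)
    for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
        if _can_pair(s[i], s[k]):
            for left in all_nested_structures(s, i + 1, k - 1):
                for right in all_nested_structures(s, k + 1, j):
                    yield left | right | frozenset([(i, k)])


class TestFold:
    def test_homopolymer_has_no_structure(self):
        st = fold("A" * 20, backend="builtin")
        assert st.dotbracket == "." * 20
        assert st.mfe == 0
        st2 = fold("A" * 20, backend="vienna")
        assert st2.mfe == 0

    @pytest.mark.parametrize("backend", ["builtin", "vienna"])
    def test_designed_stem_folds(self, backend):
        st = fold("GGGGAAAACCCC", backend=backend)
        assert st.mfe < 0
        assert len(st.pairs) >= 3
        assert st.n_loops == 1
        # hairpin loop length >= 3 everywhere
        for i, j in st.pairs:
            assert j - i - 1 >= MIN_HAIRPIN_LOOP

    def test_invalid_characters_rejected(self):
        with pytest.raises(FoldError):
            fold("ACGTXACGT" * 5)

    def test_rna_input_accepted(self):
        st = fold("GGGGAAAACCCC".replace("T", "U"), backend="builtin")
        assert st.mfe < 0

    def test_no_pseudoknots(self):
        rng = random.Random(8)
        for _ in range(10):
            s = "".join(rng.choice("ACGT") for _ in range(60))
            st = fold(s, backend="vienna")
            stack = []
            for c in st.dotbracket:  # balanced nesting is pseudoknot-freedom
                if c == "(":
                    stack.append(c)
                elif c == ")":
                    stack.pop()
            assert not stack

    def test_builtin_dp_equals_exhaustive_enumeration(self):
        """The builtin DP is an exact optimizer of score_structure over all
        nested structures on short sequences."""
        rng = random.Random(42)
        for _ in range(12):
            n = rng.choice([10, 12, 14, 16, 18])
            s = "".join(rng.choice("ACGT") for _ in range(n))
            best = min(
                score_structure(s, st) for st in all_nested_structures(s, 0, n - 1)
            )
            got = fold(s, backend="builtin")
            assert got.mfe == best
            assert score_structure(s, got.pairs) == best


class TestMFEI:
    def test_arithmetic(self):
        assert mfei(-21.0, 50, 50.0) == pytest.approx(-0.84)

    def test_zero_mfe(self):
        assert mfei(0.0, 50, 50.0) == 0.0

    def test_linear_in_mfe(self):
        assert mfei(-10, 80, 40) == pytest.approx(2 * mfei(-5, 80, 40))

    def test_gc_zero_is_explicit_error(self):
        with pytest.raises(UndefinedMFEIError):
            mfei(-5.0, 50, 0.0)

    def test_gc_percent_scale(self):
        assert gc_percent("GGCC") == 100.0
        assert gc_percent("GCAT") == 50.0


class TestDinucleotideShuffle:
    def test_homopolymer_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", 0) == "AAAA"

    def test_counts_preserved_random_sequences(self):
        rng = random.Random(10)
        for _ in range(50):
            n = rng.randrange(10, 120)
            s = "".join(rng.choice("ACGT") for _ in range(n))
            sh = dinucleotide_shuffle(s, rng.randrange(1 << 30))
            assert dinucleotide_counts(sh) == dinucleotide_counts(s)
            assert sh[0] == s[0] and sh[-1] == s[-1]
            assert sorted(sh) == sorted(s)

    def test_exhaustive_on_6mers(self):
        rng = random.Random(11)
        for tup in itertools.product("ACGT", repeat=6):
            s = "".join(tup)
            sh = dinucleotide_shuffle(s, rng.randrange(1 << 30))
            assert dinucleotide_counts(sh) == dinucleotide_counts(s)

    def test_shuffles_vary(self):
        # a mixed-composition sequence admits many Eulerian arrangements
        rng = random.Random(3)
        s = "".join(rng.choice("ACGT") for _ in range(40))
        outs = {dinucleotide_shuffle(s, rng.randrange(1 << 30)) for _ in range(50)}
        assert len(outs) >= 2

    def test_periodic_sequence_has_unique_arrangement(self):
        # every vertex of ACGT-repeat has a single out-neighbor: the walk,
        # hence the shuffle, is forced
        s = "ACGT" * 5
        assert dinucleotide_shuffle(s, 1) == s


class TestRandomizationP:
    def test_deterministic_under_seed(self):
        s = "GGGCUUCGGCCAGUAACGUUAGCCGGAAGCCC".replace("U", "T")
        a = randomization_p(s, n_shuffles=49, rng_seed=7, backend="builtin")
        b = randomization_p(s, n_shuffles=49, rng_seed=7, backend="builtin")
        assert a.p_value == b.p_value

    def test_designed_stem_is_significant(self):
        """A perfect 25-bp stem-loop is far below its dinucleotide null."""
        rng = random.Random(5)
        stem = "".join(rng.choice("ACGT") for _ in range(25))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        hairpin = stem + "CAACAA" + "".join(comp[b] for b in reversed(stem))
        res = randomization_p(hairpin, n_shuffles=999, rng_seed=1)
        assert res.p_value <= 0.01

    def test_unstructured_sequence_near_half(self):
        """A low-complexity unpairable-ish sequence behaves like its own
        null population."""
        rng = random.Random(6)
        s = "".join(rng.choice("ACC") for _ in range(60))
        res = randomization_p(s, n_shuffles=199, rng_seed=2, backend="builtin")
        assert 0.2 <= res.p_value <= 1.0

    def test_add_one_estimator_bounds(self):
        res = randomization_p("GGGGAAAACCCC" * 3, n_shuffles=19, rng_seed=3,
                              backend="builtin")
        assert 1 / 20 <= res.p_value <= 1.0


def test_terminal_loop_count_from_dotbracket():
    pairs = pairs_from_dotbracket("((((...)))).((...))")
    assert count_terminal_loops(pairs) == 2
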