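import numpy as np
import pytest

from alnconf.aligner import (
    HEAD,
    TAIL,
    Profile,
    ScoringScheme,
    align_profiles,
    load_substitution_matrix,
    pairwise_align,
    progressive_align,
)
from alnconf.guide_tree import DistanceMatrix, nj, p_distance
from alnconf.msa import Msa, Sequence, column_keys
from conftest import random_sequences
from oracles import count_gap_openings, enumerate_alignment_score


def _random_pair(rng, max_len=6, alphabet="ARND"):
    def one():
        L = int(rng.integers(1, max_len + 1))
        return "".join(alphabet[c] for c in rng.integers(0, len(alphabet), size=L))

    return one(), one()


class TestScoringScheme:
    def test_blosum62_identity_score(self):
        m = load_substitution_matrix("BLOSUM62")
        assert m[0, 0] == 4  # s(A, A)

    def test_x_scored_zero(self):
        m = load_substitution_matrix("BLOSUM62")
        assert np.all(m[20, :] == 0) and np.all(m[:, 20] == 0)

    def test_invalid_gap_params(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=0.1, gap_extend=0.5)

    def test_effective_penalties_scale_with_matrix(self):
        s = ScoringScheme()
        assert s.effective_open == pytest.approx(1.53 * s.matrix_scale)
        assert s.matrix_scale == pytest.approx(5.8)  # mean BLOSUM62 diagonal


class TestPairwiseAlignment:
    def test_identity_alignment(self):
        s = ScoringScheme()
        msa, score = pairwise_align(Sequence("a", "AAA"), Sequence("b", "AAA"), s)
        assert msa.rows == ("AAA", "AAA")
        assert score == pytest.approx(12.0)  # 3 * s(A,A)

    def test_dp_equals_enumeration(self, unit_scheme):
        rng = np.random.default_rng(17)
        for _ in range(200):
            s1, s2 = _random_pair(rng)
            _, got = pairwise_align(Sequence("a", s1), Sequence("b", s2), unit_scheme)
            want = enumerate_alignment_score(s1, s2, 1.0, -1.0, 2.0, 0.5)
            assert got == pytest.approx(want), (s1, s2)

    def test_reversed_same_score(self, unit_scheme):
        rng = np.random.default_rng(18)
        for _ in range(100):
            s1, s2 = _random_pair(rng)
            a, b = Sequence("a", s1), Sequence("b", s2)
            _, fwd = pairwise_align(a, b, unit_scheme)
            _, rev = pairwise_align(a, b, unit_scheme, reversed=True)
            assert fwd == pytest.approx(rev)

    def test_residue_conservation(self, unit_scheme):
        rng = np.random.default_rng(19)
        for _ in range(50):
            s1, s2 = _random_pair(rng, max_len=12, alphabet="ARNDCQEG")
            msa, _ = pairwise_align(Sequence("a", s1), Sequence("b", s2), unit_scheme)
            assert msa.rows[0].replace("-", "") == s1
            assert msa.rows[1].replace("-", "") == s2

    def test_gap_open_monotonicity(self, unit_matrix_path):
        """Raising gap_open never increases the number of gap openings."""
        rng = np.random.default_rng(20)
        for _ in range(30):
            s1, s2 = _random_pair(rng, max_len=10, alphabet="ARND")
            openings = []
            for go in (0.5, 1.0, 2.0, 4.0, 8.0):
                scheme = ScoringScheme(str(unit_matrix_path), go, 0.25)
                msa, _ = pairwise_align(Sequence("a", s1), Sequence("b", s2), scheme)
                openings.append(count_gap_openings(msa))
            assert all(x >= y for x, y in zip(openings, openings[1:]))

    def test_free_ends_mode(self, unit_matrix_path):
        scheme = ScoringScheme(
            str(unit_matrix_path), 2.0, 0.5, terminal_gap_policy="free_ends"
        )
        msa, score = pairwise_align(Sequence("a", "RRACDRR"), Sequence("b", "ACD"), scheme)
        assert score == pytest.approx(3.0)  # terminal gaps are free
        assert msa.rows[1] == "--ACD--"


class TestProfileAlignment:
    def test_identical_profiles_gapless(self, unit_scheme):
        a = Profile.from_msa(Msa(["a", "b"], ["ACD", "ACD"]))
        b = Profile.from_msa(Msa(["c"], ["ACD"]))
        merged, _ = align_profiles(a, b, unit_scheme)
        assert merged.to_msa().length == 3

    def test_overlapping_ids_rejected(self, unit_scheme):
        a = Profile.from_msa(Msa(["a"], ["ACD"]))
        b = Profile.from_msa(Msa(["a"], ["ACD"]))
        with pytest.raises(ValueError, match="share"):
            align_profiles(a, b, unit_scheme)

    def test_profile_column_score_is_mean_over_cross_pairs(self, unit_scheme):
        from alnconf.aligner import profile_score_matrix

        a = Profile.from_msa(Msa(["a", "b"], ["A", "R"]))
        b = Profile.from_msa(Msa(["c", "d"], ["A", "-"], permissive=True))
        # cross pairs: (A,A)=1, (R,A)=-1, (A,-)=0, (R,-)=0 -> mean over 4 = 0
        S = profile_score_matrix(a, b, unit_scheme)
        assert S[0, 0] == pytest.approx(0.0)


class TestProgressiveAlignment:
    def _chain_tree(self, ids):
        d = np.ones((len(ids), len(ids))) - np.eye(len(ids))
        return nj(DistanceMatrix(tuple(ids), d))

    def test_identical_sequences_gapless(self, unit_scheme):
        seqs = [Sequence(i, "ACDEF") for i in "abc"]
        tree = self._chain_tree("abc")
        for orient in ([0, 0], [1, 1], [0, 1]):
            msa = progressive_align(seqs, tree, unit_scheme, orient)
            assert msa.rows == ("ACDEF",) * 3

    def test_deterministic(self, unit_scheme):
        rng = np.random.default_rng(23)
        seqs = random_sequences(rng, 5, 20)
        tree = self._chain_tree([s.id for s in seqs])
        m1 = progressive_align(seqs, tree, unit_scheme)
        m2 = progressive_align(seqs, tree, unit_scheme)
        assert m1 == m2

    def test_row_order_is_input_order(self, unit_scheme):
        rng = np.random.default_rng(24)
        seqs = random_sequences(rng, 5, 15)
        tree = self._chain_tree([s.id for s in seqs])
        msa = progressive_align(seqs, tree, unit_scheme)
        assert msa.ids == tuple(s.id for s in seqs)

    def test_residue_conservation(self, unit_scheme):
        rng = np.random.default_rng(25)
        seqs = random_sequences(rng, 6, 25)
        tree = self._chain_tree([s.id for s in seqs])
        for orient in (None, [1] * 5):
            msa = progressive_align(seqs, tree, unit_scheme, orient)
            assert {s.id: s.residues for s in msa.sequences()} == {
                s.id: s.residues for s in seqs
            }

    def test_orientation_length_checked(self, unit_scheme):
        seqs = [Sequence(i, "ACDEF") for i in "abc"]
        tree = self._chain_tree("abc")
        with pytest.raises(ValueError, match="orientation"):
            progressive_align(seqs, tree, unit_scheme, [0])

    def test_leaf_mismatch_rejected(self, unit_scheme):
        seqs = [Sequence(i, "ACDEF") for i in "abc"]
        tree = self._chain_tree("abd")
        with pytest.raises(ValueError, match="tree leaves"):
            progressive_align(seqs, tree, unit_scheme)


class TestHeadTail:
    def _find_ambiguous_pair(self, unit_scheme, rng):
        """A sequence pair with co-optimal alignments where HEAD and TAIL
        place gaps differently (verified by brute-force score equality)."""
        for _ in range(500):
            L1, L2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            s1 = "".join("ARND"[c] for c in rng.integers(0, 4, size=L1))
            s2 = "".join("ARND"[c] for c in rng.integers(0, 4, size=L2))
            a, b = Sequence("a", s1), Sequence("b", s2)
            mh, sh = pairwise_align(a, b, unit_scheme)
            mt, st = pairwise_align(a, b, unit_scheme, reversed=True)
            if mh != mt:
                return a, b, mh, sh, mt, st
        pytest.fail("no co-optimal pair found")

    def test_head_and_tail_are_equal_score_co_optima(self, unit_scheme):
        rng = np.random.default_rng(29)
        a, b, mh, sh, mt, st = self._find_ambiguous_pair(unit_scheme, rng)
        assert sh == pytest.approx(st)
        assert column_keys(mh) != column_keys(mt)
        want = enumerate_alignment_score(a.residues, b.residues, 1.0, -1.0, 2.0, 0.5)
        assert sh == pytest.approx(want)

    def test_all_head_vs_all_tail_msa(self, unit_scheme):
        """On an ambiguous trio, all-HEAD and all-TAIL give different MSAs
        of equal DP behavior (both conserve residues)."""
        seqs = [Sequence("a", "CAC"), Sequence("b", "CC"), Sequence("c", "CACC")]
        d = np.ones((3, 3)) - np.eye(3)
        tree = nj(DistanceMatrix(("a", "b", "c"), d))
        mh = progressive_align(seqs, tree, unit_scheme, [HEAD, HEAD])
        mt = progressive_align(seqs, tree, unit_scheme, [TAIL, TAIL])
        assert column_keys(mh) != column_keys(mt)
        for m in (mh, mt):
            assert {s.id: s.residues for s in m.sequences()} == {
                s.id: s.residues for s in seqs
            }
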