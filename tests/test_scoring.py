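import numpy as np
import pytest

from alnconf.msa import Msa, Sequence, column_keys
from alnconf.scoring import (
    column_score,
    mask_msa,
    pair_and_spc_scores,
    residue_and_sequence_scores,
    score_report,
)
from oracles import brute_force_cs, brute_force_pair_scores


def _toy_ref():
    return Msa(["a", "b", "c"], ["AC-D", "ACE-", "AC-D"])


class TestColumnScore:
    def test_copies_of_ref_all_one(self):
        ref = _toy_ref()
        cs = column_score(ref, [ref, ref, ref])
        assert np.all(cs == 1.0)

    def test_frequency_arithmetic(self):
        ref = Msa(["a", "b"], ["AC", "AC"])
        shifted = Msa(["a", "b"], ["AC-", "A-C"])
        # column 1 of ref (ordinals 2,2) appears only in ref-like members
        cs = column_score(ref, [ref, shifted, shifted, shifted])
        assert cs[0] == 1.0  # (1,1) present in all four
        assert cs[1] == 0.25

    def test_sequence_mismatch_rejected(self):
        ref = _toy_ref()
        other = Msa(["a", "b", "c"], ["ARD", "ACE", "ACD"])
        with pytest.raises(ValueError):
            column_score(ref, [other])

    def test_matches_brute_force(self, small_ensemble):
        ref, alts = small_ensemble
        fast = column_score(ref, alts)
        slow = brute_force_cs(ref, alts.alternatives)
        assert np.array_equal(fast, slow)


class TestPairAndSpc:
    def test_copies_all_one(self):
        ref = _toy_ref()
        pair_scores, spc, fallback = pair_and_spc_scores(ref, [ref, ref])
        assert all(v == 1.0 for v in pair_scores.values())
        assert np.all(spc == 1.0)

    def test_half_ensemble_pair(self):
        ref = Msa(["a", "b"], ["AC", "AC"])
        shifted = Msa(["a", "b"], ["AC-", "A-C"])
        pair_scores, spc, _ = pair_and_spc_scores(ref, [ref, shifted])
        assert pair_scores[(("a", 2), ("b", 2))] == 0.5

    def test_matches_brute_force(self, small_ensemble):
        ref, alts = small_ensemble
        pair_scores, _, _ = pair_and_spc_scores(ref, alts)
        slow = brute_force_pair_scores(ref, alts.alternatives)
        assert pair_scores == slow

    def test_spc_ge_cs(self, small_ensemble):
        ref, alts = small_ensemble
        cs = column_score(ref, alts)
        _, spc, _ = pair_and_spc_scores(ref, alts)
        assert np.all(spc >= cs - 1e-12)

    def test_single_residue_column_falls_back_to_cs(self):
        ref = Msa(["a", "b"], ["AC-", "A-C"])
        alt = Msa(["a", "b"], ["AC-", "A-C"])
        _, spc, fallback = pair_and_spc_scores(ref, [alt])
        assert fallback == [1, 2]
        assert np.all(spc == 1.0)


class TestResidueAndSequenceScores:
    def test_uniform_pairs_give_ones(self):
        ref = _toy_ref()
        pair_scores, spc, _ = pair_and_spc_scores(ref, [ref])
        res, seq, fb = residue_and_sequence_scores(pair_scores, ref, np.ones(4))
        assert all(v == 1.0 for v in res.values())
        assert all(v == 1.0 for v in seq.values())

    def test_mean_of_two_pairs(self):
        # residue (a,1) participates in exactly two pairs scored 0.2 and 0.6
        ref = Msa(["a", "b", "c"], ["A", "C", "D"])
        pair_scores = {
            (("a", 1), ("b", 1)): 0.2,
            (("a", 1), ("c", 1)): 0.6,
            (("b", 1), ("c", 1)): 1.0,
        }
        res, _, _ = residue_and_sequence_scores(pair_scores, ref, np.ones(1))
        assert res[("a", 1)] == pytest.approx(0.4)

    def test_length_weighted_identity(self, small_ensemble):
        """mean(sequence scores weighted by length) == mean(residue scores)."""
        ref, alts = small_ensemble
        report = score_report(ref, alts)
        lengths = {s.id: len(s.residues) for s in ref.sequences()}
        weighted = sum(
            report.sequence_scores[sid] * lengths[sid] for sid in ref.ids
        ) / sum(lengths.values())
        assert weighted == pytest.approx(np.mean(list(report.residue_scores.values())))

    def test_lonely_residue_falls_back_to_cs(self):
        ref = Msa(["a", "b"], ["AC-", "A-C"])
        pair_scores = {(("a", 1), ("b", 1)): 1.0}
        cs = np.array([1.0, 0.25, 0.5])
        res, _, fb = residue_and_sequence_scores(pair_scores, ref, cs)
        assert res[("a", 2)] == 0.25  # column 2's cs
        assert res[("b", 2)] == 0.5  # column 3's cs
        assert set(fb) == {("a", 2), ("b", 2)}


class TestScoreReport:
    def test_all_scores_in_unit_interval(self, small_ensemble):
        ref, alts = small_ensemble
        report = score_report(ref, alts)
        for arr in (report.cs, report.spc):
            assert np.all((0 <= arr) & (arr <= 1))
        for d in (report.pair_scores, report.residue_scores, report.sequence_scores):
            assert all(0 <= v <= 1 for v in d.values())

    def test_covers_every_column_and_residue(self, small_ensemble):
        ref, alts = small_ensemble
        report = score_report(ref, alts)
        assert report.cs.size == ref.length
        n_residues = sum(len(s.residues) for s in ref.sequences())
        assert len(report.residue_scores) == n_residues
        assert set(report.sequence_scores) == set(ref.ids)

    def test_adding_ref_copy_never_decreases_scores(self, small_ensemble):
        ref, alts = small_ensemble
        before = score_report(ref, alts)
        after = score_report(ref, alts.alternatives + [ref])
        n0, n1 = before.n_alternatives, after.n_alternatives
        assert np.all(after.cs >= before.cs * n0 / n1 - 1e-12)
        assert np.all(after.cs >= before.cs - 1e-12)
        assert np.all(after.spc >= before.spc - 1e-12)
        for p, v in before.pair_scores.items():
            assert after.pair_scores[p] >= v - 1e-12

    def test_cs_at_least_one_over_n_when_ref_in_ensemble(self, small_ensemble):
        ref, alts = small_ensemble
        report = score_report(ref, alts.alternatives + [ref])
        assert np.all(report.cs >= 1 / report.n_alternatives - 1e-12)


class TestMask:
    def _report(self, cs):
        ref = _toy_ref()
        report = score_report(ref, [ref])
        report.cs = np.asarray(cs, dtype=float)
        return ref, report

    def test_cutoff_zero_identity(self):
        ref, report = self._report([0.1, 0.2, 0.3, 0.4])
        assert mask_msa(ref, report, 0.0, 0.0) == ref

    def test_cutoff_one_drops_imperfect(self):
        ref, report = self._report([1.0, 0.99, 1.0, 0.5])
        out = mask_msa(ref, report, 1.0, 0.0)
        assert out.length == 2

    def test_surviving_column_count(self):
        rng = np.random.default_rng(41)
        ref, report = self._report(rng.random(4))
        cutoff = 0.5
        out = mask_msa(ref, report, cutoff, 0.0)
        assert out.length == int((report.cs >= cutoff).sum())

    def test_mask_residues_mode(self, small_ensemble):
        from alnconf.msa import keys_matrix, GAP

        ref, alts = small_ensemble
        report = score_report(ref, alts)
        out = mask_msa(ref, report, mode="mask_residues", residue_cutoff=1.0)
        km = keys_matrix(ref)
        for i, sid in enumerate(ref.ids):
            for col in range(ref.length):
                o = int(km[i, col])
                if o == GAP:
                    assert out.rows[i][col] == "-"
                elif report.residue_scores[(sid, o)] < 1.0:
                    assert out.rows[i][col] == "X"
                else:
                    assert out.rows[i][col] == ref.rows[i][col]

    def test_bad_cutoff(self):
        ref, report = self._report([1, 1, 1, 1])
        with pytest.raises(ValueError):
            mask_msa(ref, report, 1.5, 0.0)
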