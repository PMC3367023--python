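import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermobin.homology import TaxonAssignment
from thermobin.io import Lineage, SequenceRecord
from thermobin.synthetic import revcomp
from thermobin.tetra import (
    REVCOMP_INDEX,
    BinCorrelationStats,
    bin_internal_stats,
    correlation_matrix,
    fit_pca,
    pearson_r,
    propagate_mates,
    recruit_unassigned,
    tetra_freqs,
)


def _word_index(word):
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    i = 0
    for c in word:
        i = (i << 2) | code[c]
    return i


class TestTetraFreqs:
    def test_homopolymer_counts_both_strands(self):
        freqs, n = tetra_freqs("AAAAAA")
        assert n == 6
        assert freqs[_word_index("AAAA")] == pytest.approx(0.5)
        assert freqs[_word_index("TTTT")] == pytest.approx(0.5)
        assert freqs.sum() == pytest.approx(1.0)

    def test_hand_enumeration_acgtacgt(self):
        # forward windows: ACGT,CGTA,GTAC,TACG,ACGT; the sequence is its own
        # reverse complement so each count doubles over 10 windows
        freqs, n = tetra_freqs("ACGTACGT")
        assert n == 10
        assert freqs[_word_index("ACGT")] == pytest.approx(0.4)
        for w in ("CGTA", "GTAC", "TACG"):
            assert freqs[_word_index(w)] == pytest.approx(0.2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            tetra_freqs("ACG")

    def test_all_n_windows_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            tetra_freqs("ACNGTNAC")  # every 4-window contains an N

    def test_n_windows_skipped_but_rest_counted(self):
        freqs, n = tetra_freqs("AAAANAAAA")
        assert n == 4  # two valid forward windows + their reverse complements
        assert freqs[_word_index("AAAA")] == pytest.approx(0.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=120))
    def test_strand_invariance_and_rc_symmetry(self, seq):
        freqs, _ = tetra_freqs(seq)
        # profile equals that of the reverse complement
        freqs_rc, _ = tetra_freqs(revcomp(seq))
        assert np.allclose(freqs, freqs_rc)
        # and within one profile, freq(w) == freq(revcomp(w))
        assert np.allclose(freqs, freqs[REVCOMP_INDEX])


class TestFitPca:
    def test_two_points_mirror_on_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.random(256)
        b = rng.random(256)
        scores = fit_pca(np.vstack([a, b]))
        assert scores.shape == (2, 10)
        assert scores[0, 0] == pytest.approx(-scores[1, 0])
        assert np.allclose(scores[:, 1:], 0.0, atol=1e-9)

    def test_identical_rows_warn_and_zero(self):
        with pytest.warns(UserWarning, match="identical"):
            scores = fit_pca(np.ones((3, 256)))
        assert np.allclose(scores, 0.0)

    def test_scores_are_centered(self):
        rng = np.random.default_rng(1)
        scores = fit_pca(rng.random((20, 256)))
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.random((15, 256))
        assert np.allclose(fit_pca(x), fit_pca(x.copy()))


class TestPearson:
    def test_identity_and_negation(self):
        u = np.arange(10.0)
        assert pearson_r(u, u) == pytest.approx(1.0)
        assert pearson_r(u, -u) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        u = np.arange(1.0, 11.0)
        assert pearson_r(u, 2 * u) == pytest.approx(1.0)

    def test_zero_variance_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert pearson_r(np.ones(10), np.arange(10.0)) == 0.0

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(3)
        scores = rng.random((6, 10))
        mat = correlation_matrix(scores)
        for i in range(6):
            for j in range(6):
                assert mat[i, j] == pytest.approx(pearson_r(scores[i], scores[j]))


def _cands(ids, length=1000):
    return [SequenceRecord(id=i, sequence="A" * length) for i in ids]


def _stats(bin_id, members, internal):
    return BinCorrelationStats(bin_id, list(members), internal)


class TestRecruitment:
    LIN_A = Lineage.from_names("Bacteria", "PA")
    LIN_B = Lineage.from_names("Bacteria", "PB")

    def _scores(self):
        rng = np.random.default_rng(4)
        # two tight clusters in PC space
        center_a = rng.normal(0, 1, 10)
        center_b = -center_a
        scores = {}
        for i in range(60):
            scores[f"a{i}"] = center_a + rng.normal(0, 0.05, 10)
            scores[f"b{i}"] = center_b + rng.normal(0, 0.05, 10)
        scores["cand_a"] = center_a + rng.normal(0, 0.01, 10)
        scores["cand_far"] = rng.normal(0, 1, 10)
        return scores

    def test_rule_by_construction(self):
        scores = self._scores()
        bins = {
            "PA": [f"a{i}" for i in range(60)],
            "PB": [f"b{i}" for i in range(60)],
        }
        stats = bin_internal_stats(bins, scores, min_bin_size=50)
        out = recruit_unassigned(
            _cands(["cand_a", "cand_far"]),
            stats,
            scores,
            {"PA": self.LIN_A, "PB": self.LIN_B},
        )
        assert out["cand_a"].method == "tetra"
        assert out["cand_a"].lineage == self.LIN_A
        assert not out["cand_far"].assigned

    def test_ambiguous_candidate_unassigned(self):
        scores = {}
        rng = np.random.default_rng(5)
        for i in range(60):
            scores[f"a{i}"] = rng.normal(0, 1, 10)  # incoherent bin
            scores[f"b{i}"] = rng.normal(0, 1, 10)
        scores["c"] = np.arange(10.0)
        stats = {
            "PA": _stats("PA", [f"a{i}" for i in range(60)], -0.5),
            "PB": _stats("PB", [f"b{i}" for i in range(60)], -0.5),
        }
        out = recruit_unassigned(
            _cands(["c"]), stats, scores, {"PA": self.LIN_A, "PB": self.LIN_B}
        )
        # candidate exceeds both internal means -> conservative unassigned
        assert not out["c"].assigned

    def test_short_candidate_ineligible(self):
        scores = self._scores()
        bins = {"PA": [f"a{i}" for i in range(60)]}
        stats = bin_internal_stats(bins, scores, min_bin_size=50)
        scores["short"] = scores["cand_a"]
        out = recruit_unassigned(
            _cands(["short"], length=850), stats, scores, {"PA": self.LIN_A}
        )
        assert not out["short"].assigned

    def test_small_bins_never_recruit(self):
        scores = self._scores()
        stats = bin_internal_stats(
            {"PA": [f"a{i}" for i in range(40)]}, scores, min_bin_size=50
        )
        assert stats == {}
        out = recruit_unassigned(
            _cands(["cand_a"]), stats, scores, {"PA": self.LIN_A}
        )
        assert not out["cand_a"].assigned


class TestPropagateMates:
    LIN = Lineage.from_names("Bacteria", "PA")
    LIN2 = Lineage.from_names("Bacteria", "PB")

    def _pair(self):
        r1 = SequenceRecord("r/1", "ACGT", mate_id="r/2")
        r2 = SequenceRecord("r/2", "ACGT", mate_id="r/1")
        return [r1, r2]

    def test_assigned_mate_propagates(self):
        records = self._pair()
        assignments = {
            "r/1": TaxonAssignment("r/1", self.LIN, method="consensus"),
            "r/2": TaxonAssignment("r/2"),
        }
        out, conflicts = propagate_mates(assignments, records)
        assert out["r/2"].method == "mate" and out["r/2"].lineage == self.LIN
        assert conflicts == []

    def test_both_unassigned_unchanged(self):
        records = self._pair()
        assignments = {"r/1": TaxonAssignment("r/1"), "r/2": TaxonAssignment("r/2")}
        out, conflicts = propagate_mates(assignments, records)
        assert not out["r/1"].assigned and not out["r/2"].assigned

    def test_conflicting_pair_flagged_not_overridden(self):
        records = self._pair()
        assignments = {
            "r/1": TaxonAssignment("r/1", self.LIN, method="consensus"),
            "r/2": TaxonAssignment("r/2", self.LIN2, method="consensus"),
        }
        out, conflicts = propagate_mates(assignments, records)
        assert out["r/1"].lineage == self.LIN and out["r/2"].lineage == self.LIN2
        assert conflicts == [("r/1", "r/2")]
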