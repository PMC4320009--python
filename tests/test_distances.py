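import math
import random

import numpy as np
import pytest

import barcodegap as bg
from barcodegap.errors import (
    EmptyComparisonError,
    LabelingError,
    SaturatedDistanceError,
)

from conftest import BASES, PURINES, brute_force_k2p, random_alignment


class TestK2P:
    def test_zero_for_identical(self):
        assert bg.k2p(0.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "P,Q,expected",
        [
            (0.1, 0.0, -0.5 * math.log(0.8)),
            (0.1, 0.1, -0.5 * math.log(0.7) - 0.25 * math.log(0.8)),
        ],
    )
    def test_known_values(self, P, Q, expected):
        assert bg.k2p(P, Q) == pytest.approx(expected, abs=1e-12)

    def test_accepts_pair_counts(self):
        pc = bg.PairCounts(P=0.1, Q=0.0, m=100)
        assert bg.k2p(pc) == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_saturation_raises(self):
        with pytest.raises(SaturatedDistanceError):
            bg.k2p(0.5, 0.1)  # 1 - 2P - Q = -0.1
        with pytest.raises(SaturatedDistanceError):
            bg.k2p(0.0, 0.5)  # 1 - 2Q = 0

    def test_monotone_in_P_and_Q_and_exceeds_pdistance(self):
        """d increases in each argument and d >= P + Q on a grid."""
        grid = np.linspace(0.0, 0.2, 21)
        for Q in grid:
            vals = [bg.k2p(P, Q) for P in grid]
            assert all(b > a for a, b in zip(vals, vals[1:]))
            for P, v in zip(grid, vals):
                assert v >= P + Q - 1e-12
        for P in grid:
            vals = [bg.k2p(P, Q) for Q in grid]
            assert all(b > a for a, b in zip(vals, vals[1:]))


class TestPairCounts:
    def test_transition(self):
        pc = bg.pair_counts("ACGT", "GCGT")
        assert (pc.P, pc.Q, pc.m) == (0.25, 0.0, 4)

    def test_transversion(self):
        pc = bg.pair_counts("ACGT", "TCGT")
        assert (pc.P, pc.Q, pc.m) == (0.0, 0.25, 4)

    def test_gap_and_ambiguity_excluded(self):
        pc = bg.pair_counts("ACGT", "-CGN")
        assert pc.m == 2 and pc.P == 0.0 and pc.Q == 0.0

    def test_all_missing_raises(self):
        with pytest.raises(EmptyComparisonError):
            bg.pair_counts("NN--", "AC-N")

    def test_random_pairs_match_bruteforce_tally(self):
        rng = random.Random(42)
        for _ in range(20):
            aln = random_alignment(rng, n=2, L=573, mut=0.15)
            a, b = aln.seqs
            pc = bg.pair_counts(a, b)
            ts = sum(
                1 for x, y in zip(a, b)
                if x != y and (x in PURINES) == (y in PURINES)
            )
            tv = sum(
                1 for x, y in zip(a, b)
                if x != y and (x in PURINES) != (y in PURINES)
            )
            assert pc.P == pytest.approx(ts / 573)
            assert pc.Q == pytest.approx(tv / 573)


class TestDistanceMatrix:
    def test_identical_sequences(self):
        aln = bg.BarcodeAlignment(ids=["a", "b"], seqs=["ACGT", "ACGT"])
        dm = bg.distance_matrix(aln, se_reps=10, seed=0)
        assert dm.d[0, 1] == 0.0
        assert dm.se[0, 1] == 0.0

    def test_matrix_equals_composed_pair_operations(self, tiny_alignment):
        dm = bg.distance_matrix(tiny_alignment, deletion_mode="pairwise")
        for i, a in enumerate(tiny_alignment.ids):
            for j, b in enumerate(tiny_alignment.ids):
                if i == j:
                    continue
                expected = bg.k2p(
                    bg.pair_counts(tiny_alignment.seqs[i], tiny_alignment.seqs[j])
                )
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-14)

    def test_complete_deletion_drops_columns_study_wide(self):
        # the gap in c removes column 0 for every pair
        aln = bg.BarcodeAlignment(
            ids=["a", "b", "c"], seqs=["AACGTT", "GACGTT", "-ACGTT"]
        )
        dm = bg.distance_matrix(aln, deletion_mode="complete")
        assert dm.d[0, 1] == 0.0  # A/G difference was in the dropped column
        dm2 = bg.distance_matrix(aln, deletion_mode="pairwise")
        assert dm2.d[0, 1] > 0.0

    def test_permutation_equivariance(self, pencilfish):
        aln = pencilfish.alignment
        rng = np.random.default_rng(5)
        perm = rng.permutation(aln.n)
        dm = bg.distance_matrix(aln)
        dmp = bg.distance_matrix(aln.reorder(perm))
        assert np.allclose(dm.d[np.ix_(perm, perm)], dmp.d)

    def test_se_reproducible_and_optional(self, tiny_alignment):
        d1 = bg.distance_matrix(tiny_alignment, deletion_mode="pairwise",
                                se_reps=50, seed=11)
        d2 = bg.distance_matrix(tiny_alignment, deletion_mode="pairwise",
                                se_reps=50, seed=11)
        assert np.array_equal(d1.se, d2.se)
        d3 = bg.distance_matrix(tiny_alignment, deletion_mode="pairwise")
        assert d3.se is None
        assert np.allclose(d1.d, d3.d)

    def test_saturation_identifies_pair(self):
        aln = bg.BarcodeAlignment(ids=["a", "b"], seqs=["AAAA", "TTTT"])
        with pytest.raises(SaturatedDistanceError) as exc:
            bg.distance_matrix(aln)
        assert exc.value.pair == ("a", "b")


class TestGapSummary:
    @staticmethod
    def _records(mapping):
        return [bg.SpecimenRecord(k, v) for k, v in mapping.items()]

    def test_two_species_forced_values(self):
        ids = ["a1", "a2", "b1", "b2"]
        d = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                d[i, j] = d[j, i] = 0.10
        dm = bg.DistanceMatrix(ids=ids, d=d)
        recs = self._records({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        g = bg.gap_summary(dm, recs)
        assert g.conspecific.mean == 0.0
        assert g.congeneric.mean == pytest.approx(10.0)
        assert g.has_gap

    def test_singleton_species_contribute_no_conspecific_pairs(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        dm = bg.DistanceMatrix(ids=["a", "b"], d=d)
        g = bg.gap_summary(dm, self._records({"a": "A", "b": "B"}))
        assert g.conspecific.n_pairs == 0
        assert g.conspecific.mean is None  # empty, not zero

    def test_missing_label_raises(self, tiny_alignment):
        dm = bg.distance_matrix(tiny_alignment, deletion_mode="pairwise")
        with pytest.raises(LabelingError):
            bg.gap_summary(dm, self._records({"a": "A"}))

    def test_matches_bruteforce_pair_loop(self, pencilfish, pencilfish_dm):
        g = bg.gap_summary(pencilfish_dm, pencilfish.records)
        species = {r.specimen_id: r.species for r in pencilfish.records}
        intra, inter = [], []
        ids = pencilfish_dm.ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                v = pencilfish_dm.d[i, j] * 100
                (intra if species[ids[i]] == species[ids[j]] else inter).append(v)
        assert g.conspecific.mean == pytest.approx(np.mean(intra))
        assert g.conspecific.min == pytest.approx(min(intra))
        assert g.conspecific.max == pytest.approx(max(intra))
        assert g.congeneric.mean == pytest.approx(np.mean(inter))
        assert g.conspecific.n_pairs == len(intra)
        assert g.congeneric.n_pairs == len(inter)


class TestGroupMeanMatrix:
    def test_two_singletons(self):
        d = np.array([[0.0, 0.162], [0.162, 0.0]])
        dm = bg.DistanceMatrix(ids=["x", "y"], d=d)
        gm = bg.group_mean_matrix(dm, {"x": "G1", "y": "G2"})
        assert gm.mean[0, 1] == pytest.approx(0.162)
        assert gm.mean[0, 0] == 0.0 and gm.mean[1, 1] == 0.0

    def test_unknown_group_label(self, tiny_alignment):
        dm = bg.distance_matrix(tiny_alignment, deletion_mode="pairwise")
        with pytest.raises(LabelingError):
            bg.group_mean_matrix(dm, {"a": "G1"})

    def test_three_groups_match_bruteforce(self):
        rng = random.Random(7)
        aln = random_alignment(rng, n=9, L=300, mut=0.1)
        dm = bg.distance_matrix(aln)
        groups = {sid: f"G{i % 3}" for i, sid in enumerate(aln.ids)}
        gm = bg.group_mean_matrix(dm, groups)
        for a, la in enumerate(gm.labels):
            for b, lb in enumerate(gm.labels):
                vals = [
                    dm.d[i, j]
                    for i in range(aln.n)
                    for j in range(i + 1, aln.n)
                    if {groups[aln.ids[i]], groups[aln.ids[j]]} ==
                       ({la, lb} if a != b else {la})
                ]
                assert gm.mean[a, b] == pytest.approx(np.mean(vals))

    def test_site_bootstrap_se_reproducible(self, tiny_alignment):
        aln = bg.BarcodeAlignment(
            ids=["a", "b", "c", "d"],
            seqs=["ACGTACGTAC", "GCGTACGTAC", "ACGAACGTAC", "ACGTACGAAC"],
        )
        dm = bg.distance_matrix(aln)
        groups = {"a": "G1", "b": "G1", "c": "G2", "d": "G2"}
        g1 = bg.group_mean_matrix(dm, groups, aln=aln, se_reps=50, seed=3)
        g2 = bg.group_mean_matrix(dm, groups, aln=aln, se_reps=50, seed=3)
        assert g1.se is not None and np.array_equal(g1.se, g2.se)
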