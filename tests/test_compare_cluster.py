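"""Superposition, TM scores, secondary structure, clustering, coverage."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pseudocycle.structure_io import ProteinStructure, RepeatSpec
from pseudocycle.compare_cluster import (
    align_structures, assign_ss, cluster_scaffolds, kabsch_rmsd,
    pairwise_tm_matrix, subsample_coverage, tm_d0, tm_score)
from pseudocycle.synthetic_backbones import (
    CyclicBackboneSpec, build_cyclic, build_unit)
from conftest import DISTINCT_RECIPES, perturb, rigid_move


def brute_force_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Independent minimal-RMSD oracle: coarse rotation grid followed by
    local refinement over the rotation vector (no SVD)."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ R.T - ref_c) ** 2, axis=1)))

    best = math.inf
    grid = np.linspace(-math.pi, math.pi, 7)
    for rv in itertools.product(grid, grid, grid):
        res = minimize(cost, rv, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_inputs_zero(self):
        pts = np.random.default_rng(0).normal(0, 5, (10, 3))
        assert kabsch_rmsd(pts, pts).rmsd_A == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 5, (30, 3))
        R = Rotation.random(random_state=2).as_matrix()
        moved = pts @ R.T + rng.normal(0, 10, 3)
        assert kabsch_rmsd(pts, moved).rmsd_A == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_rotation_oracle(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        mob = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 1]])
        assert kabsch_rmsd(ref, mob).rmsd_A == pytest.approx(
            brute_force_rmsd(ref, mob), abs=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_triangle_sanity_after_common_superposition(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 5, (20, 3))
        b = a + rng.normal(0, 0.5, (20, 3))
        c = a + rng.normal(0, 1.0, (20, 3))
        ab = kabsch_rmsd(a, b).rmsd_A
        bc = kabsch_rmsd(b, c).rmsd_A
        ac = kabsch_rmsd(a, c).rmsd_A
        assert ac <= ab + bc + 1e-9


class TestTMScore:
    def test_self_score_is_one(self, c5_backbone):
        pair = tm_score(c5_backbone, c5_backbone)
        assert pair.tm_avg == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, base_scaffolds):
        a, b = base_scaffolds[0], base_scaffolds[1]
        assert tm_score(a, b).tm_avg == pytest.approx(
            tm_score(b, a).tm_avg, abs=1e-9)

    def test_noisy_pair_scores_high_and_beats_single_pass_bound(
            self, c5_backbone):
        noisy = perturb(c5_backbone, sd=1.0 / math.sqrt(3), seed=4)
        pair = tm_score(c5_backbone, noisy)
        assert pair.tm_avg > 0.8
        # single full-superposition pass is a lower bound on the iterated max
        sup = kabsch_rmsd(c5_backbone.ca_coords(), noisy.ca_coords())
        d = np.linalg.norm(sup.apply(noisy.ca_coords())
                           - c5_backbone.ca_coords(), axis=1)
        L = len(c5_backbone)
        bound = np.sum(1 / (1 + (d / tm_d0(L)) ** 2)) / L
        assert pair.tm_ab >= bound - 1e-9

    def test_distinct_scaffolds_below_singleton_threshold(
            self, base_scaffolds):
        tms = [tm_score(a, b).tm_avg
               for a, b in itertools.combinations(base_scaffolds, 2)]
        assert max(tms) < 0.45

    def test_d0_formula_floored(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)
        assert tm_d0(16) == 0.5
        assert tm_d0(21) == 0.5  # 1.24*6^(1/3)-1.8 ~ 0.45 -> floored


class TestAlignStructures:
    def test_identity_correspondence_for_identical(self, c5_backbone):
        pairs = align_structures(c5_backbone, c5_backbone)
        assert pairs == [(i, i) for i in range(len(c5_backbone))]

    def test_leading_deletion_recovered_as_offset(self, c5_backbone):
        trunc = ProteinStructure(c5_backbone.residues[5:])
        pairs = align_structures(c5_backbone, trunc)
        offsets = {i - j for i, j in pairs}
        assert offsets == {5}
        assert len(pairs) >= 90

    def test_unrelated_structures_score_low(self, base_scaffolds):
        trunc = ProteinStructure(base_scaffolds[1].residues[:-7])
        pair = tm_score(base_scaffolds[0], trunc,
                        align_structures(base_scaffolds[0], trunc))
        assert pair.tm_avg < 0.3


class TestSecondaryStructure:
    def test_ideal_helix_interior_all_h(self):
        ss = assign_ss(build_unit("H" * 20))
        assert set(ss[1:-1]) == {"H"}
        assert ss[0] == "L" and ss[-1] == "L"

    def test_ideal_strand_interior_all_e(self):
        ss = assign_ss(build_unit("E" * 15))
        assert set(ss[1:-1]) == {"E"}

    def test_short_runs_demoted_to_loop(self):
        # 2-residue helical stints never reach the 4-residue H minimum
        ss = assign_ss(build_unit("HHLLHHLLHHLLHHLL"))
        assert "H" not in ss
        # 3-residue helical stints are also demoted; 3 strands survive
        ss2 = assign_ss(build_unit("EEEELLLEEEELLLE"))
        assert "EEEE" in ss2 or "EEE" in ss2


class TestClustering:
    def test_three_copies_plus_one_matches_brute_force(self, base_scaffolds):
        a, b = base_scaffolds[0], base_scaffolds[5]
        structs = [a, rigid_move(a, 1), rigid_move(a, 2), b]
        specs = [RepeatSpec(5, 20)] * 3 + [RepeatSpec(2, 50)]
        report = cluster_scaffolds(structs, specs)
        # brute-force over all partitions of 4 items with the same
        # objective (min singleton fraction s.t. intra-TM >= 0.85) gives
        # {a,a,a} + {b}: 2 clusters, singleton fraction 1/2, intra TM 1
        assert report.n_clusters == 2
        assert report.singleton_fraction == pytest.approx(0.5)
        assert report.mean_intra_tm == pytest.approx(1.0, abs=1e-6)
        groups = {}
        for i, c in report.assignments.items():
            groups.setdefault(c, set()).add(i)
        assert sorted(map(len, groups.values())) == [1, 3]

    def test_all_dissimilar_structures_are_singletons(self, base_scaffolds):
        structs = base_scaffolds[:4]
        specs = [RepeatSpec(n, len(t)) for n, t, _ in DISTINCT_RECIPES[:4]]
        report = cluster_scaffolds(structs, specs)
        assert report.n_clusters == 4
        assert report.singleton_fraction == 1.0

    def test_two_tight_families_recovered(self, base_scaffolds):
        fam_a = [perturb(rigid_move(base_scaffolds[0], s), 0.02, s)
                 for s in range(5)]
        fam_b = [perturb(rigid_move(base_scaffolds[3], s), 0.02, 10 + s)
                 for s in range(5)]
        structs = fam_a + fam_b
        specs = [RepeatSpec(5, 20)] * 5 + [RepeatSpec(4, 25)] * 5
        report = cluster_scaffolds(structs, specs)
        assert report.n_clusters == 2
        assert report.singleton_fraction == 0.0
        labels_a = {report.assignments[i] for i in range(5)}
        labels_b = {report.assignments[i] for i in range(5, 10)}
        assert len(labels_a) == 1 and len(labels_b) == 1
        assert labels_a != labels_b

    def test_permutation_invariance(self, base_scaffolds):
        a, b = base_scaffolds[0], base_scaffolds[5]
        structs = [a, rigid_move(a, 1), b, rigid_move(a, 2)]
        specs = [RepeatSpec(5, 20), RepeatSpec(5, 20), RepeatSpec(2, 50),
                 RepeatSpec(5, 20)]
        rep1 = cluster_scaffolds(structs, specs)
        order = [3, 2, 0, 1]
        rep2 = cluster_scaffolds([structs[i] for i in order],
                                 [specs[i] for i in order])
        sets1 = {frozenset(i for i, c in rep1.assignments.items() if c == k)
                 for k in set(rep1.assignments.values())}
        sets2 = {frozenset(order[i] for i, c in rep2.assignments.items()
                           if c == k)
                 for k in set(rep2.assignments.values())}
        assert sets1 == sets2


class TestCoverage:
    @pytest.fixture()
    def family_population(self, base_scaffolds):
        """8 families of 5 near-copies plus 2 uniques (42 structures)."""
        structs = []
        labels = []
        for f in range(8):
            for k in range(5):
                structs.append(perturb(base_scaffolds[f], 0.3, 100 * f + k))
                labels.append(f)
        structs += [base_scaffolds[8], base_scaffolds[9]]
        labels += [8, 9]
        return structs, labels, pairwise_tm_matrix(structs)

    def test_identical_population_has_no_singletons(self, c5_backbone):
        structs = [rigid_move(c5_backbone, s) for s in range(6)]
        rep = subsample_coverage(structs, sizes=[3, 6], replicates=4, seed=0)
        assert all(r["singleton_fraction"] == 0.0 for r in rep.rows)

    def test_all_dissimilar_population_is_all_singletons(
            self, base_scaffolds):
        rep = subsample_coverage(base_scaffolds, sizes=[5, 10],
                                 replicates=3, seed=1)
        assert all(r["singleton_fraction"] == 1.0 for r in rep.rows)

    def test_fraction_decreases_with_subset_size(self, family_population):
        structs, _, M = family_population
        rep = subsample_coverage(structs, sizes=[10, 20, 40],
                                 replicates=10, seed=2, tm_matrix=M)
        means = [rep.mean_fraction(s) for s in (10, 20, 40)]
        assert means[0] > means[2]
        # non-increasing within Monte-Carlo error
        assert means[1] <= means[0] + 0.05
        assert means[2] <= means[1] + 0.05

    def test_size_above_population_rejected(self, base_scaffolds):
        with pytest.raises(ValueError):
            subsample_coverage(base_scaffolds, sizes=[99], replicates=1)
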