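"""Exemplar-exclusion rules, generalization matrices, cluster inference."""

from itertools import product

import numpy as np
import pytest

from megdecode.datamodel import ConfigError, PipelineConfig
from megdecode.generalization import (
    GeneralizationSpec,
    Group,
    admissible_combinations,
    cluster_permutation_2d,
    generalization_matrix,
)
from megdecode.mvpa import compute_empirical_rdms
from megdecode.simulate import SimConfig, simulate_dataset


def _grp(name, *conds):
    return Group(name, tuple(conds))


def _brute_force_combos(spec):
    """Independent filter over the full cross product of exemplar choices."""
    A, B = spec.train_groups
    C, D = spec.test_groups
    out = []
    for ta, tb, ca, cb in product(A.conditions, B.conditions,
                                  C.conditions, D.conditions):
        drop = False
        for tg, tcond in ((A, ta), (B, tb)):
            for sg, scond in ((C, ca), (D, cb)):
                if tg == sg and tcond.split(":")[0] == scond.split(":")[0]:
                    drop = True
        if not drop:
            out.append(((ta, tb), (ca, cb)))
    return out


class TestAdmissibleCombinations:
    def test_disjoint_groups_keep_all_sixteen(self):
        spec = GeneralizationSpec(
            (_grp("a", "f1:pre", "f2:pre"), _grp("b", "n1:s1", "n2:s1")),
            (_grp("c", "f1:post", "f2:post"), _grp("d", "n1:s2", "n2:s2")))
        assert len(admissible_combinations(spec)) == 16

    def test_shared_nonsense_group_drops_same_image_pairs(self):
        non = _grp("non", "n1:s1", "n2:s1")
        spec = GeneralizationSpec(
            (_grp("pre", "f1:pre", "f2:pre"), non),
            (_grp("post", "f1:post", "f2:post"), non))
        combos = admissible_combinations(spec)
        # object image may repeat across state; nonsense image may not
        assert len(combos) == 8
        for (tr_a, tr_b), (te_a, te_b) in combos:
            assert tr_b.split(":")[0] != te_b.split(":")[0]

    def test_identical_train_test_pairs_leave_four_survivors(self):
        a = _grp("a", "f1:post", "f2:post")
        b = _grp("b", "n1:s2", "n2:s2")
        spec = GeneralizationSpec((a, b), (a, b))
        combos = admissible_combinations(spec)
        assert len(combos) == 4
        for (tr_a, tr_b), (te_a, te_b) in combos:
            assert tr_a != te_a and tr_b != te_b

    @pytest.mark.parametrize("shared", ["none", "one", "both"])
    def test_matches_brute_force_oracle(self, shared):
        non = _grp("non", "n1:s1", "n2:s1")
        obj_a = _grp("a", "f1:pre", "f2:pre")
        obj_c = {"none": _grp("c", "f1:post", "f2:post"),
                 "one": _grp("c", "f1:post", "f2:post"),
                 "both": obj_a}[shared]
        test_non = non if shared in ("one", "both") else _grp(
            "non2", "n1:s2", "n2:s2")
        spec = GeneralizationSpec((obj_a, non), (obj_c, test_non))
        assert admissible_combinations(spec) == _brute_force_combos(spec)

    def test_exclusion_emptying_all_combos_rejected(self):
        solo = _grp("solo", "f1:post")
        non = _grp("non", "n1:s2")
        spec = GeneralizationSpec((solo, non), (solo, non))
        with pytest.raises(ConfigError):
            admissible_combinations(spec)


@pytest.fixture(scope="module")
def gen_dataset():
    cfg = SimConfig(n_subjects=4, regions=["r"], n_vertices=24, n_trials=60,
                    rng_seed=31)
    return simulate_dataset(cfg)


class TestGeneralizationMatrix:
    def test_matrix_shape_matches_bin_count(self, gen_dataset):
        ds = gen_dataset
        pc = PipelineConfig(rng_seed=31)
        spec = GeneralizationSpec(
            (_grp("pre", "face1:pre", "face2:pre"),
             _grp("n1", "nonsense1:s1", "nonsense2:s1")),
            (_grp("post", "face1:post", "face2:post"),
             _grp("n2", "nonsense1:s2", "nonsense2:s2")))
        gm = generalization_matrix(ds, "r", spec, pc,
                                   design=ds.design.for_category("face"))
        assert gm.accuracy.shape == (4, 51, 51)
        assert np.all((gm.accuracy >= 0) & (gm.accuracy <= 1))
        assert gm.combos_used == 16

    def test_same_pair_diagonal_consistent_with_pairwise_decoding(
            self, gen_dataset):
        """Within-group diagonal tracks the post-vs-nonsense decodability.

        The exclusion rule makes the diagonal cross-exemplar, so agreement
        with the within-pair CV accuracies holds in distribution (the
        generator draws exchangeable exemplar patterns), not cell-by-cell.
        """
        ds = gen_dataset
        pc = PipelineConfig(rng_seed=31)
        design = ds.design.for_category("face")
        post = _grp("post", "face1:post", "face2:post")
        non = _grp("n2", "nonsense1:s2", "nonsense2:s2")
        gm = generalization_matrix(
            ds, "r", GeneralizationSpec((post, non), (post, non)), pc,
            design=design)
        rdms = compute_empirical_rdms(ds, design, pc)
        comp = np.array([p.component for p in rdms.pair_labels])
        rn = rdms.accuracies[:, 0][:, comp == "RN"].mean()
        diag = np.diagonal(gm.accuracy.mean(axis=0)).mean()
        assert diag == pytest.approx(rn, abs=0.08)

    def test_unknown_condition_rejected(self, gen_dataset):
        pc = PipelineConfig(rng_seed=31)
        spec = GeneralizationSpec(
            (_grp("x", "bogus:pre"), _grp("n", "nonsense1:s1")),
            (_grp("y", "face1:post"), _grp("m", "nonsense1:s2")))
        with pytest.raises(ConfigError, match="bogus"):
            generalization_matrix(gen_dataset, "r", spec, pc)


class TestClusterPermutation:
    def test_exact_chance_matrices_give_no_clusters(self):
        mats = np.full((6, 20, 20), 0.5)
        res = cluster_permutation_2d(mats, 0.5,
                                     PipelineConfig(n_permutations=200),
                                     np.random.default_rng(0))
        assert res.clusters == [] and res.significant == []

    def test_broad_effect_found_as_single_significant_cluster(self):
        rng = np.random.default_rng(1)
        mats = 0.5 + rng.normal(0, 0.01, size=(8, 30, 30))
        mats[:, 8:20, 10:22] += 0.2
        res = cluster_permutation_2d(mats, 0.5,
                                     PipelineConfig(n_permutations=300),
                                     np.random.default_rng(2))
        assert len(res.significant) == 1
        mask, size, p = res.significant[0]
        ti, tj = np.nonzero(mask)
        assert set(range(8, 20)) <= set(ti.tolist())
        assert set(range(10, 22)) <= set(tj.tolist())
        assert p < 0.05

    def test_cluster_p_monotone_in_size(self):
        rng = np.random.default_rng(3)
        mats = 0.5 + rng.normal(0, 0.05, size=(10, 40, 40))
        mats[:, 5:15, 5:15] += 0.08
        mats[:, 25:28, 25:28] += 0.12
        res = cluster_permutation_2d(mats, 0.5,
                                     PipelineConfig(n_permutations=300),
                                     np.random.default_rng(4))
        sizes = [s for _, s, _ in res.clusters]
        ps = [p for _, _, p in res.clusters]
        assert sizes == sorted(sizes, reverse=True)
        assert ps == sorted(ps)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigError):
            cluster_permutation_2d(np.full((1, 5, 5), 0.6))

    def test_low_permutation_count_warns(self):
        mats = np.full((4, 5, 5), 0.5)
        with pytest.warns(UserWarning, match="permutations"):
            cluster_permutation_2d(mats, 0.5,
                                   PipelineConfig(n_permutations=50),
                                   np.random.default_rng(5))
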