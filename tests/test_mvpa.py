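"""Downsampling, pseudo-trials, PCA features and LDA cross-validation.

The cross-validation test pits the vectorised fold computation against an
explicit brute-force double loop over held-out pairs (the independent
oracle); they must agree to numerical precision.
"""

import itertools

import numpy as np
import pytest

from megdecode.datamodel import ConditionExcluded, ConfigError, PipelineConfig
from megdecode.mvpa import (
    PseudoTrials,
    compute_empirical_rdms,
    cross_validated_accuracy,
    cv_accuracy_timecourse,
    downsample_epochs,
    extract_region_features,
    make_pseudotrials,
    train_lda,
)
from megdecode.simulate import SimConfig, simulate_dataset


class TestDownsampling:
    def test_501_samples_at_ratio_10_give_51_bins(self):
        epochs = np.random.default_rng(0).normal(size=(4, 501, 3))
        assert downsample_epochs(epochs, 10).shape == (4, 51, 3)

    def test_constant_signal_is_preserved(self):
        epochs = np.full((2, 40, 3), 3.25)
        np.testing.assert_allclose(downsample_epochs(epochs, 10), 3.25)

    def test_ramp_averages_to_midpoint(self):
        epochs = np.arange(10.0)[None, :, None]
        np.testing.assert_allclose(downsample_epochs(epochs, 10),
                                   [[[4.5]]])

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ConfigError):
            downsample_epochs(np.zeros((2, 10, 2)), 0)


class TestPseudoTrials:
    def test_75_trials_into_10_groups_of_7_and_8(self):
        rng = np.random.default_rng(1)
        pt = make_pseudotrials(np.zeros((3, 5, 75)), 10, 50, rng)
        sizes = sorted(pt.group_sizes)
        assert sizes == [7] * 5 + [8] * 5

    def test_50_trials_into_10_groups_of_5(self):
        pt = make_pseudotrials(np.zeros((3, 5, 50)), 10, 50,
                               np.random.default_rng(1))
        assert list(pt.group_sizes) == [5] * 10

    def test_below_threshold_raises_condition_excluded(self):
        with pytest.raises(ConditionExcluded) as err:
            make_pseudotrials(np.zeros((3, 5, 49)), 10, 50,
                              np.random.default_rng(1), subject="s1",
                              condition="face1:pre")
        assert err.value.subject == "s1"
        assert err.value.n_trials == 49

    @pytest.mark.parametrize("n,k", [(50, 10), (63, 10), (80, 10), (55, 7)])
    def test_partition_disjoint_and_covering(self, n, k):
        for seed in range(5):
            pt = make_pseudotrials(np.zeros((2, 3, n)), k, 50,
                                   np.random.default_rng(seed))
            all_idx = np.concatenate(pt.source_trial_indices)
            assert len(all_idx) == n
            assert len(set(all_idx.tolist())) == n
            assert max(pt.group_sizes) - min(pt.group_sizes) <= 1

    def test_pseudo_trial_is_group_mean(self):
        rng = np.random.default_rng(2)
        trials = rng.normal(size=(4, 6, 54))
        pt = make_pseudotrials(trials, 10, 50, rng)
        for g, idx in enumerate(pt.source_trial_indices):
            np.testing.assert_allclose(pt.data[g],
                                       trials[..., idx].mean(axis=-1))


class TestRegionFeatures:
    def _pseudos(self, data_by_cond):
        return {c: PseudoTrials(d, np.array([1] * len(d)), [])
                for c, d in data_by_cond.items()}

    def test_rank1_data_concentrates_variance_in_pc1(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=12)
        weights = rng.normal(size=(8, 5))
        data = np.einsum("kt,v->kvt", weights, v)
        feats = extract_region_features(self._pseudos({"a": data}), n_pc=3)
        assert feats.explained_variance[0] >= 0.99

    def test_basis_orthonormal(self):
        rng = np.random.default_rng(4)
        data = {c: rng.normal(size=(6, 10, 7)) for c in "ab"}
        feats = extract_region_features(self._pseudos(data), n_pc=3)
        np.testing.assert_allclose(feats.pc_basis.T @ feats.pc_basis,
                                   np.eye(3), atol=1e-10)

    def test_rank3_data_reconstructs_exactly(self):
        rng = np.random.default_rng(5)
        basis = np.linalg.qr(rng.normal(size=(10, 3)))[0]
        latent = rng.normal(size=(6, 3, 8))
        data = {"a": np.einsum("vd,kdt->kvt", basis, latent)}
        feats = extract_region_features(self._pseudos(data), n_pc=3)
        scores = feats.scores["a"]                    # (k, T, 3)
        recon = np.einsum("vd,ktd->kvt", feats.pc_basis, scores)
        recon += np.mean(data["a"], axis=(0, 2))[None, :, None]
        np.testing.assert_allclose(recon, data["a"], atol=1e-8)

    def test_too_few_vertices_rejected(self):
        data = {"a": np.zeros((5, 2, 4))}
        with pytest.raises(ConfigError):
            extract_region_features(self._pseudos(data), n_pc=3)


class TestLda:
    def test_separable_clouds_classified_perfectly(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(9, 3)) * 0.1 + [5, 0, 0]
        B = rng.normal(size=(9, 3)) * 0.1 - [5, 0, 0]
        clf = train_lda(A, B)
        assert clf.predict_first(A).all()
        assert not clf.predict_first(B).any()

    def test_isotropic_covariance_recovers_mean_difference_direction(self):
        rng = np.random.default_rng(7)
        noise = rng.normal(size=(400, 3))
        A = noise[:200] + [1, 0, 0]
        B = noise[200:]
        w = train_lda(A, B).w
        w = w / np.linalg.norm(w)
        assert abs(w[0]) > 0.98

    def test_identical_distributions_give_chance_heldout_accuracy(self):
        rng = np.random.default_rng(8)
        accs = [
            cross_validated_accuracy(rng.normal(size=(10, 3)),
                                     rng.normal(size=(10, 3)))
            for _ in range(60)
        ]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.04)


class TestCrossValidation:
    def _brute_force(self, A, B):
        """Independent oracle: explicit double loop over held-out pairs."""
        k = A.shape[0]
        correct = 0
        for i, j in itertools.product(range(k), range(k)):
            train_a = np.delete(A, i, axis=0)
            train_b = np.delete(B, j, axis=0)
            clf = train_lda(train_a, train_b)
            correct += int(clf.predict_first(A[i][None])[0])
            correct += int(~clf.predict_first(B[j][None])[0])
        return correct / (2 * k * k)

    def test_vectorised_folds_match_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            A = rng.normal(size=(10, 3)) + 0.5
            B = rng.normal(size=(10, 3))
            fast = cross_validated_accuracy(A, B)
            assert fast == pytest.approx(self._brute_force(A, B), abs=1e-12)

    def test_fold_count_is_k_squared(self):
        # the brute-force enumeration above visits exactly k^2 = 100 folds
        assert len(list(itertools.product(range(10), range(10)))) == 100

    def test_separable_classes_reach_perfect_accuracy(self):
        A = np.random.default_rng(10).normal(size=(10, 3)) * 0.05 + 3
        B = np.random.default_rng(11).normal(size=(10, 3)) * 0.05 - 3
        assert cross_validated_accuracy(A, B) == 1.0

    def test_accuracy_invariant_to_common_affine_map(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(10, 3)) + 0.8
        B = rng.normal(size=(10, 3))
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        shift = rng.normal(size=3)
        base = cross_validated_accuracy(A, B)
        mapped = cross_validated_accuracy(A @ M + shift, B @ M + shift)
        assert mapped == pytest.approx(base, abs=1e-9)

    def test_unequal_counts_rejected(self):
        with pytest.raises(ConfigError):
            cross_validated_accuracy(np.zeros((10, 3)), np.zeros((9, 3)))

    def test_timecourse_variant_matches_per_bin_calls(self):
        rng = np.random.default_rng(13)
        A = rng.normal(size=(8, 4, 3))
        B = rng.normal(size=(8, 4, 3))
        tc = cv_accuracy_timecourse(A, B)
        per_bin = [cross_validated_accuracy(A[:, t], B[:, t])
                   for t in range(4)]
        np.testing.assert_allclose(tc, per_bin, atol=1e-12)


class TestEmpiricalRdms:
    def test_output_dimensions_and_pair_count(self, small_dataset,
                                              small_config):
        design = small_dataset.design.for_category("face")
        rdms = compute_empirical_rdms(small_dataset, design, small_config)
        n_s = len(small_dataset.subjects)
        assert rdms.accuracies.shape == (n_s, 2, 28, 51)
        assert np.all((rdms.accuracies >= 0) & (rdms.accuracies <= 1))

    def test_short_condition_drops_subject(self, small_dataset,
                                           small_config):
        ds = small_dataset
        trimmed = dict(ds.epochs)
        key = (ds.subjects[0], ds.regions[0], "face1:pre")
        trimmed[key] = trimmed[key][:, :, :49]
        clone = type(ds)(subjects=ds.subjects, regions=ds.regions,
                         time_axis=ds.time_axis,
                         sampling_step_ms=ds.sampling_step_ms,
                         design=ds.design, epochs=trimmed)
        rdms = compute_empirical_rdms(
            clone, ds.design.for_category("face"), small_config)
        assert ds.subjects[0] in rdms.excluded_subjects
        assert rdms.accuracies.shape[0] == len(ds.subjects) - 1
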