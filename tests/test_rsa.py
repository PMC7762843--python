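"""Pair enumeration, model RDM, Spearman RSA, profile and effect map.

The pair-role assignment is verified against an independent rule table
applied to explicit condition tuples, written from the design semantics
rather than the implementation's classifier.
"""

from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from megdecode.datamodel import ConditionDesign, ConfigError
from megdecode.rsa import (
    COMPONENT_WEIGHTS,
    COMPONENTS,
    build_model_rdm,
    compute_profile,
    enumerate_condition_pairs,
    profile_contrast,
    rsa_correlation,
    searchlight_effect_map,
)


def _oracle_role(a, b, cat):
    """Independent pair-role table (state tuples, not the package rules)."""
    ta = (a.category == cat, a.state)
    tb = (b.category == cat, b.state)
    same_stim = a.stimulus_id == b.stimulus_id
    roles = {
        ((True, "pre"), (True, "pre")): "dU",
        ((True, "post"), (True, "post")): "dR",
        ((False, "s1"), (False, "s1")): "dN",
        ((False, "s2"), (False, "s2")): "dN",
    }
    key = tuple(sorted([ta, tb]))
    if key in roles:
        return roles[key]
    if not ta[0] and not tb[0]:
        return "sNa" if same_stim else "dNa"
    if ta[0] != tb[0]:
        obj_state = ta[1] if ta[0] else tb[1]
        return "RN" if obj_state == "post" else "UN"
    return "sRU" if same_stim else "dRU"


class TestPairEnumeration:
    def test_twenty_eight_pairs_with_table_multiplicities(self, face_design):
        pairs = enumerate_condition_pairs(face_design)
        assert len(pairs) == 28
        counts = Counter(p.component for p in pairs)
        assert tuple(counts[c] for c in COMPONENTS) == COMPONENT_WEIGHTS
        assert counts["UN"] == 8 and counts["sRU"] == 2

    def test_roles_match_independent_oracle(self, face_design):
        by_members = {
            frozenset((p.member_a, p.member_b)): p.component
            for p in enumerate_condition_pairs(face_design)
        }
        for a, b in combinations(face_design.conditions, 2):
            expected = _oracle_role(a, b, "face")
            assert by_members[frozenset((a.label, b.label))] == expected

    def test_tool_design_enumerates_identically(self):
        pairs = enumerate_condition_pairs(ConditionDesign.default("tool"))
        counts = Counter(p.component for p in pairs)
        assert tuple(counts[c] for c in COMPONENTS) == COMPONENT_WEIGHTS


class TestModelRdm:
    def test_twelve_ones_on_recognition_boundary(self, face_design):
        pairs = enumerate_condition_pairs(face_design)
        model = build_model_rdm(pairs)
        assert int(model.values.sum()) == 12
        for p, v in zip(pairs, model.values):
            assert v == (1.0 if p.component in ("RN", "sRU", "dRU") else 0.0)


class TestRsaCorrelation:
    def test_perfect_match_and_reversal(self, face_design):
        model = build_model_rdm(enumerate_condition_pairs(face_design))
        assert rsa_correlation(model.values, model).rho == pytest.approx(1.0)
        assert rsa_correlation(1 - model.values,
                               model).rho == pytest.approx(-1.0)

    def test_high_boundary_entries_give_perfect_rank_correlation(
            self, face_design):
        pairs = enumerate_condition_pairs(face_design)
        model = build_model_rdm(pairs)
        emp = np.where(model.values == 1, 0.7, 0.5)
        assert rsa_correlation(emp, model).rho == pytest.approx(1.0)

    def test_matches_manual_rank_oracle(self, face_design):
        model = build_model_rdm(enumerate_condition_pairs(face_design))
        rng = np.random.default_rng(0)
        emp = rng.uniform(0.4, 0.9, size=28)

        def ranks(x):
            order = np.argsort(x)
            r = np.empty(28)
            r[order] = np.arange(1, 29)
            for v in np.unique(x):
                r[x == v] = r[x == v].mean()
            return r

        ra, rb = ranks(emp), ranks(model.values)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rsa_correlation(emp, model).rho == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self, face_design):
        model = build_model_rdm(enumerate_condition_pairs(face_design))
        emp = np.random.default_rng(1).uniform(0.3, 0.9, size=28)
        base = rsa_correlation(emp, model).rho
        assert rsa_correlation(np.exp(3 * emp), model).rho == \
            pytest.approx(base)

    def test_zero_variance_flagged_degenerate(self, face_design):
        model = build_model_rdm(enumerate_condition_pairs(face_design))
        res = rsa_correlation(np.full(28, 0.5), model)
        assert res.degenerate and res.rho == 0.0 and res.z == 0.0


class TestProfile:
    def test_constant_rdm_gives_flat_profile(self, face_design):
        pairs = enumerate_condition_pairs(face_design)
        prof = compute_profile(np.full(28, 0.5), pairs)
        np.testing.assert_allclose(prof.component_means, 0.5)
        assert prof.low_avg == prof.high_avg == 0.5

    def test_weights_follow_pair_multiplicities(self, face_design):
        prof = compute_profile(np.full(28, 0.5),
                               enumerate_condition_pairs(face_design))
        assert prof.weights.tolist() == [1, 1, 2, 2, 2, 8, 8, 2, 2]
        assert prof.weights.sum() == 28

    def test_elevated_un_component_and_weighted_average_oracle(
            self, face_design):
        pairs = enumerate_condition_pairs(face_design)
        emp = np.array([0.6 if p.component == "UN" else 0.5 for p in pairs])
        prof = compute_profile(emp, pairs)
        expected = dict(zip(COMPONENTS, [0.5] * 9))
        expected["UN"] = 0.6
        np.testing.assert_allclose(
            prof.component_means,
            [expected[c] for c in COMPONENTS])
        # weighted-mean oracle over the six low components (weights 1,1,2,2,2,8)
        assert prof.low_avg == pytest.approx(
            (0.5 * (1 + 1 + 2 + 2 + 2) + 0.6 * 8) / 16)
        assert prof.high_avg == pytest.approx(0.5)

    def test_low_high_averages_recombine_to_overall_mean(self, face_design):
        pairs = enumerate_condition_pairs(face_design)
        emp = np.random.default_rng(2).uniform(0.4, 0.9, size=28)
        prof = compute_profile(emp, pairs)
        overall = (prof.low_avg * 16 + prof.high_avg * 12) / 28
        assert overall == pytest.approx(emp.mean())


class TestProfileContrast:
    def test_identical_profiles_give_zero_contrast(self):
        prof = np.tile(np.linspace(0.5, 0.6, 9), (6, 1))
        values, test = profile_contrast(prof, "RN-UN")
        np.testing.assert_allclose(values, prof[:, 6] - prof[:, 5])

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ConfigError):
            profile_contrast(np.zeros((4, 9)), "XX-YY")

    def test_sna_contrast_tests_against_chance(self):
        prof = np.full((8, 9), 0.5)
        prof[:, 4] = 0.6
        values, test = profile_contrast(prof, "sNa")
        np.testing.assert_allclose(values, 0.6)
        assert test.degenerate  # no variance across subjects


class TestEffectMap:
    def test_all_zero_z_yields_no_significance(self):
        z = np.zeros((5, 3, 10))
        emap = searchlight_effect_map(z, ["a", "b", "c"],
                                      np.arange(10) * 10.0)
        assert not emap.table["significant"].any()

    def test_cell_count_is_regions_times_bins(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(4, 82, 51))
        emap = searchlight_effect_map(z, [f"r{i}" for i in range(82)],
                                      np.arange(51) * 10.0)
        assert len(emap.table) == 82 * 51

    def test_window_summary_applies_half_bins_rule(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(8, 2, 20)) * 0.1
        z[:, 0, 5:10] += 3.0          # strong effect in bins 5..9
        bin_times = np.arange(20) * 10.0
        emap = searchlight_effect_map(z, ["hit", "miss"], bin_times,
                                      windows=[(50.0, 90.0)])
        assert emap.window_summaries[(50.0, 90.0)] == ["hit"]

    def test_single_subject_rejected(self):
        with pytest.raises(ConfigError):
            searchlight_effect_map(np.zeros((1, 2, 5)), ["a", "b"],
                                   np.arange(5.0))
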