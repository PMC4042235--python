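"""Feature perception, hypothesis enumeration and survival scoring."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gridqsar as g
from gridqsar.chem import molecule_from_smiles
from gridqsar.pharmacophore import (FeatureSite, best_site_match,
                                    enumerate_hypotheses, perceive_features,
                                    score_hypothesis, selectivity_score,
                                    volume_overlap)
from conftest import random_rigid_motion, rigid_copy


def _type_counts(mol):
    return Counter(f.feature_type for f in perceive_features(mol))


class TestPerceiveFeatures:
    def test_benzene_single_ring_site(self):
        mol = molecule_from_smiles("c1ccccc1", "bz")
        counts = _type_counts(mol)
        assert counts["R"] == 1
        assert counts["D"] == 0 and counts["A"] == 0
        ring = next(f for f in perceive_features(mol) if f.feature_type == "R")
        np.testing.assert_allclose(ring.position, mol.coords.mean(axis=0),
                                   atol=1e-6)
        assert np.linalg.norm(ring.direction) == pytest.approx(1.0, abs=1e-6)

    def test_thiosemicarbazone_donors_and_ring(self, tsc_molecule):
        counts = _type_counts(tsc_molecule)
        assert counts["D"] >= 2  # terminal NH2 and hydrazide NH
        assert counts["R"] >= 1

    def test_water_donor_and_acceptor_coincide(self):
        mol = molecule_from_smiles("O", "water")
        feats = perceive_features(mol)
        counts = Counter(f.feature_type for f in feats)
        assert counts["D"] == 1 and counts["A"] == 1
        d = next(f for f in feats if f.feature_type == "D")
        a = next(f for f in feats if f.feature_type == "A")
        np.testing.assert_allclose(d.position, a.position)

    def test_ddhrr_feature_inventory(self, ddhrr_molecule):
        counts = _type_counts(ddhrr_molecule)
        assert counts["D"] >= 2 and counts["R"] == 2 and counts["H"] >= 1

    def test_rigid_motion_covariance(self, ddhrr_molecule):
        feats = perceive_features(ddhrr_molecule)
        R, t = random_rigid_motion(13)
        moved = rigid_copy(ddhrr_molecule, 13, "moved")
        moved_feats = perceive_features(moved)
        assert len(moved_feats) == len(feats)
        for f0, f1 in zip(feats, moved_feats):
            assert f0.feature_type == f1.feature_type
            np.testing.assert_allclose(f1.position, R @ f0.position + t,
                                       atol=1e-6)

    def test_direction_normalized(self, ddhrr_molecule):
        for f in perceive_features(ddhrr_molecule):
            if f.direction is not None:
                assert np.linalg.norm(f.direction) == pytest.approx(1.0,
                                                                    abs=1e-6)


class TestEnumerateHypotheses:
    def test_identical_molecules_all_combinations_common(self, ddhrr_actives):
        hyps = enumerate_hypotheses(ddhrr_actives, max_sites=5)
        assert hyps
        assert all(h.match_count == 3 for h in hyps)
        letters = {h.letters for h in hyps}
        assert "DDHRR" in letters

    def test_disjoint_feature_types_give_empty(self):
        a = molecule_from_smiles("c1ccccc1", "ring_only")  # 1 R site
        b = molecule_from_smiles("CCCC", "alkane")  # 1 H site
        assert enumerate_hypotheses([a, b], max_sites=3) == []

    def test_constructed_ddr_triangle(self):
        # three synthetic feature sets sharing one D-D-R triangle geometry
        def sites(jitter_seed):
            rng = np.random.default_rng(jitter_seed)
            base = [FeatureSite("D", [0.0, 0.0, 0.0]),
                    FeatureSite("D", [3.0, 0.0, 0.0]),
                    FeatureSite("R", [0.0, 4.0, 0.0])]
            R, t = random_rigid_motion(jitter_seed)
            return [FeatureSite(s.feature_type, R @ s.position + t)
                    for s in base]
        mols = [molecule_from_smiles("C", f"m{i}") for i in range(3)]
        hyps = enumerate_hypotheses(mols, max_sites=3,
                                    features=[sites(i) for i in range(3)])
        assert len(hyps) == 1
        assert hyps[0].letters == "DDR"
        assert hyps[0].match_count == 3
        assert sorted(np.round(hyps[0].intersite_distances, 6)) == pytest.approx(
            [3.0, 4.0, 5.0])

    def test_id_letters_sorted_and_variants_numbered(self, ddhrr_actives):
        hyps = enumerate_hypotheses(ddhrr_actives, max_sites=4)
        for h in hyps:
            assert h.letters == "".join(sorted(h.letters))
        by_letters = Counter(h.letters for h in hyps)
        for letters, count in by_letters.items():
            ids = [h.id for h in hyps if h.letters == letters]
            assert ids == [f"{letters}.{i + 1}" for i in range(count)]

    def test_min_active_count_enforced(self, ddhrr_molecule):
        with pytest.raises(ValueError):
            enumerate_hypotheses([ddhrr_molecule], max_sites=5)


class TestSurvivalScore:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 3), min_size=4, max_size=4),
           st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_equals_weighted_sum_exactly(self, weights, scores):
        w = g.SurvivalWeights(w_site=weights[0], w_vec=weights[1],
                              w_vol=weights[2], w_sel=weights[3])
        s = g.survival_score(scores[0], scores[1], scores[2], scores[3], w)
        expected = (weights[0] * scores[0] + weights[1] * scores[1]
                    + weights[2] * scores[2] + weights[3] * scores[3])
        assert s == pytest.approx(expected, abs=1e-12)

    def test_component_sum_reference_case(self):
        # unit weights over site/vector/volume, zero selectivity: survival is
        # the plain sum of the three component scores
        w = g.SurvivalWeights(1, 1, 1, 1, 0, 0, 0)
        s = g.survival_score(0.318008, 0.908012, 0.581835, 0.0, w)
        assert s == pytest.approx(1.807855, abs=1e-12)

    def test_zero_components_zero_survival(self):
        w = g.SurvivalWeights(1, 1, 1, 1, 0, 5, 3)
        assert g.survival_score(0, 0, 0, 0, w) == 0.0

    def test_doubling_weights_doubles_survival(self):
        w1 = g.SurvivalWeights(0.5, 1.0, 1.5, 2.0, 0, 0, 0)
        w2 = g.SurvivalWeights(1.0, 2.0, 3.0, 4.0, 0, 0, 0)
        args = (0.3, 0.9, 0.5, 0.7)
        assert g.survival_score(*args, w2) == pytest.approx(
            2 * g.survival_score(*args, w1), rel=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            g.SurvivalWeights(w_site=-1.0)


class TestScoring:
    def test_self_hypothesis_maximal_site_score(self, ddhrr_actives):
        hyps = enumerate_hypotheses(ddhrr_actives, max_sites=5)
        h = next(x for x in hyps if x.letters == "DDHRR")
        scores = score_hypothesis(h, ddhrr_actives)
        assert scores.site_score == pytest.approx(1.0, abs=1e-6)
        assert scores.matches == 3
        assert scores.survival_inactive is None

    def test_survival_inactive_subtracts(self, ddhrr_actives):
        hyps = enumerate_hypotheses(ddhrr_actives, max_sites=5)
        h = next(x for x in hyps if x.letters == "DDHRR")
        inactives = [molecule_from_smiles("c1ccccc1", "bz")]
        scores = score_hypothesis(h, ddhrr_actives, inactives)
        # benzene cannot match a 5-site DDHRR hypothesis: inactive term 0
        assert scores.survival_inactive == pytest.approx(scores.survival)

    def test_selectivity_is_rarity(self, ddhrr_actives):
        hyps = enumerate_hypotheses(ddhrr_actives, max_sites=5)
        h = next(x for x in hyps if x.letters == "DDHRR")
        sel = selectivity_score(h, ddhrr_actives)
        # 3 of the 18 five-site combinations (6 per molecule) share this key
        assert sel == pytest.approx(-np.log10(3 / 18), abs=1e-9)

    def test_volume_overlap_identity_and_disjoint(self):
        pts = np.random.default_rng(0).standard_normal((5, 3))
        assert volume_overlap(pts, pts) == pytest.approx(1.0)
        assert volume_overlap(pts, pts + 100.0) == pytest.approx(0.0)


class TestRanking:
    def _scored(self, hid, survival, selectivity):
        h = g.PharmacophoreHypothesis(
            hid, [FeatureSite("D", [0, 0, 0]), FeatureSite("R", [1, 0, 0]),
                  FeatureSite("H", [0, 1, 0])],
            [1.0, 1.0, np.sqrt(2)])
        s = g.HypothesisScores(hid, 0, 0, 0, selectivity, 0, 0, 3,
                               survival)
        return h, s

    def test_single_hypothesis(self):
        scored = [self._scored("DHR.1", 2.0, 1.0)]
        assert g.rank_hypotheses(scored) == scored

    def test_tie_broken_by_selectivity(self):
        low = self._scored("DHR.1", 2.0, 1.0)
        high = self._scored("DHR.2", 2.0, 2.0)
        ranked = g.rank_hypotheses([low, high])
        assert [h.id for h, _ in ranked] == ["DHR.2", "DHR.1"]

    def test_order_independent_of_input_permutation(self):
        items = [self._scored(f"DHR.{i + 1}", s, sel)
                 for i, (s, sel) in enumerate([(2.0, 1.0), (3.0, 0.5),
                                               (2.0, 2.0)])]
        a = g.rank_hypotheses(items)
        b = g.rank_hypotheses(items[::-1])
        assert [h.id for h, _ in a] == [h.id for h, _ in b]


class TestBestSiteMatch:
    def test_source_molecule_matches_with_zero_rmsd(self, ddhrr_actives):
        hyps = enumerate_hypotheses(ddhrr_actives, max_sites=5)
        h = next(x for x in hyps if x.letters == "DDHRR")
        source = next(m for m in ddhrr_actives if m.id == h.source_id)
        match = best_site_match(h, perceive_features(source))
        assert match is not None
        assert match.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_missing_type_returns_none(self, ddhrr_actives):
        hyps = enumerate_hypotheses(ddhrr_actives, max_sites=5)
        h = next(x for x in hyps if x.letters == "DDHRR")
        benzene = molecule_from_smiles("c1ccccc1", "bz")
        assert best_site_match(h, perceive_features(benzene)) is None
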