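"""Tests of the objective functions: fingerprints, dice similarity, the
synthetic-accessibility / solubility / drug-likeness components, their
normalizations, the composite score, and the mock predictor backend."""

import math

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import QED
from rdkit.Chem.AtomPairs import Pairs

from mclig.compound import Compound, benzene
from mclig.fixtures import REFERENCE_COMPONENT_ROWS
from mclig.moves import MoveSet, propose
from mclig.scoring import (
    CompositeWeights,
    MockBackend,
    ScoreBreakdown,
    ScoringConfig,
    atom_pair_fingerprint,
    composite_score,
    dice_from_counts,
    dice_similarity,
    esol_score,
    normalize_esol,
    normalize_sa,
    qed_no_mw,
    sa_score,
)


class TestAtomPairFingerprint:
    def test_single_heavy_atom_has_no_pairs(self):
        assert atom_pair_fingerprint(Compound.from_smiles("C")) == {}

    def test_atom_order_invariance(self):
        a = atom_pair_fingerprint(Compound.from_smiles("c1ccccc1CCO"))
        b = atom_pair_fingerprint(Compound.from_smiles("OCCc1ccccc1"))
        assert a == b

    def test_butane_pair_count_totals(self):
        # n-butane has C(4,2)=6 heavy-atom pairs, each counted once
        fp = atom_pair_fingerprint(Compound.from_smiles("CCCC"))
        assert sum(fp.values()) == 6

    def test_matches_reference_implementation(self):
        c = Compound.from_smiles("CC(=O)Nc1ccc(O)cc1")
        ref = Pairs.GetAtomPairFingerprint(c.mol).GetNonzeroElements()
        assert atom_pair_fingerprint(c) == dict(ref)


class TestDiceSimilarity:
    def test_identity(self):
        for smi in ["C", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1"]:
            assert dice_similarity(
                Compound.from_smiles(smi), Compound.from_smiles(smi)
            ) == pytest.approx(1.0)

    def test_benzene_toluene_matches_reference(self):
        a, b = benzene(), Compound.from_smiles("Cc1ccccc1")
        ref = DataStructs.DiceSimilarity(
            Pairs.GetAtomPairFingerprint(a.mol), Pairs.GetAtomPairFingerprint(b.mol)
        )
        assert dice_similarity(a, b) == pytest.approx(ref)

    def test_symmetry_on_random_pairs(self, diverse_compounds):
        rng = np.random.default_rng(0)
        for _ in range(100):
            i, j = rng.integers(len(diverse_compounds), size=2)
            a, b = diverse_compounds[i], diverse_compounds[j]
            assert dice_similarity(a, b) == pytest.approx(dice_similarity(b, a))

    def test_empty_fingerprints_count_as_identical(self):
        assert dice_from_counts({}, {}) == 1.0


class TestSAScore:
    def test_scale_direction_complexity(self):
        simple = sa_score(Compound.from_smiles("c1ccccc1"))
        spiro = sa_score(Compound.from_smiles("C1CC2(CC1)CCC1(CCCC1)CC2"))
        assert spiro > simple

    def test_benzene_is_easy(self):
        assert sa_score(benzene()) < 5.5

    @pytest.mark.parametrize(
        "row", REFERENCE_COMPONENT_ROWS, ids=lambda r: r.smiles[:20]
    )
    def test_reference_values(self, row):
        assert sa_score(Compound.from_smiles(row.smiles)) == pytest.approx(
            row.sa_raw, abs=0.1
        )


class TestESOLScore:
    def test_long_alkyl_chain_reduces_solubility(self):
        short = esol_score(Compound.from_smiles("CCO"))
        long = esol_score(Compound.from_smiles("CCCCCCCCCCCCO"))
        assert long < short

    @pytest.mark.parametrize(
        "row", REFERENCE_COMPONENT_ROWS, ids=lambda r: r.smiles[:20]
    )
    def test_reference_values(self, row):
        assert esol_score(Compound.from_smiles(row.smiles)) == pytest.approx(
            row.esol_raw, abs=0.3
        )

    def test_methane_limit_is_near_intercept(self):
        # with MW/logP contributions only (no rotatable bonds, no aromatics)
        c = Compound.from_smiles("C")
        from rdkit.Chem import Crippen, Descriptors

        expected = (
            0.16
            - 0.63 * Crippen.MolLogP(c.mol)
            - 0.0062 * Descriptors.MolWt(c.mol)
        )
        assert esol_score(c) == pytest.approx(expected)


class TestQEDNoMW:
    @pytest.mark.parametrize(
        "row", REFERENCE_COMPONENT_ROWS, ids=lambda r: r.smiles[:20]
    )
    def test_reference_values(self, row):
        assert qed_no_mw(Compound.from_smiles(row.smiles)) == pytest.approx(
            row.qed, abs=0.05
        )

    def test_heavy_molecule_not_penalized_for_weight(self):
        # a very heavy but otherwise drug-like molecule: dropping the MW
        # desirability must raise the score relative to full QED
        heavy = Compound.from_smiles(
            "CCCCCCCCCCCCCCCCCCCCCCCCc1ccc(C(=O)NCCN(CC)CC)cc1OC"
        )
        assert qed_no_mw(heavy) > QED.qed(heavy.mol)

    def test_bounded(self, diverse_compounds):
        for c in diverse_compounds:
            assert 0.0 <= qed_no_mw(c) <= 1.0


class TestNormalizations:
    def test_sa_at_threshold_is_one(self):
        assert normalize_sa(5.0, threshold=5.0) == 1.0
        assert normalize_sa(3.2, threshold=5.0) == 1.0

    def test_sa_at_ten_is_zero(self):
        assert normalize_sa(10.0, threshold=5.0) == 0.0

    def test_sa_midpoint(self):
        assert normalize_sa(7.5, threshold=5.0) == pytest.approx(0.5)

    def test_esol_boundaries_and_midpoint(self):
        assert normalize_esol(-1.0, lo=-10.0, hi=-1.0) == 1.0
        assert normalize_esol(-10.0, lo=-10.0, hi=-1.0) == 0.0
        assert normalize_esol(-5.5, lo=-10.0, hi=-1.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            normalize_esol(0.0, lo=1.0, hi=0.0)


class TestCompositeScore:
    def test_all_ones_gives_one(self):
        bd = ScoreBreakdown.combine(confidence=1.0, sa_raw=1.0, esol_raw=0.0, qed=1.0)
        assert bd.sa_norm == 1.0 and bd.esol_norm == 1.0
        assert bd.composite == pytest.approx(1.0)

    def test_confidence_only_weights(self):
        w = CompositeWeights(1.0, 0.0, 0.0, 0.0)
        bd = ScoreBreakdown.combine(
            confidence=0.4321, sa_raw=9.9, esol_raw=-12.0, qed=0.1, weights=w
        )
        assert bd.composite == 0.4321

    def test_half_confidence_rest_zero(self):
        bd = ScoreBreakdown.combine(
            confidence=0.5, sa_raw=10.0, esol_raw=-100.0, qed=0.0
        )
        assert bd.composite == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "row", REFERENCE_COMPONENT_ROWS, ids=lambda r: r.smiles[:20]
    )
    def test_reference_composites_from_printed_components(self, row):
        """With the calibrated solubility window and SA threshold, the
        published composite is reproduced from its printed components."""
        bd = ScoreBreakdown.combine(
            confidence=row.confidence,
            sa_raw=row.sa_raw,
            esol_raw=row.esol_raw,
            qed=row.qed,
        )
        assert bd.composite == pytest.approx(row.composite, abs=0.01)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            CompositeWeights(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            CompositeWeights(-0.1, 0.6, 0.25, 0.25)

    def test_breakdown_identity_holds_on_walk_compounds(self, diverse_compounds):
        backend = MockBackend()
        w, cfg = CompositeWeights(), ScoringConfig()
        for c in diverse_compounds:
            bd = composite_score(c, backend, "", w, cfg)
            expected = (
                w.w_conf * bd.confidence
                + w.w_sa * bd.sa_norm
                + w.w_esol * bd.esol_norm
                + w.w_qed * bd.qed
            )
            assert bd.composite == pytest.approx(expected, abs=1e-12)
            for v in (bd.confidence, bd.sa_norm, bd.esol_norm, bd.qed, bd.composite):
                assert 0.0 <= v <= 1.0


class TestBoundedness:
    def test_components_bounded_over_random_walk(self):
        """All normalized components stay in [0, 1] across a move-engine walk."""
        backend = MockBackend()
        ms = MoveSet()
        rng = np.random.default_rng(11)
        cur = benzene()
        for _ in range(300):
            o = propose(cur, ms, rng)
            if not o.feasible:
                continue
            cur = o.compound
            bd = composite_score(cur, backend, "")
            assert 0.0 <= bd.composite <= 1.0
            assert 0.0 <= bd.sa_norm <= 1.0
            assert 0.0 <= bd.esol_norm <= 1.0
            assert 0.0 <= bd.qed <= 1.0
            assert 0.0 <= bd.confidence <= 1.0


class TestMockBackend:
    def test_deterministic(self):
        b = MockBackend()
        assert b.predict("MKV", "c1ccccc1") == b.predict("MKV", "c1ccccc1")

    def test_value_one_at_optimum(self):
        c = Compound.from_smiles("CC(=O)Nc1ccc(O)cc1")
        b = MockBackend()
        d = b.descriptors(c.mol)
        tuned = MockBackend(optimum=d)
        conf, structure = tuned.predict("", c.smiles)
        assert conf == pytest.approx(1.0)
        assert structure is None

    def test_farther_is_strictly_lower(self):
        b = MockBackend(optimum=(6.0, 0.0, 0.0, 1.0))  # benzene's descriptors
        near, _ = b.predict("", "c1ccccc1")
        mid, _ = b.predict("", "Cc1ccccc1")
        far, _ = b.predict("", "CCCCCCCCCCc1ccc(O)c(O)c1")
        assert near > mid > far

    def test_bounded(self, diverse_compounds):
        b = MockBackend()
        for c in diverse_compounds:
            conf, _ = b.predict("", c.smiles)
            assert 0.0 <= conf <= 1.0
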