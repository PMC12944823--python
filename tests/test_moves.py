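"""Unit and property tests of the nine chemical-move operators."""

import numpy as np
import pytest
from rdkit import Chem

from mclig.compound import Compound, benzene
from mclig.moves import (
    DEFAULT_MOVE_PROBS,
    MoveKind,
    MoveSet,
    add_atom_in_chain,
    add_group,
    apply_move,
    break_ring,
    change_atom_type,
    change_bond_type,
    form_ring,
    propose,
    rearrange_bonds,
    remove_atom,
    toggle_aromatic,
)


def products(op, smiles, n=300, seed=0, **kw):
    """Set of canonical SMILES reachable by one application of ``op``."""
    c = Compound.from_smiles(smiles)
    rng = np.random.default_rng(seed)
    out = set()
    for _ in range(n):
        o = op(c, rng, **kw)
        if o.feasible:
            out.add(o.compound.smiles)
    return out


class TestMoveSet:
    def test_default_probabilities_are_standard(self):
        ms = MoveSet()
        probs = dict(ms.entries)
        assert probs[MoveKind.ADD_GROUP] == 0.3
        assert probs[MoveKind.REMOVE_ATOM] == 0.2
        assert probs[MoveKind.CHANGE_ATOM_TYPE] == 0.1
        assert probs[MoveKind.ADD_ATOM_IN_CHAIN] == 0.15
        assert probs[MoveKind.CHANGE_BOND_TYPE] == 0.025
        assert probs[MoveKind.FORM_RING] == 0.025
        assert probs[MoveKind.BREAK_RING] == 0.05
        assert probs[MoveKind.TOGGLE_AROMATIC] == 0.05
        assert probs[MoveKind.REARRANGE_BONDS] == 0.1
        assert abs(sum(probs.values()) - 1.0) < 1e-9

    @pytest.mark.parametrize(
        "entries",
        [
            [(MoveKind.ADD_GROUP, 0.5)],  # does not sum to 1
            [(MoveKind.ADD_GROUP, -0.1), (MoveKind.REMOVE_ATOM, 1.1)],
        ],
    )
    def test_invalid_probabilities_rejected(self, entries):
        with pytest.raises(ValueError):
            MoveSet(entries=entries)


class TestAddGroup:
    def test_benzene_to_toluene(self):
        assert "Cc1ccccc1" in products(add_group, "c1ccccc1")

    def test_methane_to_methanol(self):
        assert "CO" in products(add_group, "C")

    def test_no_substitutable_position(self, rng):
        # fully fluorinated carbon: no H anywhere
        c = Compound.from_smiles("FC(F)(F)F")
        o = add_group(c, rng)
        assert not o.feasible
        assert o.compound == c


class TestRemoveAtom:
    def test_toluene_to_benzene(self):
        assert "c1ccccc1" in products(remove_atom, "Cc1ccccc1")

    def test_ethane_to_methane(self):
        assert products(remove_atom, "CC") == {"C"}

    def test_single_atom_infeasible(self, rng):
        assert not remove_atom(Compound.from_smiles("C"), rng).feasible

    def test_ring_atom_removal_opens_ring(self):
        # deleting a benzene carbon leaves a sanitizable acyclic C5 chain
        prods = products(remove_atom, "c1ccccc1")
        assert prods
        for smi in prods:
            m = Chem.MolFromSmiles(smi)
            assert m is not None
            assert m.GetRingInfo().NumRings() == 0
            assert m.GetNumHeavyAtoms() == 5

    def test_disconnection_keeps_largest_fragment(self):
        # central atom of an asymmetric chain: biggest side is retained
        prods = products(remove_atom, "CCCCCOCC")
        assert "CCCCC" in prods


class TestChangeAtomType:
    def test_benzene_to_pyridine(self):
        assert "c1ccncc1" in products(change_atom_type, "c1ccccc1")

    def test_methanol_to_methanethiol(self):
        assert "CS" in products(change_atom_type, "CO")

    def test_isolated_atom_swap_infeasible(self, rng):
        # methane C -> F would need a tetravalent halogen; rejected
        c = Compound.from_smiles("C")
        for _ in range(20):
            assert not change_atom_type(c, rng).feasible

    def test_valence_filter_blocks_halogen_in_chain(self):
        # propane's central carbon (two heavy bonds) can never become F
        prods = products(change_atom_type, "CCC")
        assert "CFC" not in prods


class TestAddAtomInChain:
    def test_ethane_to_propane(self):
        assert "CCC" in products(add_atom_in_chain, "CC")

    def test_methanol_to_ethanol_skeleton(self):
        assert "CCO" in products(add_atom_in_chain, "CO")

    def test_aromatic_insert_gives_seven_ring(self):
        prods = products(add_atom_in_chain, "c1ccccc1", n=100)
        sizes = set()
        for s in prods:
            m = Chem.MolFromSmiles(s)
            if m is not None:
                sizes.update(len(r) for r in m.GetRingInfo().AtomRings())
        assert 7 in sizes


class TestChangeBondType:
    def test_ethane_to_ethene_and_back(self):
        assert products(change_bond_type, "CC") == {"C=C"}
        assert products(change_bond_type, "C=C") == {"CC"}

    def test_quaternary_carbon_infeasible(self, rng):
        c = Compound.from_smiles("CC(C)(C)C")
        for _ in range(50):
            o = change_bond_type(c, rng)
            assert not o.feasible


class TestFormRing:
    def test_hexane_to_cyclohexane(self):
        assert "C1CCCCC1" in products(form_ring, "CCCCCC")

    def test_propane_to_cyclopropane(self):
        assert "C1CC1" in products(form_ring, "CCC")

    def test_ethane_infeasible(self, rng):
        assert not form_ring(Compound.from_smiles("CC"), rng).feasible


class TestBreakRing:
    def test_cyclohexane_to_hexane(self):
        assert products(break_ring, "C1CCCCC1") == {"CCCCCC"}

    def test_benzene_to_triene(self):
        prods = products(break_ring, "c1ccccc1")
        assert "C=CC=CC=C" in prods
        for smi in prods:
            m = Chem.MolFromSmiles(smi)
            assert all(not a.GetIsAromatic() for a in m.GetAtoms())

    def test_acyclic_infeasible(self, rng):
        assert not break_ring(Compound.from_smiles("C"), rng).feasible


class TestToggleAromatic:
    def test_cyclohexane_aromatizes_to_benzene(self, rng):
        o = toggle_aromatic(Compound.from_smiles("C1CCCCC1"), rng)
        assert o.feasible and o.compound.smiles == "c1ccccc1"

    def test_benzene_dearomatizes_to_diene_ring(self, rng):
        o = toggle_aromatic(benzene(), rng)
        assert o.feasible
        m = o.compound.mol
        assert all(not a.GetIsAromatic() for a in m.GetAtoms())
        assert m.GetRingInfo().NumRings() == 1

    def test_cyclopentane_cannot_aromatize(self, rng):
        for _ in range(10):
            assert not toggle_aromatic(Compound.from_smiles("C1CCCC1"), rng).feasible

    def test_pyrrolidine_aromatizes_with_nh(self, rng):
        o = toggle_aromatic(Compound.from_smiles("C1CCNC1"), rng)
        assert o.feasible and o.compound.smiles == "c1cc[nH]c1"


class TestRearrangeBonds:
    def test_isobutane_to_nbutane(self):
        # brute-force enumeration: n-butane must be among the legal products
        assert "CCCC" in products(rearrange_bonds, "CC(C)C")

    def test_ethane_infeasible(self, rng):
        assert not rearrange_bonds(Compound.from_smiles("CC"), rng).feasible

    def test_neopentane_to_isopentane(self):
        assert "CCC(C)C" in products(rearrange_bonds, "CC(C)(C)C")


class TestReversibilityPairs:
    """Mutually inverse move pairs on the worked examples."""

    def test_add_then_remove_restores_benzene(self):
        toluene = "Cc1ccccc1"
        assert toluene in products(add_group, "c1ccccc1")
        assert "c1ccccc1" in products(remove_atom, toluene)

    def test_form_then_break_restores_hexane(self):
        assert "C1CCCCC1" in products(form_ring, "CCCCCC")
        assert "CCCCCC" in products(break_ring, "C1CCCCC1")

    def test_toggle_aromatic_is_self_inverse(self, rng):
        hexadiene_ring = toggle_aromatic(benzene(), rng).compound
        back = toggle_aromatic(hexadiene_ring, np.random.default_rng(0))
        assert back.feasible and back.compound.smiles == "c1ccccc1"


class TestPropose:
    def test_forced_single_move(self, rng):
        ms = MoveSet(entries=[(MoveKind.ADD_GROUP, 1.0)])
        o = propose(benzene(), ms, rng)
        assert o.feasible and o.move_kind == MoveKind.ADD_GROUP

    def test_degenerate_input_returns_infeasible(self, rng):
        ms = MoveSet(entries=[(MoveKind.REMOVE_ATOM, 1.0)])
        o = propose(Compound.from_smiles("C"), ms, rng)
        assert not o.feasible
        assert o.compound.smiles == "C"

    def test_determinism(self):
        ms = MoveSet()
        a = propose(benzene(), ms, np.random.default_rng(77))
        b = propose(benzene(), ms, np.random.default_rng(77))
        assert a.compound.smiles == b.compound.smiles
        assert a.move_kind == b.move_kind
        assert a.detail == b.detail

    def test_draw_frequencies_match_probabilities(self):
        # chi-square of drawn move kinds against the standard probabilities
        ms = MoveSet()
        rng = np.random.default_rng(5)
        n = 10_000
        counts = {k: 0 for k in ms.kinds}
        for _ in range(n):
            counts[ms.draw(rng)] += 1
        for (kind, p) in ms.entries:
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[kind] - n * p) < 3 * sigma, kind


class TestClosure:
    """Every proposal from any reachable state must sanitize."""

    def test_random_walks_stay_valid(self, diverse_compounds):
        ms = MoveSet()
        rng = np.random.default_rng(0)
        for c in diverse_compounds:
            cur = c
            for _ in range(150):
                o = propose(cur, ms, rng)
                if o.feasible:
                    # independently re-sanitize through a SMILES round trip
                    assert Chem.MolFromSmiles(o.compound.smiles) is not None
                    cur = o.compound

    def test_reachability_from_benzene(self):
        """A long walk from benzene visits every allowed element, small and
        large rings, and at least one aromatic heterocycle."""
        ms = MoveSet()
        rng = np.random.default_rng(3)
        cur = benzene()
        elements, ring_sizes, het_aromatic = set(), set(), False
        for _ in range(10_000):
            o = propose(cur, ms, rng)
            if not o.feasible:
                continue
            cur = o.compound
            m = cur.mol
            for a in m.GetAtoms():
                elements.add(a.GetSymbol())
                if a.GetIsAromatic() and a.GetSymbol() != "C":
                    het_aromatic = True
            for ring in m.GetRingInfo().AtomRings():
                ring_sizes.add(len(ring))
        assert {"C", "N", "O", "S", "F", "Cl", "Br", "P"} <= elements
        assert {3, 4, 5, 6, 7} <= ring_sizes
        assert het_aromatic


class TestApplyMove:
    @pytest.mark.parametrize("kind", list(MoveKind))
    def test_every_operator_runs(self, kind):
        c = Compound.from_smiles("CC(=O)Nc1ccc(O)cc1")
        rng = np.random.default_rng(1)
        outcomes = [apply_move(c, kind, rng) for _ in range(30)]
        assert any(o.feasible for o in outcomes), kind
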