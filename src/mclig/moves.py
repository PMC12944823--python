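"""Elementary chemical moves for the atomistic-step Monte Carlo search.

Nine operators each turn a valid molecule into a new valid molecule by a
small constitutional edit: adding a substituent, deleting an atom, mutating
an element, inserting an atom into a bond, toggling a bond order, closing or
opening a ring, switching a ring between aromatic and non-aromatic form, and
migrating a substituent between neighbouring atoms.  Every operator draws its
edit site from the supplied RNG and returns a :class:`MoveOutcome`; edits
that cannot yield a sanitizable neutral molecule are reported as infeasible
rather than raised.

Aromatic systems are kekulized (with aromatic flags cleared) before any edit
that touches them, and aromaticity is re-perceived by sanitization afterwards,
so the chain never carries a partially aromatic state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops

from .compound import Compound


class MoveKind(str, enum.Enum):
    ADD_GROUP = "add_group"
    REMOVE_ATOM = "remove_atom"
    CHANGE_ATOM_TYPE = "change_atom_type"
    ADD_ATOM_IN_CHAIN = "add_atom_in_chain"
    CHANGE_BOND_TYPE = "change_bond_type"
    FORM_RING = "form_ring"
    BREAK_RING = "break_ring"
    TOGGLE_AROMATIC = "toggle_aromatic"
    REARRANGE_BONDS = "rearrange_bonds"


#: Standard selection probabilities of the atomistic move catalogue.
DEFAULT_MOVE_PROBS: dict[MoveKind, float] = {
    MoveKind.ADD_GROUP: 0.3,
    MoveKind.REMOVE_ATOM: 0.2,
    MoveKind.CHANGE_ATOM_TYPE: 0.1,
    MoveKind.ADD_ATOM_IN_CHAIN: 0.15,
    MoveKind.CHANGE_BOND_TYPE: 0.025,
    MoveKind.FORM_RING: 0.025,
    MoveKind.BREAK_RING: 0.05,
    MoveKind.TOGGLE_AROMATIC: 0.05,
    MoveKind.REARRANGE_BONDS: 0.1,
}

#: Substituent inventory for ``add_group``: (name, fragment SMILES, index of
#: the attachment atom in the fragment, bond order, H atoms consumed).
DEFAULT_GROUPS: list[tuple[str, str, int, Chem.BondType, int]] = [
    ("CH3", "C", 0, Chem.BondType.SINGLE, 1),
    ("OH", "O", 0, Chem.BondType.SINGLE, 1),
    ("NH2", "N", 0, Chem.BondType.SINGLE, 1),
    ("F", "F", 0, Chem.BondType.SINGLE, 1),
    ("Cl", "Cl", 0, Chem.BondType.SINGLE, 1),
    ("Br", "Br", 0, Chem.BondType.SINGLE, 1),
    ("=O", "O", 0, Chem.BondType.DOUBLE, 2),
    ("OCH3", "OC", 0, Chem.BondType.SINGLE, 1),
    ("SH", "S", 0, Chem.BondType.SINGLE, 1),
    ("CN", "C#N", 0, Chem.BondType.SINGLE, 1),
    ("CF3", "C(F)(F)F", 0, Chem.BondType.SINGLE, 1),
    ("COCH3", "C(C)=O", 0, Chem.BondType.SINGLE, 1),
    ("CONH2", "C(N)=O", 0, Chem.BondType.SINGLE, 1),
]

#: Elements allowed for atom mutation and chain insertion.
DEFAULT_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "P")

# Bond-order capacity per element used as a pre-filter for atom mutation and
# chain insertion.  S and P are capped at their common organic-chemistry
# valences (sulfide/phosphine-like) so mutations do not flood the search with
# hypervalent ring systems; higher oxidation states can still be reached via
# group addition.  Final validity is always decided by RDKit sanitization.
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "P": 3}

#: Ring sizes considered by ``form_ring``.
DEFAULT_RING_WINDOW: tuple[int, int] = (3, 7)

#: Relative draw weights for the atom inserted by ``add_atom_in_chain``;
#: carbon-dominant to mirror the composition of organic scaffolds (element
#: diversity enters mainly through atom-type mutation).
DEFAULT_INSERT_WEIGHTS: dict[str, float] = {"C": 0.60, "N": 0.20, "O": 0.12, "S": 0.06, "P": 0.02}

MAX_PROPOSE_RETRIES = 25

#: Reactive or unstable motifs the move engine never emits.  The search
#: otherwise accretes these faster than it can shed them (they mimic the
#: pair-count statistics of amide/heterocycle motifs at a fraction of the
#: constitutional cost) and they are shunned in medicinal chemistry anyway.
_STRUCTURAL_ALERTS: list[tuple[str, str]] = [
    ("cumulene", "[*]=[*]=[*]"),
    ("nitroso", "[NX2]=O"),
    ("peroxide", "[#8]~[#8]"),
    ("disulfide", "[#16]~[#16]"),
    ("aldehyde", "[CX3H1]=[OX1]"),
    ("thiocarbonyl-H", "[CX3H1]=[SX1]"),
    ("acyclic imine", "[C;!R]=[N;!R]"),
    ("1,2-diketone", "[CX3](=[OX1])[CX3](=[OX1])"),
    ("sulfenamide", "[SX2][#7]"),
    ("tetrasubstituted acyclic alkene", "[C;X3;H0;!R]=[C;X3;H0;!R]"),
]
_ALERT_PATTERNS = [
    (name, Chem.MolFromSmarts(smarts)) for name, smarts in _STRUCTURAL_ALERTS
]


@dataclass(frozen=True)
class MoveOutcome:
    """Result of applying one chemical move."""

    compound: Compound
    move_kind: Optional[MoveKind]
    feasible: bool
    detail: str = ""


@dataclass
class MoveSet:
    """Catalogue of move operators with selection probabilities."""

    entries: list[tuple[MoveKind, float]] = field(
        default_factory=lambda: list(DEFAULT_MOVE_PROBS.items())
    )

    def __post_init__(self) -> None:
        total = 0.0
        for kind, p in self.entries:
            if p < 0:
                raise ValueError(f"negative probability for {kind}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"move probabilities sum to {total}, expected 1")

    @property
    def kinds(self) -> list[MoveKind]:
        return [k for k, _ in self.entries]

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.entries], dtype=float)

    def draw(self, rng: np.random.Generator) -> MoveKind:
        idx = rng.choice(len(self.entries), p=self.probabilities)
        return self.entries[idx][0]

    @classmethod
    def from_mapping(cls, probs: dict[str, float]) -> "MoveSet":
        return cls(entries=[(MoveKind(k), float(v)) for k, v in probs.items()])


# ---------------------------------------------------------------------------
# helpers


def _infeasible(c: Compound, kind: Optional[MoveKind], detail: str) -> MoveOutcome:
    return MoveOutcome(compound=c, move_kind=kind, feasible=False, detail=detail)


def _kekulized_rw(mol: Chem.Mol) -> Chem.RWMol:
    m = Chem.RWMol(mol)
    Chem.Kekulize(m, clearAromaticFlags=True)
    return m


def _finalize(
    mol: Chem.Mol, original: Compound, kind: MoveKind, detail: str
) -> MoveOutcome:
    """Sanitize an edited molecule; reject edits that leave chemistry invalid
    or introduce formal charges (all moves operate on neutral molecules)."""
    # normalize H bookkeeping so deleted bonds are healed with implicit H
    # instead of silently becoming radical centres
    for a in mol.GetAtoms():
        a.SetNumRadicalElectrons(0)
        a.SetNoImplicit(False)
    try:
        product = Compound.from_mol(mol)
    except Exception:
        return _infeasible(original, kind, f"{detail}: sanitization failed")
    if any(
        a.GetFormalCharge() != 0 or a.GetNumRadicalElectrons() != 0
        for a in product.mol.GetAtoms()
    ):
        return _infeasible(original, kind, f"{detail}: charged/radical product")
    # stay inside drug-like ring space: no rings beyond the form_ring window
    # (macrocycles otherwise accrete via repeated chain insertion) and no
    # tropone-type aromatic rings larger than 6 atoms, which RDKit's
    # aromaticity model would happily perceive
    ring_info = product.mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if len(ring) > DEFAULT_RING_WINDOW[1]:
            return _infeasible(original, kind, f"{detail}: ring size {len(ring)}")
        if len(ring) not in (5, 6) and all(
            product.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring
        ):
            return _infeasible(original, kind, f"{detail}: aromatic {len(ring)}-ring")
        if len(ring) <= 4:
            n_double = sum(
                1
                for i in ring
                for j in ring
                if i < j
                and (b := product.mol.GetBondBetweenAtoms(i, j)) is not None
                and b.GetBondType() == Chem.BondType.DOUBLE
            )
            if n_double > 1:  # cyclobutadiene-type strained rings
                return _infeasible(original, kind, f"{detail}: strained diene ring")
    for name, patt in _ALERT_PATTERNS:
        if product.mol.HasSubstructMatch(patt):
            return _infeasible(original, kind, f"{detail}: {name}")
    # keep S and P at their common organic valences regardless of which move
    # produced them (RDKit itself tolerates hypervalent states); aromatic
    # heteroatoms are fine as long as they carry no extra H (thiophene yes,
    # thiabenzene no)
    for a in product.mol.GetAtoms():
        sym = a.GetSymbol()
        if sym in ("F", "Cl", "Br"):
            # halogens only on carbon (N-halogen/O-halogen are not drug-like)
            nbrs = a.GetNeighbors()
            if nbrs and nbrs[0].GetSymbol() != "C":
                return _infeasible(original, kind, f"{detail}: {sym} on heteroatom")
            continue
        if sym not in ("S", "P"):
            continue
        if a.GetIsAromatic():
            if a.GetTotalNumHs() > 0:
                return _infeasible(original, kind, f"{detail}: aromatic {sym}-H")
            continue
        if _bond_order_sum(a) + a.GetTotalNumHs() > _MAX_VALENCE[sym]:
            return _infeasible(original, kind, f"{detail}: hypervalent {sym}")
        if sym == "P" and any(
            b.GetBondType() != Chem.BondType.SINGLE for b in a.GetBonds()
        ):
            return _infeasible(original, kind, f"{detail}: multiply bonded P")
    return MoveOutcome(compound=product, move_kind=kind, feasible=True, detail=detail)


def _bond_order_sum(atom: Chem.Atom) -> float:
    return sum(b.GetBondTypeAsDouble() for b in atom.GetBonds())


def _try_aromatize(
    base: Chem.Mol,
    ring: Sequence[int],
    original: Compound,
    kind: MoveKind,
    detail: str,
) -> Optional[MoveOutcome]:
    """Attempt to make ``ring`` of ``base`` (a kekulé molecule with aromatic
    flags cleared) aromatic, adjusting bond orders and H counts as needed.

    Exocyclic double bonds on ring atoms may be demoted to single bonds, and
    one ring nitrogen may become a pyrrole-type H-bearer.  Variants are tried
    in a deterministic order preferring minimal adjustment; returns the first
    sanitizable outcome or ``None``.
    """
    import itertools

    ring_set = set(ring)
    exo_doubles = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in base.GetBonds()
        if b.GetBondType() != Chem.BondType.SINGLE
        and (b.GetBeginAtomIdx() in ring_set) != (b.GetEndAtomIdx() in ring_set)
    ]
    n_candidates = [None] + [
        i for i in ring if base.GetAtomWithIdx(i).GetAtomicNum() == 7
    ]
    for k in range(len(exo_doubles) + 1):
        for demote in itertools.combinations(exo_doubles, k):
            for nh_atom in n_candidates:
                rw = Chem.RWMol(base)
                for ai, bi in demote:
                    rw.GetBondBetweenAtoms(ai, bi).SetBondType(Chem.BondType.SINGLE)
                for i in ring:
                    a = rw.GetAtomWithIdx(i)
                    a.SetIsAromatic(True)
                    a.SetNoImplicit(False)
                    a.SetNumExplicitHs(1 if i == nh_atom else 0)
                for i in ring:
                    for j in ring:
                        if i < j:
                            b = rw.GetBondBetweenAtoms(i, j)
                            if b is not None:
                                b.SetBondType(Chem.BondType.AROMATIC)
                                b.SetIsAromatic(True)
                out = _finalize(rw, original, kind, detail)
                if out.feasible:
                    return out
    return None


def _edited_rings(mol: Chem.Mol, touched: Sequence[int]) -> list[tuple[int, ...]]:
    """Rings of an (unsanitized) edited molecule that contain a touched atom
    and have an aromatizable size."""
    m = Chem.Mol(mol)
    Chem.GetSymmSSSR(m)
    return [
        ring
        for ring in m.GetRingInfo().AtomRings()
        if len(ring) in (5, 6) and any(i in ring for i in touched)
    ]


# ---------------------------------------------------------------------------
# the nine operators


#: Largest substituent (heavy atoms) that ``add_group`` may displace.
MAX_REPLACED_GROUP_ATOMS = 6


def _substituent_sites(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Terminal substituents eligible for replacement: single, acyclic bonds
    (anchor_idx, root_idx) whose root-side subtree holds at most
    ``MAX_REPLACED_GROUP_ATOMS`` heavy atoms."""
    sites = []
    for b in mol.GetBonds():
        if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
            continue
        for anchor, root in (
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            (b.GetEndAtomIdx(), b.GetBeginAtomIdx()),
        ):
            # size of the subtree hanging off `anchor` through `root`
            seen = {anchor, root}
            stack = [root]
            n = 1
            while stack and n <= MAX_REPLACED_GROUP_ATOMS:
                for nb in mol.GetAtomWithIdx(stack.pop()).GetNeighbors():
                    i = nb.GetIdx()
                    if i not in seen:
                        seen.add(i)
                        stack.append(i)
                        n += 1
            if n <= MAX_REPLACED_GROUP_ATOMS:
                sites.append((anchor, root))
    return sites


def add_group(
    c: Compound,
    rng: np.random.Generator,
    groups: Sequence[tuple[str, str, int, Chem.BondType, int]] = tuple(DEFAULT_GROUPS),
) -> MoveOutcome:
    """Attach a small substituent at a random accessible point.

    The point is either an H-bearing atom (the new group displaces one or two
    hydrogens) or the anchor of an existing small terminal substituent, which
    is excised and replaced by the new group in a single step.
    """
    gi = rng.integers(len(groups))
    name, frag_smi, attach_idx, order, h_needed = groups[gi]
    # most additions displace hydrogen; one in four displaces an existing
    # small terminal substituent instead (single-step group swap)
    sites: list[tuple[int, Optional[int]]] = []
    if rng.random() < 0.25:
        # replacing a substituent frees one H-equivalent at the anchor, so a
        # double-bonded group still needs one H already present
        sites = [
            (anchor, root)
            for anchor, root in _substituent_sites(c.mol)
            if c.mol.GetAtomWithIdx(anchor).GetTotalNumHs() >= h_needed - 1
        ]
    if not sites:
        sites = [
            (a.GetIdx(), None)
            for a in c.mol.GetAtoms()
            if a.GetTotalNumHs() >= h_needed
        ]
    if not sites:
        return _infeasible(c, MoveKind.ADD_GROUP, f"no site for {name}")
    site, replaced_root = sites[rng.integers(len(sites))]
    site = int(site)
    frag = Chem.MolFromSmiles(frag_smi)
    base = Chem.RWMol(c.mol)
    if order == Chem.BondType.DOUBLE:
        # a double bond cannot attach to an atom inside an aromatic system
        Chem.Kekulize(base, clearAromaticFlags=True)
    if replaced_root is not None:
        # excise the old substituent subtree, keeping the anchor
        seen = {site, int(replaced_root)}
        stack = [int(replaced_root)]
        while stack:
            for nb in base.GetAtomWithIdx(stack[-1]).GetNeighbors():
                i = nb.GetIdx()
                if i not in seen:
                    seen.add(i)
                    stack.append(i)
                    break
            else:
                stack.pop()
        seen.discard(site)
        for i in sorted(seen, reverse=True):
            base.RemoveAtom(i)
            if i < site:
                site -= 1
    combo = Chem.RWMol(Chem.CombineMols(base, frag))
    combo.AddBond(site, base.GetNumAtoms() + attach_idx, order)
    a = combo.GetAtomWithIdx(site)
    if a.GetNumExplicitHs() > 0:
        h_used = h_needed if replaced_root is None else h_needed - 1
        a.SetNumExplicitHs(max(0, a.GetNumExplicitHs() - h_used))
    what = "H" if replaced_root is None else "substituent"
    return _finalize(combo, c, MoveKind.ADD_GROUP, f"add {name} at atom {site} replacing {what}")


def remove_atom(c: Compound, rng: np.random.Generator) -> MoveOutcome:
    """Delete one heavy atom; if the graph splits, keep the largest fragment."""
    if c.num_heavy_atoms < 2:
        return _infeasible(c, MoveKind.REMOVE_ATOM, "single-atom molecule")
    idx = int(rng.integers(c.num_heavy_atoms))
    rw = _kekulized_rw(c.mol)
    rw.RemoveAtom(idx)
    try:
        frags = rdmolops.GetMolFrags(rw, asMols=True, sanitizeFrags=False)
    except Exception:
        return _infeasible(c, MoveKind.REMOVE_ATOM, "fragmentation failed")
    if len(frags) > 1:
        keep = _largest_fragment(frags)
    else:
        keep = frags[0]
    return _finalize(keep, c, MoveKind.REMOVE_ATOM, f"remove atom {idx}")


def _largest_fragment(frags: Sequence[Chem.Mol]) -> Chem.Mol:
    def key(m: Chem.Mol):
        try:
            smi = Chem.MolToSmiles(Chem.Mol(m))
        except Exception:
            smi = "~"  # sorts after any real SMILES
        return (-m.GetNumHeavyAtoms(), smi)

    return sorted(frags, key=key)[0]


def change_atom_type(
    c: Compound,
    rng: np.random.Generator,
    elements: Sequence[str] = DEFAULT_ELEMENTS,
) -> MoveOutcome:
    """Swap the element of a random atom to another from the allowed set."""
    idx = int(rng.integers(c.num_heavy_atoms))
    atom = c.mol.GetAtomWithIdx(idx)
    if atom.GetDegree() == 0:
        # swapping the element of an isolated atom (methane -> HF etc.) is
        # not a meaningful chemical step
        return _infeasible(c, MoveKind.CHANGE_ATOM_TYPE, "isolated atom")
    current = atom.GetSymbol()
    order_sum = _bond_order_sum(atom)
    candidates = [
        e for e in elements if e != current and _MAX_VALENCE[e] >= order_sum
    ]
    if not candidates:
        return _infeasible(c, MoveKind.CHANGE_ATOM_TYPE, f"no swap for atom {idx}")
    new_el = candidates[rng.integers(len(candidates))]
    # Aromatic nitrogen may need an explicit H (pyrrole-type); try 0 then 1.
    for n_h in (0, 1):
        rw = Chem.RWMol(c.mol)
        a = rw.GetAtomWithIdx(idx)
        a.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(new_el))
        a.SetFormalCharge(0)
        a.SetNoImplicit(False)
        a.SetNumExplicitHs(n_h)
        out = _finalize(rw, c, MoveKind.CHANGE_ATOM_TYPE, f"atom {idx} {current}->{new_el}")
        if out.feasible:
            return out
    return _infeasible(c, MoveKind.CHANGE_ATOM_TYPE, f"atom {idx} {current}->{new_el} invalid")


def add_atom_in_chain(
    c: Compound,
    rng: np.random.Generator,
    elements: Sequence[str] = DEFAULT_ELEMENTS,
) -> MoveOutcome:
    """Insert a new atom into a randomly chosen bond (a-b becomes a-X-b)."""
    n_bonds = c.mol.GetNumBonds()
    if n_bonds == 0:
        return _infeasible(c, MoveKind.ADD_ATOM_IN_CHAIN, "no bonds")
    bidx = int(rng.integers(n_bonds))
    # the inserted atom forms two single bonds, so it needs capacity >= 2
    insertable = [e for e in elements if _MAX_VALENCE[e] >= 2]
    weights = np.array([DEFAULT_INSERT_WEIGHTS.get(e, 0.02) for e in insertable])
    new_el = insertable[rng.choice(len(insertable), p=weights / weights.sum())]
    was_aromatic = c.mol.GetBondWithIdx(bidx).GetIsAromatic()
    rw = _kekulized_rw(c.mol)
    bond = rw.GetBondWithIdx(bidx)
    ai, bi = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    rw.RemoveBond(ai, bi)
    x = rw.AddAtom(Chem.Atom(new_el))
    rw.AddBond(ai, x, Chem.BondType.SINGLE)
    rw.AddBond(x, bi, Chem.BondType.SINGLE)
    detail = f"insert {new_el} in bond {ai}-{bi}"
    if was_aromatic:
        # inserting into an aromatic bond: prefer expanding the pi system
        # (5-ring -> 6-ring heteroaromatic and the like) over leaving a
        # kekule ring behind
        for ring in _edited_rings(rw, [x]):
            out = _try_aromatize(rw, ring, c, MoveKind.ADD_ATOM_IN_CHAIN, detail)
            if out is not None:
                return out
    return _finalize(rw, c, MoveKind.ADD_ATOM_IN_CHAIN, detail)


def change_bond_type(c: Compound, rng: np.random.Generator) -> MoveOutcome:
    """Toggle a random non-aromatic bond between single and double order."""
    bonds = [
        b
        for b in c.mol.GetBonds()
        if not b.GetIsAromatic()
        and b.GetBondType() in (Chem.BondType.SINGLE, Chem.BondType.DOUBLE)
    ]
    if not bonds:
        return _infeasible(c, MoveKind.CHANGE_BOND_TYPE, "no togglable bond")
    bond = bonds[rng.integers(len(bonds))]
    ai, bi = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    to_double = bond.GetBondType() == Chem.BondType.SINGLE
    rw = Chem.RWMol(c.mol)
    rwb = rw.GetBondBetweenAtoms(ai, bi)
    rwb.SetBondType(Chem.BondType.DOUBLE if to_double else Chem.BondType.SINGLE)
    if to_double:
        for i in (ai, bi):
            a = rw.GetAtomWithIdx(i)
            if a.GetNumExplicitHs() > 0:
                a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
    return _finalize(
        rw, c, MoveKind.CHANGE_BOND_TYPE,
        f"bond {ai}-{bi} {'single->double' if to_double else 'double->single'}",
    )


def form_ring(
    c: Compound,
    rng: np.random.Generator,
    ring_window: tuple[int, int] = DEFAULT_RING_WINDOW,
) -> MoveOutcome:
    """Close a ring by bonding two atoms a suitable topological distance apart."""
    lo, hi = ring_window
    mol = c.mol
    n = mol.GetNumAtoms()
    if n < lo:
        return _infeasible(c, MoveKind.FORM_RING, "too few atoms")
    dist = Chem.GetDistanceMatrix(mol)
    # an endpoint can accept one more bond if it has an H to give up, or if it
    # is a two-coordinate aromatic N whose lone pair can shift into the ring
    # (pyridine-type N becoming a bridgehead, as in indolizine)
    has_h = [
        a.GetTotalNumHs() >= 1
        or (a.GetSymbol() == "N" and a.GetIsAromatic() and a.GetDegree() == 2)
        for a in mol.GetAtoms()
    ]
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if has_h[i] and has_h[j]
        and lo - 1 <= dist[i, j] <= hi - 1
        and mol.GetBondBetweenAtoms(i, j) is None
    ]
    if not pairs:
        return _infeasible(c, MoveKind.FORM_RING, "no closable chain")
    i, j = pairs[rng.integers(len(pairs))]
    endpoint_aromatic = any(
        mol.GetAtomWithIdx(int(k)).GetIsAromatic() for k in (i, j)
    )
    rw = Chem.RWMol(mol)
    if endpoint_aromatic:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    for k in (i, j):
        a = rw.GetAtomWithIdx(int(k))
        if a.GetNumExplicitHs() > 0:
            a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
    detail = f"close ring {i}-{j}"
    if endpoint_aromatic:
        # a closure onto an aromatic system may extend the pi system into the
        # new ring (pyridine -> indolizine-type fusions); try that first
        for ring in _edited_rings(rw, [int(i), int(j)]):
            out = _try_aromatize(rw, ring, c, MoveKind.FORM_RING, detail)
            if out is not None:
                return out
    return _finalize(rw, c, MoveKind.FORM_RING, detail)


def break_ring(c: Compound, rng: np.random.Generator) -> MoveOutcome:
    """Remove a random ring bond, dearomatizing the ring if necessary."""
    ring_bonds = [b.GetIdx() for b in c.mol.GetBonds() if b.IsInRing()]
    if not ring_bonds:
        return _infeasible(c, MoveKind.BREAK_RING, "no ring")
    bidx = ring_bonds[rng.integers(len(ring_bonds))]
    rw = _kekulized_rw(c.mol)
    bond = rw.GetBondWithIdx(bidx)
    ai, bi = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    rw.RemoveBond(ai, bi)
    return _finalize(rw, c, MoveKind.BREAK_RING, f"open ring bond {ai}-{bi}")


def toggle_aromatic(c: Compound, rng: np.random.Generator) -> MoveOutcome:
    """Aromatize a random non-aromatic ring, or partially saturate an aromatic one.

    Dearomatization kekulizes the system and demotes one ring double bond to a
    single bond (benzene -> cyclohexadiene); aromatization flags ring atoms and
    bonds aromatic and lets sanitization find a valid electron assignment,
    trying a pyrrole-type N-H if the plain form fails.
    """
    ri = c.mol.GetRingInfo()
    rings = ri.AtomRings()
    if not rings:
        return _infeasible(c, MoveKind.TOGGLE_AROMATIC, "no ring")
    ring = rings[rng.integers(len(rings))]
    ring_set = set(ring)
    aromatic = all(c.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    if not aromatic and not 5 <= len(ring) <= 7:
        # only common ring sizes are candidates for aromatization
        return _infeasible(c, MoveKind.TOGGLE_AROMATIC, f"ring size {len(ring)}")
    if aromatic:
        rw = _kekulized_rw(c.mol)
        dbl = [
            b
            for b in rw.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetBeginAtomIdx() in ring_set
            and b.GetEndAtomIdx() in ring_set
        ]
        if not dbl:
            return _infeasible(c, MoveKind.TOGGLE_AROMATIC, "no ring double bond")
        bond = dbl[rng.integers(len(dbl))]
        bond.SetBondType(Chem.BondType.SINGLE)
        return _finalize(rw, c, MoveKind.TOGGLE_AROMATIC, f"dearomatize ring {ring}")
    # Aromatize: the ring's bond orders and H counts may be adjusted
    # (exocyclic double bonds demoted, a pyrrole-type N-H introduced) until a
    # sanitizable aromatic form is found.
    try:
        kek = _kekulized_rw(c.mol)
    except Exception:
        return _infeasible(c, MoveKind.TOGGLE_AROMATIC, "kekulization failed")
    out = _try_aromatize(kek, ring, c, MoveKind.TOGGLE_AROMATIC, f"aromatize ring {ring}")
    if out is not None:
        return out
    return _infeasible(c, MoveKind.TOGGLE_AROMATIC, f"ring {ring} cannot be aromatic")


def rearrange_bonds(c: Compound, rng: np.random.Generator) -> MoveOutcome:
    """Migrate a substituent from an atom of degree > 2 to one of its neighbours."""
    pivots = [a.GetIdx() for a in c.mol.GetAtoms() if a.GetDegree() > 2]
    if not pivots:
        return _infeasible(c, MoveKind.REARRANGE_BONDS, "no atom of degree > 2")
    p = int(pivots[rng.integers(len(pivots))])
    rw = _kekulized_rw(c.mol)
    neighbors = [a.GetIdx() for a in rw.GetAtomWithIdx(p).GetNeighbors()]
    s = int(neighbors[rng.integers(len(neighbors))])
    targets = [
        n for n in neighbors if n != s and rw.GetBondBetweenAtoms(n, s) is None
    ]
    if not targets:
        return _infeasible(c, MoveKind.REARRANGE_BONDS, f"no target neighbour at {p}")
    t = int(targets[rng.integers(len(targets))])
    order = rw.GetBondBetweenAtoms(p, s).GetBondType()
    rw.RemoveBond(p, s)
    rw.AddBond(t, s, order)
    a = rw.GetAtomWithIdx(t)
    if a.GetNumExplicitHs() > 0:
        a.SetNumExplicitHs(max(0, a.GetNumExplicitHs() - 1))
    detail = f"migrate {s} from {p} to {t}"
    if any(c.mol.GetAtomWithIdx(i).GetIsAromatic() for i in (p, s, t)):
        # a migration that contracts or expands an aromatic ring should leave
        # an aromatic ring behind when the electron count allows it
        for ring in _edited_rings(rw, [p, s, t]):
            out = _try_aromatize(rw, ring, c, MoveKind.REARRANGE_BONDS, detail)
            if out is not None:
                return out
    return _finalize(rw, c, MoveKind.REARRANGE_BONDS, detail)


_OPERATORS = {
    MoveKind.ADD_GROUP: add_group,
    MoveKind.REMOVE_ATOM: remove_atom,
    MoveKind.CHANGE_ATOM_TYPE: change_atom_type,
    MoveKind.ADD_ATOM_IN_CHAIN: add_atom_in_chain,
    MoveKind.CHANGE_BOND_TYPE: change_bond_type,
    MoveKind.FORM_RING: form_ring,
    MoveKind.BREAK_RING: break_ring,
    MoveKind.TOGGLE_AROMATIC: toggle_aromatic,
    MoveKind.REARRANGE_BONDS: rearrange_bonds,
}


def apply_move(c: Compound, kind: MoveKind, rng: np.random.Generator) -> MoveOutcome:
    """Apply one named operator at a random site."""
    return _OPERATORS[kind](c, rng)


def propose(
    c: Compound,
    moveset: MoveSet,
    rng: np.random.Generator,
    max_retries: int = MAX_PROPOSE_RETRIES,
) -> MoveOutcome:
    """Draw a move kind by its probability and apply it.

    Infeasible draws (wrong site, valence clash, no applicable site) redraw
    both the kind and the site up to ``max_retries`` times; if all attempts
    fail the input is returned with ``feasible=False`` so the engine can count
    the step as rejected.
    """
    for _ in range(max_retries):
        kind = moveset.draw(rng)
        outcome = _OPERATORS[kind](c, rng)
        if outcome.feasible:
            return outcome
    return _infeasible(c, None, "all moves infeasible after retries")
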