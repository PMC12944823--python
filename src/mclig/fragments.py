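"""Fragment-level Monte Carlo moves built on BRICS decomposition.

Instead of elementary atom/bond edits, the chemical state is an assembly of
retrosynthetic fragments.  Molecules are cut at the 16 BRICS bond
environments; every cut leaves a pair of labelled dummy atoms (attachment
points), and two attachment points may be re-bonded only if their labels form
one of the published BRICS link-type pairs.  Two moves operate on such
assemblies: bonding a new library fragment onto a randomly chosen open
attachment point, and cutting a random inter-fragment bond, discarding the
detached side and restoring the attachment point that the bond consumed.

For scoring, open attachment points are capped with hydrogen so every
assembly corresponds to a complete, sanitizable molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .compound import Compound, InvalidSmilesError


def _brics_compatibility() -> tuple[set[tuple[int, int]], dict[tuple[int, int], Chem.BondType]]:
    """Label pairs that may bond, and the bond order each pair forms,
    taken from RDKit's published BRICS reaction definitions.

    Environment sub-labels (7a/7b etc.) are collapsed onto their numeric
    isotope label, which is how BRICS dummies are marked in practice.
    """
    pairs: set[tuple[int, int]] = set()
    orders: dict[tuple[int, int], Chem.BondType] = {}
    for group in BRICS.reactionDefs:
        for a, b, bond in group:
            ia, ib = int(a.rstrip("ab")), int(b.rstrip("ab"))
            key = (min(ia, ib), max(ia, ib))
            pairs.add(key)
            orders[key] = (
                Chem.BondType.DOUBLE if bond == "=" else Chem.BondType.SINGLE
            )
    return pairs, orders


COMPATIBLE_PAIRS, PAIR_BOND_ORDERS = _brics_compatibility()


def labels_compatible(a: int, b: int) -> bool:
    return (min(a, b), max(a, b)) in COMPATIBLE_PAIRS


@dataclass(frozen=True)
class Fragment:
    """A BRICS fragment: SMILES with labelled dummy atoms ([4*], [16*], ...)."""

    smiles: str

    @property
    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise InvalidSmilesError(f"bad fragment SMILES {self.smiles!r}")
        return m

    @property
    def attachment_labels(self) -> list[int]:
        return [
            a.GetIsotope() for a in self.mol.GetAtoms() if a.GetAtomicNum() == 0
        ]

    def __post_init__(self) -> None:
        mol = self.mol
        labels = self.attachment_labels
        if not labels:
            return
        if any(lab == 0 for lab in labels):
            raise ValueError(f"unlabelled attachment dummy in {self.smiles!r}")
        # the fragment minus its dummies must stand on its own
        if capped(mol) is None:
            raise ValueError(f"fragment {self.smiles!r} does not H-cap to a molecule")


@dataclass
class FragmentLibrary:
    """Pool of BRICS fragments the add-fragment move may draw from."""

    fragments: list[Fragment]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("fragment library is empty")

    def compatible_with(self, label: int) -> list[Fragment]:
        return [
            f
            for f in self.fragments
            if any(labels_compatible(label, lab) for lab in f.attachment_labels)
        ]

    @classmethod
    def from_compounds(cls, compounds: Iterable[Compound]) -> "FragmentLibrary":
        frags: dict[str, Fragment] = {}
        for c in compounds:
            for f in brics_decompose(c):
                frags[f.smiles] = f
        return cls(fragments=list(frags.values()))

    @classmethod
    def from_file(cls, path: str) -> "FragmentLibrary":
        frags = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                smi = line.split()[0] if line.split() else ""
                if not smi:
                    continue
                try:
                    frags.append(Fragment(smi))
                except Exception as exc:
                    raise ValueError(f"{path}:{ln}: invalid fragment {smi!r}: {exc}")
        return cls(fragments=frags)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(f.smiles + "\n")


def capped(mol: Chem.Mol) -> Optional[Compound]:
    """Replace every attachment dummy with hydrogen and sanitize; ``None`` if
    the capped molecule does not sanitize."""
    rw = Chem.RWMol(mol)
    dummies = sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    )
    aromatic_n_neighbors = []
    for idx in dummies:
        for nb in rw.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetAtomicNum() == 7 and nb.GetIsAromatic():
                aromatic_n_neighbors.append(nb.GetIdx())
        rw.RemoveAtom(idx)
    for a in rw.GetAtoms():
        a.SetNoImplicit(False)
    try:
        return Compound.from_mol(rw)
    except Exception:
        pass
    # an aromatic N that lost its substituent needs a pyrrole-type H
    shift = {i: sum(1 for d in dummies if d < i) for i in aromatic_n_neighbors}
    for i in aromatic_n_neighbors:
        a = rw.GetAtomWithIdx(i - shift[i])
        a.SetNumExplicitHs(a.GetNumExplicitHs() + 1)
    try:
        return Compound.from_mol(rw)
    except Exception:
        return None


@dataclass
class FragmentedCompound:
    """A fragment assembly: molecule that may carry open attachment dummies."""

    mol: Chem.Mol
    feasible: bool = True
    detail: str = ""

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def open_sites(self) -> list[tuple[int, int]]:
        """(atom index, BRICS label) of each open attachment dummy."""
        return [
            (a.GetIdx(), a.GetIsotope())
            for a in self.mol.GetAtoms()
            if a.GetAtomicNum() == 0
        ]

    def as_compound(self) -> Compound:
        """H-capped complete molecule (used for all scoring)."""
        c = capped(self.mol)
        if c is None:
            raise InvalidSmilesError(f"assembly {self.smiles!r} does not cap")
        return c

    @classmethod
    def from_fragment(cls, fragment: Fragment) -> "FragmentedCompound":
        return cls(mol=fragment.mol)


# ---------------------------------------------------------------------------
# decomposition


def _oriented_labels(
    mol: Chem.Mol, i: int, j: int, la: str, lb: str
) -> tuple[int, int]:
    """Dummy labels for FragmentOnBonds so each dummy carries the BRICS
    environment label of the atom it stays bonded to.

    ``la``/``lb`` are the environment labels of atoms ``i``/``j``.  The first
    returned label marks the dummy replacing the bond's begin atom (which
    lands in the end atom's fragment), so it must be the label of the *end*
    side, honouring the bond object's own atom order.
    """
    ia, ib = int(la.rstrip("ab")), int(lb.rstrip("ab"))
    bond = mol.GetBondBetweenAtoms(i, j)
    if bond.GetBeginAtomIdx() == i:
        return (ib, ia)
    return (ia, ib)


def brics_decompose(c: Compound) -> list[Fragment]:
    """Cut every BRICS bond of a molecule and return the fragment multiset.

    Unlike the usual deduplicated decomposition this keeps one entry per
    fragment occurrence, so reassembling the returned list along compatible
    attachment points can reproduce the input constitution exactly.
    """
    bonds = list(BRICS.FindBRICSBonds(c.mol))
    if not bonds:
        return [Fragment(Chem.MolToSmiles(c.mol))]
    bond_ids, labels = [], []
    for (i, j), (la, lb) in bonds:
        bond_ids.append(c.mol.GetBondBetweenAtoms(i, j).GetIdx())
        labels.append(_oriented_labels(c.mol, i, j, la, lb))
    cut = Chem.FragmentOnBonds(c.mol, bond_ids, dummyLabels=labels)
    frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    return [Fragment(Chem.MolToSmiles(f)) for f in frags]


# ---------------------------------------------------------------------------
# fragment-level moves


def _join(
    assembly: Chem.Mol,
    site_idx: int,
    fragment: Fragment,
    frag_site_label: int,
    rng: np.random.Generator,
) -> Optional[Chem.Mol]:
    """Bond ``assembly``'s dummy at ``site_idx`` to one of ``fragment``'s
    dummies carrying ``frag_site_label``; both dummies are consumed."""
    fmol = fragment.mol
    fr_sites = [
        a.GetIdx()
        for a in fmol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetIsotope() == frag_site_label
    ]
    if not fr_sites:
        return None
    fr_site = int(fr_sites[rng.integers(len(fr_sites))])
    a_label = assembly.GetAtomWithIdx(site_idx).GetIsotope()
    key = (min(a_label, frag_site_label), max(a_label, frag_site_label))
    order = PAIR_BOND_ORDERS.get(key, Chem.BondType.SINGLE)
    n = assembly.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(assembly, fmol))
    a_nbr = combo.GetAtomWithIdx(site_idx).GetNeighbors()[0].GetIdx()
    f_nbr = combo.GetAtomWithIdx(n + fr_site).GetNeighbors()[0].GetIdx()
    for idx in sorted((site_idx, n + fr_site), reverse=True):
        combo.RemoveAtom(idx)
        a_nbr -= a_nbr > idx
        f_nbr -= f_nbr > idx
    try:
        combo.AddBond(int(a_nbr), int(f_nbr), order)
        Chem.SanitizeMol(combo)
    except Exception:
        return None
    return combo.GetMol()


def add_fragment(
    fc: FragmentedCompound,
    lib: FragmentLibrary,
    rng: np.random.Generator,
) -> FragmentedCompound:
    """Bond a compatible library fragment onto a random open attachment point."""
    sites = fc.open_sites
    if not sites:
        return FragmentedCompound(fc.mol, feasible=False, detail="no open site")
    site_idx, label = sites[rng.integers(len(sites))]
    candidates = lib.compatible_with(label)
    if not candidates:
        return FragmentedCompound(
            fc.mol, feasible=False, detail=f"no fragment compatible with L{label}"
        )
    frag = candidates[rng.integers(len(candidates))]
    frag_labels = [
        lab for lab in frag.attachment_labels if labels_compatible(label, lab)
    ]
    frag_label = int(frag_labels[rng.integers(len(frag_labels))])
    joined = _join(fc.mol, int(site_idx), frag, frag_label, rng)
    if joined is None:
        return FragmentedCompound(fc.mol, feasible=False, detail="join failed")
    return FragmentedCompound(
        joined, detail=f"added {frag.smiles} at L{label}"
    )


def remove_fragment(
    fc: FragmentedCompound, rng: np.random.Generator
) -> FragmentedCompound:
    """Cut a random inter-fragment (BRICS) bond; the side with more heavy
    atoms is kept and regains an open attachment point with the original
    label."""
    bonds = list(BRICS.FindBRICSBonds(fc.mol))
    if not bonds:
        return FragmentedCompound(
            fc.mol, feasible=False, detail="single-fragment assembly"
        )
    (i, j), (la, lb) = bonds[rng.integers(len(bonds))]
    bond_id = fc.mol.GetBondBetweenAtoms(i, j).GetIdx()
    # as in brics_decompose: keep each environment label on its own side
    labels = _oriented_labels(fc.mol, i, j, la, lb)
    cut = Chem.FragmentOnBonds(fc.mol, [bond_id], dummyLabels=[labels])
    try:
        frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    except Exception:
        return FragmentedCompound(fc.mol, feasible=False, detail="cut failed")
    if len(frags) != 2:
        return FragmentedCompound(fc.mol, feasible=False, detail="bond not severing")

    def heavy(m: Chem.Mol) -> int:
        return sum(1 for a in m.GetAtoms() if a.GetAtomicNum() > 1 and a.GetAtomicNum() != 0)

    keep = max(frags, key=lambda m: (heavy(m), Chem.MolToSmiles(m)))
    return FragmentedCompound(Chem.Mol(keep), detail=f"cut bond {i}-{j}")


def random_fragment_start(
    lib: FragmentLibrary, rng: np.random.Generator
) -> FragmentedCompound:
    """Uniformly drawn single fragment used to seed a fragment-MC chain."""
    frag = lib.fragments[rng.integers(len(lib.fragments))]
    return FragmentedCompound.from_fragment(frag)


# ---------------------------------------------------------------------------
# guided reassembly (round-trip verification)


def enumerate_reassemblies(
    fragments: Sequence[Fragment], max_states: int = 20000
) -> set[str]:
    """Canonical SMILES of every complete molecule obtainable by joining all
    of ``fragments`` along compatible attachment points.

    Backtracking enumeration over join orders and site pairings; used to
    verify that a BRICS decomposition can be reassembled into the original
    constitution.  ``max_states`` bounds the search.
    """
    if len(fragments) == 1:
        return {Compound.from_smiles(fragments[0].smiles).smiles}
    results: set[str] = set()
    counter = {"n": 0}
    rng = np.random.default_rng(0)  # only used to pick dummy among equals

    def rec(assembly: Chem.Mol, remaining: list[Fragment]) -> None:
        if counter["n"] > max_states:
            return
        counter["n"] += 1
        open_sites = [
            (a.GetIdx(), a.GetIsotope())
            for a in assembly.GetAtoms()
            if a.GetAtomicNum() == 0
        ]
        if not remaining:
            if not open_sites:
                c = capped(assembly)
                if c is not None:
                    results.add(c.smiles)
            return
        if not open_sites:
            return
        # always extend the first open site: join order does not matter
        site_idx, label = open_sites[0]
        tried: set[tuple[str, int]] = set()
        for k, frag in enumerate(remaining):
            for frag_label in set(frag.attachment_labels):
                if not labels_compatible(label, frag_label):
                    continue
                if (frag.smiles, frag_label) in tried:
                    continue
                tried.add((frag.smiles, frag_label))
                joined = _join(assembly, site_idx, frag, frag_label, rng)
                if joined is None:
                    continue
                rec(joined, remaining[:k] + remaining[k + 1:])

    seen_starts: set[str] = set()
    for k, frag in enumerate(fragments):
        if frag.smiles in seen_starts:
            continue
        seen_starts.add(frag.smiles)
        rest = list(fragments[:k]) + list(fragments[k + 1:])
        rec(frag.mol, rest)
    return results


def reassembles_to(c: Compound) -> bool:
    """True if the BRICS fragment multiset of ``c`` can be joined back into
    the constitution of ``c``."""
    frags = brics_decompose(c)
    return c.smiles in enumerate_reassemblies(frags)
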