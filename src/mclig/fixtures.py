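"""Reference compound sets shipped with the package.

``RECOVERY_TARGETS`` are the ligand-recovery targets (PDB entry code and ligand
SMILES as deposited); ``REFERENCE_COMPONENT_ROWS`` are published
per-component scores for three generated bromodomain binders, used to
calibrate and verify the composite-score arithmetic; ``KNOWN_LIGANDS`` are
experimentally characterized binders of the four study targets
(bromodomain, p38 MAP kinase, Pim-1 kinase, beta-1 adrenergic receptor).
PDB codes are labels only; nothing is downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compound import Compound

#: Recovery targets: (PDB code, ligand SMILES).
RECOVERY_TARGETS: list[tuple[str, str]] = [
    ("4lzs", "CNC(=O)c1[nH]c(c(c1CC)C(=O)C)C"),
    ("5mli", "CNc1cnn(c(=O)c1Cl)C"),
    ("3vc4", "O=C1NC(=O)/C(=C/c2cccc(c2)C(F)(F)F)/S1"),
    ("6fnx", "CCn1cnc2c1c(=O)[nH]c(=O)n2Cc1ccccc1"),
    ("2yek", "CCNC(=O)C[C@@H]1N=C(c2ccc(cc2)Cl)c2c(-n3c1nnc3C)ccc(c2)OC"),
    ("4a9i", "CC(=O)c1cc(c2n1cccc2)c1ccccn1"),
    ("3iw7", "SCc1ccc(cc1)C(=O)N1CCC(CC1)Cc1ccccc1"),
    ("1di9", "COc1cc2c(ncnc2cc1OC)Nc1cccc(c1)SC"),
    ("1mnc", "CNC(=O)[C@H](Cc1ccccc1)NC(=O)[C@@H](CC(=O)NO)CC(C)C"),
    ("1a07", "CCCCCN(C(=O)[C@@H](NC(=O)[C@H](Cc1ccccc1)NC(=O)C)CCC(=O)[O-])CCCCC"),
]

#: The five targets recoverable at desk scale (small or protocol-reduced).
SIMPLE_RECOVERY_TARGETS = ("5mli", "3vc4", "4a9i", "4lzs", "3iw7")


@dataclass(frozen=True)
class ComponentRow:
    """Published per-component scores of one generated compound."""

    smiles: str
    composite: float
    confidence: float
    sa_raw: float
    esol_raw: float
    qed: float


#: Generated bromodomain binders with their printed score components.
REFERENCE_COMPONENT_ROWS: list[ComponentRow] = [
    ComponentRow(
        "CCOC1(C)COc2cc(NC)n(OC)c(=S)c2N(C)C1",
        0.908, 0.902, 4.347, -2.954, 0.857,
    ),
    ComponentRow(
        "C=CNCC1Cn2cc(C)c(C)c2C2=C1c1c(nnc(C)c1CC)C2",
        0.919, 0.917, 4.405, -4.240, 0.929,
    ),
    ComponentRow(
        "CCC1CCC(C)(N)N1CCCn1oc(=NC)n(C)c1=O",
        0.918, 0.908, 4.798, -1.687, 0.844,
    ),
]

#: Experimentally characterized binders: (PDB code, protein, SMILES).
KNOWN_LIGANDS: list[tuple[str, str, str]] = [
    ("5mli", "bromodomain", "CNc1cnn(c(=O)c1Cl)C"),
    ("4o7a", "bromodomain", "Clc1cccc(c1)C1=C(Nc2ccc(c(c2)Cl)O)C(=O)NC1=O"),
    ("4hbw", "bromodomain", "CCNS(=O)(=O)c1ccc2c(c1)CN(C(=O)N2)C"),
    ("5igk", "bromodomain", "CCOC(=O)Nc1cc(nn2c1nnc2C)c1ccc(c(c1)NS(=O)(=O)C)C"),
    ("5khm", "bromodomain",
     "COc1nnc2n1nc(cc2)N1CCC(CC1)c1ccc(cc1)OCC[N@H+]1CCN(C(=O)[C@H]1C)C"),
    ("3iw8", "p38 kinase",
     "O=C(Nc1scc(n1)[C@@H](COCc1ccccc1)[NH3+])Nc1ccc(c(c1)Cl)F"),
    ("3iw7", "p38 kinase", "SCc1ccc(cc1)C(=O)N1CCC(CC1)Cc1ccccc1"),
    ("6m95", "p38 kinase", "COc1cc(SC)ccc1C(=O)N1CCC(CC1)Cc1ccccc1"),
    ("3l8s", "p38 kinase",
     "O=C(Nc1snc(c1C(=O)N)OCc1c(F)cc(cc1F)Br)NCCCC[NH+]1CCCC1"),
    ("6ohd", "p38 kinase",
     "Cc1ccc(cc1c1cnc2c(c1)[nH]c(=O)n2C(C)(C)C)C(=O)Nc1nocc1"),
    ("4xh6", "pim-1 kinase", "COc1c(O)cc2c(c1O)c(=O)cc(o2)c1ccc(cc1)O"),
    ("5kcx", "pim-1 kinase",
     "C[NH+]1CCN(CC1)c1ccc(cc1)c1cc2c(n1C)nc(cc2Cl)C(=O)N"),
    ("4xhk", "pim-1 kinase",
     "O=C(c1csc(n1)c1c(F)cccc1F)Nc1cnccc1O[C@@H]1C[NH2+]CC1"),
    ("5v82", "pim-1 kinase",
     "Cc1cncc(n1)c1ncc2c(c1)n(nc2)c1cccc(n1)[C@H]1C[NH2+]CCC1(F)F"),
    ("4n70", "pim-1 kinase",
     "C[C@H]1CN(C[C@H]([C@@H]1O)[NH3+])c1cc[nH+]cc1NC(=O)c1ccc(c(n1)c1c(F)cccc1F)F"),
    ("3zpr", "beta-1 receptor", "Cc1cc(nc2c1cccc2)N1CC[NH2+]CC1"),
    ("3zpq", "beta-1 receptor", "C1[NH2+]CCN(C1)c1cccc2c1cc[nH]2"),
]


def recovery_target_compounds() -> dict[str, Compound]:
    """Recovery targets parsed, stereo-stripped and canonicalized."""
    return {code: Compound.from_smiles(smi) for code, smi in RECOVERY_TARGETS}


def bundled_ligand_compounds() -> list[Compound]:
    """All fixture ligands (recovery targets plus known binders), neutralized
    where the deposited form carries protonation charges."""
    from rdkit import Chem

    out = []
    for smi in [s for _, s in RECOVERY_TARGETS] + [s for _, _, s in KNOWN_LIGANDS]:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        out.append(Compound.from_mol(_neutralized(mol)))
    return out


def _neutralized(mol):
    """Remove simple protonation charges ([NH3+], [O-] ...) from a molecule."""
    from rdkit import Chem

    rw = Chem.RWMol(mol)
    for a in rw.GetAtoms():
        q = a.GetFormalCharge()
        if q == 0:
            continue
        if q > 0 and a.GetTotalNumHs() >= q:
            a.SetFormalCharge(0)
            a.SetNumExplicitHs(max(0, a.GetNumExplicitHs() - q))
        elif q < 0:
            a.SetFormalCharge(0)
            a.SetNumExplicitHs(a.GetNumExplicitHs() - q)
    Chem.SanitizeMol(rw)
    return rw.GetMol()


def bundled_fragment_library(n_fragments: int = 50, seed: int = 0):
    """A packaged library of BRICS fragments drawn from the fixture ligands.

    Stands in for a random draw from a large compound database: the fixture
    ligands are decomposed and ``n_fragments`` distinct fragments are sampled
    reproducibly.
    """
    import numpy as np

    from .fragments import FragmentLibrary

    lib = FragmentLibrary.from_compounds(bundled_ligand_compounds())
    frags = sorted(lib.fragments, key=lambda f: f.smiles)
    rng = np.random.default_rng(seed)
    if len(frags) > n_fragments:
        idx = rng.choice(len(frags), size=n_fragments, replace=False)
        frags = [frags[i] for i in sorted(idx)]
    return FragmentLibrary(fragments=frags)
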