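"""Molecule container used throughout the Monte Carlo engine.

A :class:`Compound` carries a sanitized RDKit molecule together with its
canonical SMILES.  Stereochemistry is stripped on input: every chemical move
operates at the constitution level (atoms, bonds, aromaticity), so stereo
flags would only create spurious distinctions between otherwise identical
states of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

# RDKit logs every failed sanitization attempt; the move engine probes many
# candidate edits per step and failures are expected, so silence the C++ log.
RDLogger.DisableLog("rdApp.*")


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed and sanitized."""


@dataclass(frozen=True)
class Compound:
    """An immutable, chemically valid molecule.

    Attributes
    ----------
    smiles:
        Canonical SMILES without stereochemistry; round-trips through RDKit.
    mol:
        The sanitized RDKit molecule the SMILES was derived from.
    """

    smiles: str
    mol: Chem.Mol = field(compare=False, repr=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Compound":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise InvalidSmilesError(f"cannot parse/sanitize SMILES: {smiles!r}")
        return cls.from_mol(mol)

    @classmethod
    def from_mol(cls, mol: Chem.Mol, sanitize: bool = True) -> "Compound":
        """Build from an RDKit molecule, stripping stereo and re-canonicalizing."""
        mol = Chem.Mol(mol)
        if sanitize:
            try:
                Chem.SanitizeMol(mol)
            except Exception as exc:  # pragma: no cover - message carries detail
                raise InvalidSmilesError(f"sanitization failed: {exc}") from exc
        if mol.GetNumHeavyAtoms() < 1:
            raise InvalidSmilesError("molecule has no heavy atoms")
        Chem.RemoveStereochemistry(mol)
        smiles = Chem.MolToSmiles(mol)
        # Re-parse so the stored mol corresponds exactly to the canonical form.
        canon = Chem.MolFromSmiles(smiles)
        if canon is None:
            raise InvalidSmilesError(f"canonical SMILES failed to re-parse: {smiles!r}")
        return cls(smiles=smiles, mol=canon)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def __str__(self) -> str:
        return self.smiles


BENZENE = "c1ccccc1"


def benzene() -> Compound:
    """The default starting compound of the search."""
    return Compound.from_smiles(BENZENE)
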