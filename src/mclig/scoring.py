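"""Objective functions for the Monte Carlo search.

Two families of objectives are provided:

* **Recovery mode** — Dice similarity between count-based atom-pair
  fingerprints of the evolving compound and a fixed target, used to verify
  that the move set can reach arbitrary drug-like constitutions.

* **Design mode** — a composite score

  ``score = 0.8 * confidence + 0.1 * SA' + 0.05 * ESOL' + 0.05 * QED``

  where *confidence* is the self-estimated reliability of a protein-ligand
  co-folding backend (pluggable; a deterministic mock is provided for desk
  runs), SA is the synthetic-accessibility estimate (1 = easy ... 10 = hard)
  mapped so that anything at or below a threshold counts as fully accessible,
  ESOL is the estimated log10 aqueous solubility from the classic linear
  descriptor model, affinely mapped onto [0, 1], and QED is the quantitative
  estimate of drug-likeness with the molecular-weight desirability omitted.
"""

from __future__ import annotations

import math
import os
import sys
from dataclasses import dataclass
from typing import Optional, Protocol

from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, QED
from rdkit.Chem import rdFingerprintGenerator

from .compound import Compound

# The synthetic-accessibility scorer ships with RDKit as a contrib module
# (fragment-frequency contributions plus complexity penalties).
sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402

__all__ = [
    "ScoreBreakdown",
    "CompositeWeights",
    "PredictorBackend",
    "MockBackend",
    "atom_pair_fingerprint",
    "dice_similarity",
    "dice_from_counts",
    "sa_score",
    "esol_score",
    "qed_no_mw",
    "normalize_sa",
    "normalize_esol",
    "composite_score",
    "ScoringConfig",
]


# ---------------------------------------------------------------------------
# fingerprints and similarity

_AP_GENERATOR = rdFingerprintGenerator.GetAtomPairGenerator()


def atom_pair_fingerprint(c: Compound) -> dict[int, int]:
    """Count-based atom-pair fingerprint as a sparse ``{feature: count}`` map.

    Features encode (atom type, atom type, topological distance) for every
    heavy-atom pair; the map is invariant to input atom ordering.
    """
    fp = _AP_GENERATOR.GetSparseCountFingerprint(c.mol)
    return dict(fp.GetNonzeroElements())


def dice_from_counts(a: dict[int, int], b: dict[int, int]) -> float:
    """Dice coefficient ``2 * sum(min(x_i, y_i)) / (sum(x) + sum(y))``."""
    total = sum(a.values()) + sum(b.values())
    if total == 0:
        # two molecules with no heavy-atom pairs (single atoms): identical
        return 1.0
    overlap = sum(min(v, b.get(k, 0)) for k, v in a.items())
    return 2.0 * overlap / total


def dice_similarity(a: Compound, b: Compound) -> float:
    """Dice similarity of the atom-pair count fingerprints of two molecules."""
    return dice_from_counts(atom_pair_fingerprint(a), atom_pair_fingerprint(b))


# ---------------------------------------------------------------------------
# component scores

#: SA values at or below this threshold count as fully synthesizable.  A hard
#: floor on "ease" is deliberate: a binder must carry some complexity to fill
#: a pocket, so the score only penalizes beyond the threshold.
DEFAULT_SA_THRESHOLD = 5.0

#: Affine window mapping ESOL (log10 mol/L) onto [0, 1]; calibrated once by
#: least squares against published composite/component reference rows
#: (see scripts/calibrate_normalization.py).
DEFAULT_ESOL_WINDOW = (-13.705, -1.486)


def sa_score(c: Compound) -> float:
    """Synthetic-accessibility estimate, 1 (easy) to 10 (hard)."""
    return float(sascorer.calculateScore(c.mol))


def esol_score(c: Compound) -> float:
    """Estimated log10 aqueous solubility (mol/L) from the linear model

    ``0.16 - 0.63 clogP - 0.0062 MW + 0.066 RB - 0.74 AP``

    with AP the aromatic proportion (aromatic heavy atoms / heavy atoms).
    """
    mol = c.mol
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = Descriptors.NumRotatableBonds(mol)
    ap = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / mol.GetNumHeavyAtoms()
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


_QED_WEIGHTS_NO_MW = QED.WEIGHT_MEAN._replace(MW=0.0)


def qed_no_mw(c: Compound) -> float:
    """Drug-likeness as a weighted geometric mean of property desirabilities,
    with the molecular-weight desirability dropped and the remaining weights
    renormalized."""
    return float(QED.qed(c.mol, w=_QED_WEIGHTS_NO_MW))


def normalize_sa(sa_raw: float, threshold: float = DEFAULT_SA_THRESHOLD) -> float:
    """Map raw SA onto [0, 1]: 1 at or below ``threshold``, linear decay to 0
    at SA = 10."""
    if sa_raw <= threshold:
        return 1.0
    return max(0.0, min(1.0, (10.0 - sa_raw) / (10.0 - threshold)))


def normalize_esol(
    esol_raw: float,
    lo: float = DEFAULT_ESOL_WINDOW[0],
    hi: float = DEFAULT_ESOL_WINDOW[1],
) -> float:
    """Affine map of ESOL onto [0, 1], clamped; ``lo`` maps to 0, ``hi`` to 1."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    return max(0.0, min(1.0, (esol_raw - lo) / (hi - lo)))


# ---------------------------------------------------------------------------
# composite score

@dataclass(frozen=True)
class CompositeWeights:
    """Weights of the composite objective; must be non-negative and sum to 1."""

    w_conf: float = 0.8
    w_sa: float = 0.1
    w_esol: float = 0.05
    w_qed: float = 0.05

    def __post_init__(self) -> None:
        vals = (self.w_conf, self.w_sa, self.w_esol, self.w_qed)
        if any(w < 0 for w in vals):
            raise ValueError("weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {sum(vals)}, expected 1")


@dataclass(frozen=True)
class ScoringConfig:
    sa_threshold: float = DEFAULT_SA_THRESHOLD
    esol_lo: float = DEFAULT_ESOL_WINDOW[0]
    esol_hi: float = DEFAULT_ESOL_WINDOW[1]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-component record of one composite evaluation."""

    confidence: float
    sa_raw: float
    sa_norm: float
    esol_raw: float
    esol_norm: float
    qed: float
    composite: float

    @classmethod
    def combine(
        cls,
        confidence: float,
        sa_raw: float,
        esol_raw: float,
        qed: float,
        weights: CompositeWeights = CompositeWeights(),
        config: ScoringConfig = ScoringConfig(),
    ) -> "ScoreBreakdown":
        sa_norm = normalize_sa(sa_raw, config.sa_threshold)
        esol_norm = normalize_esol(esol_raw, config.esol_lo, config.esol_hi)
        composite = (
            weights.w_conf * confidence
            + weights.w_sa * sa_norm
            + weights.w_esol * esol_norm
            + weights.w_qed * qed
        )
        return cls(confidence, sa_raw, sa_norm, esol_raw, esol_norm, qed, composite)


class PredictorBackend(Protocol):
    """Contract for a protein-ligand structure-prediction backend.

    ``predict`` must be deterministic for fixed inputs and configuration and
    return a confidence in [0, 1]; the second element is an optional 3D
    complex structure (file content or path) for backends that produce poses.
    """

    def predict(
        self, protein_sequence: str, ligand_smiles: str
    ) -> tuple[float, Optional[object]]: ...


def composite_score(
    c: Compound,
    backend: PredictorBackend,
    protein_sequence: str = "",
    weights: CompositeWeights = CompositeWeights(),
    config: ScoringConfig = ScoringConfig(),
) -> ScoreBreakdown:
    """Evaluate the full design-mode objective for one compound.

    Backend failures propagate to the caller; the engine treats them as a
    rejected step rather than aborting the run.
    """
    confidence, _structure = backend.predict(protein_sequence, c.smiles)
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"backend confidence {confidence} outside [0, 1]")
    return ScoreBreakdown.combine(
        confidence=confidence,
        sa_raw=sa_score(c),
        esol_raw=esol_score(c),
        qed=qed_no_mw(c),
        weights=weights,
        config=config,
    )


# ---------------------------------------------------------------------------
# mock backend

@dataclass(frozen=True)
class MockBackend:
    """Deterministic stand-in for a co-folding backend.

    The confidence is a smooth Gaussian-shaped function of a small descriptor
    vector (heavy atoms, H-bond donors, H-bond acceptors, rings) centred on a
    configurable optimum, so the chain has a climbable landscape with value
    exactly 1 at the optimum.  No structure is returned.
    """

    optimum: tuple[float, float, float, float] = (20.0, 2.0, 4.0, 3.0)
    width: float = 10.0

    def descriptors(self, mol: Chem.Mol) -> tuple[float, float, float, float]:
        return (
            float(mol.GetNumHeavyAtoms()),
            float(Descriptors.NumHDonors(mol)),
            float(Descriptors.NumHAcceptors(mol)),
            float(Descriptors.RingCount(mol)),
        )

    def predict(
        self, protein_sequence: str, ligand_smiles: str
    ) -> tuple[float, Optional[object]]:
        mol = Chem.MolFromSmiles(ligand_smiles)
        if mol is None:
            raise ValueError(f"mock backend got invalid SMILES {ligand_smiles!r}")
        d = self.descriptors(mol)
        dist2 = sum((x - o) ** 2 for x, o in zip(d, self.optimum))
        return math.exp(-dist2 / (2.0 * self.width**2)), None
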