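"""Readers, writers and run configuration.

Formats handled: SMILES lists (``.smi``, one molecule per line with an
optional name), SDF (seed molecules), FASTA (protein sequence for the
predictor backend), YAML (run configuration), and JSONL/CSV trajectory
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO
from rdkit import Chem

from .compound import Compound, InvalidSmilesError
from .engine import TrajectoryRecord

logger = logging.getLogger("mclig")

TRAJECTORY_SCHEMA_VERSION = 1

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def load_smiles_list(path: str | Path) -> list[Compound]:
    """Read one SMILES per line (optional whitespace-separated name).

    Raises ``InvalidSmilesError`` naming the line and offending string on the
    first unparseable record.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            try:
                out.append(Compound.from_smiles(fields[0]))
            except InvalidSmilesError as exc:
                raise InvalidSmilesError(
                    f"{path}: line {ln}: invalid SMILES {fields[0]!r}"
                ) from exc
    return out


def load_sdf_first(path: str | Path) -> Compound:
    """First record of an SDF file as a Compound."""
    try:
        supplier = Chem.SDMolSupplier(str(path))
        for mol in supplier:
            if mol is not None:
                return Compound.from_mol(mol)
    except OSError as exc:
        raise InvalidSmilesError(f"{path}: unreadable SDF: {exc}") from exc
    raise InvalidSmilesError(f"{path}: no readable molecule")


def load_fasta_sequence(path: str | Path) -> str:
    """Sequence of the first FASTA record, validated against the amino-acid
    alphabet (plus X); warns if further records are ignored."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if len(records) > 1:
        logger.warning("%s: %d records, using the first", path, len(records))
    seq = str(records[0].seq).upper()
    bad = set(seq) - _AA_ALPHABET
    if not seq or bad:
        raise ValueError(f"{path}: illegal sequence characters {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(records: list[TrajectoryRecord], out_dir: str | Path) -> None:
    """Write a trajectory as JSONL (lossless) plus a CSV mirror."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "trajectory.jsonl", "w") as fh:
        fh.write(json.dumps({"schema_version": TRAJECTORY_SCHEMA_VERSION}) + "\n")
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")
    rows = []
    for r in records:
        row = r.to_dict()
        bd = row.pop("breakdown") or {}
        row.update({f"score_{k}": v for k, v in bd.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "trajectory.csv", index=False)


def read_trajectory(out_dir: str | Path) -> list[TrajectoryRecord]:
    """Read back a JSONL trajectory written by :func:`write_trajectory`."""
    path = Path(out_dir) / "trajectory.jsonl"
    records = []
    with open(path) as fh:
        header = json.loads(fh.readline())
        version = header.get("schema_version")
        if version != TRAJECTORY_SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported schema version {version}")
        for line in fh:
            d = json.loads(line)
            records.append(TrajectoryRecord(**d))
    return records


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Fully serializable description of one MC run."""

    mode: str = "recover"  # recover | design | fragments
    seed: int = 0
    beta: float = 50.0
    n_steps: int = 10_000
    reset_interval: int = 100
    start_smiles: str = "c1ccccc1"
    target_smiles: Optional[str] = None
    protein_fasta: Optional[str] = None
    backend: str = "mock"
    out_dir: str = "runs"
    # two-stage recovery protocol
    stage1_replicas: int = 0
    stage1_steps: int = 5000
    sync_every: int = 500
    # fragment mode
    fragment_library: Optional[str] = None
    ligands_file: Optional[str] = None
    p_add: float = 0.6
    # moveset override: move name -> probability
    move_probabilities: Optional[dict] = None
    cleanup: bool = False

    _MODES = ("recover", "design", "fragments")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_steps < 0 or self.reset_interval < 1:
            raise ValueError("n_steps >= 0 and reset_interval >= 1 required")
        if not 0.0 <= self.p_add <= 1.0:
            raise ValueError("p_add must lie in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = {k: v for k, v in dataclasses.asdict(self).items() if v is not None}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**d)


def window_acceptance_rates(
    records: list[TrajectoryRecord], window: int = 500
) -> list[tuple[int, float]]:
    """(window start step, acceptance fraction) per fixed-width step window."""
    if not records:
        return []
    props = [r for r in records if not r.is_reset]
    out = []
    max_step = max(r.step for r in props)
    for start in range(0, max_step + 1, window):
        sel = [r for r in props if start <= r.step < start + window]
        if sel:
            out.append((start, sum(r.accepted for r in sel) / len(sel)))
    return out
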