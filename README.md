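# mclig — Monte Carlo ligand design in chemical space

`mclig` evolves a small organic molecule by a Metropolis Monte Carlo walk
over chemical space.  Each step applies one elementary chemical edit —
adding or swapping a substituent, deleting an atom, mutating an element,
inserting an atom into a bond, toggling a bond order, closing, opening or
(de)aromatizing a ring, or migrating a substituent — or, in fragment mode,
adds/removes whole BRICS fragments at labelled attachment points.  A
proposal that improves the objective is always kept; one that lowers it by
`d` survives with probability `exp(-beta * d)`, and every 100th step the
chain resets to the best structure found so far.

Two objectives are built in:

* **Recovery** — Dice similarity between count-based atom-pair fingerprints
  of the evolving molecule and a target compound.  Reaching 1.0 means the
  target's constitution was rebuilt exactly; this mode verifies that the
  move set can reach arbitrary drug-like structures from a benzene seed.
* **Design** — a composite objective

  `score = 0.8 * confidence + 0.1 * SA' + 0.05 * ESOL' + 0.05 * QED`

  where *confidence* comes from a pluggable protein–ligand co-folding
  backend (a deterministic mock ships for CPU-only runs; real runs wrap an
  external structure-prediction model behind the `PredictorBackend`
  contract), SA' is the synthetic-accessibility score with values at or
  below 5 counting as fully accessible, ESOL' the affinely normalized
  log-solubility estimate, and QED the drug-likeness estimate without its
  molecular-weight term.  An optional cleanup phase then optimizes only
  the three biases while forbidding the confidence to drop more than 0.02
  below its starting value.

The package is aimed at computational chemists who want a transparent,
fully scriptable stochastic baseline for de novo ligand generation — one
whose every move, filter and acceptance decision is inspectable — rather
than a learned generative model.

## Worked example

Rebuild the bromodomain ligand of PDB entry 5mli from benzene:

```bash
mclig recover --target-smiles "CNc1cnn(c(=O)c1Cl)C" --seed 2 \
      --stage2-steps 10000 --out runs/5mli
```

```
INFO mclig: best compound CNc1cnn(C)c(=O)c1Cl (score 1.0000) -> runs/5mli
```

The best compound is the target's canonical constitution and the score is
the Dice similarity — 1.0000 means the atom-pair fingerprints coincide,
i.e. the ligand was recovered exactly.  `runs/5mli/` holds the full
trajectory (`trajectory.jsonl` + CSV mirror: step, SMILES, move kind,
score, accepted/reset flags), the per-window acceptance rates, and a YAML
echo of the configuration for replay.

A design run against a protein sequence with the mock backend:

```bash
mclig design --protein protein.fasta --backend mock --steps 2000 \
      --cleanup --seed 1 --out runs/design
```

and a fragment-recombination run seeded from a set of known ligands:

```bash
mclig fragments --from-ligands ligands.smi \
      --target-smiles "SCc1ccc(cc1)C(=O)N1CCC(CC1)Cc1ccccc1" \
      --steps 500 --beta 5 --seed 1 --out runs/frag
```

From Python, the same machinery is three calls:

```python
from mclig import Compound, benzene, run_recovery_chain

target = Compound.from_smiles("CNc1cnn(c(=O)c1Cl)C")
state, trajectory = run_recovery_chain(target, benzene(), seed=2)
print(state.best.smiles, state.best_score)   # CNc1cnn(C)c(=O)c1Cl 1.0
```

## Documentation

`docs/methods.md` describes the model, the normalizations and their
calibration, the move-engine design decisions (ring-size window, validity
filters, aromatic ring resizing), the run protocols, what the mock backend
does and does not emulate, and known limitations.
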