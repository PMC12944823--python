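"""Monte Carlo state machine: Metropolis acceptance, reset-to-best, and the
run protocols (single chain, two-stage multi-replica recovery, design run,
cleanup phase).

A proposal that improves the score is always accepted; a proposal that lowers
it by ``d`` survives with probability ``exp(-beta * d)``, with ``beta`` acting
as an inverse effective temperature: small ``beta`` samples broadly, large
``beta`` approaches greedy hill climbing.  Every ``reset_interval`` steps the
chain is pulled back to the best structure seen so far to escape local optima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from .compound import Compound
from .moves import MoveKind, MoveSet, DEFAULT_MOVE_PROBS, propose
from .scoring import (
    CompositeWeights,
    MockBackend,
    PredictorBackend,
    ScoreBreakdown,
    ScoringConfig,
    atom_pair_fingerprint,
    composite_score,
    dice_from_counts,
    esol_score,
    qed_no_mw,
    sa_score,
)

#: objective: Compound -> (score, optional per-component breakdown)
Objective = Callable[[Compound], tuple[float, Optional[ScoreBreakdown]]]


# ---------------------------------------------------------------------------
# objectives


class DiceObjective:
    """Similarity-driven recovery objective: Dice coefficient between the
    atom-pair count fingerprints of the evolving compound and a fixed target.
    Reaches 1.0 exactly when the fingerprints coincide."""

    def __init__(self, target: Compound):
        self.target = target
        self._target_fp = atom_pair_fingerprint(target)

    def __call__(self, c: Compound) -> tuple[float, Optional[ScoreBreakdown]]:
        return dice_from_counts(atom_pair_fingerprint(c), self._target_fp), None


class CompositeObjective:
    """Design-mode objective: backend confidence plus synthesizability,
    solubility and drug-likeness biases."""

    def __init__(
        self,
        backend: PredictorBackend,
        protein_sequence: str = "",
        weights: CompositeWeights = CompositeWeights(),
        config: ScoringConfig = ScoringConfig(),
    ):
        self.backend = backend
        self.protein_sequence = protein_sequence
        self.weights = weights
        self.config = config

    def __call__(self, c: Compound) -> tuple[float, Optional[ScoreBreakdown]]:
        bd = composite_score(
            c, self.backend, self.protein_sequence, self.weights, self.config
        )
        return bd.composite, bd


class CleanupObjective:
    """Bias-only objective for the cleanup phase: the SA/ESOL/QED terms with
    their design-mode weights renormalized to sum to 1, under a hard floor on
    the backend confidence.  A proposal whose confidence drops below
    ``floor`` scores ``-inf`` and is therefore rejected outright."""

    def __init__(
        self,
        backend: PredictorBackend,
        floor: float,
        protein_sequence: str = "",
        weights: CompositeWeights = CompositeWeights(),
        config: ScoringConfig = ScoringConfig(),
    ):
        self.backend = backend
        self.floor = floor
        self.protein_sequence = protein_sequence
        self.weights = weights
        self.config = config

    def __call__(self, c: Compound) -> tuple[float, Optional[ScoreBreakdown]]:
        bd = composite_score(
            c, self.backend, self.protein_sequence, self.weights, self.config
        )
        w_bias = self.weights.w_sa + self.weights.w_esol + self.weights.w_qed
        bias = (
            self.weights.w_sa * bd.sa_norm
            + self.weights.w_esol * bd.esol_norm
            + self.weights.w_qed * bd.qed
        ) / w_bias
        if bd.confidence < self.floor:
            return -math.inf, bd
        return bias, bd


# ---------------------------------------------------------------------------
# state and records


@dataclass
class TrajectoryRecord:
    step: int
    smiles: str
    move_kind: Optional[str]
    score: float
    accepted: bool
    is_reset: bool = False
    breakdown: Optional[dict] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MCState:
    """Mutable chain state; ``best_score`` is non-decreasing in ``step``."""

    current: Compound
    current_score: float
    best: Compound
    best_score: float
    step: int = 0
    n_proposed: int = 0
    n_accepted: int = 0
    current_breakdown: Optional[ScoreBreakdown] = None
    best_breakdown: Optional[ScoreBreakdown] = None

    @property
    def acceptance_ratio(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0

    @classmethod
    def from_start(cls, start: Compound, objective: Objective) -> "MCState":
        score, bd = objective(start)
        return cls(
            current=start,
            current_score=score,
            best=start,
            best_score=score,
            current_breakdown=bd,
            best_breakdown=bd,
        )


# ---------------------------------------------------------------------------
# acceptance rule


def metropolis_accept(
    s_new: float, s_cur: float, beta: float, rng: np.random.Generator
) -> bool:
    """Accept score-improving proposals always; accept a score decrease of
    magnitude ``d = s_cur - s_new`` with probability ``exp(-beta * d)``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if s_new >= s_cur:
        return True
    d = s_cur - s_new
    if d == math.inf:
        return False
    return bool(rng.random() < math.exp(-beta * d))


# ---------------------------------------------------------------------------
# chain driver


def advance(
    state: MCState,
    objective: Objective,
    moveset: MoveSet,
    beta: float,
    rng: np.random.Generator,
    n_steps: int,
    reset_interval: int = 100,
    records: Optional[list[TrajectoryRecord]] = None,
    stop_at: Optional[float] = None,
) -> MCState:
    """Run ``n_steps`` propose/score/accept iterations on a chain in place.

    The step counter continues from ``state.step`` so a chain can be advanced
    in segments (used by the multi-replica synchronization).  ``stop_at``
    ends the run early once the best score reaches that value (used when the
    objective has a known ceiling such as Dice = 1).
    """
    if reset_interval < 1:
        raise ValueError("reset_interval must be >= 1")
    for _ in range(n_steps):
        if stop_at is not None and state.best_score >= stop_at - 1e-12:
            break
        state.step += 1
        outcome = propose(state.current, moveset, rng)
        state.n_proposed += 1
        if not outcome.feasible:
            if records is not None:
                records.append(
                    TrajectoryRecord(
                        step=state.step,
                        smiles=state.current.smiles,
                        move_kind=None,
                        score=state.current_score,
                        accepted=False,
                    )
                )
        else:
            try:
                score, bd = objective(outcome.compound)
            except Exception:
                # scoring failure rejects the step; the chain survives
                score, bd = None, None
            if score is None:
                accepted = False
            else:
                accepted = metropolis_accept(score, state.current_score, beta, rng)
            if accepted:
                state.n_accepted += 1
                state.current = outcome.compound
                state.current_score = score
                state.current_breakdown = bd
                if score > state.best_score:
                    state.best = outcome.compound
                    state.best_score = score
                    state.best_breakdown = bd
            if records is not None:
                records.append(
                    TrajectoryRecord(
                        step=state.step,
                        smiles=outcome.compound.smiles,
                        move_kind=outcome.move_kind.value if outcome.move_kind else None,
                        score=score if score is not None else math.nan,
                        accepted=accepted,
                        breakdown=_bd_dict(bd),
                    )
                )
        if state.step % reset_interval == 0:
            state.current = state.best
            state.current_score = state.best_score
            state.current_breakdown = state.best_breakdown
            if records is not None:
                records.append(
                    TrajectoryRecord(
                        step=state.step,
                        smiles=state.best.smiles,
                        move_kind=None,
                        score=state.best_score,
                        accepted=True,
                        is_reset=True,
                    )
                )
    return state


def _bd_dict(bd: Optional[ScoreBreakdown]) -> Optional[dict]:
    return None if bd is None else asdict(bd)


def run_chain(
    start: Compound,
    objective: Objective,
    beta: float,
    n_steps: int,
    reset_interval: int = 100,
    moveset: Optional[MoveSet] = None,
    seed: int | Sequence[int] = 0,
    stop_at: Optional[float] = None,
) -> tuple[MCState, list[TrajectoryRecord]]:
    """Run a single Monte Carlo chain from ``start`` and return the final
    state plus the full trajectory."""
    moveset = moveset or MoveSet()
    rng = np.random.default_rng(seed)
    state = MCState.from_start(start, objective)
    records: list[TrajectoryRecord] = []
    advance(
        state, objective, moveset, beta, rng, n_steps, reset_interval,
        records, stop_at,
    )
    return state, records


# ---------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class RecoveryProtocol:
    """Two-stage similarity-driven recovery settings.

    Stage 1 runs ``n_replicas`` chains; every ``sync_every`` steps all chains
    are set to the best structure found by any chain so far.  Stage 2 refines
    with a single chain and periodic reset-to-best.
    """

    beta: float = 50.0
    n_replicas: int = 30
    stage1_steps: int = 5000
    sync_every: int = 500
    stage2_steps: int = 10_000
    reset_interval: int = 100


def run_recovery_chain(
    target: Compound,
    start: Compound,
    beta: float = 50.0,
    n_steps: int = 10_000,
    reset_interval: int = 100,
    moveset: Optional[MoveSet] = None,
    seed: int | Sequence[int] = 0,
    stop_at: Optional[float] = 1.0,
) -> tuple[MCState, list[TrajectoryRecord]]:
    """Single-chain dice-similarity recovery of ``target`` from ``start``."""
    return run_chain(
        start,
        DiceObjective(target),
        beta=beta,
        n_steps=n_steps,
        reset_interval=reset_interval,
        moveset=moveset,
        seed=seed,
        stop_at=stop_at,
    )


def run_multireplica_recovery(
    target: Compound,
    start: Compound,
    protocol: RecoveryProtocol = RecoveryProtocol(),
    moveset: Optional[MoveSet] = None,
    seed: int = 0,
    stop_at: Optional[float] = 1.0,
) -> MCState:
    """Two-stage recovery: synchronized multi-replica exploration followed by
    a single refinement chain; returns the final (best-holding) state.

    Each replica owns an independent RNG stream derived from
    ``(seed, replica_index)``, so results do not depend on scheduling; the
    global best is the highest score with ties broken by lowest replica index
    (then earliest occurrence, implicit in sequential comparison).
    """
    moveset = moveset or MoveSet()
    objective = DiceObjective(target)
    replicas = [
        MCState.from_start(start, objective) for _ in range(protocol.n_replicas)
    ]
    rngs = [
        np.random.default_rng([seed, i]) for i in range(protocol.n_replicas)
    ]
    n_segments = protocol.stage1_steps // protocol.sync_every
    for _seg in range(n_segments):
        if stop_at is not None and any(
            r.best_score >= stop_at - 1e-12 for r in replicas
        ):
            break
        for state, rng in zip(replicas, rngs):
            advance(
                state, objective, moveset, protocol.beta, rng,
                protocol.sync_every,
                reset_interval=protocol.reset_interval,
                stop_at=stop_at,
            )
        # synchronize: everyone continues from the best structure found so far
        global_best = max(replicas, key=lambda r: r.best_score)
        for state in replicas:
            state.current = global_best.best
            state.current_score = global_best.best_score
            state.best = global_best.best
            state.best_score = global_best.best_score
    global_best = max(replicas, key=lambda r: r.best_score)
    # stage 2: single refinement chain from the stage-1 best
    stage2 = MCState.from_start(global_best.best, objective)
    rng2 = np.random.default_rng([seed, protocol.n_replicas])
    advance(
        stage2, objective, moveset, protocol.beta, rng2,
        protocol.stage2_steps, protocol.reset_interval, stop_at=stop_at,
    )
    if global_best.best_score > stage2.best_score:
        stage2.best = global_best.best
        stage2.best_score = global_best.best_score
    return stage2


def run_design(
    protein_sequence: str,
    backend: PredictorBackend,
    start: Compound,
    beta: float = 50.0,
    n_steps: int = 2000,
    reset_interval: int = 100,
    moveset: Optional[MoveSet] = None,
    weights: CompositeWeights = CompositeWeights(),
    config: ScoringConfig = ScoringConfig(),
    seed: int | Sequence[int] = 0,
) -> tuple[MCState, list[TrajectoryRecord]]:
    """De novo design run: single chain under the composite objective."""
    objective = CompositeObjective(backend, protein_sequence, weights, config)
    return run_chain(
        start,
        objective,
        beta=beta,
        n_steps=n_steps,
        reset_interval=reset_interval,
        moveset=moveset,
        seed=seed,
    )


#: Cleanup-phase move probabilities: mass on atom removal and atom-type
#: mutation doubled relative to the standard set, then renormalized -- the
#: phase trims and simplifies rather than grows.
CLEANUP_MOVE_PROBS: dict[MoveKind, float] = {
    k: (p * 2 if k in (MoveKind.REMOVE_ATOM, MoveKind.CHANGE_ATOM_TYPE) else p)
    / 1.3
    for k, p in DEFAULT_MOVE_PROBS.items()
}


def run_cleanup(
    state: MCState,
    backend: PredictorBackend,
    protein_sequence: str = "",
    n_steps: int = 100,
    beta: float = 50.0,
    floor_margin: float = 0.02,
    reset_interval: int = 100,
    moveset: Optional[MoveSet] = None,
    weights: CompositeWeights = CompositeWeights(),
    config: ScoringConfig = ScoringConfig(),
    seed: int | Sequence[int] = 0,
) -> tuple[MCState, list[TrajectoryRecord]]:
    """Post-design cleanup: optimize only the SA/ESOL/QED biases while the
    backend confidence may never fall below its starting value minus
    ``floor_margin`` (proposals at exactly the floor remain eligible)."""
    start = state.best
    start_bd = state.best_breakdown
    if start_bd is None:
        start_bd = composite_score(start, backend, protein_sequence, weights, config)
    floor = start_bd.confidence - floor_margin
    objective = CleanupObjective(backend, floor, protein_sequence, weights, config)
    moveset = moveset or MoveSet(entries=list(CLEANUP_MOVE_PROBS.items()))
    return run_chain(
        start,
        objective,
        beta=beta,
        n_steps=n_steps,
        reset_interval=reset_interval,
        moveset=moveset,
        seed=seed,
    )


@dataclass
class FragmentMCState:
    """Chain state of a fragment-level run; scores refer to the H-capped
    assembly."""

    current: "FragmentedCompound"
    current_score: float
    best: "FragmentedCompound"
    best_score: float
    step: int = 0
    n_proposed: int = 0
    n_accepted: int = 0

    @property
    def acceptance_ratio(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0


def run_fragment_chain(
    lib: "FragmentLibrary",
    objective: Objective,
    start: Optional["FragmentedCompound"] = None,
    beta: float = 5.0,
    n_steps: int = 500,
    reset_interval: int = 50,
    p_add: float = 0.6,
    seed: int | Sequence[int] = 0,
    stop_at: Optional[float] = None,
) -> tuple[FragmentMCState, list[TrajectoryRecord]]:
    """Fragment-recombination Monte Carlo chain.

    Each step either bonds a compatible library fragment onto a random open
    attachment point (probability ``p_add``) or cuts a random inter-fragment
    bond and discards the detached side.  Because whole fragments change the
    score in large jumps, the default inverse temperature is much smaller
    than in the atomistic protocol.  The start is a uniformly drawn library
    fragment when not given.
    """
    from .fragments import add_fragment, random_fragment_start, remove_fragment

    rng = np.random.default_rng(seed)
    if start is None:
        start = random_fragment_start(lib, rng)
    score, _ = objective(start.as_compound())
    state = FragmentMCState(
        current=start, current_score=score, best=start, best_score=score
    )
    records: list[TrajectoryRecord] = []
    for _ in range(n_steps):
        if stop_at is not None and state.best_score >= stop_at - 1e-12:
            break
        state.step += 1
        state.n_proposed += 1
        do_add = rng.random() < p_add
        proposal = (
            add_fragment(state.current, lib, rng)
            if do_add
            else remove_fragment(state.current, rng)
        )
        accepted = False
        score = state.current_score
        smiles = state.current.smiles
        if proposal.feasible:
            try:
                score, _ = objective(proposal.as_compound())
            except Exception:
                score = None
            smiles = proposal.smiles
            if score is not None:
                accepted = metropolis_accept(score, state.current_score, beta, rng)
            if accepted:
                state.n_accepted += 1
                state.current = proposal
                state.current_score = score
                if score > state.best_score:
                    state.best = proposal
                    state.best_score = score
        records.append(
            TrajectoryRecord(
                step=state.step,
                smiles=smiles,
                move_kind="add_fragment" if do_add else "remove_fragment",
                score=score if score is not None else math.nan,
                accepted=accepted,
            )
        )
        if state.step % reset_interval == 0:
            state.current = state.best
            state.current_score = state.best_score
            records.append(
                TrajectoryRecord(
                    step=state.step,
                    smiles=state.best.smiles,
                    move_kind=None,
                    score=state.best_score,
                    accepted=True,
                    is_reset=True,
                )
            )
    return state, records


def acceptance_rate(
    trajectory: Sequence[TrajectoryRecord],
    window: Optional[tuple[int, Optional[int]]] = None,
) -> float:
    """Fraction of proposals accepted within a ``(start_step, end_step)``
    window (end ``None`` = end of run); reset records are not proposals."""
    lo, hi = (0, None) if window is None else window
    props = [
        r
        for r in trajectory
        if not r.is_reset and r.step >= lo and (hi is None or r.step < hi)
    ]
    if not props:
        raise ValueError("no proposals in window")
    return sum(r.accepted for r in props) / len(props)
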