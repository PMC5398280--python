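"""The evolutionary loop: fitness, selection, reproduction, rotation.

Fitness is the vector magnitude of the two per-class scores,

    f = sqrt((acc_pos + out_pos)^2 + (acc_neg + out_neg)^2),

where ``acc_c`` is the class-conditional accuracy on class c and
``out_c`` is an output reward — the fraction of class-c examples on which
the network asserted *any* class — included so that "empty" circuits
still feel selection pressure toward producing outputs.  A perfect
classifier scores sqrt(8).  An example of class c counts as correctly
answered iff the class-c channel is asserted and the opposite channel is
not; asserting both or neither is incorrect (asserting both is legal but
rarely pays).

Each update (generation): every not-yet-scored individual is evaluated on
the active training chunk, the next population is built by tournament
selection plus mutation (with a small elite carried over unchanged), and
at chunk rotations all cached fitnesses are invalidated so the population
is rescored on the new chunk.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .data import PairDataset, TrainingSchedule
from .encoding import FittedEncoder, encode_matrix
from .genome import (
    CircuitNetwork,
    Genome,
    MutationRates,
    classify_batch,
    compile_circuit,
    decode_genome,
    mutate,
    random_genome,
)

MAX_FITNESS = math.sqrt(8.0)


@dataclasses.dataclass(frozen=True)
class FitnessComponents:
    """Per-class accuracies and output rewards plus their combination."""

    acc_pos: float
    acc_neg: float
    out_pos: float
    out_neg: float

    @property
    def f(self) -> float:
        return math.sqrt(
            (self.acc_pos + self.out_pos) ** 2 + (self.acc_neg + self.out_neg) ** 2
        )


def combined_fitness(
    acc_pos: float, acc_neg: float, out_pos: float, out_neg: float
) -> float:
    """The scalar fitness for given component values."""
    return FitnessComponents(acc_pos, acc_neg, out_pos, out_neg).f


def fitness_from_encoded(
    network: CircuitNetwork,
    X_bits: np.ndarray,
    labels: np.ndarray,
    n_steps: int = 1,
) -> FitnessComponents:
    """Score a network on pre-encoded examples (the engine's hot path)."""
    y = np.asarray(labels) == 1
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("fitness needs both classes present in the example set")
    neg_assert, pos_assert = classify_batch(network, X_bits, n_steps)
    answered = neg_assert | pos_assert
    correct_pos = pos_assert & ~neg_assert & y
    correct_neg = neg_assert & ~pos_assert & ~y
    return FitnessComponents(
        acc_pos=float(correct_pos.sum()) / n_pos,
        acc_neg=float(correct_neg.sum()) / n_neg,
        out_pos=float((answered & y).sum()) / n_pos,
        out_neg=float((answered & ~y).sum()) / n_neg,
    )


def fitness(
    network: CircuitNetwork,
    dataset: PairDataset,
    encoder: FittedEncoder,
    n_steps: int = 1,
) -> FitnessComponents:
    """Score a network on raw examples, encoding them first."""
    X = encode_matrix(dataset.features, encoder)
    return fitness_from_encoded(network, X, dataset.labels, n_steps)


def tournament_select(
    fitnesses: Sequence[float], tournament_size: int, rng: np.random.Generator
) -> int:
    """Index of the winner of one tournament.

    ``tournament_size`` individuals are drawn uniformly with replacement;
    the highest-fitness entrant wins, with exact ties broken uniformly.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.size == 0:
        raise ValueError("population is empty")
    entrants = rng.integers(0, fitnesses.size, size=tournament_size)
    best = entrants[fitnesses[entrants].argmax()]
    ties = entrants[fitnesses[entrants] == fitnesses[best]]
    if ties.size > 1:
        best = ties[rng.integers(ties.size)]
    return int(best)


@dataclasses.dataclass
class EvolutionConfig:
    """All knobs of one evolutionary run.

    Full-scale defaults follow the reference parameterization (100,000
    updates, population 500, 100 starting gates, up to 4 inputs/outputs
    per gate, site mutation 0.001, gene duplication/deletion 0.05).
    """

    updates: int = 100_000
    population_size: int = 500
    starting_gates: int = 100
    inputs_per_gate: int = 4
    outputs_per_gate: int = 4
    rates: MutationRates = dataclasses.field(default_factory=MutationRates)
    tournament_size: int = 2
    elitism: int = 1
    n_hidden: int = 64
    n_steps: int = 1
    max_genome_length: int = 40_000
    address_bytes: int = 1
    checkpoint_every: int = 25_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("population_size", "tournament_size", "checkpoint_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("updates", "starting_gates", "elitism", "n_hidden"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if not 1 <= self.inputs_per_gate <= 4 or not 1 <= self.outputs_per_gate <= 4:
            raise ValueError("gate arity limits must be in [1, 4]")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than the population")


@dataclasses.dataclass
class RunResult:
    """Outcome of one evolutionary run."""

    best_genome: Genome
    best_fitness: float
    fitness_trace: list[tuple[int, float]]
    checkpoints: dict[int, Genome]
    config: EvolutionConfig


def run_evolution(
    config: EvolutionConfig,
    dataset: PairDataset,
    schedule: TrainingSchedule,
    encoder: FittedEncoder,
) -> RunResult:
    """Evolve a population of circuit genomes on rotating training chunks.

    Fully reproducible: one generator seeded from ``config.seed`` drives
    every stochastic choice.  ``fitness_trace`` records the population
    best at update 0 and at every checkpoint; ``checkpoints`` holds the
    best-of-population genome at each checkpoint mark (and at the final
    update).  With ``updates=0`` the best of the random initial
    population is returned.
    """
    rng = np.random.default_rng(config.seed)
    n_inputs = encoder.width

    enc_chunks = [
        (
            encode_matrix(dataset.features[idx], encoder),
            dataset.labels[idx],
        )
        for idx in schedule.chunks
    ]

    population = [
        random_genome(
            config.starting_gates, rng, config.max_genome_length, config.address_bytes
        )
        for _ in range(config.population_size)
    ]

    cache: dict[bytes, float] = {}

    def score(genome: Genome, chunk: tuple) -> float:
        key = genome.tobytes()
        f = cache.get(key)
        if f is None:
            if config.n_steps == 1:
                net = compile_circuit(
                    genome, n_inputs, config.n_hidden, config.address_bytes
                )
            else:
                net = decode_genome(
                    genome, n_inputs, config.n_hidden, config.address_bytes
                )
            f = fitness_from_encoded(net, chunk[0], chunk[1], config.n_steps).f
            cache[key] = f
        return f

    chunk_id = schedule.chunk_id(0)
    chunk = enc_chunks[chunk_id]
    fits = np.array([score(g, chunk) for g in population])

    trace: list[tuple[int, float]] = [(0, float(fits.max()))]
    checkpoints: dict[int, Genome] = {}

    for u in range(config.updates):
        new_id = schedule.chunk_id(u)
        if new_id != chunk_id:
            chunk_id = new_id
            chunk = enc_chunks[chunk_id]
            cache.clear()
            fits = np.array([score(g, chunk) for g in population])

        order = np.argsort(fits)[::-1]
        elite = [population[i] for i in order[: config.elitism]]
        offspring = []
        for _ in range(config.population_size - config.elitism):
            parent = population[
                tournament_select(fits, config.tournament_size, rng)
            ]
            offspring.append(
                mutate(parent, config.rates, rng, config.address_bytes)
            )
        population = elite + offspring
        fits = np.array([score(g, chunk) for g in population])

        done = u + 1
        if done % config.checkpoint_every == 0 or done == config.updates:
            best = int(fits.argmax())
            trace.append((done, float(fits[best])))
            checkpoints[done] = population[best].copy()

    best = int(fits.argmax())
    return RunResult(
        best_genome=population[best].copy(),
        best_fitness=float(fits[best]),
        fitness_trace=trace,
        checkpoints=checkpoints,
        config=config,
    )


def assemble_committee(
    run_results: Sequence[RunResult],
    encoder: FittedEncoder,
    at_checkpoint: int | None = None,
):
    """Collect one best genome per run into a voting committee.

    ``at_checkpoint`` selects a recorded checkpoint mark (e.g. the 75,000
    update mark, which gave the full-scale protocol its best committees)
    instead of the final best genome.
    """
    from .committee import Committee  # local import to avoid a cycle

    if not run_results:
        raise ValueError("need at least one run to assemble a committee")
    members: list[CircuitNetwork] = []
    n_steps = run_results[0].config.n_steps
    for r in run_results:
        genome = (
            r.best_genome if at_checkpoint is None else r.checkpoints[at_checkpoint]
        )
        members.append(
            decode_genome(genome, encoder.width, r.config.n_hidden, r.config.address_bytes)
        )
    return Committee(members, encoder=encoder, n_steps=n_steps)
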