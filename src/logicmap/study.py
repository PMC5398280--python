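"""Desk-scale reference studies: parameter recovery and feature reduction.

These functions pin down one fully-specified synthetic experiment so that
validation, documentation and scripted reproduction all run the same
conditions.  The desk profile scales the full-scale reference protocol
(60 runs x 100,000 updates, population 500, 100 gates over thousands of
input bits) down to something a workstation finishes in minutes while
keeping its structure: rotating disjoint training chunks, tournament
selection with a single elite, a committee of per-run champions, and a
held-out test set at the sparse "testing-style" contact prevalence.

Scaling choices (fixed here, discussed in the methods note):

* training prevalence 0.35155 and test prevalence 0.0278 copy the
  reference dataset compositions;
* 100 features (15 binary) with 10 planted informative ones — continuous
  plants shift the positive-class mean by +2 SD, binary plants flip from
  P(1)=0.1 to 0.9 across classes;
* population 50, 500 updates, two rotating chunks of 2,000, 5 runs;
* 20 starting gates and 16 hidden nodes, keeping roughly the reference
  ratio of gate taps to input bits at the ~200-bit encoded width;
* the split-4 / 2-bits-per-feature encoding (the best and simplest of the
  five reference encodings).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .committee import (
    Committee,
    EvaluationReport,
    evaluate,
    predict_dataset,
    random_baseline_fmax,
)
from .data import (
    PairDataset,
    TEST_POSITIVE_RATE,
    TRAIN_POSITIVE_RATE,
    generate_synthetic,
    training_schedule,
)
from .encoding import fit_encoder
from .evolve import EvolutionConfig, RunResult, assemble_committee, run_evolution
from .genome import MutationRates
from .salience import RecognitionTable, recognition_table, reduced_dataset

N_FEATURES = 100
N_BINARY = 15
#: planted class-informative features: eight binary near-deterministic
#: markers (the analog of the reference dataset's sequence-separation
#: indicator bins, its most-recognized features) plus two strongly
#: shifted continuous features
PLANTED = (
    (1, 1.0),
    (3, 1.0),
    (5, 1.0),
    (7, 1.0),
    (9, 1.0),
    (11, 1.0),
    (13, 1.0),
    (14, 1.0),
    (15, 5.0),
    (16, 5.0),
)
N_TRAIN = 5_000
N_TEST = 2_000
ENCODING = "split16"
CHUNK_SIZE = 2_000
ROTATE_EVERY = 250
REDUCED_MIN_NETWORKS = 3


def desk_config(seed: int, n_inputs_hint: int | None = None) -> EvolutionConfig:
    """The desk-scale evolution configuration for one run."""
    return EvolutionConfig(
        updates=500,
        population_size=50,
        starting_gates=20,
        rates=MutationRates(site_rate=0.001, dup_rate=0.05, del_rate=0.05),
        tournament_size=2,
        elitism=1,
        n_hidden=16,
        n_steps=1,
        checkpoint_every=125,
        seed=int(seed),
    )


def _derive_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def make_study_data(seed: int) -> tuple[PairDataset, PairDataset]:
    """The training and held-out testing sets for one study seed."""
    s_train, s_test = _derive_seeds(seed, 2)
    train = generate_synthetic(
        n_proteins=50,
        pairs_per_protein=N_TRAIN // 50,
        n_features=N_FEATURES,
        n_binary=N_BINARY,
        informative=PLANTED,
        positive_rate=TRAIN_POSITIVE_RATE,
        seed=s_train,
    )
    test = generate_synthetic(
        n_proteins=20,
        pairs_per_protein=N_TEST // 20,
        n_features=N_FEATURES,
        n_binary=N_BINARY,
        informative=PLANTED,
        positive_rate=TEST_POSITIVE_RATE,
        seed=s_test,
    )
    return train, test


@dataclasses.dataclass
class RecoveryResult:
    """Outcome of one parameter-recovery study seed."""

    report: EvaluationReport
    baseline_fmax: float
    table: RecognitionTable
    planted_mean: float
    null_mean: float
    committee: Committee
    runs: list[RunResult]
    train: PairDataset
    test: PairDataset

    @property
    def fmax(self) -> float:
        return self.report.fmax

    @property
    def fmax_ratio(self) -> float:
        return self.fmax / self.baseline_fmax

    @property
    def recovered(self) -> bool:
        return self.fmax > 3.0 * self.baseline_fmax and (
            self.planted_mean > self.null_mean
        )


def parameter_recovery_study(seed: int, n_runs: int = 5) -> RecoveryResult:
    """Evolve a desk-scale committee on planted data and measure recovery.

    Measures (a) held-out committee Fmax against the label-blind random
    baseline at guess rate 0.5 on the same test composition, and (b) the
    mean recognition count of the planted features against that of the
    null features.
    """
    train, test = make_study_data(seed)
    encoder = fit_encoder(train.features, train.feature_metas, ENCODING)
    run_seeds = _derive_seeds(seed + 1_000_003, n_runs)
    schedule = training_schedule(train, CHUNK_SIZE, ROTATE_EVERY, 500)
    runs = [
        run_evolution(desk_config(s), train, schedule, encoder) for s in run_seeds
    ]
    committee = assemble_committee(runs, encoder)
    rng = np.random.default_rng(_derive_seeds(seed + 2_000_003, 1)[0])
    preds = predict_dataset(committee, test, rng)
    report = evaluate(preds)
    n_pos = int((test.labels == 1).sum())
    baseline = random_baseline_fmax(n_pos, len(test) - n_pos, 0.5)
    table = recognition_table(
        committee, encoder.scheme.bits_per_feature, N_FEATURES
    )
    planted_idx = [f for f, _ in PLANTED]
    null_idx = [f for f in range(N_FEATURES) if f not in set(planted_idx)]
    return RecoveryResult(
        report=report,
        baseline_fmax=baseline,
        table=table,
        planted_mean=float(table.feature_counts[planted_idx].mean()),
        null_mean=float(table.feature_counts[null_idx].mean()),
        committee=committee,
        runs=runs,
        train=train,
        test=test,
    )


@dataclasses.dataclass
class ReductionResult:
    """Full- versus reduced-feature study outcome for one seed."""

    full_fmax: float
    reduced_fmax: float
    n_kept: int

    @property
    def relative_loss(self) -> float:
        if self.full_fmax == 0:
            return float("inf")
        return (self.full_fmax - self.reduced_fmax) / self.full_fmax


def reduced_feature_study(
    recovery: RecoveryResult,
    min_networks: int = REDUCED_MIN_NETWORKS,
    n_runs: int = 5,
) -> ReductionResult:
    """Re-evolve on the recognition-thresholded feature subset.

    Keeps the features recognized by at least ``min_networks`` members of
    the recovery committee, refits the encoder on the reduced training
    data, reruns the same desk-scale protocol, and compares held-out
    committee Fmax with the full-feature result.
    """
    red_train, keep = reduced_dataset(recovery.train, recovery.table, min_networks)
    red_test = PairDataset(
        recovery.test.labels,
        recovery.test.protein_ids,
        recovery.test.res_i,
        recovery.test.res_j,
        recovery.test.features[:, keep],
        red_train.feature_metas,
    )
    encoder = fit_encoder(red_train.features, red_train.feature_metas, ENCODING)
    base_seed = recovery.runs[0].config.seed
    run_seeds = _derive_seeds(base_seed + 3_000_017, n_runs)
    schedule = training_schedule(red_train, CHUNK_SIZE, ROTATE_EVERY, 500)
    runs = [
        run_evolution(desk_config(s), red_train, schedule, encoder)
        for s in run_seeds
    ]
    committee = assemble_committee(runs, encoder)
    rng = np.random.default_rng(_derive_seeds(base_seed + 4_000_037, 1)[0])
    preds = predict_dataset(committee, red_test, rng)
    report = evaluate(preds)
    return ReductionResult(
        full_fmax=recovery.fmax,
        reduced_fmax=report.fmax,
        n_kept=len(keep),
    )
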