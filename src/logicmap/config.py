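"""Run configuration files, named profiles, and run manifests.

A run configuration is a flat key-value YAML file mirroring the
evolutionary parameter table plus encoding, seed and output settings.
Two named profiles ship with the package:

``paper``
    The full-scale reference parameterization: 60 runs of 100,000
    updates, population 500, 100 starting gates, training chunks of
    50,000 rotated every 25,000 updates.
``desk``
    A workstation-scale profile: 5 runs of 500 updates, population 50,
    20 starting gates, chunks of 2,000 rotated every 250 updates.

A :class:`RunManifest` records everything needed to reproduce a finished
run set exactly — the resolved configuration, the per-run seeds, and the
artifact paths — as a JSON file next to the artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .evolve import EvolutionConfig
from .genome import MutationRates

PROFILES: dict[str, dict] = {
    "paper": {
        "n_runs": 60,
        "updates": 100_000,
        "population_size": 500,
        "starting_gates": 100,
        "n_hidden": 64,
        "chunk_size": 50_000,
        "rotate_every": 25_000,
        "checkpoint_every": 25_000,
    },
    "desk": {
        "n_runs": 5,
        "updates": 500,
        "population_size": 50,
        "starting_gates": 20,
        "n_hidden": 16,
        "chunk_size": 2_000,
        "rotate_every": 250,
        "checkpoint_every": 125,
    },
}

_COMMON_DEFAULTS = {
    "encoding": "split4-2bit",
    "site_rate": 0.001,
    "dup_rate": 0.05,
    "del_rate": 0.05,
    "tournament_size": 2,
    "elitism": 1,
    "n_steps": 1,
    "max_genome_length": 40_000,
    "address_bytes": 1,
    "seed": 0,
}


def resolve_config(settings: dict | None = None, profile: str = "desk") -> dict:
    """Merge profile defaults with explicit settings (settings win)."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    merged = dict(_COMMON_DEFAULTS)
    merged.update(PROFILES[profile])
    merged["profile"] = profile
    merged.update(settings or {})
    return merged


def load_config(path) -> dict:
    """Read a YAML config file and resolve it against its profile."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a key-value mapping")
    profile = raw.pop("profile", "desk")
    return resolve_config(raw, profile)


def evolution_config(resolved: dict, seed: int) -> EvolutionConfig:
    """Build one run's :class:`EvolutionConfig` from a resolved config."""
    return EvolutionConfig(
        updates=int(resolved["updates"]),
        population_size=int(resolved["population_size"]),
        starting_gates=int(resolved["starting_gates"]),
        rates=MutationRates(
            site_rate=float(resolved["site_rate"]),
            dup_rate=float(resolved["dup_rate"]),
            del_rate=float(resolved["del_rate"]),
        ),
        tournament_size=int(resolved["tournament_size"]),
        elitism=int(resolved["elitism"]),
        n_hidden=int(resolved["n_hidden"]),
        n_steps=int(resolved["n_steps"]),
        max_genome_length=int(resolved["max_genome_length"]),
        address_bytes=int(resolved["address_bytes"]),
        checkpoint_every=int(resolved["checkpoint_every"]),
        seed=seed,
    )


def derive_run_seeds(seed: int, n_runs: int) -> list[int]:
    """Independent per-run seeds derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n_runs, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclasses.dataclass
class RunManifest:
    """A reproducibility record for a completed run set."""

    config: dict
    run_seeds: list[int]
    checkpoint_marks: list[int]
    genome_files: list[str]
    encoder_file: str | None = None
    predictions_file: str | None = None
    report_file: str | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)

    def artifacts_exist(self, root: Path | str = ".") -> bool:
        root = Path(root)
        paths = list(self.genome_files)
        for p in (self.encoder_file, self.predictions_file, self.report_file):
            if p is not None:
                paths.append(p)
        return all((root / p).exists() for p in paths)
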