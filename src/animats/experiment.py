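"""Scenario planning, orchestration, and result persistence.

The canonical grid is 6 pattern lengths x 12 pattern replicates x 2
architectures = 144 evolving scenarios, each with 100 animats.  For
length 3 the twelve replicates cycle the only three possible patterns
(011, 101, 110) four times each.  After evolution, every
final-generation animat runs the pattern-matching task and the
random-sequence task (one shuffled probe per scenario, shared by all
animats so comparisons are paired).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evolution import (
    EvolutionConfig,
    EvolveOutcome,
    ScenarioConfig,
    evolve,
    scenario_rngs,
)
from .network import ARCH_DEEP, ARCH_SHALLOW, Architecture
from .sequences import (
    CANONICAL_PATTERN_LENGTHS,
    CANONICAL_SEQUENCE_LENGTH,
    LENGTH3_PATTERNS,
    PatternString,
    generate_pattern,
    shuffle_sequence,
)
from .tasks import run_population, run_task, trace_to_csv

__all__ = [
    "CANONICAL_ARCHITECTURES",
    "CANONICAL_REPLICATES",
    "PRESETS",
    "ExperimentPlan",
    "ScenarioResult",
    "plan_canonical_experiment",
    "run_scenario",
    "run_replicates",
    "write_scenario_outputs",
]

CANONICAL_ARCHITECTURES = (ARCH_SHALLOW, ARCH_DEEP)
CANONICAL_REPLICATES = 12

#: Scaled-down presets for desk-scale runs; "canonical" matches the
#: full protocol exactly.
PRESETS: dict[str, dict] = {
    "canonical": {"generations": 1000, "replicates": CANONICAL_REPLICATES},
    "quick": {"generations": 200, "replicates": 3},
    "smoke": {"generations": 5, "replicates": 1},
}


@dataclass(frozen=True)
class ExperimentPlan:
    scenarios: tuple[ScenarioConfig, ...]
    master_seed: int

    def __len__(self) -> int:
        return len(self.scenarios)


def plan_canonical_experiment(
    master_seed: int,
    *,
    pattern_lengths: tuple[int, ...] = CANONICAL_PATTERN_LENGTHS,
    architectures: tuple[Architecture, ...] = CANONICAL_ARCHITECTURES,
    replicates: int = CANONICAL_REPLICATES,
    evolution: EvolutionConfig | None = None,
    sequence_length: int = CANONICAL_SEQUENCE_LENGTH,
) -> ExperimentPlan:
    """Enumerate the scenario grid, deterministically seeded.

    Scenario seeds and per-replicate patterns are derived from
    ``master_seed`` by stable spawn indices, so two plans built from the
    same seed are identical and any subset can be re-run in isolation.
    """
    if evolution is None:
        evolution = EvolutionConfig()
    root = np.random.SeedSequence(master_seed)
    # one child per (arch, length, replicate) cell, enumeration-stable
    n_cells = len(architectures) * len(pattern_lengths) * replicates
    children = root.spawn(n_cells)
    scenarios = []
    cell = 0
    for arch in architectures:
        for length in pattern_lengths:
            for rep in range(replicates):
                ss = children[cell]
                cell += 1
                pattern_ss, scenario_ss = ss.spawn(2)
                if length == 3:
                    pattern = PatternString.from_string(
                        LENGTH3_PATTERNS[rep % len(LENGTH3_PATTERNS)]
                    )
                else:
                    pattern = generate_pattern(length, np.random.default_rng(pattern_ss))
                scenarios.append(
                    ScenarioConfig(
                        pattern=pattern,
                        architecture=arch,
                        sequence_length=sequence_length,
                        evolution=evolution,
                        scenario_seed=int(scenario_ss.generate_state(1)[0]),
                        replicate_id=rep,
                    )
                )
    return ExperimentPlan(scenarios=tuple(scenarios), master_seed=master_seed)


@dataclass
class ScenarioResult:
    """Everything produced by one scenario run."""

    config: ScenarioConfig
    log: pd.DataFrame
    metrics: pd.DataFrame  # one row per animat per task
    fittest_index: int
    fittest_pattern_trace: object  # TaskResult
    fittest_random_trace: object  # TaskResult
    final_genes: np.ndarray
    stopped_early: bool

    @property
    def fittest_row(self) -> pd.Series:
        pattern = self.metrics[self.metrics["task"] == "pattern_matching"]
        return pattern[pattern["animat"] == self.fittest_index].iloc[0]


def run_scenario(
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    *,
    checkpoint_path=None,
) -> ScenarioResult:
    """Evolve one scenario, then probe the final generation on both tasks."""
    outcome: EvolveOutcome = evolve(config, checkpoint_path=checkpoint_path)
    pattern_seq = outcome.sequence
    shuffle_rng = scenario_rngs(config.scenario_seed)["shuffle"]
    random_seq = shuffle_sequence(pattern_seq, shuffle_rng)

    genes = outcome.metapopulation.all_genes()
    rows = []
    fitness_by_task = {}
    for task_name, seq in (
        ("pattern_matching", pattern_seq),
        ("random_sequence", random_seq),
    ):
        fitness, avg_response = run_population(genes, config.architecture, seq)
        fitness_by_task[task_name] = fitness
        for animat in range(genes.shape[0]):
            rows.append(
                {
                    "animat": animat,
                    "task": task_name,
                    "fitness": int(fitness[animat]),
                    "accuracy": fitness[animat] / len(seq),
                    "average_response": float(avg_response[animat]),
                    "pattern_length": config.pattern.length,
                    "architecture": str(config.architecture),
                    "replicate_id": config.replicate_id,
                    "scenario_seed": config.scenario_seed,
                }
            )
    metrics = pd.DataFrame(rows)

    fittest_index = int(np.argmax(fitness_by_task["pattern_matching"]))
    from .genome import Chromosome

    fittest_chromosome = Chromosome(
        genes=genes[fittest_index], architecture=config.architecture
    )
    fittest_pattern_trace = run_task(fittest_chromosome, pattern_seq)
    fittest_random_trace = run_task(fittest_chromosome, random_seq)

    result = ScenarioResult(
        config=config,
        log=outcome.log,
        metrics=metrics,
        fittest_index=fittest_index,
        fittest_pattern_trace=fittest_pattern_trace,
        fittest_random_trace=fittest_random_trace,
        final_genes=genes,
        stopped_early=outcome.stopped_early,
    )
    if out_dir is not None:
        write_scenario_outputs(result, out_dir)
    return result


def run_replicates(
    *,
    pattern_length: int,
    architecture: Architecture,
    master_seed: int,
    replicates: int = 3,
    generations: int = 1000,
    early_stop_fitness: int | None = None,
    pattern: PatternString | None = None,
    sequence_length: int = CANONICAL_SEQUENCE_LENGTH,
    stop_when=None,
) -> list[ScenarioResult]:
    """Run replicate scenarios of one condition with derived seeds.

    Replicate seeds (and, unless ``pattern`` is given, replicate
    patterns) are spawned deterministically from ``master_seed``.  For
    length 3 the replicates cycle the three possible patterns.  If
    ``stop_when`` is given it is called with each finished
    :class:`ScenarioResult`; a truthy return stops further replicates
    (used by scaled-down endpoint checks that only need one success).
    """
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(replicates)
    evolution = EvolutionConfig(
        generations=generations, early_stop_fitness=early_stop_fitness
    )
    results = []
    for rep in range(replicates):
        pattern_ss, scenario_ss = children[rep].spawn(2)
        if pattern is not None:
            pat = pattern
        elif pattern_length == 3:
            pat = PatternString.from_string(LENGTH3_PATTERNS[rep % 3])
        else:
            pat = generate_pattern(pattern_length, np.random.default_rng(pattern_ss))
        config = ScenarioConfig(
            pattern=pat,
            architecture=architecture,
            sequence_length=sequence_length,
            evolution=evolution,
            scenario_seed=int(scenario_ss.generate_state(1)[0]),
            replicate_id=rep,
        )
        result = run_scenario(config)
        results.append(result)
        if stop_when is not None and stop_when(result):
            break
    return results


def write_scenario_outputs(result: ScenarioResult, out_dir: str | Path) -> None:
    """Persist log, metrics, fittest traces, and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label = result.config.label
    result.log.to_csv(out / f"{label}_log.csv", index=False)
    result.metrics.to_csv(out / f"{label}_metrics.csv", index=False)
    trace_to_csv(result.fittest_pattern_trace, out / f"{label}_trace_pattern.csv")
    trace_to_csv(result.fittest_random_trace, out / f"{label}_trace_random.csv")
    manifest = {
        "version": __version__,
        "pattern": str(result.config.pattern),
        "pattern_length": result.config.pattern.length,
        "architecture": str(result.config.architecture),
        "sequence_length": result.config.sequence_length,
        "scenario_seed": result.config.scenario_seed,
        "replicate_id": result.config.replicate_id,
        "generations": result.config.evolution.generations,
        "stopped_early": result.stopped_early,
        "fittest_index": result.fittest_index,
    }
    with open(out / f"{label}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
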