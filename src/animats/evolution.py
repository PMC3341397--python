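"""Island-model genetic algorithm.

Five demes of twenty real-valued genomes evolve under tournament
selection (size 2), per-gene uniform crossover, 5% per-gene mutation
with a uniform [-0.1, 0.1) step clipped back into the gene interval,
and full generational replacement.  Every 100 generations each deme's
champion is copied into another, randomly chosen deme, replacing that
deme's least-fit member, so deme sizes never change.

Randomness is organised as named sub-streams spawned from one scenario
seed (init / ga / migration / shuffle), so evolutionary trajectories and
probe-sequence shuffles can be varied independently and replays are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GENE_HIGH, GENE_LOW, Chromosome, random_chromosome
from .network import Architecture
from .sequences import (
    CANONICAL_SEQUENCE_LENGTH,
    PatternString,
    make_periodic_sequence,
)
from .tasks import run_population

__all__ = [
    "EvolutionConfig",
    "ScenarioConfig",
    "Deme",
    "Metapopulation",
    "tournament_select",
    "crossover",
    "mutate",
    "next_generation",
    "migrate",
    "evolve",
    "EvolveOutcome",
    "scenario_rngs",
    "save_checkpoint",
    "load_checkpoint",
]

# largest double below 1.0: the gene interval is closed-open [-1, 1)
_GENE_MAX = np.nextafter(GENE_HIGH, GENE_LOW)

_STREAM_NAMES = ("init", "ga", "migration", "shuffle")


@dataclass(frozen=True)
class EvolutionConfig:
    """Genetic-algorithm settings (defaults are the canonical ones)."""

    generations: int = 1000
    n_demes: int = 5
    deme_size: int = 20
    mutation_prob: float = 0.05
    mutation_low: float = -0.1
    mutation_high: float = 0.1
    migration_interval: int = 100
    tournament_size: int = 2
    early_stop_fitness: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation probability must be in [0, 1]")
        if self.mutation_low > self.mutation_high:
            raise ValueError("mutation interval is ill-ordered")
        if self.tournament_size != 2:
            raise ValueError("only size-2 tournaments are supported")
        if min(self.generations, self.n_demes, self.deme_size) < 1:
            raise ValueError("generations, demes and deme size must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """One evolving scenario: a pattern, an architecture, and GA settings."""

    pattern: PatternString
    architecture: Architecture
    sequence_length: int = CANONICAL_SEQUENCE_LENGTH
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    scenario_seed: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.sequence_length % self.pattern.length != 0:
            raise ValueError(
                "sequence length must be a multiple of the pattern length"
            )

    @property
    def label(self) -> str:
        return (
            f"L{self.pattern.length}_arch{self.architecture}"
            f"_rep{self.replicate_id}_seed{self.scenario_seed}"
        )


@dataclass
class Deme:
    """A subpopulation plus its (optionally evaluated) fitnesses."""

    members: list[Chromosome]
    fitnesses: np.ndarray | None = None
    average_responses: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def evaluated(self) -> bool:
        return self.fitnesses is not None

    def champion_index(self) -> int:
        if not self.evaluated:
            raise RuntimeError("deme has no fitnesses")
        return int(np.argmax(self.fitnesses))

    def worst_indices(self, k: int = 1) -> list[int]:
        if not self.evaluated:
            raise RuntimeError("deme has no fitnesses")
        order = np.argsort(self.fitnesses, kind="stable")
        return [int(i) for i in order[:k]]


@dataclass
class Metapopulation:
    demes: list[Deme]
    generation: int = 0

    @property
    def total_size(self) -> int:
        return sum(d.size for d in self.demes)

    def all_genes(self) -> np.ndarray:
        return np.stack([c.genes for d in self.demes for c in d.members])

    def global_best(self) -> tuple[int, int, Chromosome]:
        """(deme index, member index, chromosome) of the fittest animat."""
        best = None
        for di, deme in enumerate(self.demes):
            ci = deme.champion_index()
            f = deme.fitnesses[ci]
            if best is None or f > best[0]:
                best = (f, di, ci)
        _, di, ci = best
        return di, ci, self.demes[di].members[ci]


def scenario_rngs(scenario_seed: int) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from one scenario seed."""
    children = np.random.SeedSequence(scenario_seed).spawn(len(_STREAM_NAMES))
    return {
        name: np.random.default_rng(ss) for name, ss in zip(_STREAM_NAMES, children)
    }


# ---------------------------------------------------------------------------
# GA operators

def tournament_select(deme: Deme, rng: np.random.Generator) -> Chromosome:
    """Size-2 tournament: two distinct members, higher fitness wins.

    Ties are broken uniformly at random.
    """
    if not deme.evaluated:
        raise RuntimeError("cannot select from an unevaluated deme")
    a, b = rng.choice(deme.size, size=2, replace=False)
    fa, fb = deme.fitnesses[a], deme.fitnesses[b]
    if fa == fb:
        winner = a if rng.integers(2) == 0 else b
    else:
        winner = a if fa > fb else b
    return deme.members[int(winner)]


def crossover(
    parent_a: Chromosome, parent_b: Chromosome, rng: np.random.Generator
) -> Chromosome:
    """Per-gene uniform crossover: each child gene copies a random parent."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents have mismatched gene counts")
    from_a = rng.integers(0, 2, size=len(parent_a)).astype(bool)
    genes = np.where(from_a, parent_a.genes, parent_b.genes)
    return Chromosome(genes=genes, architecture=parent_a.architecture)


def mutate(
    chromosome: Chromosome, config: EvolutionConfig, rng: np.random.Generator
) -> Chromosome:
    """Per-gene mutation with clipping back into [-1, 1).

    Each gene is perturbed with probability ``mutation_prob`` by a
    uniform draw from [mutation_low, mutation_high); the result is
    clipped to the closed-open gene interval.
    """
    n = len(chromosome)
    hit = rng.random(n) < config.mutation_prob
    steps = rng.uniform(config.mutation_low, config.mutation_high, n)
    genes = chromosome.genes + np.where(hit, steps, 0.0)
    genes = np.clip(genes, GENE_LOW, _GENE_MAX)
    return Chromosome(genes=genes, architecture=chromosome.architecture)


def next_generation(
    deme: Deme, config: EvolutionConfig, rng: np.random.Generator
) -> Deme:
    """Full generational replacement: each child gets two tournament
    parents (drawn independently), crossover, then mutation."""
    children = []
    for _ in range(deme.size):
        pa = tournament_select(deme, rng)
        pb = tournament_select(deme, rng)
        children.append(mutate(crossover(pa, pb, rng), config, rng))
    return Deme(members=children)


def migrate(metapop: Metapopulation, rng: np.random.Generator) -> None:
    """Copy each deme's champion into another, randomly chosen deme.

    All champions and destinations are decided from the pre-migration
    snapshot.  Each destination replaces its least-fit members (one per
    incoming migrant) with the migrants, so sizes are conserved; the
    migrant keeps its fitness record in the destination.
    """
    n = len(metapop.demes)
    if n < 2:
        return
    snapshot = [
        (d.members[d.champion_index()], int(d.fitnesses[d.champion_index()]),
         float(d.average_responses[d.champion_index()])
         if d.average_responses is not None else np.nan)
        for d in metapop.demes
    ]
    destinations: dict[int, list[tuple[Chromosome, int, float]]] = {}
    for source in range(n):
        choices = [i for i in range(n) if i != source]
        dest = int(rng.choice(choices))
        destinations.setdefault(dest, []).append(snapshot[source])
    for dest, migrants in destinations.items():
        deme = metapop.demes[dest]
        slots = deme.worst_indices(len(migrants))
        for slot, (chrom, fit, avg) in zip(slots, migrants):
            deme.members[slot] = chrom
            deme.fitnesses[slot] = fit
            if deme.average_responses is not None:
                deme.average_responses[slot] = avg


# ---------------------------------------------------------------------------
# the full loop

@dataclass
class EvolveOutcome:
    metapopulation: Metapopulation
    log: pd.DataFrame
    sequence: object  # TaskSequence the animats evolved on
    stopped_early: bool = False


def _evaluate(metapop: Metapopulation, architecture, sequence) -> None:
    genes = metapop.all_genes()
    fitness, avg_response = run_population(genes, architecture, sequence)
    offset = 0
    for deme in metapop.demes:
        deme.fitnesses = fitness[offset : offset + deme.size].astype(np.int64)
        deme.average_responses = avg_response[offset : offset + deme.size].copy()
        offset += deme.size


def _log_rows(metapop: Metapopulation, rows: list[dict]) -> None:
    for di, deme in enumerate(metapop.demes):
        ci = deme.champion_index()
        rows.append(
            {
                "generation": metapop.generation,
                "deme": di,
                "best_fitness": int(deme.fitnesses[ci]),
                "mean_fitness": float(np.mean(deme.fitnesses)),
                "best_avg_response": float(deme.average_responses[ci]),
            }
        )


def evolve(
    scenario: ScenarioConfig,
    *,
    checkpoint_path=None,
    checkpoint_interval: int = 100,
    resume_from=None,
) -> EvolveOutcome:
    """Run one evolving scenario from scratch (or from a checkpoint).

    Generation 0 is a uniform random population.  Each generation is
    evaluated on the pattern-matching task starting from genotypic
    weights; migration happens after the evaluation of every
    ``migration_interval``-th generation; breeding is per-deme with full
    replacement.  Fully deterministic given ``scenario.scenario_seed``.
    """
    cfg = scenario.evolution
    sequence = make_periodic_sequence(scenario.pattern, scenario.sequence_length)
    rngs = scenario_rngs(scenario.scenario_seed)
    rows: list[dict] = []

    if resume_from is not None:
        metapop, rngs, rows = load_checkpoint(resume_from, scenario.architecture)
        _evaluate(metapop, scenario.architecture, sequence)
        start = metapop.generation
    else:
        init_rng = rngs["init"]
        metapop = Metapopulation(
            demes=[
                Deme(
                    members=[
                        random_chromosome(scenario.architecture, init_rng)
                        for _ in range(cfg.deme_size)
                    ]
                )
                for _ in range(cfg.n_demes)
            ],
            generation=0,
        )
        _evaluate(metapop, scenario.architecture, sequence)
        _log_rows(metapop, rows)
        start = 0

    stopped_early = False
    for gen in range(start + 1, cfg.generations + 1):
        metapop = Metapopulation(
            demes=[next_generation(d, cfg, rngs["ga"]) for d in metapop.demes],
            generation=gen,
        )
        _evaluate(metapop, scenario.architecture, sequence)
        if gen % cfg.migration_interval == 0:
            migrate(metapop, rngs["migration"])
        _log_rows(metapop, rows)
        if checkpoint_path is not None and gen % checkpoint_interval == 0:
            save_checkpoint(checkpoint_path, metapop, rngs, rows)
        best = max(int(d.fitnesses[d.champion_index()]) for d in metapop.demes)
        if cfg.early_stop_fitness is not None and best >= cfg.early_stop_fitness:
            stopped_early = True
            break

    log = pd.DataFrame(
        rows,
        columns=[
            "generation",
            "deme",
            "best_fitness",
            "mean_fitness",
            "best_avg_response",
        ],
    )
    return EvolveOutcome(
        metapopulation=metapop,
        log=log,
        sequence=sequence,
        stopped_early=stopped_early,
    )


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path, metapop: Metapopulation, rngs, rows) -> None:
    """JSON snapshot of population, fitnesses, RNG states, and the log."""
    payload = {
        "generation": metapop.generation,
        "demes": [
            {
                "genes": [c.genes.tolist() for c in d.members],
                "fitnesses": None
                if d.fitnesses is None
                else [int(f) for f in d.fitnesses],
            }
            for d in metapop.demes
        ],
        "rng_states": {name: rng.bit_generator.state for name, rng in rngs.items()},
        "log_rows": rows,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path, architecture: Architecture):
    with open(path) as fh:
        payload = json.load(fh)
    demes = [
        Deme(
            members=[
                Chromosome(genes=np.asarray(g, dtype=float), architecture=architecture)
                for g in d["genes"]
            ]
        )
        for d in payload["demes"]
    ]
    metapop = Metapopulation(demes=demes, generation=int(payload["generation"]))
    rngs = {}
    for name in _STREAM_NAMES:
        rng = np.random.default_rng()
        rng.bit_generator.state = payload["rng_states"][name]
        rngs[name] = rng
    return metapop, rngs, list(payload["log_rows"])
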