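import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from animats.evolution import (
    Deme,
    EvolutionConfig,
    Metapopulation,
    ScenarioConfig,
    crossover,
    evolve,
    load_checkpoint,
    migrate,
    mutate,
    next_generation,
    save_checkpoint,
    scenario_rngs,
    tournament_select,
)
from animats.genome import Chromosome, random_chromosome
from animats.network import ARCH_SHALLOW
from animats.sequences import PatternString


def _deme(fitnesses, arch=ARCH_SHALLOW, seed=0):
    rng = np.random.default_rng(seed)
    members = [random_chromosome(arch, rng) for _ in fitnesses]
    return Deme(
        members=members,
        fitnesses=np.asarray(fitnesses, dtype=np.int64),
        average_responses=np.zeros(len(fitnesses)),
    )


def _tiny_scenario(**overrides):
    defaults = dict(
        pattern=PatternString.from_string("101"),
        architecture=ARCH_SHALLOW,
        sequence_length=60,
        evolution=EvolutionConfig(
            generations=6, n_demes=3, deme_size=6, migration_interval=3
        ),
        scenario_seed=42,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


class TestTournament:
    def test_higher_fitness_wins(self, rng):
        deme = _deme([2000, 1500])
        for _ in range(20):
            assert tournament_select(deme, rng) is deme.members[0]

    def test_requires_evaluation(self, rng):
        deme = Deme(members=[random_chromosome(ARCH_SHALLOW, 0)] * 4)
        with pytest.raises(RuntimeError):
            tournament_select(deme, rng)

    def test_equal_fitness_uniform(self, rng):
        deme = _deme([7, 7, 7, 7])
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            winner = tournament_select(deme, rng)
            idx = next(i for i, m in enumerate(deme.members) if m is winner)
            counts[idx] += 1
        # chi-square sanity bound: each ~n/4
        chi2 = np.sum((counts - n / 4) ** 2 / (n / 4))
        assert chi2 < 16.3  # 99.9% quantile, 3 dof

    def test_best_of_20_selected_one_in_ten(self, rng):
        # best member appears in 19 of the C(20,2)=190 unordered pairs -> 1/10
        deme = _deme(list(range(20)))
        n = 20_000
        hits = sum(
            tournament_select(deme, rng) is deme.members[19] for _ in range(n)
        )
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(hits / n - 0.1) < 4 * se


class TestCrossover:
    def test_identical_parents_identity(self, rng):
        p = random_chromosome(ARCH_SHALLOW, 1)
        child = crossover(p, p, rng)
        assert np.array_equal(child.genes, p.genes)

    def test_every_gene_from_a_parent(self, rng):
        a = random_chromosome(ARCH_SHALLOW, 1)
        b = random_chromosome(ARCH_SHALLOW, 2)
        for _ in range(50):
            child = crossover(a, b, rng)
            assert np.all((child.genes == a.genes) | (child.genes == b.genes))

    def test_parent_share_is_half(self, rng):
        a = Chromosome(genes=np.zeros(21), architecture=ARCH_SHALLOW)
        b = Chromosome(genes=np.ones(21) * 0.5, architecture=ARCH_SHALLOW)
        total, from_a = 0, 0
        for _ in range(500):
            child = crossover(a, b, rng)
            from_a += int(np.sum(child.genes == 0.0))
            total += 21
        se = np.sqrt(0.25 / total)
        assert abs(from_a / total - 0.5) < 4 * se

    def test_mismatched_lengths_raise(self, rng):
        from animats.network import ARCH_DEEP

        with pytest.raises(ValueError):
            crossover(
                random_chromosome(ARCH_SHALLOW, 0),
                random_chromosome(ARCH_DEEP, 0),
                rng,
            )


class TestMutate:
    def test_zero_probability_is_identity(self, rng):
        cfg = EvolutionConfig(mutation_prob=0.0)
        c = random_chromosome(ARCH_SHALLOW, 3)
        assert np.array_equal(mutate(c, cfg, rng).genes, c.genes)

    def test_clipping_at_lower_bound(self):
        # gene -0.98 plus perturbation -0.05 clips to exactly -1.0
        cfg = EvolutionConfig(mutation_prob=1.0, mutation_low=-0.05, mutation_high=-0.05)
        genes = np.full(21, -0.98)
        c = Chromosome(genes=genes, architecture=ARCH_SHALLOW)
        out = mutate(c, cfg, np.random.default_rng(0))
        assert np.all(out.genes == -1.0)

    def test_upper_bound_is_open(self):
        cfg = EvolutionConfig(mutation_prob=1.0, mutation_low=0.1, mutation_high=0.1)
        c = Chromosome(genes=np.full(21, 0.99), architecture=ARCH_SHALLOW)
        out = mutate(c, cfg, np.random.default_rng(0))
        assert np.all(out.genes < 1.0)
        assert np.all(out.genes >= 0.99)

    def test_mutated_fraction_matches_probability(self, rng):
        cfg = EvolutionConfig(mutation_prob=0.05)
        total, changed = 0, 0
        for s in range(300):
            c = random_chromosome(ARCH_SHALLOW, s)
            out = mutate(c, cfg, rng)
            changed += int(np.sum(out.genes != c.genes))
            total += 21
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(changed / total - 0.05) < 4 * se

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31))
    def test_genes_stay_in_interval(self, seed):
        rng = np.random.default_rng(seed)
        cfg = EvolutionConfig(mutation_prob=0.5)
        c = random_chromosome(ARCH_SHALLOW, rng)
        for _ in range(20):
            c = mutate(c, cfg, rng)
            assert np.all(c.genes >= -1.0) and np.all(c.genes < 1.0)


class TestNextGeneration:
    def test_size_conserved(self, rng):
        deme = _deme(list(range(20)))
        child = next_generation(deme, EvolutionConfig(), rng)
        assert child.size == 20
        assert not child.evaluated

    def test_monomorphic_deme_without_mutation_is_closed(self, rng):
        c = random_chromosome(ARCH_SHALLOW, 9)
        deme = Deme(
            members=[c] * 10,
            fitnesses=np.full(10, 5, dtype=np.int64),
        )
        out = next_generation(deme, EvolutionConfig(mutation_prob=0.0), rng)
        for child in out.members:
            assert np.array_equal(child.genes, c.genes)

    def test_children_in_gene_interval(self, rng):
        deme = _deme(list(range(20)))
        out = next_generation(deme, EvolutionConfig(), rng)
        for child in out.members:
            assert np.all(child.genes >= -1.0) and np.all(child.genes < 1.0)


class TestMigrate:
    def test_sizes_conserved(self, rng):
        demes = [_deme(list(range(20)), seed=s) for s in range(5)]
        meta = Metapopulation(demes=demes)
        migrate(meta, rng)
        assert [d.size for d in meta.demes] == [20] * 5

    def test_single_deme_noop(self, rng):
        deme = _deme([1, 2, 3])
        genes_before = [c.genes.copy() for c in deme.members]
        migrate(Metapopulation(demes=[deme]), rng)
        for before, after in zip(genes_before, deme.members):
            assert np.array_equal(before, after.genes)

    def test_global_best_never_lost(self, rng):
        for trial in range(30):
            demes = [_deme(list(range(s, s + 8)), seed=s) for s in range(4)]
            meta = Metapopulation(demes=demes)
            best_before = max(int(d.fitnesses.max()) for d in meta.demes)
            migrate(meta, np.random.default_rng(trial))
            best_after = max(int(d.fitnesses.max()) for d in meta.demes)
            assert best_after == best_before

    def test_champions_duplicated_not_removed(self, rng):
        demes = [_deme([10 + s, 1, 2], seed=s) for s in range(3)]
        champions = [d.members[0] for d in demes]
        meta = Metapopulation(demes=demes)
        migrate(meta, rng)
        for champ in champions:
            count = sum(
                any(m is champ for m in d.members) for d in meta.demes
            )
            assert count >= 1  # source keeps its champion


class TestEvolve:
    def test_determinism_bit_identical(self):
        scenario = _tiny_scenario()
        a = evolve(scenario)
        b = evolve(scenario)
        pd.testing.assert_frame_equal(a.log, b.log)
        assert np.array_equal(
            a.metapopulation.all_genes(), b.metapopulation.all_genes()
        )

    def test_population_conserved_every_generation(self):
        out = evolve(_tiny_scenario())
        counts = out.log.groupby("generation")["deme"].count()
        assert (counts == 3).all()
        assert out.metapopulation.total_size == 18

    def test_fitness_bounds(self):
        out = evolve(_tiny_scenario())
        assert (out.log["best_fitness"] >= 0).all()
        assert (out.log["best_fitness"] <= 60).all()

    def test_gene_interval_after_evolution(self):
        out = evolve(_tiny_scenario())
        genes = out.metapopulation.all_genes()
        assert np.all(genes >= -1.0) and np.all(genes < 1.0)

    def test_generation_zero_near_chance(self):
        # random genomes: average response biased toward 1 (threshold at 0),
        # so mean fitness lies between the 1/2 and 2/3 reference levels
        out = evolve(_tiny_scenario(evolution=EvolutionConfig(
            generations=1, n_demes=5, deme_size=20)))
        gen0 = out.log[out.log["generation"] == 0]
        assert 0.3 * 60 < gen0["mean_fitness"].mean() < 0.9 * 60

    def test_early_stop(self):
        scenario = _tiny_scenario(
            evolution=EvolutionConfig(
                generations=50,
                n_demes=3,
                deme_size=6,
                migration_interval=10,
                early_stop_fitness=1,  # trivially reached
            )
        )
        out = evolve(scenario)
        assert out.stopped_early
        assert out.metapopulation.generation < 50

    def test_selection_improves_over_random(self):
        # best fitness in late generations should not fall below gen-0 best
        # on a learnable scenario (monotone trend over a few seeds)
        improvements = []
        for seed in range(3):
            out = evolve(
                _tiny_scenario(
                    scenario_seed=seed,
                    evolution=EvolutionConfig(
                        generations=30, n_demes=3, deme_size=10, migration_interval=10
                    ),
                )
            )
            per_gen = out.log.groupby("generation")["best_fitness"].max()
            improvements.append(per_gen.iloc[-5:].mean() - per_gen.iloc[0])
        assert np.mean(improvements) >= 0


class TestCheckpointing:
    def test_resume_reproduces_uninterrupted_run(self, tmp_path):
        scenario = _tiny_scenario(
            evolution=EvolutionConfig(
                generations=9, n_demes=3, deme_size=6, migration_interval=3
            )
        )
        full = evolve(scenario)

        ckpt = tmp_path / "ckpt.json"
        evolve(
            ScenarioConfig(
                pattern=scenario.pattern,
                architecture=scenario.architecture,
                sequence_length=scenario.sequence_length,
                evolution=EvolutionConfig(
                    generations=6, n_demes=3, deme_size=6, migration_interval=3
                ),
                scenario_seed=scenario.scenario_seed,
            ),
            checkpoint_path=ckpt,
            checkpoint_interval=6,
        )
        resumed = evolve(scenario, resume_from=ckpt)
        pd.testing.assert_frame_equal(full.log, resumed.log)
        assert np.array_equal(
            full.metapopulation.all_genes(), resumed.metapopulation.all_genes()
        )

    def test_checkpoint_roundtrip(self, tmp_path):
        demes = [_deme([3, 1, 2], seed=s) for s in range(2)]
        meta = Metapopulation(demes=demes, generation=7)
        rngs = scenario_rngs(5)
        rngs["ga"].random(10)  # advance a stream
        path = tmp_path / "state.json"
        save_checkpoint(path, meta, rngs, rows=[{"generation": 0}])
        loaded, loaded_rngs, rows = load_checkpoint(path, ARCH_SHALLOW)
        assert loaded.generation == 7
        assert np.array_equal(loaded.all_genes(), meta.all_genes())
        assert loaded_rngs["ga"].random() == rngs["ga"].random()
        assert rows == [{"generation": 0}]


class TestConfigValidation:
    def test_bad_mutation_prob(self):
        with pytest.raises(ValueError):
            EvolutionConfig(mutation_prob=1.5)

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            EvolutionConfig(mutation_low=0.2, mutation_high=-0.2)

    def test_sequence_must_be_multiple_of_pattern(self):
        with pytest.raises(ValueError):
            ScenarioConfig(
                pattern=PatternString.from_string("101"),
                architecture=ARCH_SHALLOW,
                sequence_length=100,
            )
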