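# animats

Agent-based evolutionary simulator for the emergence of probability
matching and perseveration in a repeated binary prediction task.

Populations of *animats* — small plastic feedforward perceptron networks
whose synaptic weights, biases, and per-synapse Hebbian learning
parameters are all heritable genes in `[-1, 1)` — evolve under an
island-model genetic algorithm to predict the next element of a binary
sequence built by repeating a short pattern (one third zeros, two thirds
ones, total length 2916).  Final-generation animats are then probed with
a frequency-preserving random shuffle of their sequence:

* high-capacity agents (two hidden layers of 4) that learned a short
  pattern keep matching the digit frequencies and score near the 5/9
  probability-matching level on the shuffled probe;
* low-capacity agents (one hidden layer of 4) facing long patterns
  perseverate on the majority digit in both tasks, scoring ~2/3.

## Package layout

| module | contents |
| --- | --- |
| `animats.sequences` | pattern strings, periodic/shuffled task sequences |
| `animats.network` | plastic perceptron nets: forward pass, feedback encoding, Hebbian update |
| `animats.genome` | flat chromosome layout, decode/encode, serialization |
| `animats.evolution` | island-model GA: tournament, crossover, mutation, migration, checkpointing |
| `animats.tasks` | scalar task runner with full traces + vectorised population evaluator, metrics |
| `animats.analytics` | closed-form strategy accuracies/gaps, mean ± SE aggregation |
| `animats.experiment` | scenario grid planning, orchestration, persistence |
| `animats.cli` | `animats` command-line entry point |

## CLI

```bash
# one scenario: length-3 pattern, deep architecture
animats simulate --pattern 101 --arch 4x4 --generations 1000 --seed 1 --out-dir runs

# the canonical 144-scenario grid (or a subset)
animats experiment --seed 1 --preset quick --lengths 3,729 --limit 4 --out-dir runs

# aggregate per-animat metrics into mean ± SE per condition
animats analyze runs/*_metrics.csv --out summary.csv

# analytic accuracy curves for the three strategies
animats baseline --p 0.6667 --p 0.75
```

Presets: `canonical` (1000 generations, 12 replicates), `quick`
(200 generations, 3 replicates), `smoke` (tiny sanity run).

## Reproducibility

Every source of randomness flows from explicit seeds through named
`numpy` `SeedSequence` streams (init / ga / migration / shuffle), so
scenario replays are bit-identical.  `evolve` can checkpoint population,
fitness, log, and RNG states to JSON and resume to the same final state.
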