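"""Flat real-valued genomes and their decode/encode maps.

Gene layout (frozen; any fixed bijection would do, but freezing one
keeps runs reproducible): first all synaptic weights, layer by layer
from input to output, each layer row-major (post-node major); then all
biases, layer by layer; then the per-synapse learning parameters in
exactly the weight order.  Every gene lives in [-1, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Architecture, NetworkState

__all__ = [
    "GENE_LOW",
    "GENE_HIGH",
    "Chromosome",
    "random_chromosome",
    "decode",
    "encode",
    "split_genes",
    "chromosomes_to_csv",
    "chromosomes_from_csv",
    "chromosome_to_json",
    "chromosome_from_json",
]

GENE_LOW = -1.0
GENE_HIGH = 1.0  # exclusive


@dataclass(frozen=True, eq=False)
class Chromosome:
    """An immutable genome: gene vector plus the architecture it encodes."""

    genes: np.ndarray
    architecture: Architecture

    def __post_init__(self) -> None:
        genes = np.ascontiguousarray(self.genes, dtype=float)
        if genes.ndim != 1:
            raise ValueError("genes must be a 1-D vector")
        if genes.size != self.architecture.n_genes:
            raise ValueError(
                f"architecture {self.architecture} needs "
                f"{self.architecture.n_genes} genes, got {genes.size}"
            )
        genes.setflags(write=False)
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return int(self.genes.size)


def random_chromosome(
    architecture: Architecture,
    rng: int | np.random.Generator | np.random.SeedSequence,
) -> Chromosome:
    """Genes i.i.d. uniform on [-1, 1)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    genes = rng.uniform(GENE_LOW, GENE_HIGH, architecture.n_genes)
    return Chromosome(genes=genes, architecture=architecture)


def split_genes(
    chromosome: Chromosome,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Slice the flat gene vector into (weights, biases, learning rates)."""
    arch = chromosome.architecture
    genes = chromosome.genes
    shapes = arch.weight_shapes
    ns = arch.n_synapses

    def take_weights(offset: int) -> list[np.ndarray]:
        mats, pos = [], offset
        for o, i in shapes:
            mats.append(genes[pos : pos + o * i].reshape(o, i).copy())
            pos += o * i
        return mats

    weights = take_weights(0)
    biases, pos = [], ns
    for o, _ in shapes:
        biases.append(genes[pos : pos + o].copy())
        pos += o
    etas = take_weights(ns + arch.n_biases)
    return weights, biases, etas


def decode(chromosome: Chromosome) -> NetworkState:
    """Build the phenotype network encoded by a chromosome."""
    weights, biases, etas = split_genes(chromosome)
    return NetworkState(chromosome.architecture, weights, biases, etas)


def encode(state: NetworkState) -> Chromosome:
    """Inverse of :func:`decode`, reading the *genotypic* weights."""
    parts = [w.ravel() for w in state._genotype_weights]
    parts += [b for b in state.biases]
    parts += [e.ravel() for e in state.learning_rates]
    return Chromosome(genes=np.concatenate(parts), architecture=state.architecture)


# ---------------------------------------------------------------------------
# serialization

def chromosomes_to_csv(chromosomes, path) -> None:
    """One genome per row; requires a homogeneous architecture."""
    archs = {c.architecture for c in chromosomes}
    if len(archs) != 1:
        raise ValueError("all chromosomes must share one architecture")
    matrix = np.stack([c.genes for c in chromosomes])
    frame = pd.DataFrame(matrix, columns=[f"g{i}" for i in range(matrix.shape[1])])
    frame.insert(0, "architecture", str(next(iter(archs))))
    frame.to_csv(path, index=False)


def chromosomes_from_csv(path) -> list[Chromosome]:
    frame = pd.read_csv(path)
    arch = Architecture.from_spec(str(frame["architecture"].iloc[0]))
    genes = frame.drop(columns="architecture").to_numpy(dtype=float)
    return [Chromosome(genes=row, architecture=arch) for row in genes]


def chromosome_to_json(chromosome: Chromosome) -> str:
    return json.dumps(
        {
            "architecture": str(chromosome.architecture),
            "genes": chromosome.genes.tolist(),
        }
    )


def chromosome_from_json(text: str) -> Chromosome:
    payload = json.loads(text)
    return Chromosome(
        genes=np.asarray(payload["genes"], dtype=float),
        architecture=Architecture.from_spec(payload["architecture"]),
    )
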