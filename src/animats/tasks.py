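"""Run prediction tasks for animats and score them.

Two evaluation routes exist on purpose:

* :func:`run_task` — the readable scalar path built on
  :class:`~animats.network.NetworkState`; records a full trace.
* :func:`run_population` — a vectorised whole-population kernel used
  inside the genetic algorithm (JIT-compiled when numba is available).

Both follow the same per-trial protocol: deliver feedback about the
previous trial, forward pass, threshold the output, score against the
next sequence element, then apply one Hebbian step.  The first trial
receives neutral (0) feedback and still counts toward fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Chromosome, decode, split_genes
from .network import (
    FEEDBACK_CORRECT,
    FEEDBACK_NONE,
    FEEDBACK_WRONG,
    GAIN,
    WEIGHT_BOUND,
    Architecture,
)
from .sequences import TaskSequence

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = [
    "TaskResult",
    "run_task",
    "run_population",
    "classify_strategy",
    "trace_to_csv",
    "trace_from_csv",
]

_TASK_KIND_BY_SEQUENCE = {"periodic": "pattern_matching", "shuffled": "random_sequence"}


@dataclass(frozen=True, eq=False)
class TaskResult:
    """Outcome of one animat lifetime on one sequence."""

    predictions: np.ndarray
    targets: np.ndarray
    feedbacks: np.ndarray
    outputs: np.ndarray
    task_kind: str

    def __post_init__(self) -> None:
        n = len(self.targets)
        for name in ("predictions", "targets", "feedbacks", "outputs"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        object.__setattr__(
            self, "predictions", np.asarray(self.predictions, dtype=np.int8)
        )
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=np.int8))

    @classmethod
    def from_predictions(
        cls,
        predictions,
        targets,
        *,
        task_kind: str = "pattern_matching",
        feedbacks=None,
        outputs=None,
    ) -> "TaskResult":
        """Score an externally produced prediction stream (stub agents)."""
        predictions = np.asarray(predictions, dtype=np.int8)
        targets = np.asarray(targets, dtype=np.int8)
        if feedbacks is None:
            correct = predictions == targets
            feedbacks = np.empty(len(targets))
            feedbacks[0] = FEEDBACK_NONE
            feedbacks[1:] = np.where(correct[:-1], FEEDBACK_CORRECT, FEEDBACK_WRONG)
        if outputs is None:
            outputs = np.where(predictions == 1, 1.0, -1.0)
        return cls(predictions, targets, feedbacks, outputs, task_kind)

    @property
    def n_trials(self) -> int:
        return int(len(self.targets))

    @property
    def fitness(self) -> int:
        """Number of correct predictions."""
        return int((self.predictions == self.targets).sum())

    @property
    def accuracy(self) -> float:
        return self.fitness / self.n_trials

    @property
    def average_response(self) -> float:
        """Fraction of trials on which the animat predicted 1."""
        return float(self.predictions.mean())


def run_task(
    chromosome: Chromosome,
    sequence: TaskSequence,
    *,
    task_kind: str | None = None,
) -> TaskResult:
    """Run one animat, freshly decoded from its genome, over a sequence."""
    if task_kind is None:
        task_kind = _TASK_KIND_BY_SEQUENCE[sequence.kind]
    state = decode(chromosome)
    state.reset_to_genotype()
    targets = sequence.elements
    n = len(targets)
    predictions = np.empty(n, dtype=np.int8)
    feedbacks = np.empty(n)
    outputs = np.empty(n)
    previous_correct: bool | None = None
    for t in range(n):
        fb = (
            FEEDBACK_NONE
            if previous_correct is None
            else (FEEDBACK_CORRECT if previous_correct else FEEDBACK_WRONG)
        )
        prediction, value = state.forward(fb)
        state.hebbian_update()
        predictions[t] = prediction
        feedbacks[t] = fb
        outputs[t] = value
        previous_correct = prediction == targets[t]
    return TaskResult(predictions, targets, feedbacks, outputs, task_kind)


# ---------------------------------------------------------------------------
# vectorised population evaluation

def _pack_population(genes: np.ndarray, architecture: Architecture):
    """Pack per-layer parameters into padded arrays for the kernel.

    Returns ``(W, B, E, sizes)`` with ``W``/``E`` shaped
    ``(pop, n_layers, nmax, nmax)`` (layer slot 0 unused) and ``B``
    shaped ``(pop, n_layers, nmax)``.
    """
    sizes = np.asarray(architecture.layer_sizes, dtype=np.int64)
    n_layers = len(sizes)
    nmax = int(sizes.max())
    pop = genes.shape[0]
    W = np.zeros((pop, n_layers, nmax, nmax))
    B = np.zeros((pop, n_layers, nmax))
    E = np.zeros((pop, n_layers, nmax, nmax))
    for p in range(pop):
        weights, biases, etas = split_genes(
            Chromosome(genes=genes[p], architecture=architecture)
        )
        for l in range(1, n_layers):
            o, i = weights[l - 1].shape
            W[p, l, :o, :i] = weights[l - 1]
            B[p, l, :o] = biases[l - 1]
            E[p, l, :o, :i] = etas[l - 1]
    return W, B, E, sizes


@njit(cache=False)
def _simulate_kernel(W, B, E, sizes, targets, gain, wbound, predictions):
    pop = W.shape[0]
    n_layers = sizes.shape[0]
    nmax = W.shape[2]
    n = targets.shape[0]
    fitness = np.zeros(pop, dtype=np.int64)
    for p in range(pop):
        w = W[p].copy()  # lifetime weights, genotype untouched
        y = np.zeros((n_layers, nmax))
        feedback = 0.0
        for t in range(n):
            y[0, 0] = feedback
            for l in range(1, n_layers):
                nin = sizes[l - 1]
                nout = sizes[l]
                for j in range(nout):
                    s = 0.0
                    for i in range(nin):
                        s += w[l, j, i] * y[l - 1, i]
                    y[l, j] = math.tanh(gain * (s + B[p, l, j]))
            pred = 1 if y[n_layers - 1, 0] >= 0.0 else 0
            predictions[p, t] = pred
            correct = pred == targets[t]
            if correct:
                fitness[p] += 1
            for l in range(1, n_layers):
                nin = sizes[l - 1]
                nout = sizes[l]
                for j in range(nout):
                    for i in range(nin):
                        w[l, j, i] += E[p, l, j, i] * y[l, j] * y[l - 1, i]
                        if w[l, j, i] > wbound:
                            w[l, j, i] = wbound
                        elif w[l, j, i] < -wbound:
                            w[l, j, i] = -wbound
            feedback = 5.0 if correct else -5.0
    return fitness


def run_population(
    genes: np.ndarray,
    architecture: Architecture,
    sequence: TaskSequence,
    *,
    return_predictions: bool = False,
):
    """Evaluate a whole population on one sequence.

    Parameters
    ----------
    genes
        ``(pop, n_genes)`` matrix of genomes.
    architecture
        Shared network architecture.
    sequence
        Task sequence; every animat starts from genotypic weights.

    Returns
    -------
    fitness : ``(pop,)`` int array of correct-prediction counts.
    average_response : ``(pop,)`` float array, fraction of 1-responses.
    predictions : ``(pop, n)`` int8 array, only if requested.
    """
    genes = np.ascontiguousarray(genes, dtype=float)
    if genes.ndim != 2 or genes.shape[1] != architecture.n_genes:
        raise ValueError(
            f"genes must be (pop, {architecture.n_genes}), got {genes.shape}"
        )
    W, B, E, sizes = _pack_population(genes, architecture)
    targets = np.asarray(sequence.elements, dtype=np.int64)
    predictions = np.empty((genes.shape[0], len(targets)), dtype=np.int8)
    fitness = _simulate_kernel(
        W, B, E, sizes, targets, GAIN, WEIGHT_BOUND, predictions
    )
    average_response = predictions.mean(axis=1)
    if return_predictions:
        return fitness, average_response, predictions
    return fitness, average_response


# ---------------------------------------------------------------------------
# strategy classification and trace I/O

def classify_strategy(
    result_or_response,
    majority_freq: float = 2.0 / 3.0,
    *,
    perseveration_threshold: float = 0.9,
    matching_band: float = 0.1,
) -> str:
    """Label behaviour from the average response.

    ``perseveration`` when the 1-response rate is at least
    ``perseveration_threshold``; ``probability_matching`` when it is
    within ``matching_band`` of the majority-digit frequency (and below
    the perseveration threshold); ``other`` otherwise.
    """
    if not 0.5 < majority_freq < 1.0:
        raise ValueError("majority frequency must lie in (0.5, 1)")
    r = (
        result_or_response.average_response
        if isinstance(result_or_response, TaskResult)
        else float(result_or_response)
    )
    if r >= perseveration_threshold:
        return "perseveration"
    if abs(r - majority_freq) <= matching_band:
        return "probability_matching"
    return "other"


def trace_to_csv(result: TaskResult, path) -> None:
    frame = pd.DataFrame(
        {
            "t": np.arange(result.n_trials),
            "feedback": result.feedbacks,
            "output_value": result.outputs,
            "prediction": result.predictions,
            "target": result.targets,
            "correct": (result.predictions == result.targets).astype(int),
            "task_kind": result.task_kind,
        }
    )
    frame.to_csv(path, index=False)


def trace_from_csv(path) -> TaskResult:
    frame = pd.read_csv(path).sort_values("t")
    return TaskResult(
        predictions=frame["prediction"].to_numpy(dtype=np.int8),
        targets=frame["target"].to_numpy(dtype=np.int8),
        feedbacks=frame["feedback"].to_numpy(dtype=float),
        outputs=frame["output_value"].to_numpy(dtype=float),
        task_kind=str(frame["task_kind"].iloc[0]),
    )
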