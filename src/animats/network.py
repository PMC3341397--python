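"""Plastic feedforward perceptron networks.

Each animat is a fully connected feedforward net with one raw-valued
input node (the reward-feedback signal), one or two hidden layers, and a
single output node thresholded at zero to produce a binary prediction.
All computing nodes use ``tanh(5x)``.  Synaptic weights change during
life by a Hebbian product rule with a heritable per-synapse learning
parameter; biases and learning parameters are fixed for life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAIN",
    "WEIGHT_BOUND",
    "FEEDBACK_CORRECT",
    "FEEDBACK_WRONG",
    "FEEDBACK_NONE",
    "Architecture",
    "ARCH_SHALLOW",
    "ARCH_DEEP",
    "NetworkState",
    "activation",
    "encode_feedback",
]

#: Slope of the activation function tanh(GAIN * x).
GAIN = 5.0

#: Lifetime weights are kept within [-WEIGHT_BOUND, WEIGHT_BOUND] by the
#: plasticity rule — the same bounded range the genes live in.  Without
#: this, weights drift without limit during life and learned dynamics are
#: so sensitive to crossover/mutation that they are never retained across
#: generations.
WEIGHT_BOUND = 1.0

FEEDBACK_CORRECT = 5.0
FEEDBACK_WRONG = -5.0
FEEDBACK_NONE = 0.0


@dataclass(frozen=True)
class Architecture:
    """Feedforward topology: 1 input node, hidden layers, 1 output node."""

    hidden_layer_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.hidden_layer_sizes)
        if len(sizes) == 0 or any(s < 1 for s in sizes):
            raise ValueError("need at least one hidden layer of positive size")
        object.__setattr__(self, "hidden_layer_sizes", sizes)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (1,) + self.hidden_layer_sizes + (1,)

    @property
    def weight_shapes(self) -> tuple[tuple[int, int], ...]:
        sizes = self.layer_sizes
        return tuple((sizes[l + 1], sizes[l]) for l in range(len(sizes) - 1))

    @property
    def n_synapses(self) -> int:
        return sum(o * i for o, i in self.weight_shapes)

    @property
    def n_biases(self) -> int:
        return sum(self.layer_sizes[1:])

    @property
    def n_genes(self) -> int:
        # weights + biases + one learning parameter per synapse
        return 2 * self.n_synapses + self.n_biases

    @property
    def n_hidden(self) -> int:
        return sum(self.hidden_layer_sizes)

    @classmethod
    def from_spec(cls, spec: str) -> "Architecture":
        """Parse strings like ``"4"`` or ``"4x4"``."""
        try:
            sizes = tuple(int(part) for part in spec.lower().split("x"))
        except ValueError:
            raise ValueError(f"cannot parse architecture spec {spec!r}") from None
        return cls(sizes)

    def __str__(self) -> str:
        return "x".join(str(s) for s in self.hidden_layer_sizes)


#: Canonical low-capacity net: 4 hidden nodes in one layer.
ARCH_SHALLOW = Architecture((4,))
#: Canonical high-capacity net: two layers of 4 hidden nodes.
ARCH_DEEP = Architecture((4, 4))


def activation(x):
    """Node activation ``tanh(5x)``, strictly inside (-1, 1)."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("activation input must be finite")
    out = np.tanh(GAIN * arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def encode_feedback(previous_correct: bool | None) -> float:
    """Reward feedback delivered to the input node.

    +5 after a correct prediction, -5 after a wrong one, 0 on the very
    first trial when there is no previous response.
    """
    if previous_correct is None:
        return FEEDBACK_NONE
    return FEEDBACK_CORRECT if previous_correct else FEEDBACK_WRONG


class NetworkState:
    """Decoded, mutable network for one animat.

    ``weights`` drift during life under the plasticity rule; ``biases``
    and ``learning_rates`` never change after decoding.  The genotypic
    weights are retained so a life can be restarted with
    :meth:`reset_to_genotype`.
    """

    def __init__(
        self,
        architecture: Architecture,
        weights: list[np.ndarray],
        biases: list[np.ndarray],
        learning_rates: list[np.ndarray],
    ) -> None:
        shapes = architecture.weight_shapes
        if len(weights) != len(shapes) or len(learning_rates) != len(shapes):
            raise ValueError("wrong number of weight layers for architecture")
        if len(biases) != len(shapes):
            raise ValueError("wrong number of bias layers for architecture")
        for l, (o, i) in enumerate(shapes):
            if weights[l].shape != (o, i) or learning_rates[l].shape != (o, i):
                raise ValueError(f"layer {l}: expected weight shape {(o, i)}")
            if biases[l].shape != (o,):
                raise ValueError(f"layer {l}: expected bias shape {(o,)}")
        self.architecture = architecture
        self.weights = [np.array(w, dtype=float) for w in weights]
        self.biases = [np.array(b, dtype=float) for b in biases]
        self.learning_rates = [np.array(e, dtype=float) for e in learning_rates]
        self._genotype_weights = [w.copy() for w in self.weights]
        self.last_outputs: list[np.ndarray] | None = None

    # -- dynamics -----------------------------------------------------------

    def forward(self, feedback_input: float) -> tuple[int, float]:
        """One forward pass.

        The input node emits ``feedback_input`` raw (no bias, no
        activation).  Returns ``(prediction, output_value)`` where the
        prediction is 1 iff the output node value is >= 0.  Node outputs
        are stored for the subsequent plasticity step.
        """
        if not math.isfinite(feedback_input):
            raise ValueError("feedback input must be finite")
        y = np.array([float(feedback_input)])
        outputs = [y]
        for W, b in zip(self.weights, self.biases):
            y = activation(W @ y + b)
            outputs.append(y)
        self.last_outputs = outputs
        output_value = float(outputs[-1][0])
        prediction = 1 if output_value >= 0.0 else 0
        return prediction, output_value

    def hebbian_update(self) -> None:
        """One plasticity step using the outputs of the latest forward pass.

        For every synapse i -> j: ``w_ji += eta_ji * y_j * y_i`` with
        both outputs taken from the same time-step, then clipped into
        [-WEIGHT_BOUND, WEIGHT_BOUND].  The input node participates with
        its raw feedback value.  Applied once per time-step; biases and
        learning parameters are untouched.
        """
        if self.last_outputs is None:
            raise RuntimeError("hebbian_update() requires a prior forward() call")
        for l, (W, E) in enumerate(zip(self.weights, self.learning_rates)):
            pre = self.last_outputs[l]
            post = self.last_outputs[l + 1]
            W += E * np.outer(post, pre)
            np.clip(W, -WEIGHT_BOUND, WEIGHT_BOUND, out=W)

    def reset_to_genotype(self, chromosome=None) -> None:
        """Restore genotypic weights and clear activation history.

        With a ``chromosome`` argument, install that genome's values
        instead (it must match the architecture).
        """
        if chromosome is not None:
            from .genome import split_genes

            if chromosome.architecture != self.architecture:
                raise ValueError("chromosome architecture mismatch")
            weights, biases, etas = split_genes(chromosome)
            self._genotype_weights = [w.copy() for w in weights]
            self.biases = [b.copy() for b in biases]
            self.learning_rates = [e.copy() for e in etas]
        self.weights = [w.copy() for w in self._genotype_weights]
        self.last_outputs = None
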