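"""Closed-form strategy accuracies and cross-replicate aggregation.

On a structureless binary stream whose majority symbol occurs with
frequency ``p``:

* pattern decoding predicts every element, accuracy 1;
* perseveration (always choosing the majority symbol) scores ``p``;
* probability matching (responding 1 with frequency ``p``,
  independently of the stream) scores ``p^2 + (1 - p)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "STRATEGIES",
    "StrategyAccuracy",
    "StrategyGaps",
    "expected_accuracy",
    "strategy_accuracy_table",
    "strategy_gaps",
    "matching_gap",
    "optimal_gap_frequency",
    "summarize",
]

STRATEGIES = ("pattern", "max", "pm")


def _check_p(p: float, *, closed_top: bool) -> float:
    p = float(p)
    top_ok = p <= 1.0 if closed_top else p < 1.0
    if not (0.5 < p and top_ok):
        kind = "(0.5, 1]" if closed_top else "(0.5, 1)"
        raise ValueError(f"majority frequency must lie in {kind}, got {p}")
    return p


def expected_accuracy(strategy: str, p: float) -> float:
    """Expected accuracy of a strategy at majority frequency ``p``."""
    p = _check_p(p, closed_top=True)
    if strategy == "pattern":
        return 1.0
    if strategy == "max":
        return p
    if strategy == "pm":
        return p * p + (1.0 - p) * (1.0 - p)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


@dataclass(frozen=True)
class StrategyAccuracy:
    p: float
    acc_pattern: float
    acc_max: float
    acc_pm: float


def strategy_accuracy_table(p: float) -> StrategyAccuracy:
    return StrategyAccuracy(
        p=float(p),
        acc_pattern=expected_accuracy("pattern", p),
        acc_max=expected_accuracy("max", p),
        acc_pm=expected_accuracy("pm", p),
    )


class StrategyGaps(NamedTuple):
    gap_pattern_max: float
    gap_max_pm: float
    ratio: float


def strategy_gaps(p: float) -> StrategyGaps:
    """Accuracy gaps between the three strategies at frequency ``p``.

    ``gap_pattern_max = 1 - p``; ``gap_max_pm = (2p - 1)(1 - p)``;
    ``ratio`` is their quotient.
    """
    p = _check_p(p, closed_top=False)
    gap_pattern_max = expected_accuracy("pattern", p) - expected_accuracy("max", p)
    gap_max_pm = expected_accuracy("max", p) - expected_accuracy("pm", p)
    return StrategyGaps(gap_pattern_max, gap_max_pm, gap_pattern_max / gap_max_pm)


def matching_gap(p):
    """Vectorised ``gap_max_pm``: advantage of perseverating over matching."""
    p = np.asarray(p, dtype=float)
    return (2.0 * p - 1.0) * (1.0 - p)


def optimal_gap_frequency(resolution: int = 200_001) -> float:
    """Majority frequency maximising the perseveration-vs-matching gap.

    Found numerically (coarse grid then bounded scalar optimisation);
    the closed form puts it at 3/4.
    """
    grid = np.linspace(0.5, 1.0, resolution)[1:-1]
    p0 = grid[int(np.argmax(matching_gap(grid)))]
    res = optimize.minimize_scalar(
        lambda p: -matching_gap(p),
        bounds=(max(0.5, p0 - 0.01), min(1.0, p0 + 0.01)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def summarize(results: pd.DataFrame | Iterable[dict]) -> pd.DataFrame:
    """Per-condition mean and standard error of accuracy and response.

    Input rows need the columns ``pattern_length``, ``architecture``,
    ``task``, ``accuracy``, ``average_response``.  The standard error is
    the n-1 sample standard deviation over replicates divided by
    sqrt(n); with a single replicate it is NaN.
    """
    frame = pd.DataFrame(results)
    required = {"pattern_length", "architecture", "task", "accuracy", "average_response"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if frame.empty:
        raise ValueError("no results to summarize")

    def _se(x: pd.Series) -> float:
        if len(x) < 2:
            return float("nan")
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    grouped = frame.groupby(
        ["architecture", "pattern_length", "task"], sort=True, as_index=False
    ).agg(
        n=("accuracy", "size"),
        mean_accuracy=("accuracy", "mean"),
        se_accuracy=("accuracy", _se),
        mean_avg_response=("average_response", "mean"),
        se_avg_response=("average_response", _se),
    )
    return grouped
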