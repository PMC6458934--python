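"""Class target times, time-to-first-spike decoding, and fitness functions.

Classification is read off the output neuron's first firing time: class k of
a K-class problem is assigned the target time 12 + 3k ms, and a pattern is
predicted to belong to the class whose target lies nearest the observed
output spike (ties toward the smaller class id; a silent output neuron is a
rejection, always counted as incorrect).  The simulation ends 2 ms after the
last target.

Two fitness functions are defined over the design subset, both minimised:

* squared error  E_s = sum_p (t_a(p) - t_d(p))^2  between actual and desired
  output spike times (one output neuron);
* accuracy error E_a = 1 - C/T, the misclassification rate.

A genotype whose grammar mapping fails receives a sentinel fitness strictly
worse than any attainable valid value, so the search engines treat invalid
individuals uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .grammar import Grammar, Genotype, WordParseError, map_genotype, parse_word
from .srm import NetworkTopology, SRMParams, simulate_batch

__all__ = [
    "ClassTargets",
    "FitnessRecord",
    "REJECT",
    "SENTINEL_SQUARED",
    "SENTINEL_ACCURACY",
    "class_targets",
    "predict",
    "squared_error",
    "accuracy_error",
    "evaluate_genotype",
    "make_fitness_fn",
]

# Prediction marker for a silent output neuron.
REJECT = -1

# Worst-case fitness for genotypes whose mapping/parsing fails.  Both exceed
# any attainable valid value: E_a <= 1 and E_s is bounded by P * t_end^2 for
# the problem sizes this tool targets.
SENTINEL_SQUARED = 1e9
SENTINEL_ACCURACY = 2.0

FIRST_TARGET_MS = 12.0
TARGET_SPACING_MS = 3.0
END_MARGIN_MS = 2.0


@dataclass(frozen=True)
class ClassTargets:
    """Per-class desired output firing times (ms) and the simulation end."""

    targets: tuple[float, ...]
    t_end: float

    def __post_init__(self) -> None:
        if len(self.targets) < 2:
            raise ValueError("need targets for at least 2 classes")
        if any(b <= a for a, b in zip(self.targets, self.targets[1:])):
            raise ValueError("targets must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.targets)


def class_targets(n_classes: int) -> ClassTargets:
    """Targets {12, 15, 18, ...} ms; simulation ends 2 ms after the last."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    targets = tuple(
        FIRST_TARGET_MS + TARGET_SPACING_MS * k for k in range(n_classes)
    )
    return ClassTargets(targets=targets, t_end=targets[-1] + END_MARGIN_MS)


def predict(output_time: Optional[float], targets: ClassTargets) -> int:
    """Nearest-target class for an output spike; REJECT when silent.

    Ties between two targets resolve toward the smaller class id.
    """
    if output_time is None or (
        isinstance(output_time, float) and math.isnan(output_time)
    ):
        return REJECT
    diffs = [abs(output_time - t) for t in targets.targets]
    return int(np.argmin(diffs))  # argmin takes the first minimum: smaller id


def predict_batch(output_times: np.ndarray, targets: ClassTargets) -> np.ndarray:
    """Vectorised :func:`predict`; nan output times become REJECT."""
    times = np.asarray(output_times, dtype=float)
    tgt = np.asarray(targets.targets)
    diffs = np.abs(times[:, None] - tgt[None, :])
    preds = np.argmin(diffs, axis=1)
    return np.where(np.isnan(times), REJECT, preds)


def squared_error(
    actual: Sequence[float], desired: Sequence[float]
) -> float:
    """E_s = sum_p (t_actual(p) - t_desired(p))^2 over one output neuron."""
    a = np.asarray(actual, dtype=float)
    d = np.asarray(desired, dtype=float)
    if a.shape != d.shape:
        raise ValueError("actual and desired lengths differ")
    return float(np.sum((a - d) ** 2))


def accuracy_error(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """E_a = 1 - C/T; REJECT predictions are never correct."""
    preds = np.asarray(predictions, dtype=int)
    lbls = np.asarray(labels, dtype=int)
    if preds.shape != lbls.shape:
        raise ValueError("predictions and labels lengths differ")
    if preds.size == 0:
        raise ValueError("need at least one prediction")
    correct = int(np.sum((preds == lbls) & (preds != REJECT)))
    return 1.0 - correct / preds.size


@dataclass(frozen=True)
class FitnessRecord:
    """Fitness of one genotype plus evaluation metadata for auditing."""

    value: float
    valid: bool
    word: Optional[str] = None
    output_times: Optional[tuple[float, ...]] = None  # nan = non-firing


def evaluate_genotype(
    genotype: Union[Genotype, Sequence[int], np.ndarray],
    grammar: Grammar,
    spike_matrix: np.ndarray,
    labels: np.ndarray,
    params: SRMParams,
    targets: ClassTargets,
    fitness_kind: str = "accuracy",
    n_inputs: Optional[int] = None,
) -> FitnessRecord:
    """Map, parse and simulate a genotype against an encoded design set.

    ``spike_matrix`` is the (P, n_features) matrix of input spike times.  A
    failed mapping or an unparseable word yields an invalid record carrying
    the sentinel fitness.  For the squared-error fitness, a silent output
    neuron contributes an actual time of ``t_end`` (maximally late), giving a
    finite penalty.  Deterministic and side-effect-free.
    """
    if fitness_kind not in ("squared", "accuracy"):
        raise ValueError(f"unknown fitness kind {fitness_kind!r}")
    spikes = np.asarray(spike_matrix, dtype=float)
    if spikes.ndim != 2 or spikes.shape[0] == 0:
        raise ValueError("encoded design set must be a non-empty 2-D matrix")
    if n_inputs is None:
        n_inputs = spikes.shape[1]
    sentinel = SENTINEL_SQUARED if fitness_kind == "squared" else SENTINEL_ACCURACY

    word = map_genotype(genotype, grammar)
    if word is None:
        return FitnessRecord(value=sentinel, valid=False)
    try:
        topology = parse_word(word, n_inputs)
    except (WordParseError, ValueError):
        return FitnessRecord(value=sentinel, valid=False, word=word)

    output_times, _ = simulate_batch(topology, spikes, params)
    if fitness_kind == "squared":
        desired = np.asarray(targets.targets)[np.asarray(labels, dtype=int)]
        actual = np.where(np.isnan(output_times), targets.t_end, output_times)
        value = squared_error(actual, desired)
    else:
        preds = predict_batch(output_times, targets)
        value = accuracy_error(preds, np.asarray(labels, dtype=int))
    return FitnessRecord(
        value=value,
        valid=True,
        word=word,
        output_times=tuple(float(t) for t in output_times),
    )


def make_fitness_fn(
    grammar: Grammar,
    spike_matrix: np.ndarray,
    labels: np.ndarray,
    params: SRMParams,
    targets: ClassTargets,
    fitness_kind: str = "accuracy",
):
    """Engine-facing closure: fitness_fn(codons) -> float."""
    spikes = np.asarray(spike_matrix, dtype=float)
    lbls = np.asarray(labels, dtype=int)

    def fitness_fn(codons) -> float:
        return evaluate_genotype(
            codons, grammar, spikes, lbls, params, targets, fitness_kind
        ).value

    return fitness_fn
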