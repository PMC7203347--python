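"""Incremental neuron accuracy, neuron-to-class assignment and scoring.

The spiking layer is unsupervised, so class predictions require a linking
step: during a test phase each neuron's fires are tallied against the input
labels, the per-neuron accuracy for class c is 100 * fires_with_label_c /
total_fires, and after the test phase (100 fire events by default) every
neuron is linked to its maximum-accuracy class.  Under neuronal redundancy
several neurons fold into the same predicted class.  Displayed percentages
truncate toward zero (two fires out of three shows 66%), while internal
arithmetic stays in exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TEST_PHASE_FIRES = 100


@dataclass
class NeuronStats:
    """Per-neuron fire counts keyed by input label."""

    n_neurons: int
    counts: dict[int, dict[int, int]] = field(default_factory=dict)

    def update(self, neuron: int, label: int) -> "NeuronStats":
        if not 0 <= neuron < self.n_neurons:
            raise ValueError(f"neuron {neuron} outside 0..{self.n_neurons - 1}")
        per = self.counts.setdefault(int(neuron), {})
        per[int(label)] = per.get(int(label), 0) + 1
        return self

    def total_fires(self, neuron: int) -> int:
        return sum(self.counts.get(int(neuron), {}).values())

    def accuracy_percent(self, neuron: int, label: int) -> int:
        """Truncated integer percentage of this neuron's fires carrying ``label``."""
        total = self.total_fires(neuron)
        if total == 0:
            return 0
        return 100 * self.counts.get(int(neuron), {}).get(int(label), 0) // total


def update_neuron_accuracy(stats: NeuronStats, neuron: int, label: int) -> NeuronStats:
    """Record one fire event; thin functional alias of ``NeuronStats.update``."""
    return stats.update(neuron, label)


@dataclass
class Assignment:
    """Neuron -> class link (many-to-one under redundancy)."""

    mapping: dict[int, int | None]
    unassigned: list[int]

    def predicted_class(self, neuron: int) -> int | None:
        return self.mapping.get(int(neuron))


def assign_neurons(stats: NeuronStats, test_phase_fires: int = TEST_PHASE_FIRES) -> Assignment:
    """Link each neuron to its argmax-accuracy class after the test phase.

    The argmax over the per-neuron accuracy equals the argmax over raw
    counts; ties break toward the lower class label.  A neuron that never
    fired is left unassigned and flagged.  ``test_phase_fires`` documents the
    fire budget the stats were collected under; the link itself uses whatever
    counts are present (the stream may have ended early).
    """
    mapping: dict[int, int | None] = {}
    unassigned: list[int] = []
    for n in range(stats.n_neurons):
        per = stats.counts.get(n, {})
        if not per:
            mapping[n] = None
            unassigned.append(n)
            continue
        best = max(per.items(), key=lambda kv: (kv[1], -kv[0]))
        mapping[n] = best[0]
    return Assignment(mapping, unassigned)


@dataclass
class ConfusionResult:
    matrix: pd.DataFrame  # rows: true labels, cols: predicted classes (+ "unassigned")
    global_accuracy: float | None  # percent over fire events; None if no fires


def score(assignment: Assignment, fire_log) -> ConfusionResult:
    """Confusion matrix and global accuracy over a (neuron, true label) log.

    Each fire event predicts the firing neuron's assigned class; redundancy
    folds multiple neurons into one prediction.  Fires from unassigned
    neurons land in a dedicated ``"unassigned"`` column and count as errors.
    An empty log yields an empty matrix and accuracy ``None``.
    """
    fire_log = list(fire_log)
    if not fire_log:
        return ConfusionResult(pd.DataFrame(), None)
    true_labels = sorted({int(lab) for _, lab in fire_log})
    pred_classes = sorted(
        {c for c in assignment.mapping.values() if c is not None}
    )
    cols: list = list(pred_classes)
    if any(assignment.predicted_class(n) is None for n, _ in fire_log):
        cols = cols + ["unassigned"]
    matrix = pd.DataFrame(0, index=true_labels, columns=cols)
    correct = 0
    for neuron, label in fire_log:
        pred = assignment.predicted_class(neuron)
        col = "unassigned" if pred is None else pred
        matrix.loc[int(label), col] += 1
        if pred == int(label):
            correct += 1
    return ConfusionResult(matrix, 100.0 * correct / len(fire_log))
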