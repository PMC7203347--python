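"""End-to-end pipeline driver and run configuration.

A run wires the three stages together: (train or load the filter bank) ->
calibrate the pattern lookup on an unlabeled stream -> drive the spiking
layer with equalized frames alternating with LFSR noise -> link neurons to
classes during a test phase -> score a held-out stream.  Everything is
seeded from one master seed and replayable byte-for-byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .equalizer import Lut, PatternBank, build_lut, build_pattern_bank, equalize
from .evaluation import (
    Assignment,
    ConfusionResult,
    NeuronStats,
    assign_neurons,
    score,
)
from .filters import train_filter_bank
from .lfsr import Lfsr
from .stdp import WtaNetwork
from .synthetic import (
    default_feature_spec,
    make_synthetic_feature_stream,
    make_synthetic_images,
)


def enumerate_nontrained_configurations(
    n_classes: int = 10, max_size: int = 5
) -> list[tuple[int, ...]]:
    """All non-trained class subsets of sizes 1..max_size (637 for 10/5)."""
    out: list[tuple[int, ...]] = []
    for k in range(1, max_size + 1):
        out.extend(itertools.combinations(range(n_classes), k))
    return out


@dataclass
class ExperimentConfig:
    trained_classes: tuple = (0, 1, 2, 4, 7, 8, 9)
    nontrained_classes: tuple = (3, 5, 6)
    dataset: str = "synthetic-maps"  # "synthetic-maps" | "synthetic-images" | "idx"
    idx_dir: str | None = None
    redundancy: int = 3
    bank_size: int = 16
    seed: int = 0
    calibration_length: int = 2000
    learn_items: int = 1500  # images/maps presented during on-line learning
    assign_fires: int = 100  # test-phase fire budget for neuron linking
    score_items: int = 800
    images_per_class: int = 40  # filter-training set size (image-level runs)
    fallback: str = "none"
    stdp: dict = field(default_factory=dict)

    def __post_init__(self):
        trained, non = set(self.trained_classes), set(self.nontrained_classes)
        if trained & non:
            raise ValueError("trained and non-trained classes overlap")
        if not (trained | non) <= set(range(10)):
            raise ValueError("classes must lie in 0..9")
        if len(non) > 5:
            raise ValueError("at most 5 non-trained classes")
        if self.dataset not in ("synthetic-maps", "synthetic-images", "idx"):
            raise ValueError(f"unknown dataset source {self.dataset!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("trained_classes", "nontrained_classes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["trained_classes"] = list(self.trained_classes)
        d["nontrained_classes"] = list(self.nontrained_classes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    n_lut_lines: int
    n_ff_entries: int
    assignment: Assignment
    confusion: ConfusionResult
    fire_accuracy: float | None  # percent over fire events (scoring phase)
    fire_accuracy_nontrained: float | None
    strict_accuracy: float  # percent over items; no-response counts as error
    strict_accuracy_nontrained: float | None
    no_response_items: int
    windows: np.ndarray  # (n_neurons, n_lut_patterns)

    def to_text(self) -> str:
        lines = [
            f"trained_classes={','.join(map(str, self.config.trained_classes))}",
            f"nontrained_classes={','.join(map(str, self.config.nontrained_classes))}",
            f"dataset={self.config.dataset}",
            f"redundancy={self.config.redundancy}",
            f"seed={self.config.seed}",
            f"n_lut_lines={self.n_lut_lines}",
            f"n_ff_entries={self.n_ff_entries}",
            f"fire_accuracy={_fmt(self.fire_accuracy)}",
            f"fire_accuracy_nontrained={_fmt(self.fire_accuracy_nontrained)}",
            f"strict_accuracy={_fmt(self.strict_accuracy)}",
            f"strict_accuracy_nontrained={_fmt(self.strict_accuracy_nontrained)}",
            f"no_response_items={self.no_response_items}",
        ]
        for n in range(len(self.assignment.mapping)):
            lines.append(f"neuron_{n}_class={self.assignment.mapping.get(n)}")
        return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    return "none" if x is None else f"{x:.4f}"


def _labeled_cycles(net: WtaNetwork, frames, labels, lfsr: Lfsr):
    """Present one pattern frame + one noise frame per item.

    A fire during either frame of an item's cycle is attributed to that
    item.  Items whose frame is ``None`` still get their noise frame (the
    background never pauses).  Returns a list of (label, fired_neuron|None).
    """
    events = []
    for frame, label in zip(frames, labels):
        fired = None
        if frame is not None:
            r = net.run_frame(frame, "pattern")
            fired = r.fired_neuron
        else:
            net._frame_index += 1
        r2 = net.run_frame(lfsr.noise_frame(), "noise")
        if fired is None:
            fired = r2.fired_neuron
        events.append((int(label), fired))
    return events


def _equalize_stream(maps: np.ndarray, lut: Lut, bank: PatternBank):
    return [equalize(m, lut, bank) for m in maps]


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full continual-learning pipeline for one configuration."""
    seed = config.seed
    spec = default_feature_spec(config.trained_classes, config.nontrained_classes,
                                n_bits=config.bank_size)

    if config.dataset == "synthetic-maps":
        def stream(n, sub_seed):
            return make_synthetic_feature_stream(spec, n, seed=seed * 1009 + sub_seed)
    else:
        if config.dataset == "idx":
            from .io import load_idx

            import os

            images = labels = None
            for img_name, lab_name in (
                ("train-images-idx3-ubyte", "train-labels-idx1-ubyte"),
                ("images.idx", "labels.idx"),
            ):
                ip = os.path.join(config.idx_dir or ".", img_name)
                lp = os.path.join(config.idx_dir or ".", lab_name)
                if os.path.exists(ip) and os.path.exists(lp):
                    images, labels = load_idx(ip, lp)
                    break
            if images is None:
                raise FileNotFoundError(
                    f"no IDX image/label pair found in {config.idx_dir!r}"
                )
        else:
            n_img = config.images_per_class * 10 + config.calibration_length + \
                config.learn_items + config.score_items
            images, labels = make_synthetic_images(
                range(10), n_img, seed=seed * 1013 + 7
            )
        train_mask = np.isin(labels, config.trained_classes)
        n_train = config.images_per_class * len(config.trained_classes)
        train_idx = np.flatnonzero(train_mask)[:n_train]
        bank_filters = train_filter_bank(
            images[train_idx], labels[train_idx], config.trained_classes,
            n_total=config.bank_size, seed=seed,
        )
        rest = np.setdiff1d(np.arange(len(images)), train_idx)
        rest_images, rest_labels = images[rest], labels[rest]
        cursor = [0]

        def stream(n, sub_seed):
            lo = cursor[0] % max(1, len(rest_images) - n)
            cursor[0] += n
            sel = slice(lo, lo + n)
            return bank_filters.compute_feature_maps(rest_images[sel]), rest_labels[sel]

    # --- calibration: unlabeled pass builds the lookup table
    calib_maps, _ = stream(config.calibration_length, 1)
    n_lines_wanted = spec.n_class_filters + config.redundancy * len(
        config.nontrained_classes
    )
    pattern_bank = build_pattern_bank(max(n_lines_wanted, 1), seed=seed * 23 + 5)
    lut = build_lut(
        calib_maps,
        spec.n_class_filters,
        expected_new_classes=len(config.nontrained_classes),
        pattern_bank=pattern_bank,
        redundancy=config.redundancy,
        fallback=config.fallback,
    )

    # --- spiking layer: one neuron per LUT line
    net = WtaNetwork(max(lut.n_lines, 1), seed=seed * 41 + 11, **config.stdp)
    lfsr = Lfsr(1 + seed % 15)

    # on-line learning phase
    learn_maps, learn_labels = stream(config.learn_items, 2)
    _labeled_cycles(net, _equalize_stream(learn_maps, lut, pattern_bank),
                    learn_labels, lfsr)

    # linking (test) phase: tally fires against labels until the budget
    stats = NeuronStats(net.n_neurons)
    fires_seen = 0
    chunk = 3
    while fires_seen < config.assign_fires and chunk < 12:
        link_maps, link_labels = stream(config.assign_fires * 2, chunk)
        for label, fired in _labeled_cycles(
            net, _equalize_stream(link_maps, lut, pattern_bank), link_labels, lfsr
        ):
            if fired is not None:
                stats.update(fired, label)
                fires_seen += 1
                if fires_seen >= config.assign_fires:
                    break
        chunk += 1
    assignment = assign_neurons(stats, config.assign_fires)

    # scoring phase
    score_maps, score_labels = stream(config.score_items, 100)
    events = _labeled_cycles(
        net, _equalize_stream(score_maps, lut, pattern_bank), score_labels, lfsr
    )
    fire_log = [(fired, label) for label, fired in events if fired is not None]
    confusion = score(assignment, fire_log)
    nont = set(config.nontrained_classes)
    nt_log = [(n, lab) for n, lab in fire_log if lab in nont]
    fire_acc_nt = score(assignment, nt_log).global_accuracy if nt_log else None

    correct = sum(
        1 for label, fired in events
        if fired is not None and assignment.predicted_class(fired) == label
    )
    strict = 100.0 * correct / len(events)
    nt_events = [(lab, f) for lab, f in events if lab in nont]
    strict_nt = (
        100.0
        * sum(1 for lab, f in nt_events
              if f is not None and assignment.predicted_class(f) == lab)
        / len(nt_events)
        if nt_events
        else None
    )
    no_response = sum(1 for _, fired in events if fired is None)

    lut_patterns = pattern_bank.patterns[lut.pattern_ids()]
    return ExperimentReport(
        config=config,
        n_lut_lines=lut.n_lines,
        n_ff_entries=len(lut.ff_entries),
        assignment=assignment,
        confusion=confusion,
        fire_accuracy=confusion.global_accuracy,
        fire_accuracy_nontrained=fire_acc_nt,
        strict_accuracy=strict,
        strict_accuracy_nontrained=strict_nt,
        no_response_items=no_response,
        windows=net.windows(lut_patterns),
    )
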