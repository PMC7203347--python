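"""Digital STDP winner-take-all layer with counter synapses.

The layer receives 16-bit binary frames — equalized patterns alternating
with single-pixel noise frames — and learns on-line.  Synaptic weights are
8-bit counters (0..255).  Each neuron integrates its synaptic drive across
frames; when an integrator exceeds that neuron's threshold the strongest
neuron fires, all integrators are reset (lateral inhibition), the winner's
threshold is incremented (spike-frequency adaptation) and the winner's
synapses are updated at the falling edge of the current frame: ON synapses
are potentiated by ``delta_ltp``, OFF synapses depressed by ``delta_ltd``,
with saturation at the counter bounds.  Noise frames therefore drive the
gradual depression of background synapses while the repeated pattern drives
potentiation, opening a "synaptic window" between the mean pattern weight
and the mean background weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lfsr import Lfsr

N_INPUTS = 16
W_MIN, W_MAX = 0, 255


@dataclass
class FrameResult:
    """Outcome of one presented frame."""

    frame_index: int
    fired_neuron: int | None
    frame_kind: str  # "pattern" | "noise"
    presented: np.ndarray  # (16,) uint8; all-zero when no frame was shown


@dataclass
class SessionTrace:
    """Per-frame fire log plus periodic weight snapshots."""

    results: list[FrameResult] = field(default_factory=list)
    snapshot_frames: list[int] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)

    def fires(self) -> list[FrameResult]:
        return [r for r in self.results if r.fired_neuron is not None]


def apply_plasticity(
    row: np.ndarray, frame: np.ndarray, delta_ltp: int, delta_ltd: int
) -> np.ndarray:
    """Falling-edge counter update for the firing neuron's synapse row.

    ON synapses gain ``delta_ltp``, OFF synapses lose ``delta_ltd``; the
    result is clipped to the 8-bit counter range.
    """
    row = np.asarray(row, dtype=np.int64)
    frame = np.asarray(frame, dtype=np.int64).ravel()
    updated = row + frame * delta_ltp - (1 - frame) * delta_ltd
    return np.clip(updated, W_MIN, W_MAX)


def synaptic_window(row: np.ndarray, pattern: np.ndarray) -> float:
    """Mean weight over the pattern's ON cells minus mean over its OFF cells.

    The window is the layer's separation measure: a fully specialized neuron
    approaches 255 (ON at ceiling, OFF at floor).
    """
    row = np.asarray(row, dtype=np.float64).ravel()
    pattern = np.asarray(pattern).ravel().astype(bool)
    if pattern.all() or not pattern.any():
        raise ValueError("pattern must have at least one ON and one OFF cell")
    return float(row[pattern].mean() - row[~pattern].mean())


class WtaNetwork:
    """Winner-take-all spiking layer with counter synapses.

    Parameters
    ----------
    n_neurons : int
        Number of output neurons (one per expected lookup-table line, plus
        any redundancy spares).
    delta_ltp, delta_ltd : int
        Counter increments for potentiation / depression (default 16 / 4,
        i.e. depression four times slower, so background decays without
        destabilizing pattern learning).
    w_init : (int, int)
        Inclusive bounds of the uniform integer initial-weight distribution.
    theta0 : int, optional
        Initial fire threshold.  Default: 0.75x the drive of a 4-ON frame at
        the mean initial weight, so that a single pattern presentation can
        trigger a fire from the start.  Winner selection is then determined
        by the match between the current frame and each neuron's weights,
        which is what lets different neurons lock onto different patterns.
    delta_theta : int, optional
        Threshold increment per fire (default 5% of ``theta0``).
    theta_max : int, optional
        Saturation value of the threshold counter (default 960).  The
        threshold is a hardware-style saturating counter: it must stay below
        the drive of a fully potentiated 4-ON pattern (4 x 255 = 1020), or a
        specialized neuron would stop responding to its own pattern within a
        single frame and the competition would degrade into multi-frame
        integration over a mixture of patterns.
    adaptation : {"fire", "window", "off"}
        ``"fire"`` increments the winner's threshold on every fire (the
        digital rule); ``"window"`` only once the winner's synaptic window
        for the firing frame exceeds ``window_ref``; ``"off"`` disables
        adaptation.
    window_ref : float
        Reference window level for the ``"window"`` adaptation variant.
    seed : int
        Seed for the initial weight draw.
    """

    def __init__(
        self,
        n_neurons: int,
        *,
        delta_ltp: int = 16,
        delta_ltd: int = 4,
        w_init: tuple[int, int] = (96, 160),
        theta0: int | None = None,
        delta_theta: int | None = None,
        theta_max: int = 960,
        adaptation: str = "fire",
        window_ref: float = 128.0,
        seed: int = 0,
    ):
        if n_neurons < 1:
            raise ValueError("network needs at least one neuron")
        if adaptation not in ("fire", "window", "off"):
            raise ValueError(f"unknown adaptation mode {adaptation!r}")
        self.n_neurons = int(n_neurons)
        self.delta_ltp = int(delta_ltp)
        self.delta_ltd = int(delta_ltd)
        self.adaptation = adaptation
        self.window_ref = float(window_ref)

        rng = np.random.default_rng(seed)
        lo, hi = w_init
        self.weights = rng.integers(lo, hi + 1, size=(self.n_neurons, N_INPUTS)).astype(
            np.int64
        )
        w_mean = (lo + hi) / 2
        self.theta0 = int(theta0) if theta0 is not None else int(round(0.75 * 4 * w_mean))
        self.delta_theta = (
            int(delta_theta) if delta_theta is not None else max(1, round(0.05 * self.theta0))
        )
        self.theta_max = int(theta_max)
        if self.theta_max < self.theta0:
            raise ValueError("theta_max must be >= theta0")
        self.fire_thresholds = np.full(self.n_neurons, self.theta0, dtype=np.int64)
        self.integrators = np.zeros(self.n_neurons, dtype=np.int64)
        self.fires_count = np.zeros(self.n_neurons, dtype=np.int64)
        self._frame_index = 0

    # ------------------------------------------------------------------ core
    def run_frame(self, frame: np.ndarray, kind: str = "pattern") -> FrameResult:
        """Present one 16-bit frame and apply integration, WTA and plasticity.

        Every integrator accumulates its synaptic drive for the frame; if any
        integrator strictly exceeds its threshold, the neuron with the
        largest integrator fires (ties break to the lowest index), all
        integrators reset to zero, the winner's threshold adapts and its
        synapses update at the frame's falling edge.  At most one neuron
        fires per frame.
        """
        frame = np.asarray(frame, dtype=np.int64).ravel()
        if frame.size != N_INPUTS:
            raise ValueError(f"frame must have {N_INPUTS} bits, got {frame.size}")
        idx = self._frame_index
        self._frame_index += 1

        self.integrators += self.weights @ frame
        fired: int | None = None
        if np.any(self.integrators > self.fire_thresholds):
            crossing = self.integrators > self.fire_thresholds
            masked = np.where(crossing, self.integrators, -1)
            fired = int(np.argmax(masked))  # ties -> lowest index
            self.integrators[:] = 0  # lateral inhibition
            self.fires_count[fired] += 1
            if self.adaptation == "fire":
                self.fire_thresholds[fired] = min(
                    self.fire_thresholds[fired] + self.delta_theta, self.theta_max
                )
            elif self.adaptation == "window":
                if 0 < frame.sum() < N_INPUTS and (
                    synaptic_window(self.weights[fired], frame) >= self.window_ref
                ):
                    self.fire_thresholds[fired] = min(
                        self.fire_thresholds[fired] + self.delta_theta, self.theta_max
                    )
            self.weights[fired] = apply_plasticity(
                self.weights[fired], frame, self.delta_ltp, self.delta_ltd
            )
        return FrameResult(idx, fired, kind, frame.astype(np.uint8))

    def run_session(
        self,
        pattern_stream,
        lfsr: Lfsr,
        n_frames: int | None = None,
        *,
        schedule: str = "alternate",
        input_rate: float = 0.5,
        seed: int = 0,
        snapshot_every: int | None = None,
    ) -> SessionTrace:
        """Drive the layer with alternating pattern and noise frames.

        ``pattern_stream`` yields 16-bit patterns or ``None`` (no frame for
        that slot — the integrators simply hold).  Under the default
        ``"alternate"`` schedule, frames strictly alternate pattern slots and
        LFSR noise frames (50%/50% appearance rates); the ``"bernoulli"``
        schedule draws each frame as a pattern slot with probability
        ``input_rate`` instead.  Fully deterministic given the stream, the
        LFSR state and ``seed``.
        """
        stream = iter(pattern_stream)
        if n_frames is None:
            raise ValueError("n_frames is required")
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if schedule not in ("alternate", "bernoulli"):
            raise ValueError(f"unknown schedule {schedule!r}")
        rng = np.random.default_rng(seed)
        trace = SessionTrace()
        exhausted = False
        for i in range(n_frames):
            if schedule == "alternate":
                is_pattern = i % 2 == 0
            else:
                is_pattern = rng.random() < input_rate
            if is_pattern:
                pattern = None
                if not exhausted:
                    try:
                        pattern = next(stream)
                    except StopIteration:
                        exhausted = True
                if pattern is None:
                    # empty slot: nothing presented, integrators hold
                    trace.results.append(
                        FrameResult(
                            self._frame_index, None, "pattern",
                            np.zeros(N_INPUTS, dtype=np.uint8),
                        )
                    )
                    self._frame_index += 1
                else:
                    trace.results.append(self.run_frame(pattern, "pattern"))
            else:
                trace.results.append(self.run_frame(lfsr.noise_frame(), "noise"))
            if snapshot_every is not None and (i + 1) % snapshot_every == 0:
                trace.snapshot_frames.append(self._frame_index)
                trace.snapshots.append(self.weights.copy())
        return trace

    # ----------------------------------------------------------- inspection
    def windows(self, patterns: np.ndarray) -> np.ndarray:
        """Synaptic window of every neuron for every pattern, (n_neurons, n_patterns)."""
        patterns = np.atleast_2d(np.asarray(patterns))
        return np.array(
            [
                [synaptic_window(self.weights[n], p) for p in patterns]
                for n in range(self.n_neurons)
            ]
        )
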