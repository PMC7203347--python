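"""scikit-learn-style estimators wrapping the three pipeline stages.

``ConvFeatureExtractor`` (images -> 16-bit feature maps), ``PatternEqualizer``
(feature maps -> density-equalized 4x4 frames) and ``StdpWtaClassifier``
(frames -> on-line clustered class labels) follow the fit/transform/predict
protocol and compose with ``sklearn.pipeline.Pipeline``; the library modules
they delegate to remain usable directly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .equalizer import build_lut, build_pattern_bank, equalize
from .evaluation import NeuronStats, assign_neurons
from .filters import P_SIDE, train_filter_bank
from .lfsr import Lfsr
from .stdp import WtaNetwork


def _as_images(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 2 and X.shape[1] == P_SIDE * P_SIDE:
        X = X.reshape(-1, P_SIDE, P_SIDE)
    if X.ndim != 3 or X.shape[1:] != (P_SIDE, P_SIDE):
        raise ValueError(f"X must be (n, {P_SIDE}, {P_SIDE}) or (n, {P_SIDE * P_SIDE})")
    return X


class ConvFeatureExtractor(TransformerMixin, BaseEstimator):
    """Trainable bank of class + feature filters producing binary feature maps.

    ``fit(X, y)`` trains one class filter per class present in ``y`` (or in
    ``trained_classes`` if given) and fills the bank up to ``n_filters``
    with generic feature filters; ``transform(X)`` returns the (n, 16)
    binary feature-map matrix, class-filter bits first.
    """

    def __init__(self, trained_classes=None, n_filters: int = 16,
                 seed: int = 0, cf_epochs: int = 30, ff_epochs: int = 25):
        self.trained_classes = trained_classes
        self.n_filters = n_filters
        self.seed = seed
        self.cf_epochs = cf_epochs
        self.ff_epochs = ff_epochs

    def fit(self, X, y):
        X = _as_images(X)
        y = np.asarray(y)
        classes = (
            sorted(np.unique(y).tolist())
            if self.trained_classes is None
            else sorted(self.trained_classes)
        )
        self.bank_ = train_filter_bank(
            X, y, classes, n_total=self.n_filters, seed=self.seed,
            cf_kwargs={"epochs": self.cf_epochs},
            ff_kwargs={"epochs": self.ff_epochs},
        )
        self.n_class_filters_ = self.bank_.n_class_filters
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "bank_")
        return self.bank_.compute_feature_maps(_as_images(X))


class PatternEqualizer(TransformerMixin, BaseEstimator):
    """Calibrated lookup from feature maps to density-equalized 4x4 frames.

    ``fit(F)`` treats ``F`` as the unlabeled calibration stream: it builds
    the pattern bank and dedicates one pattern per class filter plus one per
    frequent feature-filter combination (``redundancy`` per expected new
    class).  ``transform(F)`` returns (n, 16) uint8 frames; a feature map
    matching no lookup line yields an all-zero row (no frame is presented
    downstream — a legal equalized pattern always has exactly 4 ON cells).
    """

    def __init__(self, n_class_filters: int = 7, expected_new_classes: int = 3,
                 redundancy: int = 3, fallback: str = "none", seed: int = 0):
        self.n_class_filters = n_class_filters
        self.expected_new_classes = expected_new_classes
        self.redundancy = redundancy
        self.fallback = fallback
        self.seed = seed

    def fit(self, F, y=None):
        F = np.asarray(F, dtype=np.uint8)
        n_lines = self.n_class_filters + self.redundancy * self.expected_new_classes
        self.pattern_bank_ = build_pattern_bank(n_lines, seed=self.seed)
        self.lut_ = build_lut(
            F, self.n_class_filters,
            expected_new_classes=self.expected_new_classes,
            pattern_bank=self.pattern_bank_,
            redundancy=self.redundancy, fallback=self.fallback,
        )
        return self

    def transform(self, F) -> np.ndarray:
        check_is_fitted(self, "lut_")
        F = np.asarray(F, dtype=np.uint8)
        out = np.zeros((len(F), 16), dtype=np.uint8)
        for i, fm in enumerate(F):
            pat = equalize(fm, self.lut_, self.pattern_bank_)
            if pat is not None:
                out[i] = pat
        return out


class StdpWtaClassifier(ClassifierMixin, BaseEstimator):
    """On-line STDP winner-take-all clustering with supervised neuron linking.

    ``fit(F, y)`` drives the spiking layer with one pattern frame per row of
    ``F`` (all-zero rows present nothing) alternating with LFSR noise; the
    labels are only used afterwards to link each neuron to its
    argmax-accuracy class over the last ``link_fires`` fire events.
    ``predict(F)`` maps each frame to the class of the neuron with the
    largest synaptic drive (``-1`` for empty frames or unlinked winners).
    """

    def __init__(self, n_neurons: int = 16, link_fires: int = 100, seed: int = 0,
                 **stdp_params):
        self.n_neurons = n_neurons
        self.link_fires = link_fires
        self.seed = seed
        self.stdp_params = stdp_params

    def get_params(self, deep=True):
        params = {"n_neurons": self.n_neurons, "link_fires": self.link_fires,
                  "seed": self.seed}
        params.update(self.stdp_params)
        return params

    def set_params(self, **params):
        for key in ("n_neurons", "link_fires", "seed"):
            if key in params:
                setattr(self, key, params.pop(key))
        self.stdp_params.update(params)
        return self

    def fit(self, F, y):
        F = np.asarray(F, dtype=np.uint8)
        y = np.asarray(y)
        self.net_ = WtaNetwork(self.n_neurons, seed=self.seed, **self.stdp_params)
        lfsr = Lfsr(1 + self.seed % 15)
        fire_events: list[tuple[int, int]] = []  # (neuron, label)
        for frame, label in zip(F, y):
            fired = None
            if frame.any():
                fired = self.net_.run_frame(frame, "pattern").fired_neuron
            r2 = self.net_.run_frame(lfsr.noise_frame(), "noise")
            if fired is None:
                fired = r2.fired_neuron
            if fired is not None:
                fire_events.append((fired, int(label)))
        stats = NeuronStats(self.n_neurons)
        for neuron, label in fire_events[-self.link_fires:]:
            stats.update(neuron, label)
        self.assignment_ = assign_neurons(stats, self.link_fires)
        self.classes_ = np.unique(y)
        return self

    def predict(self, F) -> np.ndarray:
        check_is_fitted(self, "net_")
        F = np.asarray(F, dtype=np.uint8)
        out = np.full(len(F), -1, dtype=np.int64)
        for i, frame in enumerate(F):
            if not frame.any():
                continue
            winner = int(np.argmax(self.net_.weights @ frame.astype(np.int64)))
            cls = self.assignment_.predicted_class(winner)
            out[i] = -1 if cls is None else cls
        return out
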