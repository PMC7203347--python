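"""Synthetic data emulating the study conditions.

Two levels of synthesis are provided:

* **Feature-map level** — class-conditional Bernoulli models of the 16-bit
  binary feature maps.  A trained class almost always raises its own
  class-filter bit; a non-trained class leaves every class-filter bit low
  and is characterized by a small set of high-rate feature-filter bits plus
  one "variant" bit of intermediate rate, so each non-trained class produces
  a dominant feature-filter combination and a couple of rarer variants (the
  structure the redundancy mechanism exists to absorb).  This path feeds the
  equalization and spiking stages directly and runs in milliseconds.

* **Image level** — stroke-composed 28x28 grayscale digit archetypes (line
  segments with endpoint jitter, stroke-intensity variation and slight
  blur), enough for the convolutional trainers to have something real to
  separate, while remaining fully programmatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

N_BITS = 16
DEFAULT_TRAINED = (0, 1, 2, 4, 7, 8, 9)
DEFAULT_NONTRAINED = (3, 5, 6)


@dataclass
class SyntheticSpec:
    """Class-conditional Bernoulli rates over the 16 feature-map bits."""

    classes: list[int]
    rates: np.ndarray  # (n_classes, 16) in [0, 1]
    priors: np.ndarray  # (n_classes,)
    n_class_filters: int
    trained_classes: list[int]
    nontrained_classes: list[int]
    cf_index: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if self.rates.shape != (len(self.classes), N_BITS):
            raise ValueError(f"rates must be (n_classes, {N_BITS})")
        if self.rates.min() < 0 or self.rates.max() > 1:
            raise ValueError("rates must lie in [0, 1]")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


def default_feature_spec(
    trained=DEFAULT_TRAINED,
    nontrained=DEFAULT_NONTRAINED,
    *,
    n_bits: int = N_BITS,
    cf_rate: float = 0.95,
    cf_leak: float = 0.02,
    ff_core_rate: float = 0.92,
    ff_variant_rate: float = 0.35,
    ff_leak: float = 0.03,
) -> SyntheticSpec:
    """The benchmark generator: 7 trained / 3 non-trained classes by default.

    Trained class ``c`` raises its own CF bit at ``cf_rate`` and every other
    CF bit at ``cf_leak``; its FF bits carry a fixed class-specific medium
    profile.  A non-trained class keeps all CF bits at ``cf_leak`` and owns
    two dedicated "core" FF bits at ``ff_core_rate`` plus one "variant" FF
    bit at ``ff_variant_rate``; the dominant combination of each non-trained
    class is therefore distinct from every trained-class signature and from
    the other non-trained classes.
    """
    trained = sorted(trained)
    nontrained = sorted(nontrained)
    if set(trained) & set(nontrained):
        raise ValueError("trained and non-trained classes must be disjoint")
    classes = trained + nontrained
    n_cf = len(trained)
    n_ff = n_bits - n_cf
    if n_ff < 2 * len(nontrained) + 1:
        raise ValueError(
            f"{n_ff} feature-filter bits cannot host distinct cores for "
            f"{len(nontrained)} non-trained classes"
        )
    rates = np.full((len(classes), n_bits), cf_leak)
    cf_index = {c: i for i, c in enumerate(trained)}
    for row, c in enumerate(trained):
        rates[row, cf_index[c]] = cf_rate
        # fixed mild FF profile, deterministic per class id
        prof = np.random.default_rng(1000 + c).uniform(0.1, 0.5, size=n_ff)
        rates[row, n_cf:] = prof
    for j, c in enumerate(nontrained):
        row = n_cf + j
        rates[row, :n_cf] = cf_leak
        rates[row, n_cf:] = ff_leak
        core = [n_cf + (2 * j) % n_ff, n_cf + (2 * j + 1) % n_ff]
        variant = n_cf + (2 * len(nontrained) + j) % n_ff
        rates[row, core] = ff_core_rate
        rates[row, variant] = ff_variant_rate
    priors = np.full(len(classes), 1.0 / len(classes))
    return SyntheticSpec(
        classes=classes,
        rates=rates,
        priors=priors,
        n_class_filters=n_cf,
        trained_classes=trained,
        nontrained_classes=nontrained,
        cf_index=cf_index,
    )


def make_synthetic_feature_stream(
    spec: SyntheticSpec, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` (feature map, label) pairs from the Bernoulli model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(spec.classes), size=n, p=spec.priors)
    maps = (rng.random((n, N_BITS)) < spec.rates[rows]).astype(np.uint8)
    labels = np.asarray(spec.classes)[rows]
    return maps, labels


# --------------------------------------------------------------------------
# Stroke-composed images
# --------------------------------------------------------------------------

# Digit-like archetypes: line segments in a 28x28 frame, ((r0,c0),(r1,c1)).
STROKE_TEMPLATES: dict[int, list[tuple[tuple[float, float], tuple[float, float]]]] = {
    0: [((5, 9), (5, 19)), ((5, 19), (22, 19)), ((22, 19), (22, 9)), ((22, 9), (5, 9))],
    1: [((4, 14), (23, 14)), ((4, 14), (8, 10))],
    2: [((6, 8), (6, 19)), ((6, 19), (14, 19)), ((14, 19), (14, 8)),
        ((14, 8), (22, 8)), ((22, 8), (22, 20))],
    3: [((5, 8), (5, 19)), ((5, 19), (13, 19)), ((13, 19), (13, 10)),
        ((13, 19), (22, 19)), ((22, 19), (22, 8))],
    4: [((4, 8), (14, 8)), ((14, 8), (14, 19)), ((4, 18), (23, 18))],
    5: [((5, 19), (5, 8)), ((5, 8), (13, 8)), ((13, 8), (13, 19)),
        ((13, 19), (22, 19)), ((22, 19), (22, 8))],
    6: [((5, 17), (12, 9)), ((12, 9), (22, 9)), ((22, 9), (22, 18)),
        ((22, 18), (14, 18)), ((14, 18), (14, 10))],
    7: [((5, 7), (5, 20)), ((5, 20), (22, 11))],
    8: [((5, 9), (5, 18)), ((5, 18), (13, 18)), ((13, 18), (13, 9)),
        ((13, 9), (5, 9)), ((13, 9), (22, 9)), ((22, 9), (22, 18)),
        ((22, 18), (13, 18))],
    9: [((5, 9), (5, 18)), ((5, 18), (13, 18)), ((13, 18), (13, 9)),
        ((13, 9), (5, 9)), ((13, 18), (23, 18))],
}


def _draw_segment(img: np.ndarray, p0, p1, width: float, intensity: float):
    (r0, c0), (r1, c1) = p0, p1
    length = max(abs(r1 - r0), abs(c1 - c0), 1.0)
    n_steps = int(length * 3) + 1
    t = np.linspace(0, 1, n_steps)
    rr = r0 + t * (r1 - r0)
    cc = c0 + t * (c1 - c0)
    half = width / 2.0
    for r, c in zip(rr, cc):
        rl, rh = int(np.floor(r - half)), int(np.ceil(r + half))
        cl, ch = int(np.floor(c - half)), int(np.ceil(c + half))
        rl, cl = max(rl, 0), max(cl, 0)
        rh, ch = min(rh, 27), min(ch, 27)
        if rl <= rh and cl <= ch:
            img[rl : rh + 1, cl : ch + 1] = np.maximum(
                img[rl : rh + 1, cl : ch + 1], intensity
            )


def make_synthetic_images(
    classes,
    n: int,
    seed: int = 0,
    *,
    templates: dict | None = None,
    priors=None,
    jitter: float = 1.2,
    width: float = 2.6,
    blur: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n`` stroke-composed labeled 28x28 images.

    Each image renders its class's segment template with Gaussian endpoint
    jitter, a randomly varied stroke intensity, slight blur, and is quantized
    to uint8.  A class whose template is an empty list yields blank images.
    Deterministic for a given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    classes = list(classes)
    templates = STROKE_TEMPLATES if templates is None else templates
    rng = np.random.default_rng(seed)
    priors = (
        np.full(len(classes), 1.0 / len(classes)) if priors is None else np.asarray(priors)
    )
    labels = np.asarray(classes)[rng.choice(len(classes), size=n, p=priors)]
    images = np.zeros((n, 28, 28), dtype=np.uint8)
    for i, lab in enumerate(labels):
        canvas = np.zeros((28, 28), dtype=np.float64)
        intensity = rng.uniform(190, 255)
        for p0, p1 in templates[int(lab)]:
            j = rng.normal(0, jitter, size=4)
            _draw_segment(
                canvas,
                (p0[0] + j[0], p0[1] + j[1]),
                (p1[0] + j[2], p1[1] + j[3]),
                width=width,
                intensity=intensity,
            )
        if blur > 0:
            canvas = gaussian_filter(canvas, sigma=blur)
        images[i] = np.clip(canvas, 0, 255).astype(np.uint8)
    return images, labels
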