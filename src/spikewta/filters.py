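"""Convolutional class/feature filters and binary feature maps.

The supervised front end of the network is a bank of 16 integer 20x20
filters applied to 28x28 grayscale images by valid cross-correlation.  Each
filter's 9x9 response matrix is max-pooled and compared (strictly) against a
per-filter threshold, yielding one bit; the ordered 16-bit vector of all
filter responses is the image's *feature map*.  Class filters (CFs) are each
trained to fire on exactly one class; feature filters (FFs) respond to
generic shape fragments shared across classes, so that classes never seen in
training still produce characteristic FF combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

P_SIDE = 28  # image side
F_SIDE = 20  # filter side
R_SIDE = P_SIDE - F_SIDE + 1  # 9: valid-convolution output side
N_FILTERS_DEFAULT = 16
W_LO, W_HI = -128, 127  # signed 8-bit filter weights


class NonSeparableError(ValueError):
    """Training data does not allow a discriminating filter."""


def validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.shape != (P_SIDE, P_SIDE):
        raise ValueError(f"image must be {P_SIDE}x{P_SIDE}, got {img.shape}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return img.astype(np.int64)


@dataclass
class ConvFilter:
    """A trained 20x20 integer filter with its binarization threshold."""

    weights: np.ndarray  # (20, 20) signed 8-bit range
    kind: str  # "class" | "feature"
    threshold: int
    target_class: int | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.int64)
        if self.weights.shape != (F_SIDE, F_SIDE):
            raise ValueError(f"filter must be {F_SIDE}x{F_SIDE}")
        if self.weights.min() < W_LO or self.weights.max() > W_HI:
            raise ValueError(f"filter weights must lie in [{W_LO}, {W_HI}]")
        if self.kind not in ("class", "feature"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "class" and self.target_class is None:
            raise ValueError("class filter needs a target_class")
        if self.kind == "feature" and self.target_class is not None:
            raise ValueError("feature filter must not carry a target_class")
        self.threshold = int(self.threshold)


def convolve_valid(image: np.ndarray, filt: ConvFilter | np.ndarray) -> np.ndarray:
    """Valid cross-correlation of a 28x28 image with a 20x20 filter.

    Entry (r, c) is the exact integer dot product of the 20x20 image window
    anchored at (r, c) with the filter weights (no kernel flip, matching the
    element-wise bus multiply of the digital design).  Accumulation is 64-bit,
    so the worst case 400 * 255 * 128 cannot overflow.
    """
    img = validate_image(image)
    w = filt.weights if isinstance(filt, ConvFilter) else np.asarray(filt, dtype=np.int64)
    if w.shape != (F_SIDE, F_SIDE):
        raise ValueError(f"filter must be {F_SIDE}x{F_SIDE}, got {w.shape}")
    windows = sliding_window_view(img, (F_SIDE, F_SIDE))  # (9, 9, 20, 20)
    return np.einsum("rcij,ij->rc", windows, w, dtype=np.int64)


def pool_and_binarize(resp: np.ndarray, threshold: int) -> int:
    """Max-pool the response matrix and compare strictly against a threshold.

    Returns 1 iff ``max(resp) > threshold``; a response exactly equal to the
    threshold does not fire.
    """
    return int(np.asarray(resp).max() > threshold)


@dataclass
class FilterBank:
    """Ordered bank of filters, all class filters first."""

    filters: list[ConvFilter]

    def __post_init__(self):
        kinds = [f.kind for f in self.filters]
        n_cf = sum(k == "class" for k in kinds)
        if kinds[:n_cf] != ["class"] * n_cf:
            raise ValueError("class filters must precede feature filters")
        self.n_class_filters = n_cf

    @property
    def n_total(self) -> int:
        return len(self.filters)

    @property
    def trained_classes(self) -> list[int]:
        return [f.target_class for f in self.filters if f.kind == "class"]

    def compute_feature_map(self, image: np.ndarray) -> np.ndarray:
        """The image's 16-bit feature map, CF bits first, bank order."""
        img = validate_image(image)
        windows = sliding_window_view(img, (F_SIDE, F_SIDE))
        bits = np.empty(self.n_total, dtype=np.uint8)
        for i, f in enumerate(self.filters):
            resp = np.einsum("rcij,ij->rc", windows, f.weights, dtype=np.int64)
            bits[i] = pool_and_binarize(resp, f.threshold)
        return bits

    def compute_feature_maps(self, images: np.ndarray) -> np.ndarray:
        """Feature maps for a stack of images, shape (n_images, n_total)."""
        imgs = np.asarray(images, dtype=np.int64)
        if imgs.ndim != 3 or imgs.shape[1:] != (P_SIDE, P_SIDE):
            raise ValueError(f"images must be (n, {P_SIDE}, {P_SIDE})")
        windows = sliding_window_view(imgs, (F_SIDE, F_SIDE), axis=(1, 2))
        w_all = np.stack([f.weights for f in self.filters])
        resp = np.einsum("nrcij,kij->nkrc", windows, w_all, dtype=np.int64)
        peaks = resp.max(axis=(2, 3))
        thr = np.array([f.threshold for f in self.filters], dtype=np.int64)
        return (peaks > thr[None, :]).astype(np.uint8)


def compute_feature_map(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Functional alias of ``FilterBank.compute_feature_map``."""
    return bank.compute_feature_map(image)


# --------------------------------------------------------------------------
# Training.  Filters are trained on float-normalized images by gradient
# descent on the max-pooled response, then quantized to signed 8-bit and
# given an integer threshold calibrated on held-out integer responses.
# --------------------------------------------------------------------------

def _pooled_responses(windows: np.ndarray, w: np.ndarray):
    """Max-pooled response and argmax window per image for a float kernel."""
    resp = np.einsum("nrcij,ij->nrc", windows, w)
    flat = resp.reshape(resp.shape[0], -1)
    arg = flat.argmax(axis=1)
    return flat[np.arange(len(flat)), arg], arg


def _quantize(w: np.ndarray) -> np.ndarray:
    peak = np.abs(w).max()
    if peak == 0:
        return np.zeros_like(w, dtype=np.int64)
    return np.round(w / peak * W_HI).astype(np.int64)


def _youden_threshold(responses: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Integer threshold maximizing sensitivity + specificity - 1 (fire iff r > t)."""
    order = np.argsort(responses)
    r_sorted, y_sorted = responses[order], y[order]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best_j, best_t = -np.inf, int(r_sorted[0]) - 1
    candidates = np.unique(np.concatenate([[r_sorted[0] - 1], r_sorted]))
    for t in candidates:
        fired = responses > t
        tpr = (fired & (y == 1)).sum() / n_pos
        fpr = (fired & (y == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, int(t)
    return best_t, float(best_j)


def train_class_filter(
    train_images: np.ndarray,
    labels: np.ndarray,
    target_class: int,
    *,
    lr: float = 0.5,
    epochs: int = 30,
    val_fraction: float = 0.3,
    seed: int = 0,
    with_diagnostics: bool = False,
):
    """Train one class filter: fire on ``target_class``, stay silent otherwise.

    A single 20x20 kernel is fit by full-batch gradient descent on the
    max-pooled response with a logistic one-vs-rest loss (the gradient flows
    through the argmax window).  The kernel is then quantized to signed 8-bit
    and its integer threshold chosen on a held-out split to maximize
    Youden's J.
    """
    X = np.asarray(train_images, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 3 or X.shape[1:] != (P_SIDE, P_SIDE):
        raise ValueError(f"train_images must be (n, {P_SIDE}, {P_SIDE})")
    y = (labels == target_class).astype(np.float64)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            "class-filter training needs both target and non-target images"
        )
    if np.all(X == X[0]):
        raise NonSeparableError("all training images identical: classes not separable")

    rng = np.random.default_rng(seed)
    n = len(X)
    perm = rng.permutation(n)
    n_val = max(2, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if y[tr_idx].sum() in (0, len(tr_idx)) or y[val_idx].sum() in (0, len(val_idx)):
        # tiny or skewed sets: fall back to training on everything
        tr_idx = val_idx = perm

    Xn = X / 255.0
    windows = sliding_window_view(Xn, (F_SIDE, F_SIDE), axis=(1, 2))
    w = rng.normal(0.0, 0.05, size=(F_SIDE, F_SIDE))
    b = 0.0
    tr_win = windows[tr_idx]
    y_tr = y[tr_idx]
    for _ in range(epochs):
        s, arg = _pooled_responses(tr_win, w)
        p = 1.0 / (1.0 + np.exp(-(s + b)))
        g = p - y_tr  # (n_tr,)
        rows, cols = np.unravel_index(arg, (R_SIDE, R_SIDE))
        grad_w = np.einsum(
            "n,nij->ij", g, tr_win[np.arange(len(tr_win)), rows, cols]
        ) / len(g)
        w -= lr * grad_w
        b -= lr * float(g.mean())

    wq = _quantize(w)
    filt_resp = np.einsum(
        "nrcij,ij->nrc", sliding_window_view(
            X[val_idx].astype(np.int64), (F_SIDE, F_SIDE), axis=(1, 2)
        ), wq, dtype=np.int64,
    ).max(axis=(1, 2))
    threshold, j = _youden_threshold(filt_resp, y[val_idx])
    if j <= 0:
        raise NonSeparableError(
            f"class {target_class}: no threshold separates target from rest (J={j:.2f})"
        )
    filt = ConvFilter(wq, "class", threshold, target_class=target_class)
    if with_diagnostics:
        return filt, {"float_weights": w, "float_bias": b, "val_youden_j": j}
    return filt


def train_feature_filters(
    train_images: np.ndarray,
    labels: np.ndarray,
    n_filters: int,
    *,
    max_filters: int | None = None,
    lr: float = 0.5,
    epochs: int = 25,
    firing_quantile: float = 0.75,
    seed: int = 0,
) -> list[ConvFilter]:
    """Train generic feature filters on the trained-class subset.

    The filters are the first-layer kernels of a small fully-convolutional
    classifier: ``n_filters + 3`` candidate 20x20 kernels feed max-pooled
    responses into a softmax head over the trained classes, trained jointly
    by gradient descent.  The ``n_filters`` kernels with the highest response
    variance are kept, quantized, and thresholded at a fixed response
    quantile (default 0.75, so each fires on roughly a quarter of the
    training images).
    """
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    if max_filters is not None and n_filters > max_filters:
        raise ValueError(
            f"requested {n_filters} feature filters exceeds bank capacity {max_filters}"
        )
    X = np.asarray(train_images, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 3 or X.shape[1:] != (P_SIDE, P_SIDE):
        raise ValueError(f"train_images must be (n, {P_SIDE}, {P_SIDE})")
    if np.all(X == 0):
        raise NonSeparableError("blank training set: no features to extract")

    classes = np.unique(labels)
    class_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_idx[c] for c in labels])
    n, n_c = len(X), len(classes)
    rng = np.random.default_rng(seed)
    K = n_filters + 3

    Xn = X / 255.0
    windows = sliding_window_view(Xn, (F_SIDE, F_SIDE), axis=(1, 2))
    W = rng.normal(0.0, 0.05, size=(K, F_SIDE, F_SIDE))
    A = rng.normal(0.0, 0.1, size=(n_c, K))
    bias = np.zeros(n_c)
    for _ in range(epochs):
        resp = np.einsum("nrcij,kij->nkrc", windows, W)
        flat = resp.reshape(n, K, -1)
        arg = flat.argmax(axis=2)
        s = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]  # (n, K)
        logits = s @ A.T + bias
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        g = p.copy()
        g[np.arange(n), y_idx] -= 1.0
        g /= n
        grad_A = g.T @ s
        grad_s = g @ A  # (n, K)
        rows, cols = np.unravel_index(arg, (R_SIDE, R_SIDE))
        grad_W = np.zeros_like(W)
        for k in range(K):
            grad_W[k] = np.einsum(
                "n,nij->ij", grad_s[:, k], windows[np.arange(n), rows[:, k], cols[:, k]]
            )
        A -= lr * grad_A
        bias -= lr * g.sum(axis=0)
        W -= lr * grad_W

    resp = np.einsum("nrcij,kij->nkrc", windows, W)
    s = resp.reshape(n, K, -1).max(axis=2)
    order = np.argsort(-s.var(axis=0))

    filters: list[ConvFilter] = []
    seen: set[bytes] = set()
    X_int = np.asarray(train_images, dtype=np.int64)
    int_windows = sliding_window_view(X_int, (F_SIDE, F_SIDE), axis=(1, 2))
    for k in order:
        wq = _quantize(W[k])
        key = wq.tobytes()
        if key in seen:
            continue
        r_int = np.einsum("nrcij,ij->nrc", int_windows, wq, dtype=np.int64).max(axis=(1, 2))
        if np.ptp(r_int) == 0:
            continue  # constant response: useless as a feature detector
        threshold = int(np.quantile(r_int, firing_quantile))
        frac = float((r_int > threshold).mean())
        if not 0.02 < frac < 0.98:
            # quantile landed on a tie plateau; nudge to the nearest useful cut
            uniq = np.unique(r_int)
            cuts = [(abs(float((r_int > t).mean()) - (1 - firing_quantile)), int(t))
                    for t in uniq[:-1]]
            if not cuts:
                continue
            threshold = min(cuts)[1]
            frac = float((r_int > threshold).mean())
            if not 0.0 < frac < 1.0:
                continue
        seen.add(key)
        filters.append(ConvFilter(wq, "feature", threshold))
        if len(filters) == n_filters:
            return filters
    raise NonSeparableError(
        f"only {len(filters)} usable feature filters found, {n_filters} requested"
    )


def train_filter_bank(
    train_images: np.ndarray,
    labels: np.ndarray,
    trained_classes,
    *,
    n_total: int = N_FILTERS_DEFAULT,
    seed: int = 0,
    cf_kwargs: dict | None = None,
    ff_kwargs: dict | None = None,
) -> FilterBank:
    """Train the full bank: one class filter per trained class, CFs first,
    and feature filters filling the remaining slots up to ``n_total``."""
    trained_classes = sorted(trained_classes)
    n_ff = n_total - len(trained_classes)
    if n_ff < 0:
        raise ValueError(
            f"{len(trained_classes)} trained classes exceed bank size {n_total}"
        )
    cf_kwargs = dict(cf_kwargs or {})
    ff_kwargs = dict(ff_kwargs or {})
    mask = np.isin(labels, trained_classes)
    X, y = np.asarray(train_images)[mask], np.asarray(labels)[mask]
    cfs = [
        train_class_filter(X, y, c, seed=seed + 17 * i, **cf_kwargs)
        for i, c in enumerate(trained_classes)
    ]
    ffs = (
        train_feature_filters(
            X, y, n_ff, max_filters=n_ff, seed=seed + 1000, **ff_kwargs
        )
        if n_ff
        else []
    )
    return FilterBank(cfs + ffs)
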