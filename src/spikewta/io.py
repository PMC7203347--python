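"""File formats: IDX image/label files and flat-text artifact serialization.

IDX is the big-endian container used by the MNIST family (magic 2051 for
image tensors, 2049 for label vectors).  Filter banks, pattern banks and
lookup tables round-trip through documented flat text formats so a run can
be replayed exactly.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .equalizer import Lut, PatternBank
from .filters import ConvFilter, FilterBank

IDX_IMAGE_MAGIC = 2051
IDX_LABEL_MAGIC = 2049


class IdxFormatError(ValueError):
    """Malformed, truncated or mismatched IDX file."""


def save_idx_images(path, images: np.ndarray) -> None:
    images = np.asarray(images, dtype=np.uint8)
    if images.ndim != 3:
        raise ValueError("images must be (n, rows, cols)")
    n, rows, cols = images.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack(">iiii", IDX_IMAGE_MAGIC, n, rows, cols))
        fh.write(images.tobytes())


def save_idx_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">ii", IDX_LABEL_MAGIC, len(labels)))
        fh.write(labels.tobytes())


def _read_exact(fh, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IdxFormatError(f"truncated IDX file while reading {what}")
    return data


def load_idx_images(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">iiii", _read_exact(fh, 16, "header"))
        if magic != IDX_IMAGE_MAGIC:
            raise IdxFormatError(f"bad image magic {magic}, expected {IDX_IMAGE_MAGIC}")
        data = _read_exact(fh, n * rows * cols, "pixel data")
    return np.frombuffer(data, dtype=np.uint8).reshape(n, rows, cols)


def load_idx_labels(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic, n = struct.unpack(">ii", _read_exact(fh, 8, "header"))
        if magic != IDX_LABEL_MAGIC:
            raise IdxFormatError(f"bad label magic {magic}, expected {IDX_LABEL_MAGIC}")
        data = _read_exact(fh, n, "label data")
    return np.frombuffer(data, dtype=np.uint8).copy()


def load_idx(image_path, label_path) -> tuple[np.ndarray, np.ndarray]:
    """Load an aligned (images, labels) pair, validating counts and labels."""
    images = load_idx_images(image_path)
    labels = load_idx_labels(label_path)
    if len(images) != len(labels):
        raise IdxFormatError(
            f"count mismatch: {len(images)} images vs {len(labels)} labels"
        )
    if labels.size and labels.max() > 9:
        raise IdxFormatError("label values outside 0..9")
    return images, labels


# --------------------------------------------------------------------- banks

def save_filter_bank(path, bank: FilterBank) -> None:
    payload = [
        {
            "kind": f.kind,
            "target_class": f.target_class,
            "threshold": int(f.threshold),
            "weights": [int(v) for v in f.weights.ravel()],
        }
        for f in bank.filters
    ]
    Path(path).write_text(json.dumps(payload))


def load_filter_bank(path) -> FilterBank:
    payload = json.loads(Path(path).read_text())
    filters = [
        ConvFilter(
            np.array(d["weights"], dtype=np.int64).reshape(20, 20),
            d["kind"],
            d["threshold"],
            target_class=d["target_class"],
        )
        for d in payload
    ]
    return FilterBank(filters)


def save_pattern_bank(path, bank: PatternBank) -> None:
    lines = [
        f"{i} {''.join(str(b) for b in p)}" for i, p in enumerate(bank.patterns)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_pattern_bank(path) -> PatternBank:
    patterns = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _, bits = line.split()
        patterns.append([int(b) for b in bits])
    return PatternBank(np.array(patterns, dtype=np.uint8))


def save_lut(path, lut: Lut) -> None:
    lines = [f"# n_class_filters={lut.n_class_filters} fallback={lut.fallback}"]
    lines += [f"CF {i} {pid}" for i, pid in sorted(lut.cf_entries.items())]
    lines += [f"FF {key} {pid}" for key, pid in sorted(lut.ff_entries.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def load_lut(path) -> Lut:
    text = Path(path).read_text().splitlines()
    header = text[0].lstrip("# ").split()
    meta = dict(kv.split("=") for kv in header)
    cf_entries: dict[int, int] = {}
    ff_entries: dict[int, int] = {}
    for line in text[1:]:
        if not line.strip():
            continue
        tag, key, pid = line.split()
        if tag == "CF":
            cf_entries[int(key)] = int(pid)
        else:
            ff_entries[int(key)] = int(pid)
    return Lut(
        int(meta["n_class_filters"]), cf_entries, ff_entries, fallback=meta["fallback"]
    )


def save_weight_trace(path, trace) -> None:
    """Weight snapshots as CSV rows of (frame, neuron, w0..w15)."""
    with open(path, "w") as fh:
        fh.write("frame,neuron," + ",".join(f"w{j}" for j in range(16)) + "\n")
        for frame, snap in zip(trace.snapshot_frames, trace.snapshots):
            for n, row in enumerate(snap):
                fh.write(f"{frame},{n}," + ",".join(str(int(v)) for v in row) + "\n")
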