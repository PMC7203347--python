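"""Density-equalized 4x4 patterns and the feature-map lookup stage.

Binary feature maps produced by the filter bank have class-dependent ON
density, which would bias the integrate-and-fire competition downstream: a
dense map drives every neuron harder than a sparse one.  This stage therefore
re-codes each feature map as a 4x4 binary pattern with a fixed density of
4/16 = 25% ON cells, drawn from a bank in which any two patterns share at
most 2 ON cells.  Class-filter bits take priority: a firing class filter
selects its dedicated pattern outright, and only an all-zero class-filter
prefix lets the feature-filter combination address the lookup table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

PATTERN_CELLS = 16
PATTERN_ON = 4  # 25% density
MAX_OVERLAP = 2


class CapacityError(RuntimeError):
    """Raised when the pattern bank or LUT cannot host the requested entries."""


def enumerate_candidates() -> np.ndarray:
    """All 4x4 binary patterns with exactly 4 ON cells.

    Returns
    -------
    ndarray of shape (1820, 16), dtype uint8
        One row per pattern, row-major cell order, each listed once.
    """
    combos = list(itertools.combinations(range(PATTERN_CELLS), PATTERN_ON))
    out = np.zeros((len(combos), PATTERN_CELLS), dtype=np.uint8)
    for i, cells in enumerate(combos):
        out[i, list(cells)] = 1
    return out


@dataclass
class PatternBank:
    """An ordered set of equalized patterns, pairwise ON-overlap <= 2."""

    patterns: np.ndarray  # (n, 16) uint8

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        if self.patterns.ndim != 2 or self.patterns.shape[1] != PATTERN_CELLS:
            raise ValueError("pattern bank must be (n, 16)")
        if not np.all(self.patterns.sum(axis=1) == PATTERN_ON):
            raise ValueError(f"every pattern must have exactly {PATTERN_ON} ON cells")
        ov = self.overlap_matrix()
        if len(self) > 1 and ov[~np.eye(len(self), dtype=bool)].max() > MAX_OVERLAP:
            raise ValueError(f"pairwise overlap exceeds {MAX_OVERLAP}")
        if len({tuple(p) for p in self.patterns}) != len(self):
            raise ValueError("duplicate patterns in bank")

    def __len__(self) -> int:
        return self.patterns.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.patterns[i]

    def overlap_matrix(self) -> np.ndarray:
        p = self.patterns.astype(np.int64)
        return p @ p.T

    def as_grids(self) -> np.ndarray:
        return self.patterns.reshape(-1, 4, 4)


def build_pattern_bank(n: int, seed: int = 0) -> PatternBank:
    """Select ``n`` equalized patterns with pairwise overlap <= 2.

    A greedy scan over the 1820 candidates in seeded-shuffled order accepts a
    candidate iff it shares at most 2 ON cells with every pattern accepted so
    far.  Deterministic for a given ``seed``.

    Raises
    ------
    CapacityError
        If fewer than ``n`` admissible patterns are found; the message
        reports the largest admissible set size reached.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cand = enumerate_candidates()
    order = np.random.default_rng(seed).permutation(len(cand))
    accepted: list[np.ndarray] = []
    acc = np.empty((0, PATTERN_CELLS), dtype=np.int64)
    for idx in order:
        p = cand[idx]
        if acc.shape[0] == 0 or (acc @ p.astype(np.int64)).max() <= MAX_OVERLAP:
            accepted.append(p)
            acc = np.vstack([acc, p.astype(np.int64)])
            if len(accepted) == n:
                return PatternBank(np.array(accepted, dtype=np.uint8))
    raise CapacityError(
        f"only {len(accepted)} patterns with overlap <= {MAX_OVERLAP} found, "
        f"{n} requested"
    )


@dataclass
class Lut:
    """Feature-map -> pattern lookup with class-filter priority.

    ``cf_entries`` maps a class-filter index to a pattern id; ``ff_entries``
    maps a feature-filter bit combination (encoded as an integer, FF bit 0 =
    least significant) to a pattern id.  The two entry families reference
    disjoint pattern ids.  ``fallback`` is ``"none"`` (unknown combinations
    present no frame) or ``"nearest"`` (map to the stored key at minimum
    Hamming distance, ties to the lowest key).
    """

    n_class_filters: int
    cf_entries: dict[int, int]
    ff_entries: dict[int, int]
    fallback: str = "none"
    # Count of frames on which several class filters fired simultaneously;
    # the lowest-index filter wins but the event is worth surfacing.
    multi_cf_events: int = field(default=0, compare=False)

    def __post_init__(self):
        if self.fallback not in ("none", "nearest"):
            raise ValueError(f"unknown fallback policy {self.fallback!r}")
        cf_ids = set(self.cf_entries.values())
        ff_ids = set(self.ff_entries.values())
        if cf_ids & ff_ids:
            raise ValueError("cf_entries and ff_entries must use disjoint pattern ids")
        if len(cf_ids) != len(self.cf_entries) or len(ff_ids) != len(self.ff_entries):
            raise ValueError("LUT lines must map to distinct pattern ids")

    @property
    def n_lines(self) -> int:
        return len(self.cf_entries) + len(self.ff_entries)

    def pattern_ids(self) -> list[int]:
        return sorted(set(self.cf_entries.values()) | set(self.ff_entries.values()))


def ff_key(ff_bits: np.ndarray) -> int:
    """Encode a feature-filter bit vector as an integer LUT key."""
    ff_bits = np.asarray(ff_bits, dtype=np.int64)
    return int((ff_bits << np.arange(ff_bits.size)).sum())


def build_lut(
    calibration_maps: np.ndarray,
    n_class_filters: int,
    expected_new_classes: int,
    pattern_bank: PatternBank,
    redundancy: int = 3,
    fallback: str = "none",
) -> Lut:
    """Build the lookup table from an unlabeled calibration stream.

    Each class filter receives one dedicated pattern.  Among calibration maps
    whose class-filter prefix is all zero, the ``redundancy *
    expected_new_classes`` most frequent feature-filter combinations each
    receive a dedicated pattern — the appearance rate of a combination is its
    empirical frequency in the stream.  Ranking ties break toward the lower
    encoded key, so the result is deterministic for a given stream.
    """
    maps = np.asarray(calibration_maps, dtype=np.uint8)
    if maps.ndim != 2:
        raise ValueError("calibration_maps must be 2-D (n_maps, n_filters)")
    if redundancy < 1:
        raise ValueError("redundancy must be >= 1")
    n_ff_slots = redundancy * expected_new_classes

    cf_entries = {i: i for i in range(n_class_filters)}

    ff_part = maps[:, n_class_filters:]
    no_cf = maps[:, :n_class_filters].sum(axis=1) == 0
    keys = (ff_part[no_cf].astype(np.int64) << np.arange(ff_part.shape[1])).sum(axis=1)
    uniq, counts = np.unique(keys, return_counts=True)
    # most frequent first; ties resolved toward the lower key
    order = np.lexsort((uniq, -counts))
    top = uniq[order][:n_ff_slots]

    needed = n_class_filters + len(top)
    if needed > len(pattern_bank):
        raise CapacityError(
            f"LUT needs {needed} patterns but the bank holds {len(pattern_bank)}"
        )
    ff_entries = {int(k): n_class_filters + j for j, k in enumerate(top)}
    return Lut(n_class_filters, cf_entries, ff_entries, fallback=fallback)


def equalize(fm: np.ndarray, lut: Lut, bank: PatternBank) -> np.ndarray | None:
    """Map one feature map to its equalized pattern (or ``None``).

    Class filters have priority: if any CF bit is 1 the lowest-index firing
    class filter selects its pattern and the feature-filter bits are ignored.
    Otherwise the FF combination addresses ``lut.ff_entries``; a miss follows
    the fallback policy (default: no frame).
    """
    fm = np.asarray(fm, dtype=np.uint8).ravel()
    cf_bits = fm[: lut.n_class_filters]
    firing = np.flatnonzero(cf_bits)
    if firing.size:
        if firing.size > 1:
            lut.multi_cf_events += 1
        return bank[lut.cf_entries[int(firing[0])]]
    key = ff_key(fm[lut.n_class_filters:])
    if key in lut.ff_entries:
        return bank[lut.ff_entries[key]]
    if lut.fallback == "nearest":
        if not lut.ff_entries:
            return None
        stored = np.array(sorted(lut.ff_entries), dtype=np.int64)
        dist = np.array(
            [bin(int(k) ^ key).count("1") for k in stored], dtype=np.int64
        )
        best = stored[int(np.argmin(dist))]  # argmin ties -> lowest key (sorted)
        return bank[lut.ff_entries[int(best)]]
    return None
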