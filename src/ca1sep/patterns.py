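"""Binary activity patterns and the Hamming metric.

A population's activity within one ~20 ms gamma window is coded as a binary
vector: component *i* is 1 if cell *i* spiked in the window.  Patterns here
carry an *exact* number of active cells (k out of N), not i.i.d. Bernoulli
components — the experiments always drive a fixed count of presynaptic cells.

The module also provides generators for pattern *pairs* with an exactly
controlled Hamming distance, which is how the "similar" (2% of maximal HD)
and "distinct" (chance-level HD) input conditions are constructed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BinaryPattern",
    "PatternPair",
    "hamming",
    "max_hd",
    "random_pattern",
    "pair_with_hd",
    "similar_hd",
    "distinct_hd",
    "write_patterns",
    "read_patterns",
    "write_pair_manifest",
]


@dataclass(frozen=True)
class BinaryPattern:
    """A fixed-length binary vector with an exact count of active cells.

    Parameters
    ----------
    length : int
        Number of cells N (vector dimension), positive.
    active : frozenset of int
        0-based indices of the components equal to one.
    """

    length: int
    active: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"pattern length must be positive, got {self.length}")
        object.__setattr__(self, "active", frozenset(int(i) for i in self.active))
        for i in self.active:
            if not 0 <= i < self.length:
                raise ValueError(f"active index {i} outside [0, {self.length})")

    @property
    def k(self) -> int:
        """Number of active cells."""
        return len(self.active)

    @classmethod
    def from_indices(cls, length: int, indices: Iterable[int]) -> "BinaryPattern":
        return cls(length=length, active=frozenset(int(i) for i in indices))

    def indices(self) -> np.ndarray:
        """Active indices as a sorted int64 array."""
        return np.fromiter(sorted(self.active), dtype=np.int64, count=self.k)

    def to_bool(self) -> np.ndarray:
        """Dense boolean vector of shape (length,)."""
        v = np.zeros(self.length, dtype=bool)
        if self.k:
            v[self.indices()] = True
        return v


def hamming(a: BinaryPattern, b: BinaryPattern) -> int:
    """Hamming distance: the number of components at which two patterns differ.

    Equals the size of the symmetric difference of the active index sets.
    """
    if a.length != b.length:
        raise ValueError(
            f"dimension mismatch: {a.length} vs {b.length}"
        )
    return len(a.active ^ b.active)


def max_hd(length: int, k: int) -> int:
    """Largest achievable HD between two patterns of equal active count k.

    With no overlap the distance is 2k; when k exceeds length/2 the shared
    zeros limit it to 2(length - k).
    """
    if not 0 <= k <= length:
        raise ValueError(f"k={k} outside [0, {length}]")
    return min(2 * k, 2 * (length - k))


def _round_even(x: float) -> int:
    """Round to the nearest even integer, ties upward."""
    return 2 * math.floor(x / 2 + 0.5)


def similar_hd(length: int, k: int, fraction: float = 0.02) -> int:
    """Target HD for a "similar" pair: ``fraction`` of the maximal HD.

    Rounded to the nearest even integer (HD between equal-count patterns is
    necessarily even), ties upward.  The default 2% gives 62 for the CA3-scale
    population (k=1540 of 28009, max HD 3080).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return _round_even(fraction * max_hd(length, k))


def distinct_hd(length: int, k: int) -> int:
    """Target HD for a "distinct" pair: the chance-level (binomial-mean) HD.

    Two independently drawn patterns with per-cell activity p = k/length
    differ in 2p(1-p) of components on average; the mean HD is rounded to the
    nearest even integer.
    """
    if not 0 < k < length:
        raise ValueError(f"k={k} outside (0, {length})")
    from .hd_analysis import binomial_hd_stats

    stats = binomial_hd_stats(length, k / length)
    return _round_even(stats.mean_hd)


def random_pattern(length: int, k: int, rng: np.random.Generator) -> BinaryPattern:
    """Draw a pattern with exactly k active cells, uniform over index sets."""
    if not 0 <= k <= length:
        raise ValueError(f"k={k} outside [0, {length}]")
    idx = rng.choice(length, size=k, replace=False)
    return BinaryPattern.from_indices(length, idx)


@dataclass(frozen=True)
class PatternPair:
    """Two equal-count patterns at an exactly specified Hamming distance."""

    a: BinaryPattern
    b: BinaryPattern
    target_hd: int
    condition: str = "custom"

    def __post_init__(self):
        if self.a.length != self.b.length:
            raise ValueError("pair members differ in length")
        if self.a.k != self.b.k:
            raise ValueError("pair members differ in active count")
        realized = hamming(self.a, self.b)
        if realized != self.target_hd:
            raise ValueError(
                f"realized HD {realized} != target {self.target_hd}"
            )

    @property
    def realized_hd(self) -> int:
        return hamming(self.a, self.b)


def pair_with_hd(
    length: int,
    k: int,
    d: int,
    rng: np.random.Generator,
    condition: str = "custom",
) -> PatternPair:
    """Generate a pair of k-active patterns at exactly Hamming distance d.

    Construction: draw pattern ``a`` uniformly; ``b`` keeps a uniformly chosen
    core of k - d/2 of a's active indices and activates d/2 uniformly chosen
    indices from a's inactive positions.  Conditional on ``a`` this is uniform
    over all equal-count partners at distance d.
    """
    if d % 2 != 0 or d < 0:
        raise ValueError(
            f"HD between equal-count patterns is even and non-negative, got {d}"
        )
    if d > max_hd(length, k):
        raise ValueError(f"d={d} exceeds max HD {max_hd(length, k)}")
    half = d // 2
    if half > length - k:
        raise ValueError(f"d/2={half} exceeds available inactive positions")
    a = random_pattern(length, k, rng)
    if d == 0:
        return PatternPair(a=a, b=a, target_hd=0, condition=condition)
    a_idx = a.indices()
    core = rng.choice(a_idx, size=k - half, replace=False)
    inactive = np.setdiff1d(np.arange(length), a_idx, assume_unique=True)
    fresh = rng.choice(inactive, size=half, replace=False)
    b = BinaryPattern.from_indices(length, np.concatenate([core, fresh]))
    return PatternPair(a=a, b=b, target_hd=d, condition=condition)


# ---------------------------------------------------------------------------
# index-list file format: header "#length=N", one pattern per line, active
# indices space-separated, sorted ascending, 0-based.

def write_patterns(path, patterns: Sequence[BinaryPattern]) -> None:
    patterns = list(patterns)
    if not patterns:
        raise ValueError("no patterns to write")
    lengths = {p.length for p in patterns}
    if len(lengths) > 1:
        raise ValueError(f"mixed pattern lengths {sorted(lengths)}")
    with open(path, "w") as fh:
        fh.write(f"#length={patterns[0].length}\n")
        for p in patterns:
            fh.write(" ".join(str(i) for i in sorted(p.active)) + "\n")


def read_patterns(path) -> list[BinaryPattern]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#length="):
            raise ValueError(f"missing '#length=' header in {path}")
        length = int(header.split("=", 1)[1])
        out = []
        for line in fh:
            line = line.strip()
            idx = [int(t) for t in line.split()] if line else []
            out.append(BinaryPattern.from_indices(length, idx))
    return out


def write_pair_manifest(path, rows: Iterable[dict]) -> None:
    """CSV manifest: pair_id, condition, file_a, file_b, target_hd, realized_hd, seed."""
    import pandas as pd

    cols = ["pair_id", "condition", "file_a", "file_b", "target_hd", "realized_hd", "seed"]
    df = pd.DataFrame(list(rows), columns=cols)
    df.to_csv(path, index=False)
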