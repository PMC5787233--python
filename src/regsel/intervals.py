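"""Genomic interval sets: the shared currency for annotation classes, masks and bins.

All coordinates are 0-based half-open (BED convention). Interval sets are
kept normalized: per chromosome, intervals are sorted, non-overlapping and
non-adjacent (bookended intervals are merged, since every downstream use
treats a set as a set of bases).
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np

Interval = Tuple[str, int, int]


def _merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge a (k, 2) array of half-open intervals (adjacency merges)."""
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    starts, ends = arr[:, 0], arr[:, 1]
    # a new run begins where start > running max of previous ends
    run_max = np.maximum.accumulate(ends)
    new_run = np.empty(len(arr), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > run_max[:-1]
    run_id = np.cumsum(new_run) - 1
    n_runs = run_id[-1] + 1
    out = np.empty((n_runs, 2), dtype=np.int64)
    out[:, 0] = starts[new_run]
    out[:, 1] = np.maximum.reduceat(ends, np.flatnonzero(new_run))
    return out


class IntervalSet:
    """Sorted, merged, strand-agnostic half-open intervals on named chromosomes."""

    __slots__ = ("_ivals",)

    def __init__(self, intervals: Mapping[str, np.ndarray] | None = None,
                 _normalized: bool = False):
        self._ivals: Dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if a.shape[0] == 0:
                    continue
                if np.any(a[:, 1] <= a[:, 0]):
                    bad = a[a[:, 1] <= a[:, 0]][0]
                    raise ValueError(
                        f"invalid interval on {chrom}: end {bad[1]} <= start {bad[0]}")
                self._ivals[chrom] = a if _normalized else _merge(a)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[Interval]) -> "IntervalSet":
        by_chrom: Dict[str, list] = {}
        for chrom, start, end in pairs:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()})

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    # -- basic queries -----------------------------------------------------

    @property
    def chroms(self) -> list:
        return sorted(self._ivals)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivals.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._ivals.values()))

    @property
    def n_intervals(self) -> int:
        return int(sum(a.shape[0] for a in self._ivals.values()))

    def is_empty(self) -> bool:
        return not self._ivals

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self.chroms:
            for s, e in self._ivals[chrom]:
                yield (chrom, int(s), int(e))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals)

    def __repr__(self) -> str:
        return (f"IntervalSet({self.n_intervals} intervals on "
                f"{len(self._ivals)} chromosomes, {self.total_length} bp)")

    # -- set algebra -------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self._ivals) | set(other._ivals):
            out[chrom] = np.concatenate(
                [self.intervals(chrom), other.intervals(chrom)])
        return IntervalSet(out)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self._ivals) & set(other._ivals):
            a, b = self._ivals[chrom], other._ivals[chrom]
            # for each a-interval the range of b-intervals it can overlap
            lo = np.searchsorted(b[:, 1], a[:, 0], side="right")
            hi = np.searchsorted(b[:, 0], a[:, 1], side="left")
            pieces = []
            for k in range(a.shape[0]):
                if lo[k] < hi[k]:
                    s = np.maximum(b[lo[k]:hi[k], 0], a[k, 0])
                    e = np.minimum(b[lo[k]:hi[k], 1], a[k, 1])
                    pieces.append(np.stack([s, e], axis=1))
            if pieces:
                out[chrom] = np.concatenate(pieces)
        return IntervalSet(out, _normalized=True)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom, a in self._ivals.items():
            b = other.intervals(chrom)
            if b.shape[0] == 0:
                out[chrom] = a
                continue
            # complement of b over a's bounding range, then intersect with a
            bound_lo = min(a[0, 0], b[0, 0])
            bound_hi = max(a[-1, 1], b[-1, 1])
            comp = _complement_one(b, bound_lo, bound_hi)
            tmp = IntervalSet({chrom: a}, _normalized=True).intersection(
                IntervalSet({chrom: comp}, _normalized=True))
            arr = tmp.intervals(chrom)
            if arr.shape[0]:
                out[chrom] = arr
        return IntervalSet(out, _normalized=True)

    def complement(self, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        out = {}
        for chrom, size in chrom_sizes.items():
            a = self.intervals(chrom)
            comp = _complement_one(a, 0, size)
            if comp.shape[0]:
                out[chrom] = comp
        return IntervalSet(out, _normalized=True)

    def expand(self, pad: int,
               chrom_sizes: Mapping[str, int] | None = None) -> "IntervalSet":
        """Symmetrically widen every interval by `pad` bases, clipping at bounds."""
        if pad < 0:
            raise ValueError("pad must be non-negative")
        out = {}
        for chrom, a in self._ivals.items():
            b = a.copy()
            b[:, 0] = np.maximum(b[:, 0] - pad, 0)
            b[:, 1] = b[:, 1] + pad
            if chrom_sizes is not None and chrom in chrom_sizes:
                b[:, 1] = np.minimum(b[:, 1], chrom_sizes[chrom])
            b = b[b[:, 1] > b[:, 0]]
            if b.shape[0]:
                out[chrom] = b
        return IntervalSet(out)

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    # -- point queries -----------------------------------------------------

    def contains(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions (vectorized)."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        a = self.intervals(chrom)
        if a.shape[0] == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(a[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        res = np.zeros(pos0.shape, dtype=bool)
        res[ok] = pos0[ok] < a[idx[ok], 1]
        return res

    def covered_before(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Number of member bases in [0, x) per query point (vectorized)."""
        x = np.asarray(x, dtype=np.int64)
        a = self.intervals(chrom)
        if a.shape[0] == 0:
            return np.zeros(x.shape, dtype=np.int64)
        lens = a[:, 1] - a[:, 0]
        cum = np.concatenate([[0], np.cumsum(lens)])
        idx = np.searchsorted(a[:, 0], x, side="right")  # intervals with start < x
        res = cum[idx].copy()
        inside = idx > 0
        prev = idx[inside] - 1
        overhang = np.maximum(a[prev, 1] - x[inside], 0)
        res[inside] -= overhang
        return res


def _complement_one(arr: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Complement of a normalized (k, 2) array within [lo, hi)."""
    if arr.shape[0] == 0:
        return (np.array([[lo, hi]], dtype=np.int64)
                if hi > lo else np.empty((0, 2), dtype=np.int64))
    edges = np.concatenate([[lo], arr[:, [0, 1]].ravel(), [hi]])
    starts = edges[::2]
    ends = edges[1::2]
    keep = ends > starts
    out = np.stack([starts[keep], ends[keep]], axis=1)
    # clip pieces that fall outside [lo, hi) when arr extends beyond bounds
    out[:, 0] = np.maximum(out[:, 0], lo)
    out[:, 1] = np.minimum(out[:, 1], hi)
    return out[out[:, 1] > out[:, 0]]


# -- chromosome sizes ------------------------------------------------------

def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column text: chromosome name, length in bp."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def genome_set(chrom_sizes: Mapping[str, int]) -> IntervalSet:
    """The whole genome as an IntervalSet."""
    return IntervalSet({c: np.array([[0, n]]) for c, n in chrom_sizes.items()},
                       _normalized=True)
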