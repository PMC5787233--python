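"""Annotation-class geometry: merged class tracks, the selection-neutral
reference, and distance-from-CDS bins.

The neutral reference is non-annotated sequence at least ``min_cds_distance``
(default 200 kb) from any protein-coding base, after removing every supplied
exclusion track; it is used to absorb the demographic signal shared by all
classes. Distance bins stratify the genome by gap to the nearest CDS base so
that direct purifying selection on an element can be separated from
linked-purifying (background) selection leaking out of coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .intervals import IntervalSet, genome_set

DEFAULT_BIN_EDGES = (2_500, 5_000, 7_500, 10_000, 25_000, 50_000, 75_000, 100_000)
DEFAULT_MIN_CDS_DISTANCE = 200_000


@dataclass
class ClassRegistry:
    """Named annotation classes (CDS, UTR, promoter, enhancer, ...) with provenance."""
    classes: Dict[str, IntervalSet] = field(default_factory=dict)
    provenance: Dict[str, List[str]] = field(default_factory=dict)

    def add(self, code: str, iset: IntervalSet,
            sources: Sequence[str] = ()) -> None:
        if code in self.classes:
            raise ValueError(f"duplicate class code {code!r}")
        self.classes[code] = iset
        self.provenance[code] = list(sources)

    def __getitem__(self, code: str) -> IntervalSet:
        return self.classes[code]

    def __contains__(self, code: str) -> bool:
        return code in self.classes

    @property
    def codes(self) -> List[str]:
        return list(self.classes)

    def union_of(self, codes: Sequence[str]) -> IntervalSet:
        out = IntervalSet.empty()
        for code in codes:
            out = out | self.classes[code]
        return out


@dataclass
class DistanceBinning:
    """Disjoint strata of non-CDS genome binned by gap to the nearest CDS base.

    Bin k holds bases with distance in (edges[k-1], edges[k]] (edges[-1] = 0,
    so a base exactly at the first edge falls in the first bin). A trailing
    catch-all stratum beyond the last edge is kept under ``beyond``.
    """
    edges: List[int]
    bins: List[IntervalSet]
    beyond: IntervalSet

    def __len__(self) -> int:
        return len(self.bins)

    def labels(self) -> List[str]:
        lo = [0] + list(self.edges[:-1])
        return [f"({a / 1000:g}kb,{b / 1000:g}kb]"
                for a, b in zip(lo, self.edges)]


def merge_cell_lines(tracks: Sequence[IntervalSet]) -> IntervalSet:
    """Union of per-cell-line tracks for one annotation class, normalized."""
    if not tracks:
        raise ValueError("need at least one track")
    out = tracks[0]
    for t in tracks[1:]:
        out = out | t
    return out


def build_neutral_reference(exclusions: Sequence[IntervalSet],
                            cds: IntervalSet,
                            chrom_sizes: Mapping[str, int],
                            min_cds_distance: int = DEFAULT_MIN_CDS_DISTANCE,
                            ) -> IntervalSet:
    """Genome minus all exclusion tracks minus CDS widened by min_cds_distance."""
    import warnings

    ref = genome_set(chrom_sizes)
    ref = ref - cds.expand(min_cds_distance, chrom_sizes)
    for excl in exclusions:
        ref = ref - excl
    for chrom in chrom_sizes:
        if ref.intervals(chrom).shape[0] == 0:
            warnings.warn(f"neutral reference empty on {chrom}", stacklevel=2)
    return ref


def build_distance_bins(cds: IntervalSet, chrom_sizes: Mapping[str, int],
                        edges: Sequence[int] = DEFAULT_BIN_EDGES,
                        ) -> DistanceBinning:
    """Stratify non-CDS sequence by distance to the nearest CDS base.

    Distance d(b) = min over CDS bases c of |b - c|; bin k is the half-open
    distance range (edges[k-1], edges[k]]. Realized as nested expansions:
    bin k = expand(CDS, edges[k]) - expand(CDS, edges[k-1]), which is exact
    for this metric. Chromosomes without CDS contribute no binned bases.
    """
    edges = list(edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])) or edges[0] <= 0:
        raise ValueError("edges must be strictly increasing and positive")
    sizes = {c: chrom_sizes[c] for c in cds.chroms if c in chrom_sizes}
    prev = cds
    bins = []
    for e in edges:
        cur = cds.expand(e, sizes)
        bins.append(cur - prev)
        prev = cur
    beyond = genome_set(sizes) - prev
    return DistanceBinning(edges=edges, bins=bins, beyond=beyond)


def intersect_class_with_bins(class_set: IntervalSet, bins: DistanceBinning,
                              mask: IntervalSet) -> List[IntervalSet]:
    """Per-bin accessible extent of a class: class ∩ bin ∩ mask for each bin."""
    return [class_set & b & mask for b in bins.bins]


def nearest_cds_distance(cds: IntervalSet, chrom: str,
                         pos0: np.ndarray) -> np.ndarray:
    """Gap in bases from each 0-based position to the nearest CDS base.

    Returns 0 for positions inside CDS and a large sentinel (2**62) on
    chromosomes without CDS.
    """
    pos0 = np.asarray(pos0, dtype=np.int64)
    a = cds.intervals(chrom)
    if a.shape[0] == 0:
        return np.full(pos0.shape, 2**62, dtype=np.int64)
    idx = np.searchsorted(a[:, 0], pos0, side="right") - 1
    dist_left = np.full(pos0.shape, 2**62, dtype=np.int64)
    has_left = idx >= 0
    # distance to last base (end-1) of the interval at/before pos
    dist_left[has_left] = np.maximum(pos0[has_left] - (a[idx[has_left], 1] - 1), 0)
    nxt = idx + 1
    dist_right = np.full(pos0.shape, 2**62, dtype=np.int64)
    has_right = nxt < a.shape[0]
    dist_right[has_right] = a[nxt[has_right], 0] - pos0[has_right]
    return np.minimum(dist_left, dist_right)
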