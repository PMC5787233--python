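"""Positional association between annotation classes.

Each class is reduced to per-window counts of annotated bases (sliding
windows of 5/10/15 kb advanced by 1.5 kb), pairwise Pearson correlations are
computed across windows, and classes are ordered by Ward hierarchical
clustering of 1 - r. Overlapping windows induce autocorrelation, so r is
reported descriptively without significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .intervals import IntervalSet

DEFAULT_WINDOW_BP = 10_000
DEFAULT_STEP_BP = 1_500


def presence_track(class_set: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Per-base 0/1 membership indicator (materialized; for modest lengths)."""
    track = np.zeros(length, dtype=np.uint8)
    for s, e in class_set.intervals(chrom):
        track[max(s, 0):min(e, length)] = 1
    return track


def window_starts(chrom_len: int, step: int) -> np.ndarray:
    return np.arange(0, chrom_len, step, dtype=np.int64)


def window_counts(class_set: IntervalSet, chrom: str, chrom_len: int,
                  w: int = DEFAULT_WINDOW_BP,
                  step: int = DEFAULT_STEP_BP) -> np.ndarray:
    """Annotated bases per window [k*step, k*step + w), clipped at chrom end."""
    if w < step:
        raise ValueError("window must be at least the step size")
    starts = window_starts(chrom_len, step)
    ends = np.minimum(starts + w, chrom_len)
    cov_end = class_set.covered_before(chrom, ends)
    cov_start = class_set.covered_before(chrom, starts)
    return (cov_end - cov_start).astype(np.int64)


def window_counts_track(track: np.ndarray, w: int = DEFAULT_WINDOW_BP,
                        step: int = DEFAULT_STEP_BP) -> np.ndarray:
    """Same contract as window_counts but from a materialized 0/1 track."""
    if w < step:
        raise ValueError("window must be at least the step size")
    csum = np.concatenate([[0], np.cumsum(track, dtype=np.int64)])
    starts = window_starts(len(track), step)
    ends = np.minimum(starts + w, len(track))
    return csum[ends] - csum[starts]


@dataclass
class WindowCountMatrix:
    """Windows x classes matrix of annotated-base counts."""
    counts: pd.DataFrame  # index = window start, columns = class codes
    window_bp: int
    step_bp: int

    @property
    def classes(self) -> List[str]:
        return list(self.counts.columns)


def window_count_matrix(classes: Mapping[str, IntervalSet], chrom: str,
                        chrom_len: int, w: int = DEFAULT_WINDOW_BP,
                        step: int = DEFAULT_STEP_BP) -> WindowCountMatrix:
    data = {code: window_counts(iset, chrom, chrom_len, w, step)
            for code, iset in classes.items()}
    df = pd.DataFrame(data, index=window_starts(chrom_len, step))
    return WindowCountMatrix(counts=df, window_bp=w, step_bp=step)


@dataclass
class CorrelationMatrix:
    """Classes x classes Pearson r with zero-variance classes flagged."""
    r: pd.DataFrame
    dropped: List[str] = field(default_factory=list)

    @property
    def classes(self) -> List[str]:
        return list(self.r.columns)


def pairwise_pearson(wcm: WindowCountMatrix) -> CorrelationMatrix:
    """Pearson r between all class pairs across windows.

    Classes with zero variance across windows have undefined r; they are
    reported in ``dropped`` and excluded from the matrix.
    """
    df = wcm.counts
    if len(df) < 2:
        raise ValueError("need at least 2 windows")
    variances = df.var(axis=0)
    dropped = list(variances.index[variances == 0])
    kept = df.drop(columns=dropped)
    r = kept.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(r=r, dropped=dropped)


def cluster_order(cm: CorrelationMatrix) -> List[str]:
    """Leaf order from Ward hierarchical clustering on dissimilarity 1 - r."""
    classes = cm.classes
    if len(classes) <= 2:
        return list(classes)
    d = 1.0 - cm.r.values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
    z = linkage(squareform(d, checks=False), method="ward")
    return [classes[i] for i in leaves_list(z)]
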