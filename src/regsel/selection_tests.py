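"""Class-versus-neutral comparisons: two-sample Z-test, McDonald-Kreitman
neutrality index, and a pairwise Weir-Cockerham F_ST pool-homogeneity screen.

The Z-test contrasts a class estimate (theta_pi or Tajima's D, with
jackknife SEs) against the selection-neutral reference; |Z| > 1.96 is the
significance threshold, and scores beyond |Z| = 2 are flagged as outside
the range where the normal approximation maps to p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genomic_io import MISSING, GenotypeTable, PolarizedSiteTable
from .intervals import IntervalSet
from .sfs_stats import JackknifeEstimate

Z_THRESHOLD = 1.96


def z_test(e1: float, se1: float, e2: float, se2: float) -> float:
    """Two-sample Z: (e1 - e2) / sqrt(se1^2 + se2^2); NaN if pooled SE is 0."""
    denom = math.sqrt(se1**2 + se2**2)
    if denom == 0 or math.isnan(denom):
        return math.nan
    return (e1 - e2) / denom


@dataclass
class ZComparison:
    """A class-vs-neutral contrast for one statistic, pool and stratum."""
    class_code: str
    pool: str
    bin_label: str
    estimate_class: float
    se_class: float
    estimate_neutral: float
    se_neutral: float
    z_score: float
    significant: bool
    beyond_normal_range: bool

    @classmethod
    def from_estimates(cls, class_code: str, pool: str, bin_label: str,
                       est_class: JackknifeEstimate,
                       est_neutral: JackknifeEstimate) -> "ZComparison":
        z = z_test(est_class.point_estimate, est_class.standard_error,
                   est_neutral.point_estimate, est_neutral.standard_error)
        return cls(class_code=class_code, pool=pool, bin_label=bin_label,
                   estimate_class=est_class.point_estimate,
                   se_class=est_class.standard_error,
                   estimate_neutral=est_neutral.point_estimate,
                   se_neutral=est_neutral.standard_error,
                   z_score=z,
                   significant=bool(not math.isnan(z) and abs(z) > Z_THRESHOLD),
                   beyond_normal_range=bool(not math.isnan(z) and abs(z) > 2.0))


@dataclass
class MkCounts:
    """McDonald-Kreitman counts and neutrality index NI = (Pn/Ps)/(Dn/Ds).

    Pn/Dn are polymorphisms/fixed substitutions in the test class, Ps/Ds in
    the neutral reference; NI < 1 indicates relative constraint in the class.
    """
    Pn: int
    Ps: int
    Dn: int
    Ds: int

    @property
    def defined(self) -> bool:
        return self.Ps > 0 and self.Dn > 0 and self.Ds > 0

    @property
    def ni(self) -> float:
        if not self.defined:
            return math.nan
        return (self.Pn / self.Ps) / (self.Dn / self.Ds)


def _count_p_and_d(sites: PolarizedSiteTable, stratum: IntervalSet):
    in_set = sites.region_mask(stratum)
    derived_all, called_all = sites.combined()
    poly = in_set & (derived_all > 0) & (derived_all < called_all)
    subs = in_set & sites.is_fixed_substitution
    return int(poly.sum()), int(subs.sum())


def neutrality_index(sites: PolarizedSiteTable, class_set: IntervalSet,
                     neutral_set: IntervalSet, mask: IntervalSet) -> MkCounts:
    """Count combined-sample polymorphisms and fixed human-lineage
    substitutions in class ∩ mask vs neutral ∩ mask."""
    Pn, Dn = _count_p_and_d(sites, class_set & mask)
    Ps, Ds = _count_p_and_d(sites, neutral_set & mask)
    return MkCounts(Pn=Pn, Ps=Ps, Dn=Dn, Ds=Ds)


def pairwise_fst(gt: GenotypeTable, pool_a: str, pool_b: str,
                 return_n_sites: bool = False):
    """Multi-site Weir-Cockerham (1984) F_ST between two pools.

    Per-site variance components a (among populations), b (among individuals
    within populations) and c (within individuals) are combined as a ratio
    of sums across sites. Individuals with a missing haplotype at a site are
    excluded there; monomorphic sites contribute nothing. Slightly negative
    values can arise by estimation.
    """
    comps = []
    for pool in (pool_a, pool_b):
        if len(gt.pools[pool]) < 2:
            raise ValueError(f"pool {pool!r} needs >= 2 individuals")
        cols = gt.pool_columns(pool)
        h1 = gt.haplotypes[:, cols[0::2]].astype(np.int64)
        h2 = gt.haplotypes[:, cols[1::2]].astype(np.int64)
        ok = (h1 != MISSING) & (h2 != MISSING)
        n_i = ok.sum(axis=1).astype(np.float64)              # diploid counts
        alt = (np.where(ok, h1, 0) + np.where(ok, h2, 0)).sum(axis=1)
        p_i = np.divide(alt, 2.0 * n_i, out=np.zeros(len(gt.pos)),
                        where=n_i > 0)
        het = np.where(ok, h1 != h2, False).sum(axis=1)
        h_i = np.divide(het, n_i, out=np.zeros(len(gt.pos)), where=n_i > 0)
        comps.append((n_i, p_i, h_i))

    (n1, p1, h1f), (n2, p2, h2f) = comps
    usable = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    poly = usable & (pbar > 0) & (pbar < 1)
    if not np.any(poly):
        if return_n_sites:
            return math.nan, 0
        return math.nan
    n1, n2, p1, p2, h1f, h2f = (x[poly] for x in (n1, n2, p1, p2, h1f, h2f))
    nbar, pbar = nbar[poly], pbar[poly]
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1f + n2 * h2f) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                             - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    denom = float(np.sum(a + b + c))
    fst = math.nan if denom == 0 else float(np.sum(a)) / denom
    if return_n_sites:
        return fst, int(poly.sum())
    return fst
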