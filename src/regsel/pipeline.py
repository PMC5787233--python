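"""Orchestration of the full selection scan from a configuration.

Runs the per-class overall scan (theta_pi, theta_w, Tajima's D with
jackknife CIs and Z vs the non-annotated reference), the distance-from-CDS
profile with per-bin Z-tests, the MK neutrality index, the pairwise F_ST
pool screen, and the sliding-window class correlation; results are plain
pandas DataFrames, written as TSV by the CLI.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import interval_ops, selection_tests, sfs_stats
from .genomic_io import GenotypeTable, PolarizedSiteTable
from .interval_ops import ClassRegistry
from .intervals import IntervalSet, genome_set

NEUTRAL_CODE = "NON_ANN"
WHOLE_GENOME_CODE = "WHOLE_GENOME"


@dataclass
class RunConfig:
    """Paths and parameters for one analysis run."""
    vcf: str = ""
    class_beds: Dict[str, str] = field(default_factory=dict)
    mask_bed: str = ""
    outgroup_table: str = ""
    chrom_sizes: str = ""
    pools: Dict[str, List[str]] = field(default_factory=dict)
    out_dir: str = "results"
    block_bp: int = sfs_stats.DEFAULT_BLOCK_BP
    bin_edges: List[int] = field(
        default_factory=lambda: list(interval_ops.DEFAULT_BIN_EDGES))
    window_bp: int = 10_000
    step_bp: int = 1_500
    z_threshold: float = 1.96
    min_cds_distance: int = interval_ops.DEFAULT_MIN_CDS_DISTANCE
    min_outgroup_agree: int = 2
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def build_registry_with_references(registry: ClassRegistry,
                                   chrom_sizes: Mapping[str, int],
                                   min_cds_distance: int =
                                   interval_ops.DEFAULT_MIN_CDS_DISTANCE,
                                   ) -> ClassRegistry:
    """Add the NON_ANN neutral reference and WHOLE_GENOME classes.

    NON_ANN = genome minus every annotation class, at least
    ``min_cds_distance`` from CDS.
    """
    out = ClassRegistry(dict(registry.classes), dict(registry.provenance))
    annotations = [registry[c] for c in registry.codes]
    cds = registry["CDS"] if "CDS" in registry else IntervalSet.empty()
    if NEUTRAL_CODE not in out:
        out.add(NEUTRAL_CODE, interval_ops.build_neutral_reference(
            annotations, cds, chrom_sizes, min_cds_distance), ["derived"])
    if WHOLE_GENOME_CODE not in out:
        out.add(WHOLE_GENOME_CODE, genome_set(chrom_sizes), ["derived"])
    return out


def _stat_row(sites: PolarizedSiteTable, region: IntervalSet,
              mask: IntervalSet, chrom_sizes, pool: str,
              block_bp: int) -> Dict[str, float]:
    row: Dict[str, float] = {}
    for stat in ("theta_pi", "theta_w", "tajimas_d"):
        est = sfs_stats.jackknife_sfs(sites, region, mask, chrom_sizes,
                                      pool, statistic=stat, block_bp=block_bp)
        row[stat] = est.point_estimate
        row[f"{stat}_se"] = est.standard_error
        row[f"{stat}_ci_lo"], row[f"{stat}_ci_hi"] = est.ci95
        row["n_blocks"] = est.n_blocks
    return row


def run_overall_scan(sites: PolarizedSiteTable, registry: ClassRegistry,
                     mask: IntervalSet, chrom_sizes: Mapping[str, int],
                     block_bp: int = sfs_stats.DEFAULT_BLOCK_BP,
                     neutral_code: str = NEUTRAL_CODE) -> pd.DataFrame:
    """Per (class x pool): SFS statistics with jackknife CIs and Z vs NON_ANN."""
    rows = []
    cache: Dict[Tuple[str, str], Dict[str, float]] = {}
    for pool in sites.pools:
        cache[(neutral_code, pool)] = _stat_row(
            sites, registry[neutral_code], mask, chrom_sizes, pool, block_bp)
    for code in registry.codes:
        for pool in sites.pools:
            try:
                row = cache.get((code, pool)) or _stat_row(
                    sites, registry[code], mask, chrom_sizes, pool, block_bp)
            except ValueError:  # empty stratum: flag and continue
                rows.append({"class_code": code, "pool": pool,
                             "flag": "empty_stratum"})
                continue
            neutral = cache[(neutral_code, pool)]
            out = {"class_code": code, "pool": pool, "flag": "", **row}
            for stat in ("theta_pi", "tajimas_d"):
                z = selection_tests.z_test(
                    row[stat], row[f"{stat}_se"],
                    neutral[stat], neutral[f"{stat}_se"])
                out[f"z_{stat}"] = z
                out[f"significant_{stat}"] = (not math.isnan(z)
                                              and abs(z) > 1.96)
            rows.append(out)
    return pd.DataFrame(rows)


def run_distance_profile(sites: PolarizedSiteTable, registry: ClassRegistry,
                         mask: IntervalSet, chrom_sizes: Mapping[str, int],
                         bin_edges: Sequence[int] =
                         interval_ops.DEFAULT_BIN_EDGES,
                         block_bp: int = sfs_stats.DEFAULT_BLOCK_BP,
                         class_codes: Optional[Sequence[str]] = None,
                         neutral_code: str = NEUTRAL_CODE) -> pd.DataFrame:
    """Per (class x pool x distance bin): statistics plus Z of class vs
    non-annotated sequence within the same bin."""
    cds = registry["CDS"]
    bins = interval_ops.build_distance_bins(cds, chrom_sizes, bin_edges)
    labels = bins.labels()
    # non-annotated = genome minus all annotation classes (no distance filter)
    ann = registry.union_of([c for c in registry.codes
                             if c not in (neutral_code, WHOLE_GENOME_CODE)])
    non_ann = genome_set(chrom_sizes) - ann
    codes = list(class_codes) if class_codes is not None else [
        c for c in registry.codes
        if c not in ("CDS", neutral_code, WHOLE_GENOME_CODE)]

    rows = []
    nonann_cache: Dict[Tuple[int, str], Dict[str, float]] = {}
    for bi, bset in enumerate(bins.bins):
        for pool in sites.pools:
            try:
                nonann_cache[(bi, pool)] = _stat_row(
                    sites, non_ann & bset, mask, chrom_sizes, pool, block_bp)
            except ValueError:
                nonann_cache[(bi, pool)] = {}
    for code in ["NON_ANN_BINNED"] + codes:
        source = non_ann if code == "NON_ANN_BINNED" else registry[code]
        for bi, bset in enumerate(bins.bins):
            stratum = source & bset
            for pool in sites.pools:
                base = {"class_code": code, "pool": pool,
                        "bin": labels[bi], "bin_index": bi,
                        "accessible_bp": (stratum & mask).total_length}
                if code == "NON_ANN_BINNED":
                    row = nonann_cache[(bi, pool)]
                    if not row:
                        rows.append({**base, "flag": "empty_bin"})
                        continue
                    rows.append({**base, "flag": "", **row,
                                 "z_theta_pi": 0.0, "z_tajimas_d": 0.0})
                    continue
                try:
                    row = _stat_row(sites, stratum, mask, chrom_sizes, pool,
                                    block_bp)
                except ValueError:
                    rows.append({**base, "flag": "empty_bin"})
                    continue
                neutral = nonann_cache[(bi, pool)]
                out = {**base, "flag": "", **row}
                for stat in ("theta_pi", "tajimas_d"):
                    if neutral:
                        z = selection_tests.z_test(
                            row[stat], row[f"{stat}_se"],
                            neutral[stat], neutral[f"{stat}_se"])
                    else:
                        z = math.nan
                    out[f"z_{stat}"] = z
                rows.append(out)
    return pd.DataFrame(rows)


def run_mk(sites: PolarizedSiteTable, registry: ClassRegistry,
           mask: IntervalSet,
           neutral_code: str = NEUTRAL_CODE,
           class_codes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Neutrality index of every class against the neutral reference."""
    neutral = registry[neutral_code]
    codes = list(class_codes) if class_codes is not None else [
        c for c in registry.codes if c not in (neutral_code, WHOLE_GENOME_CODE)]
    rows = []
    for code in codes:
        mk = selection_tests.neutrality_index(sites, registry[code],
                                              neutral, mask)
        rows.append({"class_code": code, "Pn": mk.Pn, "Ps": mk.Ps,
                     "Dn": mk.Dn, "Ds": mk.Ds, "NI": mk.ni,
                     "flag": "" if mk.defined else "undefined_NI"})
    return pd.DataFrame(rows)


def run_fst(gt: GenotypeTable) -> pd.DataFrame:
    """Pairwise Weir-Cockerham F_ST between all pool pairs."""
    rows = []
    for a, b in itertools.combinations(gt.pools, 2):
        fst, n = selection_tests.pairwise_fst(gt, a, b, return_n_sites=True)
        rows.append({"pool_a": a, "pool_b": b, "fst": fst, "n_sites": n})
    return pd.DataFrame(rows)


def run_correlation(registry: ClassRegistry, chrom_sizes: Mapping[str, int],
                    chroms: Optional[Sequence[str]] = None,
                    window_bp: int = 10_000, step_bp: int = 1_500,
                    class_codes: Optional[Sequence[str]] = None):
    """Sliding-window Pearson correlation of class positions per chromosome.

    Returns {chrom: (CorrelationMatrix, leaf order)}.
    """
    from . import spatial_correlation as sc

    codes = list(class_codes) if class_codes is not None else [
        c for c in registry.codes if c not in (NEUTRAL_CODE, WHOLE_GENOME_CODE)]
    results = {}
    for chrom in (chroms or list(chrom_sizes)):
        wcm = sc.window_count_matrix(
            {c: registry[c] for c in codes}, chrom, chrom_sizes[chrom],
            w=window_bp, step=step_bp)
        cm = sc.pairwise_pearson(wcm)
        order = sc.cluster_order(cm)
        results[chrom] = (cm, order)
    return results
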