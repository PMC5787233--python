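"""Synthetic inputs with the statistical structure the analysis assumes.

Generates, without any external download:

* sample pools of diploid individuals under coalescent demographies —
  ``expansion`` (African-like, negative Tajima's D, neutral diversity
  ~0.001/site), ``bottleneck`` (non-African-like, positive D, reduced
  diversity) and ``constant`` (calibration);
* gene models (CDS/UTR/intron geometry) and regulatory annotation tracks
  placed around shared anchor points, so that an anchor-sharing fraction
  tunes the positional correlation between classes;
* purifying selection emulated by post-hoc frequency-biased thinning of
  neutral variants: reduced diversity inside selected elements plus an
  exponentially decaying reduction around CDS (linked selection), with an
  optional bias that removes common variants preferentially and drives
  Tajima's D negative;
* per-site alleles for three outgroups with configurable error and
  missingness, plus injected fixed human-lineage substitutions with known
  truth counts for MK validation;
* an accessibility mask with randomly placed inaccessible chunks.

Every operation is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import msprime
import numpy as np

from .genomic_io import MISSING, GenotypeTable, OutgroupAlleles
from .interval_ops import ClassRegistry, nearest_cds_distance
from .intervals import IntervalSet, genome_set

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class PoolSpec:
    """One sample pool: its size and demographic preset."""
    n_individuals: int = 9
    demography: str = "constant"  # constant | expansion | bottleneck


@dataclass(frozen=True)
class ClassSpec:
    """Geometry of one planted regulatory class."""
    elements_per_mb: float = 30.0
    element_size: int = 600
    anchor_sharing: float = 0.0   # fraction of elements at shared anchors
    at_tss: bool = False          # anchor at gene TSS instead of random points


def six_global_pools() -> Dict[str, PoolSpec]:
    """Six pools of nine individuals: three African-like, three non-African-like."""
    return {
        "NKS": PoolSpec(9, "expansion"),
        "SKS": PoolSpec(9, "expansion"),
        "WAF": PoolSpec(9, "expansion"),
        "AMR": PoolSpec(9, "bottleneck"),
        "SAS": PoolSpec(9, "bottleneck"),
        "EUR": PoolSpec(9, "bottleneck"),
    }


def default_classes() -> Dict[str, ClassSpec]:
    return {
        "PROMOTER": ClassSpec(element_size=1200, at_tss=True),
        "ENHANCER": ClassSpec(elements_per_mb=30, element_size=600,
                              anchor_sharing=0.7),
        "TFBS": ClassSpec(elements_per_mb=30, element_size=300,
                          anchor_sharing=0.7),
        "DHS": ClassSpec(elements_per_mb=30, element_size=500,
                         anchor_sharing=0.5),
        "CTCF": ClassSpec(elements_per_mb=15, element_size=400,
                          anchor_sharing=0.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; same seed + config gives identical output."""
    seed: int = 1
    chromosomes: Tuple[Tuple[str, int], ...] = (("chr1", 10_000_000),)
    pools: Mapping[str, PoolSpec] = field(default_factory=lambda: {
        "AFR": PoolSpec(9, "expansion"), "NAFR": PoolSpec(9, "bottleneck")})
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    neutral_diversity: float = 0.001   # per-site target on neutral sequence
    ref_is_ancestral_prob: float = 0.95
    # gene / element layout
    genes_per_mb: float = 3.0
    classes: Mapping[str, ClassSpec] = field(default_factory=default_classes)
    anchors_per_mb: float = 40.0
    # selection profile
    f_inside: float = 0.5              # diversity retention inside elements
    cds_edge_reduction: float = 0.5    # 1 - retention at distance 0 from CDS
    d_half: float = 5_000.0            # bp scale of the linked-selection decay
    freq_bias_beta: float = 0.0        # >0 removes common variants preferentially
    selected_classes: Tuple[str, ...] = ("PROMOTER", "ENHANCER", "TFBS", "DHS")
    # outgroups / substitutions
    outgroup_error: float = 0.01
    outgroup_missing: float = 0.02
    substitution_rate: float = 3e-4    # injected fixed derived sites per bp
    # accessibility mask
    accessible_fraction: float = 0.9
    inaccessible_chunk_bp: int = 2_000

    @property
    def constant_ne(self) -> float:
        return self.neutral_diversity / (4.0 * self.mutation_rate)

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return dict(self.chromosomes)


# ---------------------------------------------------------------------------
# Demographies
# ---------------------------------------------------------------------------

def demography_preset(name: str, cfg: SimulationConfig) -> msprime.Demography:
    """Single-population step demographies reproducing the qualitative SFS
    signatures of African-like expansion and non-African-like bottleneck."""
    d = msprime.Demography()
    if name == "constant":
        d.add_population(name="pop", initial_size=cfg.constant_ne)
    elif name == "expansion":
        # recent 10x growth; mean pairwise TMRCA tuned to the diversity target
        n_anc = (cfg.neutral_diversity / (2.0 * cfg.mutation_rate) - 5000) / 2.0
        d.add_population(name="pop", initial_size=10.0 * n_anc)
        d.add_population_parameters_change(time=5000, initial_size=n_anc,
                                           population="pop")
    elif name == "bottleneck":
        n_anc = (cfg.neutral_diversity / (2.0 * cfg.mutation_rate) - 5000) / 2.0
        d.add_population(name="pop", initial_size=20_000)
        d.add_population_parameters_change(time=2000, initial_size=1_500,
                                           population="pop")
        d.add_population_parameters_change(time=3000, initial_size=n_anc,
                                           population="pop")
    else:
        raise ValueError(f"unknown demography preset {name!r}")
    return d


# ---------------------------------------------------------------------------
# Pool simulation
# ---------------------------------------------------------------------------

def _sim_one(cfg: SimulationConfig, preset: str, n_ind: int, length: int,
             seed_pair: Tuple[int, int]):
    ts = msprime.sim_ancestry(
        samples=n_ind, demography=demography_preset(preset, cfg),
        sequence_length=length, recombination_rate=cfg.recombination_rate,
        random_seed=seed_pair[0])
    mts = msprime.sim_mutations(
        ts, rate=cfg.mutation_rate, random_seed=seed_pair[1],
        model=msprime.BinaryMutationModel(), discrete_genome=True)
    pos = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
    gmat = mts.genotype_matrix()  # sites x haplotypes, 0 = ancestral
    return pos, (gmat > 0).astype(np.int8)


def simulate_pools(cfg: SimulationConfig
                   ) -> Tuple[GenotypeTable, Dict]:
    """Simulate neutral genotypes for every configured pool.

    Pools are simulated as independent coalescent populations; a site
    segregating in one pool is monomorphic-ancestral in the others. The
    returned table carries the true ancestral allele per site, and the truth
    record stores the full parameterization.
    """
    rng = np.random.default_rng(cfg.seed)
    pool_names = list(cfg.pools)
    individuals = [f"{p}_{i}" for p in pool_names
                   for i in range(cfg.pools[p].n_individuals)]
    pools = {p: [f"{p}_{i}" for i in range(cfg.pools[p].n_individuals)]
             for p in pool_names}
    hap_offset = {}
    off = 0
    for p in pool_names:
        hap_offset[p] = off
        off += 2 * cfg.pools[p].n_individuals
    n_hap_total = off

    chrom_l, pos_l, ref_l, alt_l, anc_l, hap_rows = [], [], [], [], [], []
    for chrom, length in cfg.chromosomes:
        seen = np.empty(0, dtype=np.int64)
        for p in pool_names:
            spec = cfg.pools[p]
            seeds = tuple(int(s) for s in rng.integers(1, 2**31 - 1, size=2))
            pos, gmat = _sim_one(cfg, spec.demography, spec.n_individuals,
                                 length, seeds)
            # rare cross-pool position collision: earlier pool wins
            new = ~np.isin(pos, seen)
            pos, gmat = pos[new], gmat[new]
            seen = np.concatenate([seen, pos])
            ns = len(pos)
            if ns == 0:
                continue
            anc_idx = rng.integers(4, size=ns)
            der_idx = (anc_idx + 1 + rng.integers(3, size=ns)) % 4
            anc = _BASES[anc_idx]
            der = _BASES[der_idx]
            ref_is_anc = rng.random(ns) < cfg.ref_is_ancestral_prob
            ref = np.where(ref_is_anc, anc, der)
            alt = np.where(ref_is_anc, der, anc)
            anc_code = np.where(ref_is_anc, 0, 1).astype(np.int8)
            der_code = (1 - anc_code).astype(np.int8)
            block = np.repeat(anc_code[:, None], n_hap_total, axis=1)
            o = hap_offset[p]
            cols = slice(o, o + gmat.shape[1])
            block[:, cols] = np.where(gmat > 0, der_code[:, None],
                                      anc_code[:, None])
            chrom_l.extend([chrom] * ns)
            pos_l.extend((pos + 1).tolist())  # to 1-based
            ref_l.extend(ref.tolist())
            alt_l.extend(alt.tolist())
            anc_l.extend(anc.tolist())
            hap_rows.append(block)

    gt = GenotypeTable(
        chrom=np.asarray(chrom_l, dtype=object),
        pos=np.asarray(pos_l, dtype=np.int64),
        ref=np.asarray(ref_l, dtype="<U1"),
        alt=np.asarray(alt_l, dtype="<U1"),
        haplotypes=(np.vstack(hap_rows) if hap_rows
                    else np.empty((0, n_hap_total), dtype=np.int8)),
        individuals=individuals, pools=pools,
        ancestral=np.asarray(anc_l, dtype="<U1"))
    truth = {"config": cfg, "n_sites": gt.n_sites}
    return gt, truth


def simulate_split_pools(cfg: SimulationConfig, pool_a: str, pool_b: str,
                         split_time: float,
                         n_individuals: int = 9) -> GenotypeTable:
    """Two pools drawn from populations that diverged ``split_time``
    generations ago (0 = one panmictic population), for the F_ST screen."""
    rng = np.random.default_rng(cfg.seed)
    ne = cfg.constant_ne
    individuals = ([f"{pool_a}_{i}" for i in range(n_individuals)]
                   + [f"{pool_b}_{i}" for i in range(n_individuals)])
    pools = {pool_a: individuals[:n_individuals],
             pool_b: individuals[n_individuals:]}
    chrom_l, pos_l, hap_rows = [], [], []
    for chrom, length in cfg.chromosomes:
        seeds = rng.integers(1, 2**31 - 1, size=2)
        if split_time > 0:
            d = msprime.Demography()
            d.add_population(name="A", initial_size=ne)
            d.add_population(name="B", initial_size=ne)
            d.add_population(name="anc", initial_size=ne)
            d.add_population_split(time=split_time, derived=["A", "B"],
                                   ancestral="anc")
            samples = {"A": n_individuals, "B": n_individuals}
            ts = msprime.sim_ancestry(
                samples=samples, demography=d, sequence_length=length,
                recombination_rate=cfg.recombination_rate,
                random_seed=int(seeds[0]))
        else:
            ts = msprime.sim_ancestry(
                samples=2 * n_individuals, population_size=ne,
                sequence_length=length,
                recombination_rate=cfg.recombination_rate,
                random_seed=int(seeds[0]))
        mts = msprime.sim_mutations(
            ts, rate=cfg.mutation_rate, random_seed=int(seeds[1]),
            model=msprime.BinaryMutationModel(), discrete_genome=True)
        gmat = (mts.genotype_matrix() > 0).astype(np.int8)
        pos = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
        keep = np.concatenate([[True], np.diff(pos) > 0])
        chrom_l.extend([chrom] * int(keep.sum()))
        pos_l.extend((pos[keep] + 1).tolist())
        hap_rows.append(gmat[keep])
    haps = (np.vstack(hap_rows) if hap_rows
            else np.empty((0, 4 * n_individuals), dtype=np.int8))
    n = len(pos_l)
    return GenotypeTable(
        chrom=np.asarray(chrom_l, dtype=object),
        pos=np.asarray(pos_l, dtype=np.int64),
        ref=np.full(n, "A", dtype="<U1"), alt=np.full(n, "G", dtype="<U1"),
        haplotypes=haps, individuals=individuals, pools=pools,
        ancestral=np.full(n, "A", dtype="<U1"))


# ---------------------------------------------------------------------------
# Annotation layout
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    utr5_bp: int = 200
    n_exons: int = 5
    exon_bp: int = 200
    intron_bp: int = 1_500
    utr3_bp: int = 500

    @property
    def span(self) -> int:
        return (self.utr5_bp + self.n_exons * self.exon_bp
                + (self.n_exons - 1) * self.intron_bp + self.utr3_bp)


def plant_annotations(cfg: SimulationConfig,
                      gene_model: Optional[GeneModel] = None
                      ) -> Tuple[ClassRegistry, Dict]:
    """Place gene models and regulatory classes along the chromosomes.

    Genes are laid out on an even grid with jitter; each contributes UTR5 +
    exons/introns + UTR3. Regulatory elements sit on anchor points: each
    class draws a fraction ``anchor_sharing`` of its anchors from a common
    per-chromosome pool (tuning pairwise positional correlation) and the
    rest independently. ``at_tss`` classes sit at gene starts instead.
    """
    gm = gene_model or GeneModel()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    cds, utr, intron = [], [], []
    tss: Dict[str, List[int]] = {}
    shared_anchors: Dict[str, np.ndarray] = {}
    for chrom, length in cfg.chromosomes:
        n_genes = int(length * cfg.genes_per_mb / 1e6)
        tss[chrom] = []
        if n_genes > 0:
            spacing = length / n_genes
            for i in range(n_genes):
                lo = i * spacing
                hi = min((i + 1) * spacing - gm.span, length - gm.span)
                if hi <= lo:
                    continue
                start = int(rng.uniform(lo, hi))
                tss[chrom].append(start)
                cursor = start
                utr.append((chrom, cursor, cursor + gm.utr5_bp))
                cursor += gm.utr5_bp
                for e in range(gm.n_exons):
                    cds.append((chrom, cursor, cursor + gm.exon_bp))
                    cursor += gm.exon_bp
                    if e < gm.n_exons - 1:
                        intron.append((chrom, cursor, cursor + gm.intron_bp))
                        cursor += gm.intron_bp
                utr.append((chrom, cursor, cursor + gm.utr3_bp))
        n_anchor = max(int(length * cfg.anchors_per_mb / 1e6), 1)
        shared_anchors[chrom] = rng.integers(0, length, size=n_anchor)

    registry = ClassRegistry()
    registry.add("CDS", IntervalSet.from_pairs(cds), ["planted"])
    registry.add("UTR", IntervalSet.from_pairs(utr), ["planted"])
    registry.add("INTRON", IntervalSet.from_pairs(intron), ["planted"])

    for code, spec in cfg.classes.items():
        pairs = []
        for chrom, length in cfg.chromosomes:
            if spec.at_tss:
                anchors = np.asarray(tss[chrom], dtype=np.int64)
            else:
                n_el = max(int(length * spec.elements_per_mb / 1e6), 1)
                n_shared = int(round(spec.anchor_sharing * n_el))
                pool = shared_anchors[chrom]
                shared = rng.choice(pool, size=min(n_shared, len(pool)),
                                    replace=False)
                fresh = rng.integers(0, length,
                                     size=n_el - len(shared))
                anchors = np.concatenate([shared, fresh])
            half = spec.element_size // 2
            for a in anchors:
                s = max(int(a) - half, 0)
                e = min(int(a) - half + spec.element_size, length)
                if e > s:
                    pairs.append((chrom, s, e))
        registry.add(code, IntervalSet.from_pairs(pairs), ["planted"])

    truth = {"tss": tss, "shared_anchors": {c: a.tolist()
                                            for c, a in shared_anchors.items()}}
    return registry, truth


def plant_correlated_tracks(chrom: str, length: int, n_anchors: int,
                            element_size: int, sharing: float,
                            seed: int) -> Tuple[IntervalSet, IntervalSet]:
    """Two tracks whose positional correlation is tuned by anchor sharing."""
    rng = np.random.default_rng(seed)
    a_anchors = rng.integers(0, length, size=n_anchors)
    n_shared = int(round(sharing * n_anchors))
    b_anchors = np.concatenate([
        a_anchors[:n_shared],
        rng.integers(0, length, size=n_anchors - n_shared)])
    half = element_size // 2

    def build(anchors):
        return IntervalSet.from_pairs(
            (chrom, max(int(a) - half, 0),
             min(int(a) - half + element_size, length))
            for a in anchors)

    return build(a_anchors), build(b_anchors)


def generate_mask(cfg: SimulationConfig) -> IntervalSet:
    """Accessibility mask: the genome minus randomly placed inaccessible chunks."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    removed = []
    for chrom, length in cfg.chromosomes:
        n_chunks = int((1.0 - cfg.accessible_fraction) * length
                       / cfg.inaccessible_chunk_bp)
        for start in rng.integers(0, max(length - cfg.inaccessible_chunk_bp, 1),
                                  size=n_chunks):
            removed.append((chrom, int(start),
                            int(start) + cfg.inaccessible_chunk_bp))
    genome = genome_set(cfg.chrom_sizes)
    if not removed:
        return genome
    return genome - IntervalSet.from_pairs(removed)


# ---------------------------------------------------------------------------
# Selection thinning
# ---------------------------------------------------------------------------

def impose_selection(gt: GenotypeTable, registry: ClassRegistry,
                     cfg: SimulationConfig) -> Tuple[GenotypeTable, Dict]:
    """Thin variants to emulate direct and linked purifying selection.

    Retention probability r(b, k) = 1 - (1 - f(b)) * g(k) where
    f(b) = [f_inside if b is in a selected element else 1]
           * [1 - cds_edge_reduction * exp(-dist(b, CDS) / d_half)]
    and g(k) = 1 with frequency bias off (uniform thinning: diversity scales
    by f) or (1 + beta) * (k/m)^beta with bias on, removing common variants
    preferentially so that theta_pi drops more than theta_w and D goes
    negative — the signature attributed to constraint.
    """
    if gt.ancestral is None:
        raise ValueError("genotype table lacks ancestral-allele truth")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    cds = registry["CDS"] if "CDS" in registry else IntervalSet.empty()
    selected = registry.union_of([c for c in cfg.selected_classes
                                  if c in registry])
    pos0 = gt.pos - 1
    dist = np.empty(gt.n_sites, dtype=np.float64)
    in_sel = np.zeros(gt.n_sites, dtype=bool)
    for chrom in np.unique(gt.chrom):
        sel = gt.chrom == chrom
        dist[sel] = np.minimum(
            nearest_cds_distance(cds, str(chrom), pos0[sel]), 2**61)
        in_sel[sel] = selected.contains(str(chrom), pos0[sel])
    f_link = 1.0 - cfg.cds_edge_reduction * np.exp(-dist / cfg.d_half)
    f = np.where(in_sel, cfg.f_inside, 1.0) * f_link

    if cfg.freq_bias_beta > 0:
        anc_code = np.where(gt.ref == gt.ancestral, 0, 1).astype(np.int8)
        der_code = (1 - anc_code).astype(np.int8)
        ok = gt.haplotypes != MISSING
        m = ok.sum(axis=1)
        kcnt = ((gt.haplotypes == der_code[:, None]) & ok).sum(axis=1)
        g = (1.0 + cfg.freq_bias_beta) * (kcnt / np.maximum(m, 1)) ** cfg.freq_bias_beta
    else:
        g = np.ones(gt.n_sites)
    retain = np.clip(1.0 - (1.0 - f) * g, 0.0, 1.0)
    keep = rng.random(gt.n_sites) < retain
    truth = {"mean_retention": float(retain.mean()) if gt.n_sites else 1.0,
             "n_removed": int((~keep).sum()),
             "retention_inside_elements": (float(retain[in_sel].mean())
                                           if in_sel.any() else 1.0)}
    return gt.subset_sites(keep), truth


# ---------------------------------------------------------------------------
# Outgroups and fixed substitutions
# ---------------------------------------------------------------------------

def generate_outgroups(gt: GenotypeTable, cfg: SimulationConfig,
                       mask: Optional[IntervalSet] = None
                       ) -> Tuple[GenotypeTable, OutgroupAlleles, Dict]:
    """Outgroup alleles for every site plus injected human-fixed substitutions.

    Each of the three outgroups carries the true ancestral allele, flipped to
    a random other base with probability ``outgroup_error`` and missing with
    probability ``outgroup_missing``. Fixed substitutions (all human
    haplotypes derived, outgroups ancestral) are injected uniformly at
    ``substitution_rate`` per accessible base; their positions are the truth
    for MK validation.
    """
    if gt.ancestral is None:
        raise ValueError("genotype table lacks ancestral-allele truth")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    existing = {(c, int(p)) for c, p in zip(gt.chrom, gt.pos)}

    sub_chrom, sub_pos, sub_ref, sub_alt, sub_anc = [], [], [], [], []
    space = (mask if mask is not None else genome_set(cfg.chrom_sizes))
    for chrom, _length in cfg.chromosomes:
        ivals = space.intervals(chrom)
        if ivals.shape[0] == 0:
            continue
        acc_len = int((ivals[:, 1] - ivals[:, 0]).sum())
        n_sub = rng.poisson(cfg.substitution_rate * acc_len)
        # uniform over accessible bases via the coverage inverse
        offsets = np.sort(rng.choice(acc_len, size=min(n_sub, acc_len),
                                     replace=False))
        cum = np.concatenate([[0], np.cumsum(ivals[:, 1] - ivals[:, 0])])
        iv = np.searchsorted(cum, offsets, side="right") - 1
        positions = ivals[iv, 0] + (offsets - cum[iv])
        for p in positions:
            pos1 = int(p) + 1
            if (chrom, pos1) in existing:
                continue
            anc = _BASES[rng.integers(4)]
            der = _BASES[(np.flatnonzero(_BASES != anc))[rng.integers(3)]]
            sub_chrom.append(chrom)
            sub_pos.append(pos1)
            sub_ref.append(anc)   # fixed non-reference: ref = ancestral
            sub_alt.append(der)
            sub_anc.append(anc)

    n_sub = len(sub_pos)
    if n_sub:
        sub_haps = np.ones((n_sub, gt.n_haplotypes), dtype=np.int8)
        gt2 = GenotypeTable(
            chrom=np.concatenate([gt.chrom, np.asarray(sub_chrom, object)]),
            pos=np.concatenate([gt.pos, np.asarray(sub_pos, np.int64)]),
            ref=np.concatenate([gt.ref, np.asarray(sub_ref, "<U1")]),
            alt=np.concatenate([gt.alt, np.asarray(sub_alt, "<U1")]),
            haplotypes=np.vstack([gt.haplotypes, sub_haps]),
            individuals=list(gt.individuals), pools=dict(gt.pools),
            ancestral=np.concatenate([gt.ancestral,
                                      np.asarray(sub_anc, "<U1")]))
    else:
        gt2 = gt

    # outgroup alleles aligned to the augmented table
    n_sites = gt2.n_sites
    alleles = np.repeat(gt2.ancestral[:, None], 3, axis=1).astype("<U1")
    if cfg.outgroup_error > 0:
        err = rng.random((n_sites, 3)) < cfg.outgroup_error
        for i, j in zip(*np.nonzero(err)):
            others = _BASES[_BASES != gt2.ancestral[i]]
            alleles[i, j] = others[rng.integers(3)]
    if cfg.outgroup_missing > 0:
        miss = rng.random((n_sites, 3)) < cfg.outgroup_missing
        alleles[miss] = "."
    og = OutgroupAlleles(chrom=gt2.chrom.copy(), pos=gt2.pos.copy(),
                         alleles=alleles)
    truth = {"n_injected_substitutions": n_sub,
             "substitution_sites": list(zip(sub_chrom, sub_pos))}
    return gt2, og, truth


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    genotypes: GenotypeTable
    outgroups: OutgroupAlleles
    registry: ClassRegistry
    mask: IntervalSet
    chrom_sizes: Dict[str, int]
    truth: Dict


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full generator pipeline: pools -> annotations -> selection -> outgroups."""
    gt, truth_pools = simulate_pools(cfg)
    registry, truth_ann = plant_annotations(cfg)
    mask = generate_mask(cfg)
    gt, truth_sel = impose_selection(gt, registry, cfg)
    gt, og, truth_out = generate_outgroups(gt, cfg, mask=mask)
    return SyntheticDataset(
        genotypes=gt, outgroups=og, registry=registry, mask=mask,
        chrom_sizes=cfg.chrom_sizes,
        truth={"pools": truth_pools, "annotations": truth_ann,
               "selection": truth_sel, "outgroups": truth_out})
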