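"""Reading and validating variant, interval, mask and outgroup inputs.

Variants are loaded from VCF into a compact haplotype matrix; only biallelic
autosomal-style SNPs are kept, and everything excluded is counted in a load
report. Ancestral/derived polarity is assigned by comparing the two human
alleles against three primate outgroup alleles with a configurable consensus
rule. All internal arithmetic is 0-based half-open; VCF positions (1-based)
and BED records are converted at this boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .intervals import IntervalSet

MISSING = -1

# polarity_status codes
POLARIZED = 0
UNPOLARIZABLE = 1
NO_OUTGROUP = 2

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class LoadReport:
    """Counts of records kept/excluded while reading a VCF."""
    n_kept: int = 0
    excluded: Dict[str, int] = field(default_factory=dict)

    def count(self, reason: str) -> None:
        self.excluded[reason] = self.excluded.get(reason, 0) + 1


@dataclass
class GenotypeTable:
    """Biallelic variant sites x haplotypes for one or more sample pools.

    ``haplotypes`` holds allele indices (0 = ref, 1 = alt, -1 = missing) with
    shape (n_sites, 2 * n_individuals); haplotype columns 2i and 2i+1 belong
    to individual ``individuals[i]``. Positions are 1-based and strictly
    increasing within a chromosome.
    """
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    individuals: List[str]
    pools: Dict[str, List[str]]
    ancestral: Optional[np.ndarray] = None  # known truth in synthetic data
    load_report: Optional[LoadReport] = None

    def __post_init__(self):
        self._sort()
        self._validate()

    def _sort(self) -> None:
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            for name in ("chrom", "pos", "ref", "alt"):
                setattr(self, name, getattr(self, name)[order])
            self.haplotypes = self.haplotypes[order]
            if self.ancestral is not None:
                self.ancestral = self.ancestral[order]

    def _validate(self) -> None:
        if self.haplotypes.shape != (len(self.pos), 2 * len(self.individuals)):
            raise ValueError("haplotype matrix shape mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"duplicate or unsorted positions on {c}")
        listed = {i for ids in self.pools.values() for i in ids}
        missing = listed - set(self.individuals)
        if missing:
            raise ValueError(f"pool individuals not in table: {sorted(missing)}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def pool_columns(self, pool: str) -> np.ndarray:
        """Haplotype column indices belonging to a pool."""
        idx = {name: i for i, name in enumerate(self.individuals)}
        cols = []
        for ind in self.pools[pool]:
            i = idx[ind]
            cols.extend((2 * i, 2 * i + 1))
        return np.asarray(cols, dtype=np.int64)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            chrom=self.chrom[keep], pos=self.pos[keep], ref=self.ref[keep],
            alt=self.alt[keep], haplotypes=self.haplotypes[keep],
            individuals=list(self.individuals), pools=dict(self.pools),
            ancestral=None if self.ancestral is None else self.ancestral[keep],
            load_report=self.load_report)


@dataclass
class OutgroupAlleles:
    """Per-site alleles for three outgroups ('.' = missing), 1-based positions."""
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray  # (n_sites, 3) of single characters

    def __post_init__(self):
        key = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if len(set(key)) != len(key):
            raise ValueError("duplicate outgroup records for a site")


@dataclass
class PolarizedSiteTable:
    """Per-site derived-allele counts after outgroup polarization.

    ``derived``/``called`` have one column per pool (order = ``pools``).
    For unpolarizable sites the alt allele stands in as "derived"; this is
    harmless for frequency-symmetric statistics and such sites are excluded
    from derived-allele analyses via ``status``.
    """
    chrom: np.ndarray
    pos: np.ndarray
    pools: List[str]
    derived: np.ndarray
    called: np.ndarray
    status: np.ndarray
    is_fixed_substitution: np.ndarray

    def __post_init__(self):
        if np.any(self.derived > self.called) or np.any(self.derived < 0):
            raise ValueError("derived counts outside [0, called]")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pool_index(self, pool: str) -> int:
        return self.pools.index(pool)

    def region_mask(self, region: IntervalSet) -> np.ndarray:
        """Boolean site mask for membership of a region (positions 1-based)."""
        out = np.zeros(self.n_sites, dtype=bool)
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            out[sel] = region.contains(str(c), self.pos[sel] - 1)
        return out

    def combined(self) -> tuple:
        """Summed derived and called counts across all pools."""
        return self.derived.sum(axis=1), self.called.sum(axis=1)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(vcf_path, pool_spec: Mapping[str, Sequence[str]],
                  chroms: Optional[Sequence[str]] = None,
                  min_call_rate: float = 0.8) -> GenotypeTable:
    """Load biallelic SNPs from a VCF for the individuals named in pool_spec.

    Indels, multiallelic records and sites with a haplotype call rate below
    ``min_call_rate`` are excluded and counted in the load report.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    wanted = [ind for ids in pool_spec.values() for ind in ids]
    missing = [ind for ind in wanted if ind not in samples]
    if missing:
        raise ValueError(f"individuals not present in VCF: {missing}")
    col_of = {s: i for i, s in enumerate(samples)}
    take = [col_of[ind] for ind in wanted]

    report = LoadReport()
    chrom_l, pos_l, ref_l, alt_l, hap_l = [], [], [], [], []
    chrom_filter = set(chroms) if chroms is not None else None
    for i, v in enumerate(vcf):
        if chrom_filter is not None and v.CHROM not in chrom_filter:
            report.count("off_target_chrom")
            continue
        if len(v.ALT) != 1:
            report.count("multiallelic")
            continue
        if not v.is_snp:
            report.count("indel" if v.is_indel else "other")
            continue
        gts = np.array(v.genotypes, dtype=object)
        try:
            haps = np.array([[g[0], g[1]] for g in gts], dtype=np.int64)
        except (IndexError, TypeError) as exc:
            raise ValueError(f"malformed genotype record at line ~{i + 1}: {exc}")
        haps = haps[take].reshape(-1)
        haps = np.where(haps < 0, MISSING, haps).astype(np.int8)
        if (haps != MISSING).mean() < min_call_rate:
            report.count("low_call_rate")
            continue
        chrom_l.append(v.CHROM)
        pos_l.append(v.POS)
        ref_l.append(v.REF)
        alt_l.append(v.ALT[0])
        hap_l.append(haps)
    report.n_kept = len(pos_l)

    n_hap = 2 * len(wanted)
    table = GenotypeTable(
        chrom=np.asarray(chrom_l, dtype=object),
        pos=np.asarray(pos_l, dtype=np.int64),
        ref=np.asarray(ref_l, dtype="<U1"),
        alt=np.asarray(alt_l, dtype="<U1"),
        haplotypes=(np.asarray(hap_l, dtype=np.int8).reshape(-1, n_hap)
                    if hap_l else np.empty((0, n_hap), dtype=np.int8)),
        individuals=wanted,
        pools={p: list(ids) for p, ids in pool_spec.items()},
        load_report=report)
    return table


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a minimal phased VCF (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(gt.chrom.tolist())):
            cmax = int(gt.pos[gt.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={cmax}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.individuals) + "\n")
        for i in range(gt.n_sites):
            haps = gt.haplotypes[i]
            calls = "\t".join(
                f"{_gtstr(haps[2 * j])}|{_gtstr(haps[2 * j + 1])}"
                for j in range(len(gt.individuals)))
            fh.write(f"{gt.chrom[i]}\t{gt.pos[i]}\t.\t{gt.ref[i]}\t{gt.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def _gtstr(a: int) -> str:
    return "." if a == MISSING else str(int(a))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_intervals(bed_path) -> IntervalSet:
    """Read a 3+ column BED file into a normalized IntervalSet."""
    pairs = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{bed_path}:{lineno}: end {end} <= start {start}")
            pairs.append((chrom, start, end))
    return IntervalSet.from_pairs(pairs)


def write_intervals(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in iset:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Outgroup tables
# ---------------------------------------------------------------------------

def read_outgroups(path) -> OutgroupAlleles:
    """Tabular per-site outgroup alleles: chrom, pos(1-based), a1, a2, a3."""
    chrom_l, pos_l, al_l = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: need 5 columns")
            chrom_l.append(fields[0])
            pos_l.append(int(fields[1]))
            al_l.append(fields[2:5])
    return OutgroupAlleles(
        chrom=np.asarray(chrom_l, dtype=object),
        pos=np.asarray(pos_l, dtype=np.int64),
        alleles=np.asarray(al_l, dtype="<U1") if al_l else np.empty((0, 3), "<U1"))


def write_outgroups(og: OutgroupAlleles, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\toutgroup1\toutgroup2\toutgroup3\n")
        for i in range(len(og.pos)):
            fh.write(f"{og.chrom[i]}\t{og.pos[i]}\t"
                     + "\t".join(og.alleles[i]) + "\n")


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def _align_outgroups(gt: GenotypeTable, og: OutgroupAlleles) -> np.ndarray:
    """Outgroup alleles aligned to gt's sites; '.' where no record exists."""
    out = np.full((gt.n_sites, 3), ".", dtype="<U1")
    og_key = {(c, int(p)): i for i, (c, p) in enumerate(zip(og.chrom, og.pos))}
    for i in range(gt.n_sites):
        j = og_key.get((gt.chrom[i], int(gt.pos[i])))
        if j is not None:
            out[i] = og.alleles[j]
    return out


def _pool_counts(gt: GenotypeTable, derived_code: np.ndarray):
    """Per-pool derived and called haplotype counts (derived_code per site)."""
    pools = list(gt.pools)
    derived = np.zeros((gt.n_sites, len(pools)), dtype=np.int32)
    called = np.zeros((gt.n_sites, len(pools)), dtype=np.int32)
    for pi, pool in enumerate(pools):
        cols = gt.pool_columns(pool)
        haps = gt.haplotypes[:, cols]
        ok = haps != MISSING
        called[:, pi] = ok.sum(axis=1)
        derived[:, pi] = ((haps == derived_code[:, None]) & ok).sum(axis=1)
    return pools, derived, called


def polarize(gt: GenotypeTable, og: OutgroupAlleles,
             min_agree: int = 2) -> PolarizedSiteTable:
    """Assign ancestral/derived state per site from the outgroup consensus.

    A site is polarized iff at least ``min_agree`` non-missing outgroup
    alleles agree AND that consensus equals one of the two human alleles;
    the derived allele is then the other human allele. Sites with no
    outgroup record are NO_OUTGROUP; consensus failures or a consensus
    matching neither human allele are UNPOLARIZABLE.
    """
    aligned = _align_outgroups(gt, og)
    counts = np.stack([(aligned == b).sum(axis=1) for b in _BASES], axis=1)
    n_called = (aligned != ".").sum(axis=1)
    top = counts.max(axis=1)
    cons_base = _BASES[counts.argmax(axis=1)]
    has_consensus = top >= min_agree
    status = np.full(gt.n_sites, UNPOLARIZABLE, dtype=np.int8)
    status[n_called == 0] = NO_OUTGROUP
    cons_is_ref = has_consensus & (cons_base == gt.ref)
    cons_is_alt = has_consensus & (cons_base == gt.alt)
    status[cons_is_ref | cons_is_alt] = POLARIZED
    derived_code = np.ones(gt.n_sites, dtype=np.int8)  # default: alt stands in
    derived_code[cons_is_alt] = 0

    pools, derived, called = _pool_counts(gt, derived_code)
    return PolarizedSiteTable(
        chrom=gt.chrom.copy(), pos=gt.pos.copy(), pools=pools,
        derived=derived, called=called, status=status,
        is_fixed_substitution=np.zeros(gt.n_sites, dtype=bool))


def call_substitutions(gt: GenotypeTable, og: OutgroupAlleles,
                       mask: IntervalSet,
                       min_agree: int = 2) -> PolarizedSiteTable:
    """Polarize and flag fixed human-lineage substitutions.

    A site is a fixed substitution when it lies in accessible sequence, is
    polarized, and every called haplotype in the combined sample carries the
    derived allele.
    """
    table = polarize(gt, og, min_agree=min_agree)
    derived_all, called_all = table.combined()
    in_mask = table.region_mask(mask)
    fixed = (in_mask
             & (table.status == POLARIZED)
             & (called_all > 0)
             & (derived_all == called_all))
    table.is_fixed_substitution = fixed
    return table
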