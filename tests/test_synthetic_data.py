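"""Determinism, selection-thinning and outgroup contracts of the generator."""

import dataclasses

import numpy as np
import pytest

from regsel.genomic_io import POLARIZED, call_substitutions, polarize
from regsel.interval_ops import build_distance_bins
from regsel.intervals import IntervalSet, genome_set
from regsel.synthetic_data import (ClassSpec, SimulationConfig, generate_mask,
                                   generate_outgroups, impose_selection,
                                   plant_annotations, simulate_dataset,
                                   simulate_pools)

SMALL = SimulationConfig(seed=5, chromosomes=(("chr1", 1_000_000),))


class TestDeterminism:
    def test_same_seed_identical_output(self, tmp_path):
        from regsel.genomic_io import write_vcf

        a = simulate_dataset(SMALL)
        b = simulate_dataset(SMALL)
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(a.genotypes, pa)
        write_vcf(b.genotypes, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.mask == b.mask
        assert np.array_equal(a.outgroups.alleles, b.outgroups.alleles)

    def test_different_seed_differs(self):
        a, _ = simulate_pools(SMALL)
        b, _ = simulate_pools(dataclasses.replace(SMALL, seed=6))
        assert a.n_sites != b.n_sites or not np.array_equal(a.pos, b.pos)


class TestSimulatePools:
    def test_pool_structure(self):
        gt, _ = simulate_pools(SMALL)
        assert set(gt.pools) == {"AFR", "NAFR"}
        assert all(len(ids) == 9 for ids in gt.pools.values())
        assert gt.n_haplotypes == 36
        assert gt.ancestral is not None

    def test_positions_strictly_increasing(self):
        gt, _ = simulate_pools(SMALL)
        assert np.all(np.diff(gt.pos) > 0)


class TestPlantAnnotations:
    def test_gene_classes_disjoint(self):
        reg, _ = plant_annotations(SMALL)
        assert (reg["CDS"] & reg["UTR"]).total_length == 0
        assert (reg["CDS"] & reg["INTRON"]).total_length == 0

    def test_no_genes_empty_distance_bins(self):
        cfg = dataclasses.replace(SMALL, genes_per_mb=0.0)
        reg, _ = plant_annotations(cfg)
        assert reg["CDS"].total_length == 0
        bins = build_distance_bins(reg["CDS"], cfg.chrom_sizes)
        assert all(b.total_length == 0 for b in bins.bins)

    def test_promoters_at_tss(self):
        reg, truth = plant_annotations(SMALL)
        tss = truth["tss"]["chr1"]
        prom = reg["PROMOTER"]
        hits = prom.contains("chr1", np.asarray(tss))
        assert hits.mean() > 0.9  # merged elements may shift a boundary


class TestImposeSelection:
    def test_no_reduction_identity(self):
        gt, _ = simulate_pools(SMALL)
        reg, _ = plant_annotations(SMALL)
        cfg = dataclasses.replace(SMALL, f_inside=1.0, cds_edge_reduction=0.0)
        out, truth = impose_selection(gt, reg, cfg)
        assert out.n_sites == gt.n_sites
        assert truth["n_removed"] == 0

    def test_thinning_reduces_inside_elements(self):
        cfg = dataclasses.replace(SMALL, chromosomes=(("chr1", 4_000_000),),
                                  f_inside=0.5, cds_edge_reduction=0.0,
                                  genes_per_mb=0.0)
        gt, _ = simulate_pools(cfg)
        reg, _ = plant_annotations(cfg)
        out, truth = impose_selection(gt, reg, cfg)
        sel = reg.union_of(cfg.selected_classes)
        before = sel.contains("chr1", gt.pos - 1).sum()
        after = sel.contains("chr1", out.pos - 1).sum()
        assert 0.35 < after / before < 0.65
        assert truth["retention_inside_elements"] == pytest.approx(0.5, abs=0.01)

    def test_frequency_bias_skews_sfs_negative(self):
        """Preferential removal of common variants lowers D inside elements."""
        from regsel.sfs_stats import summarize_region

        from regsel.synthetic_data import PoolSpec

        cfg = dataclasses.replace(
            SMALL, chromosomes=(("chr1", 6_000_000),), genes_per_mb=0.0,
            f_inside=0.5, cds_edge_reduction=0.0, freq_bias_beta=2.0,
            substitution_rate=0.0, pools={"AFR": PoolSpec(9, "constant")})
        gt, _ = simulate_pools(cfg)
        reg, _ = plant_annotations(cfg)
        out, _ = impose_selection(gt, reg, cfg)
        sel = reg.union_of(cfg.selected_classes)
        genome = genome_set(cfg.chrom_sizes)
        neutral = genome - sel
        _, og, _ = generate_outgroups(out, cfg)
        sites = polarize(out, og)
        d_in = summarize_region(sites, sel, genome, "AFR").tajimas_d
        d_out = summarize_region(sites, neutral, genome, "AFR").tajimas_d
        assert d_in < d_out


class TestGenerateOutgroups:
    def test_zero_error_full_recovery(self):
        cfg = dataclasses.replace(SMALL, outgroup_error=0.0,
                                  outgroup_missing=0.0, substitution_rate=0.0)
        gt, _ = simulate_pools(cfg)
        gt2, og, _ = generate_outgroups(gt, cfg)
        t = polarize(gt2, og)
        assert np.all(t.status == POLARIZED)
        # derived allele is the true derived allele at every site
        anc_is_ref = gt2.ref == gt2.ancestral
        derived, called = t.combined()
        ok = gt2.haplotypes >= 0
        true_derived = np.where(
            anc_is_ref[:, None], gt2.haplotypes == 1, gt2.haplotypes == 0)
        assert np.array_equal(derived, (true_derived & ok).sum(axis=1))

    def test_injected_substitutions_recovered_exactly(self):
        cfg = dataclasses.replace(SMALL, outgroup_error=0.0,
                                  outgroup_missing=0.0)
        gt, _ = simulate_pools(cfg)
        mask = generate_mask(cfg)
        gt2, og, truth = generate_outgroups(gt, cfg, mask=mask)
        t = call_substitutions(gt2, og, mask)
        assert int(t.is_fixed_substitution.sum()) == \
            truth["n_injected_substitutions"]

    def test_outgroup_disagreement_reduces_polarized_fraction(self):
        cfg = dataclasses.replace(SMALL, outgroup_error=0.05,
                                  outgroup_missing=0.0, substitution_rate=0.0)
        gt, _ = simulate_pools(cfg)
        gt2, og, _ = generate_outgroups(gt, cfg)
        t = polarize(gt2, og)
        frac = (t.status == POLARIZED).mean()
        # P(>=2 of 3 outgroups wrong) ~ 3*e^2 = 0.0075; binomial band around it
        expected = 1 - (3 * 0.05**2 * 0.95 + 0.05**3)
        se = np.sqrt(expected * (1 - expected) / t.n_sites)
        assert abs(frac - expected) < 6 * se + 0.005

    def test_mask_round_trip_files(self, tmp_path, small_dataset):
        """Generated tracks survive a BED round trip bit-for-bit."""
        from regsel.genomic_io import read_intervals, write_intervals

        for code in small_dataset.registry.codes:
            p = tmp_path / f"{code}.bed"
            write_intervals(small_dataset.registry[code], p)
            assert read_intervals(p) == small_dataset.registry[code]
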