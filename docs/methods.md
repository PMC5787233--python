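# Methods

## Statistical model

The package treats a selection scan as a comparison of site-frequency-
spectrum (SFS) summaries between genomic strata. For a stratum (an
annotation class, optionally intersected with a distance-from-CDS bin and
always intersected with the accessibility mask) and a sample pool of n
haplotypes:

- per-site heterozygosity 2k(m−k)/(m(m−1)) is summed over variant sites
  (k = derived count, m = called haplotypes at the site) and divided by the
  accessible length L to give θ_π. The term is symmetric under k ↔ m−k, so
  θ_π, θ_w and Tajima's D need only the minor/major split and are computed
  over all usable sites whether or not outgroup polarization succeeded;
- θ_w = S/(a₁L) with a₁ the (n−1)-th harmonic number;
- Tajima's D uses the full constant set of the classical test. Under
  missingness, per-site m varies; D's constants are evaluated at the modal
  m of the stratum and its S/π inputs are restricted to sites with that m
  (sites at other m are excluded from D rather than rescaled), keeping the
  variance constants well defined. θ_π and θ_w use all sites with m ≥ 2.
  D is undefined (NaN, reported as missing, never as 0) when S = 0.

### Block jackknife

SEs come from a weighted delete-one block jackknife (Busing, Meijer &
van der Leeden 1999): the genome is tiled into consecutive fixed blocks
(default 5 Mb) from each chromosome start; block j is removed, the
statistic recomputed, and pseudovalues combined with weights w_j equal to
the accessible bases the block contributes to the stratum. Blocks with
w_j = 0 are skipped; blocks whose deletion leaves D undefined are excluded.
The reported point estimate is the whole-stratum estimate; the 95% CI is
±1.96 SE. With fewer than two contributing blocks the SE is NaN and the
record is flagged. A fast path accumulates per-block sufficient statistics
(S, Σhet, L) once and forms each delete-one value by subtraction; it is
tested for exact equality against the generic recompute-everything path.

The jackknife assumes blocks are approximately independent. Validation
therefore uses replicate genomes built from independent 1 Mb chromosomes
with jackknife blocks equal to chromosomes; there the SE matches the
across-replicate SD within a few percent and 95% CI coverage is ~92%. On a
single contiguous 10 Mb chromosome, linkage between adjacent 1 Mb blocks
makes the jackknife SE ~10–15% anticonservative — at real-genome scale
(5 Mb blocks, ~550 blocks) the effect is far weaker, but it is the reason
the calibration suite uses independent-block genomes.

### Neutral reference and Z-test

The selection-neutral reference is the genome minus every annotation
class, minus CDS widened by 200 kb on both sides (configurable), clipped
to chromosome bounds. The two-sample Z-score
(θ̂_C − θ̂_ref)/√(SE_C² + SE_ref²) is thresholded at |Z| > 1.96; scores with
|Z| > 2 are flagged as beyond the range where the normal approximation
maps onto p-values, and no multiple-testing correction is applied — Z is
an effect-size-like measure here, not a calibrated p-value, and is
reported raw. Within-bin comparisons use the identical machinery with both
strata intersected with the same distance bin.

### Distance bins

Distance is physical (bp): d(b) = min over CDS bases c of |b − c|. Bin k
is the half-open range (edges[k−1], edges[k]] with default edges 2.5, 5,
7.5, 10, 25, 50, 75, 100 kb — a base exactly 2500 bp from CDS falls in the
first bin. Bins are realized exactly as nested expansions,
bin_k = expand(CDS, e_k) − expand(CDS, e_{k−1}), verified against a
per-base brute-force scan in the tests. CDS bases belong to no bin;
annotation classes are binned over their non-CDS extent per base (an
element straddling a bin boundary contributes each base to its own bin —
the alternative of assigning whole elements by a representative point is
not used). A catch-all stratum beyond the last edge is retained.

### MK neutrality index

NI = (Pn/Ps)/(Dn/Ds). Polymorphisms are combined-sample segregating sites
in accessible sequence; substitutions are accessible sites where every
called haplotype carries the derived allele relative to the outgroup
consensus. NI is defined only when Ps, Dn, Ds > 0; undefined records are
flagged, not dropped silently. NI < 1 is read as a deficit of polymorphism
consistent with constraint; it is reported, never asserted.

### Polarization

Ancestral state is the allele carried by ≥ 2 of 3 non-missing outgroups
that also matches one of the two human alleles; the derived allele is the
other human allele. Failures are classified unpolarizable (consensus
absent or matching neither human allele) or no-outgroup; the three
statuses partition all sites. The threshold is configurable. For
frequency-symmetric statistics, unpolarizable sites still contribute via
their alt-allele counts.

### F_ST

The pool-homogeneity screen uses the Weir–Cockerham (1984) two-population
variance-components estimator, combining per-site components a, b, c as a
ratio of sums across sites. Individuals with a missing haplotype are
excluded per site; sites monomorphic in the combined pair contribute
nothing; the estimate can be slightly negative by construction.

### Positional correlation

Each class is reduced to counts of annotated bases in windows of w bp
(default 10 kb; 5 and 15 kb for robustness checks) advanced by 1.5 kb.
Pearson r is computed across windows per class pair; zero-variance classes
are flagged and dropped. Classes are ordered by agglomerative hierarchical
clustering with Ward linkage on dissimilarity 1 − r (the conventional
choice; the clustering method itself does not prescribe one). Overlapping
windows induce autocorrelation, so r is descriptive and no significance is
attached.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the mechanism that produces it in real genomes.

**Demography.** Single-population msprime models, mutation rate
1.25e-8/bp/gen, recombination 1e-8:

| preset | history | measured θ_π/site | measured D (n=18) |
|---|---|---|---|
| constant | Ne = 20 000 | 0.00100 | ≈ 0 |
| expansion | Ne 175 000 now, 17 500 before gen 5 000 | 0.00100 | ≈ −0.62 |
| bottleneck | Ne 20 000 now, 1 500 during gen 2 000–3 000, 17 500 before | 0.00066 | ≈ +0.35 |

The expansion preset is tuned so mean pairwise TMRCA gives the 0.001/site
neutral diversity of an African-like pool; the bottleneck preset gives the
reduced diversity and positive D of a non-African-like pool. Pools are
simulated independently (no shared ancestry, no migration): a site
segregating in one pool is ancestral-monomorphic in the others. This
preserves each pool's marginal SFS — all that the statistics consume — but
carries no cross-pool covariance; the F_ST screen therefore uses a
dedicated two-population split model (`simulate_split_pools`).

**Annotation geometry.** Genes (UTR5 200 bp, 5 × 200 bp exons, 1.5 kb
introns, UTR3 500 bp) are placed on an even grid with jitter, default 3
genes/Mb (higher densities are used in profile validation to concentrate
distance-bin mass). Regulatory classes sit on anchor points; each class
draws a fraction `anchor_sharing` of anchors from a common per-chromosome
pool, which tunes pairwise window correlation from ~0 (sharing 0) to ~1
(sharing 1). Promoters anchor at gene starts.

**Selection.** Variants are thinned with retention probability
r(b, k) = 1 − (1 − f(b))·g(k), where f(b) multiplies an inside-element
factor (f_inside, default 0.5) and a linked-selection factor
1 − A·exp(−d(b, CDS)/d_half) with A = 0.5 and d_half = 5 kb. With the
frequency bias off, g ≡ 1 and diversity scales by exactly f in
expectation (the basis of the thinning acceptance check); with bias
β > 0, g(k) = (1+β)(k/m)^β removes common variants preferentially,
lowering θ_π more than θ_w and driving D negative, the direction real
constraint produces. Thinning is post-hoc: it reproduces the SFS
signatures the statistics see, but not linkage disequilibrium between the
selected site and its neighbours, nor any interference between selected
sites — patterns at that level are outside what passing tests demonstrate
about real data.

**Outgroups and substitutions.** Each of three outgroups carries the true
ancestral allele with per-outgroup error (default 1%) and missingness
(2%). Fixed human-lineage substitutions are injected uniformly over
accessible sequence at 3e-4/bp — a desk-scale stand-in (the human-specific
fixed-derived density is nearer 3–4e-3/bp); outgroup divergence is a free
parameter and MK validation compares against the injected truth counts,
not against real primate divergence. The human reference allele is drawn
as the ancestral allele with probability 0.95, so polarization is
exercised against reference/derived swaps.

**Accessibility.** The mask removes random 2 kb chunks totalling 10% of
the genome.

## Validation design and problem sizes

The test suite validates at desk scale: calibration uses 10 × 1 Mb
independent-chromosome genomes (100 replicates for neutrality, 150 for the
SE/SD comparison, 200 scaled 10 × 0.5 Mb replicates for CI coverage), sign
recovery 50 replicates per demography, the linked-selection profile one
100 Mb genome at 8 genes/Mb plus ten 10 Mb replicates for bin-1 power, and
the MK neutral calibration 200 × 1 Mb replicates. The neutral-reference
distance is lowered (50 kb) in small-genome end-to-end runs so that a
non-empty reference exists; at these gene densities the linked-selection
decay (d_half 5 kb) is negligible beyond ~25 kb, which the profile checks
confirm.

## Numerical and edge-case choices

- Coordinates are 0-based half-open internally; VCF (1-based) and BED are
  converted at the I/O boundary only. Bookended intervals merge, since an
  interval set is treated as a set of bases throughout.
- Sites with haplotype call rate below 0.8 (configurable) are dropped at
  load and counted in the load report, alongside indels and multiallelics.
- Empty strata raise on direct summarization and are flagged (not fatal)
  in pipeline tables; zero-weight jackknife blocks never affect estimates.
- Ties in the outgroup consensus cannot satisfy the default ≥ 2-of-3 rule
  and yield unpolarizable; with min_agree = 1 the first-ranked base wins,
  so thresholds below 2 are not recommended.
- Same seed + config → byte-identical outputs; every stochastic component
  derives its stream from the single configuration seed.

## Known limitations

- Pools lack shared ancestry and migration; cross-pool statistics other
  than F_ST (which has its own model) should not be read off the default
  generator.
- Thinning-based selection produces no LD footprint and no interference;
  the generator validates SFS-level inference only.
- The jackknife is mildly anticonservative when blocks are few and
  linked (see above).
- The MK implementation counts sites, not mutational opportunities; it
  matches the modified test it implements, not a codon-aware MK table.
- No liftover, no strand awareness, no GFF parsing: interval inputs are
  BED3 already projected to the analysis assembly.
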