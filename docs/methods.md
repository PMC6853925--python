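# Methods

This note records the statistical models, conventions and deliberate design
choices behind `selsweep`, in the spirit of the methods documentation of
mature population-genetics packages.

## Coordinates and containers

VCF positions are 1-based; every internal window and interval computation is
0-based half-open, with conversion only at I/O boundaries. The central
container, `GenotypePanel`, holds biallelic SNPs only: multiallelic and
non-SNP records are dropped at read time (counted in the log) rather than
split, because splitting would add allele-pairing semantics the downstream
statistics never use. Genotypes are alt-dosages 0/1/2 with −1 for missing;
when all GT fields are phased the haplotype matrix is retained, and every
haplotype-based statistic requires it (an optional seeded pseudo-phasing of
heterozygotes exists for unphased input, but it carries no LD model and is
off by default).

## Hard site filters

Sites pass when QD ≥ 5.0, MQ ≥ 40.0, FS ≤ 200.0, QUAL ≥ 30.0, call rate ≥ 0.9
and MAF > 0.01. Conventions the thresholds alone do not pin down:

- a missing INFO annotation passes its sub-filter — an uncalled metric is not
  evidence of failure (it is logged);
- MAF and call rate are computed over all samples pooled, missing alleles
  excluded from the denominator; a per-population mode is exposed
  (`FilterConfig.per_population`) because the filtering scope is a genuine
  open choice for multi-breed panels;
- filters are conjunctive per site, so filtering is idempotent and
  order-independent.

## Site statistics

Transitions are A↔G and C↔T; everything else is a transversion; a panel with
zero transversions reports the ratio as NaN, never +inf. A site is *fixed*
in a population only when every sample is called and homozygous-alt — a
strict complete-case reading; sites hom-alt in all called samples but with
missing calls are excluded (and logged). Per-site nucleotide diversity uses
the unbiased pairwise estimator 2·n_ref·n_alt/(n·(n−1)); window pi divides by
the full window length including invariant sequence (the convention of the
standard VCF tooling), and the mean diversity weights windows by their
length, so a truncated terminal window is not over-counted.

## ZHp

Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)², summing major/minor allele counts over
the SNPs of a window. Defaults: 150 kb windows, 50% overlap, windows anchored
at position 0 of each contig, within-population MAF ≥ 0.05 site filter,
windows with fewer than 10 SNPs dropped. A final truncated window is emitted
when uncovered sequence remains at a contig end. On a ref/alt count tie the
reference allele is called major; Hp is symmetric in its two sums, so the
tie-break cannot change it. The Z-transformation uses the sample standard
deviation (ddof = 1) over all retained windows genome-wide and refuses
degenerate input (all Hp equal). Candidate windows have ZHp strictly below
−3.5 by default; the threshold is a parameter because published analyses
have used both −3.5 and |Z| = 3.

## XP-EHH

EHH from a core SNP is the probability that two random haplotypes are
identical over every marker from the core out to distance x, computed by
grouping haplotypes on their allele strings and summing C(n_g,2)/C(n,2).
The curve starts at 1.0 at distance zero; from the first flanking marker
onward the grouping includes the core SNP's own allele, i.e. the probability
of being homozygous at *all* SNPs in [core..x] — the canonical
cross-population convention (allele-stratified, iHS-style EHH is deliberately
not used). Note the consequence: EHH can step well below 1 already at the
first flanking marker, and a monomorphic marker can never split groups
(asserted by test), but inserting one still adds a knot to the
piecewise-linear curve, so the trapezoid area is not exactly knot-invariant;
that is a property of trapezoidal integration, not of EHH.

iHH is the trapezoid area under EHH versus physical distance (no genetic
map is used), both directions summed. Integration proceeds out to and
including the first marker where EHH drops below the cutoff (0.05); the
worked triangle example (EHH falling linearly 1→0 over 1 kb ⇒ side area 500)
fixes this convention — no partial segment beyond that marker and no
interpolated crossing point. For XP-EHH the stop marker per side is set by
the *pooled* two-population EHH, so both populations are integrated over
identical bounds; cores whose walk runs off the end of the data before the
pooled EHH falls below the cutoff are flagged truncated and excluded from
the z-normalization by default (truncated areas bias the ratio towards the
contig interior). raw = ln(iHH_obs/iHH_ref) is left NaN when either area is
zero. The normalization is a plain z-score (ddof = 1) over scored cores.

Two engines implement the identical walk — a numba-compiled kernel (default;
needed for the multi-megabase neutral control) and a pure-Python reference —
and the test suite asserts they agree exactly on a shared panel, keeping the
fast path honest against the readable one.

## Window significance

50 kb non-overlapping windows; each window's summary is the literal maximum
of the normalized scores of its SNPs (so an all-negative window is
summarised by its least-negative score; a positive-only mode is available,
in which windows without a positive score are dropped). Windows with zero
scored SNPs are dropped, hence the SNP-count bins are [1,500), [500,1000)
and [1000,∞). Within a bin, p_i is the fraction of windows whose summary is
strictly greater than window i's — the window itself never counts, ties get
the same p, and the bin's top window always has p = 0. Significance is
strict (p < 0.005). An optional (r+1)/(n+1) pseudo-count form exists but is
off, to keep the literal counting rule the default. Because the rule is
rank-based, its false-positive floor is (#bins)/(#windows) regardless of the
data; interpreting the 0.5% level therefore needs at least ~200 windows per
bin.

## Region calling

Significant windows of each method are merged when they overlap or are
book-ended; merging is idempotent and order-independent, and regions of one
method never touch after merging. The best statistic carried is the minimum
for ZHp and the maximum otherwise. A gene (BED 0-based half-open, or GFF3
1-based inclusive converted on read; IDs from column 4 or the `ID=`/`gene_id`
attribute) is assigned to a region on ≥ 1 bp overlap — book-ended intervals
do not overlap — with strand ignored. Cross-method agreement is reported at
the gene level (intersection of unique gene sets), with a bp-level region
intersection emitted for completeness.

## The synthetic-data generator

A forward-in-time Wright–Fisher simulator: a founder population of 60
haplotypes evolves for 150 burn-in generations; its final pool seeds two
populations (sampling with replacement — a founder bottleneck) of
2 × 12 and 2 × 10 haplotypes ("JH", "TB") that evolve independently for 100
further generations on a 2 Mb contig. Per generation each offspring
haplotype takes one uniform crossover between two random parents with
probability min(1, r·L) and acquires Poisson(μ·L) mutations at uniform
finite sites; sites lost or fixed everywhere are pruned. Defaults
μ = 3 × 10⁻⁶ and r = 5 × 10⁻⁷ per bp per generation are scaled-up
surrogates chosen so a desk-sized contig reaches roughly one SNP per 650 bp
(about 3,000 SNPs at 2 Mb) with realistic allele-frequency spectra, linkage
decay and post-split divergence; they are not equine parameters, and the
demography is not a horse demography. Ref/alt bases are drawn with a 2:1
transition bias so the simulated genome-wide Ts/Tv sits near 2. INFO metrics
are synthesized in passing ranges; a `contaminate` flag plants failing
values to exercise the filters.

A hard sweep is injected after the fact: one donor haplotype's alleles are
copied into a fraction (default 0.9) of one population's haplotypes around a
core, each carrier's copied extent per side drawn Uniform(0.5·halo, halo)
(default halo 150 kb). The taper emulates the truncation of a swept
haplotype by recombination at increasing distance from the core; a
sharp-edged copy (taper 0) is available and is used by the boundary tests,
but as a default it concentrates the XP-EHH maximum at the halo edges — an
artefact real sweeps do not show. Injection by copying, rather than
simulating selection dynamics, buys an exact truth interval
([core − halo, core + halo), clipped) for benchmarking. Everything is
deterministic given the seed; the exported fixture (VCF, pop map, truth BED,
genes BED, manifest) is byte-reproducible.

What passing the benchmark does *not* show: performance on real data with
genotyping error, missingness structure, variable recombination and
mutation rate, statistical phasing error, or soft/partial sweeps — the
generator models none of these.

## Problem sizes

The packaged sweep fixture is the generator's default (2 Mb, 22 diploids,
carrier frequency 0.9, 150 kb halo, fixed seed); the scans run in seconds
there. The neutral control runs the full XP-EHH + empirical-p procedure on
20 independent 10 Mb neutral genomes: at 10 Mb there are 200 windows per
genome, so the rank-based floor of the empirical-p rule (one p = 0 window
per bin) is 0.005, and the ≤ 1% false-positive bound is meaningful — at the
2 Mb fixture scale (40 windows) the floor alone would be 2.5%, which is why
the control uses the larger contig. Oracles (exhaustive pair enumeration
for EHH and pi, direct formula evaluation for Hp, strict-dominance ranks
for empirical p) run on panels of ≤ 12 haplotypes or 10,000 random windows.

## Known limitations

- Physical distance only; no genetic map, no local recombination-rate
  awareness in the scans.
- The ZHp min-SNP rule (≥ 10 SNPs after the MAF ≥ 0.05 filter) can drop the
  windows *inside* a strong sweep on sparse panels — near-fixation leaves
  few sites above the MAF cutoff — so on small fixtures the most negative
  retained window may sit at the sweep's shoulder rather than its core.
- Empirical p-values are rank-based and bounded below by bin occupancy; they
  are not tail probabilities under a null model.
- `pseudo_phase` is a coin-flip phaser for pipeline plumbing, not a
  substitute for statistical phasing.
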