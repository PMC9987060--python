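# Methods

## Data model and coordinates

Genotypes are stored as alt-allele dosages {0, 1, 2} with a single missing
sentinel; half-calls (`0/.`) are conservatively treated as missing rather
than imputed, and phase separators `/` and `|` are equivalent because all
statistics here are computed from dosages. Only biallelic SNPs are kept.
All internal coordinates are 1-based inclusive (the VCF/GFF convention);
the conversion to 0-based half-open happens exactly once, at the BED
writer/reader, which eliminates off-by-one drift between modules.

## Site filters

A site passes iff its missing fraction over **all** samples is strictly
below 0.20 and its minor-allele frequency, pooled over all samples, is
strictly above 0.05. Both bounds are strict, and the MAF is pooled rather
than per-population, because a single global SNP set is filtered before
any per-population analysis; per-population usability (≥ 2 called
diploids) is then decided statistic by statistic, so a site unusable in
one population still contributes to the others.

## Diversity statistics

Within a population, with p̂ the alt frequency over the 2n called
haplotypes at a site:

* Ho = heterozygote count / called diploids,
* He = 2p̂(1−p̂),
* PIC = 1 − (p̂² + q̂²) − 2p̂²q̂² (biallelic Botstein closed form; the
  general multi-allele expression reduces to this for two alleles).

Population values are unweighted means over the sites usable in that
population. PIC ≤ He ≤ 0.5 holds per site, with He = 0.5 only at
p̂ = 0.5 and the PIC maximum 0.375 at the same point. The report is
sorted by ascending PIC so the most selection-eroded populations head the
table.

## F_ST

The estimator is Weir & Cockerham's (1984) θ for the two-population
diploid case, computed per site as the variance components a (among
populations), b (among individuals within populations) and c (within
individuals) from sample sizes, allele frequencies and observed
heterozygosity. Multi-site values — windows or the whole genome — are
the ratio of sums Σa / Σ(a+b+c), never the mean of per-site ratios, which
keeps low-information sites from dominating. Small negative values are
reported as computed (the estimator is unbiased around zero, so nulls
straddle it); they cannot exceed a positive selection threshold, so no
clamping is needed. A Hudson-type estimator
(num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
den = p₁(1−p₂) + p₂(1−p₁), haplotype counts n) is provided purely as an
independent cross-check; on Balding–Nichols fixtures with 20 diploids per
population the two windowed estimators correlate at r > 0.99.

## Nucleotide diversity

π per site is the exact mean pairwise difference over called haplotypes,
k(2n−k) / C(2n, 2) with k the alt-allele count — algebraically the
unbiased (2n/(2n−1))·2p̂(1−p̂), but implemented from integer counts so
that it is bit-identical to brute-force pair enumeration. Window π sums
usable sites and divides by the true window length in bp (tail windows
are normalised by their truncated length). Monomorphic sites contribute
zero; sites with fewer than two called diploids are skipped.

## The scan

Windows are enumerated per contig starting at 1, 1+step, … while the
start is inside the contig, with defaults window = 100 kb and
step = 10 kb; terminal windows are truncated and kept by default
(`drop_tails` removes them). Windows with fewer than `min_snps = 10`
jointly usable SNPs are masked: with fewer sites both statistics are
dominated by sampling noise, and masked windows are excluded from
quantile computation so they can neither be selected nor distort the
thresholds.

The per-window score pair is (F_ST, ln(π_ref/π_focal)). The log-ratio is
oriented reference-over-focal so that diversity loss in the scanned
population gives positive scores; it is masked when either π is zero
(log undefined) — in practice only in near-empty windows. Selection
thresholds are the empirical 0.95-quantiles (linear/type-7 interpolation)
of each statistic over unmasked windows, computed globally across contigs
by default (`per_contig_quantile` is available); a window is selected iff
it reaches **both** thresholds, ties included. Intersecting two 5% tails
can only shrink the flagged set, so the null selection rate is bounded by
5% and is ≈ 0.25% when the two statistics are independent.

Selected windows that overlap or bookend on a contig are merged into
candidate regions (idempotent union; `merge=False` reproduces raw
windows). A gene belongs to a region iff the intervals share at least one
bp, 1-based inclusive — bookended intervals do not overlap. Gene sets
from several focal-population scans are compared by full Venn partition,
the all-way intersection being the usual "shared candidate" set.

## LD

r² is the composite (Rogers–Huff) form: the squared Pearson correlation
of dosages over jointly called samples, undefined (pair skipped) when
fewer than two samples remain or either site is monomorphic among them.
Genotypes here are unphased, so haplotype r² (as phased tools like
Haploview compute) is unavailable; composite r² is the standard
phase-free surrogate and is monotonically related under Hardy–Weinberg —
a documented divergence, not an equivalence. Pairs are enumerated only up
to `max_dist` (default 100 kb), keeping cost O(sites × window) instead of
O(sites²), and pooled genome-wide into contiguous distance bins (default
1 kb). The half-decay distance is where the per-bin mean first falls to
half its maximum, linearly interpolated between flanking bin midpoints,
with an infinite sentinel when never reached. For n samples at
independent sites, E[r²] ≈ 1/n, which the null test checks.

## Summary-statistics ANOVA

From printed (mean, SE, n) triples the one-way ANOVA F is exactly
recoverable: SS_between from the means, SS_within = Σ(nᵢ−1)·(SEᵢ√nᵢ)²,
F on (k−1, N−k) df. Pairwise comparisons use Welch t-tests (t =
Δmean/√(SE₁²+SE₂²), Welch–Satterthwaite df) without multiplicity
correction; compact letters are assigned in descending-mean order, two
groups sharing a letter iff their pairwise p ≥ α. The printed "±" values
are interpreted as SEMs (the convention for tables of this size); a
`pm_is_sd` switch reinterprets them as SDs. With the bundled worker-bee
morphometry table this reproduces the printed pattern: 29 of 30 pairwise
calls significant at the 0.01 level, with basitarsus width (MT) SZ–WC the
single non-significant pair (p ≈ 0.06). Whether the original analysis
used a different post-hoc procedure is unknowable from the summaries; the
Welch choice is recorded in the output manifest.

## Synthetic data

The generator's defaults define the standard test conditions: one 2 Mb
contig, 20,000 SNPs (one per 100 bp, a realistic post-filter density for
a small insect genome), two populations of 20 diploids (reference "SZ",
focal "JL"), background F = 0.05 (weak structure, so sweeps must stand
out against noise rather than against a flat background), 5% random
missingness (typical of hard-filtered short-read call sets), and three
planted 100-kb sweeps. Inside a sweep the focal population's frequency
is redrawn within ε = 0.02 of whichever boundary (0 or 1) its
Balding–Nichols draw was nearer, mimicking near-fixation of a selected
haplotype: π collapses and F_ST rises simultaneously, which is exactly
the two-signal signature the intersection rule requires. Genes are tiled
deterministically (2 kb every 10 kb) so the truth gene set is an exact
interval computation, and realized per-population drift and per-region
diversity ratios are recorded in the truth object for sanity checks.

What the generator deliberately lacks: linkage (sites are exchangeable
given frequencies), demography (no bottlenecks, migration or growth),
recombination-rate variation, and haplodiploid genetics. Passing the
recovery tests therefore shows the scan machinery is correct and
calibrated under its own model — not that the statistical power measured
here transfers to real data, where background LD and demography inflate
the variance of both statistics. LD analyses use a separate copying-chain
generator (two-state Markov haplotype chains with autocorrelation
exp(−d/L) and a small re-randomisation noise), because Balding–Nichols
fixtures have no LD by construction; its correlation length L is a dial
for making one population's LD decay faster than another's, not a
population-genetic parameter.

Sweep recovery is scored in base pairs: recall = truth bp covered by
called regions / truth bp; precision = called bp inside truth / called
bp. With 100-kb windows on 100-kb sweeps, precision is structurally
bounded near 0.8 — any window that clears the thresholds while straddling
a sweep edge drags flanking sequence into the merged region — so recall
≈ 1 with precision ≈ 0.8 is the expected signature of a correct scan, not
a deficiency.

## Numerical and edge-case choices

* Quantiles: numpy's default linear (type-7) interpolation; ties at the
  threshold are selected (inclusive "top 5%").
* Degenerate windows: zero denominator in the F_ST ratio, or fewer than
  `min_snps` usable sites, masks the window; fewer than 20 unmasked
  windows aborts selection (the empirical quantile is meaningless).
* All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs serialize to
  byte-identical VCFs.
* Problem sizes in the test suite and acceptance script (2 Mb / 20 k
  sites / 20 diploids per population) were chosen as the smallest
  configuration at which the Monte-Carlo tolerances quoted in the tests
  (±0.03 on F_ST recovery, ±0.01 on He convergence, ±0.5 windows on the
  null intersection mean) hold comfortably.

## Known limitations

* Composite r² differs from phased-haplotype r² away from
  Hardy–Weinberg equilibrium.
* The W&C estimator is implemented for the two-population case used by
  the scan and the pairwise matrix; multi-population θ across >2 groups
  simultaneously is out of scope.
* Window enumeration covers contigs present in the genotype matrix's
  contig map (VCF header or observed maximum position); scaffolds absent
  from the VCF are not scanned unless an explicit contig-length map is
  passed.
* The letter-display algorithm assigns letters over runs in
  descending-mean order; for pathological non-transitive significance
  patterns with many groups a clique-based display could differ.
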