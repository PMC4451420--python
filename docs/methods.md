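# Methods

`bovidemog` analyses diploid SNP-array genotype panels from structured
livestock populations — the motivating system is domestic cattle, with its
two interfertile lineages (taurine *Bos taurus* and indicine *Bos
indicus*), African/non-African sub-structure, admixed breeds, and strong
recent selection.  This note records the statistical models, the choices
made where the design was open, and what the synthetic-data calibration
does and does not demonstrate.

## Data model and QC

Genotypes are alternate-allele counts in {0, 1, 2} with a distinct missing
sentinel; the alternate allele of a PED/MAP input is the second distinct
allele observed in file order, which makes the coding deterministic for
any input.  Coordinates are 1-based inclusive everywhere; BED input is
converted on read.  Call-rate filtering drops samples below the threshold
first and then SNPs, computed on the remaining samples — the order
matters and is fixed, and both thresholds keep at "≥" (the protocol
phrase "95% call rate" does not specify strictness; we chose ≥ and state
it rather than guess an intent).  LD pruning for structure analyses
(window 50 SNPs, step 10, r² > 0.1, MAF ≥ 0.01) uses unphased genotype
correlation because pruning precedes phasing in the intended workflow,
and removes the later-positioned SNP of an offending pair.

## Diversity statistics

Observed heterozygosity Ho is the mean over variants of the heterozygote
fraction among non-missing calls.  Expected heterozygosity uses Nei's
small-sample correction, he = k/(k−1) · (1 − p² − q²) with k the number of
non-missing allele copies.  F_IS = 1 − Ho/He is computed from the ratio of
multilocus means (not the mean of per-locus ratios), which is the standard
multilocus estimator, robust at low-He loci; monomorphic loci are retained
in the means because an array panel is fixed across populations.  Group
comparisons use Welch's unequal-variance t-test
(scipy.stats.ttest_ind, equal_var=False).

The package ships a transcribed reference table of per-breed N/Ho/F for a
56-breed bovine SNP panel (`data/breed_panel_diversity.tsv`) used to
verify group-mean arithmetic (taurine Ho 0.28 / F 0.18; indicine Ho
0.20 / F 0.42) and the extreme Chillingham value F = 1 − 0.026/0.34 ≈
0.924.  Absolute diversity comparisons across lineages on SNP arrays are
confounded by ascertainment bias — the SNP discovery panel was mostly
taurine — so such values are meaningful within, not between, major
groups.

## Reynolds distance and trees

Between-population distance is Reynolds, Weir & Cockerham's least-squares
coancestry estimator, θ = Σ_v Σ_alleles (p−q)² / (2 Σ_v (1 − Σ p·q)),
appropriate for short drift-dominated divergence because it does not
assume mutation.  Loci fixed identically in both populations contribute
zero to numerator and denominator; a fully-fixed pair of populations has
undefined distance (NaN), not zero.

The dendrogram is Saitou–Nei neighbor joining, written from scratch with a
deterministic tie-break (smallest row/column index on equal Q), rooted for
display at the final join with the last edge split evenly (path lengths
are preserved).  Negative NJ branch lengths are clamped to zero for
display unless raw output is requested.  Bootstrap support resamples
variants with replacement, recomputes frequencies → Reynolds → NJ, and
scores each internal edge by the fraction of replicates containing the
same bipartition; bipartitions are compared as label sets, ignoring
lengths and rooting.  Support thresholds are left to the caller.  A
split-network (NeighbourNet) view is intentionally not implemented; the
dendrogram is the supported tree output.

## LD-based Ne trajectories

Hill–Robertson r² is computed from phased haplotype frequencies,
r² = D²/(p_A(1−p_A)p_B(1−p_B)), for all within-chromosome SNP pairs
separated by 5 kb–1 Mb with MAF ≥ 0.05 at both ends; pairs are pooled
across chromosomes and grouped into 30 equal-count distance bins.
Binning is implemented as a stable sort-and-slice, which realizes the
empirical-quantile definition deterministically and guarantees bin sizes
differing by at most one even under distance ties; an all-ties input
collapses to a single flagged bin.  Each bin's mean r² is inverted with
Sved's relation N = (1/(4f(c)))(1/r² − 1) and read as the effective size
t = 1/(2c) generations ago, with c from physical distance under a strict
1 cM/Mb map; the 1 Mb ceiling therefore makes t = 50 generations the most
recent point of any trajectory.  The default mapping is f(c) = c; the
second-order form f(c) = c(1−c/2)/(1−2c)² is available as `sved_paper`
(the two agree to <0.5% at c ≤ 0.001, and the published rendering of the
second-order denominator is typographically corrupt, so the transparent
linear form is the default rather than a silent guess).  No finite-sample
r² correction is applied by default; an optional r² − 1/n_haplotypes
adjustment exists.  Trajectories report generations; a ×4 years-per-
generation conversion is applied only at reporting time.

## XP-EHH selection scan

EHH at flanking position x is the probability that two haplotypes drawn
from the *whole sample* are identical over the interval from the core SNP
to x (the unpartitioned form that the cross-population statistic
integrates; the classic allele-partitioned EHH is retained for testing
only).  The curve is anchored at (core, 1) — identity over a zero-length
interval — and every flanking value groups haplotypes by the allele
string from the core to x inclusive, which equals the brute-force
pairwise identity count.  Curves truncate where EHH < 0.05, at chromosome
ends, and at the last SNP before an inter-SNP gap above 400 kb (the gap
ceiling suited to ~50 kb medium-density array spacing); the record is
kept with shortened support rather than discarded.  iHH is the
trapezoidal integral of EHH over physical distance on both sides (under
the 1 cM/Mb map, physical and genetic integration are proportional).
XP-EHH is ln(iHH_A/iHH_B) per SNP with MAF ≥ 0.05 in both populations and
both iHH > 0; scores are standardized per chromosome (sample sd) and
flagged at the 5%/95% linear-interpolation quantiles of the standardized
scores over all tested markers genome-wide, with inclusive comparisons
(a per-chromosome quantile option exists; genome-wide is the default
reading of thresholds taken "for all markers").  If the two thresholds
coincide the distribution is degenerate and nothing is flagged.

The production iHH path is a vectorized equivalence of the per-core walk:
for every haplotype pair the first-mismatch index beyond each core is
precomputed, so EHH at any extension is a suffix count and the truncation
point an order statistic.  Tests assert bit-level agreement with the
direct walk, and the walk in turn against the pairwise-identity oracle.

## Replicated consensus and annotation

Several pairwise scans between members of two groups act as biological
replicates.  A SNP is called under selection when it is tested in ≥ m
comparisons and flagged with the same sign in ≥ m; the default rule also
vetoes any SNP with an opposite-sign flag in another comparison (the
source protocol does not address conflicts, so the conservative rule is
the default and a permissive switch disables the veto).  The canonical
design is: between-species K = 4 pairings with m = 3 (tolerating one
MAF-untested comparison), and two within-species K = 3, m = 3 designs.
Under independent flags the per-SNP null call rate is 2q^m for K = m
(2.5×10⁻⁴ at q = 0.05) and 2·Σ_{j≥m} C(K,j) q^j (1−2q)^{K−j} with the
no-conflict rule; a Monte-Carlo estimator of the same quantity is
provided for calibration.  Called SNPs link to every gene whose interval
intersects ±50 kb (distance 0 inside a gene, else the gap to the nearer
edge), and biotype tallies count distinct genes per direction, not links.

## Synthetic data generator

The forward Wright–Fisher simulator emulates what a fixed SNP-array panel
sees: standing variation only (no new mutation), founding frequencies
drawn uniform on [0.05, 0.95] to mimic array ascertainment (bounds
configurable), a strictly proportional 1 cM/Mb genetic map, Poisson
crossovers with uniform placement, piecewise-constant Ne schedules,
clean splits, two-parent admixed foundings (each founding haplotype from
parent A with probability α, boundary α = 1 allowed), and hard additive
sweeps (fitness 1, 1+s, 1+2s) confined to named populations.  A lost
sweep is reported in the truth record, not raised; an option retries the
whole run with derived seeds until the focal allele reaches a
configurable frequency.  Multiple chromosomes are simulated as
independent forward runs — unlinked loci but also independent pedigrees,
a deliberate approximation that slightly understates cross-chromosome
drift correlation.  Identical configuration and seed give bit-identical
output.

What passing calibration shows — and does not.  The generator reproduces
drift (heterozygosity decay matches h0(1−1/2Ne)^g), binomial reproduction
variance, admixture frequency expectations, LD decay at drift-
recombination balance, and sweep haplotype structure.  It does not model
genotyping error, phasing error (inputs are taken as perfectly phased),
mutation, gene conversion, variable recombination, overlapping
generations, or non-random mating within populations, so green
calibration results bound what the estimators do under those idealized
conditions, not under every failure mode of real array data.

## Calibration experiment designs (frozen)

* **Sweep power**: ancestor Ne 500 splits into two Ne-500 populations 100
  generations ago; a hard sweep (s = 0.1, 2Ns = 100) starts 55 generations
  ago from a rare standing variant (frequency 0.01), conditioned on
  reaching 0.5; 2000 SNPs / 60 Mb, 50 diploids per side, 50 replicates.
  Detection = a tested SNP within 100 kb of the focal site flagged in the
  high tail.  The 100 kb criterion is a detection window, not an argmax
  localization claim: a hard sweep's iHH footprint is flat over hundreds
  of kilobases to megabases under a 1 cM/Mb map, so the position of the
  single largest score within the footprint is noise-driven, while
  detection within the window is the scan's operating characteristic.
* **Neutral consensus null**: six Ne-150 populations split from one
  Ne-200 ancestor 60 generations ago; three disjoint pairwise scans;
  3000 SNPs / 60 Mb; five replicates.  The observed call rate over SNPs
  tested in all three comparisons is compared with the analytic
  2.5×10⁻⁴ within three binomial standard errors of the null.
* **Constant-Ne recovery**: one Ne-200 population run 500 generations
  (~2.5 Ne, enough for LD at 5 kb–1 Mb to approach balance) on two
  independent 25 Mb chromosomes of 1000 SNPs; the median bin estimate is
  required within ±25% of truth.  Deeper bins are noisier: few variants
  stay polymorphic long enough, and bins with t beyond the simulated
  horizon never equilibrated — a limitation of any finite run.
* **Declining Ne**: 1000 → 100 over 500 generations (stepwise); the
  recovered trajectory must rank recent bins below ancient bins (a rank
  property — absolute recovery under rapid decline is not claimed).
* **Tree recovery**: five sampled populations with known topology
  ((A,B),(C,D),O), all splits ≥ 50 generations at Ne 100; NJ on Reynolds
  distances must recover both non-trivial bipartitions with bootstrap
  support ≥ 0.95 over 100 replicates.

Problem sizes throughout (SNP counts, sample sizes, replicate counts)
are the package's chosen desk-scale study conditions; they are stated
here and in `bovidemog/calibration.py` so reruns measure the same thing.

## Numerical conventions

Missing genotypes use a sentinel code, never −1 arithmetic.  Quantiles
are linear-interpolation order statistics.  Standard deviations in
standardization are sample (ddof = 1) estimates; a zero-variance
chromosome is an error naming the chromosome.  Equal-count binning uses a
stable sort.  NJ ties break on the smallest index pair.  Seeds derived
from user seeds stay below 2³¹.
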