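# Methods

This note documents the models, numerical choices and simulation designs the
package implements, and what its synthetic-data tests do and do not show
about real data.

## Per-SNP statistics

Each biallelic SNP contributes a 2×2 allele-depth table (REF/ALT read counts
in the two bulks). Three statistics are computed on it:

* **Two-sided Fisher's exact test.** The P-value sums the probabilities of
  all outcomes on the observed table's margin whose hypergeometric
  probability does not exceed the observed one (relative tolerance 1+1e-7
  for floating-point ties) — the classical two-sided rule, identical to
  scipy's. Two-sided is the right alternative here: either allele may be
  enriched in either bulk. Because the Monte-Carlo thresholds need P-values
  for millions of simulated tables whose margins repeat heavily, the test is
  evaluated as a cached (depth1+1)×(depth2+1) grid per unique depth pair,
  built from vectorized hypergeometric log-pmfs. The test suite checks the
  grid against an exhaustive integer-arithmetic enumeration oracle on every
  table with margins ≤ 15 and against `scipy.stats.fisher_exact` on random
  tables.
* **ΔAF** = ALT frequency in bulk 2 minus ALT frequency in bulk 1. Its sign
  flips when REF and ALT are swapped in both bulks, which is why the ΔAF
  method requires a reference parent to orient every SNP consistently.
* **G** = 2 Σ O ln(O/E) with E the independence expectation
  (row total × column total / grand total); empty cells contribute 0 (the
  limit x ln x → 0), and E is never 0 when both called alleles are observed
  somewhere. Both Fisher's P and G are invariant under the simultaneous
  REF/ALT swap, so they are usable without parental data.

Tables with zero reads in a bulk are rejected as contract violations; the
simulator never emits them (zero Poisson depth draws are redrawn as one
read) and real zero-depth calls are missing values removed by filtering.

## Smoothing and sSNP calling

Raw per-SNP series are noisy at practical (< 100×) depths. Each series
(P, ΔAF, G, and the simulated per-SNP threshold series) is smoothed with a
Savitzky–Golay filter applied independently per chromosome over SNP *index*
order (not physical distance): window 51 points, polynomial order 3, both
configurable. A chromosome with fewer points than the window is passed
through unchanged (no padding). The defaults suppress sequencing noise
without flattening multi-hundred-SNP peaks; all calibration and recovery
tests hold at these settings without tuning. A SNP is an sSNP when its
*smoothed* P is strictly below α (default 0.01); ties at α are
non-significant.

Note an intentional asymmetry: real-data sSNPs are called on smoothed P at
α = 0.01, while simulated null replicates call sSNPs on raw P at
α_sim = 0.10. The looser simulation α produces more simulated sSNPs and
hence a deliberately higher (conservative) ratio threshold, and smoothing
inside every replicate would be both unfaithful to the procedure and
needlessly expensive. A practical consequence, visible in the null
calibration test, is that genome scans of null data produce essentially no
candidate windows: under the null, a 51-point smoothed P almost never drops
below 0.01, while the threshold is simulated from raw P at α = 0.10.

## Monte-Carlo thresholds

All thresholds simulate the null by keeping each SNP's observed per-bulk
depths and redrawing ALT reads binomially at the population null ALT
frequency — 0.5 for an F2, configurable for other designs (e.g. 0.25/0.75
for a backcross). The null frequency is the theoretical one, not estimated
from data. Percentiles are nearest-rank order statistics
(`np.percentile(..., method="inverted_cdf")`). Defaults: 10,000 replicates;
99% confidence band for ΔAF; 99.5th percentile for G and for the ratio.

* **Per-SNP ΔAF/G thresholds.** The null distribution of either statistic
  depends on a SNP only through its depth pair, so thresholds are computed
  once per unique (depth1, depth2) pair and shared by all SNPs with that
  pair — distributionally exact and orders of magnitude faster than
  per-SNP loops. The per-SNP threshold series are then smoothed per
  chromosome like the real series, and a window's threshold is the mean
  over its SNPs.
* **Genome-wide ratio threshold.** Each replicate samples, with
  replacement, as many SNPs as the average window holds, simulates them
  under the null, calls sSNPs at α_sim and records the sSNP/totalSNP
  ratio; the threshold is the 99.5th percentile of replicate ratios.
  Sampling with replacement keeps replicates independent and is immaterial
  when the dataset dwarfs a window.
* **Window verification.** Candidate ratio peaks (maximal runs of
  consecutive windows above the genome-wide threshold) are re-tested
  against a threshold simulated from exactly their own window's SNPs.
  SNP-poor windows get visibly higher thresholds, which is the point of the
  verification stage.

A single root seed drives everything: per-purpose generator streams are
spawned deterministically (`SeedSequence(seed, spawn_key=...)`), so results
are bit-reproducible for a given (inputs, config, seed) and independent of
evaluation order; per-peak verification streams are indexed by candidate
order.

## SNP filtering and AD/GT swapping

Ten hygiene rules run in a fixed order, and each removed record is counted
against the first rule it fails, making the removal report deterministic and
conservative (removals + survivors = inputs; filtering is idempotent):
excluded (organellar/unplaced) chromosomes; missing values in any used
field; fixed non-reference loci (zero REF reads, single ALT everywhere —
false positives of calling against a non-parental reference); ≥ 3 ALT
alleles; two ALT alleles with REF reads; genotype/allele-set disagreement;
genotype/AD inconsistency (a homozygote must have zero reads of the
non-called allele, a heterozygote must have reads of both called alleles —
the strictest reading, applied identically everywhere); bulk GQ below 20;
bulk depth above 6× the average coverage (run-level coverage if supplied,
else the per-bulk median depth); heterozygous parents. Records with exactly
two ALT alleles and zero REF reads everywhere are first re-anchored on
their first ALT allele (REF count dropped from the AD lists) before the
genotype-agreement rules run.

With a separate parental table, parents are filtered by the same applicable
rules, the bulk and parent sets are intersected on (chromosome, position,
allele set), and the parental GQ floor (the same 20 — the parental
threshold is otherwise unspecified, and symmetry is the least surprising
choice) is applied only *after* the intersection so marginal parental calls
do not shrink the common set prematurely. After filtering, when parents are
used, every record is re-oriented so the reference parent's allele occupies
the REF position: genotype pairs and AD pairs of all samples are reversed
where needed. The swap never changes total depth and is an involution.

## Sliding windows and peaks

Windows are 1-based half-open [start, start+size), starting at 1 and
advancing by the step until the chromosome's last SNP is covered; trailing
SNP-free windows are dropped, interior empty windows carry an undefined
(NaN) ratio. Defaults 2 Mb / 10 kb; a 5 Mb / 10 kb preset ships for
maize-scale genomes. A window's ratio equals the mean of its SNPs' sSNP
indicators; its ΔAF/G value is the mean of the smoothed per-SNP values.

Peaks are maximal runs of consecutive significant windows (ratio above the
genome-wide threshold; G above its averaged simulated threshold; ΔAF
outside its averaged confidence band in either direction — valleys count).
The run's extreme window is the peak, reported at the window start
(midpoint optional). Tie-break: around a strong locus the ratio saturates
at 1.0 over a plateau, so tied ratio maxima are resolved by the largest
window mean G, which keeps decaying with genetic distance; remaining ties
take the plateau's central window. Verified means the peak window's ratio
exceeds its own simulated window threshold.

## The synthetic-data generator

The generator emulates the canonical design: two fully homozygous,
maximally divergent inbred parents; an F2 (defaults: 178 individuals, tail
bulks of 23 — a rice-scale study); meiosis with Poisson crossover counts
per chromosome (default 4 cM/Mb), uniform crossover positions, no
interference, so every locus segregates 1:2:1 and linkage decays with
distance; phenotype = Σ per-QTL a·(g−1) + d·a·[g=1] + Gaussian noise
(d = 0 additive/incomplete dominant, d = 1 fully dominant); bulks are the
phenotypic tails with random tie-breaking (so a selected subset of a
phenotype class is exchangeable); sequencing draws per-bulk Poisson depths
(default 8×; zero redrawn as 1) and binomial ALT reads at the bulk's true
frequency, GQ fixed at 40.

Realism knobs for the with/without-parents comparison:

* REF/ALT orientation is random per SNP — a reference genome from neither
  parent agrees with each at random — which is exactly what breaks
  unswapped ΔAF;
* **htSNPs**: loci heterozygous in one parent, segregating
  trait-independently (bulk ALT frequency 0.25 or 0.75 by which parent is
  heterozygous);
* **bsSNPs**: loci absent from the parental data, with uniform(0,1) allele
  frequency (artifacts plus regions unsequenced in the parents);
* contaminant classes are drawn in *tracts* along the SNP index (Markov
  chain, stationary distribution = the configured rates, mean tract length
  30 SNPs by default) because residual heterozygosity and unsequenced
  regions are block-like in real data; per-SNP-independent contamination
  (tract length 1) is an unrealistically adversarial input for any
  smoothing-based pipeline.

SNP density defaults to a desk-scale 100 SNPs/Mb (real shotgun datasets are
10–40× denser; density only rescales window SNP counts and runtimes).

What passing tests show: segregation, linkage decay, selection response,
filtering/swap bookkeeping, threshold calibration and end-to-end locus
recovery under the modelled noise sources. What they do not show: robustness
to mapping bias, duplicated regions, depth overdispersion beyond Poisson,
genotyping-caller artifacts, or mis-phenotyped individuals — none of which
are modelled.

## Problem sizes in the test suite

Library defaults follow the published procedure (10,000 replicates); the
test and acceptance runs use smaller, fixed problem sizes chosen once as
reasonable desk-scale designs: null-calibration scans use two 20 Mb
chromosomes at 100 SNPs/Mb, 8× depth, 600 replicates over 20 seeds; the
recovery study uses one 40 Mb chromosome at 500 SNPs/Mb, an additive locus
at 20 Mb, 20× depth, bulks of 23 from 178, 10% htSNP + 8% bsSNP
contamination in 20-SNP tracts, 1,000 threshold replicates, 20 seeded
replicates. The denser map in the recovery study keeps the 51-point
smoothing window (~0.1 Mb) short relative to contamination tracts, as it is
in real data. The contaminated-versus-clean contrast in those runs
reproduces the method's central observation: contamination inflates window
totals far more than sSNP counts, lowering peak ratios while preserving
detection of strong loci, whereas localization to sub-window precision is
assessed on the uncontaminated runs.

## Known limitations

* The exact real-data genome scans of published studies are not
  reproducible here: they require the raw read archives and a full variant
  calling chain, which are outside this package's scope (it consumes the
  tabular output of such a chain).
* Smoothing operates on SNP index, so physical smoothing bandwidth varies
  with local SNP density.
* InDels are treated exactly like SNPs; there is no InDel-specific logic or
  left-alignment.
* The ratio statistic saturates near strong loci; sub-window localization
  there relies on the G tie-break described above.
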