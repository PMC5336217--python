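# Methods

This note records the models behind `walnutpg`, the defaults and why they
were chosen, the numerical decisions taken where conventions diverge, and
what the synthetic-data tests do and do not establish about real data.

## The coalescent + GSM kernel

All simulation — the island-model generator, the bottleneck equilibrium
distributions and the ABC scenario simulator — runs through one kernel
(`walnutpg.coalescent`).  Time runs backward in generations; within a
pool of diploid effective size N, k lineages coalesce at rate
k(k−1)/(4N); demographic events change the pool structure
piecewise-constantly.  After the genealogy is built, mutations fall as a
Poisson process of rate μ per lineage per generation and each mutation
moves the allele by a signed number of repeat units:

* **GSM** — |step| ~ Geometric(1−P) on {1, 2, …}; P = 0 is the strict
  SMM, the mean step is 1/(1−P) and E[step²] = (1+P)/(1−P)².
* **TPM** — a one-step mutation with probability p₁ (default 0.70),
  otherwise a geometric step whose success probability is solved from a
  variance parameter (default 30, so q = 1/6).  The 70/30 split is the
  conventional microsatellite setting; the multistep *size* distribution
  is not dictated by that convention, so the variance-30 geometric
  (the BOTTLENECK default) is declared here as the package's choice.

The root allele is fixed at 100 repeat units — an arbitrary but
reproducible ladder origin.  Allele sizes are unbounded by default (an
optional clamp window exists in `LocusModel`); in the rare event a
locus's random walk would reach a non-positive size, the whole locus is
shifted up by a motif multiple.  An affine shift changes no allele
counts, heterozygosities, size variances or distances, so every statistic
the pipeline consumes is unaffected.  Diploid genotypes pair consecutive
sampled gene copies; coalescent lineages are exchangeable, so this equals
random pairing in distribution.

Closed forms used to verify the kernel: for two gene copies in a
stationary pool, E[(ΔX)²] = θ(1+P)/(1−P)² with θ = 4Nμ; under the strict
SMM the equilibrium homozygosity is 1/√(1+2θ).  The test suite checks
both within 3 Monte-Carlo standard errors (θ ∈ {1, 2, 5}, P ∈ {0, 0.2};
6,000 pairs per setting, 500 loci for the homozygosity check).

## Scenarios, priors, simulation plan

A scenario declares pools (each with a size parameter), a backward event
list — MERGE(t, source→sink), ADMIX(t, derived→parents, rate = share
from parent A), SIZECHANGE(t, pool, size) — priors for every parameter,
and strict inequalities among time parameters.  Validation checks prior
coverage, admixture-rate priors inside (0, 1), acyclicity of the
constraint graph, and that under the midpoint draw plus 20 random prior
draws every sampled lineage reaches a single final ancestor.  Parameter
vectors are drawn by whole-vector rejection against the constraints.

The eleven shipped walnut scenarios use: effective sizes ~ U(100, 10,000)
(stage-2 posterior supports fall inside this range); event times
t4 ~ U(100, 10,000) (Last Glacial Period), t3 ~ U(10, 200) (post-LGM),
t2 ~ U(20, 60) (Bronze/Iron Age), t1 ~ U(10, 25) (Hellenistic–Roman),
td ~ U(1, 15) and tm ~ U(1, 10) (Middle Ages) — td/tm assigned so that
their supports match the reported 95% intervals of the expansion and
decline times; admixture rates ~ U(0.001, 0.999); one
μ ~ U(10⁻⁴, 10⁻³) and one GSM P ~ U(0.1, 0.3) per dataset, shared
across loci (no per-locus rate heterogeneity).  The stage-1 scenarios
are reconstructed from the narrative description of the competing
colonisation routes and are marked "reconstructed" in their YAML files.
In scenario 6b the rate rb is bound to the t1 admixture event (western
Europe × Balkans → north-eastern Europe); the published parameter table
describes rb against the ancestral pool instead, an inconsistency we
record rather than resolve.  The t2 calendar conversion is reproduced by
the arithmetic (51.3 × 80/110 = 4,104/5,643 BP) rather than by the
printed 4,140/5,630.

## Summary statistics and the ABC loop

Per pool: mean allele count per locus, mean unbiased expected
heterozygosity, mean allele-size variance (ddof = 1).  Per unordered pool
pair: multilocus Weir–Cockerham θ, and a classification index — the
fraction of individuals whose mean shared-allele distance
DAS(x,y) = 1 − shared/(2·loci) to their own pool (self excluded) is
smaller than to the other pool, averaged over both directions, ties
counting one half.  Per ordered pair: the mean log₁₀ genotype likelihood
of pool i's individuals under pool j's allele frequencies, add-one
smoothed over the locus allele set.  For P pools the vector has
3P + P(P−1)/2 + P(P−1) + P(P−1)/2 entries (36 at P = 4).  The precise
assignment-likelihood and DAS formulas are declared conventions: the
reference GUI implementation does not publish them at this level of
detail.

Reference-table statistics are normalised by their median absolute
deviation; statistics with zero MAD drop out of the Euclidean distance
with a warning.  Rejection keeps the ⌈fraction·rows⌉ closest rows, ties
broken by row index.  The direct posterior is the scenario share among
the closest rows (default 500) with normal multinomial CIs; the logistic
posterior is a multinomial logit of scenario label on centred statistics
over the retained rows, evaluated at the origin, CIs by the delta method
on the intercepts; on separation or non-convergence the fit is redone
with a small ridge penalty and flagged.  Parameter estimation retains
rows of the chosen scenario, maps each parameter to the real line by a
logit of its prior-bounded range (log scale for log-uniform priors),
adjusts by weighted local-linear regression with Epanechnikov weights
1 − (d/d_max)², back-transforms — which automatically respects the prior
bounds — and reports weighted mean, median and the 90% equal-tail
interval.  A parameter pinned at a prior bound in more than half the
retained rows is left unadjusted and flagged.

Determinism: every reference-table row, pod and posterior-predictive
simulation draws from a counter-keyed `SeedSequence` substream of the
master seed, so any partitioning of the work reproduces the serial
result bit for bit.

## Diversity estimators

HE pooling follows the two table conventions: pooled frequencies for the
per-locus summary, per-population frequencies for the population table.
Rarefaction standardises on g = 16 gene copies (eight diploids),
configurable; a population below depth at a locus skips that locus for
Rs, and PAR uses only loci where every population reaches depth.
Missing data are complete-case per locus; the diploid pair is missing as
a unit.  Jost's D uses the Nei–Chesser small-sample estimators with the
harmonic-mean sample size; the multilocus combination is the harmonic
mean across loci (the SMOGD convention), with the arithmetic mean also
reported, since no single combination is canonical.  The harmonic mean
is reported as undefined when any per-locus D is non-positive.  The
null-allele EM treats visible homozygotes as mixtures of true
homozygotes and visible/null heterozygotes and missing genotypes as
null/null (convergence |Δr| < 10⁻⁸, ≤1,000 iterations).  "Sequential
Bonferroni" is implemented as Holm's method, its standard
identification.  The F_IS permutation test shuffles alleles among
individuals within the population per locus and reports both the
two-sided and the homozygote-excess p-value with the (count+1)/(n+1)
convention.

## Bottleneck procedures

The heterozygosity-excess null is built per locus by calibrating θ with
a bisection so the mean simulated allele count matches the observed k
(120 probe simulations per bisection step, 14 steps), then retaining
simulations with exactly k alleles until the requested sample size
(default 10,000) is reached.  The per-locus standardized differences
(He − mean Heq)/sd(Heq) feed a one-tailed Wilcoxon signed-rank test
(exact null for ≤25 loci).  Because the null sample depends only on
(k, n, mutation model, replicates), callers may pass a memoisation
dictionary; the calibration experiments share one cache across fixtures.

A known limitation, documented by a deliberately strict test in the
suite: the conditional simulation is exact — observed He values rank
uniformly within the simulated Heq sample on matched-model fixtures —
but He | k is left-skewed, so P(He > mean Heq) ≈ 0.6 at equilibrium and
the signed-rank symmetry assumption fails.  The one-tailed test
therefore rejects stationary populations at ≈ 0.15 rather than 0.05.
This is a property of the published mean-centered procedure itself, not
of the implementation; significant results near the nominal threshold
should be read accordingly.

Mode-shift pools polymorphic-locus allele frequencies into ten 0.1-wide
classes; the spectrum is "L-shaped" only when the (0, 0.1] class is
strictly modal — ties count as "shifted", conservative toward signalling
disturbance.  The M-ratio is k/(r+1) with the range r in repeat units,
averaged arithmetically over loci with ≥2 alleles and compared to the
fixed 0.68 criterion; its calibration presumes mostly stepwise mutation,
and fixtures for its stationary behaviour are simulated under the strict
SMM (θ = 5, 50 diploids).

## Trees, clustering, rasters

Nei's unbiased identities can go non-positive in tiny samples; they are
floored at 1/(allele count), and negative distances are clamped to zero.
Pairs without shared alleles get an infinite distance and must be
resolved before NJ, which requires finite entries and breaks Q-criterion
ties by the smallest index pair; the final edge is split evenly, which
preserves all leaf-to-leaf path lengths.  Negative branch lengths are
kept but logged.

Run alignment minimises the summed squared difference to the first run
over all K! column permutations (K ≤ 8).  ΔK is the absolute second
difference of the mean log-likelihood divided by its standard deviation,
undefined at the endpoints and where sd = 0.  IDW uses power 2 and the
all-points neighbourhood on planar coordinates by default (the common
GIS defaults; the power/neighbourhood used originally are unstated), with
an optional great-circle mode for lon/lat; a cell within 10⁻⁹ of a data
point takes that point's value.  Rasters are written as plain-text ESRI
ASCII grids; cluster colours are a fixed eight-colour palette, cosmetic
and overridable.

## GenePop dialect

GenePop stores neither population names nor locus metadata.  The writer
embeds both losslessly while remaining readable by standard parsers:
individual lines are `<pop>|<ind> , codes` and locus lines carry
`motif=<bp>`.  Plain files are accepted and flagged `raw` (no
motif-ladder validation, motif defaulting to 1).  Codes are written
3-digit; 2- or 3-digit files parse.  Allele calls are stored as raw
base-pair sizes; repeat-unit conversion happens on demand from the locus
motif and the common size remainder, so I/O is lossless whichever
convention (bp or repeats) the source data used.

## What the synthetic data do and do not show

The island-model and scenario generators reproduce the statistical
structure the estimators assume: exchangeable coalescent samples, motif
ladders, HWE within pools, equilibrium or event-driven demography.  The
study-shaped fixture (91 populations, 2,008 diploids, 14 loci) draws
each population through a founder subset growing from 8 gene copies in
the west to 44 in the east of a common ancestral pool whose θ = 14 per
locus was set so the expected total allele count lands near 200; it
emulates serial founder effects, not spatially explicit dispersal.  Real
SSR data add scoring error, allele dropout, linkage, null alleles
(available separately via injection) and non-equilibrium spatial
structure none of the generators produce — passing tests demonstrate
correctness of the estimators and the inference machinery under their
stated models, not robustness to those artefacts.

Calibration experiments run at desk scale by design: three well-separated
two-pool toy scenarios (20+20 diploids, 14 loci, 500-row tables, 50
pseudo-observed datasets) for scenario recovery; a two-pool split
(50+50 diploids, 2,000-row table, 50 replicates) with truth N = 2,000,
t = 50 for parameter recovery, with μ essentially fixed at 5×10⁻⁴ so N
is identified by diversity rather than confounded with the mutation
rate, and priors whose medians lie far outside factor-two of the truth
so that success requires genuine posterior contraction.  The
study-scale analysis (10⁵ rows per scenario, sampling plan
41/131/279/650) uses the identical code path.

## Known limitations

* No linkage-disequilibrium statistics, no HWE exact tests beyond the
  F_IS permutation test, no ENA-corrected F_ST, no bootstrap support on
  trees, no greedy alignment mode for K > 8.
* The logistic posterior CIs come from the delta method at the origin;
  for near-degenerate retained sets the ridge-flagged fit widens them
  only approximately.
* The heterozygosity-excess one-tailed test over-rejects at equilibrium
  (see above); the M-ratio's 0.68 criterion presumes mostly stepwise
  mutation.
* Raster output is ESRI ASCII only; no GeoTIFF/projection handling.
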