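# Methods

This note documents the models, parameters and numerical choices behind
`hydroxymut`, and what the synthetic-data experiments do and do not show.

## Per-site model and site classes

Each cytosine carries four read counts: BS-Seq total/unconverted and
TAB-Seq total/unconverted. Unconverted BS reads indicate any
modification, unconverted TAB reads indicate 5hmC; the derived levels are

- mod level = bs_unconverted / bs_total,
- 5hmC level = tab_unconverted / tab_total,
- 5mC level = mod level − 5hmC level,
- 5hmC_rel = 5hmC level / mod level.

Because the two assays are independent binomial estimates, sampling noise
can make 5hmC level exceed mod level; the 5mC level is clipped at zero
(the raw difference is recoverable from the stored counts). 5hmC_rel is
undefined (NaN) below the modification floor of 10%, where the ratio is
dominated by noise.

Site classes follow the threshold definitions: a site is 5mC-high when
mod level > 10% and 5hmC_rel ≤ 0.3, and 5hmC-high when mod level > 10%
and 5hmC_rel ≥ 0.5; both ratio comparisons are inclusive, the floor
comparison strict. The floor appears a second time as an *inclusive*
filter (mod level ≥ 10%) where modified sites are selected for gradient
binning and window averaging; both variants are exposed in configuration.
Coordinates are 0-based half-open internally; VCF/MAF and modification
tables are 1-based on disk and shifted at the I/O boundary. Modification
records stay strand-resolved; no symmetric-CpG collapsing is performed at
parse time.

Sites with ≤ 5 TAB-Seq reads are dropped on load (the 5hmC estimate is
too noisy below that depth); the threshold is a parameter.

## Mutation classification and joining

SNVs are normalised to the pyrimidine of the mutated Watson-Crick pair
and classified by their 5' and 3' flanks into the standard 96
trinucleotide types (fixed lexicographic order: substitution major,
flanks minor). Spectra divide per-type counts by genome-wide
trinucleotide frequencies. A mutation matches a modification site iff
chromosome and position coincide and the mutation's pyrimidine strand
equals the strand carrying the site's cytosine. Whole-exome samples are
restricted to merged exons before any fraction is computed.

## Cohort statistics

Per sample and site class, the mutated fraction is (mutated sites)/
(eligible sites). Classes are compared with the paired Wilcoxon
signed-rank test: zero differences dropped, the exact null distribution
for n ≤ 25 untied differences, otherwise the normal approximation with
continuity correction (per-cancer-type cohorts are often small, so the
exact tail matters). The effect summary is 1 − mean(5hmC-high fraction)/
mean(5mC-high fraction) with unweighted means over samples. Degenerate
input (all differences zero) reports p = 1 with a flag rather than an
error.

Pairing visits 5hmC-high sites in an order shuffled by a recorded seed
and assigns each the nearest not-yet-used 5mC-high site sharing
chromosome, exon status, and context class; equidistant candidates
resolve to the smaller coordinate (the underlying procedure is silent on
ties, so the rule is fixed and logged). The implementation uses
path-compressed nearest-alive pointers over position-sorted arrays,
giving near-linear total cost; tests verify exact agreement with the
quadratic greedy scan. The per-sample paired difference is a *count*
difference (mutated 5mC-in-pairs minus mutated 5hmC-in-pairs): pair sets
are equal-sized, so counts and frequencies order samples identically.

The aligned profile anchors on modified sites with no other modified site
within a 2 kb radius and reports mutations per bp per anchor per sample
in offset bins, the anchor position separately. Bins with no anchors are
NaN, never zero.

## Window and gene GLMs

All count models share one core: Poisson GLM, log link, offset =
log(exposure) where exposure is the eligible-site count (times the
number of samples for window models). The source analyses describe
fitting "mutation frequency" with a Poisson model without stating an
exposure; a Poisson response is only coherent for counts, so the offset
formulation is adopted as the one deliberate modeling interpretation —
it leaves D² well defined and makes coefficients rates per eligible
site. D² = 1 − residual/null deviance, with the null the
intercept-plus-offset fit; the model-vs-null test is the deviance (LR)
chi-squared. Overdispersion (Pearson χ²/df) is reported but deviances
are never rescaled by it, keeping D² comparable across models.

Window features (per 100 kb by default, tiling anchored at 0, partial
terminal windows kept at true size): means of 5hmC, 5mC, 5hmC_rel over
sites with mod ≥ 10%; mean raw mod level over all sites; coverage-based
gene/exon/CGI densities; CpG and modified-CpG densities; coverage-
weighted mean log(1+expression). Windows without eligible CpGs are
excluded from fitting. Predictor rankings sort by univariate D² and
report cumulative nested-model D², which is non-decreasing by
construction. Cross-tissue matrices z-score rows of raw D² to remove
cohort-size effects; zero-variance rows give flagged NaNs.

Gene models use mean exonic hmc_rel and log median expression as
predictors and six response kinds (modC>T, CpG>T, C>T, C>N, N>N, T>N),
each a count over its eligible-site denominator. Denominators for the
broad kinds (C, T, all sites) require reference-genome composition; the
API takes a per-gene composition table, which the synthetic generator
emits in its ledger. Outliers are flagged per response by
y ≥ Q(0.999) + 2.5·(Q(0.999) − Q(0.001)) with linearly interpolated
quantiles (the rule is quantile-estimator sensitive, so the estimator is
fixed and documented); a gene flagged in any kind is excluded from all.
A literal reading of the rule flags everything when the two quantiles
coincide, so near-constant vectors flag nothing. ΔD²(A over B) =
D²(A+B) − D²(B) with a 1-df nested deviance test.

Gradient regression fits per-bin mutated fractions on bin midpoints,
unweighted across bins by default (each bin is one observation of the
dose-response curve; a site-count-weighted option exists). Bins are
right-open with the top bin closed at 1 so hmc_rel = 1 is binned.
Quantile binning isolates all hmc_rel = 0 sites in the first bin and
splits the rest into n−1 equal-occupancy bins.

Track smoothing uses a Gaussian kernel of length n = 50 windows with
σ = 2.5 (window units), renormalised at chromosome edges and around
missing windows so constant tracks are fixed points; z-scoring is per
chromosome, with zero-variance tracks flagged NaN.

## Power simulation

Each window of a tiled genome gets a Beta(3,4) predictor p_i; the rate
coefficient is c = T / Σ n_i p_i with T = 174 (the observed average
CpG>T burden per whole genome), so a patient's expected total burden
Σ n_i p_i c equals T exactly; per patient, window counts are
Binomial(n_i, p_i c), clipped at probability 1 with a warning (reachable
only on degenerate tiny genomes). The GLM refits patient-summed counts
on the predictor with offset log(n_i × patients). This establishes how
much D² is attainable at each window/cohort size even with a perfect
predictor, which is how low D² at small windows should be read.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume,
with defaults fixed once as the package's study conditions:

- genome: 2 chromosomes × 5 Mb, CpG density 0.01/bp (~10⁵ CpGs) —
  large enough for stable class fractions, small enough for seconds-scale
  simulation;
- true levels: mod ~ Beta(5, 1.5) (mostly-high, as in somatic CpGs);
  hmc_rel ~ 0.30·δ(0) + 0.70·Beta(mean m_w, concentration 4), the
  zero-inflation populating the 5mC-high class and the Beta component
  the 5hmC-high class; the local mean m_w follows a smooth window-level
  field (amplitude 0.15 on a 100 kb lattice, interpolated to sites), so
  window features have genuine spatial autocorrelation;
- observation: BS depth ~ Poisson(30), TAB depth ~ Poisson(25) (floored
  at 1), binomial unconverted counts;
- mutations: per patient, each CpG mutates C>T with probability
  5×10⁻⁴ · (1 + 6·mc + 0·hmc). The relative risks make methylated sites
  about twice as mutable as hydroxymethylated ones realized over the
  level priors, while 5hmC itself is neutral — its apparent protection
  comes from displacing 5mC, matching the observation that
  hydroxymethylated sites mutate like unmodified ones. Rates are ~100×
  real somatic rates so that effects are measurable at desk scale;
  background mutations at exonic non-CpG C and T pairs use 10⁻⁴ per
  site per patient, the same scale-up of the real ~10⁻⁶/bp;
- annotations: exponential-length genes covering 40% of the genome, 5
  equal exon blocks per gene (30% of gene length), CpG islands at
  8/Mbp, lognormal expression over 5 pseudo-samples;
- every draw comes from one `numpy` Generator seeded by the config
  (default seed 17082), so outputs are byte-for-byte reproducible.

The ground-truth ledger records true per-site levels and probabilities,
realized per-class event counts, injected parameters, and the per-gene
site composition.

What the generator does **not** emulate: realistic CpG clustering (sites
are uniform, so at the default density no site is isolated within 2 kb —
the aligned profile needs a sparse map, see `examples/03`), sequence
composition beyond a GC fraction, selection on driver genes, tumor
purity, signature mixtures beyond CpG>T plus uniform background, or
read-level artifacts. Passing tests therefore demonstrate correctness of
the statistical machinery and recoverability of injected effects under
the stated noise model, not performance on real cohorts.

## Scaled-down analyses

The test suite runs every stage at sizes chosen for seconds-to-minutes
runtimes while keeping each test adequately powered: the default cohort
(~10⁵ sites, 100 patients) for recovery and attribution checks; 500
replicate null cohorts of ~2×10³ sites and 24 patients for false-positive
calibration (under equal relative risks the mutation probability depends
only on mod level, which is independent of hmc_rel, so the class-
comparison null holds exactly); 100-seed batches of 150-window cross-map
and 50 000-site gradient simulations; and 30–100 Mb synthetic genomes for
the power simulation.

## Known limitations

- The pairing tie rule and visit-order seed make results reproducible
  but not canonical; different seeds give different (equally valid)
  matchings.
- Gene location lookup assumes non-overlapping gene exon blocks, as the
  generator produces; overlapping transcripts on real annotations should
  be pre-merged per gene.
- The quasi-Poisson dispersion is diagnostic only; strongly overdispersed
  real data would need a negative-binomial extension.
- `tissue_ratio_correlation` requires ≥ 4 tissues and treats the bulk
  5hmC measurements as fixed, ignoring their measurement error.
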