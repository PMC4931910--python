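# hydroxymut

Cytosine-modification-aware analysis of somatic CpG>T mutation frequency.

## The problem

C>T transitions at CpG dinucleotides are the dominant somatic mutation
type in most cancers, driven by spontaneous deamination of
5-methylcytosine (5mC). A large fraction of 5mC in somatic tissues —
especially brain — exists as 5-hydroxymethylcytosine (5hmC), and the two
modifications are indistinguishable in ordinary bisulfite sequencing.
Combining bisulfite (BS-Seq, detects any modification) with Tet-assisted
bisulfite (TAB-Seq, detects 5hmC specifically) gives, per cytosine,

- `mod level` = unconverted/total BS reads,
- `5hmC level` = unconverted/total TAB reads,
- `5mC level` = mod level − 5hmC level,
- `5hmC_rel` = 5hmC level / mod level (defined for mod level ≥ 10%).

`hydroxymut` is a library for researchers in cancer epigenomics who want
to relate such base-resolution modification maps to somatic mutation
catalogs. It implements, end to end:

- **Site classes** — 5mC-high (mod level > 10%, 5hmC_rel ≤ 0.3) vs
  5hmC-high (mod level > 10%, 5hmC_rel ≥ 0.5), and per-sample mutated
  fractions compared with the paired Wilcoxon signed-rank test, including
  threshold sweeps and expression strata.
- **96-type mutation classification** — every SNV normalised to the
  pyrimidine strand in its trinucleotide context, with genome-frequency
  normalised spectra.
- **Matched pairing control** — each 5hmC-high site greedily paired with
  the nearest unused 5mC-high site of the same exon status and sequence
  context, removing regional confounding.
- **Gradients** — mutation frequency across 9 hmc_rel bins (even or
  quantile) with an F-test for the linear trend, and the 9×9
  (5mC × 5hmC) grid with its marginal slices.
- **Window and gene GLMs** — Poisson regression of mutation counts with
  an eligible-site exposure offset; model quality as explained deviance
  D² = 1 − residual/null deviance; univariate and cumulative predictor
  rankings, cross-tissue prediction matrices with row z-scores, ΔD²
  attribution of hmc_rel vs gene expression across six response kinds,
  and Gaussian-smoothed genome tracks.
- **Power simulation** — a generative model (Beta(3,4) window predictor,
  binomial counts calibrated to 174 mutations per patient) quantifying
  how window size and cohort size bound attainable D².
- **Synthetic cohorts** — a first-class generator producing modification
  tables, annotations, expression and patient catalogs with known
  ground-truth dependence of mutation probability on modification state,
  so every stage is testable without external data.

## Worked example

```python
import hydroxymut as hm

cohort = hm.simulate_cohort()                      # default synthetic cohort
labels = hm.classify_sites(cohort.sites)           # mc_high / hmc_high / neither
joins  = hm.join_mutations_to_sites(cohort.sites, cohort.catalogs, ("C>T",))
table  = hm.class_fractions(cohort.sites, labels, joins, cohort.catalogs)
res    = hm.compare_classes(table)
print(f"reduction: {100*res.reduction:.1f}%  p = {res.p_value:.2e}")
print(f"ledger truth: {100*cohort.truth.realized_reduction:.1f}%")
```

prints

```
reduction: 50.4%  p = 3.95e-18
ledger truth: 53.3%
```

i.e. predominantly hydroxymethylated CpGs are mutated about half as often
as predominantly methylated ones, the pipeline's estimate from noisy read
counts (50.4%) closely tracking the generator's ground truth (53.3%), at
overwhelming paired-test significance across the 100 simulated patients.
The `examples/` directory has one short script per capability
(simulation, class comparison, pairing, gradients, window GLM, gene
attribution, power simulation, cross-tissue analysis); each prints the
numbers it computes and a line on what they mean.

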