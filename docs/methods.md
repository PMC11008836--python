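# Methods

This note documents the statistical models behind `msatqc`, the choices
made where conventions differ between programs, and what the synthetic
validation does and does not demonstrate.

## Data model

Alleles are identified by fragment size in base pairs, as a fragment
analyzer reports them; the constant adapter tail (19 bp for an M13-tailed
design) is part of the size and is carried as locus metadata, so repeat
arithmetic (stuttering, pooling) uses the locus motif length rather than
assuming sizes start at zero. Missing genotypes ("blanks") are distinct
from the reserved 999999 null-homozygote code: interpreting a blank as a
null homozygote is an explicit, per-locus recoding decision, because blanks
at a locus with heterozygote *excess* cannot be null homozygotes and should
stay missing.

## F-statistics

Wright's fixation indices are estimated with Weir & Cockerham's (1984)
variance components: for each allele, the indicator variance is split among
populations (a), among individuals within populations (b) and within
individuals (c), using the unequal-sample-size weights n̄, n_c. Per-locus
and multilocus statistics are ratios of summed components (never means of
per-locus ratios), which reproduces the behaviour of the classical Fstat
program and makes bootstrap-over-loci and jackknife-over-loci resampling a
matter of re-summing stored per-locus components. Monomorphic or
all-missing loci are undefined and excluded from the sums. With a single
population only F_IS exists (the among-population term needs r ≥ 2).

The estimator is verified against an independent moment-ANOVA oracle
(nested mean squares on allele indicators) exhaustively on all two-allele
two-population six-individual instances and on random multiallelic
instances; both routes agree to machine precision.

### Permutation tests

* F_IS: alleles are shuffled among individuals within subsamples. Because
  this keeps allele frequencies fixed, each permuted F_IS is a monotone
  function of the locus's total heterozygote count, which the
  implementation exploits for speed (the identity is derived in the
  docstring). One-sided p-values (heterozygote deficit) use the
  (k+1)/(n+1) convention; two-sided p-values double p for positive F_IS and
  double (1−p) otherwise, capped at 1.
* Subdivision: the G log-likelihood-ratio statistic of the allele ×
  population table, summed over loci, with whole individuals permuted
  among subsamples.
* Linkage disequilibrium: per locus pair, G on the two-locus genotype
  contingency table summed over subsamples, permuting one locus's
  genotypes among individuals within each subsample (genotype-level
  permutation; the allele-level variant is not what a diploid LD test
  should condition on). The pair series is BY-adjusted because pairs
  sharing a locus are dependent; per-site significant-test proportions are
  compared with a Fisher exact test (chi-square for > 2 sites).

Permutation p-values are discrete and slightly conservative on small
datasets (ties at the observed statistic count as "as extreme"); measured
type-I error at α = 0.05 is ≈ 0.03–0.05 at study-like sizes.

### Generalized-binomial p combination

k one-sided p-values are combined with the statistic
S = min_r Pr(Binomial(k, p_(r)) ≥ r) over the sorted p-values, calibrated
by Monte-Carlo on k iid uniforms (default 10,000 draws). For k = 1 it
returns the input p up to Monte-Carlo error; on uniform inputs the
combined p is uniform (checked by KS test). The exact algorithm of the
program that popularized this combination is not published in detail;
this construction is the natural reading and is validated by those two
properties.

## Null alleles

The EM estimator treats each observed homozygote i/i as a mixture of true
i/i and i/null, and — under the blank-as-null-homozygote model — each blank
as null/null. Without that model the likelihood is conditioned on
visibility (truncated EM, imputing the expected number of unseen null
homozygotes each step). Convergence: max frequency change < 1e-9 or 10,000
iterations; the log-likelihood is asserted non-decreasing on every run.
Measured accuracy: mean absolute error < 0.01 at n = 500 per population
over ancestral null frequencies 0.05–0.2.

ENA-corrected F_ST ("excluding null alleles") is computed as an
*EM-completed* Weir–Cockerham estimator: per-population frequencies come
from the EM (visible alleles plus a null class), apparent homozygotes are
split into true homozygotes and visible/null heterozygotes using the EM
posterior weight p²/(p² + 2pq), and the null class's terms are then dropped
from the component sums. Two properties motivated this construction over a
frequency-only (gene-level) θ: it reduces *exactly* to the uncorrected
genotype-level estimator when all null frequencies are zero, and on
simulations it removes most of the upward bias that apparent homozygote
excess puts into the uncorrected estimate (measured: bias −0.0015 vs
+0.0040 at 3 × 50 individuals, true differentiation 0.05, null frequency
0.2).

INA-corrected chord distances insert the EM null frequency q of the
individual's population as an extra profile class (visible profile scaled
by 1 − q), so apparent homozygotes are no longer certainly identical;
blanks at recoded loci become pure-null profiles. Locus distances
d = (2/π)·sqrt(2(1 − Σ√(x·y))) are averaged over loci typed in both
individuals — averaging, not summing, so individuals with missing loci
remain comparable. The (2/π) normalization is stated explicitly because
chord-distance conventions differ across software.

## Marker QC

* **Short-allele dominance**: one-sided (negative) Spearman correlation of
  per-allele F_IT with allele size; a weighted least-squares regression of
  per-allele F_IS on size with weights p(1−p) (one-sided negative slope)
  serves as confirmation. A locus is flagged only when the BH-adjusted
  Spearman arm and the regression arm agree.
* **Stuttering**: the expected share of one-motif-step pairs among
  heterozygous pairs is computed from the allele frequencies under
  within-population random mating; the observed one-step count among
  observed heterozygotes is tested with a one-sided (deficit) exact
  binomial, and per-population p-values are combined with the generalized
  binomial. The cited stuttering method is not reprinted in the source
  literature; this one-step-deficit construction is the natural statistic
  for the artifact (stuttering converts one-step heterozygotes into
  homozygotes for the longer allele) and its remediation path is the
  allele-pooling cure (single-linkage classes of sizes within 1–2 bp).
  Measured power at a strong setting (miscall rate 0.3, three subsamples of
  200): ≈ 0.55 at α = 0.05, with the false-positive rate at the nominal
  level.
* **Outlier rules**: a locus is an F_IS/F_ST outlier when its per-locus
  value falls outside the multilocus bootstrap CI; the exclusion rule
  (configurable) discards loci that are F_ST outliers *and* either F_IS
  outliers or members of a BY-significant LD pair — the signature of
  selection or shared artifacts rather than demography. Loci with > 50%
  missing data are dropped outright.

## Demography

* Heterozygote-excess Ne = −1/(2 F_IS) − F_IS/(2(1+F_IS)), applied only to
  loci with F_IS < 0 and averaged. Conditioning on an observed excess
  biases the estimator low at small sample sizes; on Wright–Fisher
  simulations at Ne = 25 the median estimate lands within an order of
  magnitude of the truth, which is how the estimate should be read.
* LD-Ne: Burrows composite disequilibrium Δ̂ between all pairs of unlinked
  loci, squared correlation r² = Δ̂²/(v_u v_v) with the composite variances
  v = E[x²]/2 − 2p², alleles below Pcrit = 0.05 dropped, one allele per
  locus dropped (compositional redundancy), sample size taken pairwise
  (individuals typed at both loci — the missing-data adjustment). The
  drift signal is r̄² minus the sampling expectation (1/S + 3.19/S² for
  S ≥ 30; the small-S variant otherwise), inverted through the
  random-mating quadratic. Non-positive drift signal → infinite estimate,
  flagged; the parametric CI treats the allele-pair comparisons as
  chi-square degrees of freedom. Median recovery on Wright–Fisher truth
  Ne = 100 (20 loci, 50 sampled): within [50, 200].
* Island model: Nem = (1 − F'ST)/(4 F'ST) with F'ST = F_ST(ENA)/F_ST_max,
  the maximum computed on Meirmans-recoded data (each population's alleles
  made private). The same ENA correction is applied to numerator and
  denominator, which keeps F'ST exactly 1 for populations sharing no
  alleles and reduces to the plain recoded maximum at zero null frequency.
  CIs transform the F'ST CI endpoints through the (monotone decreasing)
  Nem map.
* Geodesics: Vincenty's inverse solution on the WGS84 ellipsoid,
  implemented directly (no geodesic library is a dependency); distances
  agree with an R `geosphere::distGeo` oracle to the metre on the study
  coordinates. A spherical great-circle formula is ~4 km off at these
  distances and would not reproduce the published 1159/2693 km extremes.
* Dispersal: m = Nem/Ne for the minimum/average/maximum Ne, δ = m × D_geo
  per pair and for the mean pairwise distance; yearly migrants multiply
  Nem by the generations per year (default 12, a one-month generation).

## Synthetic data

The generator draws ancestral allele frequencies from a symmetric
Dirichlet, per-population frequencies from Dirichlet(p(1−F)/F)
(Balding–Nichols, exact one-parameter control of the target F_ST), and HWE
genotypes within populations. Allele sizes sit on the motif lattice as
near-contiguous ladders (steps of one repeat with occasional two-repeat
gaps), matching how stepwise mutation shapes real marker panels — this
matters for the stuttering test, which needs one-step neighbours to exist.
Defaults mirror the study layout: three subsamples of 24 (12 F/12 M),
11 di-/tri-nucleotide loci, sizes 130–310 bp including the adapter tail.

Artifacts are generative: the null is a hidden allele whose per-population
frequency is drawn from the same Balding–Nichols marginal as real alleles
(visible/null heterozygotes become visible homozygotes; null homozygotes
become blanks; the truth record keeps the full-system genotypes, so tests
can compare estimators against the realized truth); stuttering miscalls
one-step heterozygotes as long-allele homozygotes at a fixed rate;
short-allele dominance drops the longer allele with probability
proportional to the size difference; random technical dropout comes last;
sex-linked loci make females hemizygous and read homozygous.

What passing synthetic tests shows: the estimators and tests are correct
for data that satisfy their own assumptions (island model, HWE within
populations, independent loci, the artifact models above). What it does
not show: robustness to features real data may add — linked loci,
isolation by distance, age/size structure, allele-calling noise beyond the
modelled artifacts, or selection at the markers themselves.

## Problem sizes and numerics

Default analysis settings are the study protocol's (10,000 permutations,
5,000 bootstraps, BY for the LD family, BH elsewhere). The test-suite and
the acceptance script scale Monte-Carlo studies to keep a full run in
minutes on one CPU: permutation calibration uses 1,000 replicates × 150
permutations; power studies use 60–100 replicates at the strong artifact
settings; F_ST-recovery uses 50 replicates of 3 × 50 × 20 loci; the
LD-Ne check uses 12 Wright–Fisher populations of 100 for 100 generations.
EM tolerance 1e-9; permutation ties counted as extreme; bootstrap CIs are
percentile intervals; NJ clamps negative branch lengths to zero with the
difference moved to the adjacent branch.

## Known limitations

* Only two of the five effective-size estimators used in comparable field
  studies are implemented (heterozygote-excess and LD); coancestry,
  identity-probability and sibship methods are out of scope, so
  grand-average Ne values from such studies are not directly comparable.
* The ENA/INA algebra and the stuttering statistic follow the published
  descriptions of their sources, which do not print the exact algorithms;
  both are validated by reduction and simulation properties rather than
  against the original binaries.
* The exclusion rule for outlier loci codifies a judgment call; it is
  configurable and its decisions are logged rather than silently applied.
* Admixture-style Bayesian clustering is deliberately absent; the
  individual-level chord-distance/NJ view covers outlier-individual
  detection.
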