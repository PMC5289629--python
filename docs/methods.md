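# Methods

## The model

`regionsim` simulates a single gene region — roughly 100 kb of human
genome — evolving forward in time in a diploid Wright–Fisher
population under recurrent unconditionally deleterious mutation,
recombination, Gaussian stabilizing selection on a quantitative
(disease-liability) phenotype, and drift.

Mutations occur under the infinitely-many-sites model at continuous
positions on [0, 1); genetic and physical maps coincide, so at full
scale (N = 20 000, mu = 0.00125 per gamete per generation,
r = 0.00125 per diploid) the region has theta = rho = 100.  A causal
mutation receives a trait effect c drawn once from an Exponential
distribution with mean lambda; effects never change, and there are no
trait-decreasing (compensatory) mutations, so every causal mutation is
expected to be deleterious.  Neutral mutations (effect 0) occur at ten
times the causal rate and serve as markers.

Three genotype-to-phenotype maps are implemented:

* **AC (additive co-dominant)** — G is the sum of effects over both
  haplotypes.
* **GBR (gene-based recessive)** — each haplotype gets a score (the sum
  of its effects) and G is the geometric mean of the two scores.
  Recessivity is a property of the *gene region*: a compound
  heterozygote (Ab/aB) carries no wild-type haplotype and is affected —
  mutations in the region fail to complement.  Equivalently, the model
  encodes cis-acting intralocus epistasis.
* **MR (multiplicative recessive)** —
  G = prod_het (1 + h c) * prod_hom (1 + 2c) − 1 over sites, with
  site-level dominance h (h = 0, "cMR", makes compound heterozygotes
  wild type; h = 1 approximates AC for small effects).  The −1 is part
  of the genetic value so that an unmutated individual has G = 0 and
  fitness 1; this realizes the "subtract one from the phenotype"
  convention exactly once.  Zygosity is per exact position — under
  infinite sites, homozygosity arises only by identity by descent.

Phenotypes are P = G + E with E ~ N(0, sigma_e^2) drawn fresh every
generation (environmental noise is not heritable); sigma_e^2 stands in
for both true environmental variance and the rest of the genome.
Fitness is Gaussian stabilizing selection around an optimum of 0:
w = exp(−P² / (2 sigma_s²)) with sigma_s = 1 throughout.  In the
strong-selection (house-of-cards) regime the equilibrium genetic
variance is approximately 4 mu_d sigma_s² for additive gene action and
2 mu_d sigma_s² for recessive gene action, independent of N and
lambda — the property that makes scaled-down runs quantitatively
comparable to full-scale ones.

## Parameters that matter

| parameter | meaning | default |
|---|---|---|
| N | diploid population size | 20 000 (x scale) |
| burn-in | generations at constant N | 8N |
| mu | neutral mutation rate / gamete / generation | 0.00125 |
| mu_d | causal mutation rate | 0.1 mu |
| r | crossover rate / diploid / generation | 0.00125 |
| lambda | mean (and SD) of trait effects | study grid 0.01–0.5 |
| sigma_s | width of the fitness function | 1 |
| sigma_e | environmental SD | tuned per model so E[H²] is 0.08 or 0.04 |
| h | MR dominance for trait effects | 1 (co-dominance) |

The sigma_e values pairing each model with a target heritability are:
H² ~ 0.08 — AC 0.075, GBR/cMR 0.053, iMR(h=0.25) 0.068;
H² ~ 0.04 — AC 0.11, GBR/cMR 0.075, iMR 0.098.

Demographies: constant N; "growth" (500 generations of exponential
expansion 2e4 → 1e6 appended to the burn-in); and a European-ancestry
piecewise preset (ancestral 7310, growth to 14474, out-of-Africa
bottleneck 1861, second bottleneck 1032, two-phase exponential growth
to 512 000; no migration), stored as editable package data.

**Scaling.** `scale` multiplies N and epoch durations while holding
per-gamete rates fixed.  This preserves the house-of-cards V_G and
hence H², but *not* frequency-spectrum-dependent quantities: theta and
rho shrink with scale, so there are fewer, relatively more-drifted
segregating sites.  In particular the GBR equilibrium V_G, which
depends on two-haplotype coincidences, is inflated by ~25% at
scale = 0.05 (N = 1000) relative to N >= 2000 runs; passing scaled
tests therefore validates the machinery and the additive-model
quantities tightly, and the recessive-model quantities to within that
small-N inflation.

## Engines

Two implementations of the generation loop produce bit-identical
results from the same seed (asserted in the test suite): a readable
vectorized-numpy loop and a numba kernel storing gametes as sparse
mutation-id lists (at these mutation rates a gamete carries O(1)
mutations, so sparse copies beat dense matrices by the region length).
Parent selection uses rejection sampling with the natural envelope
w <= 1; each accepted integer draw over gamete rows encodes both the
parent and the transmitted gamete.  Crossovers are Poisson-thinned:
the generation's total crossover count is Poisson(r * 2N) and each
lands on a uniform offspring gamete.  Fixed mutations are pruned from
gametes every generation and logged with their effects, so the fixed,
segregating and total components of genetic load remain computable
(the total is not the sum of the parts under Gaussian fitness).

## Downstream analyses

**Variance partitioning.** True genetic values are regressed on the
additive (0/1/2) dosage codes — and jointly on the orthogonal
dominance codes (0, 2q, 4q−2), constructed to be uncorrelated with
dosage under Hardy–Weinberg — of all causal sites with risk-allele
frequency q <= x, columns ordered by decreasing frequency then effect.
The adjusted r² of each fit is the cumulative fraction of V_G
explained; the joint-versus-additive difference is the dominance
share.  Regression (rather than per-site formulas) is required because
a GBR variant's effect depends on its haplotype background.  Rank
deficiency is handled by the least-squares pseudoinverse with the
effective predictor count taken from the design rank; a
causal-monomorphic population returns 0 by convention.

**GRMs and Haseman–Elston regression.** Additive GRM entries
standardize dosage by sqrt(2q(1−q)); dominance GRM entries use the
HWE-centered orthogonal code over its HWE variance (2q(1−q))².  HE
regression regresses pairwise products of standardized phenotypes on
GRM off-diagonals (jointly across components or MAF bins); the
coefficients estimate variance fractions.  The standard orientation
(cross-products as response) is used; the reverse orientation gives
identical t-statistics but different coefficient scales.

**Twin studies.** MZ pairs share one recombinant gamete per parent and
differ only in E; DZ pairs get independent gamete pairs.  Couples are
sampled without replacement; there is no shared environment.
H² = r_MZ, delta² = 2(r_MZ − 2 r_DZ), h² = 4 r_DZ − r_MZ, with
double-entry Pearson correlations.  Replicate studies are pooled
before computing correlations.  Under AC, delta² is centered at zero;
under GBR, compound-heterozygote recessivity depresses r_DZ and
surfaces as positive delta² — non-additivity that per-site dominance
GRMs cannot capture, reproducing the twin-versus-SNP discrepancy.

**Case-control GWAS.** Cases are drawn uniformly from the top 15% of
phenotypes (empirical quantile), controls from within 0.5 SD of the
mean, disjointly and without replacement; the minor allele is defined
within the panel.  The single-marker test is a minor-allele-dosage
logistic regression with a likelihood-ratio p-value, implemented as a
sufficient-statistics Newton solver vectorized across sites (dosage
has three levels, so six counts per site determine the likelihood);
perfectly separated or monomorphic sites are flagged with p = 1.  A
"gene chip" keeps panel-MAF >= 5%; "resequencing" keeps all
polymorphic sites.  Power is the fraction of replicates whose smallest
p-value reaches the threshold.  For top-hit MAF distributions, chip
markers are subsampled to a flat MAF histogram (20 bins on
[0.01, 0.5], each bin cut to the smallest non-empty bin's count) after
removing MAF < 0.01, ties for the top hit are broken at random, and
simulated and empirical MAF sets are compared by a two-sample KS test.

**Region tests.** Common variants (panel MAF >= 0.05) are removed
first.  c-Alpha measures overdispersion of the case/control split of
minor-allele copies; SKAT is the score statistic Q = r' G W W' G' r
with linear or Beta(1,25) weights; ESM_K sums the excess of the K
(default 50) smallest single-marker −log10 p-values over their
uniform-order-statistic expectation.  With linear weights Q equals
c-Alpha plus a label-invariant constant, so the two are identical
under permutation — the package exploits this as a cross-check.
Significance is by case/control label permutation with the add-one
convention; inside permutation loops ESM uses a vectorized
allele-count chi-square as the per-site test.  Adaptive early stopping
(99% CI excluding alpha) is available but off by default.

## Study sizes used by the packaged checks

The packaged tests and the acceptance script run the study at
scale = 0.05 (N = 1000, 8000-generation burn-in), a size at which the
preserved quantities are measurable on a single CPU: 20 replicates per
heritability condition with V_G averaged over the second half of the
burn-in; 100 replicates per association condition with panels of 150
cases and 150 controls (15% of the population per stratum, mirroring
the full-scale 3000 of 20 000) and desk-scale significance thresholds
of 1e-4 (single marker) and 1e-3 with 2000 fixed permutations (region
tests), preserving the alpha x permutation pairing of the full-scale
design; and 100 twin-study replicates of 80 MZ + 160 DZ pairs (the 2:1
DZ weighting minimizes the variance of delta² at fixed pair budget).

## What the synthetic data do and do not show

The simulator *is* the study's data-generating process, so the tests
validate the machinery, the exact identities (additive variance curves
reaching unity, c-Alpha/SKAT equivalence, estimator algebra) and the
directional phenomena (growth inflating rare-variant shares, GBR
leaving variance unexplained, permutation tests calibrated).  They do
not show anything about real genotype data: there is no genotyping
error, imputation, population structure, covariates, shared twin
environment, or linkage to flanking regions, and sigma_e absorbs the
entire rest of the genome.  Scaled runs additionally understate the
number of segregating sites and modestly inflate recessive-model
variance (above).

## Numerical choices and degenerate inputs

Adjusted r² uses the standard small-sample correction and refuses
designs with p >= n − 1.  The logistic solver clips Newton steps to
±5, caps iterations at 40, detects perfect separation by disjoint
dosage supports, and never fails a whole scan on one site.  Empirical
p-values use (1 + exceedances) / (1 + permutations), making the null
distribution super-uniform and the smallest achievable p equal to
1/(B+1).  Position collisions (probability zero in floating point) are
resolved by redrawing.  GRMs reject monomorphic sites.  Loads are
computed from genetic values (environment-free) in time series.

## Known limitations

Single region only (no multi-locus whole-trait simulation); no
migration or multiple concurrent populations; REML-based variance
components (GREMLd) are out of scope — HE regression is the in-package
estimator; SKAT's analytic (Davies) p-values are not implemented, as
permutation significance is the point of comparison; no SKAT-O grid.
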