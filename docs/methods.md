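# Methods

`apicomp` implements an absolute-abundance and compositional analysis of the
honey bee queen gut microbiota sampled from four alimentary-tract niches
(mouth, midgut, ileum, rectum) in a two-way design (chronological age class
x queen source), with fat-body protein carbonyl as a biological-age
covariate. This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## From reads to cells

Amplicon reads count 16S rRNA *gene copies*, not cells: a genome carrying
four rRNA operons contributes four reads for every one contributed by a
single-operon genome at equal cell density. Given a sample's proportional
read abundances `p_i`, per-genome copy numbers `c_i`, and the qPCR estimate
`T` of total gene copies per extraction, cell abundance is estimated as

    cells_i = T * p_i / c_i.

The copy-number map carries four copies for the core phylotypes
(*Lactobacillus* firm5 and firm4, *S. alvi*, *G. apicola*, *Delftia*), five
for *L. kunkeei*, two for *B. asteroides*, one for *P. apium*, and one for
Acetobacteraceae Alpha 2.1 by affinity with its closest relative. OTUs
outside the nine-member panel are pooled into an `other` column corrected
by the mean copy number 4.2.

Two conventions deserve comment:

* **Direction of the copy-number correction.** Cell abundance requires
  *division* of gene-copy mass by per-genome copy number; multiplying
  would double-count multi-operon genomes. The multiplication variant is
  still exposed (`convention="multiply"`) for sensitivity checks.
* **Proportion base.** By default proportions are taken over *all* reads,
  so panel plus `other` partitions the community and the copy-weighted
  total is conserved exactly: `sum_i cells_i*c_i + other*4.2 = T` to
  floating-point precision for every sample. A `renormalize="panel"`
  option instead renormalises over the panel alone (then
  `sum_i cells_i*c_i = T`); the partition convention is the default because
  it keeps the pooled fraction on the same absolute scale as the panel.

## Compositional transform

The centered log-ratio transform `z_i = ln x_i - mean_j ln x_j` is applied
per sample to the cell panel. Rows sum to zero and the transform is
invariant to per-sample scaling, which makes the scores usable by ordinary
multivariate machinery. Zeros are handled by multiplicative replacement
with a half-read equivalent in cell units (`0.5/N * T/c_i` for a sample
with read total `N`), a conventional compositional pseudocount; the policy
is recorded on the `ClrMatrix` object. Because a CLR matrix over `k`
components has rank `k-1`, MANOVA responses are the nine named-OTU columns
of the CLR computed over the ten-component panel (nine OTUs + `other`),
which keeps the error cross-product matrix nonsingular while preserving
the "OTUs 1-9 as dependent variables" framing.

## Statistical models

* **MANOVA / MANCOVA (Pillai's trace).** Two-level factors are coded
  sum-to-zero; hypothesis cross-products use Type III contrasts so term
  tests are order-invariant in the unbalanced 16/16/15/16 design. Pillai's
  `V = sum lambda/(1+lambda)` over eigenvalues of `E^-1 H` is converted to
  an F via the standard `(s, m, n)` approximation, exact at `s = 1`.
  Covariates (log carbonyl) enter as regression columns; a constant
  covariate is dropped with a warning. Verified against an independent
  MANOVA implementation to 1e-8 in the test suite.
* **Rank tests.** Wilcoxon rank-sum per taxon on normalized cell
  abundances, exact null enumeration when both groups have n <= 8 without
  ties, tie-corrected normal approximation otherwise. Corrections:
  Bonferroni, Benjamini-Hochberg, and Benjamini-Yekutieli. The study's
  analysis lists "FDR" alongside Benjamini-Hochberg even though BH is
  itself an FDR procedure; the separate label is implemented as BY, the
  standard stricter FDR control under dependence. All three adjusted
  columns are always reported.
* **ANOSIM.** `R = (rB - rW)/(M/2)` on ranked distances, p by label
  permutation with the observed labelling counted in numerator and
  denominator; an exhaustive mode enumerates all label permutations for
  small n.
* **DistLM.** Gower-centered `G = -1/2 J D^2 J`; pseudo-F partitions
  `tr(G)` by the predictor's hat matrix; p by permuting raw predictor rows
  (default) or reduced-model residuals — for a single predictor block the
  two schemes permute the same exchangeable set. On Euclidean distances of
  a univariate response the pseudo-F reduces algebraically to the
  classical regression F, which the tests exploit as an oracle.
* **CLR-PCA.** Eigendecomposition of the CLR covariance;
  covariance-biplot scaling (loadings are eigenvectors scaled by the root
  eigenvalue, so vector length is proportional to the standard deviation of
  that taxon's log-ratio to the rest). Carbonyl is rendered as a
  supplementary vector via its correlation with the sample scores, never
  entering the decomposition.
* **SparCC.** Basis correlations from the log-ratio variance matrix
  `t_ij = var(log x_i/x_j)` under the sparse-correlation approximation;
  fractions are Dirichlet-posterior means with an add-one prior; up to 20
  exclusion rounds remove the most correlated pair above |rho| = 0.1 and
  re-solve, matching the reference implementation's conventions (the
  original study used a ported implementation without stating parameters,
  so these defaults are declared, not inferred). Bootstrap pseudo
  p-values: `(1 + #{|rho_boot| >= |rho_obs|})/(1 + n_boot)` over
  column-wise count shuffles. Estimates are flagged unreliable when the
  count panel exceeds 70% zeros — strictly greater than, so a panel at
  exactly 70% is not flagged.
* **Distances.** Bray-Curtis on copy-corrected relative abundances is the
  default companion for ANOSIM/DistLM; Euclidean-on-CLR is available. The
  source analysis does not name its metric; the choice is logged in every
  run log.

## Carbonyl assay

Beer-Lambert with the millimolar extinction coefficient of aliphatic
hydrozones (22 mM^-1 cm^-1) at 345 nm: `mM = A345/(22*path)`;
`nmol = mM * volume_ul` (1 mM = 1 nmol/ul); result per mg protein. Path
length defaults to 1 cm (cuvette geometry unspecified in the assay
description) and the log transform defaults to natural log (the base used
upstream is unstated; it only rescales correlations' inputs
monotonically). Zeros are offset to half the smallest positive value
before logging.

## Synthetic-data generator

The generator emulates the real design so every stage is testable without
study data: 63 queens (16 young CA, 16 old CA, 15 young AZ, 16 old AZ),
one sample per queen x niche (252 libraries). Per sample, counts are
Dirichlet-multinomial around an effect-shifted niche base composition;
sequencing depth is lognormal around the reported per-niche averages
(21/25/30/38 K reads); qPCR totals are lognormal around the reported
community sizes (mouth 1.4 M, midgut 14.2 M, ileum 17.9 M, rectum
121.2 M gene copies). Base compositions encode the reported structure:
mouth/midgut dominated by *P. apium* + *L. kunkeei*, hindgut dominated by
firm5 with asteroides/firm4 rising toward the rectum; the pooled rare mass
(1.5-2.3% per niche) is split over 51 rare OTUs with shallow power-law
weights, which under the Dirichlet makes them individually sparse
(median prevalence ~7%). Age and source effects are multiplicative
(2^log2) shifts in composition space followed by renormalisation, with
default directions following the reported age succession. Carbonyl is an
age-class mean (4 vs 8 nmol/mg, sd 1.5) plus a source shift plus optional
slopes on centered rectum CLR scores, truncated at zero.

Dispersion calibration: the study's qPCR spread within cohorts is not
reported, so the generator's noise scales are set by the detectability the
design is required to have — a 2-fold (log2 = 1) age effect on a
mid-abundance taxon must be recoverable by the BH-corrected Wilcoxon
battery at n = 16 per group with power >= 0.8. Dirichlet concentration 80
per niche with qPCR geometric log-sd 0.25 (about a 1.3-fold geometric
spread) encodes that condition; both are single config fields for
sensitivity analyses.

What the generator does **not** emulate: read-level error, primer or
chimera artefacts, phylogenetic correlation among rare taxa, batch or
extraction effects, and any queen-level correlation between niches beyond
the carbonyl linkage. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under the assumed
generating process, not that the biological conclusions of any particular
real dataset would reproduce.

## Numerical choices and degenerate inputs

Ties in OTU ranking break by OTU id. All-zero samples are excluded with a
logged warning (the real study excluded four mouthpart libraries).
Percent change with age is `100*(old-young)/young`, bounded below by -100
(cell loss cannot exceed 100%) and undefined (NA) at a zero young mean.
Negative SparCC basis variances are clipped to 1e-10 with a warning;
exclusion stops before any taxon drops below three partners. Permutation
p-values always include the observed arrangement. Exact rarefaction uses
the hypergeometric expectation with log-gamma arithmetic. Every
stochastic stage takes a seed derived deterministically from the run
seed, so report bundles are byte-identical across reruns.

## Problem sizes used by the test suite

Type-I error calibration runs 2000 null replicates of one 63-sample niche
per battery (MANOVA, MANCOVA, Wilcoxon+BH, ANOSIM and DistLM at 99
permutations each); power uses 500 replicates at n = 16 per group; SparCC
recovery uses 20 taxa x 500 samples; the determinism check runs the full
252-sample pipeline twice at 999 permutations. `scripts/acceptance.py`
runs the complete default study once with 999 permutations and a
100-shuffle SparCC bootstrap.

## Known limitations

The Pillai F is approximate for s > 1 terms (exact for the two-level
factors used here). The whole-gut projection assumes the per-niche qPCR
totals are unbiased for the niche's share of the gut; differential
extraction efficiency between tissues would bias it. The caste-specificity
rule is implemented generically over any two phenotype groups; applying it
to queens vs workers requires a user-supplied worker table, and the
pipeline's built-in report uses the two age classes as the grouping when
no worker data is given.
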