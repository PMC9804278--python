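# Methods

This note documents the models implemented in `conunit`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate about real data.

## Filtering (genotypes)

The cascade runs in a fixed order: (1) individuals with >55% missing
genotypes; (2) SNPs absent from any site ("common across sites"); (3) global
minor allele count < 10 (the MAC > 9 rule); (4) per-SNP mean depth outside
[6, 100] — per-genotype depth thresholds are not applied, only the mean
across genotyped individuals, with inclusive bounds; (5) call rate < 80%;
(6) whole loci carrying more than 7 SNPs (a paralog/misassembly signature);
(7) one SNP per locus, keeping the highest-MAC SNP and breaking ties toward
the smallest within-locus position (deterministic); (8) a Hardy–Weinberg
screen — the two-sided exact test on heterozygote counts (full conditional
enumeration, no mid-p correction), dropping SNPs with p < 0.05 in five or
more sites, evaluated only at sites with ≥10 individuals; (9) an
all-heterozygote screen at sites with ≥7 genotyped individuals. The cascade
is idempotent and its report reconciles (removed + remaining = input) at
every step.

## Diversity and differentiation (popgen)

Expected heterozygosity uses the small-sample factor 2n/(2n−1) on 2p(1−p).
Nucleotide diversity divides the summed per-SNP expected heterozygosity by
an explicit assayed length in bp: RAD-style π is computed over all assayed
positions, most of which are invariant, which is why published π values are
two to three orders of magnitude below He. The denominator is a parameter;
synthetic runs use n_SNPs × 90 bp, emulating 90-bp RAD loci after
one-SNP-per-locus thinning.

Weir–Cockerham θ is the two-population 1984 estimator with the observed-
heterozygosity term, combined across loci as a ratio of summed components
Σa / Σ(a+b+c) (not a mean of per-locus ratios). Loci monomorphic within a
pair are skipped; negative θ is reported unclamped. Nei's standard distance
averages J_x, J_y, J_xy over loci and sets D = −ln I, with D = ∞ when
I = 0 (no shared alleles).

## LD effective population size (ne)

For unphased diploid dosages the Burrows composite correlation is
algebraically the Pearson correlation of the two dosage columns; the
implementation computes it that way (vectorized, pairwise-complete over
missing genotypes) and multiplies each pair's r² by (S/(S−1))², the
small-sample bias factor of the composite estimator. That factor matters:
the sample-size expectations E(r²_S) = 1/S + 3.19/S² (S ≥ 30) and
0.0018 + 0.907/S + 4.44/S² (S < 30) are calibrated to the bias-corrected
estimator — numerically both curves equal (S/(S−1))²/(S−1) to four decimals
— so subtracting them from a plain Pearson mean r² would over-correct and
inflate Ne roughly twofold.

r̂²′ = mean r̂² − E(r²_S) is inverted to Ne with the S-regime-specific
quadratic roots; a non-positive r̂²′ or negative discriminant yields +∞ (no
detectable drift signal). S is the harmonic mean of per-pair shared sample
sizes; all pairs are weighted equally. Alleles below Pcrit (defaults 0.05
and 0.10; the 0.05 run is the headline) drop the whole SNP. Confidence
intervals come from a delete-one-individual jackknife on r̂²′ mapped through
the same inversion (the estimator is monotone decreasing, so the upper r̂²′
bound gives the lower Ne bound); the individual jackknife was chosen over a
locus-pair jackknife because locus pairs sharing a locus are not
independent. The chromosome-number correction divides point estimate and CI
bounds by 0.098 + 0.219 ln C (C = 13 chromosome pairs by default, matching
the study species' karyotype); the divisor is < 1 for C < 61.5, so the
correction inflates estimates, compensating the downward bias from
physically linked pairs retained in a finite genome.

## Genotype–environment association (gea)

`fit_rda` implements RDA as column-centred multivariate least squares
followed by an SVD of the fitted values; with conditioners, response and
predictors are first replaced by their residuals (pRDA). Eigenvalues follow
the variance convention s²/(n−1). SNP columns are centred but not
variance-scaled by default; the model exposes both the raw SVD axis loadings
(the "species scores" convention of the RDA-GEA literature) and per-SNP
correlations with each axis. Outlier detection z-scores the raw loadings per
axis and flags |z| ≥ 3.5 on any scanned axis, assigning each candidate the
predictor with the largest |Pearson r| to its genotype column. Raw loadings
are used because they are sums across rows (approximately normal under the
null), so the SD-threshold rule has close to the nominal normal tail mass;
per-SNP correlations at ~30 sites are bounded and noticeably lighter-tailed,
which would systematically under-flag.

Two analysis choices differ between real and synthetic data, deliberately:

- **Conditioning.** On real data the pipeline conditions on genotype PCs
  (default 7, configurable) to absorb population structure. The island-model
  generator has no neutral spatial structure, so its top PCs are dominated
  by the coordinated adaptive/environment direction itself; conditioning on
  them would remove the planted signal by construction. Synthetic power
  analyses therefore use ordinary RDA.
- **Axes scanned.** The default scans the first two constrained axes. With
  three deliberately weakly correlated synthetic predictors the three
  constrained eigenvalues are near-equal, making any two-axis restriction an
  arbitrary rotation; synthetic analyses scan all three axes (the screeplot
  logic used in practice to pick the axis count).

Batch (lane) effects are removed by an RDA on batch indicator variables with
a ±4 SD loading threshold on the first constrained axis. Missing genotypes
are imputed by the per-site modal genotype (global mode as fallback, ties to
the lower dosage); the imputer is pluggable, and mode imputation is the only
built-in.

## Gravity models (gravity)

Flow (1 − Nei's D) between sites is modelled on the log scale as a linear
function of log distance, log at-site covariates of the edge's origin node,
and log between-site covariates, with a random intercept per origin site —
the singly constrained form that accounts for the non-independence of edges
sharing a site. The origin is the lower-indexed node at graph-build time,
recorded per edge. Covariates that are not strictly positive (e.g.,
temperatures in °C, z-scored indices) are shifted by 1 − min before the log;
shifts are learned at fit time, stored with the model, and re-applied at
prediction.

Model competition uses ML fits and AICc with k = fixed effects (including
the intercept) + 2 variance parameters; the landscape-term count (distance +
at-site + between-site, the convention of published hypothesis tables) is
reported alongside. Coefficients are reported from REML fits with 95%
Wald-type CIs using a t quantile at (number of origin sites − 1) degrees of
freedom — a between–within approximation; plug-in normal quantiles
noticeably undercover site-level terms when there are tens of clusters.
Even so, simulated coverage of cluster-level coefficients sits near 93–95%
rather than exactly 95%, the familiar cost of not propagating
variance-parameter uncertainty (a Kenward–Roger-style correction is out of
scope). Fits that fail to converge or return non-finite standard errors
fall back to OLS (the correct σ_u → 0 limit) and are flagged; flagged fits
are excluded when choosing the best model, mirroring the treatment of a
non-convergent global model in practice.

Back-transformed predictions use the Duan smearing factor φ = mean(exp(e))
over conditional residuals, so φ → exp(σ_e²/2) for Gaussian residuals;
population-level predictions (random effects at zero) are φ·exp(Xβ̂),
clipped to ≤ 1 with a logged count. Graphs are Delaunay triangulations or
saturated; pruning removes edges above a distance threshold (50 km for
fitting networks, 15 km — the observed maximum multiyear dispersal — for
prediction). Betweenness is Freeman/Brandes on the unweighted graph
(a length-weighted option exists, off by default); alpha centrality solves
(I − αAᵀ)x = 1 with α = 0.85/λ_max. Edge covariates take the median of
raster cells intersecting the straight segment, optionally buffered; the
native cell width is the default since medians are nearly width-invariant
on smooth surfaces.

## AMOVA (amova)

Three strata: among groups, among sites within groups, within sites. Sums of
squares come from pairwise squared Euclidean distances between individual
dosage vectors (missing entries mean-imputed per SNP after pruning SNPs with
≥5% missingness); variance components use the standard unbalanced-design
expected-mean-square coefficients, and negative components are reported
flagged rather than truncated. There is no within-individual stratum — the
decomposition matches three-stratum published layouts. Percentages are
components over their total; an all-identical input is flagged degenerate
with zero components. Permutation significance testing is omitted: the
comparison of groupings uses only percent variance among groups, reported
next to the group count (a grouping with many singleton groups can buy
variance explained at the cost of useless units).

## Synthetic data (synth)

The generator's defaults describe one fixed study condition set: 31 sites ×
12 diploids (the study's modal sample size), 5,000 neutral + 50 adaptive
loci, island-model F_ST = 0.2, 5% missing genotypes, Poisson(30) depths
(≈ the study's 29× mean coverage), a 60-km landscape at 30-m cells, and
three climate predictors (two orthogonal precipitation trends plus a
noise-driven winter minimum temperature) with two topographic covariates
(cti, hli) for gravity modelling.

- **Genotypes.** Neutral deme frequencies are Beta((1−F)/F-scaled) draws
  around a Uniform(0.1, 0.9) ancestral frequency — the Balding–Nichols
  model, chosen because E(F_ST) = F gives a closed-form oracle. Setting
  `n_groups > 1` inserts a group level (Beta at `group_fst`) above demes for
  hierarchical-structure tests. Adaptive loci respond logistically to one
  standardized predictor with slope 1.0 per SD (a strong cline: allele
  frequency swings ≈ 0.12→0.88 across ±2 SD of environment) plus N(0, 0.02)
  noise.
- **Wright–Fisher.** A single diploid population of size Ne, run 4·Ne
  generations from Uniform(0.2, 0.8) frequencies with free recombination;
  drift decays heterozygosity as (1 − 1/(2Ne))^t, the oracle for LD-Ne.
- **Flows.** Generated from exactly the log-linear mixed model the fitting
  code assumes, with configurable site and residual noise (defaults 0.15 and
  0.2 on the ln-flow scale).
- **Determinism.** All randomness derives from a single seed through
  fixed per-operation substreams; identical configs give bit-identical
  output.

What the generator does *not* emulate: isolation-by-distance within the
neutral background (demes are exchangeable), linkage between loci,
sequencing error and allele-dropout, age structure, and the extreme
real-system differentiation (published pairwise F_ST reaches 0.75 between
disjunct regions, far above the simulated 0.2). Passing tests therefore
demonstrate estimator correctness under the stated models, not robustness
to these violations.

## Problem sizes

Simulation-based checks run at: F_ST — 24 sites × 12 diploids × 5,000 loci;
LD-Ne — 25 Wright–Fisher replicates (Ne = 50, 2,000 loci, 30 sampled);
GEA — one default-condition run (31 × 12, 5,050 loci) plus a 40,000-SNP
normal-tail check; gravity — 50 replicate fits on 100-site saturated graphs
(4,950 edges) and one ~10,000-edge run for the smearing limit; graph
metrics — exhaustive enumeration on 100 random ≤7-node graphs; AMOVA —
brute-force algebraic comparison on ≤9-individual instances and a 12-site
three-group hierarchy. These sizes keep the full suite under a minute of
simulation time while leaving comfortable statistical margins.
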