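# Methods

`barrierscan` asks a single compound question about a pair of hybridizing
sister species sampled across a contact zone: **do the loci underlying
intraspecific mating-trait variation coincide with the loci that act as
interspecific barriers to gene flow?** Answering it requires seven analysis
stages, each of which is implemented here against an explicit statistical
model, plus synthetic-data generators that plant known truth so that every
stage can be validated end to end without any sequencing data.

## Divergence scans (`divergence`, `integration`)

Site-wise differentiation uses the Weir & Cockerham (1984) variance-component
estimator: per site, components *a* (among populations), *b* (among
individuals within populations) and *c* (within individuals) are computed
from per-population sample sizes, allele frequencies and observed
heterozygosity; F_ST = a/(a+b+c). Sites monomorphic across all populations
are undefined (excluded from averages), and negative per-site estimates are
retained rather than clamped — clamping is available but biases multi-site
means upward. Multi-site summaries report both the per-site average
("mean of ratios", the headline style) and the ratio of summed components.

Nucleotide diversity (π) and absolute divergence (d_XY) are computed in
fixed, non-overlapping windows (10 kb by default) with *callable-site
denominators*: invariant genotyped sites contribute allele-pair comparisons
with zero differences, so windows with little variant data are not inflated.
Without callable-site counts the estimates fall back to variant-only
denominators and are flagged — these are not comparable across windows with
different missingness.

Outliers are the values at or above the empirical 99th-percentile threshold
(linear-interpolation quantile, ties included). The orchestrated scan plan
runs five comparisons — species A vs B overall, in allopatry only, in
sympatry only, and allopatric-vs-sympatric within each species — and the
"best-supported" barrier candidates are genes lying in **both** the F_ST and
the d_XY outlier regions. Outlier genes are called by strict SNP/window
overlap; the ±10 kb flank convention is reserved for trait-association gene
mapping.

## Introgression (`introgression`)

Patterson's D and f4 are computed from population-level derived-allele
frequencies: ABBA = Σ(1−p₁)p₂p₃(1−p₄), BABA = Σp₁(1−p₂)p₃(1−p₄),
D = (ABBA−BABA)/(ABBA+BABA), f4 = mean (p₁−p₂)(p₃−p₄). Sites are polarized
with an outgroup; by default only outgroup-fixed sites are used (the
polymorphism threshold is configurable). Significance comes from a
delete-one block jackknife over 20 contiguous equal-SNP blocks (count
configurable; the appropriate block size depends on the linkage scale of
the data). Trio enumeration tests every unordered population triple,
assigning P1/P2/P3 so the BBAA-like pattern sum is maximal and D ≥ 0, and a
trio is declared significant only when all three conditions hold: Z > 3,
Benjamini–Hochberg-adjusted p < 0.05 across all trios, and D > 0.05. Note
that the canonical D ≥ 0 ordering makes null trios report |D|, so mean-D
contrasts between trio classes are conservative.

## Demographic model comparison (`demography`)

Four two-population scenarios are compared on the unfolded joint SFS:
strict isolation (`no_mig`: nu1, nu2, T1), isolation with continuous
symmetric migration (`sym_mig`: + m), ancestral migration that ceased at T2
(`anc_mig`), and secondary contact beginning at T2 (`sec_contact`). Times
are in units of 2·N_ref generations, sizes relative to N_ref, migration in
units of 2·N_ref × rate.

Expected spectra come from a **Monte Carlo structured coalescent** rather
than a diffusion solver: genealogies are simulated backward in time with
per-deme pairwise coalescence rate 1/nu and per-lineage migration rate m/2
inside the model's migration epoch, and each branch adds its length to the
SFS cell of its subtended sample configuration. The same random seed is
reused at every likelihood evaluation (common random numbers), so the
Nelder–Mead simplex optimizes a fixed, internally consistent surface. The
composite likelihood is Poisson per unmasked cell with θ profiled
analytically (θ̂ = Σobs/Σmodel); the fixed corners [0,0] and [n1,n2] are
always masked. Optimization runs in rounds (default replicates 10/20/30/40)
of Nelder–Mead starts perturbing the incumbent best by log-uniform
fold-changes that shrink round by round; positivity is enforced by log
parameterization and T2 < T1 by a logit parameterization of T2/T1. Every
start supplies an explicit initial simplex (0.4 log-units per coordinate):
the library default simplex degenerates when a log-parameter starts at
zero. Because the Monte Carlo likelihood at the working replicate count
carries a parameter-dependent noise bias (under-sampled small cells are
log-penalized), fits finish with a polish on a 4× -replicate surface and
report their final log-likelihood at 10× replicates under a seed shared by
all models fitted with the same seed, so AIC differences are comparable.
`fit_model_sequence` fits a model set in order of parameter count, seeding
each richer model from the best nested fit plus small- and large-migration
anchors — the usual staged strategy that prevents a nested model from
spuriously "beating" its own generalization.
Projection to smaller sample sizes is exact hypergeometric redistribution.
Model fits and selection are validated at n = 8+8 haploids and 5,000 loci
with reduced rounds [5,10] and 1,000 Monte Carlo replicates per evaluation —
sizes chosen so a full model comparison runs in seconds while parameter
recovery stays within a few percent; the machinery is size-agnostic.
An independent cross-check against msprime's branch-length spectrum for the
same two-deme model is part of the test suite.

## Sweep scans (`selection`, `synthetic_data.simulate_forward_region`)

EHH at a flanking site is the probability that two haplotypes from the core
allele class are identical over the intervening stretch
(Σ C(n_g,2)/C(n,2) over identity groups). iHH integrates EHH against
physical distance by the trapezoid rule, outward in both directions, until
EHH drops below 0.05 (configurable); integrals that reach the region end
before crossing the cutoff are flagged truncated and kept, since simulated
regions are short. iHS_raw = ln(iHH_ancestral/iHH_derived) and scores are
standardized to mean 0/SD 1 within 20 equal-width derived-frequency bins;
outliers are |standardized| scores at or above the empirical 99th
percentile. Scans are run per species.

The forward simulator is a discrete-generation Wright–Fisher population
with random mating, Poisson(r·L) crossovers per meiosis and infinite-sites
mutation. Sweep runs use a neutral burn-in, then introduce a single
beneficial copy (additive fitness 1, 1+s, 1+2s) and condition on its
survival by restarting on loss, stopping when it reaches a target frequency
(0.9 in the validation fixtures). Population sizes are scaled down with
inflated per-bp rates; the validation fixture uses N = 1,500 diploids,
300 kb regions, μ = 2.5e-8 and r = 4e-8 per bp per generation with a
4N-generation burn-in. The scaled-down regime has a known artifact worth
stating plainly: at the end of a sweep the ancestral allele class has
collapsed through a bottleneck whose strength scales as 1/(N·s), leaving
clone pairs that inflate iHH_ancestral and shrink |iHS| at the core relative
to what an effectively infinite population would show. N = 1,500 keeps this
distortion modest; at N ≲ 300 it erases the signal entirely.

## Trait association (`association`)

The per-SNP model is y = Wα + xβ + u + ε with u ~ N(0, σ_g²K) and
ε ~ N(0, σ_e²I), where K is the centered-genotype relatedness matrix
K = ZZᵀ/(2Σf(1−f)) (missing dosages mean-imputed per site) and W holds the
intercept plus body-size covariates. K is eigendecomposed once; per SNP the
variance ratio λ = σ_g²/σ_e² is maximized by maximum likelihood on a coarse
log-λ grid (evaluated for all SNPs at once with GLS algebra) followed by
bounded Brent refinement, and the SNP effect is tested with a Wald statistic
against χ²(1). ML rather than REML keeps the per-SNP profile likelihood
closed-form; with K = I the scan reduces exactly to OLS. The multi-trait
scan (for CHC principal components) combines per-trait Wald z-scores into
Σz² against χ²(#traits) — an omnibus approximation to a full multivariate
mixed model, exact when traits are uncorrelated given covariates.
"BH" (Benjamini–Hochberg step-up) is the default multiple-testing
adjustment, with Bonferroni available.

## Genotype–environment association (`gea`)

SNP dosages are modelled as Y = XBᵀ + UVᵀ + E with X the standardized
environmental matrix (latitude, longitude) and U/V rank-K latent factors.
The factors are **initialized from the SVD of Y itself** and then refined by
alternating ridge estimation of B and truncated SVD of Y − XBᵀ. The
initialization matters: the (B, U) split is not identified where
environmental and structure axes align, and starting the factors from Y
ensures environment-aligned population structure is absorbed by U (where it
is held in check by collinearity in the scan) rather than laundered into
false environmental effects through B. Per SNP and environmental variable,
the z-score comes from joint regression of the dosage on [X, U]; the
genomic inflation factor GIF = median(z²)/0.4549 rescales the statistics,
and a SNP is an environmental hit only when calibrated p < 0.001 for *both*
variables — deliberately conservative, with no additional FDR step. K is a
configuration parameter (default 6); note that calibration requires the
rank of the population structure to be at most K, and environment measured
at the individual level — with environment constant within few populations,
chance population-level alignment is genuine confounding that no K can
remove.

## Structure summaries (`structure`)

LD pruning slides SNP-count windows (50 SNPs, step 10) and greedily drops
one SNP of any pair with r² above the threshold (more-missing first, then
the later position). PCA operates on mean-imputed centered dosages.
Ancestry fractions minimize ‖D/2 − QFᵀ‖² with Q rows on the K-simplex and F
in [0,1]; the blocks are updated by projected-gradient steps with
backtracking line search from three random restarts. Plain least-squares
followed by projection does not guarantee a monotone objective, which the
projected-gradient scheme does; this least-squares formulation replaces the
binomial-likelihood block relaxation of the original ancestry estimators
and is adequate for synthetic-truth validation, not a reimplementation of
them.

## Synthetic data (`synthetic_data`)

Two generators cover the two regimes the analyses need:

* **Site-level engine** (unlinked SNPs, used for F_ST/D/GWA/GEA tests):
  hierarchical Balding–Nichols frequencies — ancestral u ~ U(0.05, 0.95),
  species frequency ~ Beta with drift parameter F_between (default 0.10),
  population frequency ~ Beta around the species value with F_within
  (default 0.02); genotypes Binomial(2, freq) with overlaid missingness,
  depth and quality. Introgression is frequency mixing
  (1−α)·own + α·other applied only to sympatric populations. **Barrier
  loci** are modelled as divergently selected: the alt allele is pushed
  toward fixation in one species and loss in the other, with residual
  frequencies within (1−barrier_F)/2 of the boundaries. A plain
  Balding–Nichols draw at elevated F produces the right *expected*
  divergence but scatters so widely that planted loci are not reliably
  recoverable as outliers — divergent displacement is what "barrier" means
  mechanistically, and it makes the truth usable.
* **Haplotype engine** (the forward Wright–Fisher simulator above) wherever
  linkage matters.
* **Coalescent SFS sampler**: independent non-recombining genealogies from
  the same structured-coalescent kernel as the demographic expectations;
  by default one mutation per locus placed proportionally to branch length,
  or Poisson(θ·L) per locus. The single-mutation mode conditions each locus
  on segregating and is *not* exactly the Poisson sampling the composite
  likelihood assumes; parameter-recovery validation therefore uses the
  Poisson mode, while model *selection* is robust to either.

The default population layout is two allopatric plus two sympatric
populations per species along a latitudinal transect with a central contact
zone, 16–24 diploids each, plus a small outgroup sample (its frequencies
drawn with deep drift, F = 0.5, around the ancestral frequency).

What the generators deliberately do not emulate: linkage in the site-level
engine, selection other than additive hard sweeps, recombination within the
SFS loci, sex chromosomes, genotyping error beyond missingness/depth/quality
overlays, and any realistic CHC chemistry. Passing tests therefore
demonstrate that each estimator recovers the truth *of its own generative
model* at desk scale — they quantify correctness of the machinery, not
robustness to the full messiness of reduced-representation sequencing data.

## Numerical conventions

Internal coordinates are 0-based half-open; VCF positions are 1-based at the
boundary; BED is native. Dosage missingness is −1. Filtering order: per-call
depth masking, then site QUAL/missingness/MAC, then sample missingness, then
one MAC re-check. Depth is filtered per call (call → missing), not per site
mean. Multi-allelic records are skipped, not split; half-calls are missing.
All generators and fits are exactly reproducible given their seed; every
stochastic default is documented at the call site.
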