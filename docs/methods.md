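# Methods

This note records the models implemented in `popsel`, the conventions and
parameter choices that were genuinely open, and what the synthetic-data
validation does and does not establish.

## Data model and polarization

Phased biallelic haplotypes are held as an n_hap × n_site matrix of
{0, 1, missing} with strictly increasing 1-based positions (VCF
convention; BED inputs are converted from 0-based half-open on ingest).
Ancestral states are assigned per site by outgroup parsimony anchored on
the closest outgroup: its allele is ancestral when at least one further
outgroup agrees or none is informative; disagreement without a majority,
or outgroups matching neither allele, leaves the site unresolved.
Unresolved sites are excluded from every derived-allele statistic (unfolded
SFS, Fay & Wu's H, DIND, iHS) and logged, rather than guessed.

Sites with any missing call in the focal population are excluded from the
SFS summary entirely — the spectrum needs a common sample size — while
per-site frequency tables (DAF/MAF) use the reduced called count. Regions
with under 80% accessible sequence (against a BED accessibility mask) are
dropped; per-site diversity uses the accessible length, not the raw span
(the raw-span alternative changes only the per-site scaling, not any
normalized statistic).

## Neutrality statistics

θ_W and π are the standard estimators. Tajima's D uses the 1989 constants.
Fu & Li's D*/F* use the starred (within-sample) singleton contrasts with
the corrected constants of Simonsen, Churchill & Aquadro (1995); because no
installed package provides these statistics, the constants are validated
against the Monte-Carlo distribution of the statistic under the package's
own (independently cross-checked) coalescent: the normalized statistics
must come out centered with unit-scale spread, which fails if either the
centering or the variance constants are wrong. Fay & Wu's H is the
normalized version of Zeng et al. (2006), computed on resolved sites only,
with θ and θ² estimated by S/a_n and S(S−1)/(a_n²+b_n) from resolved
segregating sites.

Monomorphic input yields a missing value, never 0 — windows and panel
entries without variation must not dilute empirical nulls. Sliding windows
(default 5 kb span, 500 bp step) are anchored at the region start and
trailing partial windows dropped; window values can be flagged against a
panel null's 5th percentile for plotting.

## FST and haplotype statistics

F_ST is the per-SNP Hudson (1992) estimator with the n/(n−1) within-
population correction; slightly negative estimates are reported unclamped
so empirical percentiles stay unbiased. EHH curves start at 1 on the focal
SNP and are truncated at 100 kb per side or when the curve drops below
0.05 (the convention of the standard tools); iHH and iES are trapezoids
over physical distance (no genetic-map support). iHS is standardized
within 50 equal-width DAF bins of a calibration panel; lnRsb is
(lnRsb′ − median)/sd over the calibration SNPs. DIND uses a constant 40
flanking variants (20 per side); SNPs without a full flank get no value,
preserving the constant-flank calibration, and iπ_D = 0 produces the
dataset-wide maximum finite DIND + 20, flagged as capped.

## Empirical nulls and the composite caller

Panel percentile tables use linear interpolation; classes with fewer than
20 observations are flagged unreliable, and DIND DAF classes where capped
values would carry the 95th percentile (more than 5% capped) are marked
undefined and yield no significance call — at low DAF most iπ_D are 0, so
selection on low-frequency derived alleles is undetectable by design.

The caller's signature families are diversity (θ_W, π; low tail), SFS
(D, D*, F*, H; low), differentiation (F_ST; high) and haplotype (DIND;
high); the family map lives in configuration so alternative groupings are
testable. θ_W and π count as one family. Tails are strict (rank > 0.95 or
< 0.05). For the SNP-based families, a gene's evidence is its fraction of
SNPs past the per-SNP binned 95th percentile, ranked against the control
panel's per-gene fractions: taking the best SNP's rank directly saturates
at 1.0 for any gene with many SNPs and would fire the 1%-tail clause on
neutral data, whereas the two-stage rank is exchangeable with the panel by
construction. The neutral per-gene false-positive rate of the full caller
is checked empirically (< 5%).

Balancing candidates (θ_W or π above the panel's 95th percentile in at
least one population) are reported as balancing only when the MLHKA test
rejects neutrality at p < 0.05 in at least one population; high diversity
with proportionally high divergence is treated as mutation-rate variation,
not selection.

## MLHKA

The likelihood is Poisson: S_i ~ Pois(k_i θ_i a_{n_i}),
D_i ~ Pois(θ_i (T+1)) with k fixed at 1 for reference loci. Estimation is
profile maximum likelihood rather than MCMC: given T, reference-locus
θ̂_i = (S_i+D_i)/(a_i+T+1) is closed-form and each test locus is saturated
(θ̂ = D/(T+1), k̂ = S(T+1)/(D a)), reducing the fit to a bounded
one-dimensional search over log T. The LRT against the all-k=1 null is
referred to χ² with one degree of freedom per free k. The profile solution
is checked against a brute-force grid maximization of the same likelihood.
Test loci with D = 0 make k unidentifiable and are rejected with a clear
error, as is a panel with no divergence at all.

## Coalescent p-values and TMRCA

Neutral p-values for SFS statistics are Monte-Carlo:
p = (1 + #{sim ≥ obs})/(m + 1) (mirrored for the lower tail), conditioning
on θ — not on the observed S — under a configurable piecewise-constant
demography (African-like constant size; non-African-like bottleneck then
recovery). m counts replicates in which the statistic is defined; more
than half undefined aborts with an error rather than returning a biased p.

TMRCA is the mean pairwise difference of all chromosomes to the MRCA
sequence — taken as the ancestral allele at every segregating site —
divided by a mutation rate calibrated on human–chimpanzee fixed
differences: μ_year = fixed differences/(2 × 6 × 10⁶ years), with 25-year
generations for the per-generation rate. The standard deviation is a
bootstrap over segregating sites (1,000 resamples), standing in for the
original closed-form variance, and is labelled as such in the output.
Against recorded true TMRCAs in simulation the estimator's median relative
error is under 35%; it is a point summary, not a posterior.

## Synthetic data

The coalescent generator is a Hudson-style structured coalescent (event-
driven over piecewise-constant epochs and splits, no migration) with
infinite-sites mutation at rate θ/2 per unit branch length; time is in
units of 2N_ref generations. It records the true TMRCA and is cross-
checked against msprime on first and second moments. There is no
intra-locus recombination: the per-locus SFS statistics and their nulls do
not depend on it, and haplotype-test positive controls come from the
forward simulator instead. The default control panel emulates the study
design: ~1,000 unlinked gene-sized loci (5 kb), two populations of 40
chromosomes (constant-size African-like; non-African-like with a 0.15×
bottleneck between 0.02 and 0.08 time units), per-locus θ log-normal with
median 5 (≈10⁻³ per bp, the human point estimate for a 5 kb gene).

The forward Wright–Fisher simulator evolves a window of sites in a small
diploid population (N ≤ 1,000) with recombination and infinite-sites
mutation. Instead of a long mutation–drift burn-in it is initialized from
a neutral coalescent sample of all 2N chromosomes — exact for single-site
frequencies — followed by a short settling phase (default N/2 generations)
that lets recombination relax the initial linkage; the s = 0 mode is
verified to agree with the coalescent on Tajima's D. A beneficial mutation
(fitnesses 1, 1+hs, 1+s) is injected at the window center and re-injected
on loss (bounded retries); sampling occurs at a derived-frequency target
or at fixation, and an optional neutral copy of the population, split at
selection onset, provides the second deme for F_ST and lnRsb. At these
rescaled sizes the effective sweep strength is 2Ns: with 2Ns of a few tens
the sojourn lasts on the order of N generations and mutation partially
restores diversity during the sweep, so end-to-end detection tests use
2Ns ≈ 150 while the haplotype-test power checks keep s = 0.05.

Case/control genotype counts are multinomial draws from the penetrance
model's genotype probabilities with α derived from the K_p identity;
infeasible parameter combinations (penetrances outside (0,1)) are errors.

What passing on these data shows — and does not. The generators produce
clean biallelic, fully phased, fully polarized data with known ancestral
states, no genotyping error, no low-coverage allele-frequency bias
(the motivation for the DIND cap in the original low-coverage setting),
and simplified demography without migration. Passing establishes the
statistics, their calibration machinery, and the caller's logic; it does
not establish robustness to phasing error, polarization error, or
ascertainment, which real applications must assess separately.

## Association

The HWE test is the exact conditional (Wigginton-style) two-sided test —
the asymptotic χ² disagrees with the reference values on small rare-
homozygote counts, so exact is the default and only implementation. The
penetrance model minimizes the 6-cell goodness-of-fit χ² over (q, γ) — or
(q, β, γ) for the general model — on a logit/log parametrization with
α eliminated through K_p, using L-BFGS-B from 25 Latin-hypercube starts
(the objective has local minima); degrees of freedom are 1 (general) or 2
(constrained), and AIC = χ²_min + 2 × free parameters, i.e. AIC on the
goodness-of-fit statistic itself, matching the framework's use of χ² as
the objective. Permutation association draws the case row from the
multivariate hypergeometric distribution implied by phenotype-label
swapping — exactly equivalent to permuting labels, verified against
exhaustive enumeration on small tables — with p = (1+R)/(B+1) and a
mandatory seed.

On the reference genotype table the fitted values (q = 0.079, α = 0.20,
γ = 3.23, χ² = 1.82, df = 2) and the exact HWE p-values (0.041 cases,
>0.99 controls) reproduce the reference analysis. The label-swap
permutation p-values computed from the printed counts are 0.049
(genotypic) and 0.035 (recessive) by exhaustive enumeration; these are
what the implementation returns.

## Numerical conventions

Percentiles interpolate linearly; percentile ranks are P(panel ≤ value)
within the matched class; all Monte-Carlo p-values use the +1/(m+1)
estimator to avoid zero; optimizers run on unconstrained transforms
(logit, log, log(γ−1)) with multi-start; every stochastic routine takes an
explicit `numpy` Generator or seed, and pipeline results directories
record the resolved configuration, seed, and package version.

## Problem sizes used in validation

Chosen to keep the full suite in minutes on one CPU: neutral-mean checks
use 2,000 coalescent replicates (n = 20, θ = 5); simulator moments 5,000
replicates; MLHKA calibration 500 neutral panels of 20 loci and 200
recovery replicates; the end-to-end scan an 80-locus forward-simulated
two-deme panel with 6 injected sweeps plus a 120-locus coalescent panel
with 8 excess-polymorphism loci; haplotype-test power 50 sweep and 50
neutral forward replicates. Full-scale analyses (987-locus panels, 10,000
simulation iterations and permutations) use the same code paths through
the configuration defaults.
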