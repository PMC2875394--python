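# Methods

This note records the models implemented in paddymix, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that shape the results.

## Data model

Accessions are inbred lines, so genotypes are haploid-coded: 0 (reference),
1 (alternate), missing. Heterozygous diploid input — residual heterozygosity
or genotyping artifacts — is resolved by policy: `het_as_missing` (default)
or `het_as_major`; neither is privileged by the data-generating process, so
both are exposed. Coordinates are 1-based bp; windows are half-open
`[k·w, (k+1)·w)`. QC keeps SNPs with minor allele frequency **strictly**
greater than `maf_min` (default 0.01) and missingness ≤ `max_missing`
(default 0.2).

## Admixture model and EM

The likelihood treats each non-missing call as a draw from a mixture over K
ancestral clusters:

    log L(Q, P) = Σ_{i,l} g_il log(Σ_k q_ik p_kl) + (1−g_il) log(Σ_k q_ik (1−p_kl))

Point estimates come from EM with closed-form updates (responsibilities are
marginalized analytically, so an iteration is four matrix products). Ten
random restarts by default, best final likelihood wins — the same
best-replicate logic used when this model is fit by MCMC, but deterministic
given a seed. Initialization: Q rows flat-Dirichlet, P as the observed
frequencies plus uniform ±0.1 noise. Convergence at Δlog L < 1e-4 (absolute)
or 2,000 iterations. Frequencies are clipped to [1e-6, 1−1e-6] so fixed
sites cannot produce −∞ at a discordant call. EM monotonicity is asserted at
every iteration. Cluster labels are arbitrary; `align_components` resolves
label switching against a reference by optimal assignment on column-wise
correlations. Classification: an accession joins its top cluster unless that
share is below 0.80 (strictly less than — the boundary value is assigned),
in which case it is admixed.

No Bayesian priors (ancestry concentration α, frequency prior λ) are
implemented: the downstream quantities are point estimates of Q and P, and
maximum likelihood targets the same point with far less compute and exact
reproducibility.

## Local ancestry: linkage-model HMM

Hidden state = ancestral origin of SNP *l* in accession *i* (K states).
Initial distribution q_i. Transition over distance d bp: stay with
a = e^{−rd}, otherwise re-draw from q_i (so the transition matrix is
aI + (1−a)1q_iᵀ, and the forward/backward updates need no K×K products).
Emission p_kl^g (1−p_kl)^{1−g}; missing calls emit 1 for every state.
Per-site scaling makes the recursion stable at L ≈ 10³ and yields the exact
log-likelihood; posteriors are validated against brute-force path
enumeration (K ≤ 3, L ≤ 8) to 1e-10. Chromosomes are independent.

`fit_switch_rate` picks r from a grid by total forward likelihood.

### Why a refinement stage exists

Conditioning the HMM on the *global* EM fit fails for exactly the case the
scan targets: an otherwise-pure accession carrying a short introgressed
block. Globally its minor ancestry rounds to ~0 (making the HMM's switch
penalty effectively infinite), and the recipient cluster's frequency
estimates absorb the carriers' block genotypes, erasing the emission
contrast. `refine_local_ancestry` therefore re-estimates P from the local
posteriors themselves (each genotype counts toward the cluster its posterior
assigns it to), with the ancestry prior held at the global Q mixed with
uniform weight τ = 0.2 so every origin stays reachable for every accession.
Two phases mirror the two-phase burn-in used when this model is fit by
MCMC: a permissive phase (6 iterations at r = 1e-6/bp) lets candidate blocks
seed the frequency updates; the chain is then cooled to the rate in
{1, 2, 3, 5}×1e-7 that maximizes the likelihood under the refined
frequencies, and iterated 8 more times. Soft (posterior-weighted) updates
are used throughout: hard or trimmed updates were evaluated and rejected —
excluding ambiguous sites from the frequency estimates creates a selection
bias that manufactures spurious evidence and destroys precision.

### Introgression definition, profiles, segments

Introgression is donor ancestry that disagrees with an accession's
subpopulation assignment. The subpopulation profile is the per-SNP mean of
the donor component over member accessions; its threshold is the **top-5%
nearest-rank cutoff** — the smallest of the ⌈0.05·L⌉ largest per-SNP means
(on a profile of 95 values at 0.01 and 5 at 0.50 the cutoff is 0.50).
Segments are maximal runs of consecutive same-chromosome SNPs with donor
posterior > 0.5 (majority ancestry), reported when ≥ 5 SNPs long.

### Detection limits

At 260-kb marker spacing the emission evidence for a donor block is
0.5–1.15 nats per SNP depending on the subpopulation pair (low-divergence
pairs such as indica–aus are the weakest), while entering and leaving a
donor state costs ~11 nats at the fitted switch rate. Blocks of ~8 SNPs
(~2 Mb) therefore cannot reach a majority posterior even with the true
parameters — consistent with the empirical finding that sub-Mb
introgressions at this marker density go undetected — and reliable recovery
requires blocks at the multi-Mb scale that selected introgressions actually
span. The recovery benchmark plants 35-SNP (~9 Mb) blocks carried by 20
accessions; measured per-SNP sensitivity is ~0.8 and precision ~0.86, with
the residual losses being donor misattribution between weakly diverged
clusters and attraction to the smallest (14-member) cluster, whose
frequencies are noisy.

## Unbiased F_ST

For m groups with haploid sample sizes n_i (non-missing calls) and
frequencies p_i at a SNP:

    pbar = Σ n_i p_i / Σ n_i
    MSG  = Σ n_i p_i (1−p_i) / Σ (n_i − 1)
    MSP  = Σ n_i (p_i − pbar)² / (m − 1)
    n_c  = (Σ n_i − Σ n_i² / Σ n_i) / (m − 1)
    F̂   = (MSP − MSG) / (MSP + (n_c − 1) MSG), negative values set to 0

A SNP needs ≥ 2 groups with ≥ 2 calls, else NA. Genome-wide and windowed
aggregates use the ratio of summed numerators to summed denominators
(clamped after aggregation as well); the mean of per-SNP values is also
reported since either convention is defensible for a summary table.
Calibration: over 200 Balding–Nichols replicates (2×50 haploids, 1,000
SNPs) the mean genome-wide estimate is within ±0.02 of the generating F at
F ∈ {0.1, 0.3, 0.5}.

## Trees

Allele-sharing distance = proportion of mismatching calls over SNPs
non-missing in both accessions (pairwise deletion); an accession pair with
no shared SNP is an error, not a guess. NJ joins the pair minimizing the
Q-criterion, ties broken by the smallest (i, j) index pair; negative branch
estimates are clamped to 0 with the deficit moved to the sibling edge, so
path lengths are preserved. Newick children are ordered by their smallest
leaf label, making output byte-reproducible; labels with reserved characters
are single-quoted.

## Mapping

**Admixture mapping**: ordinary least squares of the trait on the donor
component of the local-ancestry posterior, SNP by SNP, over a chosen subset
(normally the admixed class); two-sided t-test on the slope; SNPs with zero
component variance are NA. No covariates — the method's power comes from the
block structure of ancestry, and the benchmark panel emulates landrace-style
admixture (switch rate 3e-7/bp, ~3 Mb blocks, i.e. many generations of
recombination) because with very recent admixture local ancestry barely
varies along the genome and no regression on it can localize anything.

**Mixed model**: y = μ + SNP·β + Q·γ + u + e with u ~ N(0, σ_g² KIN), KIN
the allele-sharing similarity (1 − distance). One Q column is dropped
against the intercept. The variance ratio h = σ_g²/(σ_g²+σ_e²) is estimated
once by REML on the null model through a single eigendecomposition of KIN
(bounded scalar optimization after a 40-point bracketing grid; validated
against a dense grid search to 1e-3), then every SNP is tested by
generalized least squares in the rotated coordinates — the standard
approximation that makes 10³ tests cheap. With identity kinship the
procedure reduces exactly to per-SNP OLS (checked to 1e-8). Missing
genotypes are mean-imputed in the design matrix. Wald t-tests use
df = n − p − 1. Genomic-control inflation on polygenic null traits stays in
[0.8, 1.2].

**Bonferroni**: threshold α / (number of non-NA tests); with 1,311 tests at
α = 0.05 that is 3.81e-5.

## Synthetic-panel generator

What it emulates: K = 5 subpopulations whose allele frequencies follow the
Balding–Nichols model — per locus an ancestral frequency uniform on
(0.1, 0.9) (array SNPs are ascertained to be informative, hence no rare
ancestral alleles), then p_kl ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k). The
default divergences F = (0.20, 0.26, 0.40, 0.60, 0.45) for (indica, aus,
tropical japonica, temperate japonica, group V) were chosen so realized
pairwise F̂_ST spans ≈0.23–0.53 with indica–aus the closest pair, matching
the divergence structure of the five rice subpopulations; a least-squares
fit to the full pairwise table is impossible under independent
per-population divergence (the table is non-additive because indica/aus and
the japonica clade share hierarchical history), so the span and the extreme
pairs were matched instead. Default sizes: (77, 57, 97, 60, 14) pure + 90
admixed = 395 accessions; 12 chromosomes × 109 markers at 260-kb spacing =
1,308 SNPs.

Admixed accessions draw Q from Dirichlet(0.5) over 2 (80%) or 3 (20%)
random subpopulations and a Markov ancestry mosaic with per-bp switch rate
`switch_rate` (default 1e-8 — recent admixture, near-chromosome-scale
blocks) whose stationary distribution is their Q. Introgression events give
`carrier_fraction` of the recipient subpopulation donor ancestry over the
same interval (a shared selected segment); genotypes everywhere are
Bernoulli draws from the frequency of the local ancestral origin.

Traits are additive over causal SNPs with Gaussian noise scaled so the
genetic variance fraction equals h² in expectation; h² = 0 yields pure
unit-variance noise, and missing causal genotypes contribute the panel
frequency.

What it does **not** emulate: linkage disequilibrium beyond the ancestry
mosaic (within-subpopulation LD is absent, so single-SNP association is, if
anything, easier than in real data); coalescent haplotype sharing;
genotyping error; ascertainment bias beyond the common-frequency range.
Passing tests therefore demonstrate correctness and calibration of the
estimators under the stated generative model, not performance on any real
panel.

## Problem sizes used in the checks

Calibration and recovery checks run at: 200 replicates per divergence level
for F_ST calibration; one 250 × 1,308 panel (3 EM restarts) for ancestry
recovery; two panels × two 35-SNP events × 20 carriers for introgression
recovery; 20 trait replicates (power) and 200 (family-wise error) on a
180-accession mapping panel; 8 random trees (n ≤ 12) for NJ. The pipeline's
EM restart default remains 10; benchmark fits use 2–3 restarts, which on
these well-separated panels reach the same optimum.

## Known limitations

* Local-ancestry resolution is bounded by marker density; sub-Mb
  introgressions are invisible at 260-kb spacing (see Detection limits).
* The frequency-based linkage model cannot distinguish a shared introgressed
  haplotype carried by most of a subpopulation from standing variation; at
  carrier fractions ≳ 50% detection degrades.
* The mixed model estimates variance components once (null model), not per
  SNP; for very large effects the per-SNP ratio would differ slightly.
* K is a user choice; the package reports likelihood per K but does not
  automate model selection.
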