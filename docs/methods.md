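# Methods

## Model

Let `bhat_t`, `s_t` be marginal (single-SNP) regression estimates and
standard errors over the p SNPs of one locus in population t ∈ {1, 2},
computed on standardized genotypes, and let `R_t` be the population's SNP
correlation (LD) matrix.  The summary-level likelihood is

    bhat_t ~ N( R_t (Σ_k γ_k β_tk + φ_t),  c_t S_t R_t S_t ),

with three latent layers:

* γ_k ∈ {0,1}^p, one-hot, uniform prior 1/p — component k's causal SNP,
  shared across populations;
* (β_1k, β_2k) ~ N(0, Σ_k) — the component's effect sizes, free to differ
  between populations (Σ_k is a 2×2 covariance, estimated);
* (φ_1j, φ_2j) ~ N(0, Ω) iid over SNPs — the dense polygenic background
  (Ω a 2×2 per-SNP covariance, fixed during the locus fit).

c_t ≥ 1 inflates the noise covariance to absorb confounding that marginal
GWAS did not adjust (population stratification, socioeconomic structure);
c_t is the LD score regression intercept.

**Assumptions.** Effects are on the standardized-genotype scale; the locus
LD matrices are estimated from population-matched panels and are treated
as known; the two GWAS share no samples; causal configurations are shared
across populations (effect sizes need not be).

## Two-step estimation

**Step 1 (genome-wide, `ldsc` module).**  Univariate LD score regression
per population, `chi2_j ≈ c + n·ω·ell_j`, estimated by weighted least
squares with 1/max(ell, 1) weights and one reweighting pass, SNPs with
chi2 > max(80, 0.001 n) excluded, and a 200-block contiguous jackknife for
standard errors.  The cross term ω12 comes from regressing `z1·z2` on
cross-population scores `ell_cross_j = Σ_l r1_jl · r2_jl` through the
origin (no shared samples ⇒ zero intercept).  The assembled Ω is clamped
PSD (|ω12| ≤ 0.999·√(ω1ω2), zero variances floored at 1e-6 of the larger
one so Ω stays invertible); intercepts below 1 are clamped to 1 by default
because an apparent deflation would tighten the standard errors and
overstate evidence (flag to disable).  The cross-score definition is the
natural trans-ancestry analogue of the single-population score and is
flagged to the user as such.

**Step 2 (locus, `core` module).**  With θ = (Ω, c) fixed, a variational
EM maximizes an evidence lower bound over the factorized family
q = Π_k q(γ_k) q(β_k | γ_k) · q(φ): categorical × bivariate-normal per
component, 2p-dimensional Gaussian for the background.  Because each
factor's coordinate update is the exact conditional optimum, the ELBO is
monotone; only the Σ_k are re-estimated (M-step: the π̃-weighted posterior
second moment, PSD by construction).

Update order per sweep: components 1..K sequentially (each residualizing
the evidence against all other components and the polygenic mean), then
the polygenic posterior, then the M-step.  **Initialization:** π̃ uniform,
μ̃ = 0, Σ_k = (1/p)·I, and the polygenic posterior set to its conditional
optimum given those zeros *before* the first sweep.  The last point
matters: with the background started at zero, the first component sweep
would claim dense polygenic signal at high-LD SNPs (whose marginal
polygenic variance n·ω·ell_j can rival a causal signal) and coordinate
ascent converges to an overconfident basin.  Measured on the scenario-1
benchmark with oracle (Ω, c): pooled empirical FDR at nominal 0.1 was 0.22
with the zero-background start and 0.10 with the background-first start.
Both schedules are valid coordinate ascent; the package uses the latter.

The polygenic posterior covariance Λ = (blockdiag(S_t⁻¹R_tS_t⁻¹/c_t) +
Ω⁻¹⊗I_p)⁻¹ depends only on fixed quantities, so its 2p×2p Cholesky
factorization is computed once per fit and each iteration solves for the
mean at O(p²).  A per-population eigenbasis trick cannot decouple the
system because the two populations' scaled LD matrices do not share
eigenvectors; the one-time factorization has the same O(p³)-once cost and
is verified against a dense inverse to ~1e-8 (test suite).

**Numerical choices.**  Convergence at |ΔELBO| < 1e-4 (absolute) or 200
sweeps; softmax computed on stabilized logits; Σ_k inverses use a 1e-10
ridge retry when near-singular; a component whose trace(Σ_k) falls below
1e-12 is frozen as inactive (excluded from PIPs and credible sets).  On
null-ish data Σ_k shrinks sub-geometrically, so fits may exhaust the sweep
budget with a warning while the PIPs are long since stable; results are
still returned.  The ELBO is reported up to an additive constant
independent of the variational state and Σ; in the K = 1, Ω = 0, equal-SE
case the constant is available in closed form and ELBO + constant equals
the enumeration log evidence exactly (tested).

## Inference outputs

* PIP_j = 1 − Π_k (1 − π̃_kj) over active components.
* Local fdr_j = 1 − PIP_j; global-FDR selection sorts by local fdr and
  selects the largest prefix whose running mean stays strictly below ξ
  (default 0.1); ties break by original SNP order.
* A level-α credible set per component (default α = 0.95; 0.99 available):
  the smallest set of SNPs, taken in descending π̃ order, reaching
  cumulative mass α.  Purity = the minimum absolute pairwise LD within the
  set, per population; a set is discarded only when purity < 0.1 in
  *every* population (singletons have purity 1 by convention).  Duplicate
  sets from different components are reported and flagged.

Choosing K larger than the number of true signals is safe by design: the
background absorbs small effects, redundant components shrink toward zero
variance and spread their categorical mass near-uniformly, and the purity
filter removes their (near-locus-wide, LD-incoherent) credible sets.

## Synthetic-data generator

The `simulate` module reproduces the benchmark conditions the method is
validated under, at a working scale that keeps the full two-step pipeline
in a test budget:

* **LD** — block-diagonal AR(1) per population: locus decay ρ = 0.25 in
  population 1 (weak LD) and ρ = 0.95 in population 2 (strong LD), blocks
  of 50 SNPs; background blocks cycle through a per-population grid of
  decays so genome-wide LD scores vary (with a single decay all scores are
  equal and the LDSC slope is unidentifiable — real LD is heterogeneous).
  Candidate causal SNPs follow the leverage-of-diversity filter: high LD
  (|r| > 0.9) with ≥ 3 SNPs in the strong-LD population, weak LD
  (|r| > 0.6 with < 2 SNPs) in the other.
* **Effects** — polygenic (φ_1j, φ_2j) ~ N(0, [[0.005, 0.004], [0.004,
  0.005]]/500) on every SNP: per-SNP heritability 1e-5, cross-population
  genetic correlation 0.8.  Causal effects independent per population with
  variance 0.25/500 = 5e-4 (a 50-fold per-SNP enrichment).  A scaled-t
  option (df 16 or 4, variance-matched) exercises model misspecification.
* **Summary statistics** — *summary mode* draws bhat_t ~ N(R_t(b_t+φ_t) +
  δ_t, S R S) with s = 1/√n directly (exact second moments, fast);
  *individual mode* draws standardized MVN genotypes per LD block
  (streamed in two passes so the n×p matrix is never materialized), builds
  the phenotype, and runs the per-SNP marginal regressions literally.
  Both modes agree in first and second moments (tested).
* **Confounder** — a structure axis u with iid per-SNP loadings
  f_j ~ N(0, 0.02²), *independent of local LD*: ancestry allele-frequency
  differences — the driver of real stratification — are not LD-structured,
  and that independence is precisely what routes the induced inflation
  into the LDSC intercept rather than the slope (a genotype-PC confounder
  on LD-block MVN genotypes loads on LD scores and acts like spurious
  heritability instead).  Individual mode adds u_i·f_j to the genotypes
  and the rescaled axis (variance v_t) to the phenotype; summary mode uses
  the equivalent analytic mean shift √v_t·f_j.  Expected intercept:
  c_t ≈ 1 + n_t·v_t·sd(f)², e.g. ≈ 2.6 at n = 20,000, v = 0.2 (matches
  the estimated intercepts in the test runs).  The confounded scenario
  keeps n = 20,000 and v = (0.05, 0.2): the inflation scales with n·v, so
  shrinking n would remove the phenomenon being tested.
* **Scales** — default locus p = 200 with p_genome = 5,000 background SNPs
  for the LDSC stage (2,500 in the confounded scenario); the per-SNP
  generative quantities above do not depend on these sizes.  Sample sizes
  stay at the realistic n = 20,000 (summary mode makes them free).

**What the generator does not emulate:** real LD (long-range structure,
allele-frequency-dependent correlation), discrete allele counts (a
Bernoulli-threshold mode exists for spot checks but the likelihood depends
only on second moments), case-control ascertainment, relatedness, and
sample overlap.  Passing the bundled benchmarks therefore demonstrates
internal correctness and calibration *under the stated generative law*,
not performance on any particular real cohort.

## Evaluation metrics

Empirical FDR = 1 − (true causals among selected)/(selected), pooled over
replicates because each locus carries at most K_true causal SNPs; power =
recall of causal SNPs; pAUC = trapezoidal area under the PIP-ranked ROC
truncated at an FPR cap (0.1/0.2/0.3) and normalized by the cap;
credible-set size summaries over kept sets.  The pAUC implementation is
verified against an exhaustive threshold-sweep oracle.

## Known limitations

* The mean-field factorization makes component posteriors somewhat
  overconfident relative to the exact posterior (the polygenic layer's
  uncertainty is not propagated into the per-SNP evidence); on the bundled
  benchmark the global-FDR procedure remains calibrated, but single-SNP
  PIPs near the selection boundary should be read with that in mind.
* Under weak signals (causal |z| ≲ 2) no ranking method can recover the
  causal SNP; roughly half the draws from the default effect distribution
  fall there at n = 20,000.  Power figures must be interpreted against
  that ceiling.
* T = 2 populations in the primary data path; the formulas are written
  per-population and extend to T > 2 by widening the 2×2 blocks, but only
  T = 2 is exercised by the test suite.
* The LDSC stage needs genuinely variable LD scores and a few thousand
  SNPs; below ~50 SNPs it warns and results are unstable.  All of Ω, c
  may instead be supplied directly, bypassing the stage entirely.
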