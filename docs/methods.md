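# Methods

## Model

Participation follows a liability-threshold model: a latent liability
X = Gx + εx with Var(Gx) = hx², Var(εx) = 1 − hx², standard normal in the
population; an invited individual participates iff X > t_α = Φ⁻¹(1 − α).
A phenotype Y = Gy + εy is standardized in the population, with genetic
correlation ρg = Corr(Gx, Gy) and nongenetic correlation ρe = Corr(εx, εy).
The model is symmetric in sign; binary phenotypes are treated on the liability
scale (conversion of prevalence differences to liability-scale mean shifts is
deliberately not implemented).

Gy decomposes as a·Gx + Gw with a = ρg√(hy²/hx²) and Gw ⟂ Gx,
Var(Gw) = (1 − ρg²)hy²; likewise εy = b·εx + εw. The four components are
independent in the population. Conditioning on X > t_α shrinks the variances
of Gx and εx and makes them negatively correlated (collider structure); Gw
and εw are untouched. All second-moment distortion is carried by
ξ(α) = 1 − Var(X | X > t_α) through the Pearson–Lawley identity

    Cov(U, V | X > t_α) = Cov(U, V) − ξ(α) · Cov(U, X) · Cov(V, X)

for (U, V, X) jointly Gaussian with unit-variance X (`trunc.selected_cov`).

Joint normality of (Gx, Gw, εx, εw) is assumed throughout — appropriate for
polygenic traits; X is treated as exactly standard normal.

## Apparent quantities and the adjustment

`forward` implements the closed forms for the apparent (selected-sample)
heritability, participation–phenotype genetic correlation, and cross-phenotype
genetic correlation. Because typeset groupings of such expressions are easy to
misread, every closed form has a constructive twin built only from
`selected_cov` (projection of Y on the post-selection-orthogonal pair
(Gx, Gw)); tests require agreement to 1e-10 over hundreds of random parameter
draws, and a truncated-MVN Monte-Carlo oracle (`trunc.mc_truncated_mvn`)
provides a third, sampling-based route.

`adjust` inverts the chain: the observed mean shift δ̂ (standardized by the
participant-sample SD) identifies the phenotypic correlation ρ̂; the LDSC
genetic correlation of the phenotype with the (population-scale) participation
statistics is converted to an apparent genetic covariance, de-selected into
the population genetic covariance, and substituted into the exact inverse of
the apparent-heritability form. The nongenetic correlation follows from the
composition identity ρ = ρg√(hx²hy²) + ρe√((1−hx²)(1−hy²)).

Two deliberate choices:

* **Cross-phenotype inversion.** The cross-phenotype adjustment uses the
  *adjusted* participation genetic covariances in its cross terms. With the
  raw (sample-scale) covariances there the map is only approximate; with the
  adjusted ones it is the exact algebraic inverse of the forward expression,
  which the round-trip tests certify at 1e-10. The numerical difference is
  second-order in ξρ̂ᵢ² and negligible at biobank-like parameter values.
* **No silent clamping.** Adjusted values outside their natural ranges
  (h̃y² ∉ [0,1], |ρ̃| > 1, a mean shift larger than any correlation can
  produce) are returned raw with machine-readable flags. Clamping would break
  the linearity that makes jackknife pseudovalues valid.

Standard errors: LDSC-style estimators provide leave-one-block-out series
over contiguous SNP blocks; `jackknife_adjust` recomputes the full adjustment
chain per replicate and forms pseudovalues p_b = B·θ − (B−1)·θ₍₋b₎, giving
mean(p) as the point estimate and √(Var(p)/B) as the SE. Quantities estimated
without SNP blocking (δ̂, and hx² when supplied externally) are held fixed
across replicates. An `hx2_scale` multiplier (default 1.0) exposes
invitation-stage bias scenarios (e.g. 0.75) without modelling invitation
explicitly.

### Mean shift

`compute_mean_shift` implements: optional rank-based inverse-normal transform
applied to the two cohorts *pooled* (per stratum, e.g. sex, when strata are
supplied); covariate model fitted by OLS on the reference cohort and applied
to both; δ̂ = (mean_sample − mean_reference)/SD_sample. Pooling before the
rank transform is essential — transforming each cohort separately would force
both means to zero — and makes δ̂ invariant to any strictly monotone
transform of the raw values. Fitting covariates on the reference keeps
composition differences (e.g. age structure) out of the shift while leaving
the genuine location difference in.

The δ ↔ ρ map: ρ̂ = αδ̂/√(ξα²δ̂² + φ(t_α)²) is the exact inverse of the
model's mean-shift formula, but only shifts with |δ̂| < λ/√(1−ξ) (the |ρ|→1
limit) invert into (−1, 1); noisier shifts map monotonically to |ρ̂| up to
1/√ξ and are flagged downstream rather than clamped.

## LD-score regression (`ldsc`)

Heritability: weighted regression of χ² on N·ℓ/M with weights
1/max(ℓ,1) × 1/(1 + N·h²ℓ/M)², the heteroscedasticity factor updated in a
fixed two-step iteration (determinism over convergence ambiguity); intercept
free by default (the convention for phenotype heritability) or fixed at 1.
Genetic correlation: regression of z₁z₂ on √(N₁N₂)·ℓ/M, intercept optionally
fixed to 0 (the convention when the participation GWAS and the phenotype GWAS
share no samples). Delete-one-block refits reuse the full-data weights.
Allele alignment flips z for swapped A1/A2 and drops irreconcilable SNPs
(error above 10%). Out of scope: partitioned heritability, annotation
stratification, and any correction for selection-induced long-range LD (its
effect on these estimates is small at the simulated settings, and the
adjusted estimates inherit only that small residual).

## Simulator (`sim`)

The generator reproduces the validation design:

* **Genotypes.** m = 10,000 SNPs in 50-SNP LD blocks. Within a block,
  haplotype alleles form a stationary two-state Markov chain with stationary
  frequency f and lag-1 correlation ρ_l; binary chains regress linearly, so
  the lag-k correlation is exactly ρ_l^k — the AR(1) block correlation matrix
  holds exactly, and true LD scores have the closed form
  ℓ_j = Σ_k ρ_l^{2|j−k|}. A genotype is the sum of two independent haplotype
  chains, itself a Markov chain on {0,1,2} sampled directly. ρ_l ~ U(0.1, 0.9)
  per block; **one allele frequency per block**, f ~ U(0.1, 0.9): with
  per-SNP frequencies the binary-correlation feasibility bound
  would be violated for a large share of adjacent pairs at high ρ_l, so the
  homogeneous block is the design that actually admits the AR(1) target
  (heterogeneous per-SNP frequencies remain supported, with feasibility
  errors naming the offending block).
* **Effects.** 10% of SNPs causal (uniformly at random); effects on
  (X, Y₁[, Y₂]) drawn from a multivariate normal with per-SNP variance
  h²/m_causal on standardized dosages — the divisor generalizes the
  fixed-m design so heritability targets hold at any SNP count — and
  correlations (ρg₁, ρg₂, φg). Residuals are multivariate normal with
  variances 1 − h² and correlations (ρe₁, ρe₂, φe); φe defaults to
  ρe₁·ρe₂, i.e. the two phenotype residuals are correlated only through
  their shared participation-residual loading (εw₁ ⟂ εw₂). The apparent
  cross-phenotype genetic correlation does not involve φe, so validation
  targets are insensitive to this choice.
* **Selection and scale.** Individuals with X > t_α participate (α = 0.055).
  The desk-scale default invites 550,000 individuals (~30,250 participants).
  To keep memory modest the invited cohort carries genotypes only at causal
  sites, drawn exactly via Markov skip-transitions (a subchain of a Markov
  chain is Markov, with lag-k transitions available in closed form);
  participants' remaining sites are then filled by exact conditional Markov
  bridges. Selection conditions on X, which depends on genotypes only through
  the causal sites, so the conditional law of the non-causal sites given the
  causal ones is unchanged by selection and the fill is distributionally
  exact (verified against direct full-chain generation).
* **GWAS.** Per-SNP simple linear regression z-statistics from the sample
  correlation, z = r√((n−2)/(1−r²)); monomorphic SNPs get z = 0.
* **Participation oracle.** The population-scale participation GWAS is an
  *oracle*: the latent X regressed on dosages in a fresh, independently
  simulated population cohort (100,000 by default). This stands in for what
  IBD-based sibling contrasts estimate without nonparticipant genotypes, and
  using a fresh cohort also removes sample overlap with the phenotype GWAS,
  matching the fixed-zero cross intercept. Sibling-pair machinery
  (per-block Mendelian transmission from simulated parental haplotypes, and
  a shared-environment variance calibrated by bivariate-normal orthant
  probabilities so that the sibling recurrence ratio hits λ = 2 at α = 0.055)
  is retained for model checks; the shared-environment construction is one
  consistent way to achieve λ and is flagged as such.
* **Pipeline.** `run_experiment` chains simulate → GWAS → LDSC (participation
  h² and cross-rg with intercept 0; phenotype h² and phenotype–phenotype rg
  with free intercept; 200 jackknife blocks) → mean shift (participants vs
  full invited cohort, no covariates or INT needed since the simulated
  phenotypes are already clean) → adjustment, and reports per-replicate raw
  and adjusted estimates. LD blocks, effects, genotypes and residuals are
  all redrawn each replicate from a single seed.

### What the simulator does and does not emulate

It reproduces block-wise LD with realistic decay, polygenic trivariate
architectures, threshold selection, and the estimator stack — so passing
tests show the closed forms and the adjustment chain are correct *under the
model's assumptions*. It does not emulate realistic human LD maps, rare
variants (frequencies are bounded away from 0.1), non-Gaussian liabilities,
assortative mating, invitation-stage bias, genotyping error, or indirect
genetic effects; conclusions about those features of real data are outside
what the test suite can certify.

## Study conditions and problem sizes

The validation experiment uses the two-phenotype system (hx² = 0.125,
hy² = (0.5, 0.2), ρg = ρe = (0.25, 0.5) against participation... i.e. each
phenotype has ρg = 0.25 and ρe = 0.5 with participation, φg = 0.5,
α = 0.055) at replicates of ~30,000 participants (32 in the validation
suite, whose band tests need the tighter replicate-mean SE of ≈0.006; 20 in
the standalone reproduction script) — a deliberate desk-scale rendition of
the full design (5×10⁶ sibling pairs, 50 replicates),
which is exposed through `SimConfig(n_individuals=...)` for machines with the
memory and patience for it. At desk scale the replicate mean of the raw
participant-sample heritability of the 0.2-trait converges on the closed-form
apparent value 0.2296, its adjusted mean on 0.2, the raw cross-phenotype rg
on 0.4580, and its adjusted mean on 0.5; per-replicate spread is dominated by
the effect-size draw interacting with the largest-ℓ blocks, which is why
calibration statements are made about replicate means.

## Numerical choices

* ξ is computed as λ(λ − t_α) with λ = exp(logφ(t_α) − log α), avoiding
  cancellation at small α; α = 1 is an explicit no-selection case
  (t = −∞, ξ = 0) so limit tests exercise the full chain.
* The MC oracle samples X by inverse-CDF on the truncated tail and the
  remaining coordinates from the Gaussian conditional — never rejection at
  small α (a rejection path exists for cross-checks, refusing α < 0.2).
  Seeds are mandatory; moments carry per-entry MC standard errors.
* Statistical test calibration: comparisons of closed forms against MC
  estimates use batch-spread standard errors (40 batches) and are asserted
  at the 99% level within 3 MC SEs with a hard 5-SE ceiling — a strict
  all-pass at 3σ over ~1000 comparisons would fail by chance with high
  probability, while a genuine formula error produces |z| in the hundreds.
* Monte-Carlo-confirmed degenerate corners: hx² = 0 with ρg ≠ 0 (and the
  symmetric hx² = 1 case) raise; hy²_PB at parameter corners returns limit
  values where finite.
* Genotype buffers are SNP-major int8; GWAS and score computations cast
  to float32 in bounded slabs (~80 MB); float64 is used for all
  scalar statistics.
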