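# Methods

## Scope and data model

`mrmediate` operates entirely on GWAS summary statistics: per-variant
effect sizes, standard errors, p-values and alleles for an exposure,
optional mediator traits, and an outcome. Binary-trait effects are log
odds ratios; results for binary outcomes are additionally reported on the
OR scale as exp(β) with the exponentiated CI. No individual-level data,
LD reference panels or remote services are touched: LD enters only as a
user-supplied table of pairwise r² values, and pairs absent from that
table are treated as unlinked (r² = 0). This is the right default for
summary-only workflows but means clumping without LD data prunes on
distance alone — callers who have a reference panel should export r²
for candidate pairs.

## Instrument selection

Four steps, in order: (1) significance filter, strict `p < threshold`
(default 5×10⁻⁸; mediator legs use the conventional relaxation to
5×10⁻⁶); (2) greedy LD clumping — candidates ranked by ascending
p-value with lexicographic snp-id tie-break for reproducibility, a kept
variant suppresses candidates on the same chromosome within a 10,000 kb
centre-to-centre window whose r² with it is ≥ 0.001; (3) harmonization —
outcome effects aligned to the exposure's effect allele with sign flips
for swapped alleles and strand complements where needed, palindromic
(A/T, C/G) variants removed unconditionally (no allele-frequency rescue),
and variants whose outcome p-value falls below a configurable threshold
(default 5×10⁻⁸) excluded as outcome-associated; (4) weak-instrument
filter on F = β²/SE² < 10. Every variant dropped at any stage lands in
an exclusion log with its reason, so survivors plus exclusions always
partition the input. For the exposure→mediator leg of mediation the
outcome-association exclusion is disabled (its rationale — avoiding
instruments that act on the disease directly — applies to the disease
outcome, not to the mediator).

## Estimators

All estimators consume aligned per-variant pairs (γ̂ⱼ, σ_xj, Γ̂ⱼ, σ_yj).

- **Wald ratio** (single variant): Γ̂/γ̂ with first-order delta SE
  σ_y/|γ̂|. Exposure-side uncertainty is second order here; it is
  handled explicitly by RAPS.
- **IVW**: weighted least squares of Γ̂ on γ̂ through the origin with
  weights 1/σ_y². "Random effects" is realized multiplicatively — the SE
  is scaled by max(1, √(Q/(J−1))) — so it never falls below the
  fixed-effects SE. With one variant IVW degrades to the Wald ratio.
- **MR-Egger**: the same regression with an intercept, after orienting
  every pair to γ̂ > 0. The slope is the causal estimate under InSIDE;
  the intercept estimates average directional pleiotropy and feeds the
  intercept test. SEs use the multiplicative scale with J−2 df.
- **Weighted median**: the inverse-variance-weighted 50th percentile of
  the ratio estimates (midpoint cumulative-weight convention with linear
  interpolation). SE from a seeded parametric bootstrap (default 1000
  draws) that redraws both γ̂ and Γ̂ and recomputes the weights.
- **Simple/weighted mode**: normal-kernel density over the ratio
  estimates; bandwidth is the modified Silverman rule
  0.9·min(sd, MAD)·J^(−1/5) times a user factor (default 1); the estimate
  is the density argmax on a 2048-point grid spanning the ratios ± 3
  bandwidths; degenerate zero-spread inputs return the (weight-)modal
  ratio exactly. Bootstrap SE as for the median.
- **MR-RAPS**: solves the profile-score equations in (β, τ²) with
  standardized residuals tⱼ = (Γ̂ⱼ − βγ̂ⱼ)/√(σ_yj² + β²σ_xj² + τ²); τ² is
  the systematic-pleiotropy overdispersion (fixed at 0 when disabled).
  The loss is Huber with tuning 1.345 by default (ψ-expectation
  δ = 2Φ(k)−1) or plain L2. Solution by alternating a secant solve in β
  with a bracketed root in τ² (the τ² moment equation is monotone, and a
  sign check at 0 resolves the boundary case). SE from the empirical
  sandwich of the β-score with τ² held fixed.
- **Contamination mixture**: ratio estimates modelled as valid
  (N(θ, σⱼ²)) or invalid (N(0, σⱼ² + ψ²)); ψ defaults to 1.5 × SD of the
  ratios. The profile log-likelihood assigns each variant to its better
  component along a θ grid (default 1001 points spanning the ratio median
  ± 5 SD); the estimate is the grid argmax, the 95% CI is the θ set
  within 1.92 log-likelihood units of the maximum (the enclosing
  interval is reported and non-contiguous sets are flagged multimodal),
  and the p-value is likelihood-ratio-based against θ = 0.
- **cML-MA**: for each candidate number K of invalid instruments,
  coordinate descent maximizes the constrained Gaussian likelihood in
  which exactly the K largest standardized residuals receive free
  pleiotropy parameters; per-K estimates are model-averaged with BIC
  weights exp(−BIC/2), BIC = 2·negloglik + K·log n. The penalty's n is
  the GWAS sample size, not the instrument count — with n ≈ J the
  penalty (log J) is weaker than the expected largest squared residual
  (~2 log J) and the averaging would spuriously prefer K ≥ 1 on clean
  data — so n defaults to 10,000 (a typical GWAS scale) and callers
  should pass the smaller of the two study sizes when known. The
  model-averaged SE is Buckland's Σρ_K √(se_K² + (β_K − β̄)²).
- **Multivariable IVW**: weighted multiple regression of Γ̂ on the J×E
  exposure-effect matrix without intercept, weights 1/σ_y², with the
  multiplicative scale max(1, √(Q/(J−E))); a rank-deficient design raises
  a collinearity error. With E = 1 it reproduces univariable IVW exactly.

p-values are two-sided normal for IVW/Egger/MVMR/RAPS, bootstrap-normal
for median/mode, and LR-derived for the contamination mixture. The suite
report flags `significant` (IVW p < 0.05) and `direction_consistent`
(all five primary-method estimates share one sign); which methods enter
the consistency check is configurable, defaulting to the five primary
methods.

## Sensitivity analyses

Cochran's Q on the ratio estimates (weights = inverse first-order
variances, J−1 df; identical to the Q in the IVW aux). Egger intercept
test straight from the Egger fit. MR-PRESSO: the observed statistic is
the weighted RSS of each variant against the IVW slope fitted without
it; the null distribution comes from seeded parametric simulations
(default 1000) redrawing both sides; global and per-variant p-values use
the add-one correction (r+1)/(n_sim+1), per-variant p-values are
Bonferroni-adjusted across instruments, flagged outliers are removed and
IVW re-fit for the corrected estimate, and the distortion p contrasts
the raw-vs-corrected shift with the same shift under random same-size
removals within the simulations. The corrected estimate is reported,
never silently substituted for the headline estimate. Leave-one-out
refits IVW J times and flags any removal that flips the sign or the
5%-significance of the estimate.

## Mediation

The two-step decomposition uses three IVW fits: exposure→outcome
(β_total — deliberately the total effect, not an MVMR direct effect,
matching the usual mediation-table convention), exposure→mediator (β₁)
and mediator→outcome (β₂). The mediation effect is β₁β₂ with first-order
delta SE √(β₁²SE₂² + β₂²SE₁²) (second order, adding SE₁²SE₂², is
available); the mediated proportion is 100·β₁β₂/β_total, reported with
its sign — a negative proportion marks inconsistent mediation and is
flagged, not truncated. Screening keeps candidates whose
mediator→outcome and exposure→mediator IVW p-values are below 0.05 with
five-method direction consistency, then requires sign(β₁β₂) =
sign(β_total); a funnel of counts and a per-candidate exclusion log are
always reported. No multiple-testing correction is applied across
candidates by default (the screen is exploratory); a familywise switch
exists. Bidirectional checks run the same IVW machinery on
reverse-direction instruments and flag reverse p < 0.05; an empty
reverse instrument set is reported as untestable rather than an error.

## Synthetic data

`simulate_chain` generates summary statistics for an
exposure → mediator → outcome chain entirely at the summary level: true
instrument effects are drawn N(0, σ²) with σ² = (F_target − 1)·SE², so
the expected per-variant F matches the target; observed effects add
sampling noise with SE = 1/√n for unit-variance continuous traits and
1/√(n·cf·(1−cf)) for a binary outcome with case fraction cf, whose
effects are emitted directly on the log-odds scale (a rare-disease
approximation; no liability-scale claims beyond sign and magnitude).
Defaults encode the target study's conditions: n = 5440 (exposure GWAS),
3757 (mediator), 500,348 with 3504 cases (outcome); total effect 0.145
split as direct 0.128 plus indirect 0.2 × 0.085 = 0.017 (11.7%
mediated); 30 instruments per trait at mean F 100. Horizontal pleiotropy
is a direct effect αⱼ on the outcome association of a configurable
fraction of exposure instruments — balanced (zero mean), directional
(nonzero mean), or InSIDE-violating (αⱼ correlated with γⱼ); the
mediator path carries no pleiotropy by default. Instruments are
simulated unlinked on positions spaced beyond the clumping window;
clumping is exercised on separately constructed LD fixtures. All
randomness flows from one seed through `SeedSequence` spawning, so a
given seed reproduces the study bit-for-bit.

What the generator does **not** emulate: LD between instruments, sample
overlap between the three GWAS, allele-frequency-dependent power,
genome-build issues, or selection effects in how real instruments reach
genome-wide significance. Passing recovery and calibration suites on
this generator therefore demonstrates correctness of the estimators
under their own assumptions, not robustness to those real-data
complications.

The single-cell generator produces negative-binomial counts
(gamma–Poisson, dispersion 0.5 by default) over ~1000 genes including a
mitochondrial block, programs marker positivity per group directly
(positive cells receive a nonzero marker count), and perturbs designated
cells to violate the QC rules (mitochondrial counts inflated, or 95% of
genes silenced to push detected genes below the floor). QC metrics are
recomputed from the matrix, never trusted from labels.

## Numerical choices and conventions

- Significance filters are strict inequalities; a p-value exactly at the
  threshold is excluded. p-values of exactly 0 are clamped to the
  smallest positive double with a warning.
- Clumping ties in p-value break lexicographically on snp id; clumping
  output is invariant to input row order.
- Coordinates are 1-based; the clump window is centre-to-centre.
- Bootstrap SEs use 1000 seeded draws by default — enough for the ~10%
  SE stability the suite checks, cheap enough for interactive use.
- The two-proportion comparison uses the pooled z-test, falling back to
  Fisher's exact test when any expected cell count is below 5; both
  p-values are reported, the operative one is labelled.
- Marker positivity is raw count > 0 (threshold configurable);
  mitochondrial genes are matched by a configurable case-insensitive
  prefix (`mt-`).
- Cell-level QC retains a mitochondrial fraction of exactly 5% and
  removes strictly greater; gene-count bounds are inclusive.
- Problem sizes in the test and acceptance suites (e.g. 100–2000
  replicates, 10–30 instruments) are chosen as the smallest sizes at
  which the binomial/χ² noise of the checked rates is comfortably inside
  the asserted bands.

## Known limitations

- The contamination mixture's invalid component is centred at zero with
  inflated variance. When invalid instruments carry pleiotropy
  proportional to instrument strength (InSIDE-violating), their ratios
  form a tight rival line and the profile likelihood can prefer that
  rival mode; recovery is only guaranteed when invalid ratios scatter
  off the true line (e.g. additive pleiotropy). The multimodality flag
  in the aux output marks exactly these cases.
- The Wald-ratio SE is first order; with very weak instruments it is
  anti-conservative, which is why the F ≥ 10 filter and RAPS (which
  models exposure-side noise) exist.
- MR-PRESSO's distortion test here is a simulation contrast against
  random same-size removals, simpler than the original's bootstrap of
  outlier sets; its global/outlier tests follow the original closely.
- MVMR conditions only on the exposures supplied; it does not detect
  unmeasured confounding pathways.
- Mediation treats candidate mediators independently; shared instruments
  across correlated mediator phenotypes induce correlated estimates that
  the screen does not model (mirrored by near-identical rows for related
  phenotypes in real applications).
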