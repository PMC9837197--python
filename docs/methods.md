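# Methods

## The problem

Chained-equations imputation (fully conditional specification, FCS) draws
each incomplete variable from a univariate conditional model, iterating
over variables.  The algorithm is only guaranteed to sample a well-defined
joint Bayesian posterior when (i) the conditionals are *compatible* with a
joint model and (ii) the joint prior factorizes into independent priors for
each conditional's parameters and the remaining margin (*non-informative
margins*).  Normal linear conditionals are compatible with a multivariate
normal joint model; this package supplies the informative-prior half of the
argument: the exact correspondence between a normal-inverse-Wishart (NIW)
prior on `(μ, Σ)` and per-variable normal-inverse-gamma (NIG) priors on
each regression's `(α_j, β_j, σ_j)`.

## Prior transformation and its conventions

With variable `j` ordered first, the change of variables
`(μ, Σ) ↔ (θ_j, θ_{−j})`, where `θ_j = (α_j, β_j, σ_j)` and
`θ_{−j} = (μ_{−j}, Σ_{−j})`, has Jacobian `|Σ_{−j}|` and splits the NIW
prior *exactly* into

* `σ_j ~ IW₁(ν, λ_j)` with `λ_j` the Schur complement of the IW scale,
* `β_j | σ_j ~ N(Ψ_{−j}⁻¹ψ_j, σ_j Ψ_{−j}⁻¹)`,
* `α_j | β_j, σ_j ~ N(μ₀ⱼ − β_jᵀμ₀₋ⱼ, σ_j/τ)`,
* independently `Σ_{−j} ~ IW(ν−1, Ψ_{−j})` and
  `μ_{−j} | Σ_{−j} ~ N(μ₀₋ⱼ, Σ_{−j}/τ)`.

`NIGPrior.coef_scale` stores `λ_j·P` where `P` is the σ-normalized
coefficient precision (`cov((α_j, β_j)|σ_j) = σ_j P⁻¹`); for a diagonal
`Λ = diag(60)` with `τ = 1`, `μ₀ = 0` this is `diag(60, 3600, 3600)` — the
weakly-informative per-variable prior used in the experiments.  The
factorization is an exact identity (the implementation verifies it to
machine precision), which is the operative content of the non-informative
margins condition for this family.

The inverse-Wishart is parameterized inconsistently across the literature,
so `NIWPrior` carries an explicit convention flag mapping `(m, Λ)` to the
textbook `(df, scale)` pair: `scale_literal` (default) reads `Σ ~ IW(m, Λ)`
and maps `Λ = diag(60), m = 3` to the margin `σ_j ~ W⁻¹(3, 60)`;
`density_literal` reads the density kernel literally as
`tr(Λ⁻¹Σ⁻¹)` with `df = m + 1`.  Both conventions factorize exactly; they
disagree about which NIG prior a given `(m, Λ)` denotes.  The default is
fixed by a calibration test: it is the convention that reproduces the
worked weakly-informative prior mapping above.

The marginal prior of the coefficients is Student-t.  `marginal_coef_t`
reports the conventional degrees of freedom `2m − p + 1` used in this
setting (4 for `m = p = 3`) together with the NIG-consistent shape matrix
`(λ_j/df)·Λ_{−j}⁻¹`; the large-sample normal approximation is the df → ∞
limit of that t.  The exact marginal under the stored NIG has df equal to
`sigma_df`; for the weakly-informative prior the two differ by one — the
reported df is the interface contract, the shape is chosen so the quadratic
form matches the NIG.

The α-prior is constructed jointly with β from the factorized quadratic
form rather than as a separate univariate law: the exact conditional
variance is `σ_j(1/τ + μ₀₋ⱼᵀΛ_{−j}⁻¹μ₀₋ⱼ)`, which reduces to `σ_j/τ` when
`μ₀ = 0` (the only regime exercised by the experiments).

## Samplers

All draws are exact conjugate updates; no inner MCMC.

* NIG regression update (σ first, then coefficients given σ, matching the
  prior factorization): posterior precision `P_n = P₀ + XᵀX`, mean
  `γ_n = P_n⁻¹(P₀γ₀ + Xᵀy)`, inverse-gamma shape `a₀ + n/2` and scale
  `b₀ + (yᵀy + γ₀ᵀP₀γ₀ − γ_nᵀP_nγ_n)/2`.  A proper prior regularizes
  rank-deficient designs.
* NIW update given completed data: `ν_n = ν + n`,
  `Ψ_n = Ψ + S + (τn/(τ+n))(ȳ−μ₀)(ȳ−μ₀)ᵀ`, `μ_n = (τμ₀ + nȳ)/(τ+n)`,
  `τ_n = τ + n`.
* Missing blocks are drawn per missing pattern from the conditional
  multivariate normal (block Schur formulas), vectorized over the rows of a
  pattern.

Randomness is organized as one root seed with integer substream
identifiers (`numpy.random.default_rng([seed, …ids])`): each chain and each
variable owns an independent, reproducible stream, so visit-sequence
experiments are not confounded by stream reuse.

## Imputation engines

**FCS**: missing cells are initialized with uniform draws from the
column's observed values; each iteration visits the variables in the
configured sequence, refits variable `j` on the rows where it is observed
against the *current* values of the others (sequential Gibbs update), and
overwrites only `j`'s missing cells with predictive draws.  `m` independent
chains of `n_iter` iterations (defaults 5 and 10; chained-equations samplers
typically reach their stationary distribution within 5–10 iterations) yield
the `m` imputed datasets.  Observed cells are never touched.

**JM**: data augmentation alternates the NIW posterior draw (P-step) with
per-pattern conditional-MVN redraws of all missing cells (I-step).  The `m`
imputations are taken at evenly spaced post-burn-in iterations to reduce
autocorrelation between them; the retained `(μ, Σ)` sample is the reference
posterior for the equivalence check.  Data augmentation was chosen over a
monotone decomposition because the three-pattern design is non-monotone.

## Synthetic data and amputation

`generate_mvn` draws from the study's trivariate normal
(`μ = (1, 4, 9)`, `Σ = [[4,2,2],[2,4,2],[2,2,9]]`, `n = 200` in the
experiments).  `ampute` assigns each case to one of three one-variable
missing patterns (x, y or z) with equal probability; within a pattern the
designated variable is made missing

* **MCAR**: with probability `overall_prop` (default 0.5 — read as "50% of
  cases become incomplete, one missing cell each"; alternative readings of
  the missingness volume are exposed through `overall_prop`), or
* **MARr** (right-tailed MAR): with probability `expit(a + s)` where `s` is
  the standardized unit-weight sum of the pattern's *observed* variables
  and the intercept `a` is calibrated by root finding (tolerance 1e−6) so
  the expected within-pattern missing fraction equals `overall_prop`.
  Missingness depends only on observed coordinates, so the mechanism is MAR
  by construction; the logistic-on-standardized-score form with unit slope
  is the standard amputation design for right-tailed MAR.

What the generator does *not* emulate: non-normal margins, MNAR selection,
multi-variable patterns, and clustered or longitudinal structure.  Passing
tests therefore certify the Bayesian machinery under a correctly specified
normal model, not robustness to model misspecification.

## Experiments

* **Bias / coverage / CI width** (`coverage_experiment`): per replication,
  generate → ampute → impute (m = 5, 10 iterations) → per-dataset mean of y
  with variance `s²/n` → Rubin's rules (`T = ūbar + (1+1/m)b`, symmetric
  t-interval with Barnard–Rubin degrees of freedom, complete-data df
  `n − 1`); the same incomplete data are scored by complete-case analysis
  (listwise deletion, t-interval).  500 replications in the shipped runs;
  bias is reported to the table's 2-decimal rounding.
* **Order effect** (`order_effect_experiment`): visit sequence (z, x, y)
  under MCAR; the iteration is augmented to record the OLS y-on-(x, z)
  slope right after the z-update (`β̂₁ᶻ`) and right after the x-update
  (`β̂₁ˣ`).  After 10 burn-in iterations, the differences over the recorded
  iterations are summarized by their mean and a batch-means SE (20 equal
  batches — a batch count that leaves batches much longer than the series'
  correlation length); the 95% interval `mean ± 1.96·SE` is tested against
  zero.  Because consecutive β̂ᶻ and β̂ˣ values share almost all completed
  data, the difference series telescopes and its mean is far more stable
  than the batch-means SE suggests — exclusions under the null are
  therefore much rarer than 5%, matching the published count of 3 in 500.
  The power check injects a systematic shift into x's imputed cells at the
  post-x measurement point only (a shift that persisted into the chain
  would cancel from the difference identically and is undetectable by
  construction).
* **Posterior equivalence** (`jm_fcs_posterior_draws` /
  `posterior_compare`): one amputed dataset, a single long FCS chain and a
  JM chain (2000 post-burn-in draws each, burn-in 10); JM draws are mapped
  to the regression scale via the conditional-MVN formulas; reported as
  quantile pairs and the two-sample KS statistic.

## Numerical choices

* SPD validation via symmetric eigenvalue check with relative threshold
  1e−10; Cholesky factorizations raise on failure.
* Posterior coefficient draws use `L⁻ᵀz` with `L` the Cholesky factor of
  the precision (no explicit inverse).
* Batch-means series whose length is not divisible by the batch count are
  tail-truncated with a warning.
* Inverse-gamma draws via `b_n / Gamma(a_n)` on the shared generator, so
  every draw sequence is reproducible from `(seed, stream ids)`.
* `rubin_pool` with `m = 1` returns the within variance only and warns;
  `b = 0` yields an infinite-df (normal) interval.

## Known limitations

* Univariate imputation models are normal linear only — no PMM, logistic
  or other GLM imputers, and no block or passive imputation.
* Priors outside the NIW/NIG family are out of scope; a Jeffreys-type
  analysis is approachable only as a diffuse limit of the proper prior.
* The amputation module implements MCAR and right-tailed MAR with
  one-variable patterns; MNAR and multi-variable patterns are not
  supported.
* Published CI-width cells for this design depend on details of the
  original missingness volume and MAR strength that are not stated; the
  shipped experiments fix those by the readings documented above and report
  whatever the procedure actually produces.
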