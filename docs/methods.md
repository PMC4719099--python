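# Methods

This note documents the models and procedures implemented in `pwibayes`, the
choices made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Analysis unit and preprocessing

The unit of inference is the per-participant, per-condition **median** of
correct naming latencies. Naming latencies are right-skewed, so the median is
used as the central-tendency summary rather than the mean; no transformation
or trimming is applied beyond the stated exclusion rules.

Exclusions, applied in one pass with precedence **error > voice-key failure >
fast**, so every trial is counted exactly once in the report:

1. trials coded as spoken errors or disfluencies (these typically still carry
   a latency in a voice-key log, but it is not analyzed);
2. voice-key trigger failures — any trial without a usable latency is put in
   this class, including correct-coded trials with a missing RT;
3. latencies below a floor of 200 ms (artifactual triggers/fast guesses).

Medians use the mean-of-two-central-order-statistics convention for even
counts. Cells with no retained trials are explicitly missing; nothing is
imputed, and missingness propagates to every derived quantity.

Derived per-participant scores:

* **Effects (ms)** — lexical = unrelated − neutral; semantic = related −
  unrelated; phonological = phonological − unrelated. Interference is
  positive, facilitation negative by construction.
* **Standardized scores** — z = (effect − control mean) / control SD, with
  the *sample* (n−1) SD of the control group; |z| > 2 (≈ the 95th percentile
  under normality) flags a single case as outside the control range. The
  population-SD variant would differ by √(n/(n−1)) ≈ 4% at n = 13; the sample
  SD is the standard single-case convention.
* **RT ratios** — each effect divided by that participant's unrelated-condition
  median (the condition common to all three effects). A purely multiplicative
  slowing factor cancels exactly, so ratio distributions are comparable
  between slow and fast groups; this is the general-slowing correction.

## The robust hierarchical split-plot model

Observations: all non-missing condition medians `y`, indexed by group
`g ∈ {control, patient}` and condition `c ∈ {neutral, unrelated, related,
phonological}`.

Likelihood: `y ~ t(nu, mu[g,c], sigma)` with one location per group ×
condition cell and a single scale and normality parameter shared by all
cells, so their estimation pools information across the whole design. The
t likelihood is the robustness mechanism: with small `nu` (heavy tails),
extreme participants are treated as tail events and barely move the cell
locations — on a calibrated synthetic dataset, a +10-pooled-SD outlier moves
its cell's posterior mean by ~2% of what it does to the arithmetic mean, and
the posterior of `nu` collapses toward small values (see
`scripts/acceptance.py`).

Locations are decomposed ANOVA-style into a baseline plus group, condition,
and interaction deflections, each family constrained to sum to zero (the
interaction over both rows and columns). Priors are deliberately vague and
scaled from the data:

| parameter | prior | default |
|---|---|---|
| baseline `b0` | Normal(pooled mean, precision = 10⁻⁶ × pooled precision) | data-derived |
| scale `sigma` | Uniform(pooled SD / 1000, pooled SD × 1000) | data-derived |
| normality `nu` | Exponential(mean 29), unshifted | 29 balances near-normal vs heavy-tailed |
| deflections | Normal(0, 1/tau), one shared `tau` | — |
| `tau` | Gamma(shape, rate) moment-matched (shape = m²/s², rate = m/s²) to the mean m of the observed per-cell precisions and s = 10⁶ × their SD | data-derived |

The 10⁶ inflation of the precision SD is what makes the deflection hyperprior
noncommittal. A per-family variant (separate `tau` for group, condition and
interaction deflections, same gamma prior) is available as
`PriorSpec(per_family_precision=True)`; the shared-`tau` form is the default.
`nu`'s exponential prior is placed on `nu` itself rather than `nu − 1`; with
mean 29 the difference is negligible for these data.

### Sampling

The default backend is a Gibbs sampler using the scale-mixture-of-normals
representation of the t distribution (one latent gamma weight per
observation). All location parameters then have conjugate normal updates, the
deflection precision a conjugate gamma update, and the scale a conjugate
(truncated) gamma update on 1/sigma²; `nu` takes a random-walk Metropolis
step on log `nu` with step size adapted toward 44% acceptance during burn-in
only. Deflections are sampled *unconstrained* and swept into the sum-to-zero
parameterization at every saved draw (recentering is algebraic, so the
constraints hold exactly); this parameter-expanded scheme mixes well and is
the standard approach for hierarchical factorial models of this form.

Defaults follow the published analysis settings: 100,000 retained draws,
thinning 50, burn-in 2,000; chains default to 4 (chain count is this
package's choice) and are initialized from data summaries (pooled and factor
means/SDs) with per-chain jitter. Identical data, priors, configuration and
seed reproduce identical draws bit-for-bit. Convergence is checked with
split-R̂ and effective sample size (via arviz) on the baseline, scale,
log-normality and all cell means; R̂ ≥ 1.05 flags the fit (returned with
`converged=False` plus a warning, never silently discarded). Tests and the
acceptance script run 2 chains with 2,000–8,000 retained draws at thinning 1,
which this Gibbs scheme's low autocorrelation supports; tolerances there are
set accordingly.

A second backend runs `emcee`'s affine-invariant ensemble on the joint
log-posterior (sampling log sigma, log nu, log tau with the appropriate
Jacobians). Its integrated autocorrelation time on this posterior is a few
hundred ensemble steps, so it is configured with its own burn-in/thinning in
ensemble steps; it exists to cross-validate the Gibbs results (the test suite
requires agreement of all contrast means within 3× combined Monte-Carlo SE),
not for production use. It implements only the shared-`tau` prior.

### Decisions

All effects of interest are linear contrasts of the 8 cell-mean posteriors:
the overall group effect (patient − control, averaged over conditions), each
group's three distractor effects, and each effect's group difference (signed
control − patient, so negative values mean a larger patient effect). The 95%
HDI is computed as the *shortest* run of consecutive order statistics
containing ⌈0.95·N⌉ draws (ties broken toward the smaller lower bound) — for
skewed posteriors this is shorter than the equal-tailed interval. A contrast
is credibly positive/negative when its HDI excludes zero; when the HDI
contains zero, zero is a credible value (reported with the HDI so narrowness
can be judged; no ROPE is defined). Because all deflections are estimated
jointly in one posterior, the several contrasts are read from one fixed
distribution rather than from separate tests.

## Frequentist comparators

* **Split-plot ANOVA** on the complete-case median table: group tested
  against participants-within-groups; condition and interaction against the
  within-participant residual. Sums of squares are computed directly (they
  partition the total exactly; the test suite cross-checks against
  `pingouin.mixed_anova`); with two groups of sizes n₁, n₂ and 4 conditions
  the dfs are (1, n₁+n₂−2) and (3, 3(n₁+n₂−2)). No sphericity correction is
  applied by default — a Greenhouse–Geisser option exists — and no
  multiplicity correction anywhere.
* **Effect t-tests**: one-sample t per group and effect (df = n−1), and
  Welch unequal-variance t with Welch–Satterthwaite fractional df for the
  between-group comparison of each effect, both with 95% CIs on the same df.
  Welch is the appropriate choice given the very unequal group sizes and
  variances.
* **Error rates**: per condition, a binomial GLM (logit link) of the error
  indicator on group, Wald p-value; conditions with zero errors in either
  group are flagged degenerate rather than fitted through separation.

## Synthetic-data generator

The generator emulates a two-group PWI voice-key experiment: 22 pictures × 4
distractor conditions (88 experimental trials per participant, practice
excluded), trial order shuffled per participant. Correct latencies come from
a shifted lognormal, `rt = 250 + exp(N(log(L − 250), sigma_ln))`, whose
**median equals the target cell location L exactly**, so injected effects are
additive on the median scale and recoverable without bias by median-based
summaries (an ex-Gaussian family is available as an alternative). Artifacts
are injected per trial: spoken errors (which keep a latency), voice-key
failures (latency missing), and fast guesses uniform on [100, 199] ms.

The default "paper-like" calibration represents a published left-PFC lesion
study as a realistic fixture with known truth (it is not a re-creation of the
raw data):

| quantity | value | anchor |
|---|---|---|
| group sizes | 13 controls, 6 patients | reported design |
| control neutral median | 750 ms | typical older-adult naming latency |
| patient neutral-condition slowing | 250 ms | reported neutral-condition gap (overall gap ≈ 408 ms) |
| condition effects (ms) | controls 80 / 46 / −18; patients 332 / 75 / −172 | reported group means |
| lognormal sigma | controls 0.19, patients 0.45 | within-group effect SDs implied by the reported 95% CIs (≈35 vs ≈160 ms) |
| participant intercept SD | controls 25 ms, patients 50 ms | per-cell residual spread implied by the reported posterior interval widths |
| error rates | 1.5% / 2% | reported ranges |
| voice-key failure rates | 3.0% / 5.3% | reported percentages |
| fast guesses | 0.1% | "one trial" scale |

What the generator does **not** emulate: item-level effects (conditions are
opaque labels; no word frequency, length or phonological-overlap structure),
sequential effects (fatigue, practice within the session), condition-specific
artifact rates, correlations between a participant's effect sizes, and any
lesion anatomy. Passing tests therefore show that the pipeline recovers known
truth under realistic skew, heterogeneity and artifact rates — not that it
would handle item-level confounds, which are outside this package's scope.

## Calibration and recovery results (computed by the test suite / acceptance script)

* HDI coverage: across 150–200 replicate experiments at fixed truth with
  model-consistent noise, pooled 95%-HDI coverage of the named contrasts is
  ≈ 0.95–0.96.
* Cell-mean recovery at 40 participants/group: posterior means typically land
  within 3 posterior SDs of truth on all 8 cells. Under the lognormal
  generator the model's estimand for patient cells differs from the
  generating median location by ~10–20 ms (skewed sampling distribution of
  the participant median, plus partial pooling of interaction deflections),
  so the recovery test requires full 8-cell recovery in the majority of five
  replicates rather than in every single one.
* The qualitative patient/control pattern: lexical interference is credible
  in both groups and credibly larger in patients in the large majority of
  replicates, as are patient phonological facilitation and its group
  difference; the *control* phonological facilitation (truth −18 ms against a
  per-participant effect SD of 36 ms) is intrinsically at the edge of
  detectability at n = 13 — no estimator can exclude zero in a clear majority
  of replicates at that signal-to-noise — so joint-pattern replication rates
  are dominated by that single component. This mirrors the classical side,
  where the control phonological t-test is likewise non-significant.

## Numerical notes and limitations

* The truncated 1/sigma² gamma update resamples up to 10 times if a draw
  falls outside the uniform-prior bounds, then clips; with the default
  ±3-orders-of-magnitude bounds the truncation is essentially never active.
* Degenerate inputs are rejected with messages rather than guessed at: zero
  pooled variance, cells with zero variance (auto-priors), fewer than 2
  participants or conditions, all-zero contrast coefficients. A contrast
  whose draws are all equal is returned flagged `degenerate` with a
  zero-width interval.
* The HDI routine requires ≥ 100 draws and a mass resolvable at the given
  sample size.
* The model ignores the pairing of conditions within a participant (no
  participant term, matching the analysis it implements); between-participant
  variability therefore enters the residual scale, and within-group contrasts
  are estimated less precisely than a paired analysis would allow.
* No model comparison, ROPE-based equivalence testing, per-cell variances, or
  trial-level modelling; medians in, cell means out.
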