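# Methods

This note documents the statistical model, the synthetic-data design, the
search, and every numerical decision a maintainer would want to know. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Trajectory model

Every biomarker series (a positive value per subject-visit plus baseline
covariates) is modelled on the natural-log scale:

    log y_ij = β₀ + b₀ᵢ + β₁·Age.blᵢ + β₂·sexᵢ
               + t_ij·(β₃ + b₁ᵢ + β₄·DXᵢ + β₅·ABᵢ + β₆·APOE4ᵢ) + ε_ij

- `t_ij` is the visit time centred at subject i's mean visit time. With
  correlated random effects this makes the fit invariant to shifting a
  subject's visit schedule in time (asserted in `tests/test_model.py`).
- `sex` is +1 female / −1 male; `DX` (0 = cognitively unimpaired,
  1 = impaired), `AB` (amyloid positivity) and `APOE4` are 0/1 baseline
  flags. DX, AB and APOE4 act on the slope only — the printed model is
  implemented exactly as stated, with no DX/AB intercept terms.
- `(b₀, b₁) ~ N(0, G)` with a full 2×2 covariance; `ε ~ N(0, σ_e²)`.
- When the model is fitted inside one target group (amyloid-positive CU or
  CI), the DX and AB terms are dropped because those covariates are
  constant there (`include_dx=False, include_ab=False`).

**Estimation.** REML for all reported estimates; likelihood-ratio tests
(e.g. the education covariate screen) refit both nested models by ML on
identical rows. The fitter (`cvrkit/lmm.py`) is purpose-built for this
two-random-effect structure: writing `G = σ² Ψ` and parameterising Ψ by
`(log sd₀, log sd₁, atanh ρ)`, β and σ² are profiled out analytically and
the criterion is minimised over three parameters with L-BFGS-B using an
analytic gradient. All per-subject quantities reduce to 2×2 cross-products
computed once, so a fit costs tens of milliseconds at any cohort size used
here. The profile surface can hold a local optimum with the slope variance
collapsed to zero; the optimiser therefore starts from a method-of-moments
estimate (per-subject lines on OLS residuals, which over-estimates the
slope sd and descends toward the interior optimum) and, whenever the
result lands on the collapsed boundary, verifies it against a restart with
the slope sd reset to an interior scale. `tests/test_lmm.py` pins the fitter
to two independent oracles — statsmodels `MixedLM` and lme4's `lmer` — at
matching log-likelihoods and coefficients. Genuinely singular fits (a
variance component at zero) are flagged (`singular`), not raised: in the
degenerate noise-free limit the OLS solution with zero variance components
is returned directly, since the variance parameters are then unidentified.

Wald t-statistics are estimate/SE with no degrees-of-freedom correction;
standard errors are the GLS `σ²(XᵀV⁻¹X)⁻¹` form, matching lme4.
Non-convergence returns a flagged result object; callers (notably the GA)
must check the flag.

## Trial-design metrics

**Sample size estimate (SSE).** Per-arm n for a two-arm trial measured at
baseline and at `T` years, powered at `1−β = 0.80` (two-sided α = 0.05) to
detect a `pct = 20%` reduction of the slope:

    n = ⌈ 2 (z_{1−α/2} + z_{1−β})² σ_slope² / (pct·|β₃|)² ⌉,
    σ_slope² = var(b₁) + σ_e² / Σⱼ(tⱼ−t̄)²,   Σⱼ(tⱼ−t̄)² = T²/2 for two visits.

`T` = 1.5 years (78 weeks) for the clinically-impaired target group and
all-data fits, 4.5 years (234 weeks) for the cognitively-unimpaired group
(1 year = 52 weeks at the interface). z-quantiles, not t, consistent with
the large-sample slope-difference method. The formula is validated by
simulation, not by matching any reference implementation bit-for-bit:
`simulate_trial_power` draws per-subject change scores
`slope·T + noise` with `slope ~ N(β₃, var(b₁))` (treated arm: β₃ shrunk
20%) and `noise ~ N(0, 2σ_e²)`, analyses each trial with a pooled
two-sample t-test, and the rejection rate at n = SSE must sit at the
design power (asserted at ±5 percentage points over 10,000 trials).

**Percentage error.** `100·(e^sd − 1)` maps residual variability from the
log scale to a native-scale percentage. `sd` is the model's REML residual-sd
estimate σ̂_e. The sd of the conditional residual vector estimates the same
quantity but is shrunken by the predicted random effects (downward bias on
the order of 20% at 3–4 visits/subject), which would break the
bootstrap-coverage guarantees; the empirical variant remains available as
`percentage_error(fit, empirical=True)`.

**Group separation.** The Wald t of the AB×time or DX×time term from the
all-data fit.

**Detectable effect.** The SSE formula inverted for `pct` at a given
per-arm n; evaluating it at the (pre-ceiling) SSE returns the design's 20%
exactly.

**Uncertainty.** Error and separations get model-based parametric-bootstrap
percentile CIs (2.5/97.5; default 1000 replicates, 200 in test profiles):
new `(b₀, b₁)` from the fitted covariance and residuals from σ̂_e on the
original design, refit, metric recomputed. Refits warm-start at the
original variance optimum; >10% failed replicates marks the interval
unreliable. SSE CIs use delta-method propagation instead (bootstrap
available as fallback): the covariance of the variance parameters comes
from the finite-difference Hessian of the (β-profiled) REML criterion over
`(θ, log σ²)`, combined with the GLS variance of β₃ under asymptotic
independence of mean and variance parameters, propagated through log(SSE).

## The genome and the fitness function

A candidate CVR is a vector over the 52-region atlas with codes
0/1/2 = numerator/excluded/denominator. Its fitness is

    fitness = min(t_AB, 2.6) / SSE

where t_AB comes from the all-data fit (full covariate set) and SSE from
the target-subgroup fit (amyloid-positive ∩ target cognitive group) under
that group's trial length. The 2.6 cap corresponds to the upper 0.5% tail
of a standard normal: beyond that, separation is convincing and additional
t buys nothing, which prevents the search from drifting along a
t-versus-SSE Pareto front. Two documented choices where the rule is
underdetermined: there is **no floor** on negative t_AB (a
wrong-direction separation is penalised proportionally), and the SSE
enters **pre-ceiling** so the fitness surface stays smooth.

## Genetic algorithm

Generational GA, defaults: population 32, elitism 2 (guaranteeing a
non-decreasing best fitness, asserted exactly), mutation probability 0.5,
at most 600 generations with early stopping after 100 without improvement,
three restarts with distinct seeds keeping the best (ties to the earliest
seed). Where the configuration is genuinely open the package chooses:

- **Selection**: tournament of size 2 — simple, standard, pressure
  controllable.
- **Crossover**: uniform per gene at rate 0.5 applied to non-elite
  offspring; the genome has no positional structure worth preserving, so
  uniform beats one-point.
- **Mutation** ("probability 0.5" is ambiguous): interpreted per offspring —
  with probability 0.5 one uniformly chosen gene is reassigned to a
  different code. Configurable.
- **Repair**: an offspring with an empty numerator or denominator gets one
  uniformly chosen excluded gene flipped into the missing composite; if
  impossible, it receives the worst-possible fitness (−∞) and the search
  continues. Invalid genomes and non-convergent fits are handled the same
  way rather than raising.
- **Initial population**: each gene NUM/EXC/DEN with probabilities
  (0.15, 0.70, 0.15), redrawn until valid — candidate ratios should start
  sparse.
- **Memoisation**: fitness is a deterministic function of the decoded
  composite sets and the data, so evaluations are cached on the canonical
  spec across generations and restarts (cache hit ≡ recompute, asserted).

`region_stability` reruns the whole multistart search on stratified
(DX×AB) random half-cohorts — 50% of subjects, default 100 repeats — and
reports each region's NUM/DEN/EXC selection frequencies (rows sum to 1),
suitable for stacked-bar display.

## Synthetic cohorts

The generator (`cvrkit.cohort`) emulates the structure of a large
observational ageing cohort so that every downstream stage is testable
with known truth. Per region r and subject i,

    log V_ri(t) = μ₀ᵣ + aᵣ(Ageᵢ−75) + sᵣ·sexᵢ + b₀ᵣᵢ
                  + (slopeᵣ + δDXᵣ·DXᵢ + δABᵣ·ABᵢ + δAPOEᵣ·APOE4ᵢ + b₁ᵣᵢ)·t
                  + u_iv + ε_riv

with `(b₀, b₁)` drawn per subject-region from the configured bivariate
normal, `u_iv` a per-visit scan-scale offset shared by all regions of the
visit (emulating global scaling/positioning effects; it cancels in any
region/region ratio but **not** in region/ICV, because ICV is generated
once per subject and held constant), and `ε` i.i.d. region-level noise.

Default study conditions (chosen once; every number is a config field):

| quantity | default | rationale |
| --- | --- | --- |
| subjects | 1400 | large multi-phase cohort scale |
| visits | 2 + Binomial(8, 0.3), ~0.9 yr apart (±0.45 jitter) | median follow-up ≈ 3 yr, range up to ~15 yr |
| age at baseline | 74 (sd 7) yr | elderly ageing cohort |
| education | 16 (sd 2.7) yr, zero true effect | screened covariate; null by design |
| P(female), P(APOE4) | 0.45, 0.45 | typical cohort composition |
| P(DX = CI) | 0.60 | memory-clinic-enriched sample |
| P(AB+ given DX) | 0.70 CI / 0.35 CU | amyloid coupled to cognitive status |
| sd(b₀), sd(b₁), corr | 0.10, 0.004/yr, −0.2 | ~10% between-subject volume spread, slope heterogeneity a fraction of disease effects |
| σ_e (regions), scan-scale sd | 0.04, 0.02 | single-region ratio error ≈ 4.6%, matching the few-percent regime of volumetric biomarkers |
| ventricles | +2.5%/yr, +1.2%/yr if AB+, +1.0%/yr if CI | pathological expansion |
| disease-signature regions (hippocampus, entorhinal, amygdala, accumbens, thalamus, ventral DC, parahippocampal) | −0.6%/yr base; −0.6 AB, −0.4 DX, −0.2 APOE4 %/yr increments | accelerated limbic/subcortical atrophy |
| other regions | −0.2%/yr, small increments | mild ageing atrophy |

`expected_slope` returns the delta-method annual log-slope any composite
ratio implies for a covariate profile (weights = expected baseline
volumes); it is exact when a composite's members share parameters, and is
the oracle for recovery tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no informative dropout or missing visits, no
site/scanner batch structure, no cross-region correlation of random
effects beyond the shared scan-scale factor, ICV exactly constant within
subject, linear trajectories only, and exact log-normality. Real
multi-site cohort data violate all of these to some degree; the
pipeline's comparative claims (CVR vs single-region baselines) should be
re-established on real cohorts.

## Split-half study

Subjects (never visits — the unit of independence) are split 50/50 within
strata of DX × AB × sex × APOE4 × baseline-age quartile; within a stratum
subjects are shuffled and assigned alternately, so counts differ by ≤1;
singleton strata are randomised, and a constant covariate collapses its
stratum dimension. Balance is reported as rank-sum (continuous) /
chi-squared (categorical) p-values. CVRs are discovered per half and
target group and evaluated **only** on the opposite half; the report
object carries each CVR's discovery subset and its audit refuses any
in-fold cell. One master seed derives the split seed, the GA seeds and the
bootstrap seeds through a fixed counter, making the whole study
reproducible from one integer. Heatmap scores are orientation-aware
min–max per metric column (lower better for SSE/error, higher for t;
best = 1, worst = 0; constant columns map to 0.5 with a warning).

The sensitivity analysis refits after excluding every subject with any
|Pearson residual| > 3 and reports each fixed effect's shift in units of
its original SE; losing a covariate level entirely flags the refit rather
than proceeding.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to make the suite a
desk-scale artifact: recovery at n = 500 subjects × 100 replicates,
bootstrap coverage at n = 60 with 200 bootstrap replicates × 100 outer
replicates, the planted-signal search on a 12-region atlas with 300
subjects, population 16 and patience 12 over ≤60 generations, and
stability/stagnation checks on further-reduced configurations. The
acceptance script's power calibration uses a 500-subject cohort and
10,000 simulated trials.

## Known limitations

- The fitter covers exactly the random-intercept+slope structure; no site
  random effects, heteroscedastic or autoregressive residuals, or
  Satterthwaite degrees of freedom.
- Delta-method SSE intervals rely on asymptotic normality of
  `(θ, log σ²)`; near-singular fits (slope variance on the boundary) make
  them optimistic — the bootstrap fallback is preferable there.
- Composites average raw volumes (mm³), so large structures dominate a
  composite's slope; volume-weighted or z-scored aggregation is out of
  scope.
- The GA explores bilateral regions only; hemisphere-split composites and
  multimodal features are out of scope.
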