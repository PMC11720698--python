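# Methods

## Scope and model

The package analyzes pairwise-comparison designs: two-level factors,
one or two of them, with participants — and optionally stimuli — as
random units. Three analysis layers share one data model (a long-format
observation table):

1. **Classical tests** (`classical`): independent and paired t-tests
   with the d family (d, d_z, d_av).
2. **Repeated-measures ANOVA** (`anova`): exact sum-of-squares
   decomposition for one-way between, one-way within, and 2×2
   fully-within designs on balanced data with one value per
   subject × cell.
3. **Linear mixed models** (`mixed`): the Gaussian LMM

       y = Xβ + Σ_g Z_g b_g + ε,   b_g ~ N(0, Σ_g),   ε ~ N(0, σ²I)

   with crossed random groupings g (participants, stimuli), random
   intercepts, and random slopes for any factor that varies within the
   grouping unit. Full covariance (slope–intercept correlations) is
   estimated per grouping.

The assumptions are the standard ones: Gaussian random effects and
residuals, homoscedasticity, exchangeable units, and missingness (LMM
path only) at random. The ANOVA path refuses unbalanced or incomplete
data and points the user to the LMM path rather than entering the
unbalanced sum-of-squares (Type II/III) territory.

## Effect sizes

**Eta squared (η²)** is an effect's share of *total* variance. In the
ANOVA layer it is SS_effect over the total SS about the grand mean. In
the LMM layer it is the per-term semi-partial marginal R²:
`Var(X_j β_j) / (Var(Xβ) + Σ_g v_g + σ²)`, where `v_g` is the mean
per-observation variance contributed by grouping g,
`tr(Z_g Σ_g Z_g')/n` (this reduces to the intercept variance for
intercept-only groupings and handles random slopes the way Johnson
extended the Nakagawa–Schielzeth R²). The model-level marginal R² uses
`Var(Xβ)` in the numerator. Variances of fitted contributions are
sample variances over the observed rows (n−1 denominator, R's `var()`),
which is the convention the reference implementations use; with the
population (divide-by-n) variance the reproduced values shift in the
third decimal.

**Partial eta squared (η²ₚ)** is SS_effect/(SS_effect + SS_error) in
ANOVA. It is a monotone transform of F and inherits the per-term error
stratum: values across terms are not shares of a common pool and can sum
past 1. From an LMM it additionally depends on the denominator df, which
moves with the random-effects specification even between models that fit
equally well. The LMM layer therefore computes it only on request
(`include_eta2p=True`), as t²/(t²+df), and always with a warning.

**Eta squared within (η²w)** is an effect's share of *within-unit*
variance — the variance a repeated-measures design actually resolves.
In ANOVA: SS_effect over the sum of every within-subject stratum
(all effect SS plus all effect-by-subject error SS). Equivalently, and
this is how the LMM layer computes it: center the response per unit
(subtract each unit's own mean over all its observations, plain mean
including unbalanced units), refit the identical model, and take the
semi-partial R² of the centered fit. Centering annihilates the
between-unit stratum while leaving all within-unit statistics unchanged,
so total-η² of the centered analysis equals η²w of the raw analysis;
this identity is property-tested. The random intercept of the centered
unit is retained in the refit — the ratio is unaffected because only
the allocation of variance across components changes, not the total —
which avoids the degenerate behavior some fitters show when a grouping
is dropped. A term that is constant within every centered unit (e.g. a
between-participant factor under participant centering) has no
within-unit variance to explain and is reported as undefined (`None`),
not zero.

Which unit to center by is a real choice in crossed designs: center by
the unit *within which* the effect varies (stimuli for a
between-participant factor, participants for a within-participant
factor). `effect_report` picks this automatically when every fixed term
varies within one grouping, and both centerings are available
explicitly; for an effect that is within both units the two centerings
answer slightly different questions and give similar but not identical
values.

**d family.** d = (M₁−M₂)/√((SD₁²+SD₂²)/2) for independent groups;
d_z = M_diff/SD_diff and d_av (same average-SD form as d) for paired
data. Confidence intervals invert the noncentral-t pivot (bisection to
1e−8 on the noncentrality parameter, scaled by √(1/n₁+1/n₂) or 1/√N).
The closed-form bridges d_av ≈ 2√(η²/(1−η²)) and d_z ≈ √(η²ₚ/(1−η²ₚ))
are exposed with their inverses (round-trip exact to 1e−12). All SDs
use the n−1 denominator; all p-values are two-sided. The default
independent-samples variant is Welch; the pooled (student) variant
exists because hand-checked references use it and because t² = F links
it to the one-way ANOVA.

## Contrast coding

Two-level factors are coded dummy (0/1), sum (−1/+1) or deviation
(−0.5/+0.5); deviation is the default because in a 2×2 with an
interaction its main-effect coefficients are marginal mean differences
and the interaction coefficient is the difference of simple effects.
The dummy-coding pitfall is kept reproducible on purpose: with an
interaction present, dummy-coded "main effects" are simple effects at
the other factor's reference level and can look significant when no
marginal effect exists. Fitted values and model-level R² measures are
invariant to the coding; per-term contributions are invariant between
sum and deviation (a pure rescaling) but *not* under dummy coding, whose
terms answer the simple-effect question — the per-term invariance is
asserted only across the centered codings. Level order is lexicographic
unless a reference level is given, and the comparison direction is
recorded in every CLI report, since the sign of every estimate depends
on it.

## REML engine

Estimation follows the profiled-REML formulation: with
W(θ) = I + Σ_g Z_g T_g T_g' Z_g' (T_g the relative Cholesky factor of
Σ_g/σ²), β and σ² are profiled out and

    dev(θ) = log|W| + log|X'W⁻¹X| + (n−p)(1 + log(2π r²/(n−p)))

is minimized over θ, with diagonal entries of each T_g bounded at zero.
Numerical design:

* All n-sized work happens once: the Woodbury identity reduces every
  evaluation to algebra on (Z'Z, Z'X, Z'y). The grouping with the most
  random-effect columns is handled as a batch of k×k blocks (one per
  level); remaining crossed groupings are folded in through a Schur
  complement of their much smaller stacked dimension. A fit with 500
  participants × 16 stimuli (16 000 rows) evaluates in milliseconds.
* Random-effect columns are standardized to unit RMS internally so the
  identity matrix is a reasonable start for every coding scheme;
  reported components are rescaled back.
* Optimization: Powell followed by an L-BFGS-B polish, from the
  identity start, a half-scale start, and two perturbed restarts; the
  best criterion value wins. Infeasible θ evaluates to a large finite
  penalty (1e12) rather than infinity, which derivative-free line
  searches tolerate. Convergence failure after all restarts raises.
* Singularity: a fit is flagged singular when a variance component is
  at the zero boundary (relative SD < 1e−4) or a correlation is within
  1e−4 of ±1. Singular fits are returned, not raised — boundary
  estimates are information, not errors.
* Satterthwaite df: df = 2(c'V_β c)²/Var(c'V_β c), with the denominator
  from the delta method using twice the inverse Hessian of the
  non-profiled REML deviance in (θ, σ); gradient and Hessian by central
  differences (relative step 1e−4, evaluations clipped at the variance
  boundary). On balanced classical designs this reproduces the textbook
  df (18 for the two-group random-intercept model, 9 for the paired
  model); at a singular optimum the Hessian is rank-deficient and the
  pseudo-inverse value is approximate, matching the behavior of the
  standard implementations. A `df_method="residual"` fallback (n − p)
  exists for users who distrust the approximation.

Agreement with lme4/lmerTest (checked via Rscript in the test suite and
during development on every embedded dataset) is at the level of their
printed output, 3–4 significant figures; the reference optimizer is
different, so bit-exact equality is not claimed.

## Synthetic data

`simulate_crossed` draws from exactly the model the fitter assumes:
deviation-coded fixed effects, Gaussian per-unit intercepts and slopes,
Gaussian residuals, optional independent row dropout (missing completely
at random). Factor scopes cover the three crossed layouts that occur in
practice: between participants (within stimuli), within participants
(between stimuli, as when different items instantiate conditions), and
within both (every participant sees every stimulus in both conditions).
`expected_effect_sizes` gives the closed-form population η² and η²w per
term for balanced specs: a ±0.5-coded main effect with coefficient β
contributes β²/4 (a two-factor interaction β²/16, and a slope SD s
contributes s²·E[x²] in the same way); η²w removes the centered unit's
intercept variance and any fixed term constant within that unit from
the denominator. These closed forms are population quantities; the
centered-refit estimator carries a finite-sample attenuation of order
σ²/m (m observations per unit), so recovery tests use designs with
m ≥ 32.

What the generator does *not* emulate: bounded/ordinal responses (Likert
scales), heavy tails or skew, heteroscedastic units, non-random
missingness, sequence/practice effects. Passing recovery tests therefore
show the estimators are correct under the model's own assumptions, not
that the model is right for any particular real dataset.

Parameter-recovery checks (fixed seeds): a between-groups design with
200 participants × 4 observations recovers component SDs within 10% and
marginal R² within 0.02 of the analytic ratio; a crossed 500 × 16
within-both design recovers η² and η²w within 0.02 of the closed form,
with the empirical value averaged over three generated datasets to
measure the estimator rather than one draw's sampling noise. Problem
sizes were chosen so the whole suite stays desk-scale.

## Embedded datasets

Five toy datasets ship in the package (`fixtures`), stored in their
printed wide layout and reshaped on load, with SHA-256 checksums
guarding the transcription: a two-group working-memory comparison
(20 × 2 days), its longitudinal counterpart (10 × 2 ages × 2 days), a
2×2 fully-within design (10 × 8), a face-rating study with crossed
participants and stimuli (20 × 10), and a bilingual text-reading study
(12 × 20 texts). They are real analysis inputs, not just test data: the
README's worked example and the acceptance script run on them.

## Known limitations

* Two levels per factor, at most two fixed factors, no covariates, no
  nesting; mixed between/within factorial ANOVA beyond one between
  factor is out of scope (the LMM path covers those designs).
* No generalized LMMs, no more than a handful of random groupings (the
  Schur path is exact but its cost grows with the non-dominant
  groupings' total columns).
* The noncentral-t CI method for d matches the printed reference
  intervals to two decimals; other CI constructions (e.g. bootstrap)
  are not implemented.
* Hedges' small-sample correction and sphericity corrections are
  deliberately absent (two-level factors satisfy sphericity trivially).
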