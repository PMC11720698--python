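# etawithin

Standardized effect sizes for pairwise experimental designs — from
t-tests and repeated-measures ANOVA up to linear mixed-effects (LME)
models with crossed participant and stimulus random effects.

The package is aimed at experimental psychologists and other
behavioral/life scientists who run 2-condition and 2×2 designs and need
effect sizes that survive the move from ANOVA to mixed models. The
difficulty it addresses: in repeated-measures designs the popular
partial eta squared (η²ₚ) is a transform of the test statistic, not a
share of variance — per-term values routinely sum past 1, and in LME
they additionally depend on the (ill-defined) denominator degrees of
freedom. The package therefore reports, for every fixed effect:

* **η² (eta squared)** — the effect's share of *total* variance. In a
  mixed model this is the per-term semi-partial marginal R², computed
  Nakagawa–Schielzeth style: `Var(X_j β_j) / (Var(Xβ) + Σ random
  variances + σ²)`, with Johnson's extension for random slopes.
* **η²w (eta squared within)** — the effect's share of *within-unit*
  variance. In ANOVA, the effect SS divided by the sum of all
  within-subject strata (effects plus their error terms). In LME, the
  response is centered per unit (participant or stimulus), the identical
  model is refit, and the semi-partial R² of the centered fit is
  reported. This is the repeated-measures analogue of d_z the way η²
  is the analogue of d/d_av, but it remains a true variance share.
* the d family (d, d_z, d_av) with noncentral-t confidence intervals,
  and closed-form conversions d_av ≈ 2·√(η²/(1−η²)),
  d_z ≈ √(η²ₚ/(1−η²ₚ)).

The LME fitter is a self-contained REML engine (profiled restricted
likelihood over relative Cholesky factors, Woodbury/Schur-complement
linear algebra for crossed groupings) with Satterthwaite denominator
degrees of freedom; it reproduces lme4/lmerTest output to the precision
those packages print.

## Worked example

Five small worked datasets are embedded (`etawithin.list_fixtures()`):
`wm_between`, `wm_longitudinal`, `twobytwo`, `faces`, `reading`. The
2×2 fully-within dataset (`twobytwo`: 10 participants × 2 days × 2
stimulus types × 2 measurements, a crossed interaction with no main
effects) analyzed as an LME with deviation (±0.5) coding:

```python
import etawithin as ew

table = ew.load_fixture("twobytwo")
report = ew.effect_report(
    table,
    fixed=["day", "stimulus_type", "day:stimulus_type"],
    random=[ew.RandomSpec("participant",
                          ("1", "day", "stimulus_type", "day:stimulus_type"))],
    center_by="participant",
)
print(report.table.round(4).to_string(index=False))
print("marginal R2:", round(report.r2_marginal, 4))
```

prints

```
             term  estimate     SE       t      df      p   eta2  eta2_w
      (Intercept)     5.275 0.4927 10.7067  9.0010 0.0000    NaN     NaN
              day     0.400 0.3567  1.1212  9.1794 0.2907 0.0098  0.0237
    stimulus_type     0.150 0.2913  0.5149 14.0697 0.6146 0.0014  0.0033
day:stimulus_type    -2.000 0.6874 -2.9095  9.0095 0.0173 0.0613  0.1480
marginal R2: 0.0725
```

Reading: only the Day × StimulusType interaction is reliable
(t(9.0) = −2.91, p = .017); its coefficient −2.0 is the difference of
the two simple effects. The three fixed effects jointly explain 7.3% of
the total variance (marginal R²), and the interaction explains 6.1% of
total variance (η²) but 14.8% of the variance that remains once
between-participant level differences are removed (η²w) — the
quantity a repeated-measures design is built to resolve. Had the model
been fit with default dummy (0/1) coding, both "main effects" would have
looked significant, because with an interaction present they are simple
effects at the other factor's reference level.

The same analysis from the shell:

```bash
etawithin lmm --fixture twobytwo \
  --fixed day --fixed stimulus_type --fixed day:stimulus_type \
  --random "participant: intercept + day + stimulus_type + day:stimulus_type" \
  --center-by participant
```

Subcommands `ttest`, `anova`, `simulate` and `fixtures` cover the
classical tests, the ANOVA path (`--effect-size total,partial,within`),
synthetic crossed-design generation from a JSON spec, and fixture
export. Every report embeds the resolved options, and reports always
include per-cell means and SDs next to the standardized effect sizes.

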