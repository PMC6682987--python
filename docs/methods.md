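# Methods

## Scope and data model

The pipeline scores diet quality and diversity for a two-recall survey
design: each subject contributes two non-consecutive 24-h recalls, each
recall carrying total energy (kcal), amounts of 17 dietary factors (g/d,
mg/d, or % of energy), and grams consumed from nine diversity food groups.
Subjects are stratified into 64 subgroups (8 countries × 2 sexes × 4 age
bands: 15–19, 20–34, 35–49, 50–65, bands closed on both printed endpoints)
plus a socio-economic level (high/middle/low) used for reporting only.

Interchange is CSV (comma, header, "." decimal). Missing values are allowed
only for anthropometry; intake values must be present because the scoring
rules define no missingness behaviour.

## Usual-intake estimator

The published workflow feeds recalls through the Multiple Source Method web
tool. That tool is not scriptable or archivable, so this package implements
the shrinkage core of that class of estimators explicitly:

1. **Energy adjustment first.** Each day's g/d and mg/d amounts are scaled
   by 2000 / (that day's energy). Ordering (adjust-then-estimate vs
   estimate-then-adjust) is not dictated by the index definition; the per-day
   density method was chosen because it removes day-level energy
   misreporting before the variance decomposition sees it. % energy factors
   are already energy-normalized and pass through.
2. **Transform.** Day values x become log(x + c), c = half the smallest
   positive observed value in the (subgroup, factor) cell. The offset keeps
   episodic factors' zero days finite while preserving order. A
   `transform="none"` mode skips this step.
3. **Variance components.** One-way random-effects ANOVA of day values on
   subjects (method of moments, unbalanced-design n₀), within the subgroup:
   σ²_w = MS_within; σ²_b = (MS_between − MS_within)/n₀, truncated at 0.
4. **Shrinkage.** Subject i's day mean x̄ᵢ (nᵢ ∈ {1,2} days) becomes
   μ + λᵢ(x̄ᵢ − μ), λᵢ = σ²_b/(σ²_b + σ²_w/nᵢ), with μ the unweighted mean
   of subject day means.
5. **Back-transform.** exp(·) − c, clipped at 0. A multiplicative lognormal
   bias correction exp(σ²_w(1 − λᵢ)/2) exists behind a flag and is off by
   default (it helps population means slightly but is immaterial for rank-
   based scoring, which is invariant to monotone transforms of a factor).

Degenerate cells behave predictably: if all values are identical everyone
gets that constant; a cell with no 2-day subject cannot separate the
components and falls back to raw day means with a `fallback` flag; a
single-recall subject is retained with nᵢ = 1 (stronger shrinkage).

Two properties are exact **on the estimation scale** (and therefore exact on
the original scale in `transform="none"` mode): the mean of shrunken values
equals the mean of subject day means, and their variance never exceeds it.
After the exponential back-transform these hold only approximately; tests
assert exactness in the raw mode and structure (λ ∈ [0,1], monotonicity,
non-negativity) in the log mode. For the same reason the variance-recovery
test runs in raw mode, where the generator's truth is closed-form
(σ²_b = Var(latent), σ²_w = E[latent²]·CV²); in log mode the +c offset
attenuates both components by roughly (x̄/(x̄+c))², which is checked only
loosely. Because all subjects with two recalls share one λ, shrinkage is
nearly monotone in the day mean; the practical gain shows up as a small but
systematic increase in correlation with the latent truth over raw 2-day
means (asserted as an average over seeds, since the per-dataset gain is of
the same order as its sampling noise).

An optional two-part mode for episodic factors estimates the population
consumption probability p̂ and the usual consumption-day amount separately
(usual = p̂ × amount); subjects never observed consuming receive the pooled
consumption-day amount rather than zero. Default is the simpler offset mode.

## Diet Quality Score

Quintiles are **near-equal-size rank blocks**, not value percentiles: with
heavily tied factors (zero consumers of nuts, fish, whole grains) value
cut-points cannot produce the near-equal pooled quintile sizes the design
requires. Conventions, fixed and config-visible:

- sort ascending by (usual intake, subject_id); the deterministic tie-break
  makes scores invariant to input row order (a seeded random tie-break is
  available);
- n = 5k + r gives the first r (lowest) blocks one extra member, so sizes
  differ by at most one;
- subgroups smaller than 5 (configurable) are an error.

Item score = q (healthy) or 6 − q (unhealthy); raws are integer sums;
standardization is 100·raw/max (max 50/35/85), so the attainable
standardized range is [20, 100]. In any subgroup whose size is divisible by
5 the mean item score is exactly 3 and the mean standardized score exactly
60 — a useful invariant that the test suite asserts to 1e-9. Min–max
standardization was rejected because it recenters the tie-free expectation
to 50%, inconsistent with the scale on which the survey's score means
(~60–65%) are reported.

## Diet Diversity Score

One point per food group with ≥ 15 g consumed (threshold inclusive) on the
first recall day; 9 points maximum. Two 9-group schemes are implemented and
selectable — household-style (`hdds9`: cereals; white roots and tubers;
vegetables; fruits; meat, poultry, offal; fish and seafood; eggs; pulses,
legumes and nuts; milk products) and women's-diversity (`wdds9`: starchy
staples; dark green leafy vegetables; vitamin-A-rich fruits/vegetables;
other fruits/vegetables; organ meat; meat and fish; eggs; legumes, nuts and
seeds; milk products) — because the survey's protocol names the former while
its frequency reporting uses the latter; neither is asserted as canonical.
Input files must carry the active scheme's nine `grp_*` columns.

Tertile bands: 1 = 0–4, 2 = 5, 3 = ≥ 6. The published band labels skip the
value 6 ("higher than 6"); band 3 is defined as ≥ 6 here so the bands
partition {0..9}, and that deviation is noted in the band definition itself.

## Anthropometry

Adult BMI bands are taken literally from the survey protocol even where
asymmetric: underweight BMI ≤ 18.5 (boundary inclusive), normal (18.5, 25),
overweight [25, 30), obese ≥ 30. Under-18 subjects use a precomputed
BMI-for-age category carried in the input (WHO 2007 reference tables are out
of scope); without one they are "unclassifiable", never guessed. Waist
cut-offs are inclusive (≥ 102 cm men / ≥ 88 cm women); neck cut-offs strict
(> 39 / > 35 cm adults, > 34.25 / > 31.5 cm adolescents).

## Synthetic populations

The generator emulates the survey's structure so every stage is testable at
scale: per-cell subject counts (equal cells, or published per-country totals
spread as evenly as possible over each country's 24 cells), two recall days
per subject with weekday probability 5/7 per day, and per-day energy from a
normal(2000, 400) truncated at 800 kcal.

Per subject and factor, latent usual intake (on the 2000-kcal-adjusted
scale) is lognormal, moment-matched to the published per-country mean/SD;
intakes are positive and right-skewed, and only means/SDs are published, so
the lognormal is the natural minimal choice. Socio-economic level multiplies
healthy-factor means by 1.10/1.00/0.90 (high/middle/low) at constant CV —
the simplest mechanism that reproduces the reported direction of the SEL
gradient. Day values are latent × lognormal noise with mean 1 and
within-person CV 0.3 (a generator knob: the survey publishes no
within-person variance). Episodic factors (fish, nuts and seeds, whole
grains) are zeroed on a day with probability 0.4 and consumption-day values
divided by 0.6, preserving the latent mean. Raw recall amounts are the
adjusted values scaled by day energy/2000, so the pipeline's energy
adjustment recovers the generating scale exactly; % energy factors have no
energy coupling. Diversity-group grams cross the 15-g threshold
independently with the published frequencies (starchy staples 0.995,
meat/fish 0.854, other fruits/vegetables 0.822, dark green leafy vegetables
0.069, organ meat 0.029) and probability 0.5 for groups without a published
figure.

What the generator deliberately does **not** model: correlations between
factors, correlation of diet with anthropometry or DDS, household
clustering, seasonality, survey weights. Consequences: passing tests show
the pipeline's algebra and bookkeeping are right at survey scale, not that
the synthetic population reproduces the survey's between-variable findings;
synthetic DQS–DDS regressions are null by construction, and the DDS mean
equals the sum of the group probabilities (≈ 4.77 with the wdds9 defaults,
below the survey's 5.6 because four groups default to 0.5). Anthropometry is
generated with plausible sex-specific means purely to exercise the
classification and stratification code; the adolescent BMI-for-age flag is a
synthetic stand-in computed from adult bands.

## Statistics

The reporting layer computes univariate one-way ANOVAs per outcome and
stratifier (the survey names MANOVA but reports univariate means, pairwise
Bonferroni comparisons and partial eta-squared, which is what is implemented;
an omnibus multivariate trace is out of scope). Effect size is partial
eta-squared = SS_between/(SS_between + SS_within); pairwise comparisons are
Welch t tests with Bonferroni adjustment min(1, m·p) over all m pairs.
Quintile summaries pool the subgroup-assigned quintiles across subgroups;
the Q5/Q1 ratio is computed from the quintile means and rounded half-up to
2 decimals, with a zero first-quintile mean reported as undefined rather
than infinite. (The survey's printed ratio column is internally shifted for
several rows; ratios here are always the quotient of the means, which
matches the survey's prose figures, e.g. 197.20 for nuts and seeds, 7.24 for
processed meats, 1.92 for polyunsaturated fat.) Regressions are OLS;
multiple R is reported as √R²; exactly collinear predictor sets are flagged
and their coefficients suppressed. p-values print at 4 decimals with
"<0.0001" below 10⁻⁴. All statistics are unweighted: the survey applied
country-level sample weighting at the design stage, but whether its score
tables are weighted is unstated, and no weights are available for synthetic
data.

## Numerical conventions

- Report tables render floats with round-half-up at 2 decimals (4 for
  p-value tables); data tables are written at full precision and round-trip
  exactly.
- Determinism: one master seed drives per-stage substreams (SHA-256 derived,
  < 2³¹); identical config + seed reproduces byte-identical outputs.
- Problem sizes used by the test and acceptance runs — 1920-subject shared
  fixture, 9218-subject (published country totals) and 10,000-subject full
  pipeline runs, n = 2000 variance-recovery simulations, 1000-trial quintile
  oracle — were chosen to keep binomial/simulation error well inside the
  asserted tolerances while remaining desk-scale (the full pipeline runs in
  seconds).

## Known limitations

- The shrinkage estimator is a deliberately simplified stand-in for
  covariate-adjusted two-part usual-intake models; it captures shrinkage of
  day-to-day noise but not covariate effects or residual pooling across
  subgroups.
- Quintile tie and remainder rules are conventions; any fixed rule yields
  near-equal blocks, but scores for tied subjects depend on the chosen rule.
- DDS uses a single recall day by design, so it inherits that day's
  sampling noise; day-2 and both-day variants exist for sensitivity checks.
- Population-level score means from synthetic data are pinned near 60% by
  the rank construction and cannot be compared to the survey's published
  means, which reflect its real (non-exchangeable) intake distributions.
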