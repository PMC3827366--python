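# Methods

This note documents the models, procedures and design choices behind
`windgain`, in the spirit of a statistical package's methods documentation.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The daily mass-gain statistic

Individual-level daily gain is deliberately out of scope: accurate
weighbridge masses for the same bird in both the morning and the evening of
one day are rare, so gain is a population-scale statistic — the difference
between the mean mass of birds returning in the evening window
(10:00–23:40, inclusive) and the mean mass of birds leaving in the morning
window (01:20–09:59, inclusive). Times in (23:40, 01:20) belong to neither
window and are rejected; because the evening window closes before midnight,
no crossing ever contributes to the next calendar day.

The pooled (both-sex) gain pools **individuals** before averaging. It is not
the average of the per-sex gains: the sexes contribute different numbers of
birds to each window, and the model consumes one pooled value per day.

### QC cascade

Rules are applied in a fixed order and a rejected crossing is tallied under
the first failing rule only, so report categories are disjoint and
`read = accepted + Σ rejected + dedup-removed` holds exactly on every input:

1. PIT not in the registry → `unknown-pit`;
2. date not in the season calendar → `unknown-date`;
3. clock time outside both windows → `outside-window`;
4. male during guard → `male-during-guard` (males do not forage while
   guarding; no plausibility band exists for them);
5. fewer than 2 recordings → `too-few-recordings`;
6. within-crossing spread ≥ 200 g → `spread` (the bound is *strict*:
   exactly 200 g is rejected);
7. mean mass outside the inclusive band (females 1700–3500 g in either
   stage; males 2000–3900 g in crèche) → `out-of-bounds`.

Steps 1–3 precede the mass rules so that implausible masses on
unattributable records never contaminate bounds diagnostics. When a bird
retains more than one accepted crossing on a day, exactly one is kept,
chosen uniformly at random under an explicit seed — there is no
deterministic preference for either window. Days on which either window has
fewer than `min_n = 15` accepted birds (the lower end of the per-window
sample sizes such studies report) are flagged `low_n` but retained;
dropping them is a caller decision, not a rule.

No outlier handling exists beyond these rules: "remaining outliers" are
whatever the three mass rules catch.

### Tests on gains

The paired test compares mean evening vs mean morning mass with one pair
per day × group (per-sex rows by default; the pooled rows via an argument —
the exact pairing is an explicit parameter because several poolings are
defensible). The between-sex comparison is a Student equal-variance t by
default (a Welch flag exists), and sex concordance is a Pearson r on
day-matched (male, female) gains, undefined below 3 matched days. All
p-values are two-sided. Zero-variance inputs are flagged `degenerate`
rather than silently producing NaNs.

## Wind and SSTA

Daily wind arrives as U/V components under the satellite-product sign
convention (negative U: wind from the East; negative V: wind from the
North). Speed is the vector magnitude `√(u²+v²)` — the only self-consistent
reading of a "speed along the direction" — and direction is the bearing of
(−u, −v) clockwise from North, i.e. the direction the wind comes *from*,
undefined (and flagged) at exactly zero speed. When sub-daily records need
aggregating, components are averaged first and then converted (vector
mean). Sector classification puts the 180° boundary in the westerly sector
by default (the tie is configurable; both half-open conventions appear in
the literature). Speed classes: calm ≤ 5 m/s (≈ Beaufort 3, no wave
formation), storm ≥ 13 m/s (inclusive), moderate in between.

Between-season wind comparisons are run component-wise (t-tests on U and on
V), never on direction itself, because direction is circular; the rationale
travels with the result object. SSTA is consumed precomputed (actual SST
minus a long-term climatology); no satellite retrieval, gridding or
climatology computation is in scope, and the speed–SSTA link in the
generator is phenomenological, not ocean physics.

## The circular GAM

The model for pooled daily gain is Gaussian additive:

    gain_d = β0 + β_season + β_stage + β_s · speed_d
             + f1(dir_d) + f2(dir_d) · speed_d + ε_d

**Basis.** Both smooths are cyclic cubic regression splines on k = 8 evenly
spaced knots over [0, 360) (k is a user parameter; it must not exceed the
number of distinct observed directions). Coefficients are the function
values at the knots; the interpolant is the periodic natural cubic spline,
so the function and its first two derivatives match at the 0/360 seam by
construction, and the penalty ∫ f″(x)² dx over the circle is available in
closed form as a quadratic form whose null space is exactly the constant
function. Directions are reduced mod 360 before evaluation, so basis rows
at 0° and 360° are bit-identical.

**Identifiability.** Each smooth is constrained to sum to zero over the
observed directions: the intercept absorbs f1's mean, and the linear speed
term absorbs the constant part of f2. The interaction is represented as a
varying-coefficient term (the slope on speed varies cyclically with
direction) rather than a full tensor product: this reproduces the
structure such analyses report — a 1-df linear speed row plus a low-EDF
interaction — and keeps the design small; a tensor-product smooth would be
the natural extension.

**Fitting.** Penalized least squares. λ = ∞ is implemented as the exact
limit (the smooth's columns are dropped), so infinite smoothing reproduces
the parametric-only OLS fit exactly rather than approximately; λ = 0 gives
the unpenalized full-basis fit. Smoothing parameters are selected by GCV,
`n·RSS/(n − edf)²`, minimised coordinate-wise on log10 λ per smooth: a
coarse unit-spaced grid over [−5, 12] followed by golden-section refinement
(tolerance 1e−4 on log λ), iterated until the score changes by less than
1e−6 relative; the reported optimum is the best point actually evaluated,
so it is ≤ every grid candidate by construction. A selection ending on the
search boundary sets a warning flag (on null-signal data the optimum is
genuinely at the upper bound — the term is smoothed away — so the flag is
informative, not an error).

**Inference.** EDF per term is the trace of the term's block of
(X'X + S_λ)⁻¹X'X; deviance explained is the Gaussian 100·(1 − RSS/TSS).
Parametric terms are tested with Wald F from the frequentist
(sandwich-form) covariance of the penalized estimator; smooths use an
EDF-rank eigen-truncated Wald statistic against an F(edf, n − edf_total)
reference with fractional degrees of freedom. These are approximations —
once λ is data-selected no exact reference distribution exists — and are
labelled as such; the test suite calibrates the interaction test's type-I
error by Monte Carlo (pure-noise rejection rate ≈ the nominal 5%) rather
than assuming it.

**Rank handling.** Structural collinearity among the parametric terms
(e.g. a factor duplicating another) is an error naming the terms.
Near-singularity that involves the smooth blocks — an arc of directions
with no observations — is not an error: the penalty regularises it, a GCV
fit is well-defined, and the condition is recorded on the model
(`design_deficient`). Only an explicitly requested λ = 0 fit then falls
back to a pseudoinverse (minimum-norm) solution.

**Prediction surface.** The surface is evaluated on a (direction × speed)
grid with factors held at their reference (first) levels, recorded in the
output's metadata. Cells are flagged extrapolated when the speed lies
outside the observed range or no observed direction lies within 15° of the
cell (circular distance) — a pragmatic hull proxy for one linear and one
circular covariate.

## The synthetic generator

The generator emulates the study design: a colony of PIT-tagged birds (the
scaled-down default: 40 birds over two 30-day seasons; the "paper-like"
scenario: 100 birds over two 62-day seasons with 13 days knocked out,
leaving 111 usable days), per-sex Gaussian baseline masses truncated
inside the QC bands, one morning and one evening crossing per foraging
bird per day, clock times from truncated normals peaking 05:00 and 18:00,
and 2–6 recordings per crossing with 1-g scale resolution. During guard
only females forage; guard-stage males appear only as occasional
non-foraging wanderers. Wind is von Mises in direction (mode 270°,
concentration 1 → ≈80% westerly-sector days), Weibull(2, 8 m/s) in speed,
and SSTA = −0.08·speed + N(0, 0.85²) °C, which implies a population
speed–SSTA correlation of −0.33, matching the study system's reported
coupling.

The planted response surface is

    g(s, d) = 250 − s + 10·s·cos(d − 270°) − 2·max(s − 13, 0)²  [g]

— gain rising with speed for westerlies, highest at low speed for
easterlies, and storm-depressed in every direction — plus shared day-level
noise (SD 80 g, the common driver that correlates male and female daily
gains) and per-bird trip noise (SD 80 g). These values reproduce the
descriptive statistics of daily gain such a study reports (mean ≈ 250–290 g,
SD ≈ 70–110 g, range ≈ 20–500 g) while keeping the planted interaction
recoverable at n = 111 days; the implied share of day-to-day variance
carried by wind (~25–35% deviance explained) is consequently higher than
the ~16% the field study itself reported — a deliberate trade-off, since at
the field effect size the interaction would be detected in only a minority
of 111-day realisations and parameter-recovery tests would be
uninformative about correctness.

Artifacts are planted per crossing with configurable probabilities:
partial crossings (a single recording), group artifacts (a second bird's
mass added to a random subset of recordings — producing either a large
spread or an out-of-bounds mean, exactly the two signatures the QC bands
were designed to catch), and outright out-of-bounds masses. A *truth
record* sidecar lists, for every crossing, the artifact planted and the
first QC rule expected to fire, computed from the same published
thresholds; the QC module is tested blind against it, and separately
against a vectorised brute-force re-implementation of the rules written
only in the test suite.

What the generator does **not** emulate — so what passing tests do not
show about real data: scale drift and recalibration, multi-transit birds
beyond the group-artifact channel, temporal autocorrelation in wind or in
foraging success (days are exchangeable given wind), individual foraging
quality, tide or daylight effects on crossing times, and any real ocean
physics behind the SSTA coupling. Within-crossing recording noise for
clean transits (SD 15 g) is a free parameter, not calibrated to any
published value.

### Exactness caveats

Two contracts hold only in degenerate settings, by design:

- "noise-free constant surface ⇒ every pooled daily gain exact": requires
  per-sex baseline distributions that are degenerate **and equal across
  sexes**. Deduplication assigns each bird to only one window, so morning
  and evening means average different birds; with any baseline spread (or a
  between-sex mass difference and random sex composition) the two window
  means differ by sampling noise even without measurement error.
- A clean crossing can in principle still be rejected (e.g. trip noise
  pushing a return mass past a band edge); the generator prevents this by
  rejection-resampling the bird-level trip noise against the band, and the
  truth record is computed from the *realised* recordings, so truth-record
  completeness holds unconditionally.

## Determinism and sizes

Every stochastic stage takes an explicit integer seed and refuses to run
without one; identical scenarios and seeds reproduce byte-identical CSV
outputs and manifests. Monte-Carlo test sizes (100 QC logs, 50 recovery
fits at n = 500, 200 null + 100 power fits at n = 111, 50 end-to-end runs)
were chosen so each check is a stable estimate of the rate it asserts while
the whole suite stays fast; all are fixed-seed and therefore reproducible
runs, not flaky samples.

## Known limitations

- Gaussian response only; no autocorrelated-residual or non-Gaussian
  extensions.
- Smooth-term p-values are EDF-based approximations; they are Monte-Carlo
  calibrated here but no claim is made that they match any particular
  software's p-value machinery.
- The varying-coefficient interaction cannot represent gain structures
  that are non-linear in speed at fixed direction (the storm term in the
  default surface is such a structure); recovery tests therefore measure
  correlation with truth, not equality.
- The spatial aggregation of gridded winds to one daily value is assumed
  done upstream; only an aggregated per-day table is consumed.
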