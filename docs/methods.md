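# Methods

This note documents the models behind each generative engine, the
parameter choices that matter, what the defaults do and do not emulate,
and the numerical conventions shared across the suite.

## Shared data model and conventions

All engines emit one row per subject-wave with 19 columns: identifiers,
dates, wave number (1–7), age in months, sex (0 male / 1 female),
parental education (0–3, 777 = refused), autism diagnosis, IQ, three
CBCL raw subscale scores (externalizing 0–70, internalizing 0–64,
attention problems 0–20), and six anatomical measures (white-matter,
gray-matter, hippocampal, amygdala and intracranial volume in mm³;
frontal-lobe cortical thickness in mm).

**Waves and ages.** Wave *w* covers ages `[84+24(w−1), 107+24(w−1)]`
months — 7–8 years at wave 1 through 19–20 years at wave 7, inclusive of
the final chronological month of the upper year. Age is recorded in
completed chronological months with a 15/16-day rounding convention: a
day residual of ≤15 days does not advance the month, ≥16 days does.
Timelines are constructed so recorded ages satisfy this convention
exactly: the wave-1 age is uniform over its window, later waves are
spaced ~24 months with integer-rounded Gaussian jitter (default sd
2 months) clipped into each window, and measurement dates place the
residual in 0–15 days. Dates of birth land so wave-1 visits fall in a
configurable study window (default 2008–2012); calendar placement is
cosmetic.

**Missing data representation.** A missed timepoint is a row whose
measure columns are blank, never a deleted row, so every default-size
table has exactly 70,000 rows regardless of attrition and the row-count
check stays meaningful. On write, missing cells serialize as empty
fields; the reader additionally accepts `NA`. Missingness fractions are
always computed over the ten nullable measure columns (IQ, three CBCL,
six brain measures) — identifiers, dates and demographics are never
missing.

**Precision.** CSV serialization applies a declared precision (volumes
and IQ to 0.1, thickness to 0.001 mm, CBCL as integers); a
write–read–write cycle is byte-stable.

## Validator

Four checks mirror a submission quality gate: (1) every required column
present and parseable as its declared type; (2) row count equals
subjects × waves; (3) every non-missing value within its allowed range
or code set; (4) missing fraction ≤ 20%. Table-derived ranges exist for
the scored columns; the anatomical bounds (ICV 1.0–2.0×10⁶ mm³, GM
4.0–9.0×10⁵, WM 3.0–6.5×10⁵, hippocampus 2,500–5,500, amygdala
1,800–4,500 mm³, thickness 1.5–4.5 mm) are configurable literature-style
plausibility bounds. Engines clip generated values into these ranges as
a final step, mirroring the practice of keeping all variables "within a
reasonable range"; at default noise levels clipping is rare. Failures
are reported, not raised, so one run lists every problem.

## Curve primitives and the normative catalog

Polynomials (degree ≤ 4, in age-months or log of age in years) and
clamped cubic B-splines cover all trajectory needs; both refuse to
extrapolate outside 84–251 months. The bundled normative catalog is a
**stylized fixture**: quartic interpolants through five anchor points
per phenotype with plausible magnitudes (ICV plateauing near
1.5×10⁶ mm³, slow hippocampal/amygdala growth, monotone frontal
thinning from ~3.2 mm), a spread curve fixed at 6% of the mean, and
female/male volume ratios of 0.91–0.94 (1.0 for thickness). These are
deliberate stand-ins for population reference charts whose coefficients
are not published; they make no claim about any external dataset.
Subcortical curves in particular are explicit fixtures. The z↔raw
transforms are exact algebraic inverses:
`raw = (mean(age) + z·sd(age)) · ratio(sex)`.

## Engine: dpn (normative z-score process)

Ten latent channels (six brain phenotypes, IQ, three CBCL subscales)
share a documented correlation matrix (gm–icv 0.75, gm–wm 0.45,
hippocampus–amygdala 0.55, brain–IQ 0.10–0.22, brain–CBCL −0.06 to
−0.10, CBCL inter-correlations 0.45–0.60; PSD-verified at load). True
baseline z-scores are `z = ε Lᵀ` with `L` the Cholesky factor, clipped
to ±4 (truncation, not rejection, for determinism). Individual
trajectories are quadratic in centered age (decades from 14 years):
`z(t) = z₀ + αu + βu²` with α ~ U(−0.35, 0.35), β ~ U(−0.15, 0.15) per
subject and channel. Per-wave measurement noise (sd 0.15 z-units,
redrawn each wave) is added before the normative transform. Observed IQ
is the constant true IQ plus per-wave noise (sd 3), then analytically
rescaled so the population stays at mean 100 / sd 15. CBCL scores map
the latent channel through a right-skewed scaled-logistic bounded map
(half-up rounding), an invented but monotone and auditable link. Autism
is thresholded from a weighted sum of brain z-scores (negative weights
on subcortical/gm volumes), standardized IQ (−0.3) and unit noise, with
per-sex analytic thresholds targeting 3.0% (male) and 0.75% (female)
prevalence. The engine applies no missingness.

## Engine: leer (latent growth curves)

The six measures form one joint LGC: per-measure intercept (wave-1
level) and slope (total wave-1→7 change) with loadings identified
λ₁ = 0, λ₇ = 1. Shapes are either quadratic with a dominant linear
component (|quadratic| < |linear| enforced) or basis-style with freely
specified loadings (gray matter and ICV by default). The 12×12
growth-factor covariance combines per-measure sds, an intercept–slope
correlation of −0.3, and cross-measure correlations (0.4 between
intercepts, 0.2 between slopes); occasion residual variance is constant
over waves and sex. Sex enters only through the factor means — setting
them equal erases all downstream covariate sex gaps, which is itself a
tested property.

Covariates are weighted sums of the standardized brain intercepts,
previously built covariate channels, and Gaussian noise, in topological
order: parental education (small positive brain weights, quantile-cut at
5.3/35.4/25.3/34%), autism (negative brain weights, thresholded at 2%),
IQ (weak positive brain correlation, kept below r = 0.3; negative weight
on the education channel, following the stated design; affine-calibrated
to 100/15), then CBCL externalizing (negative on brain, education and
autism), with internalizing and attention problems riding on their high
positive correlation with externalizing. Wave drift uses signed
half-normal steps so direction statements hold pathwise in expectation:
externalizing declines, internalizing and attention rise, IQ wobbles
symmetrically (sd 1.2).

A pool of 30,000 subjects is simulated once per seed; the three variants
are disjoint blocks of a seeded shuffle. Missingness stacks wave-level
dropout (logistic; intercepts rising from −3.2 to −2.0 across waves,
male +0.3, education −0.2, concurrent symptom load +0.03 per point), MRI
scan dropout decaying as `0.10·e^(−0.5(w−1))` (concentrated at young
ages), and MNAR psychopathology dropout in which each CBCL measure's
own true score raises its deletion log-odds (slope 0.08) — severe
non-ignorability by construction, with the concurrent (not baseline)
score as the predictor. Defaults land total missingness near 12–15%;
the 20% cap is enforced afterwards.

## Engine: osa (cross-section + splines)

The baseline cross-section draws sex (50/50), education (criteria
shares), autism as sex-specific Bernoulli (2.5% male, 0.8% female —
overall ≤ 2% with male > female), IQ from a truncated normal
(100, 15, bounds 55–145, inverse-CDF sampling), and CBCL scores through
a Gaussian copula against a predefined 3×3 correlation structure
(ext–int 0.60, ext–att 0.55, int–att 0.45) with right-skewed scaled-beta
marginals, additive male and autism shifts, and clipping applied last.
Copula Pearson correlations attenuate slightly under the skewed
marginals; targets are met within ±0.05. Cross-sectional values (IQ,
CBCL) are carried over waves unchanged; ages increment with jitter.

Brain measures follow sex-specific clamped cubic splines (five basis
coefficients over knots at 84/167.5/251 months) plus subject random
intercepts and occasion residuals. The stated four-way coupling among
ICV, hippocampal volume, parental education and IQ is realized as one
joint latent Gaussian block feeding the education quantile cut, the IQ
quantile, and the ICV/hippocampus intercepts — symmetric and auditable
rather than a chain of regressions. Diagnosed subjects receive an
age-dependent hippocampal offset, defaulting to a deficit widening
linearly to −300 mm³ by age 20 (sign and size are configurable; no
canonical value exists).

## Engine: paint (growth-chart mixed models + embedded signals)

The base process fits second-order polynomials in log(age) with a sex
covariate to the same reference anchor curves, adds a correlated
per-subject z-score (the random effect, scaled by a 6%-of-mean spread)
and per-datapoint noise (0.10 z-units). Autism is a plain binomial at
3%. The three variants embed:

1. **Lagged coupling** — for each consecutive wave pair, the attention
   score change is rewritten as `0.3 · Δwm/10⁴ mm³ + N(0, 1)`,
   preserving the wave-1 level; pooled change-on-change OLS recovers β.
   Brain phenotypes then receive 10% MCAR deletion.
2. **ASD signature** — each subject gets a direction `h = ±1` from the
   median split of a combined white-matter/ICV index over waves 1–3; the
   amygdala wave-1→3 change is rewritten as `h·s·(20 + |N(0, 25)|)` (s =
   +1 diagnosed, −1 not; noise clipped at 3 sd), wave 2 interpolated.
   The score `h·Δamygdala` is ≥ +20 for every diagnosed and ≤ −20 for
   every undiagnosed subject, so a zero threshold attains exactly 100%
   accuracy — yet because the *direction* of change is balanced within
   each group, group means never move: per-variable effect sizes stay
   |d| < 0.2 and the best single-variable threshold stays below 0.75
   balanced accuracy. (Balanced accuracy is the meaningful scale here:
   at 3% prevalence raw accuracy rewards majority voting.)
3. **Sensitive period** — thickness changes are rewritten as
   `0.05 mm/point · Δattention + N(0, 0.02)` for wave pairs 4→5 and
   5→6 only; outside the window cells are bit-identical to the
   pre-embedding table. MAR study dropout (male +0.5, education −0.35
   on the log-odds; absorbing from a uniformly drawn wave) follows,
   with cap enforcement.

## Engine: site4802 (conditional Gaussian)

Statics are drawn by simple random generation: sex and autism uniform,
education at (0.05, 0.35, 0.25, 0.35), IQ ~ N(100, 15). Taking "uniform
probability" at face value makes the default autism prevalence 0.5 —
far above any population rate; it is a prominent, documented override
(`StaticSamplingSpec.autism_probability`) rather than a silent
correction. Ages are uniform within each wave's two-year window.

Eight dynamic variables (six brain measures, CBCL internalizing and
externalizing) are jointly Gaussian around a mixed-effects polynomial
mean in centered age (years from 14) with main effects for sex, autism,
education and centered IQ, age interactions, and a subject random
intercept; the 8×8 covariance is a documented fixture. Coefficients are
fixtures standing in for values one would estimate from real cohort
data. The attention-problems score is not in the printed dynamic list
but is required by the dictionary; it is completed from its own
polynomial mean with independent noise, outside the Gaussian block.

Variant 2 adds cell-level MCAR attrition at 8% (within the stated ≤10%)
over the dynamic columns and perturbs the covariance: every off-diagonal
entry with |r| ≤ 0.8 receives symmetric N(0, 0.2²) noise *on the
correlation scale* (the threshold statement is about correlations, so
the perturbation lives there too), followed by eigenvalue-clipping PSD
repair on the correlation matrix and rescaling; a zero threshold
disables perturbation entirely. Variant 3 uses the same perturbed
covariance plus diagnosis multipliers on curve level and age-steepness:
×1.2 for behavioral measures, ×0.97/×0.90 (level/steepness) for brain
measures, making the polynomial trend more pronounced under diagnosis.

## Seeding and determinism

One master seed expands into labeled sub-streams via SHA-256 of the
component label mixed into a `SeedSequence`, so derivation is
order-independent and adding a mechanism never perturbs unrelated
draws. Multivariate normals always go through the explicit Cholesky
path (fixed column-order consumption of the standard-normal matrix),
keeping output identical across BLAS implementations. Exactly singular
PSD matrices receive a 10⁻¹² relative ridge; indefinite matrices are
rejected with the offending eigenvalue named. Same seed + same
configuration reproduces every CSV byte-for-byte, and each written file
carries a manifest sufficient to regenerate it.

## What the defaults do and do not emulate

The defaults encode the study conditions: cohort size 10,000, seven
biennial waves, ~50/50 sex, IQ at 100/15, the published education
shares, autism prevalence bounds by engine, the ≤20% missingness cap,
and the embedded-signal magnitudes above. Correlation matrices, growth
curves, covariance fixtures and noise levels are plausible documented
fixtures, not estimates from restricted data — so passing tests
demonstrate that the *mechanisms* behave as specified (correlations
recovered, biases in the stated directions, signals recoverable), not
that any marginal distribution matches a particular real cohort.
Simulated data here also omit site effects, scanner changes, practice
effects on IQ, and heavy-tailed measurement error; CBCL integer scores
come from monotone latent maps rather than item-level simulation.

## Problem sizes used in the checks

The test suite regenerates all 15 engine-variant files at the full
n = 10,000 (seconds per file) and verifies structure, validation and
the embedded signals at that scale; sampler-level distributional checks
use 100,000 draws; the LGC mixed-model recovery uses n = 2,000 with
random intercept+slope fits per measure. The acceptance script uses
n = 10,000 cohorts and 100,000-draw samplers throughout.
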