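# devcohort

Simulated longitudinal brain–behavior–cognition cohorts with known ground
truth, for benchmarking developmental analysis methods.

A recurring problem in developmental neuroimaging is that the underlying
truth is unknown: when a longitudinal model reports a brain–behavior
coupling, there is no way to know whether the method found a real effect
or an artifact of its assumptions. One answer is to analyze *simulated*
cohorts in which the generative process — and therefore every effect —
is known exactly. `devcohort` is a suite of five independent generative
engines that each encode a different school of thought about how brain,
cognition and behavior co-develop in children, all emitting the same
19-column long-format table: 10,000 subjects followed over 7 biennial
waves from 7 to 20 years of age, with demographics, IQ, three CBCL
symptom scores, and six anatomical MRI-derived measures.

## The five engines

| engine | generative idea |
|---|---|
| `dpn` | correlated true z-scores via Cholesky factorization of a phenotype correlation matrix; individual quadratic z trajectories; measurement noise; normative mean/spread curves with sex ratios map z to raw units; autism thresholded from brain z, IQ and noise |
| `leer` | joint latent growth curve model (intercept+slope per measure, 12-dim factor covariance, sex-specific means); covariates built as weighted sums of brain factors; signed half-normal wave drift; layered MAR/MNAR missingness |
| `osa` | cross-sectional sampling (truncated-normal IQ, Gaussian-copula CBCL with a predefined correlation structure), longitudinal expansion, sex-specific B-spline brain trajectories, age-dependent hippocampal offset in autism |
| `paint` | second-order log-age growth curves with correlated subject random effects, plus one embedded ground-truth signal per variant (see below) |
| `site4802` | static variables by simple random generation; dynamic variables from a conditional Gaussian with a mixed-effects polynomial mean in age and an 8×8 covariance; perturbed-covariance and autism-effect variants |

Every engine produces three variants (three seeds, splits, or embedded
patterns), so a full release is 15 files × 70,000 rows totalling 150,000
distinct subjects. Structured missingness (MCAR cells, rising wave
dropout, exponentially decaying MRI dropout, symptom-driven MNAR
deletion, absorbing MAR study dropout) never exceeds a global 20% cap,
enforced by seeded restoration. A validator reimplements the submission
quality gate: column presence and types, row counts, value ranges, and
the missingness cap.

The `paint` variants carry recoverable ground truth: (1) wave-to-wave
white-matter volume changes drive CBCL attention-score changes with a
configurable β; (2) a multivariate amygdala/white-matter/ICV signature
classifies the autism label with exactly 100% accuracy via a fixed
analytic rule while every single variable stays uninformative at the
group level; (3) behavior changes drive frontal-lobe thickness changes
only between waves 4 and 6 (a sensitive period).

## Worked example

```bash
python examples/embedded_signals.py
```

prints

```
variant 1: coupling beta 0.3 -> recovered 0.300
variant 2: signature rule accuracy 1.000 (margin 20.0)
variant 3: window slope 0.050 (target 0.05), outside 0.0059
```

Line 1: regressing attention-score changes on white-matter volume changes
(per 10 cm³) across consecutive wave pairs recovers the planted coupling
of 0.3 points. Line 2: the analytic signature rule labels every subject's
diagnosis correctly. Line 3: inside waves 4–6 the thickness-on-behavior
change slope equals the configured 0.05 mm/point; outside the window it
is indistinguishable from zero.

Generating and checking a dataset from Python:

```python
from devcohort.engines.osa import generate_osa_dataset
from devcohort import validate_dataset, write_csv

table = generate_osa_dataset(seed=7, n_subjects=1000)
print(validate_dataset(table, expected_rows=7000).to_text())
# [PASS] columns / [PASS] row_count / [PASS] ranges
# [PASS] missingness: missing fraction 0.0000
# overall: PASS
write_csv(table, "osa_demo.csv")
```

Or from the shell:

```bash
devcohort generate --engine paint --variant 2 --n 10000 --seed 1 --out paint_data2.csv
devcohort validate paint_data2.csv --expected-rows 70000
devcohort report paint_data2.csv --out qc/
```

`generate` writes a manifest next to the CSV that reproduces the file
byte-for-byte. See `examples/` for more narrative scripts (missingness
mechanisms, the full 15-file suite).

## Layout

- `src/devcohort/schema.py` — data dictionary, wave/age conventions, CSV I/O
- `src/devcohort/validation.py` — the quality checks
- `src/devcohort/trajectories.py` — polynomial/spline curves, normative z transforms
- `src/devcohort/stats.py` — Cholesky/MVN sampling, PSD repair, bounded-score maps
- `src/devcohort/engines/` — the five generative engines
- `src/devcohort/missingness.py` — attrition mechanisms and the 20% cap
- `src/devcohort/signals.py` — ground-truth embeddings and recovery rules
- `src/devcohort/config.py`, `cli.py` — run configuration, catalogs, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
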