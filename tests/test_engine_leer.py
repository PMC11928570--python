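"""LGC engine: factor moments, closed-form variances, covariate structure,
drift directions and mixed-model parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from devcohort.engines.leer import (
    CovariateWeights,
    DriftSpec,
    LGCSpec,
    LeerParams,
    MeasureGrowthSpec,
    build_covariate,
    drift_covariate,
    generate_leer_dataset,
    realize_trajectories,
    sample_growth_factors,
)
from devcohort.validation import validate_dataset

_LINEAR = tuple(w / 6.0 for w in range(7))


def _toy_spec(**overrides):
    base = dict(
        name="gm_volume",
        shape="quadratic",
        loadings=_LINEAR,
        intercept_mean=(100.0, 100.0),
        slope_mean=(12.0, 12.0),
        intercept_sd=5.0,
        slope_sd=2.0,
        is_corr=-0.3,
        quad_mean=0.0,
        residual_sd=1.5,
    )
    base.update(overrides)
    return MeasureGrowthSpec(**base)


class TestGrowthFactors:
    def test_zero_variance_puts_everyone_at_group_means(self, rng):
        spec = LGCSpec(
            measures=(_toy_spec(intercept_sd=0.0, slope_sd=0.0),),
            cross_intercept_corr=0.0,
            cross_slope_corr=0.0,
        )
        sex = np.zeros(50, dtype=int)
        f = sample_growth_factors(spec, 50, sex, rng)
        assert np.allclose(f, [100.0, 12.0])

    def test_factor_covariance_recovery(self, rng):
        spec = LGCSpec(measures=(_toy_spec(), _toy_spec(name="icv")))
        sex = np.zeros(100_000, dtype=int)
        f = sample_growth_factors(spec, 100_000, sex, rng)
        emp = np.cov(f.T)
        target = spec.factor_covariance()
        scale = np.sqrt(np.outer(np.diag(target), np.diag(target)))
        assert np.abs((emp - target) / scale).max() < 0.03

    def test_sex_specific_means(self, rng):
        spec = LGCSpec(
            measures=(_toy_spec(intercept_mean=(100.0, 90.0)),),
        )
        sex = np.array([0] * 5000 + [1] * 5000)
        f = sample_growth_factors(spec, 10_000, sex, rng)
        assert f[:5000, 0].mean() == pytest.approx(100.0, abs=0.5)
        assert f[5000:, 0].mean() == pytest.approx(90.0, abs=0.5)


class TestTrajectories:
    def test_zero_residual_basis_total_change_is_slope(self, rng):
        spec = LGCSpec(
            measures=(
                _toy_spec(
                    shape="basis",
                    loadings=(0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0),
                    intercept_sd=0.0,
                    slope_sd=0.0,
                    slope_mean=(10.0, 10.0),
                    residual_sd=0.0,
                ),
            )
        )
        f = sample_growth_factors(spec, 3, np.zeros(3, int), rng)
        y = realize_trajectories(f, spec, rng)
        assert np.allclose(y[:, 6, 0] - y[:, 0, 0], 10.0)

    def test_quadratic_has_dominant_linear_component(self):
        for m in LGCSpec().measures:
            if m.shape == "quadratic":
                assert abs(m.quad_mean) < abs(m.slope_mean[0])

    def test_per_wave_variance_matches_closed_form(self, rng):
        spec = LGCSpec(measures=(_toy_spec(),))
        n = 100_000
        f = sample_growth_factors(spec, n, np.zeros(n, int), rng)
        y = realize_trajectories(f, spec, rng)
        m = spec.measures[0]
        cov_is = m.is_corr * m.intercept_sd * m.slope_sd
        for w, lam in enumerate(m.loadings):
            expected = (
                m.intercept_sd**2
                + lam**2 * m.slope_sd**2
                + 2 * lam * cov_is
                + m.residual_sd**2
            )
            assert y[:, w, 0].var() == pytest.approx(expected, rel=0.03)


@pytest.fixture(scope="module")
def factors():
    spec = LGCSpec()
    rng = np.random.default_rng(8)
    sex = (rng.uniform(size=50_000) < 0.5).astype(int)
    return spec, sample_growth_factors(spec, 50_000, sex, rng), rng


class TestCovariates:
    def test_zero_weights_give_independence(self, factors):
        spec, f, rng = factors
        w = CovariateWeights("null", transform=("affine", 0.0, 1.0))
        channel, values = build_covariate(f, spec, {}, w, rng)
        r = np.corrcoef(values, f[:, 0])[0, 1]
        assert abs(r) < 0.02

    def test_iq_weakly_positively_correlated_with_brain(self, factors):
        spec, f, rng = factors
        w = CovariateWeights(
            "iq",
            brain_weights={name: 0.07 for name in spec.names},
            noise_sd=0.9,
            transform=("affine", 100.0, 15.0),
        )
        _, iq = build_covariate(f, spec, {}, w, rng)
        r = np.corrcoef(iq, f[:, spec.names.index("gm_volume") * 2])[0, 1]
        assert 0.02 < r < 0.3  # weak but positive

    def test_externalizing_negative_with_education_and_autism(self):
        t = generate_leer_dataset(seed=5, n_subjects=800)
        f = t.frame[t.frame.wave_number == 1].dropna(
            subset=["cbcl_externalizing_raw_score"]
        )
        ext = f["cbcl_externalizing_raw_score"].astype(float)
        r_edu = np.corrcoef(ext, f["parental_education"])[0, 1]
        assert r_edu < -0.02
        diag_gap = (
            ext[f.autism_diagnosis == 1].mean() - ext[f.autism_diagnosis == 0].mean()
        )
        assert diag_gap < 0

    def test_education_category_proportions(self, factors):
        spec, f, rng = factors
        w = CovariateWeights(
            "parental_education",
            brain_weights={name: 0.08 for name in spec.names},
            transform=("categorical", (0.053, 0.354, 0.253, 0.340)),
        )
        _, edu = build_covariate(f, spec, {}, w, rng)
        shares = np.bincount(edu, minlength=4) / len(edu)
        assert np.abs(shares - [0.053, 0.354, 0.253, 0.340]).max() < 0.01


class TestDrift:
    def test_zero_drift_constant(self, rng):
        base = np.array([5.0, 8.0])
        out = drift_covariate(base, DriftSpec("x", -1, 0.0, 0.0), 7, rng)
        assert np.allclose(out, base[:, None])

    def test_externalizing_population_mean_strictly_decreasing(self):
        t = generate_leer_dataset(seed=6, n_subjects=800)
        means = (
            t.frame.groupby("wave_number")["cbcl_externalizing_raw_score"]
            .mean()
            .astype(float)
        )
        assert (np.diff(means.values) < 0).all()

    def test_internalizing_and_attention_increase(self):
        t = generate_leer_dataset(seed=6, n_subjects=800)
        for col in (
            "cbcl_internalizing_raw_score",
            "cbcl_attentionproblem_raw_score",
        ):
            means = t.frame.groupby("wave_number")[col].mean().astype(float)
            assert means.iloc[-1] > means.iloc[0]

    def test_iq_stable(self):
        t = generate_leer_dataset(seed=6, n_subjects=800)
        means = t.frame.groupby("wave_number")["iq"].mean()
        assert means.max() - means.min() < 2.0


class TestStructuralInvariants:
    def test_statics_are_wave_constant(self):
        t = generate_leer_dataset(seed=7, n_subjects=300)
        per_subject = t.frame.groupby("subject_id")[
            ["parental_education", "autism_diagnosis", "sex"]
        ].nunique()
        assert (per_subject == 1).all().all()

    def test_sex_equal_brain_parameters_remove_covariate_sex_gap(self):
        measures = tuple(
            dataclasses.replace(
                m,
                intercept_mean=(m.intercept_mean[0], m.intercept_mean[0]),
                slope_mean=(m.slope_mean[0], m.slope_mean[0]),
            )
            for m in LGCSpec().measures
        )
        params = LeerParams(lgc=LGCSpec(measures=measures), apply_missingness=False)
        t = generate_leer_dataset(seed=9, n_subjects=2000, params=params)
        f = t.frame[t.frame.wave_number == 1]
        gap = (
            f[f.sex == 0]["iq"].mean() - f[f.sex == 1]["iq"].mean()
        )
        assert abs(gap) < 1.0

    def test_three_variants_partition_the_pool(self):
        tables = [
            generate_leer_dataset(seed=10, n_subjects=150, variant=v)
            for v in (1, 2, 3)
        ]
        suffixes = [
            set(t.frame["subject_id"].str.split("_s").str[-1]) for t in tables
        ]
        assert not (suffixes[0] & suffixes[1])
        assert not (suffixes[0] & suffixes[2])
        assert len(suffixes[0] | suffixes[1] | suffixes[2]) == 450

    def test_validator_passes_and_missingness_below_cap(self):
        t = generate_leer_dataset(seed=10, n_subjects=500)
        report = validate_dataset(t, expected_rows=3500)
        assert report.overall_pass
        assert 0.0 < t.missing_fraction() <= 0.20


class TestParameterRecovery:
    def test_mixed_model_recovers_intercept_and_slope_means(self):
        # straight-line configuration: linear loadings, no quadratic term,
        # sex-equal parameters; fit a random-intercept+slope mixed model
        import statsmodels.formula.api as smf

        m = _toy_spec(
            name="hippo_volume",
            intercept_mean=(3700.0, 3700.0),
            slope_mean=(350.0, 350.0),
            intercept_sd=220.0,
            slope_sd=100.0,
            quad_mean=0.0,
            residual_sd=70.0,
        )
        others = tuple(
            dataclasses.replace(s, quad_mean=0.0, loadings=_LINEAR, shape="quadratic")
            if s.name != "hippo_volume"
            else m
            for s in LGCSpec().measures
        )
        params = LeerParams(lgc=LGCSpec(measures=others), apply_missingness=False)
        t = generate_leer_dataset(seed=13, n_subjects=2000, params=params)
        f = t.frame[["subject_id", "wave_number", "hippo_volume"]].copy()
        f["time"] = (f["wave_number"] - 1) / 6.0
        fit = smf.mixedlm(
            "hippo_volume ~ time",
            f,
            groups=f["subject_id"],
            re_formula="~time",
        ).fit(method="lbfgs", maxiter=200)
        for term, target in (("Intercept", 3700.0), ("time", 350.0)):
            est = fit.params[term]
            se = fit.bse[term]
            assert abs(est - target) < 2 * se + 1e-9, (term, est, se)
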