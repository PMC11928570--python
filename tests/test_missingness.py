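"""Attrition mechanisms: rates, direction of biases, and cap enforcement."""

import numpy as np
import pandas as pd
import pytest

from devcohort.engines.osa import generate_osa_dataset
from devcohort.missingness import (
    MARDropoutSpec,
    MCARSpec,
    MeasureDropoutModel,
    WaveDropoutModel,
    apply_mcar,
    enforce_missing_cap,
    mar_dropout,
    mnar_psych_dropout,
    mri_measure_dropout,
    wave_dropout,
)
from devcohort.schema import BRAIN_COLUMNS, CBCL_COLUMNS, MEASURE_COLUMNS


@pytest.fixture(scope="module")
def table():
    return generate_osa_dataset(seed=3, n_subjects=1500)


class TestMcar:
    def test_rate_zero_leaves_table_unchanged(self, table, rng):
        out = apply_mcar(table, MCARSpec(rate=0.0), rng)
        pd.testing.assert_frame_equal(out.frame, table.frame)

    def test_ten_percent_rate_on_brain_columns(self, table, rng):
        out = apply_mcar(table, MCARSpec(rate=0.10), rng)
        frac = out.frame[list(BRAIN_COLUMNS)].isna().to_numpy().mean()
        assert abs(frac - 0.10) < 0.005

    def test_missingness_independent_of_values(self, table, rng):
        out = apply_mcar(table, MCARSpec(rate=0.3, columns=("gm_volume",)), rng)
        deleted = out.frame["gm_volume"].isna().to_numpy()
        values = table.frame["gm_volume"].to_numpy()
        r = np.corrcoef(deleted.astype(float), values)[0, 1]
        assert abs(r) < 0.02


class TestWaveDropout:
    def test_null_model_drops_half(self, table, rng):
        model = WaveDropoutModel(
            intercepts=(0.0,) * 7, male_coef=0, education_coef=0, psych_coef=0
        )
        out = wave_dropout(table, model, rng)
        frac = out.frame["iq"].isna().mean()
        assert abs(frac - 0.5) < 0.02

    def test_male_dropout_exceeds_female(self, table, rng):
        model = WaveDropoutModel(
            intercepts=(-1.0,) * 7, male_coef=1.0, education_coef=0, psych_coef=0
        )
        out = wave_dropout(table, model, rng)
        by_sex = out.frame.groupby("sex")["iq"].apply(lambda s: s.isna().mean())
        assert by_sex[0] > by_sex[1]

    def test_dropout_increases_over_waves(self, table, rng):
        out = wave_dropout(table, WaveDropoutModel(), rng)
        per_wave = out.frame.groupby("wave_number")["iq"].apply(
            lambda s: s.isna().mean()
        )
        assert per_wave.iloc[-1] > per_wave.iloc[0]
        assert np.polyfit(per_wave.index, per_wave.values, 1)[0] > 0

    def test_non_decreasing_intercepts_enforced(self):
        with pytest.raises(ValueError):
            WaveDropoutModel(intercepts=(0.0, -0.5, 0.0, 0.0, 0.0, 0.0, 0.0))


class TestMriDropout:
    def test_closed_form_decay_rate(self, table, rng):
        model = MeasureDropoutModel(mri_p1=0.15, mri_kappa=0.5)
        assert model.mri_rate(4) == pytest.approx(0.15 * np.exp(-1.5))
        out = mri_measure_dropout(table, model, rng)
        wave4 = out.frame[out.frame.wave_number == 4]
        frac = wave4["icv"].isna().mean()
        assert abs(frac - 0.0335) < 0.015

    def test_zero_kappa_constant_rate(self, table, rng):
        model = MeasureDropoutModel(mri_p1=0.2, mri_kappa=0.0)
        out = mri_measure_dropout(table, model, rng)
        per_wave = out.frame.groupby("wave_number")["icv"].apply(
            lambda s: s.isna().mean()
        )
        assert per_wave.max() - per_wave.min() < 0.08

    def test_rates_strictly_decreasing_for_positive_kappa(self):
        model = MeasureDropoutModel(mri_p1=0.15, mri_kappa=0.5)
        rates = model.mri_rate(np.arange(1, 8))
        assert (np.diff(rates) < 0).all()


class TestMnarPsych:
    def test_selection_bias_direction_and_null(self, table):
        truth = table.frame[list(CBCL_COLUMNS)].astype(float)
        model = MeasureDropoutModel(psych_intercept=-2.0, psych_slope=0.12)
        out = mnar_psych_dropout(
            table, truth, model, np.random.default_rng(42)
        )
        ext = "cbcl_externalizing_raw_score"
        observed_mean = out.frame[ext].dropna().astype(float).mean()
        true_mean = truth[ext].mean()
        assert observed_mean < true_mean - 0.3
        # deleting flag positively correlated with the true score
        deleted = out.frame[ext].isna().to_numpy().astype(float)
        r = np.corrcoef(deleted, truth[ext])[0, 1]
        assert r > 0.05
        # zero slope removes the bias under the same seed
        null_model = MeasureDropoutModel(psych_intercept=-2.0, psych_slope=0.0)
        null = mnar_psych_dropout(
            table, truth, null_model, np.random.default_rng(42)
        )
        null_mean = null.frame[ext].dropna().astype(float).mean()
        assert abs(null_mean - true_mean) < 0.3


class TestMarDropout:
    def test_zero_coefficients_uniform_across_groups(self, table, rng):
        spec = MARDropoutSpec(intercept=-0.5, male_coef=0.0, education_coef=0.0)
        out = mar_dropout(table, spec, rng)
        by_sex = out.frame.groupby("sex")["iq"].apply(lambda s: s.isna().mean())
        assert abs(by_sex[0] - by_sex[1]) < 0.05

    def test_default_signs_male_and_low_education_drop_more(self, table, rng):
        out = mar_dropout(table, MARDropoutSpec(intercept=-0.8), rng)
        f = out.frame
        by_sex = f.groupby("sex")["iq"].apply(lambda s: s.isna().mean())
        assert by_sex[0] > by_sex[1]
        by_edu = f.groupby("parental_education")["iq"].apply(
            lambda s: s.isna().mean()
        )
        assert by_edu[0] > by_edu[3]

    def test_dropout_is_absorbing(self, table, rng):
        out = mar_dropout(table, MARDropoutSpec(intercept=0.5), rng)
        f = out.frame
        for _, g in f.groupby("subject_id"):
            missing = g.sort_values("wave_number")["iq"].isna().to_numpy()
            if missing.any():
                first = missing.argmax()
                assert missing[first:].all()


class TestCapEnforcement:
    def test_under_cap_untouched(self, table, rng):
        light = apply_mcar(table, MCARSpec(rate=0.05), rng)
        capped, restored = enforce_missing_cap(light, table, rng=rng)
        assert restored == 0
        pd.testing.assert_frame_equal(capped.frame, light.frame)

    def test_heavy_missingness_restored_to_exactly_the_cap(self, table, rng):
        heavy = apply_mcar(
            table, MCARSpec(rate=0.30, columns=MEASURE_COLUMNS), rng
        )
        assert heavy.missing_fraction() > 0.25
        capped, restored = enforce_missing_cap(heavy, table, rng=rng)
        frac = capped.missing_fraction()
        assert frac <= 0.20
        assert frac > 0.195  # restoration stops exactly at the cap
        assert restored > 0

    def test_cap_zero_restores_everything(self, table, rng):
        heavy = apply_mcar(table, MCARSpec(rate=0.5), rng)
        capped, _ = enforce_missing_cap(heavy, table, cap=0.0, rng=rng)
        assert capped.missing_fraction() == 0.0

    def test_over_cap_without_original_raises(self, table, rng):
        heavy = apply_mcar(
            table, MCARSpec(rate=0.5, columns=MEASURE_COLUMNS), rng
        )
        with pytest.raises(ValueError, match="cap"):
            enforce_missing_cap(heavy, None, rng=rng)

    def test_mcar_preserves_correlations_among_observed(self, table, rng):
        out = apply_mcar(table, MCARSpec(rate=0.2, columns=MEASURE_COLUMNS), rng)
        f = out.frame
        full = table.frame
        pairs = [("gm_volume", "icv"), ("iq", "gm_volume")]
        for a, b in pairs:
            keep = f[a].notna() & f[b].notna()
            r_obs = np.corrcoef(f.loc[keep, a], f.loc[keep, b])[0, 1]
            r_full = np.corrcoef(full[a], full[b])[0, 1]
            assert abs(r_obs - r_full) < 0.03
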