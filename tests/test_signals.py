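"""Embedded ground-truth signals and their recovery procedures."""

import numpy as np
import pandas as pd
import pytest

from devcohort.engines.paint import PaintParams, generate_paint_dataset
from devcohort.schema import BRAIN_COLUMNS, MEASURE_COLUMNS
from devcohort.signals import (
    ASDSignatureSpec,
    CouplingSpec,
    SensitivePeriodSpec,
    embed_asd_signature,
    embed_coupled_change,
    embed_sensitive_period,
    recover_asd_rule,
    recover_coupling,
    recover_sensitive_period,
    signature_scores,
)


@pytest.fixture(scope="module")
def base_table():
    from devcohort.engines.paint import generate_paint_base
    from devcohort.schema import WaveSchedule

    return generate_paint_base(
        seed=61, n_subjects=12_000, variant=1, params=PaintParams(),
        schedule=WaveSchedule(),
    )


class TestCoupledChange:
    def test_deterministic_limit_exact_ratio(self, base_table, rng):
        # beta small enough that the outcome's range clamp never engages
        spec = CouplingSpec(
            beta=0.01, residual_sd=0.0, outcome="frontal_lobe_gm_thickness",
            predictor_scale=1e4,
        )
        out = embed_coupled_change(base_table, spec, rng)
        pred = out.frame.pivot(
            index="subject_id", columns="wave_number", values="wm_volume"
        )
        outc = out.frame.pivot(
            index="subject_id", columns="wave_number",
            values="frontal_lobe_gm_thickness",
        )
        d_out = (outc[2] - outc[1]).to_numpy()
        d_pred = ((pred[2] - pred[1]) / 1e4).to_numpy()
        ratio = d_out / d_pred
        assert np.nanquantile(np.abs(ratio - 0.01), 0.99) < 1e-6

    def test_regression_recovers_beta(self, base_table, rng):
        spec = CouplingSpec(beta=0.3, residual_sd=1.0)
        out = embed_coupled_change(base_table, spec, rng)
        assert recover_coupling(out, spec) == pytest.approx(0.3, abs=0.02)

    def test_zero_beta_leaves_no_recoverable_slope(self, base_table, rng):
        spec = CouplingSpec(beta=0.0, residual_sd=1.0)
        out = embed_coupled_change(base_table, spec, rng)
        assert abs(recover_coupling(out, spec)) < 0.02

    def test_untouched_columns_bit_identical(self, base_table, rng):
        spec = CouplingSpec(beta=0.3, residual_sd=1.0)
        out = embed_coupled_change(base_table, spec, rng)
        for col in BRAIN_COLUMNS + ("iq",):
            pd.testing.assert_series_equal(
                out.frame[col], base_table.frame[col]
            )


@pytest.fixture(scope="module")
def embedded(base_table):
    return embed_asd_signature(
        base_table, ASDSignatureSpec(), np.random.default_rng(9)
    )


class TestAsdSignature:
    def test_rule_accuracy_is_exactly_one(self, embedded):
        assert recover_asd_rule(embedded) == 1.0

    def test_pre_embedding_accuracy_near_chance_on_scores(self, base_table):
        # without the embedding the signature score carries no signal
        scores = signature_scores(base_table, ASDSignatureSpec())
        labels = (
            base_table.frame.drop_duplicates("subject_id")
            .set_index("subject_id")["autism_diagnosis"]
            .reindex(scores.index)
        )
        # balanced accuracy of the zero-threshold rule
        pred = (scores > 0).astype(int)
        tpr = (pred[labels == 1] == 1).mean()
        tnr = (pred[labels == 0] == 0).mean()
        assert abs(0.5 * (tpr + tnr) - 0.5) < 0.1

    def test_permuted_labels_break_the_rule(self, embedded):
        t = embedded.copy()
        rng = np.random.default_rng(3)
        statics = t.frame.drop_duplicates("subject_id")
        permuted = statics["autism_diagnosis"].sample(
            frac=1.0, random_state=3
        ).to_numpy()
        mapping = dict(zip(statics["subject_id"], permuted))
        t.frame["autism_diagnosis"] = t.frame["subject_id"].map(mapping)
        acc = recover_asd_rule(t)
        prevalence = statics["autism_diagnosis"].mean()
        expected = max(prevalence, 1 - prevalence)
        assert acc == pytest.approx(expected, abs=0.05)

    def test_group_effect_sizes_small_per_variable(self, embedded):
        f = embedded.frame
        labels = f["autism_diagnosis"]
        for wave in range(1, 8):
            sub = f[f.wave_number == wave]
            for col in MEASURE_COLUMNS:
                vals = sub[col].astype(float)
                d = (
                    vals[sub.autism_diagnosis == 1].mean()
                    - vals[sub.autism_diagnosis == 0].mean()
                ) / vals.std()
                assert abs(d) < 0.2, (col, wave, d)

    def test_single_variable_classifiers_stay_weak(self, embedded):
        # exhaustive threshold scan, balanced accuracy per variable-wave
        f = embedded.frame
        best = 0.0
        for wave in (1, 2, 3):
            sub = f[f.wave_number == wave]
            y = sub["autism_diagnosis"].to_numpy()
            for col in ("amygdala_volume", "wm_volume", "icv"):
                x = sub[col].to_numpy(dtype=float)
                order = np.argsort(x)
                xs, ys = x[order], y[order]
                n1, n0 = ys.sum(), (1 - ys).sum()
                tp = n1 - np.cumsum(ys)  # predict 1 above threshold
                tn = np.cumsum(1 - ys)
                bal = 0.5 * (tp / n1 + tn / n0)
                best = max(best, bal.max(), (1 - bal).max())
        assert best < 0.75

    def test_scores_separated_by_margin(self, embedded):
        spec = ASDSignatureSpec()
        scores = signature_scores(embedded, spec)
        labels = (
            embedded.frame.drop_duplicates("subject_id")
            .set_index("subject_id")["autism_diagnosis"]
            .reindex(scores.index)
        )
        assert scores[labels == 1].min() >= spec.margin - 1e-6
        assert scores[labels == 0].max() <= -spec.margin + 1e-6


class TestSensitivePeriod:
    def test_window_slope_recovered_and_outside_flat(self, base_table, rng):
        spec = SensitivePeriodSpec(coupling=0.05, residual_sd=0.02)
        out = embed_sensitive_period(base_table, spec, rng)
        inside = recover_sensitive_period(out, spec, inside=True)
        outside = recover_sensitive_period(out, spec, inside=False)
        assert inside == pytest.approx(0.05, abs=0.02)
        assert abs(outside) < 0.02

    def test_zero_coupling_no_window_effect(self, base_table, rng):
        spec = SensitivePeriodSpec(coupling=0.0, residual_sd=0.02)
        out = embed_sensitive_period(base_table, spec, rng)
        assert abs(recover_sensitive_period(out, spec, inside=True)) < 0.02

    def test_waves_outside_window_bit_identical(self, base_table, rng):
        spec = SensitivePeriodSpec()
        out = embed_sensitive_period(base_table, spec, rng)
        col = "frontal_lobe_gm_thickness"
        for wave in (1, 2, 3, 4, 7):
            before = base_table.frame[base_table.frame.wave_number == wave][col]
            after = out.frame[out.frame.wave_number == wave][col]
            if wave in (1, 2, 3, 4):  # window rewrites waves 5 and 6 only
                pd.testing.assert_series_equal(before, after)


class TestPaintVariants:
    def test_variant1_embeds_coupling_and_mcar(self):
        params = PaintParams()
        t = generate_paint_dataset(seed=62, n_subjects=2000, variant=1)
        frac = t.frame[list(BRAIN_COLUMNS)].isna().to_numpy().mean()
        assert abs(frac - 0.10) < 0.01
        assert recover_coupling(t, params.coupling) == pytest.approx(
            params.coupling.beta, abs=0.03
        )

    def test_variant2_signature_holds_end_to_end(self):
        t = generate_paint_dataset(seed=62, n_subjects=2000, variant=2)
        assert recover_asd_rule(t, PaintParams().signature) == 1.0

    def test_variant3_mar_dropout_with_sensitive_period(self):
        params = PaintParams()
        t = generate_paint_dataset(seed=62, n_subjects=2000, variant=3)
        f = t.frame
        assert 0.0 < t.missing_fraction() <= 0.20
        by_sex = f.groupby("sex")["iq"].apply(lambda s: s.isna().mean())
        assert by_sex[0] > by_sex[1]
        inside = recover_sensitive_period(t, params.sensitive_period, True)
        assert inside == pytest.approx(params.sensitive_period.coupling, abs=0.02)

    def test_autism_prevalence_three_percent(self):
        t = generate_paint_dataset(seed=63, n_subjects=10_000, variant=2)
        prev = t.frame.drop_duplicates("subject_id")["autism_diagnosis"].mean()
        assert prev == pytest.approx(0.03, abs=0.005)
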