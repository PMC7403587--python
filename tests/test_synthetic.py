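"""Synthetic-telemetry generator: determinism, forcing, calibration, plantings."""

import dataclasses

import numpy as np
import pytest

from shiftwork import synthetic as syn
from shiftwork.hypnogram import run_length_encode
from shiftwork.synthetic import (
    EPOCHS_PER_DAY,
    CohortSpec,
    EffectSpec,
    generate_epoch_features,
    generate_hypnogram,
    generate_outcomes,
    generate_temperature,
)
from shiftwork.temperature import cosinor_fit, remove_temp_artifacts


def small_spec(**kw):
    defaults = dict(n_rw=2, n_aw=2, days_baseline=2, days_work=1, seed=11)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestDeterminism:
    def test_same_seed_identical_series(self):
        spec = small_spec()
        a = generate_hypnogram(spec, 0, "RW")
        b = generate_hypnogram(spec, 0, "RW")
        assert np.array_equal(a.states, b.states)
        fa = generate_epoch_features(a, spec, 0, "RW")
        fb = generate_epoch_features(b, spec, 0, "RW")
        np.testing.assert_array_equal(fa.swa, fb.swa)
        ta = generate_temperature(a, spec, 0, "RW")
        tb = generate_temperature(b, spec, 0, "RW")
        np.testing.assert_array_equal(ta.temp_c, tb.temp_c)

    def test_cohort_growth_preserves_existing_animals(self):
        s1 = small_spec(n_rw=2)
        s2 = small_spec(n_rw=3)
        a1 = generate_hypnogram(s1, 0, "RW")
        a2 = generate_hypnogram(s2, 0, "RW")
        assert np.array_equal(a1.states, a2.states)

    def test_different_animals_differ(self):
        spec = small_spec()
        a = generate_hypnogram(spec, 0, "RW")
        b = generate_hypnogram(spec, 1, "RW")
        assert not np.array_equal(a.states, b.states)


class TestHypnogram:
    def test_forced_wake_with_zero_microsleep(self):
        spec = small_spec(effect=EffectSpec(microsleep_p=0.0))
        s = generate_hypnogram(spec, 0, "RW")
        work = s.schedule_tag == "WORK"
        assert work.any()
        assert (s.states[work] == "W").all()

    def test_work_window_tags_match_schedule(self):
        spec = small_spec()
        s = generate_hypnogram(spec, 0, "AW")
        zt = s.zt()
        day = np.arange(len(s)) // EPOCHS_PER_DAY
        in_shift = (zt >= 14) & (zt < 22) & (day >= spec.days_baseline)
        assert np.array_equal(s.schedule_tag == "WORK", in_shift)
        assert (s.schedule_tag[day < spec.days_baseline] == "BASELINE").all()

    def test_rem_entered_only_from_nrem(self):
        spec = small_spec(days_baseline=3)
        s = generate_hypnogram(spec, 0, "RW")
        prev = s.states[:-1]
        cur = s.states[1:]
        assert not np.any((cur == "R") & (prev == "W"))

    def test_dark_phase_wake_fraction_calibrated(self):
        """Pooled over many baseline days the dark-phase wake fraction sits
        near the 72.9% nocturnality target."""
        spec = CohortSpec(n_rw=6, n_aw=6, days_baseline=4, days_work=1, seed=5)
        fracs = []
        for idx, cond in spec.animals():
            s = generate_hypnogram(spec, idx, cond)
            nb = spec.days_baseline * EPOCHS_PER_DAY
            zt = s.zt()[:nb]
            fracs.append((s.states[:nb][zt >= 12] == "W").mean())
        assert np.mean(fracs) == pytest.approx(0.729, abs=0.02)


class TestFeatures:
    def test_pressure_dissipates_through_nrem(self):
        from shiftwork.synthetic import _sleep_pressure

        series_states = "W" * 360 + "N" * 720
        from conftest import make_series

        S = _sleep_pressure(make_series(series_states), EffectSpec())
        wake_part = S[:360]
        nrem_part = S[360:]
        assert np.all(np.diff(wake_part) > 0)
        assert np.all(np.diff(nrem_part) < 0)

    def test_quiet_wake_gain_applies_only_to_rw_work_days(self):
        spec = small_spec()
        s = generate_hypnogram(spec, 0, "RW")
        f_rw = generate_epoch_features(s, spec, 0, "RW")
        f_aw = generate_epoch_features(s, spec, 0, "AW")  # same stream, no boost
        ratio = f_rw.swa / f_aw.swa
        work_day = np.arange(len(s)) >= spec.days_baseline * EPOCHS_PER_DAY
        gain = spec.effect.qw_swe_gain_rw
        boosted = np.isclose(ratio, gain)
        assert boosted.any()
        assert not boosted[~work_day].any()
        assert np.all(np.isclose(ratio[~boosted], 1.0))
        assert (s.states[boosted] == "W").all()

    def test_null_gain_produces_identical_features(self):
        spec = small_spec(effect=EffectSpec(qw_swe_gain_rw=1.0))
        s = generate_hypnogram(spec, 0, "RW")
        f_rw = generate_epoch_features(s, spec, 0, "RW")
        f_aw = generate_epoch_features(s, spec, 0, "AW")
        np.testing.assert_array_equal(f_rw.swa, f_aw.swa)

    def test_nrem_swa_exceeds_wake_swa(self):
        spec = small_spec()
        s = generate_hypnogram(spec, 0, "AW")
        f = generate_epoch_features(s, spec, 0, "AW")
        assert f.swa[s.states == "N"].mean() > f.swa[s.states == "W"].mean()


class TestTemperature:
    def test_noiseless_round_trip_recovers_planted_amplitude(self):
        effect = EffectSpec(
            temp_noise_sd_c=0.0,
            artifact_rate=0.0,
            wake_increment_c=0.0,
            amp_baseline_sd_c=0.0,
        )
        spec = small_spec(days_baseline=3, effect=effect)
        s = generate_hypnogram(spec, 0, "AW")
        temp = generate_temperature(s, spec, 0, "AW")
        fit = cosinor_fit(temp, 24.0, span=(0.0, 72.0))
        assert fit.amplitude == pytest.approx(effect.amp_baseline_c, abs=1e-6)
        assert fit.acrophase_zt == pytest.approx(effect.acrophase_zt, abs=1e-4)

    def test_injected_spikes_detected_by_artifact_filter(self):
        effect_clean = EffectSpec(artifact_rate=0.0)
        effect_spiky = EffectSpec(artifact_rate=0.002)
        spec_c = small_spec(days_baseline=3, effect=effect_clean)
        spec_s = small_spec(days_baseline=3, effect=effect_spiky)
        s = generate_hypnogram(spec_c, 0, "RW")
        clean = generate_temperature(s, spec_c, 0, "RW")
        spiky = generate_temperature(s, spec_s, 0, "RW")
        injected = clean.temp_c != spiky.temp_c
        assert injected.sum() >= 10
        flagged = remove_temp_artifacts(spiky).artifact
        assert flagged[injected].mean() >= 0.95


class TestOutcomes:
    def _predictors(self, spec):
        import pandas as pd

        animals = spec.animals()
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "animal_index": [i for i, _ in animals],
                "condition": [int(c == "RW") for _, c in animals],
                "amp_change": rng.normal(-0.27, 0.2, len(animals)),
                "rem_latency": rng.normal(66, 50, len(animals)),
                "nrem_bout_len_24h": rng.normal(5.2, 1, len(animals)),
                "qw_swe_24h": rng.normal(69000, 17000, len(animals)),
                "nrem_bout_len_2h": rng.normal(5.4, 2.5, len(animals)),
                "qw_swe_2h": rng.normal(7600, 2800, len(animals)),
            }
        )

    def test_deterministic_outcome_table(self):
        spec = small_spec()
        preds = self._predictors(spec)
        a = generate_outcomes(preds, spec)
        b = generate_outcomes(preds, spec)
        for col in syn.OUTCOME_NAMES:
            np.testing.assert_array_equal(a[col], b[col])

    def test_corticosterone_time_of_day_structure(self):
        spec = CohortSpec(n_rw=30, n_aw=30, days_baseline=2, days_work=1, seed=3)
        out = generate_outcomes(self._predictors(spec), spec)
        rw = out[out.condition == 1]["corticosterone"].mean()
        aw = out[out.condition == 0]["corticosterone"].mean()
        assert rw > aw

    def test_mwm_latency_clipped_to_task_limits(self):
        spec = small_spec()
        out = generate_outcomes(self._predictors(spec), spec)
        assert out["mwm_latency"].between(5.0, 120.0).all()


def test_effect_spec_validates_probabilities():
    with pytest.raises(Exception):
        EffectSpec(microsleep_p=1.5)
    with pytest.raises(Exception):
        CohortSpec(n_rw=0)


def test_run_length_encode_round_trip(rng):
    states = rng.choice(list("WNR"), size=500)
    runs = run_length_encode(states)
    rebuilt = np.concatenate([[v] * n for _, n, v in runs])
    np.testing.assert_array_equal(rebuilt, states)
    total = sum(n for _, n, _ in runs)
    assert total == 500


def test_spec_serializable_to_plain_dict():
    d = dataclasses.asdict(CohortSpec())
    assert d["effect"]["amp_damping_rw_c"] == -0.40
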