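"""Imputation, padding/masking, augmentation and normalization."""

import numpy as np
import pytest

from chrononet import _autodiff as ad
from chrononet.cohort import CREATININE, URINE_OUTPUT, ChannelMeta, Cohort
from chrononet.losses import bce_sequence
from chrononet.preprocess import (
    PreprocessConfig,
    TruncationError,
    augment,
    cohort_channel_medians,
    impute_cohort,
    impute_series,
    normalize,
    pad_and_mask,
)

from conftest import make_profile, make_series

CFG = PreprocessConfig()


class TestImputation:
    def test_short_gap_forward_filled(self):
        s = make_series(scr=[1.0, 99.0, 1.2], scr_mask=[1, 0, 1])
        out = impute_series(s, CFG)
        np.testing.assert_allclose(out.channel(CREATININE), [1.0, 1.0, 1.2])

    def test_leading_gap_backward_filled(self):
        s = make_series(scr=[99.0, 99.0, 1.2, 1.3],
                        scr_mask=[0, 0, 1, 1])
        out = impute_series(s, CFG)
        np.testing.assert_allclose(out.channel(CREATININE),
                                   [1.2, 1.2, 1.2, 1.3])

    def test_long_gap_falls_back_to_patient_median(self):
        scr = [1.0] + [99.0] * 7 + [2.0]
        mask = [1, 0, 0, 0, 0, 0, 0, 0, 1]
        out = impute_series(make_series(scr=scr, scr_mask=mask), CFG)
        vals = out.channel(CREATININE)
        # hours 2-4 carried forward, hours 6-8 carried back; the gap of 7
        # exceeds both carry horizons at hour 5 -> observed median 1.5
        assert vals[1] == 1.0 and vals[-2] == 2.0
        assert vals[4] == pytest.approx(1.5)

    def test_fully_observed_series_unchanged(self):
        s = make_series(scr=[1.0, 1.1, 1.2])
        out = impute_series(s, CFG)
        np.testing.assert_array_equal(out.values, s.values)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            T = int(rng.integers(6, 20))
            s = make_series(scr=rng.uniform(0.5, 2, T),
                            urine=rng.uniform(10, 90, T),
                            scr_mask=rng.random(T) > 0.4,
                            urine_mask=rng.random(T) > 0.4)
            out = impute_series(s, CFG)
            assert np.array_equal(out.observed_mask, s.observed_mask)
            for j in range(2):
                m = s.observed_mask[:, j]
                assert np.array_equal(out.values[m, j], s.values[m, j])

    def test_unobserved_channel_uses_cohort_median(self, channel_meta_two):
        s1 = make_series(scr=[1.0] * 6, urine=[50.0] * 6)
        s2 = make_series(scr=[2.0] * 6, urine=[50.0] * 6,
                         scr_mask=np.zeros(6, bool), patient_id="p1")
        cohort = Cohort([s1, s2], [make_profile(), make_profile("p1")],
                        channel_meta_two)
        meds = cohort_channel_medians(cohort)
        out = impute_cohort(cohort, CFG, meds)
        np.testing.assert_allclose(out.series[1].channel(CREATININE), 1.0)

    def test_categorical_gap_gets_sentinel(self):
        meta = [ChannelMeta(CREATININE), ChannelMeta(URINE_OUTPUT),
                ChannelMeta("icu_type", "categorical")]
        s = make_series(scr=[1.0] * 4, urine=[50.0] * 4,
                        extra={"icu_type": [1, 1, 2, 2]})
        s.observed_mask[1, 2] = False
        out = impute_series(s, CFG, channel_meta=meta)
        assert out.values[1, 2] == CFG.categorical_sentinel


class TestPadding:
    def test_mask_counts_match_lengths(self):
        a = make_series(scr=np.full(6, 1.0))
        b = make_series(scr=np.full(48, 1.0), patient_id="p1")
        batch = pad_and_mask([a, b], 48)
        assert batch.pad_mask[0].sum() == 6
        assert batch.pad_mask[1].sum() == 48

    def test_full_length_series_all_real(self):
        s = make_series(scr=np.full(12, 1.0))
        assert pad_and_mask([s], 12).pad_mask.all()

    def test_overlong_sequence_raises(self):
        s = make_series(scr=np.full(13, 1.0))
        with pytest.raises(TruncationError):
            pad_and_mask([s], 12)

    def test_round_trip_recovers_values(self):
        rng = np.random.default_rng(1)
        series = [make_series(scr=rng.uniform(0.5, 2, T),
                              urine=rng.uniform(10, 90, T),
                              patient_id=f"p{T}")
                  for T in (6, 11, 17)]
        batch = pad_and_mask(series, 20)
        for i, s in enumerate(series):
            np.testing.assert_array_equal(batch.inputs[i, :s.T], s.values)
            assert (batch.inputs[i, s.T:] == 0).all()

    def test_masked_loss_equals_per_sequence_loss(self):
        rng = np.random.default_rng(2)
        lengths = (5, 9, 14)
        y = [rng.integers(0, 2, T).astype(float) for T in lengths]
        p = [rng.uniform(0.05, 0.95, T) for T in lengths]
        per_seq = np.mean([float(bce_sequence(yi, pi))
                           for yi, pi in zip(y, p)])
        T_max = max(lengths)
        Y = np.zeros((3, T_max))
        P = rng.uniform(0.05, 0.95, (3, T_max))  # garbage under the pad
        mask = np.zeros((3, T_max), bool)
        for i, T in enumerate(lengths):
            Y[i, :T], P[i, :T] = y[i], p[i]
            mask[i, :T] = True
        assert abs(float(bce_sequence(Y, P, mask)) - per_seq) < 1e-10


class TestAugmentation:
    def _series(self, T=24, seed=0):
        rng = np.random.default_rng(seed)
        return make_series(scr=rng.uniform(0.5, 2, T),
                           urine=rng.uniform(10, 90, T),
                           extra={"hr": rng.uniform(60, 100, T)})

    META = [ChannelMeta(CREATININE, essential=True),
            ChannelMeta(URINE_OUTPUT, essential=True),
            ChannelMeta("hr")]

    def test_zero_strength_is_identity(self):
        cfg = PreprocessConfig(noise_sd_frac=0.0, time_scale_range=(1, 1),
                               mask_prob=0.0)
        s = self._series()
        out = augment(s, cfg, np.random.default_rng(0), self.META)
        np.testing.assert_array_equal(out.values, s.values)
        np.testing.assert_array_equal(out.labels_aki, s.labels_aki)

    def test_full_masking_replaces_nonessential_channels(self):
        cfg = PreprocessConfig(noise_sd_frac=0.0, time_scale_range=(1, 1),
                               mask_prob=1.0)
        s = self._series()
        out = augment(s, cfg, np.random.default_rng(0), self.META)
        med = np.median(s.channel("hr"))
        np.testing.assert_allclose(out.channel("hr"), med)
        # essential channels untouched
        np.testing.assert_array_equal(out.channel(CREATININE),
                                      s.channel(CREATININE))

    def test_time_scaling_shrinks_ramp_slope(self):
        T = 40
        ramp = np.linspace(0.0, 39.0, T)
        s = make_series(scr=ramp, urine=np.full(T, 50.0))
        cfg = PreprocessConfig(noise_sd_frac=0.0,
                               time_scale_range=(1.1, 1.1), mask_prob=0.0)
        out = augment(s, cfg, np.random.default_rng(0),
                      [ChannelMeta(CREATININE), ChannelMeta(URINE_OUTPUT)])
        interior = out.channel(CREATININE)[:int(T / 1.1) - 1]
        slopes = np.diff(interior)[1:]  # first step hits the clipped left edge
        np.testing.assert_allclose(slopes, 1.0 / 1.1, rtol=1e-6)


class TestNormalization:
    def _cohort(self, seed=0, n=6, meta=None):
        rng = np.random.default_rng(seed)
        meta = meta or [ChannelMeta(CREATININE, "continuous"),
                        ChannelMeta(URINE_OUTPUT, "continuous")]
        series = [make_series(scr=rng.uniform(0.5, 2, 10),
                              urine=rng.uniform(10, 90, 10),
                              patient_id=f"p{i}") for i in range(n)]
        return Cohort(series, [make_profile(f"p{i}") for i in range(n)], meta)

    def test_training_split_standardized(self):
        out, stats = normalize(self._cohort())
        vals = np.concatenate([s.channel(CREATININE) for s in out.series])
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.std() - 1.0) < 1e-10

    def test_constant_channel_left_unscaled(self):
        c = self._cohort()
        for s in c.series:
            s.values[:, 0] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            out, _ = normalize(c)
        np.testing.assert_allclose(out.series[0].channel(CREATININE), 1.0)

    def test_validation_transformed_with_training_stats(self):
        train, stats = normalize(self._cohort(seed=0))
        val_raw = self._cohort(seed=99)
        val, _ = normalize(val_raw, stats)
        mu, sd = stats[CREATININE]
        expected = (val_raw.series[0].channel(CREATININE) - mu) / sd
        np.testing.assert_allclose(val.series[0].channel(CREATININE),
                                   expected)
        vals = np.concatenate([s.channel(CREATININE) for s in val.series])
        assert abs(vals.mean()) > 1e-6  # generally not recentred

    def test_binary_channels_untouched(self):
        meta = [ChannelMeta(CREATININE, "continuous"),
                ChannelMeta(URINE_OUTPUT, "binary")]
        c = self._cohort(meta=meta)
        raw = c.series[0].values[:, 1].copy()
        out, _ = normalize(c)
        np.testing.assert_array_equal(out.series[0].values[:, 1], raw)
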