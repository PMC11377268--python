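import numpy as np
import pytest

from gaitxai.phase import GaitPhaseModel
from gaitxai.synthetic import (
    COGNITIVE_CLASSES, ClassEffect, GeneratorConfig, WaveformParams,
    generate_cognitive_dataset, generate_pd_dataset, generate_pd_recording,
    grf_waveform, render_channels,
)


class TestWaveform:
    def test_swing_carries_no_force(self):
        assert grf_waveform(0.80) == 0.0
        assert grf_waveform(0.65) == 0.0

    def test_continuity_at_toe_off(self):
        pm = GaitPhaseModel()
        assert grf_waveform(pm.stance_fraction) == 0.0
        eps = 1e-9
        assert grf_waveform(pm.stance_fraction - eps) == pytest.approx(0.0, abs=1e-6)

    def test_double_bump_maxima_at_quarter_points_of_stance(self):
        # brute-force grid search over the closed form
        pm = GaitPhaseModel()
        phases = np.linspace(0.0, 1.0, 100_000, endpoint=False)
        f = grf_waveform(phases, pm)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(f)
        locs = phases[peaks]
        assert len(locs) == 2
        np.testing.assert_allclose(
            locs, [0.25 * pm.stance_fraction, 0.75 * pm.stance_fraction], atol=1e-3
        )

    def test_out_of_domain_phase_raises(self):
        with pytest.raises(ValueError):
            grf_waveform(1.0)
        with pytest.raises(ValueError):
            grf_waveform(-0.2)

    def test_peak_heights_follow_parameters(self):
        p = WaveformParams(peak1=2.0, peak2=1.0, valley=0.5)
        pm = GaitPhaseModel()
        assert grf_waveform(0.25 * 0.6, pm, p) == pytest.approx(2.0)
        assert grf_waveform(0.75 * 0.6, pm, p) == pytest.approx(1.0)
        assert grf_waveform(0.50 * 0.6, pm, p) == pytest.approx(0.5)


def _forces_and_phases(n=300, fs=100.0):
    pm = GaitPhaseModel()
    t = np.arange(n) / fs
    ph_l = np.mod(t / pm.cycle_duration, 1.0)
    ph_r = np.mod(ph_l + 0.5, 1.0)
    f = np.stack([grf_waveform(ph_l, pm), grf_waveform(ph_r, pm)], axis=1)
    return f, np.stack([ph_l, ph_r], axis=1)


class TestRenderChannels:
    def test_pd_sum_columns_equal_sensor_sums_exactly(self):
        f, ph = _forces_and_phases()
        rec = render_channels(f, ph, GeneratorConfig.pd(), seed=3)
        v = rec.values
        assert v.shape == (300, 19)
        np.testing.assert_array_equal(v[:, 17], v[:, 1:9].sum(axis=1))
        np.testing.assert_array_equal(v[:, 18], v[:, 9:17].sum(axis=1))

    def test_all_zero_force_gives_zero_sensors(self):
        f, ph = _forces_and_phases()
        cfg = GeneratorConfig.pd(noise_sd=0.0)
        rec = render_channels(np.zeros_like(f), ph, cfg)
        assert np.all(rec.values[:, 1:] == 0.0)

    def test_weight_factor_scales_linearly(self):
        f, ph = _forces_and_phases()
        cfg = GeneratorConfig.pd(noise_sd=0.0)
        v1 = render_channels(f, ph, cfg, weight=1.0).values[:, 1:]
        v2 = render_channels(f, ph, cfg, weight=2.0).values[:, 1:]
        np.testing.assert_allclose(v2, 2.0 * v1, atol=1e-12)

    def test_pd_channels_are_non_negative_despite_noise(self):
        f, ph = _forces_and_phases()
        rec = render_channels(f, ph, GeneratorConfig.pd(noise_sd=0.5), seed=11)
        assert np.all(rec.values[:, 1:] >= 0.0)

    def test_cognitive_layout_has_116_channels_no_timestamp(self):
        f, ph = _forces_and_phases(n=100, fs=20.0)
        rec = render_channels(f, ph, GeneratorConfig.cognitive(), seed=5)
        assert rec.values.shape == (100, 116)
        assert not rec.has_timestamp


class TestGeneratePdDataset:
    def test_window_geometry_and_balance(self):
        cfg = GeneratorConfig.pd(n_subjects=4, trials_per_subject_per_class=2)
        ds = generate_pd_dataset(cfg, seed=0)
        assert ds.values.shape == (4 * 4 * 2, 500, 18)
        for cls in ds.classes:
            assert np.sum(ds.labels == cls) == 8

    def test_determinism_under_fixed_seed(self):
        cfg = GeneratorConfig.pd(n_subjects=2, trials_per_subject_per_class=2)
        a = generate_pd_dataset(cfg, seed=42)
        b = generate_pd_dataset(cfg, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.event_windows, b.event_windows)

    def test_unknown_target_event_raises(self):
        cfg = GeneratorConfig.pd(n_subjects=1, trials_per_subject_per_class=1)
        effects = [ClassEffect("C", 0.5, 0.01, 2), ClassEffect("B", 0.5, 0.01, 2.5),
                   ClassEffect("G", 0.5, 0.01, 3)]
        pm = GaitPhaseModel(event_boundaries={
            k: v for k, v in GaitPhaseModel().event_boundaries.items()
        })
        generate_pd_dataset(cfg, effects, seed=0, phase_model=pm)  # sanity
        with pytest.raises((KeyError, ValueError)):
            ClassEffect("X", 0.5, 0.01, 2)

    def test_effects_must_cover_all_severity_classes(self):
        cfg = GeneratorConfig.pd(n_subjects=1, trials_per_subject_per_class=1)
        with pytest.raises(ValueError, match="missing"):
            generate_pd_dataset(cfg, [ClassEffect("C", 0.5, 0.01, 2)], seed=0)

    def test_raw_values_non_negative(self):
        cfg = GeneratorConfig.pd(n_subjects=2, trials_per_subject_per_class=1)
        ds = generate_pd_dataset(cfg, seed=3)
        assert np.all(ds.values >= 0.0)

    def test_planted_attenuation_lowers_in_window_signal_only(self):
        """Monte-Carlo oracle over 200 windows: severity-3 at amplitude 0.5
        on event G is weaker inside its planted windows than the matched
        no-op reference (identical streams, amplitude 1), and identical
        outside them."""
        n = 200
        base = dict(
            n_subjects=n, trials_per_subject_per_class=1,
            subject_weight_scale_range=(1.0, 1.0), subject_cadence_sd=0.0,
            window_len=300,
        )
        others = [ClassEffect("C", 1.0, 0.0, 2, tremor_amplitude=0.0),
                  ClassEffect("B", 1.0, 0.0, 2.5, tremor_amplitude=0.0)]
        ds_real = generate_pd_dataset(
            GeneratorConfig.pd(**base),
            others + [ClassEffect("G", 0.5, 0.0, 3, tremor_amplitude=0.0)], seed=9)
        ds_null = generate_pd_dataset(
            GeneratorConfig.pd(**base),
            others + [ClassEffect("G", 1.0, 0.0, 3, tremor_amplitude=0.0)], seed=9)
        idx = np.nonzero(ds_real.labels == 3)[0]
        s_in_real = np.array([ds_real.values[i][ds_real.event_windows[i]].mean()
                              for i in idx])
        s_in_null = np.array([ds_null.values[i][ds_null.event_windows[i]].mean()
                              for i in idx])
        assert s_in_real.mean() < 0.75 * s_in_null.mean()
        # outside the planted windows the signals agree in expectation;
        # here with matched noise streams they agree frame by frame
        for i in idx[:20]:
            out = ~ds_real.event_windows[i]
            np.testing.assert_allclose(ds_real.values[i][out], ds_null.values[i][out],
                                       atol=1e-10)


class TestGenerateCognitiveDataset:
    @pytest.fixture(scope="class")
    def small_cog(self):
        cfg = GeneratorConfig.cognitive(n_subjects=3, trials_per_subject_per_class=2)
        return generate_cognitive_dataset(cfg, seed=5)

    def test_shape_and_per_subject_sample_count(self, small_cog):
        ds = small_cog
        assert ds.values.shape == (3 * 5 * 2, 100, 116)
        for s in set(map(str, ds.subject_ids)):
            assert np.sum(ds.subject_ids == s) == 5 * 2

    def test_five_classes_with_m1_reference(self, small_cog):
        assert small_cog.classes == COGNITIVE_CLASSES
        m1 = small_cog.labels == "M1"
        assert not small_cog.event_windows[m1].any()

    def test_determinism(self):
        cfg = GeneratorConfig.cognitive(n_subjects=2, trials_per_subject_per_class=1)
        a = generate_cognitive_dataset(cfg, seed=3)
        b = generate_cognitive_dataset(cfg, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_dual_task_differences_localize_to_planted_frames(self):
        """M2-vs-M1 contrast: with a no-op M2 effect the in-mask statistic
        matches M1-level behaviour; with the real effect it separates,
        while out-of-mask statistics agree within 3 SE (Monte-Carlo)."""
        n = 70
        base = dict(n_subjects=n, trials_per_subject_per_class=1,
                    subject_weight_scale_range=(1.0, 1.0), subject_cadence_sd=0.0,
                    subject_signature_sd=0.0)
        effects_null = [
            ClassEffect("A", 1.0, 0.0, "M2", tremor_amplitude=0.0),
            ClassEffect("F", 1.0, 0.0, "M3", tremor_amplitude=0.0),
            ClassEffect("G", 1.0, 0.0, "M4", tremor_amplitude=0.0),
            ClassEffect("E", 1.0, 0.0, "M5", tremor_amplitude=0.0),
        ]
        effects_real = [
            ClassEffect("A", 0.5, 0.0, "M2", tremor_amplitude=0.0),
            *effects_null[1:],
        ]
        ds_null = generate_cognitive_dataset(GeneratorConfig.cognitive(**base),
                                             effects_null, seed=8)
        ds_real = generate_cognitive_dataset(GeneratorConfig.cognitive(**base),
                                             effects_real, seed=8)
        m2 = ds_null.labels == "M2"
        idx = np.nonzero(m2)[0]
        s_in_null = np.array([ds_null.values[i][ds_null.event_windows[i]].mean() for i in idx])
        s_in_real = np.array([ds_real.values[i][ds_real.event_windows[i]].mean() for i in idx])
        s_out_null = np.array([ds_null.values[i][~ds_null.event_windows[i]].mean() for i in idx])
        s_out_real = np.array([ds_real.values[i][~ds_real.event_windows[i]].mean() for i in idx])
        # inside the planted frames the attenuated signal separates clearly
        se_in = np.sqrt(s_in_null.var(ddof=1) / n + s_in_real.var(ddof=1) / n)
        assert s_in_real.mean() < s_in_null.mean() - 5 * se_in
        # outside them the matched streams agree within Monte-Carlo noise
        se_out = np.sqrt(s_out_null.var(ddof=1) / n + s_out_real.var(ddof=1) / n)
        assert abs(s_out_null.mean() - s_out_real.mean()) < 3 * se_out


class TestPdRecording:
    def test_recording_has_19_columns_and_increasing_timestamp(self):
        rec = generate_pd_recording(400, seed=2)
        assert rec.values.shape == (400, 19)
        assert np.all(np.diff(rec.values[:, 0]) > 0)
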