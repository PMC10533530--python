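"""Synthetic gait generator: planted structure, determinism, filtering."""

import numpy as np
import pytest

import imuplace as ip
from imuplace.core import BodyLocation as L
from imuplace.core import SurfaceClass as S


def _rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2, axis=-1))


class TestSimulateTrials:
    def test_default_design_counts_and_shapes(self, default_trials):
        assert len(default_trials) == 10 * 6 * 7
        assert all(t.samples.shape == (36, 600) for t in default_trials)
        assert all(t.sample_rate == 100 for t in default_trials)

    def test_same_seed_is_bit_identical(self):
        cfg = ip.GaitSimConfig(n_participants=2, trials_per_surface=1, seed=3)
        a = ip.simulate_trials(cfg)
        b = ip.simulate_trials(cfg)
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_different_seed_differs(self):
        a = ip.simulate_trials(ip.GaitSimConfig(n_participants=1, trials_per_surface=1, seed=3))
        b = ip.simulate_trials(ip.GaitSimConfig(n_participants=1, trials_per_surface=1, seed=4))
        assert not np.allclose(a[0].samples, b[0].samples)

    def test_zero_wrist_gain_no_noise_wrist_identical_across_surfaces(self):
        cfg = ip.GaitSimConfig(n_participants=2, trials_per_surface=2, noise_sd=0.0, seed=5)
        cfg.location_gain[L.WRIST] = 0.0
        trials = ip.simulate_trials(cfg)
        wrist = slice(L.WRIST.index * 6, L.WRIST.index * 6 + 6)
        for p in (1, 2):
            for j in (1, 2):
                group = [
                    t for t in trials if t.participant_id == p and t.trial_index == j
                ]
                ref = group[0].samples[wrist]
                assert all(np.allclose(t.samples[wrist], ref) for t in group)

    def test_dominant_spectral_peak_at_surface_cadence(self):
        # wrist orientation fixed: the per-trial posture rotation mixes the
        # three axes, and phase interference in a near-zero-gain channel can
        # promote a harmonic; the claim under test is the harmonic structure
        cfg = ip.GaitSimConfig(
            n_participants=2, trials_per_surface=1, noise_sd=0.0,
            wrist_orientation_deg=0.0, seed=9,
        )
        trials = ip.simulate_trials(cfg)
        for t in trials:
            eff = cfg.surface_effects[t.surface]
            f0 = cfg.step_frequency_hz * eff.cadence
            centred = t.samples - t.samples.mean(axis=1, keepdims=True)
            # Hann window: the record holds a non-integer cycle count, and
            # scalloping loss would otherwise distort peak comparisons
            centred = centred * np.hanning(centred.shape[1])
            spec = np.abs(np.fft.rfft(centred, axis=1))
            freqs = np.fft.rfftfreq(t.samples.shape[1], d=1 / t.sample_rate)
            peaks = freqs[spec[:, 1:].argmax(axis=1) + 1]
            tol = (freqs[1] - freqs[0]) + f0 * cfg.cadence_jitter
            assert np.all(np.abs(peaks - f0) <= tol)

    def test_shank_varies_across_surfaces_more_than_wrist(self, default_trials):
        assert len(default_trials) >= 100
        shank_row = L.LEFT_SHANK.index * 6 + 2  # AP accel
        wrist_row = L.WRIST.index * 6 + 2
        by_surface = {s: [] for s in S}
        for t in default_trials:
            by_surface[t.surface].append(
                (_rms(t.samples[shank_row, :400]), _rms(t.samples[wrist_row, :400]))
            )
        means = np.array([np.mean(v, axis=0) for v in by_surface.values()])
        shank_var, wrist_var = means.var(axis=0)
        assert shank_var > wrist_var

    def test_banked_surfaces_have_opposite_mediolateral_sign(self, default_trials):
        ml_row = L.RIGHT_SHANK.index * 6 + 1
        mean_ml = {
            s: np.mean([t.samples[ml_row].mean() for t in default_trials if t.surface is s])
            for s in (S.BANKED_LEFT, S.BANKED_RIGHT)
        }
        assert mean_ml[S.BANKED_LEFT] > 0 > mean_ml[S.BANKED_RIGHT]

    @pytest.mark.parametrize(
        "field,value",
        [("duration_s", 0.0), ("sample_rate", -1.0), ("step_frequency_hz", 0.0)],
    )
    def test_invalid_config_rejected(self, field, value):
        cfg = ip.GaitSimConfig(**{field: value})
        with pytest.raises(ValueError):
            ip.simulate_trials(cfg)


def _sine_trial(freq, fs=100.0, T=2000):
    t = np.arange(T) / fs
    x = np.tile(np.sin(2 * np.pi * freq * t), (36, 1))
    return ip.IMUTrial(1, S.FLAT_UNEVEN, 1, x, sample_rate=fs)


def _steady_amplitude(x, freq, fs):
    # project the second half (past the transient) onto quadrature sinusoids
    n = x.shape[-1]
    sl = slice(n // 2, n)
    t = np.arange(n)[sl] / fs
    c = np.cos(2 * np.pi * freq * t)
    s = np.sin(2 * np.pi * freq * t)
    seg = x[..., sl]
    return 2 * np.hypot(seg @ c, seg @ s) / len(t)


class TestLowpassFilter:
    def test_constant_channel_unchanged(self):
        trial = ip.IMUTrial(1, S.FLAT_UNEVEN, 1, np.full((36, 500), 3.7))
        for phase in ("zero_phase", "causal"):
            out = ip.lowpass_filter(trial, ip.FilterSpec(phase=phase))
            np.testing.assert_allclose(out.samples, 3.7, rtol=1e-9)

    def test_causal_gain_is_minus_3db_at_cutoff(self):
        trial = _sine_trial(6.0)
        out = ip.lowpass_filter(trial, ip.FilterSpec(phase="causal"))
        ratio = _steady_amplitude(out.samples[0], 6.0, 100.0)
        assert ratio == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_causal_gain_at_30hz_matches_butterworth_magnitude(self):
        trial = _sine_trial(30.0)
        out = ip.lowpass_filter(trial, ip.FilterSpec(phase="causal"))
        ratio = _steady_amplitude(out.samples[0], 30.0, 100.0)
        # analog 2nd-order magnitude |H| = (1 + (f/fc)^4)^(-1/2) ~ 0.040
        analog = 1 / np.sqrt(1 + (30 / 6) ** 4)
        assert ratio == pytest.approx(analog, abs=0.002)

    def test_filter_is_linear(self, rng):
        x = ip.IMUTrial(1, S.FLAT_UNEVEN, 1, rng.normal(size=(36, 500)))
        y = ip.IMUTrial(1, S.FLAT_UNEVEN, 1, rng.normal(size=(36, 500)))
        combo = ip.IMUTrial(1, S.FLAT_UNEVEN, 1, 2.0 * x.samples + 0.5 * y.samples)
        spec = ip.FilterSpec()
        lhs = ip.lowpass_filter(combo, spec).samples
        rhs = (
            2.0 * ip.lowpass_filter(x, spec).samples
            + 0.5 * ip.lowpass_filter(y, spec).samples
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_length_preserved(self, small_trials):
        out = ip.lowpass_filter(small_trials[0])
        assert out.n_samples == small_trials[0].n_samples

    def test_cutoff_at_or_above_nyquist_rejected(self):
        trial = _sine_trial(5.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ip.lowpass_filter(trial, ip.FilterSpec(cutoff_hz=50.0))
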