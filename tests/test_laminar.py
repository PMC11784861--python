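"""CSD estimation, wavelet spectrograms and laminar power profiles."""

import numpy as np
import pytest

from gridwaves.containers import LaminarLFP
from gridwaves.laminar import (
    band_power_ratios,
    csd,
    relative_power_profile,
    sink_bootstrap,
    time_frequency,
)
from gridwaves.synth import LaminarDipoleSpec, generate_laminar_lfp


class TestCSD:
    def test_affine_depth_profile_annihilated(self):
        z = np.arange(16, dtype=float)
        data = (3.0 * z + 7.0)[:, None] * np.ones((1, 100))
        out = csd(data, n=2, dz_um=50.0)
        np.testing.assert_allclose(out[2:-2], 0.0, atol=1e-12)

    def test_quadratic_curvature_recovered(self):
        # V = z^2 -> d2V/dz2 = 2 (per depth^2), any step n
        z = np.arange(20, dtype=float)
        data = (z**2)[:, None] * np.ones((1, 10))
        for n in (1, 2, 3):
            out = csd(data, n=n, dz_um=1.0, vaknin=False)
            np.testing.assert_allclose(out, 2.0, atol=1e-9)

    def test_linearity(self, rng):
        a = rng.normal(size=(12, 50))
        b = rng.normal(size=(12, 50))
        lhs = csd(2.5 * a + 1.5 * b, n=2, dz_um=20.0)
        rhs = 2.5 * csd(a, n=2, dz_um=20.0) + 1.5 * csd(b, n=2, dz_um=20.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_planted_sink_localized(self, laminar_dipole):
        spec, lam, truth = laminar_dipole
        out = csd(lam, n=1)
        t_peak = int(np.argmax(truth["time_course"]))
        assert int(np.argmin(out[:, t_peak])) == truth["sink_depth"]

    def test_vaknin_preserves_channel_count(self, laminar_dipole):
        _, lam, _ = laminar_dipole
        assert csd(lam, n=2).shape == lam.data.shape

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            csd(np.zeros((4, 10)), n=2, dz_um=10.0)


class TestTimeFrequency:
    def test_tone_ridge(self):
        fs = 500.0
        t = np.arange(int(2 * fs)) / fs
        spec, freqs = time_frequency(np.sin(2 * np.pi * 20 * t), fs)
        ridge = freqs[np.argmax(spec[:, len(t) // 2])]
        assert abs(ridge - 20.0) / 20.0 < 0.12

    def test_chirp_ridge_rises(self):
        from scipy.signal import chirp

        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        x = chirp(t, f0=5.0, f1=40.0, t1=t[-1])
        spec, freqs = time_frequency(x, fs)
        cols = np.linspace(int(0.5 * fs), len(t) - int(0.5 * fs), 8).astype(int)
        ridge = freqs[np.argmax(spec[:, cols], axis=0)]
        assert (np.diff(ridge) > -1e-9).all()
        assert ridge[-1] > 2 * ridge[0]

    def test_zero_signal(self):
        spec, _ = time_frequency(np.zeros(1000), 500.0)
        assert np.abs(spec).max() == 0.0


class TestBandPowerRatios:
    def _spectrogram(self, f_components, fs=500.0, dur=2.0):
        t = np.arange(int(dur * fs)) / fs
        x = sum(np.sin(2 * np.pi * f * t) for f in f_components)
        return time_frequency(x, fs), t

    def test_equal_tones_ratio_near_one(self):
        (spec, freqs), t = self._spectrogram([20.0, 60.0])  # beta and gamma
        out = band_power_ratios(spec, freqs, 500.0, {"w": (0.5, 1.5)})
        assert 0.5 < out["w"]["beta_gamma"] < 2.0

    def test_pure_gamma_ratios_small(self):
        (spec, freqs), _ = self._spectrogram([60.0])
        out = band_power_ratios(spec, freqs, 500.0, {"w": (0.5, 1.5)})
        assert out["w"]["beta_gamma"] < 0.2
        assert out["w"]["theta_gamma"] < 0.2

    def test_injected_theta_raises_late_ratio(self):
        fs = 500.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 60 * t)
        late = t >= 1.0
        x[late] += 4.0 * np.sin(2 * np.pi * 8 * t[late])
        spec, freqs = time_frequency(x, fs)
        out = band_power_ratios(spec, freqs, fs,
                                {"early": (0.2, 0.8), "late": (1.2, 1.8)})
        assert out["late"]["theta_gamma"] > 2 * out["early"]["theta_gamma"]

    def test_window_outside_record(self):
        (spec, freqs), _ = self._spectrogram([20.0])
        with pytest.raises(ValueError):
            band_power_ratios(spec, freqs, 500.0, {"bad": (1.5, 3.0)})


class TestRelativePowerProfile:
    def _laminar_with_band_peak(self, peak_channel=12, f0=20.0, fs=500.0):
        rng = np.random.default_rng(0)
        n_ch, n = 16, int(2 * fs)
        t = np.arange(n) / fs
        gains = np.exp(-0.5 * ((np.arange(n_ch) - peak_channel) / 2.0) ** 2)
        data = gains[:, None] * np.sin(2 * np.pi * f0 * t) + rng.normal(0, 0.05, (n_ch, n))
        return LaminarLFP(data, 50.0, fs)

    def test_columns_max_normalized(self):
        lam = self._laminar_with_band_peak()
        profile, freqs = relative_power_profile(lam, window=(0.0, 2.0))
        assert np.nanmax(profile, axis=0) == pytest.approx(1.0)

    def test_planted_depth_peak_recovered(self):
        lam = self._laminar_with_band_peak(peak_channel=12, f0=20.0)
        profile, freqs = relative_power_profile(lam, window=(0.0, 2.0))
        col = np.argmin(np.abs(freqs - 20.0))
        assert int(np.argmax(profile[:, col])) == 12

    def test_gain_invariance(self):
        lam = self._laminar_with_band_peak()
        scaled = LaminarLFP(lam.data * 7.3, lam.dz_um, lam.fs)
        p1, _ = relative_power_profile(lam, window=(0.0, 2.0))
        p2, _ = relative_power_profile(scaled, window=(0.0, 2.0))
        np.testing.assert_allclose(p1, p2, atol=1e-10)


class TestSinkBootstrap:
    def _trials(self, ratio, n_trials=30, seed=0):
        rng = np.random.default_rng(seed)
        spec = LaminarDipoleSpec(n_channels=16, sink_depth=4, source_depth=8,
                                 magnitude=30.0)
        lam, _ = generate_laminar_lfp(spec)
        base = lam.data
        trials, labels = [], []
        for i in range(n_trials):
            strong = i % 2 == 0
            amp = 1.0 if strong else 1.0 / ratio
            trials.append(amp * base + rng.normal(0, 0.5, base.shape))
            labels.append("strong" if strong else "weak")
        return np.array(trials), labels, lam

    def test_planted_amplitude_ratio_recovered(self):
        trials, labels, lam = self._trials(ratio=3.0)
        out = sink_bootstrap(trials, labels, lam.fs, lam.dz_um,
                             touch_index=int(0.2 * lam.fs),
                             late_window=(0.0, 0.2),  # transient peaks ~60 ms
                             superficial_channels=range(8), n_iter=30, seed=1)
        # sink is negative: magnitude ratio of medians ~ 3
        r = np.median(out["strong"]) / np.median(out["weak"])
        assert 2.0 < r < 4.0

    def test_deterministic_given_seed(self):
        trials, labels, lam = self._trials(ratio=2.0)
        kw = dict(fs=lam.fs, dz_um=lam.dz_um, touch_index=100,
                  late_window=(0.0, 0.2), n_iter=3, seed=9)
        a = sink_bootstrap(trials, labels, **kw)
        b = sink_bootstrap(trials, labels, **kw)
        np.testing.assert_array_equal(a["strong"], b["strong"])
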