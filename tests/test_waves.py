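"""Traveling-wave detection: evaluation points, source, rho, kinematics."""

import numpy as np
import pytest

from gridwaves.containers import GridLFP
from gridwaves.gp import generalized_phase
from gridwaves.preprocess import bandpass
from gridwaves.synth import WaveFieldSpec, generate_wave_lfp, grid_coords
from gridwaves.waves import (
    WaveDetector,
    build_null,
    circ_linear_corr,
    classify_late_wave,
    find_evaluation_points,
    late_wave_amplitude,
    modal_source,
    pgd,
    source_point,
    windowed_wave_count_bootstrap,
)


class TestEvaluationPoints:
    def test_count_matches_tone_cycles(self, plane_wave):
        # 10 Hz for 2 s with 100-ms edges masked -> ~18 rising crossings
        _, lfp, _ = plane_wave
        field = generalized_phase(lfp)
        eps = find_evaluation_points(field, trigger_channel=0)
        assert 16 <= len(eps) <= 19

    def test_masked_phase_yields_none(self):
        coords = grid_coords((2, 2), 0.2)
        lfp = GridLFP(np.zeros((4, 1000)), coords, 1000.0)
        field = generalized_phase(lfp)
        assert find_evaluation_points(field) == []

    def test_crossing_location(self):
        # linear phase ramp crossing -pi/2 between samples 136 and 137
        coords = grid_coords((2, 2), 0.2)
        fs = 1000.0
        t = np.arange(1000) / fs
        f0 = 10.0
        # cos phase passes -pi/2 rising at t where 2*pi*f0*t = -pi/2 + 2*pi*n
        lfp = GridLFP(np.tile(np.cos(2 * np.pi * f0 * t), (4, 1)), coords, fs)
        field = generalized_phase(lfp)
        eps = find_evaluation_points(field)
        expected = {int(round(((-0.25 + n) / f0) * fs)) for n in range(1, 20)}
        for ep in eps:
            assert min(abs(ep.index - e) for e in expected) <= 1


class TestSourcePoint:
    def test_radial_source_recovered(self, radial_wave):
        _, lfp, truth = radial_wave
        field = generalized_phase(lfp)
        for t in (400, 900, 1400):
            assert source_point(field, t) == truth["source"]

    def test_modal_source_with_noise(self):
        spec = WaveFieldSpec(geometry="radial", speed=0.3, f0=10.0,
                             amplitude=50.0, noise_sd=5.0, seed=11)
        lfp, truth = generate_wave_lfp(spec)
        field = generalized_phase(bandpass(lfp, "wideband"))
        assert modal_source(field, range(200, 1800, 100)) == truth["source"]

    def test_uniform_phase_tie_breaks_to_channel_zero(self):
        coords = grid_coords((4, 4), 0.2)
        assert source_point(np.zeros(16), coords=coords) == 0

    def test_small_grid_rejected(self):
        coords = grid_coords((2, 2), 0.2)
        with pytest.raises(ValueError):
            source_point(np.zeros(4), coords=coords)


class TestCircLinearCorr:
    def test_perfect_plane_relation(self):
        d = np.linspace(0, 0.0014, 64)
        phase = -209.4 * d + 0.3
        assert circ_linear_corr(phase, d) > 0.99

    def test_matches_independent_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            d = rng.random(40)
            phase = rng.uniform(-np.pi, np.pi, 40)
            ours = circ_linear_corr(phase, d)
            theirs = pingouin.circ_corrcl(phase, d)
            assert abs(ours - float(theirs[0])) < 1e-10

    def test_invariant_to_phase_offset_and_translation(self, rng):
        d = rng.random(30)
        phase = rng.uniform(-np.pi, np.pi, 30)
        base = circ_linear_corr(phase, d)
        shifted = circ_linear_corr(np.angle(np.exp(1j * (phase + 1.1))), d)
        translated = circ_linear_corr(phase, d + 5.0)
        assert abs(base - shifted) < 1e-10
        assert abs(base - translated) < 1e-10

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            circ_linear_corr(np.zeros(4), np.zeros(4))


class TestNull:
    def test_reproducible_threshold(self, noisy_plane_wave):
        _, lfp, _ = noisy_plane_wave
        field = generalized_phase(bandpass(lfp, "wideband"))
        eps = find_evaluation_points(field)
        a = build_null(field, eps, n_shuffles=100, seed=3)
        b = build_null(field, eps, n_shuffles=100, seed=3)
        assert a.threshold == b.threshold
        assert len(a.rho_samples) == 100

    def test_shuffled_phases_rarely_beat_threshold(self, noisy_plane_wave, rng):
        _, lfp, _ = noisy_plane_wave
        field = generalized_phase(bandpass(lfp, "wideband"))
        eps = find_evaluation_points(field)
        null = build_null(field, eps, n_shuffles=400, seed=0)
        # fresh shuffles behave like the null: ~1% exceedances
        exceed = 0
        coords = field.coords
        for i in range(300):
            t = eps[int(rng.integers(len(eps)))].index
            perm = rng.permutation(field.n_channels)
            ph = field.phase[perm, t]
            src = source_point(ph, coords=coords)
            d = np.linalg.norm(coords - coords[src], axis=1) * 1e-3
            exceed += circ_linear_corr(ph, d) >= null.threshold
        assert exceed / 300 <= 0.05


class TestClassifyAndMeasure:
    def test_formula_arithmetic(self):
        # planted k at 10 Hz: v = 2*pi*10/209.4
        assert abs(2 * np.pi * 10 / 209.4 - 0.300) < 1e-3

    def test_speed_recovered_on_noisy_plane_wave(self, noisy_plane_wave):
        spec, lfp, _ = noisy_plane_wave
        det = WaveDetector(n_shuffles=200, seed=0).fit(bandpass(lfp, "wideband"))
        events = det.detect()
        assert len(events) > 0
        v = np.median([e.v for e in events])
        assert abs(v - spec.speed) / spec.speed < 0.15

    def test_wave_event_fields(self, plane_wave):
        _, lfp, truth = plane_wave
        det = WaveDetector(n_shuffles=100, seed=0).fit(lfp)
        events = det.detect()
        e = events[0]
        assert 0 <= e.rho <= 1
        assert e.k > 0 and e.v > 0
        assert abs(e.omega - 2 * np.pi * e.f) < 1e-9
        assert np.isfinite(e.amplitude)

    def test_epoch_assignment(self, plane_wave):
        _, lfp, _ = plane_wave
        det = WaveDetector(n_shuffles=100, seed=0).fit(lfp)
        events = det.detect(touch_times=[1.0])
        for e in events:
            rel = e.t_eval - 1.0
            if rel < 0:
                assert e.epoch == "prestim"
            elif 0 <= rel < 0.05:
                assert e.epoch == "early"
            elif 0.1 <= rel < 0.3:
                assert e.epoch == "late"


class TestPGD:
    def test_plane_wave_is_one(self, plane_wave):
        _, lfp, _ = plane_wave
        field = generalized_phase(lfp)
        assert abs(pgd(field, 500) - 1.0) < 1e-6

    def test_random_gradients_small(self, rng):
        # i.i.d. random gradient directions on 64 sites: E[PGD] ~ 1/sqrt(64)
        coords = grid_coords((8, 8), 0.2)
        vals = []
        for _ in range(2000):
            phase = rng.uniform(-np.pi, np.pi, 64)
            vals.append(pgd(phase, coords=coords))
        vals = np.array(vals)
        assert vals.mean() < 0.25
        assert np.percentile(vals, 99) < 0.5

    def test_radial_below_plane(self, plane_wave, radial_wave):
        _, lfp_p, _ = plane_wave
        _, lfp_r, _ = radial_wave
        p = pgd(generalized_phase(lfp_p), 500)
        r = pgd(generalized_phase(lfp_r), 500)
        assert r < p


class TestLateWave:
    def _trial(self, late_amp, noise_sd=2.0, fs=1000.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(1.5 * fs)
        x = rng.normal(0, noise_sd, n)
        touch = int(0.6 * fs)
        i0 = touch + int(0.12 * fs)
        x[i0:i0 + 40] += late_amp
        return x, fs, touch

    def test_strong_weak_and_tie(self):
        x, fs, touch = self._trial(20.0)  # 10x SD
        assert classify_late_wave(x, fs, touch) == "strong"
        x, fs, touch = self._trial(0.0)
        assert classify_late_wave(x, fs, touch) == "weak"

    def test_exact_threshold_is_weak(self):
        fs = 1000.0
        x = np.zeros(1500)
        touch = 600
        x[:touch] = np.tile([1.0, -1.0], touch // 2)  # SD exactly 1
        sd = x[touch - 500:touch].std()
        x[touch + 100] = 3.0 * sd  # exactly 3 SD -> strict inequality -> weak
        assert classify_late_wave(x, fs, touch) == "weak"

    def test_trough_to_peak_amplitude(self):
        fs = 1000.0
        x = np.zeros(1500)
        touch = 600
        x[touch + 110] = -20.0
        x[touch + 180] = 40.0
        amp = late_wave_amplitude(x, fs, touch)
        assert abs(amp - 60.0) < 1e-9

    def test_amplitude_linearity(self):
        fs = 1000.0
        x = np.zeros(1500)
        touch = 600
        x[touch + 110] = -20.0
        x[touch + 180] = 40.0
        a1 = late_wave_amplitude(x, fs, touch)
        a2 = late_wave_amplitude(2 * x, fs, touch)
        assert abs(a2 - 2 * a1) < 1e-9


class TestWaveCountBootstrap:
    def test_planted_rate_ratio(self, rng):
        t_hi = np.sort(rng.uniform(0, 50, 2000))   # 40 Hz
        t_lo = np.sort(rng.uniform(50, 100, 1000))  # 20 Hz
        waves = np.concatenate([t_hi, t_lo])
        out = windowed_wave_count_bootstrap(
            waves, {"hi": [(0.0, 50.0)], "lo": [(50.0, 100.0)]},
            n_iter=3000, seed=1,
        )
        ratio = out["hi"].mean() / out["lo"].mean()
        assert 1.6 < ratio < 2.4

    def test_deterministic_single_draw(self):
        waves = np.arange(0, 10, 0.1)
        a = windowed_wave_count_bootstrap(waves, {"x": [(0, 10)]}, n_iter=1, seed=5)
        b = windowed_wave_count_bootstrap(waves, {"x": [(0, 10)]}, n_iter=1, seed=5)
        assert a["x"][0] == b["x"][0]

    def test_short_interval_skipped(self):
        out = windowed_wave_count_bootstrap(
            np.array([0.5]), {"x": [(0.0, 0.01)]}, n_iter=10, seed=0)
        assert out["x"].size == 0
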