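import numpy as np
import pytest

from gridwaves.synth import (
    BehaviorSpec,
    EnsembleRasterSpec,
    EnsembleSpec,
    LaminarDipoleSpec,
    WaveFieldSpec,
    generate_calcium_raster,
    generate_laminar_lfp,
    generate_wave_lfp,
    generate_whisker_traces,
)


@pytest.fixture(scope="session")
def plane_wave():
    """Noiseless 10 Hz plane wave at 0.3 m/s on the default 8x8 grid."""
    spec = WaveFieldSpec(speed=0.3, f0=10.0, noise_sd=0.0, seed=0, duration=2.0)
    lfp, truth = generate_wave_lfp(spec)
    return spec, lfp, truth


@pytest.fixture(scope="session")
def radial_wave():
    spec = WaveFieldSpec(geometry="radial", speed=0.3, f0=10.0, noise_sd=0.0,
                         seed=1, duration=2.0)
    lfp, truth = generate_wave_lfp(spec)
    return spec, lfp, truth


@pytest.fixture(scope="session")
def noisy_plane_wave():
    """SNR 10 (noise sd = amplitude / 10)."""
    spec = WaveFieldSpec(speed=0.3, f0=10.0, amplitude=50.0, noise_sd=5.0,
                         seed=2, duration=2.0)
    lfp, truth = generate_wave_lfp(spec)
    return spec, lfp, truth


@pytest.fixture(scope="session")
def planted_ensemble_raster():
    """Two disjoint planted ensembles among 80 cells."""
    spec = EnsembleRasterSpec(
        n_cells=80,
        n_frames=1500,
        frame_rate=10.0,
        ensembles=[
            EnsembleSpec(members=list(range(0, 8)), coactivation=0.3),
            EnsembleSpec(members=list(range(10, 17)), coactivation=0.3),
        ],
        background_rate=0.005,
        seed=3,
    )
    raster, truth = generate_calcium_raster(spec)
    return spec, raster, truth


@pytest.fixture(scope="session")
def laminar_dipole():
    spec = LaminarDipoleSpec(n_channels=16, sink_depth=8, source_depth=12, seed=4)
    lam, truth = generate_laminar_lfp(spec)
    return spec, lam, truth


@pytest.fixture(scope="session")
def whisker_session():
    spec = BehaviorSpec(touch_episodes=[(0.5, 0.6), (1.2, 1.35)], seed=5)
    pose, truth = generate_whisker_traces(spec)
    return spec, pose, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
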