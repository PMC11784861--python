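"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions each analysis assumes: planar
or radial phase-propagating oscillations on a 2-D electrode grid, touch
trials with early (<50 ms) and late (~100-200 ms) evoked components,
calcium event rasters with planted co-active ensembles, a laminar current
dipole, and sinusoidal whisking with touch episodes.  Noise is additive
Gaussian, white in time and independent across channels/cells.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CalciumRaster, GridLFP, LaminarLFP

__all__ = [
    "WaveFieldSpec",
    "TrialSetSpec",
    "EnsembleSpec",
    "EnsembleRasterSpec",
    "LaminarDipoleSpec",
    "BehaviorSpec",
    "generate_wave_lfp",
    "generate_trial_lfp",
    "generate_calcium_raster",
    "generate_laminar_lfp",
    "generate_whisker_traces",
    "grid_coords",
]


def grid_coords(grid_shape: tuple, pitch_mm: float) -> np.ndarray:
    """Electrode (x, y) positions in mm, row-major over a regular grid."""
    rows, cols = grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    return np.column_stack([xx.ravel() * pitch_mm, yy.ravel() * pitch_mm])


# ---------------------------------------------------------------------------
# Wave fields


@dataclass
class WaveFieldSpec:
    """A single planted oscillation propagating across the grid.

    The phase model is ``phi(x, t) = 2*pi*f0*t - k*d(x)`` with wavenumber
    ``k = 2*pi*f0/speed`` (rad/m); ``d`` is the signed projection onto the
    propagation direction for plane waves and the Euclidean distance from
    the source electrode for radial waves.
    """

    grid_shape: tuple = (8, 8)
    pitch_mm: float = 0.2
    fs: float = 1000.0
    duration: float = 2.0
    f0: float = 10.0
    speed: float = 0.3  # m/s
    geometry: str = "plane"  # or "radial"
    direction: float = 0.0  # radians, plane waves
    source: Optional[int] = None  # channel id, radial waves
    amplitude: float = 50.0  # uV
    noise_sd: float = 0.0  # uV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not (3.0 <= self.f0 <= 40.0):
            raise ValueError("f0 must lie in the wideband analysis range (3-40 Hz)")
        if min(self.grid_shape) < 2:
            raise ValueError("grid must be at least 2x2")
        if self.geometry not in ("plane", "radial"):
            raise ValueError("geometry must be 'plane' or 'radial'")

    @property
    def k(self) -> float:
        """Planted wavenumber, rad/m."""
        return 2.0 * np.pi * self.f0 / self.speed

    def distances_m(self, coords_mm: np.ndarray) -> np.ndarray:
        """Propagation distance per electrode, metres."""
        if self.geometry == "plane":
            u = np.array([np.cos(self.direction), np.sin(self.direction)])
            return (coords_mm @ u) * 1e-3
        src = self.source
        if src is None:
            rows, cols = self.grid_shape
            src = (rows // 2) * cols + cols // 2
        return np.linalg.norm(coords_mm - coords_mm[src], axis=1) * 1e-3


def generate_wave_lfp(spec: WaveFieldSpec) -> tuple:
    """Generate a grid LFP carrying the planted wave.

    Returns ``(GridLFP, ground_truth)`` where the ground truth dict records
    the planted speed, wavenumber, frequency and source/direction.
    """
    rng = np.random.default_rng(spec.seed)
    coords = grid_coords(spec.grid_shape, spec.pitch_mm)
    t = np.arange(int(round(spec.duration * spec.fs))) / spec.fs
    d = spec.distances_m(coords)
    phase = 2.0 * np.pi * spec.f0 * t[None, :] - spec.k * d[:, None]
    data = spec.amplitude * np.cos(phase)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    lfp = GridLFP(data, coords, spec.fs)
    src = spec.source
    if src is None and spec.geometry == "radial":
        rows, cols = spec.grid_shape
        src = (rows // 2) * cols + cols // 2
    truth = {
        "speed": spec.speed,
        "k": spec.k,
        "f0": spec.f0,
        "geometry": spec.geometry,
        "direction": spec.direction,
        "source": src,
        "distances_m": d,
    }
    return lfp, truth


# ---------------------------------------------------------------------------
# Trial structure


@dataclass
class TrialSetSpec:
    """Touch trials with early and late evoked components.

    ``early_amp``/``late_amp`` are per-trial amplitudes (uV); scalars are
    broadcast.  ``responsive_fraction`` controls which trials carry an
    early deflection at all.  Ground-truth strong/weak late labels mirror
    the analysis rule: strong iff the planted late amplitude exceeds three
    prestimulus noise SDs.
    """

    n_trials: int = 20
    trial_interval: float = 3.0  # s between touches
    early_amp: object = 80.0
    late_amp: object = 60.0
    early_latency: float = 0.02  # s
    late_window: tuple = (0.1, 0.2)  # s post-touch
    responsive_fraction: float = 1.0
    noise_sd: float = 5.0
    fs: float = 1000.0
    grid_shape: tuple = (8, 8)
    pitch_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.late_window[0] <= 0:
            raise ValueError("late_window must start after touch")
        self.early_amp = np.broadcast_to(
            np.asarray(self.early_amp, dtype=float), (self.n_trials,)
        ).copy()
        self.late_amp = np.broadcast_to(
            np.asarray(self.late_amp, dtype=float), (self.n_trials,)
        ).copy()
        if (self.early_amp < 0).any() or (self.late_amp < 0).any():
            raise ValueError("evoked amplitudes must be nonnegative")


def _evoked_bump(t: np.ndarray, t_on: float, t_off: float, amp: float) -> np.ndarray:
    """Smooth negative-going deflection (half-sine) between t_on and t_off."""
    out = np.zeros_like(t)
    m = (t >= t_on) & (t < t_off)
    out[m] = -amp * np.sin(np.pi * (t[m] - t_on) / (t_off - t_on))
    return out


def generate_trial_lfp(spec: TrialSetSpec, wave: Optional[WaveFieldSpec] = None) -> tuple:
    """Generate a long grid record with touch-locked evoked components.

    Returns ``(GridLFP, labels)`` with ``labels`` a DataFrame of
    touch_time_s, responsive (planted early component present),
    strong_late (planted late amplitude > 3 x noise SD).
    """
    rng = np.random.default_rng(spec.seed)
    touch_times = (1.0 + np.arange(spec.n_trials) * spec.trial_interval)
    duration = touch_times[-1] + 2.0
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs
    coords = grid_coords(spec.grid_shape, spec.pitch_mm)
    n_ch = coords.shape[0]

    n_resp = int(round(spec.responsive_fraction * spec.n_trials))
    responsive = np.zeros(spec.n_trials, dtype=bool)
    responsive[rng.choice(spec.n_trials, size=n_resp, replace=False)] = True

    sig = np.zeros(n)
    for i, tt in enumerate(touch_times):
        if responsive[i]:
            sig += _evoked_bump(
                t, tt + spec.early_latency, tt + spec.early_latency + 0.03, spec.early_amp[i]
            )
        lo, hi = spec.late_window
        sig += _evoked_bump(t, tt + lo, tt + hi, spec.late_amp[i])

    data = np.tile(sig, (n_ch, 1))
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    if wave is not None:
        carrier, _ = generate_wave_lfp(
            WaveFieldSpec(
                grid_shape=spec.grid_shape,
                pitch_mm=spec.pitch_mm,
                fs=spec.fs,
                duration=duration,
                f0=wave.f0,
                speed=wave.speed,
                geometry=wave.geometry,
                direction=wave.direction,
                source=wave.source,
                amplitude=wave.amplitude,
                noise_sd=0.0,
                seed=wave.seed,
            )
        )
        data = data + carrier.data[:, :n]

    labels = pd.DataFrame(
        {
            "touch_time_s": touch_times,
            "responsive": responsive,
            "strong_late": spec.late_amp > 3.0 * spec.noise_sd,
            "late_amp": spec.late_amp,
            "early_amp": spec.early_amp * responsive,
        }
    )
    return GridLFP(data, coords, spec.fs), labels


# ---------------------------------------------------------------------------
# Calcium rasters


@dataclass
class EnsembleSpec:
    """One planted co-active cell group.

    ``coactivation`` is the probability per non-overlapping 300-ms block
    that the group reactivates; on a reactivation, every member emits an
    event in the same (uniformly chosen) frame of the block.  The block
    matches the time scale on which ensemble analyses bin activity.
    """

    members: Sequence[int]
    coactivation: float = 0.3  # reactivation probability per 300-ms block
    amplitude: float = 1.0  # deconvolved event amplitude, dF/F units
    block_ms: float = 300.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coactivation <= 1.0):
            raise ValueError("coactivation must be in [0, 1]")


@dataclass
class EnsembleRasterSpec:
    """Calcium raster with planted ensembles over a Poisson background."""

    n_cells: int = 200
    n_frames: int = 2000
    frame_rate: float = 10.0
    ensembles: Sequence[EnsembleSpec] = field(default_factory=list)
    background_rate: float = 0.005  # events / frame / cell
    background_amplitude: float = 1.0  # dF/F units, like event amplitudes
    noise_sd: float = 0.1  # dF/F units
    calcium_tau: float = 0.5  # s, kernel decay
    seed: int = 0

    def __post_init__(self) -> None:
        for ens in self.ensembles:
            for m in ens.members:
                if not (0 <= m < self.n_cells):
                    raise ValueError(f"member id {m} out of range")


def generate_calcium_raster(spec: EnsembleRasterSpec) -> tuple:
    """Generate deconvolved events + ΔF/F with planted ensemble structure.

    Ensemble frames are drawn Bernoulli(coactivation) per 300-ms-scale
    frame; on an ensemble frame every member emits an event.  Background
    events are independent Bernoulli(background_rate).  ΔF/F is the event
    train convolved with an exponential kernel plus white noise.

    Returns ``(CalciumRaster, truth)`` with ``truth['members']`` the list of
    planted member-id lists and ``truth['ensemble_frames']`` the frames on
    which each ensemble co-fired.
    """
    rng = np.random.default_rng(spec.seed)
    deconv = np.zeros((spec.n_cells, spec.n_frames))
    bg = rng.random((spec.n_cells, spec.n_frames)) < spec.background_rate
    deconv[bg] = spec.background_amplitude

    ens_frames = []
    for ens in spec.ensembles:
        fpb = max(1, int(round(ens.block_ms / 1000.0 * spec.frame_rate)))
        n_blocks = spec.n_frames // fpb
        hit = rng.random(n_blocks) < ens.coactivation
        offsets = rng.integers(0, fpb, size=n_blocks)
        fr = (np.flatnonzero(hit) * fpb + offsets[hit]).astype(int)
        ens_frames.append(fr)
        for m in ens.members:
            deconv[m, fr] = ens.amplitude

    # exponential calcium kernel, unit peak
    n_k = max(1, int(round(5 * spec.calcium_tau * spec.frame_rate)))
    kern = np.exp(-np.arange(n_k) / (spec.calcium_tau * spec.frame_rate))
    dff = np.apply_along_axis(
        lambda row: np.convolve(row, kern)[: spec.n_frames], 1, deconv
    )
    if spec.noise_sd > 0:
        dff = dff + rng.normal(0.0, spec.noise_sd, size=dff.shape)

    centroids = rng.uniform(0, 500, size=(spec.n_cells, 2))
    raster = CalciumRaster(dff, deconv, centroids, spec.frame_rate)
    truth = {
        "members": [list(e.members) for e in spec.ensembles],
        "ensemble_frames": ens_frames,
        "background_mask": bg,
    }
    return raster, truth


# ---------------------------------------------------------------------------
# Laminar dipole


@dataclass
class LaminarDipoleSpec:
    """A sink/source pair along a linear probe.

    The generated potential is constructed so that its discrete second
    depth-difference reproduces the planted sink (negative) and source
    (positive) pattern, up to boundary channels.
    """

    n_channels: int = 16
    dz_um: float = 50.0
    sink_depth: int = 8
    source_depth: int = 12
    magnitude: float = 40.0  # uV scale of the planted curvature
    fs: float = 1000.0
    duration: float = 0.6
    touch_time: float = 0.2
    time_course: Optional[Callable] = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sink_depth == self.source_depth:
            raise ValueError("sink and source depths must differ")
        for d in (self.sink_depth, self.source_depth):
            if not (0 <= d < self.n_channels):
                raise ValueError("sink/source depth outside channel range")


def _default_time_course(t: np.ndarray) -> np.ndarray:
    """Alpha-function transient starting at t = 0 (post-touch), peak ~60 ms."""
    tau = 0.06
    out = np.where(t > 0, (t / tau) * np.exp(1 - t / tau), 0.0)
    return out


def generate_laminar_lfp(spec: LaminarDipoleSpec) -> tuple:
    """Generate a laminar LFP whose CSD localizes to the planted dipole.

    The depth profile is built by twice cumulatively summing a curvature
    profile that is negative at ``sink_depth`` and positive at
    ``source_depth`` (Gaussian spatial spread of one channel).
    """
    rng = np.random.default_rng(spec.seed)
    z = np.arange(spec.n_channels)
    curv = -np.exp(-0.5 * (z - spec.sink_depth) ** 2) + np.exp(
        -0.5 * (z - spec.source_depth) ** 2
    )
    # build the potential so its *central* second difference at channel i
    # equals curv[i]: p[i+1] = 2 p[i] - p[i-1] + curv[i]
    profile = np.zeros(spec.n_channels)
    for i in range(1, spec.n_channels - 1):
        profile[i + 1] = 2 * profile[i] - profile[i - 1] + curv[i]
    profile = profile - profile.mean()

    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    tc = (spec.time_course or _default_time_course)(t - spec.touch_time)
    data = spec.magnitude * profile[:, None] * tc[None, :]
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    truth = {
        "sink_depth": spec.sink_depth,
        "source_depth": spec.source_depth,
        "curvature": curv,
        "time_course": tc,
    }
    return LaminarLFP(data, spec.dz_um, spec.fs), truth


# ---------------------------------------------------------------------------
# Whisker behavior


@dataclass
class BehaviorSpec:
    """Sinusoidal whisking with touch episodes against a pole ROI."""

    whisk_freq: float = 8.0  # Hz
    whisk_amp: float = 40.0  # pixels at the tip
    frame_rate: float = 500.0
    duration: float = 2.0
    touch_episodes: Sequence[tuple] = field(default_factory=lambda: [(0.5, 0.6)])
    base_xy: tuple = (100.0, 200.0)
    whisker_len: float = 120.0  # pixels base->tip
    bend_px: float = 15.0  # lateral tip deflection during touch
    noise_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        eps = sorted(self.touch_episodes)
        for (a0, a1), (b0, b1) in zip(eps, eps[1:]):
            if b0 < a1:
                raise ValueError("touch episodes must not overlap")

    @property
    def roi_polygon(self) -> np.ndarray:
        """Rectangle around where the tip sits during a touch."""
        bx, by = self.base_xy
        tip_x = bx + self.whisker_len
        # sits just beyond free-whisking reach: only the planted bend
        # (touch) pushes the tip label inside
        y_lo = by + self.whisk_amp + 0.3 * self.bend_px
        return np.array(
            [
                [tip_x - 15, y_lo],
                [tip_x + 40, y_lo],
                [tip_x + 40, y_lo + 60],
                [tip_x - 15, y_lo + 60],
            ],
            dtype=float,
        )


def generate_whisker_traces(spec: BehaviorSpec) -> tuple:
    """Generate a 4-label pose table plus ground-truth touch frames.

    Outside touch episodes the four labels are collinear along the whisker
    shaft (Menger curvature 0); during an episode the tip label is driven
    into the ROI polygon and the distal labels bend off the shaft line.

    Returns ``(pose, truth)`` where ``pose`` is a DataFrame with columns
    (frame, label, x_px, y_px) and ``truth`` holds the per-frame touch
    mask, episode frame ranges and the planted whisking angle.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n) / spec.frame_rate
    angle = (spec.whisk_amp / spec.whisker_len) * np.sin(
        2 * np.pi * spec.whisk_freq * t
    )

    touch_mask = np.zeros(n, dtype=bool)
    for a, b in spec.touch_episodes:
        touch_mask[(t >= a) & (t < b)] = True
    # during touch the whisker is pinned protracted against the pole
    angle_eff = np.where(touch_mask, spec.whisk_amp / spec.whisker_len, angle)

    bx, by = spec.base_xy
    fracs = np.array([0.0, 1 / 3, 2 / 3, 1.0])  # labels base -> tip
    rows = []
    for li, fr in enumerate(fracs):
        r = fr * spec.whisker_len
        x = bx + r * np.cos(angle_eff)
        y = by + r * np.sin(angle_eff)
        # bending: lateral quadratic deviation, largest at the tip
        y = y + touch_mask * spec.bend_px * fr**2
        if spec.noise_px > 0:
            x = x + rng.normal(0, spec.noise_px, size=n)
            y = y + rng.normal(0, spec.noise_px, size=n)
        rows.append(
            pd.DataFrame({"frame": np.arange(n), "label": li, "x_px": x, "y_px": y})
        )
    pose = pd.concat(rows, ignore_index=True).sort_values(["frame", "label"]).reset_index(drop=True)
    episodes_frames = [
        (int(np.ceil(a * spec.frame_rate)), int(np.ceil(b * spec.frame_rate)))
        for a, b in spec.touch_episodes
    ]
    truth = {
        "touch_mask": touch_mask,
        "episode_frames": episodes_frames,
        "angle": angle_eff,
        "roi_polygon": spec.roi_polygon,
    }
    return pose, truth
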