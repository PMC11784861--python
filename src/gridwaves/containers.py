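"""Core in-memory containers shared across the pipeline.

Every analysis stage consumes and produces one of a small set of
dataclasses: multichannel surface LFP with electrode geometry
(:class:`GridLFP`), laminar probe LFP (:class:`LaminarLFP`), two-photon
calcium rasters (:class:`CalciumRaster`), the analytic-signal phase field
(:class:`AnalyticField`), trial epoching metadata (:class:`TrialEpochs`),
detected traveling waves (:class:`WaveEvent`), and simulator output
(:class:`SpikeRecord`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GridLFP",
    "LaminarLFP",
    "CalciumRaster",
    "AnalyticField",
    "TrialEpochs",
    "WaveEvent",
    "SpikeRecord",
    "wave_events_to_frame",
]


@dataclass
class GridLFP:
    """Surface-grid local field potential.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potential in microvolts.
    coords : ndarray, shape (n_channels, 2)
        Electrode (x, y) positions in millimetres.
    fs : float
        Sampling rate, Hz.
    t0 : float
        Time of the first sample, seconds.
    """

    data: np.ndarray
    coords: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.coords.shape != (self.data.shape[0], 2):
            raise ValueError("coords must be (n_channels, 2)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != self.coords.shape[0]:
            raise ValueError("electrode coordinates must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, **kw) -> "GridLFP":
        return replace(self, **kw)


@dataclass
class LaminarLFP:
    """Linear-probe LFP ordered superficial to deep.

    ``dz_um`` is the uniform contact spacing in micrometres.
    """

    data: np.ndarray
    dz_um: float
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 5:
            raise ValueError("laminar analysis needs >= 5 channels")
        if self.dz_um <= 0 or self.fs <= 0:
            raise ValueError("dz_um and fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) / self.fs


@dataclass
class CalciumRaster:
    """Two-photon calcium data: ΔF/F plus deconvolved event amplitudes.

    ``dff`` and ``deconv`` are (n_cells, n_frames); ``centroids`` holds ROI
    centres in micrometres.
    """

    dff: np.ndarray
    deconv: np.ndarray
    centroids: np.ndarray
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.deconv = np.asarray(self.deconv, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.dff.shape != self.deconv.shape:
            raise ValueError("dff and deconv must have identical shape")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


@dataclass
class AnalyticField:
    """Instantaneous phase/amplitude/frequency of a grid recording.

    ``phase`` is wrapped to (-pi, pi]; ``freq`` is in Hz from the forward
    difference of the unwrapped phase; ``mask`` is True on samples where the
    phase is unreliable (zero-amplitude channels, negative-frequency
    intrusions before correction, filter edges).
    """

    phase: np.ndarray
    amplitude: np.ndarray
    freq: np.ndarray
    mask: np.ndarray
    coords: np.ndarray
    fs: float
    t0: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class TrialEpochs:
    """Touch-aligned trial metadata and the responsiveness mask."""

    touch_times: np.ndarray
    window: tuple
    responsive_mask: np.ndarray
    baseline_sd: np.ndarray
    reference_channel: int
    dropped: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.touch_times)


@dataclass
class WaveEvent:
    """One detected traveling wave and its kinematics.

    ``rho`` is the circular-linear phase-distance correlation in [0, 1];
    ``k`` the wavenumber (rad/m); ``f`` the instantaneous frequency (Hz);
    ``v = 2*pi*f / k`` the speed (m/s); ``amplitude`` the LFP value at the
    next zero-phase crossing on the trigger channel.
    """

    t_eval: float
    source_channel: int
    source_xy: tuple
    rho: float
    k: float
    f: float
    v: float
    amplitude: float
    band: str = "wideband"
    epoch: str = "unassigned"

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.f


@dataclass
class SpikeRecord:
    """Spiking-simulation output.

    ``spikes`` is an (n_spikes, 2) float array of (time s, neuron id);
    ``sim_lfp`` the pooled synaptic signal as a :class:`GridLFP`-compatible
    (n_pools, n_samples) array with pool centre coordinates.
    """

    spikes: np.ndarray
    positions: np.ndarray
    is_excitatory: np.ndarray
    sim_lfp: Optional[np.ndarray] = None
    lfp_coords: Optional[np.ndarray] = None
    lfp_fs: float = 1000.0
    duration: float = 0.0

    def spike_trains(self) -> dict:
        out: dict = {}
        for t, i in self.spikes:
            out.setdefault(int(i), []).append(t)
        return {i: np.asarray(v) for i, v in out.items()}

    def as_grid_lfp(self) -> GridLFP:
        if self.sim_lfp is None:
            raise ValueError("no simulated LFP was recorded")
        return GridLFP(self.sim_lfp, self.lfp_coords, self.lfp_fs)


def wave_events_to_frame(events: list) -> pd.DataFrame:
    """Tabulate a list of :class:`WaveEvent` as the canonical TSV schema."""
    rows = [
        {
            "t_eval_s": e.t_eval,
            "source_ch": e.source_channel,
            "rho": e.rho,
            "k_rad_per_m": e.k,
            "f_hz": e.f,
            "v_m_per_s": e.v,
            "amp_uv": e.amplitude,
            "band": e.band,
            "epoch": e.epoch,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "t_eval_s",
            "source_ch",
            "rho",
            "k_rad_per_m",
            "f_hz",
            "v_m_per_s",
            "amp_uv",
            "band",
            "epoch",
        ],
    )
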