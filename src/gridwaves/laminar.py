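"""Laminar-probe analyses: CSD, spectrograms, band power and depth profiles.

The current source density is the second spatial derivative of the
laminar LFP, ``I = d2V/dz2``, estimated with an ``n``-step central
difference and Vaknin padding (duplicated boundary channels) so the full
shank length is covered.  Sinks are negative, sources positive.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pywt

from .containers import LaminarLFP
from .preprocess import BANDS

logger = logging.getLogger(__name__)

__all__ = [
    "csd",
    "time_frequency",
    "band_power_ratios",
    "relative_power_profile",
    "sink_bootstrap",
]


def csd(lfp: Union[LaminarLFP, np.ndarray], n: int = 2,
        dz_um: Optional[float] = None, vaknin: bool = True) -> np.ndarray:
    """Current source density via the n-step second spatial difference.

    ``I_i = (V_{i+n} + V_{i-n} - 2 V_i) / (n*dz)^2`` with the step
    ``s = n*dz`` taken as the differencing distance, so the estimate
    converges to d2V/dz2 for any ``n``.  With ``vaknin=True`` the top and
    bottom channels are duplicated ``n`` times so the output covers every
    input channel.  Units: uV / um^2 (with dz in micrometres).
    """
    if isinstance(lfp, LaminarLFP):
        data, dz = lfp.data, lfp.dz_um
    else:
        data = np.atleast_2d(np.asarray(lfp, dtype=float))
        if dz_um is None:
            raise ValueError("dz_um required when passing a bare array")
        dz = dz_um
    n_ch = data.shape[0]
    if n_ch < 2 * n + 1:
        raise ValueError(f"need >= {2 * n + 1} channels for n = {n}")
    if vaknin:
        pad_top = np.repeat(data[:1], n, axis=0)
        pad_bot = np.repeat(data[-1:], n, axis=0)
        padded = np.concatenate([pad_top, data, pad_bot], axis=0)
    else:
        padded = data
    s = n * dz
    out = (padded[2 * n:] + padded[:-2 * n] - 2 * padded[n:-n]) / s**2
    return out


def time_frequency(signal: np.ndarray, fs: float,
                   freqs: Optional[np.ndarray] = None,
                   f_range: tuple = (0.1, 100.0), n_freqs: int = 60,
                   wavelet: str = "cmor1.5-1.0") -> tuple:
    """Continuous-wavelet magnitude spectrogram of a single trace.

    Returns (spectrogram, freqs) with spectrogram shape (n_freqs,
    n_samples).  Frequencies whose wavelet support exceeds the record are
    dropped with a warning.
    """
    x = np.asarray(signal, dtype=float)
    if freqs is None:
        freqs = np.geomspace(f_range[0], f_range[1], n_freqs)
    fc = pywt.central_frequency(wavelet)
    # require ~2 cycles of support inside the record
    min_f = 2.0 * fs / len(x)
    keep = freqs >= min_f
    if not keep.all():
        logger.warning("record too short below %.3f Hz; truncating range", min_f)
        freqs = freqs[keep]
    scales = fc * fs / freqs
    coefs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    return np.abs(coefs), freqs


def band_power_ratios(spectrogram: np.ndarray, freqs: np.ndarray, fs: float,
                      windows: dict, t0: float = 0.0) -> dict:
    """Beta/gamma and theta/gamma summed-power ratios per time window.

    ``windows`` maps labels (e.g. 'early', 'late') to (start, end) seconds
    on the spectrogram time base.  Total power is the sum of spectrogram
    values over the band rows and window columns.
    """
    out = {}
    n = spectrogram.shape[1]
    for label, (a, b) in windows.items():
        i0 = int(round((a - t0) * fs))
        i1 = int(round((b - t0) * fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(f"window {label} = ({a}, {b}) outside record")
        seg = spectrogram[:, i0:i1]
        power = {}
        for band in ("theta", "beta", "gamma"):
            lo, hi = BANDS[band]
            rows = (freqs >= lo) & (freqs <= hi)
            power[band] = float(seg[rows].sum())
        gamma = power["gamma"]
        out[label] = {
            "beta_gamma": power["beta"] / gamma if gamma > 0 else float("inf"),
            "theta_gamma": power["theta"] / gamma if gamma > 0 else float("inf"),
            "power": power,
        }
    return out


def relative_power_profile(laminar: LaminarLFP, window: tuple = (-0.1, 0.2),
                           touch_time: float = 0.0,
                           nperseg: Optional[int] = None,
                           f_max: float = 100.0) -> tuple:
    """Depth-by-frequency relative power, each frequency column max-normed.

    Welch PSDs are computed per channel over ``window`` around
    ``touch_time`` and each frequency column is divided by its maximum
    over channels, so exactly one channel per frequency reaches 1.
    Zero-power columns are masked to NaN.

    Returns (profile, freqs) with profile shape (n_channels, n_freqs).
    """
    from scipy.signal import welch

    i0 = int(round((touch_time + window[0] - laminar.t0) * laminar.fs))
    i1 = int(round((touch_time + window[1] - laminar.t0) * laminar.fs))
    i0 = max(i0, 0)
    seg = laminar.data[:, i0:i1]
    if nperseg is None:
        nperseg = min(seg.shape[1], 256)
    freqs, psd = welch(seg, fs=laminar.fs, nperseg=nperseg, axis=1)
    keep = freqs <= f_max
    freqs, psd = freqs[keep], psd[:, keep]
    colmax = psd.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(colmax > 0, psd / colmax, np.nan)
    return profile, freqs


def sink_bootstrap(trials: np.ndarray, labels: Sequence[str], fs: float,
                   dz_um: float, touch_index: int,
                   late_window: tuple = (0.1, 0.2),
                   superficial_channels: Optional[Sequence[int]] = None,
                   n_iter: int = 50, n_per_draw: int = 20, n_csd: int = 2,
                   seed: int = 0) -> dict:
    """Bootstrap the late superficial sink with and without the late wave.

    ``trials`` is (n_trials, n_channels, n_samples); ``labels`` the
    per-trial 'strong'/'weak' late-wave class.  Each iteration resamples
    ``n_per_draw`` trials per class (with replacement; groups smaller than
    the draw are logged), averages the LFP, computes the CSD and measures
    the sink magnitude — the minimum (most negative) CSD over the
    configured superficial channels inside the late window.  Returns
    per-class sink-magnitude distributions.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    i0 = touch_index + int(round(late_window[0] * fs))
    i1 = touch_index + int(round(late_window[1] * fs))
    n_ch = trials.shape[1]
    if superficial_channels is None:
        superficial_channels = np.arange(n_ch // 3 + 1)
    superficial_channels = np.asarray(superficial_channels)
    out = {}
    for group in np.unique(labels):
        idx = np.flatnonzero(labels == group)
        if idx.size < n_per_draw:
            logger.info("group %s smaller than draw (%d < %d); sampling with replacement",
                        group, idx.size, n_per_draw)
        mags = np.empty(n_iter)
        for it in range(n_iter):
            draw = rng.choice(idx, size=n_per_draw, replace=True)
            mean_lfp = trials[draw].mean(axis=0)
            c = csd(mean_lfp, n=n_csd, dz_um=dz_um)
            mags[it] = c[np.ix_(superficial_channels, np.arange(i0, i1))].min()
        out[str(group)] = mags
    return out
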