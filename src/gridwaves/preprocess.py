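"""Filtering, artifact removal, downsampling and trial epoching.

All filters are zero-phase (forward-backward) Butterworth designs applied
as second-order sections for numerical robustness.  Canonical analysis
bands: wideband 3-40 Hz (wave detection), gamma 30-90 Hz, beta 15-30 Hz,
theta 4-12 Hz.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal

from .containers import GridLFP, TrialEpochs

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "bandpass",
    "remove_scan_artifact",
    "downsample",
    "epoch_and_filter_trials",
    "reference_channel",
]

#: named analysis bands, Hz
BANDS = {
    "wideband": (3.0, 40.0),
    "gamma": (30.0, 90.0),
    "beta": (15.0, 30.0),
    "theta": (4.0, 12.0),
}


def _resolve_band(band: Union[str, Tuple[float, float]]) -> Tuple[float, float]:
    if isinstance(band, str):
        return BANDS[band]
    return float(band[0]), float(band[1])


def bandpass(lfp: GridLFP, band: Union[str, Tuple[float, float]] = "wideband",
             order: int = 4) -> GridLFP:
    """Zero-phase Butterworth bandpass of every channel.

    ``band`` may be a named band ('wideband', 'gamma', 'beta', 'theta') or
    an explicit (lo, hi) in Hz.  The default order-4 design is applied
    forward and backward, so the effective magnitude response is squared
    and the phase response is identically zero.
    """
    lo, hi = _resolve_band(band)
    nyq = lfp.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=lfp.fs, output="sos")
    out = signal.sosfiltfilt(sos, lfp.data, axis=1)
    return lfp.copy_with(data=out)


def remove_scan_artifact(lfp: GridLFP, base_freq: float = 30.0,
                         max_freq: float = 360.0, q_order: int = 6,
                         bandwidth: float = 2.0) -> GridLFP:
    """Notch out the resonant-scanning artifact at 30 Hz and harmonics.

    A bank of zero-phase order-``q_order`` Butterworth band-stop filters is
    applied at ``base_freq``, 2x, ... up to ``max_freq`` (default 30..360
    Hz).  ``bandwidth`` is the half-width of each stop band in Hz.
    """
    if lfp.fs <= 2 * max_freq:
        raise ValueError("sampling rate too low for the requested notch bank")
    out = lfp.data
    f = base_freq
    while f <= max_freq + 1e-9:
        sos = signal.butter(
            q_order, [f - bandwidth, f + bandwidth], btype="bandstop",
            fs=lfp.fs, output="sos",
        )
        out = signal.sosfiltfilt(sos, out, axis=1)
        f += base_freq
    return lfp.copy_with(data=out)


def downsample(lfp: GridLFP, target_fs: float) -> GridLFP:
    """Anti-aliased decimation to ``target_fs`` (polyphase resampling)."""
    if target_fs > lfp.fs:
        raise ValueError("target_fs must not exceed the current rate")
    if target_fs == lfp.fs:
        return lfp.copy_with()
    from fractions import Fraction

    frac = Fraction(target_fs / lfp.fs).limit_denominator(10000)
    out = signal.resample_poly(lfp.data, frac.numerator, frac.denominator, axis=1)
    return lfp.copy_with(data=out, fs=lfp.fs * frac.numerator / frac.denominator)


def reference_channel(lfp: GridLFP, touch_times: Sequence[float],
                      post: float = 0.07) -> int:
    """Channel with the largest mean evoked |deflection| within ``post`` s.

    Used as the deterministic representative electrode for trial inclusion
    and late-wave sorting.
    """
    amps = np.zeros(lfp.n_channels)
    n_post = int(round(post * lfp.fs))
    for tt in touch_times:
        i0 = int(round((tt - lfp.t0) * lfp.fs))
        if i0 < 0 or i0 + n_post > lfp.n_samples:
            continue
        seg = lfp.data[:, i0:i0 + n_post]
        amps += np.abs(seg - seg.mean(axis=1, keepdims=True)).max(axis=1)
    return int(np.argmax(amps))


def epoch_and_filter_trials(lfp: GridLFP, touch_times: Sequence[float],
                            pre: float = 0.5, post: float = 0.07,
                            threshold_sd: float = 3.0,
                            ref_channel: Optional[int] = None) -> TrialEpochs:
    """Apply the trial-inclusion rule: keep trials with a detectable LFP.

    A trial is *responsive* when the touch-evoked deflection within
    ``post`` seconds of touch (baseline-mean subtracted, measured on the
    wideband signal handed in) exceeds ``threshold_sd`` times the SD of the
    ``pre``-second prestimulus window, on the reference channel.  Trials
    whose windows fall outside the record are dropped with a log entry.
    """
    touch_times = np.asarray(list(touch_times), dtype=float)
    if touch_times.size == 0:
        raise ValueError("need at least one touch time")
    if ref_channel is None:
        ref_channel = reference_channel(lfp, touch_times, post=post)

    n_pre = int(round(pre * lfp.fs))
    n_post = int(round(post * lfp.fs))
    keep, dropped = [], []
    for j, tt in enumerate(touch_times):
        i0 = int(round((tt - lfp.t0) * lfp.fs))
        if i0 - n_pre < 0 or i0 + n_post > lfp.n_samples:
            dropped.append(j)
            logger.info("trial %d at t=%.3fs dropped: window outside record", j, tt)
        else:
            keep.append(j)

    kept_times = touch_times[keep]
    responsive = np.zeros(len(keep), dtype=bool)
    baseline_sd = np.zeros((len(keep), lfp.n_channels))
    for m, tt in enumerate(kept_times):
        i0 = int(round((tt - lfp.t0) * lfp.fs))
        base = lfp.data[:, i0 - n_pre:i0]
        baseline_sd[m] = base.std(axis=1)
        evoked = lfp.data[ref_channel, i0:i0 + n_post] - base[ref_channel].mean()
        responsive[m] = np.abs(evoked).max() > threshold_sd * baseline_sd[m, ref_channel]

    return TrialEpochs(
        touch_times=kept_times,
        window=(pre, post),
        responsive_mask=responsive,
        baseline_sd=baseline_sd,
        reference_channel=int(ref_channel),
        dropped=dropped,
    )
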