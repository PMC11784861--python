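"""Whisker kinematics, touch detection and behavioral discriminability.

Operates on pose tables (frame, label, x_px, y_px) with four labels per
whisker ordered base to tip, recorded at 500 fps.  Whisker bending is the
Menger curvature of the three distal labels; touches are entries of the
tip label into a region of interest around the touch surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import norm

__all__ = [
    "whisker_angle",
    "whisker_phase",
    "menger_curvature",
    "curvature_series",
    "detect_touches",
    "filter_touch_intervals",
    "dprime",
    "classify_outcomes",
]


def _pose_arrays(pose: pd.DataFrame) -> np.ndarray:
    """Pose table -> (n_frames, n_labels, 2) array."""
    labels = np.sort(pose["label"].unique())
    frames = np.sort(pose["frame"].unique())
    piv_x = pose.pivot_table(index="frame", columns="label", values="x_px")
    piv_y = pose.pivot_table(index="frame", columns="label", values="y_px")
    out = np.stack([piv_x.to_numpy(), piv_y.to_numpy()], axis=-1)
    assert out.shape == (len(frames), len(labels), 2)
    return out


def whisker_angle(pose: pd.DataFrame, pad_reference: tuple) -> np.ndarray:
    """Whisker angular position per frame, radians.

    Angle of the tip label relative to the reference point on the whisker
    pad.  Frames with missing labels yield NaN.
    """
    arr = _pose_arrays(pose)
    tip = arr[:, -1, :]
    ref = np.asarray(pad_reference, dtype=float)
    return np.arctan2(tip[:, 1] - ref[1], tip[:, 0] - ref[0])


def whisker_phase(pose_or_angle, frame_rate: float = 500.0,
                  band: tuple = (1.0, 30.0),
                  pad_reference: tuple = (0.0, 0.0)) -> np.ndarray:
    """Instantaneous whisking phase from the band-filtered whisker angle.

    The angle is bandpass-filtered 1-30 Hz (zero-phase) and the phase
    taken from its analytic signal.  Convention: phase 0 at maximal
    protraction (angle maxima), +/-pi at maximal retraction.
    """
    if isinstance(pose_or_angle, pd.DataFrame):
        angle = whisker_angle(pose_or_angle, pad_reference)
    else:
        angle = np.asarray(pose_or_angle, dtype=float)
    good = np.isfinite(angle)
    filled = angle.copy()
    if not good.all():
        filled[~good] = np.interp(np.flatnonzero(~good), np.flatnonzero(good),
                                  angle[good])
    sos = sp_signal.butter(4, band, btype="bandpass", fs=frame_rate, output="sos")
    filt = sp_signal.sosfiltfilt(sos, filled - filled.mean())
    phase = np.angle(sp_signal.hilbert(filt))
    phase[~good] = np.nan
    return phase


def menger_curvature(x, y, z) -> float:
    """Menger curvature of three points: 4*Area / product of side lengths.

    The inverse circumradius of the triangle (x, y, z); 0 for collinear
    points, NaN when two points coincide.  Units 1/pixels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    a = np.linalg.norm(x - y)
    b = np.linalg.norm(y - z)
    c = np.linalg.norm(z - x)
    if a == 0 or b == 0 or c == 0:
        return float("nan")
    cross = (y[0] - x[0]) * (z[1] - x[1]) - (y[1] - x[1]) * (z[0] - x[0])
    area = 0.5 * abs(cross)
    return 4.0 * area / (a * b * c)


def curvature_series(pose: pd.DataFrame) -> np.ndarray:
    """Per-frame Menger curvature of the three distal labels."""
    arr = _pose_arrays(pose)
    out = np.empty(arr.shape[0])
    for i in range(arr.shape[0]):
        out[i] = menger_curvature(arr[i, -3], arr[i, -2], arr[i, -1])
    return out


def _point_in_polygon(pt: np.ndarray, poly: np.ndarray) -> bool:
    """Even-odd ray casting."""
    x, y = pt
    inside = False
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            xi = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            if x < xi:
                inside = not inside
    return inside


def detect_touches(pose: pd.DataFrame, roi_polygon: np.ndarray,
                   label: int = None) -> pd.DataFrame:
    """Touch frames: first frame of each entry of the tip label into the ROI.

    Consecutive in-ROI frames form one touch episode (debounced); the
    table lists one row per episode with its onset frame and duration.
    """
    arr = _pose_arrays(pose)
    li = -1 if label is None else label
    tip = arr[:, li, :]
    poly = np.asarray(roi_polygon, dtype=float)
    finite = np.isfinite(tip).all(axis=1)
    inside = np.zeros(arr.shape[0], dtype=bool)
    for i in np.flatnonzero(finite):
        inside[i] = _point_in_polygon(tip[i], poly)
    if not inside.any():
        return pd.DataFrame(columns=["touch_frame", "duration_frames"]).astype(int)
    padded = np.concatenate([[False], inside, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return pd.DataFrame({"touch_frame": starts, "duration_frames": ends - starts})


def filter_touch_intervals(touches: pd.DataFrame, frame_rate: float = 500.0,
                           min_interval_ms: float = 100.0) -> pd.DataFrame:
    """Keep the first touch and touches > ``min_interval_ms`` after the last kept.

    Removes rapid consecutive touches that would confound late-wave
    analysis.  Idempotent.
    """
    if len(touches) == 0:
        return touches.copy()
    frames = touches["touch_frame"].to_numpy()
    min_gap = min_interval_ms / 1000.0 * frame_rate
    keep = [0]
    for i in range(1, len(frames)):
        if frames[i] - frames[keep[-1]] > min_gap:
            keep.append(i)
    return touches.iloc[keep].reset_index(drop=True)


def dprime(hit_rate: float, fa_rate: float, n_trials: int = None) -> float:
    """Signal-detection discriminability D' = Z(hit) - Z(false alarm).

    ``Z`` is the standard-normal quantile function.  Rates of exactly 0 or
    1 are clamped to 1/(2N) and 1 - 1/(2N) (N = ``n_trials``, default 100)
    so D' stays finite.
    """
    n = n_trials if n_trials else 100
    eps = 1.0 / (2 * n)
    h = min(max(hit_rate, eps), 1 - eps)
    f = min(max(fa_rate, eps), 1 - eps)
    return float(norm.ppf(h) - norm.ppf(f))


def classify_outcomes(stimuli, licks, windows) -> pd.DataFrame:
    """Go/no-go outcome table from stimuli and lick times.

    ``stimuli`` is a sequence of 'go'/'nogo'; ``licks`` a flat array of
    lick times; ``windows`` the per-trial (start, end) response window
    (the 1.3-s sampling period).  go+lick = hit, go+no-lick = miss,
    no-go+lick = FA, no-go+no-lick = CR.
    """
    licks = np.sort(np.asarray(licks, dtype=float))
    rows = []
    for stim, (a, b) in zip(stimuli, windows):
        licked = bool(np.any((licks >= a) & (licks <= b)))
        if stim == "go":
            outcome = "hit" if licked else "miss"
        else:
            outcome = "fa" if licked else "cr"
        rows.append({"stimulus": stim, "licked": licked, "outcome": outcome})
    return pd.DataFrame(rows)
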