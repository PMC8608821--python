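"""Signal conditioning and concentric-phase segmentation.

Pipeline order is fixed: the full sEMG record is band-pass filtered first,
then segmented — filtering per segment would bias features at the segment
boundaries.  The digital chain assumes the hardware anti-alias low-pass
(750 Hz) has already been applied by the acquisition system and does not
reapply it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContractionSegment, EmgRecording, MechRecording

__all__ = [
    "EmgRecording",
    "MechRecording",
    "ContractionSegment",
    "bandpass_emg",
    "smooth_mechanical",
    "compute_power",
    "segment_concentric",
    "peak_power_per_rep",
    "read_mech",
    "read_emg",
]

#: sEMG analysis band (Hz): high-pass edge removes motion artifact and
#: baseline drift, low-pass edge bounds the surface-EMG spectrum.
EMG_BAND_HZ = (20.0, 250.0)


def _band_sos(fs_Hz: float, low_Hz: float, high_Hz: float,
              hp_order: int, lp_order: int) -> np.ndarray:
    hp = signal.butter(hp_order, low_Hz, btype="highpass", fs=fs_Hz, output="sos")
    lp = signal.butter(lp_order, high_Hz, btype="lowpass", fs=fs_Hz, output="sos")
    return np.vstack([hp, lp])


def bandpass_emg(
    rec: EmgRecording,
    low_Hz: float = EMG_BAND_HZ[0],
    high_Hz: float = EMG_BAND_HZ[1],
    hp_order: int = 5,
    lp_order: int = 10,
) -> EmgRecording:
    """Band-pass the raw sEMG to the 20–250 Hz analysis band.

    The band is realized as a 5th-order Butterworth high-pass cascaded
    with a 10th-order Butterworth low-pass, applied forward-backward
    (zero phase, so the effective attenuation order doubles).  Output
    length equals input length.
    """
    if rec.fs_Hz < 2 * high_Hz:
        raise ValueError("sampling rate must be at least twice the upper band edge")
    sos = _band_sos(rec.fs_Hz, low_Hz, high_Hz, hp_order, lp_order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.samples.size <= padlen:
        raise ValueError(
            f"record too short for filter warm-up (need > {padlen} samples)"
        )
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return EmgRecording(rec.channel_label, filtered, rec.fs_Hz)


def smooth_mechanical(series: np.ndarray, window_samples: int = 11) -> np.ndarray:
    """Adjacent-averaging smoother: centered moving average with shrinking
    windows at the edges; length is preserved.  The window must be odd so
    the average is centered on the sample it replaces.
    """
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError("window_samples must be a positive odd integer")
    x = np.asarray(series, dtype=float)
    if window_samples == 1 or x.size == 0:
        return x.copy()
    return (
        pd.Series(x)
        .rolling(window_samples, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def compute_power(torque_Nm: np.ndarray, velocity_deg_s: np.ndarray) -> np.ndarray:
    """Instantaneous joint power in watts: torque × angular velocity with
    the velocity converted from °/s to rad/s.  Sign follows the velocity
    sign (positive concentric, negative eccentric under extensor torque).
    """
    tq = np.asarray(torque_Nm, dtype=float)
    vel = np.asarray(velocity_deg_s, dtype=float)
    if tq.shape != vel.shape:
        raise ValueError("torque and velocity must have equal length")
    return tq * vel * np.pi / 180.0


def segment_concentric(
    mech: MechRecording,
    min_duration_s: float = 0.2,
    velocity_floor: float | None = None,
    smooth_window: int = 11,
) -> list[ContractionSegment]:
    """Identify concentric phases as contiguous runs of positive smoothed
    angular velocity (the positive bell of each cycle).

    A run qualifies when the smoothed velocity exceeds ``velocity_floor``
    (default: 5 % of the trial's 95th-percentile velocity) for at least
    ``min_duration_s``.  Repetition indices are assigned in temporal
    order; an empty list (no qualifying run) is not an error.
    """
    vel = smooth_mechanical(mech.velocity_deg_s, smooth_window)
    if velocity_floor is None:
        ref = float(np.percentile(vel, 95))
        velocity_floor = 0.05 * max(ref, 0.0)
    fs = mech.fs_Hz
    min_len = max(1, int(round(min_duration_s * fs)))

    above = vel > velocity_floor
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above.size and above[0]:
        starts = np.insert(starts, 0, 0)
    if above.size and above[-1]:
        ends = np.append(ends, above.size)

    segments: list[ContractionSegment] = []
    rep = 1
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            segments.append(ContractionSegment(rep_index=rep, start_idx=int(s), end_idx=int(e)))
            rep += 1
    return segments


def peak_power_per_rep(
    power_W: np.ndarray, segments: list[ContractionSegment]
) -> np.ndarray:
    """Peak (maximum) power within each concentric segment, ordered by
    repetition index."""
    p = np.asarray(power_W, dtype=float)
    ordered = sorted(segments, key=lambda s: s.rep_index)
    peaks = np.empty(len(ordered))
    for i, seg in enumerate(ordered):
        if seg.end_idx > p.size:
            raise ValueError(f"segment {seg.rep_index} exceeds the power trace")
        peaks[i] = float(np.max(p[seg.slice()]))
    return peaks


# ---------------------------------------------------------------------------
# delimited-text I/O for the simulator's trial files
# ---------------------------------------------------------------------------

def read_mech(path: str | Path) -> MechRecording:
    df = pd.read_csv(path, comment="#")
    return MechRecording.from_frame(df)


def read_emg(path: str | Path, channel: str | None = None) -> EmgRecording:
    df = pd.read_csv(path, comment="#")
    channels = [c for c in df.columns if c != "time_s"]
    if not channels:
        raise ValueError(f"no EMG channel columns in {path}")
    label = channel or channels[0]
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return EmgRecording(channel_label=label, samples=df[label].to_numpy(), fs_Hz=fs)
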