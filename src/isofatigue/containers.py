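"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* sample indices are 0-based and segments are half-open ``[start, end)``;
* repetition indices are 1-based (repetition 1 is the first contraction);
* EMG amplitudes are in microvolts, mechanics in SI-derived dynamometer
  units (N·m, degrees, °/s, watts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmgRecording",
    "MechRecording",
    "ContractionSegment",
    "GroundTruth",
]


@dataclass
class EmgRecording:
    """One muscle channel of surface EMG.

    Parameters
    ----------
    channel_label
        Muscle name, e.g. ``"medial_gastrocnemius"``.
    samples
        Amplitude series in microvolts.
    fs_Hz
        Sampling rate in hertz (1500 Hz for the dynamometer protocol
        emulated here).
    """

    channel_label: str
    samples: np.ndarray
    fs_Hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_Hz <= 0:
            raise ValueError("fs_Hz must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_Hz


@dataclass
class MechRecording:
    """Synchronized mechanical traces of one endurance trial.

    ``power_W`` is derived as torque × angular velocity (rad/s); it is
    recomputed on construction when not supplied.
    """

    time_s: np.ndarray
    torque_Nm: np.ndarray
    angle_deg: np.ndarray
    velocity_deg_s: np.ndarray
    power_W: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.torque_Nm = np.asarray(self.torque_Nm, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.velocity_deg_s = np.asarray(self.velocity_deg_s, dtype=float)
        n = self.time_s.size
        for name in ("torque_Nm", "angle_deg", "velocity_deg_s"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match time_s")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if self.power_W is None:
            self.power_W = self.torque_Nm * self.velocity_deg_s * np.pi / 180.0
        else:
            self.power_W = np.asarray(self.power_W, dtype=float)
            if self.power_W.size != n:
                raise ValueError("power_W length does not match time_s")

    @property
    def fs_Hz(self) -> float:
        if self.time_s.size < 2:
            raise ValueError("need at least two samples to infer a rate")
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "torque_Nm": self.torque_Nm,
                "angle_deg": self.angle_deg,
                "velocity_deg_s": self.velocity_deg_s,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MechRecording":
        return cls(
            time_s=df["time_s"].to_numpy(),
            torque_Nm=df["torque_Nm"].to_numpy(),
            angle_deg=df["angle_deg"].to_numpy(),
            velocity_deg_s=df["velocity_deg_s"].to_numpy(),
        )


@dataclass(frozen=True, order=True)
class ContractionSegment:
    """Index range of one concentric (positive-velocity) phase."""

    rep_index: int
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if self.rep_index < 1:
            raise ValueError("rep_index starts at 1")
        if not 0 <= self.start_idx < self.end_idx:
            raise ValueError("need 0 <= start_idx < end_idx")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx

    def slice(self) -> slice:
        return slice(self.start_idx, self.end_idx)


@dataclass
class GroundTruth:
    """Per-repetition truth of a simulated endurance trial.

    ``termination_index`` is the 1-based repetition at which the
    dynamometer's 75 %-of-baseline indicator would fire (equal to the
    number of repetitions when it never fires).
    """

    peak_power_W: np.ndarray
    mnf_Hz: np.ndarray
    rms_scale_uV: np.ndarray
    termination_index: int

    def __post_init__(self) -> None:
        self.peak_power_W = np.asarray(self.peak_power_W, dtype=float)
        self.mnf_Hz = np.asarray(self.mnf_Hz, dtype=float)
        self.rms_scale_uV = np.asarray(self.rms_scale_uV, dtype=float)
        n = self.peak_power_W.size
        if self.mnf_Hz.size != n or self.rms_scale_uV.size != n:
            raise ValueError("ground-truth series must have equal length")
        if not 1 <= self.termination_index <= n:
            raise ValueError("termination_index out of range")

    @property
    def n_reps(self) -> int:
        return int(self.peak_power_W.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rep": np.arange(1, self.n_reps + 1),
                "true_peak_power_W": self.peak_power_W,
                "true_mnf_Hz": self.mnf_Hz,
                "true_rms_scale": self.rms_scale_uV,
            }
        )
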