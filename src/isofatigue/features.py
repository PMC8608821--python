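"""Per-contraction sEMG fatigue parameters.

Nine parameters are computed for each concentric segment:

* amplitude — mean absolute value (MAV) and root-mean-square (RMS);
* spectral — mean (MNF) and median (MDF) frequency of the periodogram,
  restricted to the 20–250 Hz analysis band;
* instantaneous — mean (IMNF) and median (IMDF) instantaneous frequency
  of the analytic signal of the wavelet-denoised record;
* time-domain shape — zero crossings (ZC), slope-sign changes (SSC) and
  waveform length (WL).

Fatigue compresses the spectrum (MNF/MDF/IMNF/IMDF fall) and recruits
additional motor units (MAV/RMS grow), so percent-normalized trajectories
of these parameters track the loss of power output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .containers import ContractionSegment, EmgRecording

__all__ = [
    "amplitude_features",
    "spectral_features",
    "wavelet_denoise",
    "wavelet_retained_band",
    "instantaneous_features",
    "hudgins_features",
    "percent_change",
    "feature_table",
    "percent_table",
    "FEATURE_COLUMNS",
    "PERCENT_FEATURES",
]

FEATURE_COLUMNS = [
    "MAV_uV",
    "RMS_uV",
    "MNF_Hz",
    "MDF_Hz",
    "IMNF_Hz",
    "IMDF_Hz",
    "ZC_count",
    "SSC_count",
    "WL_uV",
]

#: The six predictors used for power-loss mapping, percent-normalized.
PERCENT_FEATURES = ["RMS_pct", "MAV_pct", "MNF_pct", "MDF_pct", "IMNF_pct", "IMDF_pct"]


def amplitude_features(samples: np.ndarray) -> tuple[float, float]:
    """Mean absolute value and root-mean-square of a segment (µV).

    MAV ≤ RMS always (Cauchy–Schwarz).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    mav = float(np.mean(np.abs(x)))
    rms = float(np.sqrt(np.mean(x**2)))
    return mav, rms


def spectral_features(
    samples: np.ndarray,
    fs_Hz: float,
    band_Hz: tuple[float, float] = (20.0, 250.0),
) -> tuple[float, float]:
    """Mean and median frequency of the segment periodogram.

    A single rectangular-window periodogram of the whole segment is used
    (segments are ~0.5 s, too short for averaging).  MNF is the
    power-weighted mean frequency; MDF splits the cumulative power in
    half, linearly interpolated between bins to remove bin-width
    quantization.  Both are restricted to ``band_Hz``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for a spectral estimate")
    f, p = signal.periodogram(x, fs=fs_Hz, window="boxcar", detrend=False)
    mask = (f >= band_Hz[0]) & (f <= band_Hz[1])
    f, p = f[mask], p[mask]
    total = float(np.sum(p))
    if total <= 0 or not np.isfinite(total):
        raise ValueError("spectrum has no power in the analysis band")
    mnf = float(np.sum(f * p) / total)

    cum = np.cumsum(p)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        mdf = float(f[0])
    else:
        prev = cum[i - 1]
        frac = (half - prev) / p[i] if p[i] > 0 else 0.0
        mdf = float(f[i - 1] + frac * (f[i] - f[i - 1]))
    return mnf, mdf


def wavelet_retained_band(fs_Hz: float, levels: int = 6) -> tuple[float, float]:
    """Frequency band retained by :func:`wavelet_denoise`.

    Discarding the finest detail (D1) and the final approximation leaves
    details D2..D``levels``, i.e. the dyadic band from
    ``fs / 2**(levels+1)`` up to ``fs / 4``.
    """
    return fs_Hz / 2.0**(levels + 1), fs_Hz / 4.0


def wavelet_denoise(
    samples: np.ndarray,
    levels: int = 6,
    wavelet: str = "db1",
    keep_approximation: bool = False,
) -> np.ndarray:
    """Dyadic wavelet denoising with the Haar (db1) mother wavelet.

    The record is decomposed into ``levels`` detail subbands plus one
    approximation; the finest detail (D1, the top octave of wideband
    noise) and — by default — the approximation (slow drift below
    ``fs/2**(levels+1)``) are zeroed before reconstruction, so the
    retained band at 1.5 kHz and six levels is 11.71875–375 Hz.  Set
    ``keep_approximation=True`` to retain A6 as well.  Length preserved.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2**levels:
        raise ValueError(f"need at least 2**{levels} samples")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    # coeffs = [A_levels, D_levels, ..., D2, D1]
    if not keep_approximation:
        coeffs[0] = np.zeros_like(coeffs[0])
    coeffs[-1] = np.zeros_like(coeffs[-1])
    rec = pywt.waverec(coeffs, wavelet, mode="periodization")
    return rec[: x.size]


def instantaneous_features(
    samples: np.ndarray, fs_Hz: float
) -> tuple[float, float]:
    """Instantaneous mean and median frequency via the Hilbert transform.

    The instantaneous frequency is the scaled derivative of the unwrapped
    analytic-signal phase (central differences), clipped to [0, Nyquist].
    Aggregation over the segment is weighted by the squared analytic
    envelope, which suppresses the spurious frequency spikes that occur
    where the envelope vanishes: IMNF is the weighted mean, IMDF the
    weighted median.  Intended for the wavelet-denoised signal.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 128:
        raise ValueError("need at least 128 samples")
    analytic = signal.hilbert(x)
    env2 = np.abs(analytic) ** 2
    if float(np.max(env2)) <= 0:
        raise ValueError("signal envelope is zero throughout")
    phase = np.unwrap(np.angle(analytic))
    inst_f = np.gradient(phase) * fs_Hz / (2.0 * np.pi)
    inst_f = np.clip(inst_f, 0.0, fs_Hz / 2.0)

    w = env2
    total = float(np.sum(w))
    imnf = float(np.sum(w * inst_f) / total)

    order = np.argsort(inst_f)
    f_sorted = inst_f[order]
    cum = np.cumsum(w[order])
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        imdf = float(f_sorted[0])
    else:
        prev = cum[i - 1]
        wi = cum[i] - prev
        frac = (half - prev) / wi if wi > 0 else 0.0
        imdf = float(f_sorted[i - 1] + frac * (f_sorted[i] - f_sorted[i - 1]))
    return imnf, imdf


def hudgins_features(
    samples: np.ndarray, eps: float = 0.0
) -> tuple[float, int, int, float]:
    """Time-domain pattern-recognition features of a segment.

    Returns (MAV, ZC, SSC, WL): mean absolute value; the number of zero
    crossings whose amplitude step exceeds the deadband ``eps``; the
    number of slope-sign changes whose neighbouring differences both
    exceed ``eps``; and the waveform length (total variation).  ``eps``
    defaults to 0; real recordings typically need ~10 µV to reject noise.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three samples")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    mav = float(np.mean(np.abs(x)))
    d = np.diff(x)
    wl = float(np.sum(np.abs(d)))
    zc = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(d) > eps)))
    ssc = int(
        np.sum((d[:-1] * d[1:] < 0) & ((np.abs(d[:-1]) > eps) | (np.abs(d[1:]) > eps)))
    )
    return mav, zc, ssc, wl


def percent_change(series: np.ndarray, baseline_reps: int = 2) -> np.ndarray:
    """Normalize a per-repetition series to percent of the mean of the
    first ``baseline_reps`` repetitions (so the early-trial value maps to
    100).  Scale-invariant by construction."""
    x = np.asarray(series, dtype=float)
    if x.size < baseline_reps:
        raise ValueError("series shorter than the baseline window")
    base = float(np.mean(x[:baseline_reps]))
    if base == 0.0:
        raise ZeroDivisionError("baseline mean is zero; cannot normalize")
    return 100.0 * x / base


def feature_table(
    emg: EmgRecording,
    segments: list[ContractionSegment],
    peak_power_W: np.ndarray | None = None,
    eps: float = 0.0,
    keep_approximation: bool = False,
) -> pd.DataFrame:
    """One row of the nine parameters per concentric segment.

    ``emg`` is expected to be the band-passed record; amplitude, spectral
    and time-domain features are computed on it directly, while IMNF/IMDF
    are computed on the wavelet-denoised version of the same record
    (denoised once, full length, then sliced per segment).
    """
    denoised = wavelet_denoise(emg.samples, keep_approximation=keep_approximation)
    rows = []
    for seg in sorted(segments, key=lambda s: s.rep_index):
        x = emg.samples[seg.slice()]
        try:
            mav, rms = amplitude_features(x)
            mnf, mdf = spectral_features(x, emg.fs_Hz)
            imnf, imdf = instantaneous_features(denoised[seg.slice()], emg.fs_Hz)
            _, zc, ssc, wl = hudgins_features(x, eps=eps)
        except ValueError as exc:
            raise ValueError(f"repetition {seg.rep_index}: {exc}") from exc
        rows.append(
            {
                "rep": seg.rep_index,
                "MAV_uV": mav,
                "RMS_uV": rms,
                "MNF_Hz": mnf,
                "MDF_Hz": mdf,
                "IMNF_Hz": imnf,
                "IMDF_Hz": imdf,
                "ZC_count": zc,
                "SSC_count": ssc,
                "WL_uV": wl,
            }
        )
    df = pd.DataFrame(rows, columns=["rep", *FEATURE_COLUMNS])
    if peak_power_W is not None:
        power = np.asarray(peak_power_W, dtype=float)
        if power.size != len(df):
            raise ValueError("peak power series must have one value per segment")
        df.insert(1, "peak_power_W", power)
    return df


def percent_table(table: pd.DataFrame, baseline_reps: int = 2) -> pd.DataFrame:
    """Percent-of-first-two-repetitions normalization of a feature table.

    Produces ``*_pct`` columns for the six mapping predictors and, when
    present, ``power_pct`` from ``peak_power_W``.
    """
    out = pd.DataFrame({"rep": table["rep"].to_numpy()})
    mapping = {
        "RMS_pct": "RMS_uV",
        "MAV_pct": "MAV_uV",
        "MNF_pct": "MNF_Hz",
        "MDF_pct": "MDF_Hz",
        "IMNF_pct": "IMNF_Hz",
        "IMDF_pct": "IMDF_Hz",
    }
    if "peak_power_W" in table.columns:
        out["power_pct"] = percent_change(table["peak_power_W"].to_numpy(), baseline_reps)
    for pct_col, src in mapping.items():
        out[pct_col] = percent_change(table[src].to_numpy(), baseline_reps)
    return out
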