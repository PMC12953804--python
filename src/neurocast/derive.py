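"""Derivation of minute-by-minute signals from monitor waveforms.

The processing chain mirrors standard multimodal neuromonitoring practice:

1. 10-s non-overlapping block means of ABP (-> MAP), ICP and PbtO2, which
   suppress the cardiac and respiratory components and expose the slow
   vasogenic waves.
2. Per-frame pulse amplitude AMP: the cardiac-band (0.67-3 Hz) peak of the
   Hanning-windowed DFT of each 10-s ICP frame, corrected for the window's
   coherent gain.
3. CPP = MAP - ICP on the 10-s grid.
4. Cerebrovascular reactivity indices as moving Pearson correlations over
   30 consecutive 10-s means, updated every minute (trailing, causal
   windows): PRx (ICP~MAP), PAx (AMP~MAP), RAC (AMP~CPP), RAP (AMP~ICP).
5. Minute means of the 10-s signals, giving the canonical minute table.

Missing data propagate as NaN; a 10-s frame is valid when at least half of
its samples are unmasked (AMP additionally requires a fully observed
frame), and a correlation window must be entirely valid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import WaveformRecord

__all__ = [
    "CARDIAC_BAND",
    "MINUTE_COLUMNS",
    "block_mean_10s",
    "compute_amp",
    "compute_amp_frames",
    "compute_cpp",
    "pearson",
    "moving_correlation_index",
    "derive_minute_record",
]

CARDIAC_BAND = (0.67, 3.0)

FRAMES_PER_MINUTE = 6
CORR_WINDOW_FRAMES = 30

MINUTE_COLUMNS = [
    "minute",
    "MAP",
    "ICP",
    "CPP",
    "PbtO2",
    "AMP",
    "PRx",
    "PAx",
    "RAC",
    "RAP",
]


def block_mean_10s(
    signal: np.ndarray,
    sampling_rate: float,
    missing_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping 10-s means with validity flags.

    A frame is valid iff at least 50% of its samples are unmasked; its value
    is the mean of the unmasked samples.  A trailing incomplete frame is
    dropped.  Returns ``(values, valid)``; invalid frames hold NaN.
    """
    frame_len = sampling_rate * 10.0
    if abs(frame_len - round(frame_len)) > 1e-9:
        raise ValueError("sampling_rate * 10 s must be an integer sample count")
    frame_len = int(round(frame_len))
    signal = np.asarray(signal, dtype=float)
    if missing_mask is None:
        missing_mask = np.zeros(len(signal), dtype=bool)
    missing_mask = np.asarray(missing_mask, dtype=bool)
    n_frames = len(signal) // frame_len
    if n_frames == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    x = signal[: n_frames * frame_len].reshape(n_frames, frame_len)
    m = missing_mask[: n_frames * frame_len].reshape(n_frames, frame_len)
    present = (~m).sum(axis=1)
    valid = present * 2 >= frame_len
    sums = np.where(m, 0.0, x).sum(axis=1)
    values = np.full(n_frames, np.nan)
    ok = present > 0
    values[ok] = sums[ok] / present[ok]
    values[~valid] = np.nan
    return values, valid


def compute_amp(frame: np.ndarray, sampling_rate: float) -> float:
    """Pulse amplitude of one fully observed 10-s pressure frame.

    Applies a periodic Hanning window, takes the DFT, finds the
    maximum-magnitude bin in the cardiac band and converts it back to a
    sinusoid amplitude in pressure units by dividing out the window's
    coherent gain (its mean).  An all-constant frame returns 0.
    """
    frame = np.asarray(frame, dtype=float)
    expected = int(round(sampling_rate * 10.0))
    if len(frame) != expected:
        raise ValueError(f"frame must hold exactly 10 s ({expected} samples)")
    n = len(frame)
    window = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)  # periodic Hann
    spectrum = np.fft.rfft(frame * window)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    band = (freqs >= CARDIAC_BAND[0]) & (freqs <= CARDIAC_BAND[1])
    if not band.any():
        raise ValueError("cardiac band contains no DFT bins at this frame length")
    mags = np.abs(spectrum[band])
    coherent_gain = window.mean()
    return float(2.0 * mags.max() / (n * coherent_gain))


def compute_amp_frames(
    signal: np.ndarray, sampling_rate: float, missing_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """AMP per consecutive 10-s frame; frames with any masked sample are invalid."""
    frame_len = int(round(sampling_rate * 10.0))
    signal = np.asarray(signal, dtype=float)
    if missing_mask is None:
        missing_mask = np.zeros(len(signal), dtype=bool)
    missing_mask = np.asarray(missing_mask, dtype=bool)
    n_frames = len(signal) // frame_len
    if n_frames == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    x = signal[: n_frames * frame_len].reshape(n_frames, frame_len)
    m = missing_mask[: n_frames * frame_len].reshape(n_frames, frame_len)
    valid = ~m.any(axis=1)
    n = frame_len
    window = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    band = (freqs >= CARDIAC_BAND[0]) & (freqs <= CARDIAC_BAND[1])
    spectra = np.fft.rfft(x * window, axis=1)
    mags = np.abs(spectra[:, band]).max(axis=1)
    values = 2.0 * mags / (n * window.mean())
    values[~valid] = np.nan
    return values, valid


def compute_cpp(map_mean: float | np.ndarray, icp_mean: float | np.ndarray):
    """Cerebral perfusion pressure, MAP - ICP (no clamping)."""
    return np.subtract(map_mean, icp_mean)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (missing) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    syy = yc @ yc
    if sxx <= 0.0 or syy <= 0.0:
        return float("nan")
    return float((xc @ yc) / np.sqrt(sxx * syy))


def moving_correlation_index(
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Minute-indexed moving correlation over trailing 30-frame windows.

    For minute ``m`` (0-based) the window is the 30 frames ending with that
    minute's last frame.  Minutes whose window extends before the record or
    contains any invalid frame are NaN.  Output length is the number of
    whole minutes, ``len(x) // 6``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    valid = np.asarray(valid, dtype=bool)
    n_minutes = len(x) // FRAMES_PER_MINUTE
    out = np.full(n_minutes, np.nan)
    for m in range(n_minutes):
        end = (m + 1) * FRAMES_PER_MINUTE
        start = end - CORR_WINDOW_FRAMES
        if start < 0 or not valid[start:end].all():
            continue
        out[m] = pearson(x[start:end], y[start:end])
    return out


def _minute_means(values: np.ndarray, valid: np.ndarray, min_valid: int = 4) -> np.ndarray:
    """Mean of each minute's 6 frames; NaN when fewer than ``min_valid`` are valid."""
    n_minutes = len(values) // FRAMES_PER_MINUTE
    v = values[: n_minutes * FRAMES_PER_MINUTE].reshape(n_minutes, FRAMES_PER_MINUTE)
    ok = valid[: n_minutes * FRAMES_PER_MINUTE].reshape(n_minutes, FRAMES_PER_MINUTE)
    counts = ok.sum(axis=1)
    sums = np.where(ok, v, 0.0).sum(axis=1)
    out = np.full(n_minutes, np.nan)
    enough = counts >= min_valid
    out[enough] = sums[enough] / counts[enough]
    return out


def derive_minute_record(record: WaveformRecord) -> pd.DataFrame:
    """Full minute-by-minute table for one patient record.

    Columns: minute, MAP, ICP, CPP, PbtO2, AMP, PRx, PAx, RAC, RAP.
    Raises for records shorter than 6 minutes (no correlation window fits).
    """
    fs = record.sampling_rate
    map10, map_ok = block_mean_10s(record.abp, fs, record.missing_mask["abp"])
    icp10, icp_ok = block_mean_10s(record.icp, fs, record.missing_mask["icp"])
    n_frames = len(map10)
    if n_frames < CORR_WINDOW_FRAMES + FRAMES_PER_MINUTE:
        raise ValueError("record shorter than 6 minutes; no index can be computed")

    amp10, amp_ok = compute_amp_frames(record.icp, fs, record.missing_mask["icp"])
    cpp10 = compute_cpp(map10, icp10)
    cpp_ok = map_ok & icp_ok

    if record.pbto2 is not None:
        pbt10, pbt_ok = block_mean_10s(record.pbto2, fs, record.missing_mask["pbto2"])
    else:
        pbt10 = np.full(n_frames, np.nan)
        pbt_ok = np.zeros(n_frames, dtype=bool)

    prx = moving_correlation_index(icp10, map10, icp_ok & map_ok)
    pax = moving_correlation_index(amp10, map10, amp_ok & map_ok)
    rac = moving_correlation_index(amp10, cpp10, amp_ok & cpp_ok)
    rap = moving_correlation_index(amp10, icp10, amp_ok & icp_ok)

    n_minutes = n_frames // FRAMES_PER_MINUTE
    table = pd.DataFrame(
        {
            "minute": np.arange(n_minutes, dtype=int),
            "MAP": _minute_means(map10, map_ok),
            "ICP": _minute_means(icp10, icp_ok),
            "CPP": _minute_means(cpp10, cpp_ok),
            "PbtO2": _minute_means(pbt10, pbt_ok),
            "AMP": _minute_means(amp10, amp_ok),
            "PRx": prx[:n_minutes],
            "PAx": pax[:n_minutes],
            "RAC": rac[:n_minutes],
            "RAP": rap[:n_minutes],
        }
    )
    return table
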