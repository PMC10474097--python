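"""Reference-ECG processing: filtering, R-peak detection, T-wave location.

The ECG channel is not part of the detector itself; it anchors the
evaluation windows in which S1 and S2 are expected to occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientPeaksError, InvalidFilterBandError
from .io import PipelineConfig, Recording


@dataclass
class RPeakAnnotations:
    """R-peak and T-wave-maximum times plus their median intervals.

    ``t_times`` is aligned with ``r_times``; beats whose T search window
    falls off the record carry NaN.  ``median_rr`` and ``median_rt`` are
    the medians of the R-R and R-to-T-maximum intervals.
    """

    r_times: np.ndarray
    t_times: np.ndarray
    median_rr: float
    median_rt: float


def filter_ecg(
    ecg: np.ndarray,
    sample_rate: float,
    bandpass_hz: tuple[float, float] = (1.0, 150.0),
    bandstop_hz: tuple[float, float] = (48.0, 52.0),
    order: int = 2,
) -> np.ndarray:
    """Zero-phase 1-150 Hz band-pass plus 48-52 Hz power-line band-stop."""
    ecg = np.asarray(ecg, dtype=np.float64)
    nyq = sample_rate / 2.0
    if bandpass_hz[1] >= nyq:
        raise InvalidFilterBandError(
            f"band-pass edge {bandpass_hz[1]} Hz requires rate > {2 * bandpass_hz[1]} Hz"
        )
    sos_bp = sps.butter(order, bandpass_hz, btype="bandpass", fs=sample_rate, output="sos")
    sos_bs = sps.butter(order, bandstop_hz, btype="bandstop", fs=sample_rate, output="sos")
    y = sps.sosfiltfilt(sos_bp, ecg, padtype="even")
    return sps.sosfiltfilt(sos_bs, y, padtype="even")


def butter_bandstop_gain(
    freq_hz: np.ndarray | float,
    low_hz: float,
    high_hz: float,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray | float:
    """Closed-form band-stop magnitude (test oracle), squared for zero phase."""
    w = 2.0 * np.pi * np.asarray(freq_hz, dtype=np.float64)
    wl, wh = 2.0 * np.pi * low_hz, 2.0 * np.pi * high_hz
    ratio = (w * (wh - wl)) / (w**2 - wl * wh)
    mag = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    return mag**2 if zero_phase else mag


def _local_maxima(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return np.empty(0, dtype=int)
    interior = x[1:-1]
    return np.flatnonzero((interior > x[:-2]) & (interior > x[2:])) + 1


def detect_r_peaks(
    filtered_ecg: np.ndarray,
    sample_rate: float,
    window_s: float = 5.0,
    frac: float = 0.7,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """Adaptive-threshold R detection: per 5 s window, local maxima above
    70% of the window maximum; candidates from all windows are pooled and a
    0.25 s refractory rule keeps only the largest candidate in any
    violating span.
    """
    x = np.asarray(filtered_ecg, dtype=np.float64)
    maxima = _local_maxima(x)
    if maxima.size == 0:
        return np.empty(0)
    step = int(round(window_s * sample_rate))
    candidates: list[int] = []
    for start in range(0, x.size, step):
        end = min(start + step, x.size)
        wmax = np.max(x[start:end])
        if wmax <= 0:
            continue
        in_win = maxima[(maxima >= start) & (maxima < end)]
        candidates.extend(int(i) for i in in_win if x[i] > frac * wmax)
    if not candidates:
        return np.empty(0)
    # refractory: greedy by amplitude, largest first
    candidates = sorted(set(candidates))
    order = sorted(candidates, key=lambda i: -x[i])
    min_gap = refractory_s * sample_rate
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(i)
    return np.sort(np.array(kept)) / sample_rate


def correct_r_peaks(
    r_times: np.ndarray,
    filtered_ecg: np.ndarray,
    sample_rate: float,
    low_factor: float = 0.8,
    high_factor: float = 1.3,
    recovery_window_s: float = 0.3,
    max_rounds: int = 50,
) -> np.ndarray:
    """Remove false R detections and recover missed beats.

    Applies the same confirmation machinery as heart-sound detection with
    the presumed period replaced by the median R-R interval of the input
    detections: an R-R gap below ``0.8 x median`` drops the second peak;
    a gap above ``1.3 x median`` opens a 300 ms window centered one median
    R-R after the previous peak, and the local ECG maximum closest to the
    window center (ties -> earlier) is inserted, provided it does not
    create a new sub-threshold gap.  The reference median is held fixed
    across rounds for determinism.
    """
    t = np.sort(np.asarray(r_times, dtype=np.float64))
    if t.size < 3:
        raise InsufficientPeaksError(f"need at least 3 R peaks, got {t.size}")
    x = np.asarray(filtered_ecg, dtype=np.float64)
    median_rr = float(np.median(np.diff(t)))
    maxima_idx = _local_maxima(x)
    maxima_t = maxima_idx / sample_rate
    half = recovery_window_s / 2.0
    for _ in range(max_rounds):
        changed = False
        # removal pass
        kept = [t[0]]
        for ti in t[1:]:
            if ti - kept[-1] < low_factor * median_rr:
                changed = True
            else:
                kept.append(ti)
        t = np.array(kept)
        # recovery pass
        inserted = True
        while inserted:
            inserted = False
            for a, b in zip(t[:-1], t[1:]):
                if b - a <= high_factor * median_rr:
                    continue
                center = a + median_rr
                mask = (
                    (np.abs(maxima_t - center) <= half)
                    & (maxima_t - a >= low_factor * median_rr)
                    & (b - maxima_t >= low_factor * median_rr)
                )
                cand = maxima_t[mask]
                if cand.size == 0:
                    continue
                dist = np.round(np.abs(cand - center) * 1e9)
                best = cand[np.lexsort((cand, dist))[0]]
                t = np.sort(np.append(t, best))
                changed = inserted = True
                break
        if not changed:
            break
    return t


def detect_t_wave_max(
    filtered_ecg: np.ndarray,
    r_times: np.ndarray,
    sample_rate: float,
    search_start_s: float = 0.12,
    search_end_frac: float = 0.40,
) -> tuple[np.ndarray, float]:
    """T-wave maxima: the largest sample in ``(R + 0.12 s, R + 0.40 median R-R]``.

    Beats whose search window runs past the end of the record yield NaN.
    Returns ``(t_times, median_rt)``; ``median_rt`` is NaN when no beat
    has a usable window.
    """
    x = np.asarray(filtered_ecg, dtype=np.float64)
    r = np.asarray(r_times, dtype=np.float64)
    if r.size == 0:
        raise InsufficientPeaksError("need at least one R peak")
    median_rr = float(np.median(np.diff(r))) if r.size >= 2 else np.nan
    window_len = search_end_frac * median_rr if np.isfinite(median_rr) else 0.3
    duration = x.size / sample_rate
    t_times = np.full(r.size, np.nan)
    for k, rt in enumerate(r):
        start = rt + search_start_s
        end = rt + window_len
        if end > duration or end <= start:
            continue
        i0 = int(np.round(start * sample_rate)) + 1
        i1 = int(np.round(end * sample_rate)) + 1
        if i1 <= i0 or i1 > x.size:
            continue
        t_times[k] = (i0 + int(np.argmax(x[i0:i1]))) / sample_rate
    valid = np.isfinite(t_times)
    median_rt = float(np.median(t_times[valid] - r[valid])) if valid.any() else np.nan
    return t_times, median_rt


def annotate_ecg(
    recording: Recording,
    channel: int | None = None,
    config: PipelineConfig | None = None,
) -> RPeakAnnotations:
    """Full ECG branch: filter -> detect R -> correct -> locate T maxima."""
    config = config or PipelineConfig()
    if channel is None:
        ecg_channels = recording.channels_with_role("ecg")
        if not ecg_channels:
            raise ValueError("recording has no ECG channel")
        channel = ecg_channels[0]
    ecg = recording.channel(channel)
    if config.ecg_invert:
        ecg = -ecg
    filtered = filter_ecg(
        ecg,
        recording.sample_rate,
        config.ecg_bandpass_hz,
        config.ecg_bandstop_hz,
        config.ecg_filter_order,
    )
    r = detect_r_peaks(
        filtered,
        recording.sample_rate,
        config.r_window_s,
        config.r_threshold_frac,
        config.r_refractory_s,
    )
    r = correct_r_peaks(
        r,
        filtered,
        recording.sample_rate,
        config.confirm_low_factor,
        config.confirm_high_factor,
        config.recovery_window_s,
    )
    t_times, median_rt = detect_t_wave_max(
        filtered,
        r,
        recording.sample_rate,
        config.t_search_start_s,
        config.t_search_end_frac,
    )
    median_rr = float(np.median(np.diff(r)))
    return RPeakAnnotations(
        r_times=r, t_times=t_times, median_rr=median_rr, median_rt=median_rt
    )
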