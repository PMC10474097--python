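"""ECG-anchored scoring of heart-sound detections.

S1 is expected within ``[R, R + 0.2 median(R-R))`` of each detected R
peak; S2 within ``[R + 1.2 median(R-T), R + 0.6 median(R-R))``.  Window
lengths therefore shrink as heart rate rises.  Detections are scored per
window (TP/FP/FN), summarized as sensitivity and positive predictive
value, and heart-rate series from S1-S1, S2-S2, and R-R intervals are
compared with a paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detection import detect_heart_sounds
from .ecg import RPeakAnnotations, annotate_ecg
from .errors import TooFewPairsError
from .io import PipelineConfig, Recording


@dataclass
class EvaluationWindows:
    """Per-beat half-open [start, end) windows for expected S1 and S2."""

    s1_windows: list[tuple[float, float]]
    s2_windows: list[tuple[float, float]]
    n_degenerate_s2: int = 0


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def se(self) -> float:
        """Sensitivity, % (NaN when no windows exist)."""
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def ppv(self) -> float:
        """Positive predictive value, % (NaN when nothing was detected)."""
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


@dataclass
class HRSeries:
    """Heart rate per consecutive analysis window (NaN where undefined)."""

    window_times: np.ndarray
    hr_bpm: np.ndarray


@dataclass
class EvaluationReport:
    detection_table: pd.DataFrame
    hr_table: pd.DataFrame
    hr_series: dict


def build_windows(
    r_ann: RPeakAnnotations,
    s1_factor: float = 0.2,
    s2_start_factor: float = 1.2,
    s2_end_factor: float = 0.6,
    duration: float | None = None,
) -> EvaluationWindows:
    """One expected-S1 and expected-S2 window per R peak.

    Window ends are clipped at the next R so windows of one label never
    overlap; an S2 window whose start reaches its end (possible when the
    R-T interval is long relative to the beat) is dropped and counted as
    degenerate.  Without a usable median R-T no S2 windows are produced.
    When ``duration`` is given, windows truncated by the record end are
    dropped: the sound they would score may itself be cut off.
    """
    s1_windows: list[tuple[float, float]] = []
    s2_windows: list[tuple[float, float]] = []
    degenerate = 0
    rr, rt = r_ann.median_rr, r_ann.median_rt
    r = r_ann.r_times
    limit = duration if duration is not None else np.inf
    for k, rk in enumerate(r):
        next_r = r[k + 1] if k + 1 < r.size else np.inf
        end = min(rk + s1_factor * rr, next_r)
        if end <= limit:
            s1_windows.append((rk, end))
        if np.isfinite(rt):
            start = rk + s2_start_factor * rt
            end = min(rk + s2_end_factor * rr, next_r)
            if start >= end:
                degenerate += 1
            elif end <= limit:
                s2_windows.append((start, end))
    return EvaluationWindows(s1_windows, s2_windows, degenerate)


def score_detection(
    detected_times: np.ndarray, windows: list[tuple[float, float]]
) -> DetectionMetrics:
    """TP/FP/FN against half-open per-beat windows.

    A window is credited at most one TP; extra detections inside an
    already-credited window and detections outside every window count as
    FP; windows with no detection count as FN.
    """
    t = np.sort(np.asarray(detected_times, dtype=np.float64))
    hit = [False] * len(windows)
    tp = fp = 0
    for d in t:
        matched = False
        for w, (start, end) in enumerate(windows):
            if start <= d < end:
                matched = True
                if not hit[w]:
                    hit[w] = True
                    tp += 1
                else:
                    fp += 1
                break
        if not matched:
            fp += 1
    fn = hit.count(False)
    return DetectionMetrics(tp=tp, fp=fp, fn=fn)


def summarize_metrics(values) -> dict:
    """Min, max, median, quartiles, and IQR (Q3 - Q1) of a metric set.

    Quartiles use linear interpolation between order statistics.
    """
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot summarize an empty metric list")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }


def heart_rate_series(
    event_times: np.ndarray, duration: float, window_s: float = 2.0
) -> HRSeries:
    """HR per consecutive window: 60 / median(inter-event gaps in window).

    A gap belongs to the window containing its midpoint; windows holding
    no gap are NaN (undefined), never zero-filled.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = np.sort(np.asarray(event_times, dtype=np.float64))
    starts = np.arange(0.0, duration, window_s)
    hr = np.full(starts.size, np.nan)
    if t.size >= 2:
        gaps = np.diff(t)
        mids = (t[:-1] + t[1:]) / 2.0
        which = np.floor(mids / window_s).astype(int)
        for w in range(starts.size):
            g = gaps[which == w]
            if g.size:
                hr[w] = 60.0 / np.median(g)
    return HRSeries(window_times=starts, hr_bpm=hr)


def compare_hr_paired(hr_a: np.ndarray, hr_b: np.ndarray) -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank test on jointly defined HR windows.

    Zero differences are discarded (classic convention); the exact null
    distribution is used for up to 25 non-zero pairs, the normal
    approximation with continuity correction above that.  Identical
    series return ``(0.0, 1.0, n)``.  Raises below 6 shared windows.
    """
    a = np.asarray(hr_a, dtype=np.float64)
    b = np.asarray(hr_b, dtype=np.float64)
    mask = np.isfinite(a) & np.isfinite(b)
    n = int(mask.sum())
    if n < 6:
        raise TooFewPairsError(f"need >= 6 jointly defined windows, got {n}")
    d = b[mask] - a[mask]
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return 0.0, 1.0, n
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=True, method=method
    )
    return float(res.statistic), float(res.pvalue), n


def evaluate_record(
    recording: Recording,
    config: PipelineConfig | None = None,
    pcg_channels: list[int] | None = None,
) -> EvaluationReport:
    """Detect heart sounds on every PCG channel and score them against the
    reference ECG: per-channel TP/FP/FN, SE, PPV for S1 and S2, plus
    paired Wilcoxon comparisons of the S1-, S2-, and R-derived heart-rate
    series."""
    config = config or PipelineConfig()
    if pcg_channels is None:
        pcg_channels = recording.channels_with_role("pcg")
    if not recording.channels_with_role("ecg"):
        raise ValueError("recording has no ECG channel to evaluate against")
    r_ann = annotate_ecg(recording, config=config)
    windows = build_windows(
        r_ann,
        config.s1_window_factor,
        config.s2_window_start_factor,
        config.s2_window_end_factor,
        duration=recording.duration,
    )
    hr_r = heart_rate_series(r_ann.r_times, recording.duration, config.hr_window_s)
    det_rows, hr_rows = [], []
    series = {"R": hr_r}
    for ch in pcg_channels:
        name = recording.channel_names[ch]
        ann = detect_heart_sounds(recording, ch, config)
        for label, times, wins in (
            ("S1", ann.s1_times, windows.s1_windows),
            ("S2", ann.s2_times, windows.s2_windows),
        ):
            m = score_detection(times, wins)
            det_rows.append(
                {"channel": name, "label": label, "tp": m.tp, "fp": m.fp,
                 "fn": m.fn, "se": m.se, "ppv": m.ppv}
            )
            hr = heart_rate_series(times, recording.duration, config.hr_window_s)
            series[f"{label}:{name}"] = hr
            try:
                stat, p, n = compare_hr_paired(hr_r.hr_bpm, hr.hr_bpm)
            except TooFewPairsError:
                stat, p, n = np.nan, np.nan, 0
            hr_rows.append(
                {"channel": name, "label": label, "statistic": stat,
                 "p_value": p, "n_pairs": n}
            )
    return EvaluationReport(
        detection_table=pd.DataFrame(det_rows),
        hr_table=pd.DataFrame(hr_rows),
        hr_series=series,
    )
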