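"""Heart-sound detection: envelope peaks -> interval K-means -> confirmation.

The detector finds every strict local maximum of the standardized envelope
above a permissive threshold Th1, thins peaks closer than the typical
heart-sound duration (150 ms), estimates the beat period as the mode of
lag-2 gaps among the louder (above-Th2) peaks, classifies consecutive
above-Th2 intervals into systole / diastole / longer with a 1-D K-means
seeded at 35% / 65% / 100% of that period, labels the peak before each
systole as S1 and before each diastole as S2, and finally applies
period-based confirmation rules that demote implausibly early repeats and
recover missed beats from the unclassified pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envelope import compute_envelope
from .errors import InsufficientDataError, InsufficientPeaksError
from .io import PipelineConfig, Recording
from .preprocess import preprocess_pcg

LABEL_S1 = "S1"
LABEL_S2 = "S2"
LABEL_U = "U"

_CLUSTER_NAMES = ("systole", "diastole", "longer")


@dataclass
class CandidatePeak:
    """A strict local maximum of the standardized envelope above Th1."""

    time: float
    amplitude: float
    above_th2: bool = False


@dataclass
class IntervalClassification:
    """K-means clustering of consecutive above-Th2 peak intervals."""

    intervals: np.ndarray
    cluster_labels: list[str]
    centroids: np.ndarray
    presumed_period: float


@dataclass
class HeartSoundAnnotations:
    """Final S1/S2/unclassified event times plus bookkeeping counters."""

    s1_times: np.ndarray
    s2_times: np.ndarray
    unclassified_times: np.ndarray
    presumed_period: float
    removed_as_false: int = 0
    recovered: int = 0


def compute_thresholds(mu: float, sigma: float, mean_energy: float | None = None) -> tuple[float, float]:
    """Detection thresholds on the standardized-envelope scale.

    ``Th1 = -0.9 * mu / sigma`` sits at 90% of the downward shift the
    standardization applies, just above the envelope floor, so even weak
    sounds produce candidates.  ``Th2`` is the mean of the energy signal;
    expressed on the standardized scale it equals
    ``(mean_energy - mu) / sigma``, i.e. 0 when the mean is the same
    global mean used for standardization.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    th1 = -0.9 * mu / sigma
    if mean_energy is None:
        mean_energy = mu
    th2 = (mean_energy - mu) / sigma
    return th1, th2


def detect_candidate_peaks(
    normalized_envelope: np.ndarray, sample_rate: float, th1: float
) -> list[CandidatePeak]:
    """All strict local maxima with amplitude above ``th1``, in time order."""
    x = np.asarray(normalized_envelope, dtype=np.float64)
    if x.size < 3:
        return []
    interior = x[1:-1]
    is_peak = (interior > x[:-2]) & (interior > x[2:]) & (interior > th1)
    idx = np.flatnonzero(is_peak) + 1
    return [CandidatePeak(time=i / sample_rate, amplitude=float(x[i])) for i in idx]


def enforce_min_spacing(
    peaks: list[CandidatePeak], min_gap_s: float = 0.15
) -> list[CandidatePeak]:
    """Thin peaks closer together than the typical heart-sound duration.

    Repeatedly resolves the closest violating pair by dropping its
    lower-amplitude member (ties drop the later peak) until every
    surviving gap is at least ``min_gap_s``.
    """
    kept = list(peaks)
    while len(kept) >= 2:
        gaps = np.array([kept[i + 1].time - kept[i].time for i in range(len(kept) - 1)])
        j = int(np.argmin(gaps))
        if gaps[j] >= min_gap_s:
            break
        if kept[j].amplitude >= kept[j + 1].amplitude:
            del kept[j + 1]
        else:
            del kept[j]
    return kept


def presumed_heart_period(
    above_th2_times: np.ndarray, quantum_s: float = 0.01
) -> float:
    """Mode of the lag-2 inter-peak gaps, the presumed S1-to-S1 period.

    Under ideal S1/S2 alternation every second gap spans exactly one heart
    beat, so the gaps between consecutive odd-indexed peaks and between
    consecutive even-indexed peaks cluster at the beat period even when
    occasional peaks are spurious or missed.  Gaps are quantized to
    ``quantum_s`` bins before taking the mode; ties go to the smallest
    value.
    """
    t = np.asarray(above_th2_times, dtype=np.float64)
    if t.size < 3:
        raise InsufficientPeaksError(
            f"need at least 3 peaks above Th2 to estimate the heart period, got {t.size}"
        )
    gaps = np.concatenate([np.diff(t[0::2]), np.diff(t[1::2])])
    bins = np.round(gaps / quantum_s).astype(int)
    values, counts = np.unique(bins, return_counts=True)  # ascending order
    return float(values[np.argmax(counts)] * quantum_s)


def classify_intervals_kmeans(
    intervals: np.ndarray,
    presumed_period: float,
    centroid_fractions: tuple[float, float, float] = (0.35, 0.65, 1.0),
    max_iter: int = 100,
) -> IntervalClassification:
    """1-D K-means (k=3) over interval durations, seeded from the period.

    Initial centroids sit at 35%, 65%, and 100% of the presumed period -
    the approximate systole / diastole / full-beat durations at resting
    heart rate.  Lloyd iterations run to an assignment fixed point; an
    empty cluster keeps its centroid for that iteration.  Cluster names
    follow the final centroid order (shortest = systole, longest =
    longer).
    """
    d = np.asarray(intervals, dtype=np.float64)
    if d.size == 0:
        raise ValueError("interval list is empty")
    if presumed_period <= 0:
        raise ValueError("presumed_period must be positive")
    centroids = presumed_period * np.asarray(centroid_fractions, dtype=np.float64)
    assign = np.argmin(np.abs(d[:, None] - centroids[None, :]), axis=1)
    for _ in range(max_iter):
        for k in range(3):
            members = d[assign == k]
            if members.size:
                centroids[k] = members.mean()
        new_assign = np.argmin(np.abs(d[:, None] - centroids[None, :]), axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    order = np.argsort(centroids, kind="stable")
    rank = np.empty(3, dtype=int)
    rank[order] = np.arange(3)
    labels = [_CLUSTER_NAMES[rank[k]] for k in assign]
    return IntervalClassification(
        intervals=d,
        cluster_labels=labels,
        centroids=centroids,
        presumed_period=presumed_period,
    )


def assign_labels(
    peaks: list[CandidatePeak],
    classification: IntervalClassification,
) -> tuple[np.ndarray, np.ndarray]:
    """Provisional labels for every candidate peak.

    The intervals in ``classification`` are the consecutive gaps of the
    above-Th2 subsequence of ``peaks``.  The above-Th2 peak before a
    systole interval becomes S1, before a diastole interval S2; peaks
    before "longer" intervals, the final above-Th2 peak, and every
    below-Th2 peak stay unclassified.

    Returns ``(times, labels)`` arrays over all candidate peaks.
    """
    times = np.array([p.time for p in peaks], dtype=np.float64)
    labels = np.array([LABEL_U] * len(peaks), dtype=object)
    above_idx = [i for i, p in enumerate(peaks) if p.above_th2]
    if len(above_idx) - 1 != len(classification.cluster_labels):
        raise ValueError("interval count does not match above-Th2 peak count")
    for j, cluster in enumerate(classification.cluster_labels):
        if cluster == "systole":
            labels[above_idx[j]] = LABEL_S1
        elif cluster == "diastole":
            labels[above_idx[j]] = LABEL_S2
    return times, labels


def _confirm_pass(
    times: np.ndarray,
    labels: np.ndarray,
    label: str,
    period: float,
    low_factor: float,
    high_factor: float,
    recovery_window_s: float,
) -> tuple[int, int]:
    """One removal pass then one recovery pass for a single label sequence.

    Returns (n_removed, n_recovered).  Mutates ``labels`` in place.
    """
    removed = recovered = 0
    # (a) removal: a same-label gap shorter than low_factor * period means
    # the second peak cannot be a true repeat of the same sound
    idx = np.flatnonzero(labels == label)
    prev = None
    for i in idx:
        if prev is not None and times[i] - times[prev] < low_factor * period:
            labels[i] = LABEL_U
            removed += 1
        else:
            prev = i
    # (b) recovery: a gap beyond high_factor * period suggests a missed
    # beat about one period after the previous peak; promote the
    # unclassified peak closest to that position (ties -> earlier), but
    # never create a new sub-threshold gap
    half = recovery_window_s / 2.0
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(labels == label)
        for a, b in zip(idx[:-1], idx[1:]):
            gap = times[b] - times[a]
            if gap <= high_factor * period:
                continue
            center = times[a] + period
            cand = [
                j
                for j in np.flatnonzero(labels == LABEL_U)
                if a < j < b
                and abs(times[j] - center) <= half
                and times[j] - times[a] >= low_factor * period
                and times[b] - times[j] >= low_factor * period
            ]
            if not cand:
                continue
            # distances quantized to 1 ns so float noise cannot break the
            # documented "equal distances -> earlier peak" tie-break
            best = min(
                cand,
                key=lambda j: (round(abs(times[j] - center) * 1e9), times[j]),
            )
            labels[best] = label
            recovered += 1
            changed = True
            break  # re-scan with the updated sequence
    return removed, recovered


def confirm_peaks(
    times: np.ndarray,
    labels: np.ndarray,
    presumed_period: float,
    low_factor: float = 0.8,
    high_factor: float = 1.3,
    recovery_window_s: float = 0.3,
    max_rounds: int = 50,
) -> tuple[np.ndarray, int, int]:
    """Apply removal and recovery rules to the S1 and S2 sequences.

    Rounds of one removal pass followed by recovery-to-stability repeat
    until a full round changes nothing.  Recovery only promotes a peak
    whose resulting same-label gaps both stay at or above
    ``low_factor * presumed_period``, so confirmation never creates a gap
    it would immediately have to remove, which guarantees termination.

    Returns ``(labels, n_removed, n_recovered)``.
    """
    labels = labels.copy()
    total_removed = total_recovered = 0
    for _ in range(max_rounds):
        changed = 0
        for label in (LABEL_S1, LABEL_S2):
            rem, rec = _confirm_pass(
                times, labels, label, presumed_period,
                low_factor, high_factor, recovery_window_s,
            )
            total_removed += rem
            total_recovered += rec
            changed += rem + rec
        if not changed:
            break
    return labels, total_removed, total_recovered


def detect_heart_sounds(
    recording: Recording,
    channel: int,
    config: PipelineConfig | None = None,
    return_stages: bool = False,
):
    """Run the full detection chain on one PCG channel.

    Returns :class:`HeartSoundAnnotations`; with ``return_stages=True``
    additionally returns a dict of the intermediate signals (band-passed,
    denoised, normalized, Shannon energy, smoothed envelope, standardized
    envelope) for inspection.
    """
    config = config or PipelineConfig()
    if recording.channel_roles[channel] != "pcg":
        raise ValueError(f"channel {channel} is not a PCG channel")
    if recording.duration < 3.0:
        raise InsufficientDataError(
            f"need at least 3 s of signal, got {recording.duration:.2f} s"
        )
    fs = recording.sample_rate
    pre = preprocess_pcg(recording.channel(channel), fs, config)
    env = compute_envelope(pre.samples, fs, config)
    th1, th2 = compute_thresholds(env.mu, env.sigma)

    peaks = detect_candidate_peaks(env.normalized, fs, th1)
    peaks = enforce_min_spacing(peaks, config.min_peak_spacing_s)
    for p in peaks:
        p.above_th2 = p.amplitude > th2
    above_times = np.array([p.time for p in peaks if p.above_th2])
    period = presumed_heart_period(above_times, config.period_quantum_s)
    intervals = np.diff(above_times)
    classification = classify_intervals_kmeans(
        intervals, period, config.centroid_fractions
    )
    times, labels = assign_labels(peaks, classification)
    labels, removed, recovered = confirm_peaks(
        times,
        labels,
        period,
        config.confirm_low_factor,
        config.confirm_high_factor,
        config.recovery_window_s,
    )
    ann = HeartSoundAnnotations(
        s1_times=times[labels == LABEL_S1],
        s2_times=times[labels == LABEL_S2],
        unclassified_times=times[labels == LABEL_U],
        presumed_period=period,
        removed_as_false=removed,
        recovered=recovered,
    )
    if return_stages:
        stages = {
            "bandpassed": bandpass_stage(recording, channel, config),
            "normalized": pre.samples,
            "shannon_energy": env.shannon_energy,
            "envelope": env.envelope,
            "normalized_envelope": env.normalized,
            "th1": th1,
            "th2": th2,
        }
        return ann, stages
    return ann


def bandpass_stage(recording: Recording, channel: int, config: PipelineConfig) -> np.ndarray:
    from .preprocess import bandpass_pcg

    return bandpass_pcg(
        recording.channel(channel),
        recording.sample_rate,
        config.bandpass_low_hz,
        config.bandpass_high_hz,
        config.bandpass_order,
    ).samples
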