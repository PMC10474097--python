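"""Peak detection, interval classification, confirmation, full chain."""

import numpy as np
import pytest

from pcgbeat import (
    Recording,
    SimulationSpec,
    classify_intervals_kmeans,
    compute_thresholds,
    confirm_peaks,
    detect_candidate_peaks,
    detect_heart_sounds,
    enforce_min_spacing,
    generate_recording,
    presumed_heart_period,
)
from pcgbeat.detection import CandidatePeak, assign_labels
from pcgbeat.errors import InsufficientDataError, InsufficientPeaksError


def _peaks(pairs, above=None):
    out = [CandidatePeak(time=t, amplitude=a) for t, a in pairs]
    if above is not None:
        for p, flag in zip(out, above):
            p.above_th2 = flag
    return out


class TestThresholds:
    def test_th1_is_ninety_percent_of_shift(self):
        th1, _ = compute_thresholds(mu=0.2, sigma=0.5)
        assert th1 == pytest.approx(-0.36)

    def test_th2_is_zero_on_standardized_scale(self):
        _, th2 = compute_thresholds(mu=0.2, sigma=0.5, mean_energy=0.2)
        assert th2 == 0.0

    def test_degenerate_zero_mean(self):
        th1, _ = compute_thresholds(mu=0.0, sigma=1.0)
        assert th1 == 0.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            compute_thresholds(0.2, 0.0)


class TestCandidatePeaks:
    def test_monotone_ramp_has_no_peaks(self):
        assert detect_candidate_peaks(np.linspace(0, 1, 100), 100.0, -0.36) == []

    def test_single_triangular_bump(self):
        x = np.concatenate([np.linspace(-1, 2, 30), np.linspace(2, -1, 30)[1:]])
        peaks = detect_candidate_peaks(x, 100.0, -0.36)
        assert len(peaks) == 1
        assert peaks[0].amplitude == pytest.approx(2.0)

    def test_matches_three_point_scan(self):
        """Implementation equals an exhaustive local-maximum scan."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=300)
            th1 = rng.uniform(-1, 1)
            expected = [
                i
                for i in range(1, x.size - 1)
                if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] > th1
            ]
            got = [round(p.time * 100) for p in detect_candidate_peaks(x, 100.0, th1)]
            assert got == expected


def _spacing_oracle(pairs, min_gap):
    """Closest-pair-first removal of the lower-amplitude peak, to fixed point."""
    kept = list(pairs)
    while len(kept) > 1:
        gaps = [(kept[i + 1][0] - kept[i][0], i) for i in range(len(kept) - 1)]
        gap, i = min(gaps)
        if gap >= min_gap:
            break
        kept.pop(i + 1 if kept[i][1] >= kept[i + 1][1] else i)
    return [t for t, _ in kept]


class TestMinSpacing:
    def test_close_pair_keeps_louder(self):
        out = enforce_min_spacing(_peaks([(0.0, 1.0), (0.10, 0.8)]))
        assert [p.time for p in out] == [0.0]

    def test_distant_pair_kept(self):
        out = enforce_min_spacing(_peaks([(0.0, 1.0), (0.40, 0.8)]))
        assert [p.time for p in out] == [0.0, 0.40]

    def test_chain_resolves_to_survivor(self):
        out = enforce_min_spacing(
            _peaks([(0.0, 0.5), (0.10, 0.9), (0.20, 0.6)])
        )
        assert [p.time for p in out] == [0.10]

    def test_matches_exhaustive_removal(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(2, 40)
            times = np.sort(rng.uniform(0, 3.0, size=n))
            amps = rng.uniform(0.1, 2.0, size=n)
            pairs = list(zip(times, amps))
            got = [p.time for p in enforce_min_spacing(_peaks(pairs))]
            assert got == _spacing_oracle(pairs, 0.15)
            assert np.all(np.diff(got) >= 0.15 - 1e-12)


class TestPresumedPeriod:
    def test_alternating_train(self):
        # systole 0.3, diastole 0.5 -> every lag-2 gap is 0.8
        t = np.cumsum([0.0] + [0.3, 0.5] * 5)
        assert presumed_heart_period(t) == pytest.approx(0.8)

    def test_mode_by_counting(self):
        # lag-2 gaps pool to {0.80, 0.80, 0.79, 1.62}; 10 ms mode is 0.80
        t = np.array([0.0, 0.3, 0.80, 1.09, 1.60, 2.71])
        assert presumed_heart_period(t) == pytest.approx(0.80)

    def test_matches_histogram_oracle(self):
        from collections import Counter

        rng = np.random.default_rng(13)
        for _ in range(100):
            t = np.sort(rng.uniform(0, 10, size=rng.integers(3, 30)))
            gaps = np.concatenate([np.diff(t[0::2]), np.diff(t[1::2])])
            counter = Counter(int(round(g / 0.01)) for g in gaps)
            best = min(sorted(counter), key=lambda b: (-counter[b], b))
            assert presumed_heart_period(t) == pytest.approx(best * 0.01)

    def test_too_few_peaks(self):
        with pytest.raises(InsufficientPeaksError):
            presumed_heart_period(np.array([0.0, 0.8]))


class TestIntervalKMeans:
    def test_three_cluster_example(self):
        c = classify_intervals_kmeans(
            np.array([0.28, 0.30, 0.50, 0.52, 0.80]), 0.80
        )
        assert c.cluster_labels == ["systole", "systole", "diastole", "diastole", "longer"]
        assert np.all(np.diff(np.sort(c.centroids)) >= 0)

    def test_single_interval_goes_to_nearest_centroid(self):
        c = classify_intervals_kmeans(np.array([0.30]), 0.80)
        assert c.cluster_labels == ["systole"]

    def test_exact_diastole_hit(self):
        c = classify_intervals_kmeans(np.full(4, 0.65 * 0.8), 0.8)
        assert c.cluster_labels == ["diastole"] * 4

    def test_fixed_point_on_random_instances(self):
        """Every interval ends nearest its own final centroid."""
        rng = np.random.default_rng(14)
        for _ in range(100):
            d = rng.uniform(0.1, 2.0, size=rng.integers(1, 40))
            period = rng.uniform(0.5, 1.5)
            c = classify_intervals_kmeans(d, period)
            names = ("systole", "diastole", "longer")
            order = np.argsort(c.centroids, kind="stable")
            for x, label in zip(d, c.cluster_labels):
                dist = np.abs(x - c.centroids)
                k = names.index(label)
                assert dist[k] <= np.min(dist) + 1e-12
            assert len(order) == 3


class TestAssignLabels:
    def test_alternating_short_long(self):
        peaks = _peaks(
            [(t, 1.0) for t in np.cumsum([0.0] + [0.3, 0.5] * 3)],
            above=[True] * 7,
        )
        c = classify_intervals_kmeans(np.diff([p.time for p in peaks]), 0.8)
        times, labels = assign_labels(peaks, c)
        assert list(labels) == ["S1", "S2", "S1", "S2", "S1", "S2", "U"]

    def test_all_longer_stays_unclassified(self):
        peaks = _peaks([(0.0, 1), (1.0, 1), (2.0, 1)], above=[True] * 3)
        c = classify_intervals_kmeans(np.array([1.0, 1.0]), 1.0)
        _, labels = assign_labels(peaks, c)
        assert list(labels) == ["U", "U", "U"]

    def test_below_th2_peak_stays_unclassified(self):
        peaks = _peaks(
            [(0.0, 1.0), (0.15, -0.5), (0.3, 1.0), (0.8, 1.0)],
            above=[True, False, True, True],
        )
        c = classify_intervals_kmeans(np.array([0.3, 0.5]), 0.8)
        _, labels = assign_labels(peaks, c)
        assert list(labels) == ["S1", "U", "S2", "U"]


class TestConfirmation:
    def test_missed_peak_recovered(self):
        times = np.array([0.0, 0.8, 1.58, 2.4])
        labels = np.array(["S1", "S1", "U", "S1"], dtype=object)
        out, removed, recovered = confirm_peaks(times, labels, 0.8)
        assert list(out) == ["S1", "S1", "S1", "S1"]
        assert recovered == 1 and removed == 0

    def test_early_repeat_demoted(self):
        times = np.array([0.0, 0.5, 0.8])
        labels = np.array(["S1", "S1", "S1"], dtype=object)
        out, removed, _ = confirm_peaks(times, labels, 0.8)
        assert list(out) == ["S1", "U", "S1"]
        assert removed == 1

    def test_recovery_tie_goes_to_earlier(self):
        times = np.array([0.0, 0.8, 1.55, 1.65, 2.4])
        labels = np.array(["S1", "S1", "U", "U", "S1"], dtype=object)
        out, _, _ = confirm_peaks(times, labels, 0.8)
        # window center 1.6; 1.55 and 1.65 are equidistant -> earlier wins
        assert list(out) == ["S1", "S1", "S1", "U", "S1"]

    def test_never_creates_short_gap(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            n = rng.integers(4, 40)
            times = np.sort(rng.uniform(0, 20, size=n))
            times = times[np.concatenate([[True], np.diff(times) > 0.05])]
            labels = rng.choice(["S1", "S2", "U"], size=times.size).astype(object)
            period = rng.uniform(0.6, 1.2)
            out, _, _ = confirm_peaks(times, labels, period)
            for lab in ("S1", "S2"):
                t = times[out == lab]
                if t.size >= 2:
                    assert np.min(np.diff(t)) >= 0.8 * period - 1e-12


class TestFullChain:
    def test_clean_sixty_bpm_counts(self):
        rec, truth = generate_recording(
            SimulationSpec(duration=60.0, hr_bpm=60.0, seed=21)
        )
        ann = detect_heart_sounds(rec, 1)
        assert abs(ann.s1_times.size - truth.s1_times.size) <= 1
        assert abs(ann.s2_times.size - truth.s2_times.size) <= 1
        assert ann.presumed_period == pytest.approx(1.0, abs=0.01)

    def test_detected_s1_near_truth(self, clean_recording):
        rec, truth = clean_recording
        ann = detect_heart_sounds(rec, 1)
        for t in truth.s1_times[1:-1]:
            assert np.min(np.abs(ann.s1_times - t)) < 0.05

    def test_noise_only_record_does_not_crash(self):
        rng = np.random.default_rng(16)
        rec = Recording(
            samples=rng.normal(scale=0.1, size=(int(10 * 2560), 1)),
            sample_rate=2560.0,
            channel_roles=("pcg",),
        )
        ann = detect_heart_sounds(rec, 0)
        assert ann.unclassified_times.size >= 0  # ran to completion

    def test_deterministic(self, clean_recording):
        rec, _ = clean_recording
        a = detect_heart_sounds(rec, 1)
        b = detect_heart_sounds(rec, 1)
        np.testing.assert_array_equal(a.s1_times, b.s1_times)
        np.testing.assert_array_equal(a.s2_times, b.s2_times)
        assert a.presumed_period == b.presumed_period

    def test_short_record_rejected(self):
        rec = Recording(
            samples=np.zeros((2560, 1)), sample_rate=2560.0, channel_roles=("pcg",)
        )
        with pytest.raises(InsufficientDataError):
            detect_heart_sounds(rec, 0)

    def test_non_pcg_channel_rejected(self, clean_recording):
        rec, _ = clean_recording
        with pytest.raises(ValueError):
            detect_heart_sounds(rec, 0)  # channel 0 is the ECG

    def test_time_shift_equivariance(self, clean_recording):
        """Shifting the record start by a whole normalization window shifts
        interior detections by the same amount."""
        rec, _ = clean_recording
        fs = int(rec.sample_rate)
        a = Recording(rec.samples[: 25 * fs], rec.sample_rate, rec.channel_roles)
        b = Recording(rec.samples[fs : 26 * fs], rec.sample_rate, rec.channel_roles)
        ann_a = detect_heart_sounds(a, 1)
        ann_b = detect_heart_sounds(b, 1)
        interior = ann_a.s1_times[(ann_a.s1_times > 3.0) & (ann_a.s1_times < 22.0)]
        for t in interior:
            assert np.min(np.abs(ann_b.s1_times - (t - 1.0))) < 0.005

    def test_min_spacing_holds_in_final_output(self, clean_recording):
        rec, _ = clean_recording
        ann = detect_heart_sounds(rec, 1)
        all_times = np.sort(
            np.concatenate([ann.s1_times, ann.s2_times, ann.unclassified_times])
        )
        assert np.min(np.diff(all_times)) >= 0.15 - 1e-9
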