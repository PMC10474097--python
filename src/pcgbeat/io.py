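"""Recordings, annotation tracks, and pipeline configuration.

Time convention used throughout the package: event times are seconds from
record start (float); conversion to 0-based sample indices rounds to
nearest; windows cut from a signal are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import (
    ChannelRoleMismatchError,
    MissingSampleRateError,
    RecordingReadError,
)

VALID_ROLES = ("pcg", "ecg")
VALID_LABELS = ("S1", "S2", "U", "R", "T")


@dataclass
class Recording:
    """A uniformly sampled multichannel waveform.

    ``samples`` has shape ``(n_samples, n_channels)``; amplitudes are in
    arbitrary units (the amplitude scale cancels in the per-window
    normalization stage of the pipeline).
    """

    samples: np.ndarray
    sample_rate: float
    channel_roles: tuple[str, ...]
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape[0] == 1 and self.samples.shape[1] > 1:
            # accept 1-D input as a single channel
            if len(self.channel_roles) == 1:
                self.samples = self.samples.T
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.channel_roles = tuple(self.channel_roles)
        for role in self.channel_roles:
            if role not in VALID_ROLES:
                raise ChannelRoleMismatchError(f"unknown channel role {role!r}")
        if len(self.channel_roles) != self.n_channels:
            raise ChannelRoleMismatchError(
                f"{len(self.channel_roles)} roles for {self.n_channels} channels"
            )
        if not self.channel_names:
            self.channel_names = tuple(
                f"{role.upper()}{i}" for i, role in enumerate(self.channel_roles)
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise ChannelRoleMismatchError(
                f"{len(self.channel_names)} names for {self.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sample_rate

    def channel(self, index: int) -> np.ndarray:
        return self.samples[:, index]

    def channels_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == role]


@dataclass
class AnnotationTrack:
    """Time-stamped events (detected or ground truth) on one record."""

    times: np.ndarray
    labels: np.ndarray
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.times.ndim != 1 or self.labels.shape != self.times.shape:
            raise ValueError("times and labels must be 1-D and equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        if self.amplitudes is None:
            self.amplitudes = np.full(self.times.shape, np.nan)
        else:
            self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
            if self.amplitudes.shape != self.times.shape:
                raise ValueError("amplitudes length mismatch")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PipelineConfig:
    """Every tunable of the detection and evaluation chain.

    Defaults are the published operating point of the system this package
    implements: 2-100 Hz order-2 band-pass, db12 level-5 wavelet denoising,
    1 s normalization sections, 10 Hz envelope smoothing, 150 ms minimum
    peak spacing, K-means centroid fractions 0.35/0.65/1.0 of the presumed
    heart period, 0.8x/1.3x confirmation factors with a 300 ms recovery
    window, ECG band-pass 1-150 Hz with a 48-52 Hz power-line band-stop,
    5 s / 70% adaptive R threshold, S1/S2 evaluation window factors
    0.2/1.2/0.6, and 2 s heart-rate windows.
    """

    # PCG preprocessing
    bandpass_low_hz: float = 2.0
    bandpass_high_hz: float = 100.0
    bandpass_order: int = 2
    wavelet: str = "db12"
    wavelet_level: int = 5
    normalization_window_s: float = 1.0
    # envelope
    envelope_cutoff_hz: float = 10.0
    envelope_order: int = 2
    shannon_log_base: float = 0.0  # 0.0 -> natural log
    # peak detection / classification
    min_peak_spacing_s: float = 0.15
    period_quantum_s: float = 0.01
    centroid_fractions: tuple[float, float, float] = (0.35, 0.65, 1.0)
    confirm_low_factor: float = 0.8
    confirm_high_factor: float = 1.3
    recovery_window_s: float = 0.3
    # ECG reference
    ecg_bandpass_hz: tuple[float, float] = (1.0, 150.0)
    ecg_bandstop_hz: tuple[float, float] = (48.0, 52.0)
    ecg_filter_order: int = 2
    r_window_s: float = 5.0
    r_threshold_frac: float = 0.7
    r_refractory_s: float = 0.25
    ecg_invert: bool = False
    t_search_start_s: float = 0.12
    t_search_end_frac: float = 0.40
    # evaluation
    s1_window_factor: float = 0.2
    s2_window_start_factor: float = 1.2
    s2_window_end_factor: float = 0.6
    hr_window_s: float = 2.0
    # misc
    random_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value (TOML) config; every key is optional."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def _read_wav(path: Path) -> tuple[float, np.ndarray]:
    rate, data = wavfile.read(path)
    data = np.atleast_2d(data)
    if data.shape[0] == 1:
        data = data.T if data.shape[1] > 1 else data.reshape(-1, 1)
    if np.issubdtype(data.dtype, np.integer):
        # scale integer PCM to [-1, 1]
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return float(rate), data


def _read_csv(path: Path) -> np.ndarray:
    try:
        frame = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingReadError(f"cannot parse CSV {path}: {exc}") from exc
    # tolerate a single header row of non-numeric column names
    try:
        frame = frame.astype(np.float64)
    except (TypeError, ValueError):
        try:
            frame = frame.iloc[1:].astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise RecordingReadError(f"non-numeric data in {path}") from exc
    if frame.empty:
        raise RecordingReadError(f"no samples in {path}")
    return frame.to_numpy()


def read_recording(
    path: str | Path,
    format: str | None = None,
    sample_rate_override: float | None = None,
    channel_roles: Sequence[str] | None = None,
    channel_names: Sequence[str] | None = None,
) -> Recording:
    """Read a recording from WAV (PCM16/float) or delimited numeric text.

    ``format`` is inferred from the file extension when omitted.  CSV files
    carry no rate, so ``sample_rate_override`` is then required.  When
    ``channel_roles`` is omitted, a single channel defaults to ``pcg`` and a
    multichannel file defaults to ECG in column 0 followed by PCG channels
    (the layout of the acquisition system the pipeline was built around).
    """
    path = Path(path)
    if not path.exists():
        raise RecordingReadError(f"no such file: {path}")
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    format = format.lower()
    if format == "wav":
        rate, data = _read_wav(path)
        if sample_rate_override is not None:
            rate = float(sample_rate_override)
    elif format in ("csv", "txt"):
        data = _read_csv(path)
        if sample_rate_override is None:
            raise MissingSampleRateError(
                f"{path}: CSV carries no sample rate; pass sample_rate_override"
            )
        rate = float(sample_rate_override)
    else:
        raise RecordingReadError(f"unsupported format {format!r}")
    n_ch = data.shape[1]
    if channel_roles is None:
        channel_roles = ("pcg",) if n_ch == 1 else ("ecg",) + ("pcg",) * (n_ch - 1)
    if len(channel_roles) != n_ch:
        raise ChannelRoleMismatchError(
            f"{len(channel_roles)} roles given for {n_ch} channels in {path}"
        )
    return Recording(
        samples=data,
        sample_rate=rate,
        channel_roles=tuple(channel_roles),
        channel_names=tuple(channel_names) if channel_names else (),
    )


def write_recording(recording: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as float32 WAV or plain CSV (one column per channel)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format == "wav":
        wavfile.write(path, int(round(recording.sample_rate)), recording.samples.astype(np.float32))
    elif format in ("csv", "txt"):
        np.savetxt(path, recording.samples, delimiter=",", fmt="%.9g")
    else:
        raise ValueError(f"unsupported format {format!r}")


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    """Write an annotation track as CSV: ``time_s,label,amplitude``.

    Times are printed with 6 decimals so a round trip is exact to well
    under one sample period at any plausible audio rate.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_s": [f"{t:.6f}" for t in track.times],
            "label": track.labels,
            "amplitude": [f"{a:.9g}" for a in track.amplitudes],
        }
    )
    frame.to_csv(path, index=False)


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an annotation track written by :func:`write_annotations`."""
    frame = pd.read_csv(path)
    if frame.empty:
        return AnnotationTrack(times=np.empty(0), labels=np.empty(0, dtype=object))
    return AnnotationTrack(
        times=frame["time_s"].to_numpy(dtype=np.float64),
        labels=frame["label"].to_numpy(dtype=object),
        amplitudes=frame["amplitude"].to_numpy(dtype=np.float64),
    )


def time_to_index(time_s: float | np.ndarray, sample_rate: float) -> np.ndarray | int:
    """Nearest-sample index for a time in seconds (package-wide convention)."""
    idx = np.round(np.asarray(time_s) * sample_rate).astype(int)
    return int(idx) if idx.ndim == 0 else idx
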