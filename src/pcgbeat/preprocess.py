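"""PCG preprocessing: band-pass filtering, wavelet denoising, normalization.

All linear filters in the package are Butterworth designs applied
forward-backward (zero phase) with symmetric signal extension, so heart
sound timing is preserved through every stage.  "Order" below is the
low-pass prototype order, i.e. ``order=2`` gives two poles per band edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .errors import InvalidFilterBandError, SignalTooShortError


@dataclass
class FilteredSignal:
    """A single-channel signal plus the ordered list of stages applied."""

    samples: np.ndarray
    sample_rate: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.provenance = tuple(self.provenance)


def _zero_phase(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # symmetric (mirror) extension avoids edge spikes that would become
    # false envelope peaks
    return sps.sosfiltfilt(sos, x, padtype="even")


def bandpass_pcg(
    x: np.ndarray,
    sample_rate: float,
    low_hz: float = 2.0,
    high_hz: float = 100.0,
    order: int = 2,
) -> FilteredSignal:
    """Zero-phase Butterworth band-pass, default 2-100 Hz.

    The pass band keeps the S1/S2 oscillatory energy (below 100 Hz) while
    removing baseline wander and motion drift below 2 Hz and broadband
    noise above 100 Hz.
    """
    x = np.asarray(x, dtype=np.float64)
    nyq = sample_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidFilterBandError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sample_rate, output="sos")
    y = _zero_phase(sos, x)
    return FilteredSignal(y, sample_rate, (f"bandpass({low_hz}-{high_hz}Hz,n={order})",))


def butter_bandpass_gain(
    freq_hz: np.ndarray | float,
    low_hz: float,
    high_hz: float,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray | float:
    """Closed-form magnitude response of the band-pass in :func:`bandpass_pcg`.

    From the analog low-pass prototype of the given order,
    ``|H|^2 = 1 / (1 + ((w^2 - w0^2) / (w * bw))^(2 * order))`` with
    ``w0^2 = wl * wh`` and ``bw = wh - wl``; forward-backward application
    squares the magnitude.  Used by tests as an independent oracle of the
    steady-state gain (bilinear pre-warping effects are below the test
    tolerance far from Nyquist).
    """
    w = 2.0 * np.pi * np.asarray(freq_hz, dtype=np.float64)
    wl, wh = 2.0 * np.pi * low_hz, 2.0 * np.pi * high_hz
    ratio = (w**2 - wl * wh) / (w * (wh - wl))
    mag = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    return mag**2 if zero_phase else mag


def wavelet_denoise(
    x: np.ndarray,
    wavelet: str = "db12",
    level: int = 5,
) -> FilteredSignal | np.ndarray:
    """Wavelet-shrinkage denoising (default Daubechies db12, 5 levels).

    The signal is decomposed with symmetric extension; every detail band
    is soft-thresholded with the universal threshold
    ``sigma * sqrt(2 ln N)``, where ``sigma`` is estimated as
    ``MAD(finest detail) / 0.6745``; the approximation band is untouched
    and the signal is rebuilt by the inverse transform.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(n, wav.dec_len)
    if level > max_level:
        raise SignalTooShortError(
            f"{n} samples support at most level {max_level} for {wavelet}"
        )
    coeffs = pywt.wavedec(x, wav, level=level, mode="symmetric")
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    if sigma > 0:
        thresh = sigma * np.sqrt(2.0 * np.log(n))
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
        ]
    y = pywt.waverec(coeffs, wav, mode="symmetric")[:n]
    return FilteredSignal(y, np.nan, (f"wavelet({wavelet},level={level})",))


def normalize_windowed(
    x: np.ndarray,
    sample_rate: float,
    window_s: float = 1.0,
) -> FilteredSignal:
    """Scale each consecutive non-overlapping window to peak amplitude 1.

    Within every ``window_s`` section the signal is divided by its own
    ``max |x|``, confining amplitudes to [-1, 1] while keeping loud
    transients from suppressing heart sounds elsewhere in the record.  A
    sub-epsilon (all-zero) window is returned as zeros; a trailing partial
    window is normalized by its own maximum.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.empty_like(x)
    step = max(1, int(round(window_s * sample_rate)))
    for start in range(0, x.size, step):
        seg = x[start : start + step]
        peak = np.max(np.abs(seg)) if seg.size else 0.0
        y[start : start + step] = seg / peak if peak > 1e-12 else 0.0
    return FilteredSignal(y, sample_rate, (f"normalize(window={window_s}s)",))


def preprocess_pcg(x: np.ndarray, sample_rate: float, config) -> FilteredSignal:
    """Full preprocessing chain: band-pass -> wavelet denoise -> normalize."""
    stage1 = bandpass_pcg(
        x, sample_rate, config.bandpass_low_hz, config.bandpass_high_hz, config.bandpass_order
    )
    stage2 = wavelet_denoise(stage1.samples, config.wavelet, config.wavelet_level)
    stage3 = normalize_windowed(stage2.samples, sample_rate, config.normalization_window_s)
    return FilteredSignal(
        stage3.samples,
        sample_rate,
        stage1.provenance + stage2.provenance + stage3.provenance,
    )
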