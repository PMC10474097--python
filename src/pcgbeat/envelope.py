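"""Shannon-energy envelope of the normalized PCG.

The third-order Shannon energy ``E_S = -|x^3| log|x^3|`` emphasizes
medium-intensity oscillations (it peaks at ``|x^3| = 1/e``) while
suppressing both low-level noise and samples near full scale, which makes
the S1/S2 bursts stand out as smooth humps once the energy is low-pass
filtered.  The log base only rescales the energy by a positive constant
and cancels in the thresholds, which are expressed in standardized units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConstantSignalError, InvalidFilterBandError, OutOfRangeError


@dataclass
class EnergyEnvelope:
    """Shannon energy, its smoothed version, and the standardized envelope.

    ``mu`` and ``sigma`` are the global mean and standard deviation of the
    smoothed energy; ``normalized = (envelope - mu) / sigma`` is the signal
    the peak detector operates on.
    """

    shannon_energy: np.ndarray
    envelope: np.ndarray
    normalized: np.ndarray
    mu: float
    sigma: float
    sample_rate: float


def shannon_energy(x: np.ndarray, log_base: float = 0.0) -> np.ndarray:
    """Pointwise third-order Shannon energy of a signal in [-1, 1].

    ``log_base`` of 0 selects the natural logarithm (the default); any
    other base rescales the output by ``1 / ln(base)``.  The limit
    convention ``0 * log 0 = 0`` applies, so the energy is 0 where x = 0
    and where |x| = 1, and non-negative everywhere between.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(np.abs(x) > 1.0 + 1e-9):
        raise OutOfRangeError("shannon_energy input must lie in [-1, 1]")
    a = np.abs(np.clip(x, -1.0, 1.0)) ** 3
    out = np.zeros_like(a)
    nz = a > 0
    out[nz] = -a[nz] * np.log(a[nz])
    if log_base and log_base != np.e:
        out /= np.log(log_base)
    return out


def envelope_lowpass(
    energy: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = 10.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (default 10 Hz) of the energy signal."""
    energy = np.asarray(energy, dtype=np.float64)
    nyq = sample_rate / 2.0
    if not (0.0 < cutoff_hz < nyq):
        raise InvalidFilterBandError(f"cutoff {cutoff_hz} outside (0, {nyq})")
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, energy, padtype="even")


def butter_lowpass_gain(
    freq_hz: np.ndarray | float,
    cutoff_hz: float,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray | float:
    """Closed-form low-pass magnitude, squared for forward-backward use."""
    mag = 1.0 / np.sqrt(1.0 + (np.asarray(freq_hz, dtype=np.float64) / cutoff_hz) ** (2 * order))
    return mag**2 if zero_phase else mag


def normalize_energy(envelope: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize the smoothed energy: ``(envelope - mean) / std``.

    Returns ``(normalized, mu, sigma)``; ``mu`` and ``sigma`` feed the
    detection thresholds.  Raises on (near-)constant input.
    """
    envelope = np.asarray(envelope, dtype=np.float64)
    mu = float(np.mean(envelope))
    sigma = float(np.std(envelope))
    if sigma <= 1e-15:
        raise ConstantSignalError("envelope is constant; cannot standardize")
    return (envelope - mu) / sigma, mu, sigma


def compute_envelope(
    normalized_signal: np.ndarray, sample_rate: float, config
) -> EnergyEnvelope:
    """Full envelope chain: Shannon energy -> 10 Hz smoothing -> standardize."""
    es = shannon_energy(normalized_signal, config.shannon_log_base)
    env = envelope_lowpass(es, sample_rate, config.envelope_cutoff_hz, config.envelope_order)
    normalized, mu, sigma = normalize_energy(env)
    return EnergyEnvelope(
        shannon_energy=es,
        envelope=env,
        normalized=normalized,
        mu=mu,
        sigma=sigma,
        sample_rate=sample_rate,
    )
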