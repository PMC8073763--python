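"""Analytic signal via the FFT Hilbert construction and instantaneous phase.

The Hilbert transform produces a 90°-shifted copy of the signal; together
they form the analytic signal x(t) = s(t) + j·s̃(t), from which the
instantaneous magnitude a(t) = sqrt(s² + s̃²) and phase φ(t) = atan2(s̃, s)
follow sample by sample.

The transform is computed in four steps: FFT of the input; construction of
the weight vector h with h = 1 at the DC and Nyquist bins, h = 2 over the
positive-frequency bins, and h = 0 over the negative-frequency bins;
multiplication; inverse FFT.  The imaginary part of the result is the
Hilbert transform.  Odd-length inputs are reflect-padded by one sample (the
weight vector is defined for even lengths) and trimmed after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "AnalyticSignal",
    "PhaseSeries",
    "hilbert_weights",
    "hilbert_fft",
    "instantaneous_phase",
    "unwrap_phase",
    "envelope_phase",
]


@dataclass
class AnalyticSignal:
    """Real signal, its Hilbert transform, and the instantaneous magnitude."""

    real: np.ndarray
    imag: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.real, self.imag)


@dataclass
class PhaseSeries:
    """Wrapped (−π, π] and unwrapped instantaneous phase, radians."""

    wrapped: np.ndarray
    unwrapped: np.ndarray
    fs: float
    n_degenerate: int = 0  # samples with real = imag = 0, phase carried forward


def hilbert_weights(n: int) -> np.ndarray:
    """Spectral weight vector h for an even transform length n.

    h[0] = h[n/2] = 1 (DC and Nyquist), h[1..n/2−1] = 2, rest 0
    (0-based; positions 1 and n/2+1 in 1-based counting).
    """
    if n < 4 or n % 2:
        raise ValueError(f"transform length must be even and >= 4, got {n}")
    h = np.zeros(n)
    h[0] = h[n // 2] = 1.0
    h[1 : n // 2] = 2.0
    return h


def hilbert_fft(x: np.ndarray) -> AnalyticSignal:
    """Analytic signal by FFT weighting.

    Odd-length signals are padded with one reflected end sample before the
    FFT and trimmed afterwards.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 samples for the Hilbert transform, got {n}")
    padded = n % 2 == 1
    if padded:
        x_t = np.concatenate([x, x[-2:-1]])
    else:
        x_t = x
    h = hilbert_weights(len(x_t))
    analytic = sp_fft.ifft(h * sp_fft.fft(x_t))
    imag = analytic.imag[:n] if padded else analytic.imag
    return AnalyticSignal(real=x, imag=imag)


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Remove 2π phase slips: wherever a consecutive jump is ≥ π in
    magnitude, shift the remainder by the multiple of ±2π that brings the
    jump below π.  The first sample is unchanged."""
    return np.unwrap(np.asarray(wrapped, dtype=float))


def instantaneous_phase(a: AnalyticSignal, fs: float = 1.0) -> PhaseSeries:
    """Four-quadrant instantaneous phase of an analytic signal, unwrapped.

    Samples where real and imaginary parts are both exactly zero have no
    defined angle; their phase is carried forward from the previous sample
    (and counted in ``n_degenerate``).
    """
    real, imag = a.real, a.imag
    wrapped = np.arctan2(imag, real)
    degenerate = (real == 0) & (imag == 0)
    n_deg = int(degenerate.sum())
    if n_deg:
        wrapped = wrapped.copy()
        idx = np.flatnonzero(degenerate)
        for i in idx:  # rare; loop is fine
            wrapped[i] = wrapped[i - 1] if i > 0 else 0.0
    return PhaseSeries(
        wrapped=wrapped,
        unwrapped=unwrap_phase(wrapped),
        fs=fs,
        n_degenerate=n_deg,
    )


def envelope_phase(env: np.ndarray, fs: float) -> PhaseSeries:
    """Instantaneous phase series of one envelope sample series."""
    return instantaneous_phase(hilbert_fft(env), fs)
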