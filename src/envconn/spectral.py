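"""Brick-wall Fourier filtering, boundary trimming, analytic signals and
slow (sub-1-Hz) amplitude envelopes.

All filters here are ideal (brick-wall) discrete-Fourier filters: the DFT
coefficients outside the band of interest are set exactly to zero.  They are
linear projections (idempotent), and two signals filtered into disjoint
half-open bands have an exactly zero zero-lag inner product — the property
that makes cross-frequency envelope coupling immune to zero-lag leakage.

Functions operate along the last axis and accept arrays of any leading
shape (channels x time, sources x time, ...).
"""

from __future__ import annotations

import numpy as np

from .bands import BandError, FrequencyBand, get_band

__all__ = [
    "brickwall_bandpass",
    "brickwall_lowpass",
    "trim_boundaries",
    "analytic_signal",
    "analytic_bandpass",
    "slow_envelope",
]


def _analytic_from_rfft(coeff: np.ndarray, n: int) -> np.ndarray:
    """Analytic signal from one-sided DFT coefficients.

    Standard discrete convention: DC and (for even n) the Nyquist bin are
    kept as-is, all other positive-frequency bins are doubled, negative
    bins are zero.
    """
    full = np.zeros(coeff.shape[:-1] + (n,), dtype=complex)
    full[..., : coeff.shape[-1]] = coeff
    full[..., 1 : (n + 1) // 2] *= 2.0
    return np.fft.ifft(full, axis=-1)


def brickwall_bandpass(
    x: np.ndarray, fs_hz: float, band: "FrequencyBand | str"
) -> np.ndarray:
    """Zero all DFT coefficients with |f| outside [f_lo, f_hi).

    The band edge convention is half-open: the bin at exactly ``f_lo``
    belongs to the band, the bin at ``f_hi`` does not, so the canonical
    band set partitions the spectrum with no shared bin.
    """
    band = get_band(band)
    band.check_nyquist(fs_hz)
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    coeff = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    keep = (f >= band.f_lo) & (f < band.f_hi)
    coeff[..., ~keep] = 0.0
    return np.fft.irfft(coeff, n=n, axis=-1)


def brickwall_lowpass(x: np.ndarray, fs_hz: float, cutoff_hz: float) -> np.ndarray:
    """Zero all DFT coefficients above ``cutoff_hz``; DC is retained."""
    if cutoff_hz <= 0:
        raise BandError(f"low-pass cutoff must be positive, got {cutoff_hz}")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    coeff = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    coeff[..., f > cutoff_hz] = 0.0
    return np.fft.irfft(coeff, n=n, axis=-1)


def trim_boundaries(x: np.ndarray, fs_hz: float, trim_s: float = 1.0) -> np.ndarray:
    """Drop ``trim_s`` seconds at each end of the last axis.

    Brick-wall filters wrap around the record boundary, so the first and
    last second of filtered data carry circular-convolution artifacts and
    are discarded before any statistic is computed.
    """
    if trim_s < 0:
        raise ValueError(f"trim_s must be >= 0, got {trim_s}")
    n_trim = int(round(trim_s * fs_hz))
    if n_trim == 0:
        return np.asarray(x)
    x = np.asarray(x)
    if x.shape[-1] <= 2 * n_trim:
        raise ValueError(
            f"signal of {x.shape[-1]} samples too short to trim "
            f"{n_trim} samples from each end"
        )
    return x[..., n_trim:-n_trim]


def analytic_signal(x_band: np.ndarray) -> np.ndarray:
    """Complex analytic extension (Hilbert transform) of a band-limited signal.

    Negative-frequency coefficients are zeroed and positive ones doubled;
    the real part equals the input and the magnitude is the instantaneous
    amplitude envelope.
    """
    x = np.asarray(x_band, dtype=float)
    n = x.shape[-1]
    return _analytic_from_rfft(np.fft.rfft(x, axis=-1), n)


def analytic_bandpass(
    x: np.ndarray, fs_hz: float, band: "FrequencyBand | str"
) -> np.ndarray:
    """Analytic signal of the brick-wall band-filtered input, in one pass.

    Equivalent to ``analytic_signal(brickwall_bandpass(x, fs_hz, band))``
    but with a single forward transform; the real part equals the
    band-filtered signal.
    """
    band = get_band(band)
    band.check_nyquist(fs_hz)
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    coeff = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    coeff[..., (f < band.f_lo) | (f >= band.f_hi)] = 0.0
    return _analytic_from_rfft(coeff, n)


def slow_envelope(
    analytic: np.ndarray, fs_hz: float, cutoff_hz: float = 1.0
) -> np.ndarray:
    """Slow amplitude envelope: |analytic| brick-wall low-passed at ``cutoff_hz``.

    The sub-1-Hz envelope is the quantity whose between-region Pearson
    correlation defines resting-state coupling here.
    """
    mag = np.abs(np.asarray(analytic))
    return brickwall_lowpass(mag, fs_hz, cutoff_hz)
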