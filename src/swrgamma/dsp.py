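"""Signal-processing primitives: zero-phase filters, Morlet CWT, spectra.

All filters are applied forward-backward (zero phase); the complex Morlet
wavelet uses the cmor2-1 parameterization (bandwidth 2, center frequency 1),
the standard choice for ripple-band time-frequency display in hippocampal
electrophysiology. Edge effects are handled by reflect-padding the input by
one filter/wavelet support length and trimming afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import fft as sfft
from scipy import signal

from .io_core import DataError, Trace

__all__ = [
    "ScaleMap",
    "Spectrum",
    "bandpass",
    "notch_line",
    "morlet_cwt",
    "max_abs_coeff",
    "welch_psd",
    "fft_avg_spectrum",
    "spectral_peak",
]

#: cmor2-1: Gaussian-envelope bandwidth 2, center frequency 1 (cycles per unit)
CMOR_BANDWIDTH = 2.0
CMOR_CENTER_FREQ = 1.0


@dataclass
class ScaleMap:
    """Wavelet scales with their center frequencies for a band at a given fs.

    Scales are chosen so center frequencies are log-spaced across ``band``
    (uniform relative bandwidth); ``center_freqs`` is strictly increasing and
    its first/last entries equal the band edges.
    """

    scales: np.ndarray
    center_freqs: np.ndarray
    band: tuple[float, float]
    fs: float

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @classmethod
    def for_band(cls, band: tuple[float, float], n_scales: int, fs: float,
                 spacing: Literal["log", "linear"] = "log") -> "ScaleMap":
        low, high = band
        if not 0 < low < high < fs / 2:
            raise ValueError(f"band {band} must lie inside (0, {fs / 2}) Hz")
        if n_scales < 2:
            raise ValueError("need at least two scales")
        if spacing == "log":
            freqs = np.geomspace(low, high, n_scales)
        elif spacing == "linear":
            freqs = np.linspace(low, high, n_scales)
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        # cmorB-C at scale s on a grid of step 1/fs has center frequency C*fs/s
        scales = CMOR_CENTER_FREQ * fs / freqs
        return cls(scales=scales, center_freqs=freqs, band=(low, high), fs=fs)

    def support_samples(self) -> int:
        """Half-support (samples) of the longest (lowest-frequency) wavelet.

        The cmor envelope is Gaussian with standard deviation sqrt(B/2) in
        wavelet time units; five standard deviations at the largest scale.
        """
        sigma = np.sqrt(CMOR_BANDWIDTH / 2.0)
        return int(np.ceil(5.0 * sigma * self.scales.max()))


@dataclass
class Spectrum:
    """One-sided power spectral density with its frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    method: Literal["welch", "fft_avg"]
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise DataError("spectrum frequencies must be strictly increasing")
        if self.resolution <= 0:
            raise DataError("spectral resolution must be positive")


# ---------------------------------------------------------------------------
# Filtering


def _zero_phase_sos(trace: Trace, sos: np.ndarray) -> Trace:
    """Apply an SOS filter forward-backward with reflect padding."""
    n = len(trace)
    padlen = min(n - 1, max(3 * (2 * sos.shape[0] + 1), int(0.5 * trace.fs)))
    y = signal.sosfiltfilt(sos, trace.samples, padlen=padlen)
    return trace.copy_with(y)


def bandpass(trace: Trace, low: float, high: float, order: int = 2) -> Trace:
    """Zero-phase Butterworth band-pass filter.

    ``order`` is the order of each pass; the forward-backward application
    squares the magnitude response (an order-2 design acts as an effective
    4th-order filter with zero group delay).
    """
    nyq = trace.fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {nyq}) Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=trace.fs, output="sos")
    return _zero_phase_sos(trace, sos)


def notch_line(trace: Trace, line_freq: float = 50.0,
               include_harmonics: bool = True, q: float = 30.0,
               max_freq: float | None = None) -> Trace:
    """Remove mains interference with second-order IIR notch filters.

    A notch is placed at ``line_freq`` and, when ``include_harmonics`` is set,
    at every integer harmonic below ``max_freq`` (default: Nyquist). Filters
    are applied zero-phase.
    """
    nyq = trace.fs / 2
    if not 0 < line_freq < nyq:
        raise ValueError(f"line frequency {line_freq} Hz outside (0, {nyq}) Hz")
    top = nyq if max_freq is None else min(max_freq, nyq)
    freqs = [line_freq]
    if include_harmonics:
        k = 2
        while k * line_freq < top:
            freqs.append(k * line_freq)
            k += 1
    y = trace.samples
    out = trace
    for f0 in freqs:
        b, a = signal.iirnotch(f0, q, fs=trace.fs)
        padlen = min(len(out) - 1, 3 * max(len(a), len(b)) + int(0.5 * trace.fs))
        y = signal.filtfilt(b, a, out.samples, padlen=padlen)
        out = out.copy_with(y)
    return out


# ---------------------------------------------------------------------------
# Complex Morlet wavelet transform


def _cmor_kernels(scale_map: ScaleMap) -> list[np.ndarray]:
    """Time-reversed conjugate cmor2-1 wavelets, one per scale, L2-normalized.

    psi(t) = (pi*B)^(-1/4)... up to normalization: a Gaussian envelope of
    variance B/2 carrying exp(2*pi*i*C*t); sampled over +-5 envelope SDs at
    each scale on the trace's sample grid.
    """
    kernels = []
    sigma = np.sqrt(CMOR_BANDWIDTH / 2.0)
    for s in scale_map.scales:
        half = int(np.ceil(5.0 * sigma * s))
        t = np.arange(-half, half + 1) / s  # wavelet time units
        psi = ((np.pi * CMOR_BANDWIDTH) ** -0.5
               * np.exp(-(t**2) / CMOR_BANDWIDTH)
               * np.exp(2j * np.pi * CMOR_CENTER_FREQ * t))
        # L1 (1/s) normalization: for a pure tone the |coefficient| maximum
        # falls exactly on the matching center frequency, so peak-frequency
        # readout is unbiased across the band
        kernels.append(np.conj(psi[::-1]) / s)
    return kernels


_KERNEL_FFT_CACHE: dict[tuple, tuple] = {}


def _kernel_ffts(scale_map: ScaleMap, nfft: int):
    key = (nfft, scale_map.fs, scale_map.n_scales, scale_map.band)
    hit = _KERNEL_FFT_CACHE.get(key)
    if hit is None:
        kernels = _cmor_kernels(scale_map)
        halves = np.array([(len(k) - 1) // 2 for k in kernels])
        K = np.stack([sfft.fft(k, nfft) for k in kernels])
        hit = (K, halves)
        if len(_KERNEL_FFT_CACHE) > 32:
            _KERNEL_FFT_CACHE.clear()
        _KERNEL_FFT_CACHE[key] = hit
    return hit


def morlet_cwt(trace: Trace, scale_map: ScaleMap) -> np.ndarray:
    """Complex Morlet (cmor2-1) CWT; returns an (n_scales, n_samples) matrix.

    Coefficient (s, t) is the correlation of the signal with the scaled,
    conjugated wavelet (L2 normalization, FFT convolution batched over
    scales). The input is reflect-padded by the support of the longest
    wavelet and trimmed afterwards, so coefficients near the trace edges are
    free of wrap-around artifacts. Rows are ordered as
    ``scale_map.center_freqs`` (increasing frequency).
    """
    if scale_map.fs != trace.fs:
        raise ValueError("scale map was built for a different sampling rate")
    pad = scale_map.support_samples()
    n = len(trace)
    if n < 2:
        raise DataError("trace shorter than the longest wavelet support")
    x = np.pad(trace.samples, pad, mode="reflect")
    max_len = 2 * pad + 1
    nfft = sfft.next_fast_len(len(x) + max_len - 1)
    K, halves = _kernel_ffts(scale_map, nfft)
    Xf = sfft.fft(x, nfft)
    full = sfft.ifft(K * Xf[None, :], axis=-1)
    # 'same' alignment per scale, then trim the reflect padding
    out = np.empty((scale_map.n_scales, n), complex)
    for i, h in enumerate(halves):
        out[i] = full[i, pad + h: pad + h + n]
    return out


def max_abs_coeff(coeffs: np.ndarray, window: tuple[int, int] | None = None) -> float:
    """Maximum |coefficient| over all scales within a sample-index window.

    ``window`` is a half-open ``(start, stop)`` index pair; the full extent
    when omitted.
    """
    if window is not None:
        i0, i1 = window
        coeffs = coeffs[:, i0:i1]
    if coeffs.size == 0:
        raise ValueError("empty coefficient window")
    return float(np.abs(coeffs).max())


# ---------------------------------------------------------------------------
# Spectra


def welch_psd(trace: Trace, segment_s: float = 1.0, overlap: float = 0.5) -> Spectrum:
    """Welch-averaged one-sided PSD (Hann taper), density in units²/Hz.

    For a long stationary signal the integrated density approximates the
    signal variance (Parseval).
    """
    nperseg = int(round(segment_s * trace.fs))
    if nperseg < 16:
        raise ValueError("Welch segment must hold at least 16 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if len(trace) < nperseg:
        raise DataError("trace shorter than one Welch segment")
    freqs, power = signal.welch(trace.samples, fs=trace.fs, window="hann",
                                nperseg=nperseg, noverlap=int(nperseg * overlap),
                                detrend="constant", scaling="density")
    return Spectrum(freqs=freqs[1:], power=power[1:], method="welch",
                    resolution=trace.fs / nperseg)


def fft_avg_spectrum(trace: Trace, n_segments: int = 4) -> Spectrum:
    """Mean of periodograms over consecutive non-overlapping segments.

    Splits the trace into ``n_segments`` equal contiguous pieces and averages
    their one-sided periodogram densities.
    """
    if n_segments < 1:
        raise ValueError("need at least one segment")
    seg_len = len(trace) // n_segments
    if seg_len < 16:
        raise DataError("trace too short for the requested segment count")
    psds = []
    for k in range(n_segments):
        seg = trace.samples[k * seg_len:(k + 1) * seg_len]
        freqs, p = signal.periodogram(seg, fs=trace.fs, window="hann",
                                      detrend="constant", scaling="density")
        psds.append(p)
    power = np.mean(psds, axis=0)
    return Spectrum(freqs=freqs[1:], power=power[1:], method="fft_avg",
                    resolution=trace.fs / seg_len)


def spectral_peak(spectrum: Spectrum, band: tuple[float, float]) -> tuple[float, float, bool]:
    """Frequency and power of the maximal density bin within ``band``.

    Returns ``(peak_freq, peak_power, tie)``; ties are broken toward the
    lower frequency with ``tie=True``.
    """
    low, high = band
    sel = (spectrum.freqs >= low) & (spectrum.freqs <= high)
    if not sel.any():
        raise ValueError(f"band {band} does not intersect the spectrum support")
    f = spectrum.freqs[sel]
    p = spectrum.power[sel]
    imax = int(np.argmax(p))  # argmax returns the first (lowest-frequency) maximum
    tie = bool(np.sum(p == p[imax]) > 1)
    return float(f[imax]), float(p[imax]), tie
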