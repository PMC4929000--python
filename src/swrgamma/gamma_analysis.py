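"""Characterization of oscillatory gamma (and theta) episodes.

An episode is summarized by its spectral peak — frequency and power density of
the maximal bin within the band — and by the exposure metric
``power x duration`` (peak power times episode length), which is what gets
correlated with the subsequent change in SWR area.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .dsp import bandpass, fft_avg_spectrum, spectral_peak, welch_psd
from .io_core import DataError, GammaEpoch, Trace

__all__ = [
    "GAMMA_BAND",
    "THETA_BAND",
    "find_oscillation_epochs",
    "characterize_epoch",
    "band_power",
    "compare_weak_gamma",
]

#: conventional rodent band edges; peaks are typically ~46 Hz (gamma), ~7 Hz (theta)
GAMMA_BAND = (25.0, 90.0)
THETA_BAND = (4.0, 12.0)


def find_oscillation_epochs(trace: Trace, band: tuple[float, float] = GAMMA_BAND,
                            power_k: float = 3.0, min_duration: float = 10.0,
                            epochs: Sequence[tuple[float, float]] | None = None,
                            ) -> list[tuple[float, float]]:
    """Detect contiguous episodes of band-limited oscillatory activity.

    The band-passed trace is rectified and smoothed (1 Hz zero-phase low-pass)
    into a power envelope; samples above ``median + power_k * 1.4826 * MAD``
    mark oscillatory activity, and supra-threshold runs of at least
    ``min_duration`` seconds are returned. The threshold is scale-free, so
    detection is invariant to overall amplitude scaling. Explicit ``epochs``
    annotations, when given, bypass detection and are returned verbatim.
    """
    if epochs is not None:
        return [tuple(e) for e in epochs]
    from scipy import signal as _sig

    bp = bandpass(trace, *band, order=2)
    env = np.abs(bp.samples)
    sos = _sig.butter(2, 1.0, btype="lowpass", fs=trace.fs, output="sos")
    env = _sig.sosfiltfilt(sos, env)
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    thr = med + power_k * 1.4826 * mad
    mask = env > thr
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    out = []
    for s, e in zip(starts, stops):
        if (e - s) / trace.fs >= min_duration:
            out.append((trace.t0 + s / trace.fs, trace.t0 + e / trace.fs))
    return out


def characterize_epoch(trace: Trace, epoch: tuple[float, float],
                       band: tuple[float, float] = GAMMA_BAND,
                       method: Literal["welch", "fft_avg"] = "fft_avg",
                       n_segments: int = 4, segment_s: float = 1.0,
                       overlap: float = 0.5) -> GammaEpoch:
    """Spectral summary of one oscillatory episode.

    Peak frequency and power come from the chosen spectral estimate of the
    episode restricted to ``band``; ``power_x_duration`` follows as
    peak power times episode length.
    """
    t0, t1 = epoch
    if t1 - t0 < 2.0:
        raise DataError("epoch shorter than 2 s cannot be characterized")
    seg = trace.slice(t0, t1)
    if method == "welch":
        spec = welch_psd(seg, segment_s=segment_s, overlap=overlap)
    elif method == "fft_avg":
        spec = fft_avg_spectrum(seg, n_segments=n_segments)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    peak_freq, peak_power, _tie = spectral_peak(spec, band)
    return GammaEpoch(t_start=t0, t_end=t1, peak_freq=peak_freq,
                      peak_power=peak_power)


def band_power(trace: Trace, epoch: tuple[float, float],
               band: tuple[float, float] = GAMMA_BAND,
               segment_s: float = 1.0) -> float:
    """Band-integrated Welch power of an episode (units², diagnostic output)."""
    seg = trace.slice(*epoch)
    spec = welch_psd(seg, segment_s=segment_s)
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    return float(np.trapezoid(spec.power[sel], spec.freqs[sel]))


def compare_weak_gamma(first: GammaEpoch, second: GammaEpoch
                       ) -> tuple[float, float]:
    """Power change (%) and peak-frequency change (Hz) between two episodes."""
    if first.peak_power == 0:
        raise DataError("first epoch has zero peak power; percentage undefined")
    power_change = 100.0 * (second.peak_power - first.peak_power) / first.peak_power
    return power_change, second.peak_freq - first.peak_freq
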