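"""Sharp wave-ripple detection and quantification.

The detector follows the dual-criterion scheme standard in hippocampal LFP
work: the recording is split into a sharp-wave (2-50 Hz) and a ripple
(100-300 Hz) trace; candidate events are found on the ripple trace with a
voltage threshold of mean + 6 SD of the event-free recording, adjacent
supra-threshold ripples are grouped into events, and each candidate must then
pass a spectral criterion — its maximum absolute complex-Morlet wavelet
coefficient has to exceed mean + 1 SD of the coefficients of 70 ms event-free
cutouts taken just before the candidates. Event boundaries are set at the
local minima of the sharp-wave trace flanking the peak, and the SWR area is
the area under the sharp-wave curve between those boundaries.

All thresholds are relative to baseline statistics, so detection is invariant
to an overall amplitude rescaling of the recording. Manual curation (the
by-eye rejection/boundary adjustment step) is supported through an edit list
rather than an interactive display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .dsp import ScaleMap, bandpass, max_abs_coeff, morlet_cwt
from .io_core import BaselineStats, DataError, SWREvent, Trace

__all__ = [
    "DetectionConfig",
    "ValidatedCandidate",
    "CurationEdit",
    "split_bands",
    "estimate_baseline",
    "detect_ripple_candidates",
    "spectral_validate",
    "delimit_event",
    "quantify_event",
    "detect_swr",
    "evaluate_detection",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the SWR detector (defaults per the standard recipe)."""

    sw_band: tuple[float, float] = (2.0, 50.0)
    ripple_band: tuple[float, float] = (100.0, 300.0)
    voltage_k: float = 6.0       # SD multiplier of the ripple voltage threshold
    spectral_k: float = 1.0      # SD multiplier of the wavelet-coefficient threshold
    cutout_ms: float = 70.0      # event-free cutout length for the spectral null
    n_scales: int = 27           # Morlet scales across the ripple band
    group_gap_ms: float = 20.0   # adjacent ripples closer than this merge
    min_ripples: int = 3         # supra-threshold ripple segments per event
    boundary_search_ms: float = 100.0  # local-minima search half-window
    min_neighborhood_ms: float = 5.0   # a boundary must be minimal over this span
    filter_order: int = 2
    baseline_guard_ms: float = 100.0   # guard margin around provisional events
    baseline_robust_k: float = 6.0     # MAD multiplier of the first-pass mask

    def __post_init__(self) -> None:
        if self.voltage_k <= 0 or self.spectral_k < 0:
            raise ValueError("voltage_k must be > 0 and spectral_k >= 0")
        if min(self.cutout_ms, self.group_gap_ms, self.boundary_search_ms) <= 0:
            raise ValueError("window lengths must be positive")


@dataclass
class ValidatedCandidate:
    """A candidate interval with its spectral-criterion outcome."""

    t_start: float
    t_end: float
    max_abs_coeff: float
    accepted: bool
    cutout_found: bool = True


@dataclass(frozen=True)
class CurationEdit:
    """One manual edit: accept, reject, or override an event's boundaries."""

    event_index: int
    action: str  # accept | reject | set_bounds
    t_start: float = float("nan")
    t_end: float = float("nan")


# ---------------------------------------------------------------------------


def split_bands(trace: Trace, config: DetectionConfig = DetectionConfig()
                ) -> tuple[Trace, Trace]:
    """Split a recording into sharp-wave and ripple band-passed traces."""
    if trace.fs <= 2 * config.ripple_band[1]:
        raise ValueError(
            f"sampling rate {trace.fs} Hz too low for the "
            f"{config.ripple_band} Hz ripple band")
    sw = bandpass(trace, *config.sw_band, order=config.filter_order)
    ripple = bandpass(trace, *config.ripple_band, order=config.filter_order)
    return sw, ripple


def _runs(mask: np.ndarray) -> np.ndarray:
    """Half-open [start, stop) index pairs of True runs in a boolean mask."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return np.column_stack([starts, stops])


def estimate_baseline(ripple_trace: Trace,
                      config: DetectionConfig = DetectionConfig()) -> BaselineStats:
    """Event-free baseline statistics of the ripple trace (two-pass).

    Pass 1 masks provisional events with a robust threshold
    (median + k*1.4826*MAD of the rectified trace) plus a guard margin;
    pass 2 computes mean and SD of the signed trace over the remainder.
    """
    if ripple_trace.duration < 10.0:
        raise DataError("baseline estimation needs at least 10 s of recording")
    x = ripple_trace.samples
    r = np.abs(x)
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    thr1 = med + config.baseline_robust_k * 1.4826 * mad
    provisional = r > thr1
    guard = int(round(config.baseline_guard_ms / 1000.0 * ripple_trace.fs))
    if guard > 0:
        mask = np.ones(len(x), bool)
        for s, e in _runs(provisional):
            mask[max(0, s - guard):min(len(x), e + guard)] = False
    else:
        mask = ~provisional
    n = int(mask.sum())
    if n < ripple_trace.fs * 1.0:
        raise DataError(
            "event-free region shorter than 1 s; supply a manual baseline")
    sd = float(x[mask].std())
    if sd == 0.0:
        raise DataError("degenerate baseline: event-free recording has zero SD")
    return BaselineStats(mean=float(x[mask].mean()), sd=sd, n_samples=n, mask=mask)


def detect_ripple_candidates(ripple_trace: Trace, baseline: BaselineStats,
                             config: DetectionConfig = DetectionConfig()
                             ) -> list[tuple[float, float]]:
    """Voltage-threshold candidate intervals on the rectified ripple trace.

    Individual ripples are contiguous runs above ``mean + voltage_k*SD``;
    runs separated by at most ``group_gap_ms`` merge into one event, and
    events whose rectified trace shows fewer than ``min_ripples``
    supra-threshold peaks are discarded (peaks, not runs: at moderate
    sampling rates the rectified signal need not dip below threshold between
    half-waves). Returns sorted, non-overlapping half-open time intervals.
    """
    thr = baseline.threshold(config.voltage_k)
    r = np.abs(ripple_trace.samples)
    supra = r > thr
    runs = _runs(supra)
    if runs.size == 0:
        return []
    gap = config.group_gap_ms / 1000.0 * ripple_trace.fs
    groups: list[list[int]] = [[0]]
    for k in range(1, len(runs)):
        if runs[k, 0] - runs[groups[-1][-1], 1] <= gap:
            groups[-1].append(k)
        else:
            groups.append([k])
    fs, t0 = ripple_trace.fs, ripple_trace.t0
    out = []
    for g in groups:
        i0, i1 = int(runs[g[0], 0]), int(runs[g[-1], 1])
        peaks, _ = signal.find_peaks(r[max(0, i0 - 1):i1 + 1], height=thr)
        if len(peaks) < config.min_ripples:
            continue
        out.append((t0 + i0 / fs, t0 + i1 / fs))
    return out


def _segment_max_coeff(trace: Trace, i0: int, i1: int, smap: ScaleMap) -> float:
    """Max |CWT| over [i0, i1) computed on a locally extracted segment."""
    pad = smap.support_samples()
    j0, j1 = max(0, i0 - pad), min(len(trace), i1 + pad)
    seg = Trace(trace.samples[j0:j1], trace.fs, units=trace.units)
    coeffs = morlet_cwt(seg, smap)
    return max_abs_coeff(coeffs, (i0 - j0, i1 - j0))


def spectral_validate(ripple_trace: Trace, candidates: Sequence[tuple[float, float]],
                      baseline: BaselineStats,
                      config: DetectionConfig = DetectionConfig()
                      ) -> list[ValidatedCandidate]:
    """Apply the wavelet-coefficient criterion to candidate events.

    For each candidate the latest fully event-free ``cutout_ms`` window
    preceding it supplies a null sample of max |CWT| coefficients (27-scale
    complex Morlet map over the ripple band); the acceptance threshold is
    mean + ``spectral_k``*SD of that distribution. A candidate with no
    available cutout is flagged (``cutout_found=False``) and still judged
    against the threshold built from the others.
    """
    fs, t0 = ripple_trace.fs, ripple_trace.t0
    smap = ScaleMap.for_band(config.ripple_band, config.n_scales, fs)
    W = int(round(config.cutout_ms / 1000.0 * fs))

    # event-free = baseline mask minus the candidates themselves
    ok = baseline.mask.copy()
    for (a, b) in candidates:
        ia, ib = max(0, int((a - t0) * fs)), min(len(ok), int(np.ceil((b - t0) * fs)))
        ok[ia:ib] = False
    run_len = np.zeros(len(ok) + 1, dtype=np.int64)
    for s, e in _runs(ok):
        run_len[s + 1:e + 1] = np.arange(1, e - s + 1)
    # positions where a W-long event-free window ends
    ends = np.flatnonzero(run_len >= W)

    cutout_coeffs: list[float] = []
    cutout_of: list[int | None] = []
    for (a, _b) in candidates:
        ia = int((a - t0) * fs)
        k = np.searchsorted(ends, ia, side="right") - 1
        if k < 0:
            cutout_of.append(None)
            continue
        e = int(ends[k])
        cutout_of.append(len(cutout_coeffs))
        cutout_coeffs.append(_segment_max_coeff(ripple_trace, e - W, e, smap))

    n_cutouts = len(cutout_coeffs)
    if candidates and n_cutouts < 3:
        raise DataError(
            f"only {n_cutouts} event-free cutouts available; need >= 3 "
            "for the spectral criterion")
    if n_cutouts:
        arr = np.asarray(cutout_coeffs)
        thr = float(arr.mean() + config.spectral_k * arr.std())
    else:
        thr = 0.0

    out = []
    for (a, b), cut in zip(candidates, cutout_of):
        ia, ib = int((a - t0) * fs), int(np.ceil((b - t0) * fs))
        coeff = _segment_max_coeff(ripple_trace, ia, ib, smap)
        out.append(ValidatedCandidate(
            t_start=a, t_end=b, max_abs_coeff=coeff,
            accepted=bool(coeff > thr), cutout_found=cut is not None))
    return out


def delimit_event(sw_trace: Trace, interval: tuple[float, float],
                  config: DetectionConfig = DetectionConfig()
                  ) -> tuple[float, float, bool]:
    """Find SWR boundaries at the sharp-wave local minima flanking the peak.

    From the dominant-polarity sharp-wave peak inside ``interval``, walk
    outward to the nearest minima that are minimal over a
    ``min_neighborhood_ms`` span (suppressing single-sample noise minima)
    within ``boundary_search_ms``. Returns ``(t_start, t_end, flagged)``;
    ``flagged`` is True when a side hit the search-window edge without
    finding a minimum.
    """
    fs, t0 = sw_trace.fs, sw_trace.t0
    ia = max(0, int((interval[0] - t0) * fs))
    ib = min(len(sw_trace), int(np.ceil((interval[1] - t0) * fs)))
    if ib - ia < 1:
        raise DataError("event interval contains no samples")
    x = sw_trace.samples
    seg = x[ia:ib]
    polarity = 1.0 if seg[np.argmax(np.abs(seg))] >= 0 else -1.0
    peak = ia + int(np.argmax(polarity * seg))

    search = int(round(config.boundary_search_ms / 1000.0 * fs))
    nb = max(1, int(round(config.min_neighborhood_ms / 1000.0 * fs)))
    lo = max(0, peak - search)
    hi = min(len(x), peak + search + 1)
    w = polarity * x[lo:hi]
    is_min = (w == ndimage.minimum_filter1d(w, size=2 * (nb // 2) + 1)) & (w < w[peak - lo])

    flagged = False
    mins_left = np.flatnonzero(is_min[: peak - lo])
    if mins_left.size:
        i_left = lo + int(mins_left[-1])
    else:
        i_left, flagged = lo, True
    mins_right = np.flatnonzero(is_min[peak - lo + 1:])
    if mins_right.size:
        i_right = peak + 1 + int(mins_right[0])
    else:
        i_right, flagged = hi - 1, True
    return t0 + i_left / fs, t0 + (i_right + 1) / fs, flagged


def quantify_event(sw_trace: Trace, ripple_trace: Trace,
                   interval: tuple[float, float], baseline: BaselineStats,
                   config: DetectionConfig = DetectionConfig(),
                   sw_baseline: float | None = None) -> SWREvent:
    """Compute area, amplitude, duration and ripple metrics of one event.

    Area is the trapezoid integral of the above-baseline part of the
    dominant-polarity sharp-wave deflection over the half-open interval (the
    area enclosed between the curve and the baseline level); clipping at the
    baseline makes the measure insensitive to exactly where in the flanking
    valley the boundaries land, and hence linear in event amplitude. Ripple
    count is the number of supra-threshold positive peaks of the ripple trace
    inside the interval and ripple frequency their mean cycle rate (reported
    only for >= 2 peaks).
    """
    fs, t0 = sw_trace.fs, sw_trace.t0
    ia = max(0, int((interval[0] - t0) * fs))
    ib = min(len(sw_trace), int(np.ceil((interval[1] - t0) * fs)))
    if ib - ia < 2:
        raise DataError("degenerate event interval")
    if sw_baseline is None:
        sw_baseline = float(sw_trace.samples[baseline.mask].mean())
    seg = sw_trace.samples[ia:ib] - sw_baseline
    polarity = 1.0 if seg[np.argmax(np.abs(seg))] >= 0 else -1.0
    seg = polarity * seg
    area = float(np.trapezoid(np.clip(seg, 0.0, None), dx=1.0 / fs))
    amplitude = float(seg.max())

    thr = baseline.threshold(config.voltage_k)
    rseg = ripple_trace.samples[ia:ib]
    peaks, _ = signal.find_peaks(rseg, height=thr)
    count = int(len(peaks))
    if count >= 2:
        span = (peaks[-1] - peaks[0]) / fs
        rfreq = (count - 1) / span if span > 0 else float("nan")
    else:
        rfreq = float("nan")
    return SWREvent(
        t_start=interval[0], t_end=interval[1], area=area,
        sw_amplitude=amplitude, duration=(interval[1] - interval[0]) * 1000.0,
        ripple_count=count, ripple_freq=rfreq)


def detect_swr(trace: Trace, config: DetectionConfig = DetectionConfig(),
               curation: Sequence[CurationEdit] | None = None) -> list[SWREvent]:
    """Run the full detection pipeline on a raw LFP trace.

    split -> baseline -> voltage-threshold candidates -> spectral validation
    -> boundary delimitation -> quantification, followed by optional manual
    curation edits. Returns all candidates (accepted and rejected) sorted by
    onset; rejected ones carry their ``rejection_reason``.
    """
    sw, ripple = split_bands(trace, config)
    baseline = estimate_baseline(ripple, config)
    candidates = detect_ripple_candidates(ripple, baseline, config)
    validated = spectral_validate(ripple, candidates, baseline, config)

    sw_base = float(sw.samples[baseline.mask].mean())
    events: list[SWREvent] = []
    for v in validated:
        t_start, t_end, flagged = delimit_event(sw, (v.t_start, v.t_end), config)
        ev = quantify_event(sw, ripple, (t_start, t_end), baseline, config,
                            sw_baseline=sw_base)
        ev.max_abs_coeff = v.max_abs_coeff
        if not v.accepted:
            ev.accepted, ev.rejection_reason = False, "spectral"
        elif flagged:
            ev.accepted, ev.rejection_reason = False, "boundary"
        else:
            ev.accepted, ev.rejection_reason = True, "none"
        events.append(ev)
    events.sort(key=lambda e: e.t_start)

    for edit in curation or ():
        if not 0 <= edit.event_index < len(events):
            raise ValueError(f"curation index {edit.event_index} out of range")
        ev = events[edit.event_index]
        if edit.action == "accept":
            ev.accepted, ev.rejection_reason = True, "none"
        elif edit.action == "reject":
            ev.accepted, ev.rejection_reason = False, "manual"
        elif edit.action == "set_bounds":
            new = quantify_event(sw, ripple, (edit.t_start, edit.t_end),
                                 baseline, config)
            new.max_abs_coeff = ev.max_abs_coeff
            new.accepted, new.rejection_reason = True, "none"
            events[edit.event_index] = new
        else:
            raise ValueError(f"unknown curation action {edit.action!r}")
    return events


# ---------------------------------------------------------------------------


def evaluate_detection(events: Sequence[SWREvent],
                       truth_intervals: Sequence[tuple[float, float]],
                       min_overlap: float = 0.5) -> tuple[float, float]:
    """Recall and precision of accepted events against ground-truth intervals.

    A detected event matches a true event when their overlap covers at least
    ``min_overlap`` of the shorter of the two intervals; each true event can
    be claimed once.
    """
    det = [(e.t_start, e.t_end) for e in events if e.accepted]
    matched_truth = set()
    matched_det = 0
    for (a, b) in det:
        best, best_ov = None, 0.0
        for k, (ta, tb) in enumerate(truth_intervals):
            if k in matched_truth:
                continue
            ov = min(b, tb) - max(a, ta)
            denom = min(b - a, tb - ta)
            if denom > 0 and ov / denom > best_ov:
                best, best_ov = k, ov / denom
        if best is not None and best_ov >= min_overlap:
            matched_truth.add(best)
            matched_det += 1
    recall = len(matched_truth) / len(truth_intervals) if truth_intervals else 1.0
    precision = matched_det / len(det) if det else 1.0
    return recall, precision
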