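"""Pre/post-gamma comparison statistics.

The machinery behind every group-level number: the 120 s pre/post windows
around a gamma episode (ending 10 s before onset, starting 30 s after offset),
per-window SWR summaries, normalization to the pre-gamma mean, percentage
changes with SEM, paired tests (an exact-null Wilcoxon signed-rank and the
paired t), Spearman rank correlation with an exact small-n permutation null,
and EPSC/IPSC charge-ratio analysis.

The Wilcoxon and Spearman nulls are computed from first principles: the
signed-rank distribution by enumerating sign assignments (as a rank-sum
convolution, exact for n <= 25 including average ranks for tied magnitudes)
with a continuity-corrected normal approximation above, and the Spearman null
by full permutation enumeration for n <= 9 with the t approximation above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io_core import DataError, GammaEpoch, PSCEvent, SessionComparison, SWREvent, Trace

__all__ = [
    "WindowSpec",
    "WindowSummary",
    "make_windows",
    "summarize_window",
    "wilcoxon_signed_rank",
    "paired_compare",
    "normalize_series",
    "CorrelationResult",
    "correlate",
    "psc_area",
    "epsc_ipsc_ratio",
]


@dataclass(frozen=True)
class WindowSpec:
    """Placement of the paired comparison windows around a gamma episode."""

    pre_len: float = 120.0          # s
    post_len: float = 120.0         # s
    pre_end_offset: float = 10.0    # s before gamma onset
    post_start_offset: float = 30.0  # s after gamma offset

    def __post_init__(self) -> None:
        if min(self.pre_len, self.post_len) <= 0:
            raise ValueError("window lengths must be positive")
        if min(self.pre_end_offset, self.post_start_offset) < 0:
            raise ValueError("offsets must be non-negative")


def make_windows(gamma_epoch: GammaEpoch | tuple[float, float],
                 spec: WindowSpec = WindowSpec(),
                 trace_extent: tuple[float, float] = (0.0, math.inf),
                 ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Pre/post half-open comparison windows around a gamma episode."""
    if isinstance(gamma_epoch, GammaEpoch):
        g0, g1 = gamma_epoch.t_start, gamma_epoch.t_end
    else:
        g0, g1 = gamma_epoch
    pre = (g0 - spec.pre_end_offset - spec.pre_len, g0 - spec.pre_end_offset)
    post = (g1 + spec.post_start_offset, g1 + spec.post_start_offset + spec.post_len)
    lo, hi = trace_extent
    if pre[0] < lo:
        raise DataError(
            f"pre window starts at {pre[0]:.1f} s, {lo - pre[0]:.1f} s before "
            "the recording begins")
    if post[1] > hi:
        raise DataError(
            f"post window ends at {post[1]:.1f} s, {post[1] - hi:.1f} s after "
            "the recording ends")
    return pre, post


@dataclass
class WindowSummary:
    """Per-window SWR summary metrics (means over accepted events)."""

    n_events: int
    incidence: float          # Hz
    mean_area: float          # mV·s
    mean_ripple_count: float
    mean_ripple_freq: float   # Hz
    mean_amplitude: float     # mV
    mean_duration: float      # ms
    empty: bool = False


def summarize_window(events: Sequence[SWREvent],
                     window: tuple[float, float]) -> WindowSummary:
    """Summarize accepted events whose onset falls in the half-open window."""
    w0, w1 = window
    sel = [e for e in events if e.accepted and w0 <= e.t_start < w1]
    incidence = len(sel) / (w1 - w0)
    if not sel:
        nan = float("nan")
        return WindowSummary(0, 0.0, nan, nan, nan, nan, nan, empty=True)
    rf = [e.ripple_freq for e in sel if np.isfinite(e.ripple_freq)]
    return WindowSummary(
        n_events=len(sel),
        incidence=incidence,
        mean_area=float(np.mean([e.area for e in sel])),
        mean_ripple_count=float(np.mean([e.ripple_count for e in sel])),
        mean_ripple_freq=float(np.mean(rf)) if rf else float("nan"),
        mean_amplitude=float(np.mean([e.sw_amplitude for e in sel])),
        mean_duration=float(np.mean([e.duration for e in sel])),
    )


# ---------------------------------------------------------------------------
# Paired tests


def _signed_rank_null(ranks2: np.ndarray) -> np.ndarray:
    """Counts of the null W+ distribution over doubled ranks.

    With each rank independently assigned + or -, the number of sign
    assignments giving doubled rank-sum w is the coefficient of x**w in
    prod_i (1 + x**r2_i); returned as a dense counts array of length
    sum(r2)+1. Ranks are doubled so average ranks from ties stay integral.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(diffs: Sequence[float],
                         mode: Literal["auto", "exact", "approx"] = "auto",
                         ) -> tuple[float, float, int, bool]:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    Zero differences are dropped (Wilcoxon's convention) and their count
    reported. The null of W+ is exact (sign-assignment enumeration via
    rank-sum convolution, valid with tied magnitudes) for n <= 25 in auto
    mode; larger samples use the normal approximation with tie correction
    and a continuity correction.

    Returns ``(W_plus, p, n_zero_dropped, degenerate)``.
    """
    d = np.asarray(diffs, float)
    nz = d != 0.0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        return 0.0, 1.0, n_zero, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "exact" or (mode == "auto" and n <= 25):
        ranks2 = np.round(2.0 * ranks).astype(np.int64)
        counts = _signed_rank_null(ranks2)
        total = counts.sum()  # 2**n
        w2 = int(round(2.0 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total  # P(W >= w), includes the atom at w
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, t_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return w_plus, 1.0, n_zero, True
        # continuity correction toward the mean
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return w_plus, p, n_zero, False


def paired_compare(pre: Sequence[float], post: Sequence[float],
                   test: Literal["wilcoxon", "t_paired"] = "wilcoxon",
                   metric_name: str = "") -> SessionComparison:
    """Paired pre/post comparison with normalization and percentage change.

    Values are normalized to the mean of the pre-gamma sample; the percentage
    change ``100*(mean(post)-mean(pre))/mean(pre)`` equals the mean of the
    per-pair normalized differences, whose SEM is reported alongside.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size != post.size or pre.size < 1:
        raise DataError("paired comparison needs equal-length samples, n >= 1")
    pre_mean = pre.mean()
    if pre_mean == 0:
        raise DataError("zero pre-gamma mean; percentage change undefined")
    pct = 100.0 * (post.mean() - pre_mean) / pre_mean
    per_pair = 100.0 * (post - pre) / pre_mean
    sem = float(per_pair.std(ddof=1) / math.sqrt(pre.size)) if pre.size > 1 else float("nan")

    diffs = post - pre
    degenerate = bool(np.all(diffs == 0.0))
    n_zero = 0
    if test == "wilcoxon":
        _w, p, n_zero, deg = wilcoxon_signed_rank(diffs)
        degenerate = degenerate or deg
    elif test == "t_paired":
        if pre.size < 2 or degenerate:
            p, degenerate = 1.0, True
        else:
            p = float(stats.ttest_rel(post, pre).pvalue)
            if math.isnan(p):
                p, degenerate = 1.0, True
    else:
        raise ValueError(f"unknown test {test!r}")
    return SessionComparison(
        pre_values=pre, post_values=post, metric_name=metric_name,
        normalized_post=post / pre_mean, pct_change=float(pct), sem=sem,
        test_name=test, p_value=p, n=int(pre.size),
        degenerate=degenerate, n_zero_diffs=n_zero)


def normalize_series(values: Sequence[float], pre_mask: Sequence[bool]) -> np.ndarray:
    """Divide every value by the mean of the pre-gamma (masked) values."""
    values = np.asarray(values, float)
    pre_mask = np.asarray(pre_mask, bool)
    if values.shape != pre_mask.shape:
        raise DataError("values and pre_mask must have equal length")
    if not pre_mask.any():
        raise DataError("pre mask selects no values")
    m = values[pre_mask].mean()
    if m == 0:
        raise DataError("zero pre-gamma mean; normalization undefined")
    return values / m


# ---------------------------------------------------------------------------
# Correlation


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    degenerate: bool = False


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def correlate(x: Sequence[float], y: Sequence[float],
              exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is exact — the proportion of all n! permutations of
    one rank vector with |rho| at least as extreme — for n <= ``exact_max_n``;
    larger samples use the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DataError("correlation needs equal-length samples, n >= 3")
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), float("nan"), n, degenerate=True)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, p, n)


# ---------------------------------------------------------------------------
# Postsynaptic-current analysis


def psc_area(current_trace: Trace, event_window: tuple[float, float],
             baseline_current: float | None = None,
             polarity: Literal["EPSC", "IPSC"] | None = None,
             holding_potential: float = float("nan"),
             baseline_ms: float = 50.0) -> PSCEvent:
    """Charge of one postsynaptic current over ``event_window`` (pA·s).

    The baseline current defaults to the median of the ``baseline_ms`` segment
    immediately preceding the event; the area is the magnitude of the
    trapezoid integral of the baseline-subtracted current. Polarity is
    inferred from the deflection sign (inward/negative -> EPSC) unless given.
    """
    t0, t1 = event_window
    fs = current_trace.fs
    i0 = current_trace.index_at(t0)
    i1 = current_trace.index_at(t1)
    if i0 < 0 or i1 > len(current_trace) or i1 - i0 < 2:
        raise DataError(f"event window [{t0}, {t1}) outside the trace")
    if baseline_current is None:
        j0 = max(0, i0 - int(round(baseline_ms / 1000.0 * fs)))
        if i0 - j0 < 2:
            raise DataError("no room for a pre-event baseline segment")
        baseline_current = float(np.median(current_trace.samples[j0:i0]))
    seg = current_trace.samples[i0:i1] - baseline_current
    integral = float(np.trapezoid(seg, dx=1.0 / fs))
    if polarity is None:
        polarity = "EPSC" if integral < 0 else "IPSC"
    return PSCEvent(t_start=t0, t_end=t1, area=abs(integral),
                    polarity=polarity, holding_potential=holding_potential)


def epsc_ipsc_ratio(epsc_events: Sequence[PSCEvent],
                    ipsc_events: Sequence[PSCEvent],
                    pairing: Literal["window_mean"] = "window_mean") -> float:
    """Ratio of mean EPSC charge to mean IPSC charge within one window.

    The net-excitability index of a cell; pre/post ratios across sessions are
    then compared with :func:`paired_compare`.
    """
    if pairing != "window_mean":
        raise ValueError(f"unknown pairing {pairing!r}")
    if not epsc_events or not ipsc_events:
        raise DataError("need at least one event of each polarity")
    e = float(np.mean([ev.area for ev in epsc_events]))
    i = float(np.mean([ev.area for ev in ipsc_events]))
    if i == 0:
        raise DataError("zero mean IPSC area; ratio undefined")
    return e / i
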