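"""End-to-end session analysis: detect SWRs, window them around the gamma
episode, and summarize the pre/post comparison.

This is the composition the lower modules exist for; it is also what the
examples and the acceptance benchmarks run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .gamma_analysis import GAMMA_BAND, characterize_epoch, find_oscillation_epochs
from .io_core import DataError, GammaEpoch, SWREvent, Trace
from .plasticity import WindowSpec, WindowSummary, make_windows, summarize_window
from .swr_detect import CurationEdit, DetectionConfig, detect_swr

__all__ = ["SessionResult", "analyze_session"]


@dataclass
class SessionResult:
    """One session's detected events, gamma characterization and summaries."""

    events: list[SWREvent]
    gamma: GammaEpoch
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    pre: WindowSummary
    post: WindowSummary

    def pct_change(self, metric: str = "mean_area") -> float:
        """Percentage change of a window metric from pre to post."""
        a = getattr(self.pre, metric)
        b = getattr(self.post, metric)
        if a == 0:
            raise DataError(f"zero pre-gamma {metric}; percentage undefined")
        return 100.0 * (b - a) / a


def analyze_session(trace: Trace,
                    detection: DetectionConfig = DetectionConfig(),
                    windows: WindowSpec = WindowSpec(),
                    gamma_band: tuple[float, float] = GAMMA_BAND,
                    gamma_epoch: tuple[float, float] | None = None,
                    curation: Sequence[CurationEdit] | None = None,
                    spectral_method: str = "fft_avg") -> SessionResult:
    """Run detection + gamma characterization + pre/post windowing.

    The gamma episode is detected automatically from the band-limited power
    envelope unless ``gamma_epoch`` supplies explicit bounds (e.g. from a
    behavioral annotation or the synthetic ground truth).
    """
    if gamma_epoch is None:
        epochs = find_oscillation_epochs(trace, band=gamma_band)
        if not epochs:
            raise DataError("no oscillatory episode found; pass gamma_epoch")
        gamma_epoch = max(epochs, key=lambda e: e[1] - e[0])
    gamma = characterize_epoch(trace, gamma_epoch, band=gamma_band,
                               method=spectral_method)
    pre_w, post_w = make_windows(gamma, windows,
                                 trace_extent=(trace.t0, trace.t_end))
    events = detect_swr(trace, detection, curation=curation)
    return SessionResult(
        events=events, gamma=gamma, pre_window=pre_w, post_window=post_w,
        pre=summarize_window(events, pre_w),
        post=summarize_window(events, post_w))
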