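"""Synthetic LFP and postsynaptic-current sessions with ground truth.

The generator is phenomenological: it reproduces the statistical structure the
analysis pipeline assumes — quiet epochs carrying Poisson-timed sharp
wave-ripples, a running-like epoch of theta-nested gamma, 1/f background noise
and 50 Hz line interference — without simulating any biophysics. Every
stochastic choice is annotated in a :class:`GroundTruth` object so detection
and statistics can be benchmarked against known answers.

A session is laid out as ``quiet_pre | gamma | quiet_post`` partitioning
``[0, duration)``. Each SWR is a Gaussian sharp-wave bump (FWHM
``sw_halfwidth``) carrying a ripple-band sinusoidal burst with an integer
number of cycles; the shapes make event areas and ripple counts analytically
known. Post-gamma plasticity is injected through three dials: sharp-wave
amplitudes are multiplied by ``post_area_scale``, Poisson incidence by
``post_rate_scale`` and ripple cycle counts shifted by
``post_ripple_count_delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io_core import Trace

__all__ = ["SimConfig", "TrueEvent", "GroundTruth", "simulate_session",
           "simulate_psc_trace", "LayoutWarning"]


class LayoutWarning(UserWarning):
    """Epoch layout shorter than the standard windowed protocol allows."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session.

    Defaults mirror the recording conditions the pipeline targets: ~10 min
    sessions, spontaneous SWR incidence 1.33 Hz, a ~3 min gamma episode with
    theta/gamma peaks at 7.3/46.3 Hz, and a ripple band centered near 180 Hz.
    """

    duration: float = 600.0        # s, total session length
    fs: float = 10_000.0           # Hz
    quiet_pre: float = 210.0       # s, first quiet epoch
    gamma_len: float = 180.0       # s, gamma episode length
    swr_rate: float = 1.33         # Hz, Poisson SWR incidence in quiet epochs
    sw_amp_mean: float = 0.35      # mV, sharp-wave peak amplitude (log-normal mean)
    sw_amp_sd: float = 0.10        # mV
    sw_halfwidth: float = 50.0     # ms, FWHM of the Gaussian sharp-wave bump
    ripple_freq_mean: float = 180.0  # Hz
    ripple_freq_sd: float = 20.0   # Hz
    ripples_per_event_mean: float = 7.0
    ripple_amp_frac: float = 0.5   # ripple peak amplitude / sharp-wave amplitude
    theta_freq: float = 7.3        # Hz
    gamma_freq: float = 46.3       # Hz
    theta_amp: float = 0.20        # mV
    gamma_amp: float = 0.15        # mV
    gamma_power_scale: float = 1.0  # multiplies gamma-component power
    noise_sd: float = 0.02         # mV, 1/f background noise SD
    noise_exponent: float = 1.0    # spectral exponent of the background
    line_amp: float = 0.005        # mV, 50 Hz line component
    post_area_scale: float = 1.0   # multiplies sharp-wave amplitude after gamma
    post_rate_scale: float = 1.0   # multiplies incidence after gamma
    post_ripple_count_delta: float = 0.0  # shifts ripple cycle count after gamma
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.duration, self.fs, self.quiet_pre, self.gamma_len) <= 0:
            raise ValueError("durations and sampling rate must be positive")
        if self.quiet_pre + self.gamma_len >= self.duration:
            raise ValueError("epoch layout infeasible: no room for quiet_post")
        if not 25.0 <= self.gamma_freq <= 90.0:
            raise ValueError("gamma_freq must lie in the 25-90 Hz band")
        if not 100.0 <= self.ripple_freq_mean <= 300.0:
            raise ValueError("ripple_freq_mean must lie in the 100-300 Hz band")

    @property
    def quiet_post(self) -> float:
        return self.duration - self.quiet_pre - self.gamma_len


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth annotation of one injected SWR."""

    t_start: float
    t_end: float
    true_area: float          # mV·s, analytic Gaussian integral A·sigma·sqrt(2*pi)
    true_ripple_count: int
    true_ripple_freq: float   # Hz
    amplitude: float          # mV, sharp-wave peak
    epoch: Literal["quiet_pre", "quiet_post"]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    events: list[TrueEvent]
    epochs: list[tuple[str, float, float]]
    injected: dict[str, float]

    def events_in(self, epoch: str) -> list[TrueEvent]:
        return [e for e in self.events if e.epoch == epoch]


# ---------------------------------------------------------------------------


def _one_over_f_noise(n: int, fs: float, sd: float, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power ~ 1/f**exponent, normalized to the given SD."""
    if sd == 0:
        return np.zeros(n)
    from scipy import fft as sfft

    white = rng.standard_normal(n)
    spec = sfft.rfft(white)
    freqs = sfft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs >= 1.0  # flatten below 1 Hz so DC does not blow up
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    spec *= shaping
    x = sfft.irfft(spec, n)
    x *= sd / x.std()
    return x


def _draw_event_times(rng: np.random.Generator, t0: float, t1: float, rate: float,
                      margin: float, min_gap: float) -> list[float]:
    """Poisson event centers in [t0+margin, t1-margin) with a refractory gap."""
    times: list[float] = []
    if rate <= 0:
        return times
    t = t0 + margin
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= t1 - margin:
            break
        if times and t - times[-1] < min_gap:
            continue
        times.append(t)
    return times


def _draw_events(cfg: SimConfig, rng: np.random.Generator) -> list[TrueEvent]:
    sigma = cfg.sw_halfwidth / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    margin = 4.0 * sigma
    min_gap = 3.0 * cfg.sw_halfwidth / 1000.0
    g0 = cfg.quiet_pre
    g1 = cfg.quiet_pre + cfg.gamma_len
    # log-normal amplitudes with the configured mean and SD
    cv2 = (cfg.sw_amp_sd / cfg.sw_amp_mean) ** 2
    ln_sigma = np.sqrt(np.log1p(cv2))
    ln_mu = np.log(cfg.sw_amp_mean) - 0.5 * ln_sigma**2

    events: list[TrueEvent] = []
    for epoch, (e0, e1), rate_scale, amp_scale, count_delta in (
        ("quiet_pre", (0.0, g0), 1.0, 1.0, 0.0),
        ("quiet_post", (g1, cfg.duration), cfg.post_rate_scale,
         cfg.post_area_scale, cfg.post_ripple_count_delta),
    ):
        centers = _draw_event_times(rng, e0, e1, cfg.swr_rate * rate_scale,
                                    margin, min_gap)
        for tc in centers:
            amp = amp_scale * rng.lognormal(ln_mu, ln_sigma)
            n_cyc = max(2, int(round(rng.normal(cfg.ripples_per_event_mean, 1.0)
                                     + count_delta)))
            f_r = float(np.clip(rng.normal(cfg.ripple_freq_mean, cfg.ripple_freq_sd),
                                105.0, 295.0))
            events.append(TrueEvent(
                t_start=tc - 3.0 * sigma,
                t_end=tc + 3.0 * sigma,
                true_area=amp * sigma * np.sqrt(2.0 * np.pi),
                true_ripple_count=n_cyc,
                true_ripple_freq=f_r,
                amplitude=amp,
                epoch=epoch,
            ))
    return events


def _tukey(n: int, alpha: float) -> np.ndarray:
    from scipy.signal.windows import tukey

    return tukey(n, alpha)


def _warn_if_short(cfg: SimConfig) -> None:
    if cfg.quiet_pre < 130.0 or cfg.quiet_post < 150.0:
        warnings.warn(
            "epoch layout shorter than the standard 120 s windowed protocol; "
            "fine for unit tests, not for the full comparison",
            LayoutWarning, stacklevel=3)


def simulate_session(cfg: SimConfig) -> tuple[Trace, GroundTruth]:
    """Generate one LFP session (mV) and its ground truth.

    Quiet epochs contain Poisson-timed SWRs — a Gaussian sharp-wave bump of
    FWHM ``sw_halfwidth`` carrying a ripple burst with an integer number of
    sine cycles under a Tukey envelope — while the gamma epoch holds a
    theta-frequency carrier whose phase amplitude-modulates a gamma component.
    1/f noise and a 50 Hz line ride on everything. Identical configs (same
    seed) give identical output.
    """
    _warn_if_short(cfg)
    rng = np.random.default_rng(cfg.seed)
    events = _draw_events(cfg, rng)

    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = _one_over_f_noise(n, cfg.fs, cfg.noise_sd, cfg.noise_exponent, rng)
    if cfg.line_amp:
        x += cfg.line_amp * np.sin(2.0 * np.pi * 50.0 * t)

    sigma = cfg.sw_halfwidth / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for ev in events:
        tc = 0.5 * (ev.t_start + ev.t_end)
        i0 = max(0, int((tc - 4 * sigma) * cfg.fs))
        i1 = min(n, int((tc + 4 * sigma) * cfg.fs) + 1)
        tt = t[i0:i1]
        x[i0:i1] += ev.amplitude * np.exp(-0.5 * ((tt - tc) / sigma) ** 2)
        # ripple burst: exactly true_ripple_count positive sine peaks
        burst_len = ev.true_ripple_count / ev.true_ripple_freq
        b0, b1 = tc - burst_len / 2.0, tc + burst_len / 2.0
        j0, j1 = int(np.ceil(b0 * cfg.fs)), int(np.floor(b1 * cfg.fs))
        j0, j1 = max(0, j0), min(n, j1)
        tb = t[j0:j1]
        env = _tukey(j1 - j0, 0.1)
        x[j0:j1] += (cfg.ripple_amp_frac * ev.amplitude * env
                     * np.sin(2.0 * np.pi * ev.true_ripple_freq * (tb - b0)))

    # theta-nested gamma epoch with 1 s cosine on/off ramps
    g0, g1 = cfg.quiet_pre, cfg.quiet_pre + cfg.gamma_len
    k0, k1 = int(g0 * cfg.fs), min(n, int(g1 * cfg.fs))
    tg = t[k0:k1]
    ramp = np.ones(k1 - k0)
    nr = min(int(cfg.fs), (k1 - k0) // 2)
    r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    ramp[:nr], ramp[-nr:] = r, r[::-1]
    theta = np.cos(2.0 * np.pi * cfg.theta_freq * tg)
    nesting = 0.5 * (1.0 + theta)
    g_amp = cfg.gamma_amp * np.sqrt(cfg.gamma_power_scale)
    x[k0:k1] += ramp * (cfg.theta_amp * theta
                        + g_amp * nesting * np.cos(2.0 * np.pi * cfg.gamma_freq * tg))

    truth = GroundTruth(
        events=events,
        epochs=[("quiet_pre", 0.0, g0), ("gamma", g0, g1),
                ("quiet_post", g1, cfg.duration)],
        injected={
            "post_area_scale": cfg.post_area_scale,
            "post_rate_scale": cfg.post_rate_scale,
            "post_ripple_count_delta": cfg.post_ripple_count_delta,
        },
    )
    return Trace(x, cfg.fs, units="mV", label="synthetic LFP"), truth


# ---------------------------------------------------------------------------
# Postsynaptic-current traces

PSC_TAU_RISE = 0.002   # s
PSC_TAU_DECAY = 0.015  # s


def biexp_area(amplitude: float, tau_rise: float = PSC_TAU_RISE,
               tau_decay: float = PSC_TAU_DECAY) -> float:
    """Closed-form charge of A*(exp(-t/tau_d) - exp(-t/tau_r)) on [0, inf)."""
    return amplitude * (tau_decay - tau_rise)


def simulate_psc_trace(cfg: SimConfig, polarity: Literal["EPSC", "IPSC"],
                       event_area_mean: float = 0.5, post_scale: float = 1.0,
                       noise_sd: float = 2.0,
                       area_cv: float = 0.2) -> tuple[Trace, GroundTruth]:
    """Generate a whole-cell current trace (pA) with one PSC per SWR.

    Events are time-locked to the same ground-truth SWRs a
    :func:`simulate_session` call with this config would produce (the event
    stream is drawn from the same seeded generator state). Each PSC is a
    biexponential ``A*(exp(-t/tau_d) - exp(-t/tau_r))`` starting at the SWR
    onset, negative-going for EPSCs (holding at -70 mV) and positive for
    IPSCs (0 mV). Charges are log-normal around ``event_area_mean`` (pA·s),
    multiplied by ``post_scale`` in the post-gamma epoch; the annotated
    ``true_area`` of each event is its analytic biexponential integral.
    """
    if polarity not in ("EPSC", "IPSC"):
        raise ValueError(f"unknown polarity {polarity!r}")
    _warn_if_short(cfg)
    rng = np.random.default_rng(cfg.seed)
    events = _draw_events(cfg, rng)  # same stream as simulate_session
    sign = -1.0 if polarity == "EPSC" else 1.0

    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = noise_sd * rng.standard_normal(n) if noise_sd else np.zeros(n)

    ln_sigma = np.sqrt(np.log1p(area_cv**2))
    ln_mu = np.log(event_area_mean) - 0.5 * ln_sigma**2
    psc_events: list[TrueEvent] = []
    span = 8.0 * PSC_TAU_DECAY
    for ev in events:
        area = rng.lognormal(ln_mu, ln_sigma)
        if ev.epoch == "quiet_post":
            area *= post_scale
        amp = area / (PSC_TAU_DECAY - PSC_TAU_RISE)
        i0 = int(np.ceil(ev.t_start * cfg.fs))
        i1 = min(n, int((ev.t_start + span) * cfg.fs))
        tt = t[i0:i1] - ev.t_start
        x[i0:i1] += sign * amp * (np.exp(-tt / PSC_TAU_DECAY)
                                  - np.exp(-tt / PSC_TAU_RISE))
        psc_events.append(replace(ev, true_area=area, t_end=ev.t_start + span))

    truth = GroundTruth(
        events=psc_events,
        epochs=[("quiet_pre", 0.0, cfg.quiet_pre),
                ("gamma", cfg.quiet_pre, cfg.quiet_pre + cfg.gamma_len),
                ("quiet_post", cfg.quiet_pre + cfg.gamma_len, cfg.duration)],
        injected={"post_scale": post_scale},
    )
    return Trace(x, cfg.fs, units="pA", label=f"synthetic {polarity}"), truth
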