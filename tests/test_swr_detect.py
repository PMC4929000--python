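"""SWR detector: each stage against constructed fixtures and generator truth."""

import numpy as np
import pytest

from swrgamma.io_core import BaselineStats, DataError, Trace
from swrgamma.swr_detect import (CurationEdit, DetectionConfig, delimit_event,
                                 detect_ripple_candidates, detect_swr,
                                 estimate_baseline, evaluate_detection,
                                 quantify_event, spectral_validate, split_bands)
from swrgamma.synthetic import SimConfig, simulate_session

FS = 2000.0


def ripple_burst(t, t0, n_cycles, freq, amp):
    """A burst with exactly n_cycles positive sine peaks starting at t0."""
    L = n_cycles / freq
    out = np.zeros_like(t)
    sel = (t >= t0) & (t < t0 + L)
    out[sel] = amp * np.sin(2 * np.pi * freq * (t[sel] - t0))
    return out


def noise_trace(rng, dur=30.0, sd=0.01, fs=FS):
    return Trace(rng.normal(0, sd, int(dur * fs)), fs)


def flat_baseline(n, sd=1e-6, exclude=None):
    mask = np.ones(n, bool)
    if exclude is not None:
        mask[exclude[0]:exclude[1]] = False
    return BaselineStats(mean=0.0, sd=sd, n_samples=int(mask.sum()), mask=mask)


class TestSplitBands:
    def test_band_separation(self):
        t = np.arange(int(4 * FS)) / FS
        slow = Trace(np.sin(2 * np.pi * 20 * t), FS)
        fast = Trace(np.sin(2 * np.pi * 200 * t), FS)
        sw, rip = split_bands(slow)
        assert np.abs(sw.samples[1000:-1000]).max() > 0.9
        assert np.abs(rip.samples[1000:-1000]).max() < 0.01
        sw, rip = split_bands(fast)
        assert np.abs(sw.samples[1000:-1000]).max() < 0.01
        assert np.abs(rip.samples[1000:-1000]).max() > 0.9

    def test_mixture_recovered_componentwise(self):
        t = np.arange(int(4 * FS)) / FS
        # tones at the geometric band centers, where |H|^2 ~ 1
        mix = Trace(0.5 * np.sin(2 * np.pi * 10 * t)
                    + 0.2 * np.sin(2 * np.pi * 173.2 * t), FS)
        sw, rip = split_bands(mix)
        assert np.abs(sw.samples[1000:-1000]).max() == pytest.approx(0.5, rel=0.02)
        assert np.abs(rip.samples[1000:-1000]).max() == pytest.approx(0.2, rel=0.02)

    def test_low_fs_rejected(self):
        tr = Trace(np.zeros(1000) + np.arange(1000) * 0.0 + 1.0, 500.0)
        with pytest.raises(ValueError):
            split_bands(tr)


class TestBaseline:
    def test_pure_noise_sd_recovered(self, rng):
        tr = noise_trace(rng, sd=0.02)
        b = estimate_baseline(tr)
        assert b.sd == pytest.approx(0.02, rel=0.05)
        assert b.n_samples > 0.95 * len(tr)

    def test_bursts_excluded_from_mask(self, rng):
        t = np.arange(int(30 * FS)) / FS
        x = rng.normal(0, 0.01, t.size)
        starts = np.linspace(2, 26, 10)
        for t0 in starts:
            x += ripple_burst(t, t0, 8, 200.0, 0.3)
        b = estimate_baseline(Trace(x, FS))
        for t0 in starts:
            i0, i1 = int(t0 * FS), int((t0 + 8 / 200) * FS)
            assert not b.mask[i0:i1].any()

    def test_constant_trace_degenerate(self):
        with pytest.raises(DataError):
            estimate_baseline(Trace(np.full(int(20 * FS), 1.0), FS))

    def test_short_trace_rejected(self, rng):
        with pytest.raises(DataError):
            estimate_baseline(noise_trace(rng, dur=5.0))


class TestCandidates:
    def test_noise_only_no_candidates(self, rng):
        tr = noise_trace(rng, dur=100.0, sd=0.01)
        b = estimate_baseline(tr)
        assert detect_ripple_candidates(tr, b) == []

    def test_single_burst_one_candidate(self, rng):
        t = np.arange(int(30 * FS)) / FS
        sd = 0.01
        x = rng.normal(0, sd, t.size) + ripple_burst(t, 10.0, 8, 200.0, 10 * sd)
        tr = Trace(x, FS)
        b = estimate_baseline(tr)
        cands = detect_ripple_candidates(tr, b)
        assert len(cands) == 1
        a, z = cands[0]
        assert a == pytest.approx(10.0, abs=0.01)
        assert z == pytest.approx(10.0 + 8 / 200, abs=0.01)

    def test_grouping_rule(self, rng):
        t = np.arange(int(30 * FS)) / FS
        sd = 0.01
        base = rng.normal(0, sd, t.size)
        for gap_s, expected in [(0.005, 1), (0.050, 2)]:
            x = base + ripple_burst(t, 10.0, 6, 200.0, 10 * sd) \
                + ripple_burst(t, 10.0 + 6 / 200 + gap_s, 6, 200.0, 10 * sd)
            tr = Trace(x, FS)
            b = estimate_baseline(tr)
            cands = detect_ripple_candidates(
                tr, b, DetectionConfig(group_gap_ms=20.0))
            assert len(cands) == expected


class TestSpectralValidation:
    @staticmethod
    def _trace_with_bursts(rng):
        t = np.arange(int(60 * FS)) / FS
        sd = 0.01
        x = rng.normal(0, sd, t.size)
        for t0 in (10.0, 20.0, 30.0):  # genuine ripples
            x += ripple_burst(t, t0, 8, 200.0, 10 * sd)
        return Trace(x, FS)

    def test_genuine_bursts_accepted_noise_blip_rejected(self, rng):
        # a candidate placed over plain noise (a false voltage crossing or a
        # stray manual annotation) carries no ripple-band tone: its wavelet
        # maximum stays below the event-free-cutout threshold
        raw = self._trace_with_bursts(rng)
        _, rip = split_bands(raw)
        b = estimate_baseline(rip)
        cands = [(10.0, 10.04), (20.0, 20.04), (30.0, 30.04), (45.0, 45.02)]
        validated = spectral_validate(rip, cands, b)
        assert [v.accepted for v in validated] == [True, True, True, False]
        assert validated[3].max_abs_coeff < 0.2 * validated[0].max_abs_coeff

    def test_rejected_events_keep_spectral_reason(self, rng):
        raw = self._trace_with_bursts(rng)
        events = detect_swr(raw, DetectionConfig(spectral_k=np.inf,
                                                 min_ripples=2))
        assert events
        assert all(e.rejection_reason == "spectral" for e in events)

    def test_infinite_k_rejects_all(self, rng):
        t = np.arange(int(60 * FS)) / FS
        sd = 0.01
        x = rng.normal(0, sd, t.size)
        for t0 in (10.0, 25.0, 40.0):
            x += ripple_burst(t, t0, 8, 200.0, 10 * sd)
        tr = Trace(x, FS)
        b = estimate_baseline(tr)
        cands = detect_ripple_candidates(tr, b)
        assert len(cands) == 3
        validated = spectral_validate(tr, cands, b,
                                      DetectionConfig(spectral_k=np.inf))
        assert all(not v.accepted for v in validated)
        validated0 = spectral_validate(tr, cands, b,
                                       DetectionConfig(spectral_k=0.0))
        assert all(v.accepted for v in validated0)


class TestDelimitation:
    def test_gaussian_bump_boundaries_cover_mass(self, rng):
        t = np.arange(int(10 * FS)) / FS
        amp, sigma, tc = 0.5, 0.02, 5.0
        bump = amp * np.exp(-0.5 * ((t - tc) / sigma) ** 2)
        x = bump + rng.normal(0, 0.002, t.size)
        tr = Trace(x, FS)
        t0, t1, flagged = delimit_event(tr, (tc - 0.03, tc + 0.03))
        assert t0 < tc < t1
        mass = np.trapezoid(bump[int(t0 * FS):int(t1 * FS)], dx=1 / FS)
        assert mass >= 0.95 * amp * sigma * np.sqrt(2 * np.pi)

    def test_monotone_ramp_flagged_at_window_edges(self):
        x = np.linspace(0.0, 1.0, int(2 * FS))
        tr = Trace(x, FS)
        t0, t1, flagged = delimit_event(tr, (0.9, 1.1),
                                        DetectionConfig(boundary_search_ms=100.0))
        assert flagged

    def test_adjacent_bumps_split_at_shared_valley(self):
        t = np.arange(int(4 * FS)) / FS
        b1 = 0.5 * np.exp(-0.5 * ((t - 1.90) / 0.02) ** 2)
        b2 = 0.5 * np.exp(-0.5 * ((t - 2.10) / 0.02) ** 2)
        tr = Trace(b1 + b2 + 1e-4 * np.sin(2 * np.pi * 3 * t), FS)
        _, t1a, _ = delimit_event(tr, (1.87, 1.93))
        t0b, _, _ = delimit_event(tr, (2.07, 2.13))
        assert 1.95 < t1a < 2.05
        assert 1.95 < t0b < 2.05


class TestQuantification:
    def test_half_sine_closed_form(self):
        # A = 0.5 mV, T = 50 ms -> area 2AT/pi = 0.0159 mV*s
        fs = 10_000.0
        t = np.arange(int(2 * fs)) / fs
        A, T, t0 = 0.5, 0.050, 1.0
        x = np.zeros(t.size)
        sel = (t >= t0) & (t < t0 + T)
        x[sel] = A * np.sin(np.pi * (t[sel] - t0) / T)
        sw = Trace(x, fs)
        baseline = flat_baseline(t.size, exclude=(int(0.9 * fs), int(1.2 * fs)))
        ev = quantify_event(sw, sw.copy_with(np.zeros(t.size)), (t0, t0 + T),
                            baseline)
        assert ev.area == pytest.approx(2 * A * T / np.pi, rel=0.001)
        assert ev.area == pytest.approx(0.0159, rel=0.01)
        assert ev.sw_amplitude == pytest.approx(A, rel=0.001)
        assert ev.duration == pytest.approx(50.0, rel=0.001)

    def test_zero_trace_zero_metrics(self):
        n = int(2 * FS)
        z = Trace(np.zeros(n) + 1e-12, FS)
        ev = quantify_event(z, z, (0.5, 0.6), flat_baseline(n))
        assert ev.area == pytest.approx(0.0, abs=1e-9)
        assert ev.ripple_count == 0
        assert not ev.accepted

    def test_generator_ripple_count_and_freq(self, rng):
        t = np.arange(int(20 * FS)) / FS
        sd = 0.005
        x = rng.normal(0, sd, t.size) + ripple_burst(t, 10.0, 7, 180.0, 0.15)
        tr = Trace(x, FS)
        b = estimate_baseline(tr)
        ev = quantify_event(tr.copy_with(np.zeros(t.size)), tr,
                            (10.0 - 0.01, 10.0 + 7 / 180 + 0.01), b)
        assert ev.ripple_count == 7
        assert ev.ripple_freq == pytest.approx(180.0, rel=0.05)


class TestFullDetector:
    def test_recall_precision_on_small_session(self, small_session):
        cfg, trace, truth = small_session
        events = detect_swr(trace)
        recall, precision = evaluate_detection(
            events, [(e.t_start, e.t_end) for e in truth.events])
        assert recall >= 0.9 and precision >= 0.9

    def test_determinism(self, small_session):
        _, trace, _ = small_session
        e1 = detect_swr(trace)
        e2 = detect_swr(trace)
        assert [(e.t_start, e.t_end, e.area) for e in e1] == \
            [(e.t_start, e.t_end, e.area) for e in e2]

    def test_amplitude_scale_invariance(self, small_session):
        _, trace, _ = small_session
        e1 = detect_swr(trace)
        e2 = detect_swr(trace.copy_with(3.0 * trace.samples))
        assert [(e.t_start, e.accepted) for e in e1] == \
            [(e.t_start, e.accepted) for e in e2]
        for a, b in zip(e1, e2):
            assert b.area == pytest.approx(3.0 * a.area, rel=1e-6)

    def test_voltage_threshold_monotone_in_candidates(self, small_session):
        _, trace, _ = small_session
        _, rip = split_bands(trace)
        b = estimate_baseline(rip)
        counts = [len(detect_ripple_candidates(rip, b,
                                               DetectionConfig(voltage_k=k)))
                  for k in (2.0, 4.0, 6.0, 12.0)]
        assert counts[0] > 0
        assert all(a >= b_ for a, b_ in zip(counts, counts[1:]))

    def test_spectral_threshold_monotone_in_accepted(self, small_session):
        _, trace, _ = small_session
        counts = []
        for k in (0.0, 1.0, 3.0, 10.0):
            events = detect_swr(trace, DetectionConfig(spectral_k=k))
            counts.append(sum(e.accepted for e in events))
        assert counts[0] > 0
        assert all(a >= b_ for a, b_ in zip(counts, counts[1:]))

    def test_curation_edits(self, small_session):
        _, trace, _ = small_session
        events = detect_swr(trace)
        assert len(events) >= 4
        edited = detect_swr(trace, curation=[CurationEdit(3, "reject")])
        assert edited[3].accepted is False
        assert edited[3].rejection_reason == "manual"
        t0, t1 = events[2].t_start - 0.01, events[2].t_end + 0.01
        rebound = detect_swr(trace, curation=[
            CurationEdit(2, "set_bounds", t_start=t0, t_end=t1)])
        assert rebound[2].t_start == pytest.approx(t0)
        assert rebound[2].duration > events[2].duration

    def test_noise_only_trace_empty(self, rng):
        tr = noise_trace(rng, dur=60.0, sd=0.01)
        events = detect_swr(tr)
        assert [e for e in events if e.accepted] == []
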