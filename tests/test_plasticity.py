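"""Windowing, paired tests, correlation and PSC charge analysis.

The Wilcoxon and Spearman implementations are checked against brute-force
enumeration oracles and cross-checked against scipy's independent
implementations.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from swrgamma.benchmarks import brute_force_wilcoxon_p
from swrgamma.io_core import DataError, GammaEpoch, PSCEvent, SWREvent, Trace
from swrgamma.plasticity import (WindowSpec, correlate, epsc_ipsc_ratio,
                                 make_windows, normalize_series,
                                 paired_compare, psc_area, summarize_window,
                                 wilcoxon_signed_rank)


class TestWindows:
    def test_standard_offsets(self):
        g = GammaEpoch(130.0, 310.0)
        pre, post = make_windows(g, WindowSpec(), trace_extent=(0.0, 600.0))
        assert pre == (0.0, 120.0)
        assert post == (340.0, 460.0)

    def test_insufficient_pre_recording(self):
        g = GammaEpoch(100.0, 310.0)
        with pytest.raises(DataError, match="pre window"):
            make_windows(g, WindowSpec(), trace_extent=(0.0, 600.0))

    def test_zero_offsets_abut_epoch(self):
        g = GammaEpoch(100.0, 200.0)
        spec = WindowSpec(pre_len=60.0, post_len=60.0, pre_end_offset=0.0,
                          post_start_offset=0.0)
        pre, post = make_windows(g, spec, trace_extent=(0.0, 600.0))
        assert pre[1] == 100.0 and post[0] == 200.0


class TestWindowSummary:
    @staticmethod
    def _events(times, area=0.01):
        return [SWREvent(t_start=t, t_end=t + 0.1, area=area, accepted=True,
                         ripple_count=5, ripple_freq=180.0) for t in times]

    def test_incidence_arithmetic(self):
        # 108 events in a 120 s window -> 0.9 Hz
        evs = self._events(np.linspace(10.0, 100.0, 108))
        s = summarize_window(evs, (0.0, 120.0))
        assert s.incidence == pytest.approx(0.9)
        assert s.n_events == 108

    def test_empty_window_flagged(self):
        s = summarize_window([], (0.0, 120.0))
        assert s.empty and s.incidence == 0.0 and np.isnan(s.mean_area)

    def test_equal_areas(self):
        evs = self._events([1.0, 2.0, 3.0], area=0.02)
        assert summarize_window(evs, (0.0, 10.0)).mean_area == pytest.approx(0.02)

    def test_rejected_events_excluded(self):
        evs = self._events([1.0, 2.0])
        evs[1].accepted = False
        assert summarize_window(evs, (0.0, 10.0)).n_events == 1


class TestWilcoxon:
    def test_all_positive_n11_closed_form(self):
        w, p, nz, deg = wilcoxon_signed_rank(np.arange(1.0, 12.0))
        assert p == pytest.approx(2.0 / 2**11)
        assert not deg and nz == 0

    def test_spec_n6_vector_matches_enumeration(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])
        _, p, _, _ = wilcoxon_signed_rank(d, mode="exact")
        assert p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_random_vectors_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(1, 13))
            d = rng.integers(-9, 10, n).astype(float)
            _, p, _, _ = wilcoxon_signed_rank(d, mode="exact")
            assert p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_cross_check_scipy_exact_no_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 12)  # continuous: no ties, no zeros
            _, p, _, _ = wilcoxon_signed_rank(d, mode="exact")
            p_sp = sstats.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(p_sp, abs=1e-12)

    def test_approx_agrees_with_scipy_large_n(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.2, 1.0, 40)
        _, p, _, _ = wilcoxon_signed_rank(d, mode="approx")
        p_sp = sstats.wilcoxon(d, method="approx", correction=True).pvalue
        assert p == pytest.approx(p_sp, rel=0.05)

    def test_all_zero_differences_degenerate(self):
        w, p, nz, deg = wilcoxon_signed_rank(np.zeros(8))
        assert deg and p == 1.0 and nz == 8

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-9, max_value=9), min_size=1,
                    max_size=10))
    def test_exact_p_equals_enumeration_property(self, diffs):
        d = np.asarray(diffs, float)
        _, p, _, _ = wilcoxon_signed_rank(d, mode="exact")
        assert p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        c = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.pct_change == 0.0 and c.degenerate and c.p_value == 1.0

    def test_pct_change_and_sem(self):
        pre = np.array([1.0, 1.0, 1.0, 1.0])
        post = np.array([1.2, 1.3, 1.1, 1.4])
        c = paired_compare(pre, post)
        assert c.pct_change == pytest.approx(25.0)
        per_pair = 100.0 * (post - pre) / pre.mean()
        assert c.sem == pytest.approx(per_pair.std(ddof=1) / 2)

    def test_t_paired_matches_scipy(self):
        rng = np.random.default_rng(5)
        pre = rng.normal(1.0, 0.1, 10)
        post = pre + rng.normal(0.05, 0.1, 10)
        c = paired_compare(pre, post, test="t_paired")
        assert c.p_value == pytest.approx(sstats.ttest_rel(post, pre).pvalue)


class TestNormalization:
    def test_worked_example(self):
        out = normalize_series([2.0, 4.0, 6.0], [True, True, False])
        np.testing.assert_allclose(out, [2 / 3, 4 / 3, 2.0])

    def test_all_equal_gives_ones(self):
        out = normalize_series([3.0, 3.0, 3.0], [True, True, True])
        np.testing.assert_allclose(out, 1.0)

    def test_pre_mean_is_exactly_one(self, rng):
        for _ in range(10):
            v = rng.uniform(0.5, 2.0, 20)
            mask = np.zeros(20, bool)
            mask[rng.choice(20, 8, replace=False)] = True
            out = normalize_series(v, mask)
            assert out[mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_pre_mean_rejected(self):
        with pytest.raises(DataError):
            normalize_series([0.0, 1.0], [True, False])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.1, max_value=10.0), min_size=2,
                    max_size=15), st.integers(min_value=1))
    def test_normalized_pre_mean_is_one_property(self, values, n_pre):
        n_pre = 1 + n_pre % len(values)
        mask = np.zeros(len(values), bool)
        mask[:n_pre] = True
        out = normalize_series(values, mask)
        assert out[mask].mean() == pytest.approx(1.0, abs=1e-9)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert correlate(x, [2.0, 3.0, 8.0, 20.0]).rho == pytest.approx(1.0)
        assert correlate(x, [20.0, 8.0, 3.0, 2.0]).rho == pytest.approx(-1.0)

    def test_rho_matches_scipy(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r = correlate(x, y)
        assert r.rho == pytest.approx(sstats.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_p_matches_direct_enumeration(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        r = correlate(x, y)
        rx = sstats.rankdata(x)
        ry = sstats.rankdata(y)

        def rho_of(perm):
            p = np.asarray(perm)
            return np.corrcoef(rx, p)[0, 1]

        obs = abs(rho_of(ry))
        count = sum(1 for perm in itertools.permutations(ry)
                    if abs(rho_of(perm)) >= obs - 1e-12)
        assert r.p == pytest.approx(count / 720, abs=1e-12)

    def test_t_approximation_large_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 2.0, 30)
        r = correlate(x, y)
        p_sp = sstats.spearmanr(x, y).pvalue
        assert r.p == pytest.approx(p_sp, rel=0.05)

    def test_constant_input_degenerate(self):
        r = correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert r.degenerate


class TestPSC:
    def test_rectangular_pulse_area(self):
        fs = 10_000.0
        x = np.zeros(int(fs))
        x[int(0.5 * fs):int(0.55 * fs)] = 100.0  # 100 pA for 50 ms
        ev = psc_area(Trace(x, fs, units="pA"), (0.5, 0.55), baseline_current=0.0)
        assert ev.area == pytest.approx(5.0, rel=0.01)  # 5 pA*s of charge
        assert ev.polarity == "IPSC"  # positive-going

    def test_zero_trace_zero_area(self):
        fs = 1000.0
        ev = psc_area(Trace(np.zeros(1000), fs, units="pA"), (0.3, 0.5),
                      baseline_current=0.0)
        assert ev.area == 0.0

    def test_baseline_from_pre_event_median(self):
        fs = 1000.0
        x = np.full(1000, 7.0)
        x[400:500] -= 50.0
        ev = psc_area(Trace(x, fs, units="pA"), (0.4, 0.5))
        assert ev.area == pytest.approx(5.0, rel=0.02)
        assert ev.polarity == "EPSC"

    def test_holding_potential_mismatch_warns(self):
        with pytest.warns(UserWarning, match="holding"):
            PSCEvent(0.0, 0.1, area=1.0, polarity="EPSC", holding_potential=0.0)


class TestRatio:
    @staticmethod
    def _evs(areas, pol):
        return [PSCEvent(0.0, 0.1, area=a, polarity=pol) for a in areas]

    def test_equal_means_unity(self):
        r = epsc_ipsc_ratio(self._evs([1.0, 3.0], "EPSC"),
                            self._evs([2.0, 2.0], "IPSC"))
        assert r == pytest.approx(1.0)

    def test_homogeneity(self):
        e = self._evs([1.0, 3.0], "EPSC")
        i = self._evs([0.5, 1.5], "IPSC")
        assert epsc_ipsc_ratio(self._evs([2.0, 6.0], "EPSC"), i) == \
            pytest.approx(2 * epsc_ipsc_ratio(e, i))

    def test_empty_side_rejected(self):
        with pytest.raises(DataError):
            epsc_ipsc_ratio([], self._evs([1.0], "IPSC"))
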