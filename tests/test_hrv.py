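"""Time-domain, Lomb frequency-domain and Poincaré HRV correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import murecg as m
from murecg.errors import DegenerateSpectrumError, InsufficientDataError
from conftest import lomb_direct


def series(rr):
    return m.RRSeries.from_rr(np.asarray(rr, dtype=float))


class TestTimeDomain:
    def test_constant_series_has_zero_variability(self):
        td = m.compute_time_domain(series([100.0] * 4))
        assert td.sdrr == 0 and td.rmssd == 0 and td.prr50 == 0
        assert td.average_rr == td.median_rr == 100.0

    def test_alternating_series_hand_values(self):
        # diffs are +-60 ms -> RMSSD 60, every diff > 50 ms -> pRR50 100;
        # sample SD of {120,180,120,180,120} = sqrt(4320/4)
        td = m.compute_time_domain(series([120, 180, 120, 180, 120]))
        assert td.rmssd == pytest.approx(60.0)
        assert td.prr50 == 100.0
        assert td.sdrr == pytest.approx(np.sqrt(1080.0), abs=1e-9)
        assert td.sdrr == pytest.approx(32.86, abs=0.01)

    def test_prr50_is_strict_inequality(self):
        # successive differences of exactly 50 ms do not count
        td = m.compute_time_domain(series([100, 150, 100, 150, 100]))
        assert td.prr50 == 0.0

    def test_mask_excludes_intervals(self):
        rr = series([100, 100, 500, 100, 100])
        rr.included[2] = False
        td = m.compute_time_domain(rr)
        assert td.sdrr == 0 and td.rmssd == 0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            m.compute_time_domain(series([100.0]))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(50, 500), min_size=3, max_size=60),
           st.floats(0.1, 10))
    def test_scale_equivariance(self, rr, c):
        a = m.compute_time_domain(series(rr))
        b = m.compute_time_domain(series([c * v for v in rr]))
        for f in ("sdrr", "sdsd", "rmssd"):
            assert getattr(b, f) == pytest.approx(c * getattr(a, f),
                                                  rel=1e-9, abs=1e-9)


class TestPoincare:
    def test_constant_series(self):
        pc = m.poincare(series([130.0] * 10))
        assert pc.sd1 == 0 and pc.sd2 == 0

    def test_alternating_limit(self):
        # long 120/180 alternation: all dispersion is perpendicular to the
        # identity line -> SD1 -> 60/sqrt(2), SD2 -> 0
        rr = series([120.0, 180.0] * 100)
        pc = m.poincare(rr)
        assert pc.sd1 == pytest.approx(60 / np.sqrt(2), rel=1e-3)
        assert pc.sd2 == pytest.approx(0.0, abs=0.5)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(11)
        rr = series(150 + 20 * rng.standard_normal(200))
        pc = m.poincare(rr)
        a, b = rr.rr[:-1], rr.rr[1:]
        assert pc.sd1 == pytest.approx(np.std((a - b) / np.sqrt(2)), rel=1e-12)
        assert pc.sd2 == pytest.approx(np.std((a + b) / np.sqrt(2)), rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_identity_suite(self, seed):
        """SD1^2 = SDSD_pop^2/2; SD1^2 + SD2^2 = 2 SDRR_pop^2 (on the paired
        points); RMSSD^2 = SDSD_pop^2 + mean(diff)^2."""
        rng = np.random.default_rng(seed)
        rr = series(np.abs(150 + 30 * rng.standard_normal(50)) + 1.0)
        pc = m.poincare(rr)
        d = np.diff(rr.rr)
        sdsd_pop = np.std(d)
        assert pc.sd1 ** 2 == pytest.approx(sdsd_pop ** 2 / 2, rel=1e-9)
        # Var(a)+Var(b) identity; the mean-difference term corrects for the
        # pooled variance of concatenating both coordinates
        paired = np.concatenate([rr.rr[:-1], rr.rr[1:]])
        delta = np.mean(rr.rr[:-1]) - np.mean(rr.rr[1:])
        assert pc.sd1 ** 2 + pc.sd2 ** 2 == pytest.approx(
            2 * np.std(paired) ** 2 - delta ** 2 / 2, rel=1e-9)
        td = m.compute_time_domain(rr)
        assert td.rmssd ** 2 == pytest.approx(sdsd_pop ** 2 + np.mean(d) ** 2,
                                              rel=1e-9)


class TestLomb:
    def _modulated(self, f0, amp=20.0, mean=150.0, n_sec=120, seed=0):
        rng = np.random.default_rng(seed)
        t, rr = 0.0, []
        times = [0.0]
        while t < n_sec * 1000:
            iv = mean + amp * np.sin(2 * np.pi * f0 * t / 1000.0)
            t += iv
            times.append(t)
            rr.append(iv)
        return m.RRSeries.from_beat_times(np.array(times))

    def test_matches_direct_formula(self):
        rr = self._modulated(1.3, seed=2)
        grid = np.linspace(0.05, 5.0, 200)
        spec = m.lomb_periodogram(rr, grid)
        t_s = rr.beat_times[:-1] / 1000.0
        direct = lomb_direct(t_s, rr.rr, grid)
        rel = np.abs(spec.power - direct) / np.maximum(direct, 1e-30)
        assert np.max(rel[direct > 1e-12]) < 1e-8

    @pytest.mark.parametrize("f0", [0.5, 3.0])
    def test_peak_at_injected_frequency(self, f0):
        spec = m.lomb_periodogram(self._modulated(f0))
        step = spec.frequencies[1] - spec.frequencies[0]
        peak = spec.frequencies[np.argmax(spec.power)]
        assert abs(peak - f0) <= step + 1e-12

    def test_constant_series_degenerate(self):
        spec = m.lomb_periodogram(series([150.0] * 60))
        assert spec.degenerate
        assert np.all(spec.power == 0)
        with pytest.raises(DegenerateSpectrumError):
            m.band_powers(spec)

    def test_single_tone_band_dominance(self):
        hf = m.band_powers(m.lomb_periodogram(self._modulated(3.0)))
        assert hf.hf_pct >= 95
        lf = m.band_powers(m.lomb_periodogram(self._modulated(0.5)))
        assert lf.lf_pct >= 95
        assert lf.lf_hf > 10

    def test_two_equal_tones_balanced(self):
        """Equal-amplitude 0.5 and 3 Hz tones give two equal Lomb peaks.

        Peak powers agree within 10%; the integrated LF/HF ratio carries an
        uneven-sampling pedestal that grows toward high frequency, so it is
        checked against the independent direct-formula oracle rather than
        against exact unity.
        """
        t, times = 0.0, [0.0]
        while t < 180 * 1000:
            iv = 120 + 6 * np.sin(2 * np.pi * 0.5 * t / 1000) \
                     + 6 * np.sin(2 * np.pi * 3.0 * t / 1000)
            t += iv
            times.append(t)
        rr = m.RRSeries.from_beat_times(np.array(times))
        spec = m.lomb_periodogram(rr)
        f, p = spec.frequencies, spec.power
        peak_lf = p[(f >= 0.4) & (f < 0.6)].max()
        peak_hf = p[(f >= 2.9) & (f < 3.1)].max()
        assert abs(peak_lf - peak_hf) / max(peak_lf, peak_hf) < 0.10
        fd = m.band_powers(spec)
        oracle = lomb_direct(rr.beat_times[:-1] / 1000.0, rr.rr, f)
        lf_o = np.trapezoid(oracle[(f >= 0.15) & (f < 1.5)],
                            f[(f >= 0.15) & (f < 1.5)])
        hf_o = np.trapezoid(oracle[(f >= 1.5) & (f <= 5.0)],
                            f[(f >= 1.5) & (f <= 5.0)])
        assert fd.lf_hf == pytest.approx(lf_o / hf_o, rel=1e-6)
        assert 0.7 < fd.lf_hf < 1.2

    def test_percentages_sum_to_100(self):
        fd = m.band_powers(m.lomb_periodogram(self._modulated(2.0, seed=5)))
        assert fd.vlf_pct + fd.lf_pct + fd.hf_pct == pytest.approx(100.0)
        assert fd.lf_hf == pytest.approx(fd.lf_pct / fd.hf_pct)

    def test_needs_30_intervals(self):
        with pytest.raises(InsufficientDataError):
            m.lomb_periodogram(series([150.0, 160.0] * 10))
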