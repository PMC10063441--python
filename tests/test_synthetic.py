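"""Generator correctness: RR modulation, ECG construction, disorder
injection and virtual-heart determinism."""

import numpy as np
import pytest

import murecg as m
from murecg.synthetic import AutonomicPreset


def flat_preset(mean_rr=150.0, **kw):
    base = dict(name="flat", mean_rr=mean_rr, lf_amp=0.0, lf_freq=0.5,
                hf_amp=0.0, hf_freq=2.5, wander_amp=0.0, noise_sd=0.0, seed=0)
    base.update(kw)
    return AutonomicPreset(**base)


class TestRRGenerator:
    def test_modulation_free_limit_is_constant(self):
        rr = m.generate_rr_series(flat_preset(), 15)
        assert np.allclose(rr.rr, 150.0)

    def test_point_process_consistency(self):
        rr = m.generate_rr_series(m.get_preset("awake", seed=1), 30)
        assert rr.beat_times[-1] == pytest.approx(np.sum(rr.rr), rel=1e-12)
        assert np.all(np.diff(rr.beat_times) > 0)

    def test_deterministic_for_fixed_seed(self):
        a = m.generate_rr_series(m.get_preset("mmf", seed=9), 30)
        b = m.generate_rr_series(m.get_preset("mmf", seed=9), 30)
        assert np.array_equal(a.rr, b.rr)
        c = m.generate_rr_series(m.get_preset("mmf", seed=10), 30)
        assert not np.array_equal(a.rr, c.rr)

    def test_awake_median_near_target(self):
        rr = m.generate_rr_series(m.get_preset("awake", seed=4), 300)
        assert np.median(rr.rr) == pytest.approx(126.10, rel=0.05)

    def test_invalid_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            m.generate_rr_series(flat_preset(lf_amp=0.6, hf_amp=0.5), 15)

    def test_band_edge_validation(self):
        with pytest.raises(ValueError):
            flat_preset(hf_amp=0.1, hf_freq=1.0).validate()  # HF below band
        with pytest.raises(ValueError):
            flat_preset(lf_amp=0.1, lf_freq=2.0).validate()  # LF above band

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            m.generate_rr_series(flat_preset(), 5)

    def test_spectral_fidelity_single_tone(self):
        """A lone sinusoidal modulation at f0 puts the Lomb peak within one
        grid step of f0 (generator -> analysis round trip)."""
        p = flat_preset(mean_rr=120.0, hf_amp=0.05, hf_freq=2.7)
        rr = m.generate_rr_series(p, 180)
        spec = m.lomb_periodogram(rr)
        step = spec.frequencies[1] - spec.frequencies[0]
        assert abs(spec.frequencies[np.argmax(spec.power)] - 2.7) <= step + 1e-12


class TestEcgSynthesis:
    def test_uniform_train_r_times(self):
        rr = m.RRSeries.from_rr(np.full(9, 150.0))
        truth = m.truth_from_rr(rr, t_start=150.0)
        sig, tr = m.synthesize_ecg(truth)
        assert np.allclose(tr.beat_times, 150.0 + 150.0 * np.arange(10))
        assert sig.sampling_rate == 2000.0

    def test_low_sampling_rate_rejected(self, uniform_truth):
        with pytest.raises(ValueError):
            m.synthesize_ecg(uniform_truth, sampling_rate=500)

    def test_nonconducted_p_has_no_qrs(self):
        rr = m.RRSeries.from_rr(np.full(20, 150.0))
        truth = m.synthetic.inject_avb3(m.truth_from_rr(rr), 5, 2)
        sig, tr = m.synthesize_ecg(truth)
        blocked = [b for b in tr.beats if not b.conducted]
        assert len(blocked) == 2
        for b in blocked:
            assert b.r_peak is None
            # P lobe present, no R spike in that cycle: max voltage between
            # p_offset and the next 60 ms stays below half the P amplitude
            t = sig.times_ms
            win = (t > b.p_offset + 2) & (t < b.p_offset + 60)
            assert np.max(np.abs(sig.samples[win])) < 0.1

    def test_fiducial_ordering_violation_rejected(self, uniform_truth):
        bad = uniform_truth.copy()
        bad.beats[3].p_offset = bad.beats[3].qrs_onset + 5.0
        with pytest.raises(ValueError):
            m.synthesize_ecg(bad)

    def test_noise_is_seeded(self, uniform_truth):
        a, _ = m.synthesize_ecg(uniform_truth, noise_sd=0.05, seed=1)
        b, _ = m.synthesize_ecg(uniform_truth, noise_sd=0.05, seed=1)
        assert np.array_equal(a.samples, b.samples)


class TestDisorderInjection:
    def test_wenckebach_cycle_structure(self, uniform_truth):
        t = m.inject_conduction_disorder(uniform_truth, "wenckebach",
                                         start_index=10, n_cycles=2,
                                         run_length=3, pr_start=35.0,
                                         pr_step=10.0)
        cyc = t.beats[10:14]
        prs = [b.qrs_onset - b.p_onset for b in cyc[:3]]
        assert prs == pytest.approx([35.0, 45.0, 55.0])
        assert cyc[3].conducted is False and cyc[3].r_peak is None
        # exactly one non-conducted P per cycle of 4
        assert [b.conducted for b in t.beats[10:18]] == [True] * 3 + [False] \
            + [True] * 3 + [False]

    def test_avb3_run_below_two_rejected(self, uniform_truth):
        with pytest.raises(ValueError):
            m.synthetic.inject_avb3(uniform_truth, 5, n_blocked=1)

    def test_ventricular_run_length_guard(self, uniform_truth):
        with pytest.raises(ValueError):
            m.inject_conduction_disorder(uniform_truth, "ventricular_run",
                                         start_index=5, length=3)
        t = m.inject_conduction_disorder(uniform_truth, "ventricular_run",
                                         start_index=5, length=4)
        assert sum(b.beat_class == "ventricular" for b in t.beats) == 4
        assert all(b.p_onset is None for b in t.beats[5:9])

    def test_no_injection_negative_control(self):
        rr = m.generate_rr_series(m.get_preset("awake", seed=6), 60)
        fid = m.fiducials_from_truth(m.truth_from_rr(rr))
        findings = m.analyze_rhythm(fid)
        assert not any(findings.flags.values())

    def test_sinus_arrhythmia_raises_local_cv(self, uniform_truth):
        t = m.inject_conduction_disorder(uniform_truth, "sinus_arrhythmia",
                                         start_index=20, n_beats=30, seed=2)
        anchors = np.array([b.anchor() for b in t.beats])
        rr = np.diff(anchors)
        cv_in = np.std(rr[20:50]) / np.mean(rr[20:50])
        cv_out = np.std(rr[:20]) / np.mean(rr[:20])
        assert cv_in > 0.15 > cv_out

    def test_unknown_disorder(self, uniform_truth):
        with pytest.raises(ValueError):
            m.inject_conduction_disorder(uniform_truth, "torsade")


class TestVirtualHeart:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            m.VirtualHeartParams(two_to_one_cl_true=90, wb_cl_true=85).validate()
        with pytest.raises(ValueError):
            m.VirtualHeartParams(atrial_induction_prob=1.5).validate()

    def test_simulation_deterministic(self):
        heart = m.VirtualHeartParams(atrial_induction_prob=0.3, seed=5)
        proto = m.standard_protocol()
        a = m.simulate_ep_responses(heart, proto).to_frame()
        b = m.simulate_ep_responses(heart, proto).to_frame()
        assert a.equals(b)

    def test_unknown_chamber_rejected(self):
        proto = m.ProtocolSpec([m.synthetic.Maneuver(kind="snrt",
                                                     chamber="his_bundle",
                                                     drive_cl=120.0,
                                                     duration_s=30.0)])
        with pytest.raises(ValueError):
            m.simulate_ep_responses(m.VirtualHeartParams(), proto)
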