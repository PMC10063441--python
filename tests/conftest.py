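import numpy as np
import pytest

import murecg as m


@pytest.fixture(scope="session")
def awake_rr():
    """60 s awake-state tachogram, fixed seed."""
    return m.generate_rr_series(m.get_preset("awake", seed=3), 60)


@pytest.fixture(scope="session")
def uniform_truth():
    """80 identical sinus beats at RR 150 ms with default morphology."""
    rr = m.RRSeries.from_rr(np.full(80, 150.0))
    return m.truth_from_rr(rr)


@pytest.fixture(scope="session")
def clean_ecg(awake_rr):
    """Noise-free synthetic ECG + truth for the awake tachogram."""
    truth = m.truth_from_rr(awake_rr)
    return m.synthesize_ecg(truth)


def lomb_direct(t_s, y, freqs_hz):
    """Independent brute-force evaluation of the classical normalized Lomb
    periodogram (per-frequency tau-shifted sums; O(N*F))."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t_s, dtype=float)
    yc = y - y.mean()
    var = np.var(y)
    out = np.empty(len(freqs_hz))
    for i, f in enumerate(freqs_hz):
        w = 2.0 * np.pi * f
        tau = np.arctan2(np.sum(np.sin(2 * w * t)),
                         np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out[i] = 0.5 * ((yc @ c) ** 2 / (c @ c) + (yc @ s) ** 2 / (s @ s)) / var
    return out
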