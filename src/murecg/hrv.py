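"""Heart-rate-variability analysis of murine RR tachograms.

Implements the three standard HRV views used in small-animal telemetry:

* time domain — average/median RR, SDRR, SDSD, RMSSD, pRR50;
* frequency domain — normalized Lomb periodogram of the unevenly sampled
  tachogram, integrated over the murine VLF (0–0.15 Hz), LF (0.15–1.5 Hz)
  and HF (1.5–5 Hz) bands;
* nonlinear — Poincaré SD1/SD2 about the line of identity RR(n) = RR(n+1).

All intervals are in milliseconds, frequencies in Hz.  The Lomb periodogram
is evaluated directly on (beat time, RR) pairs, so no resampling onto a
uniform grid is needed — the natural choice for a point process whose
sampling times are the beats themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lombscargle

from .errors import DegenerateSpectrumError, InsufficientDataError

#: Murine spectral band edges in Hz: VLF 0–0.15, LF 0.15–1.5, HF 1.5–5.0.
BAND_EDGES = (0.0, 0.15, 1.5, 5.0)

#: Threshold (ms) for pRR50: fraction of successive differences strictly
#: longer than 50 ms.
PRR50_THRESHOLD_MS = 50.0


@dataclass
class RRSeries:
    """Beat-to-beat interval series with absolute beat times.

    ``rr[i] = beat_times[i+1] - beat_times[i]`` (ms); ``included`` masks
    intervals adjacent to ectopy or artifact out of the statistics.
    """

    beat_times: np.ndarray  # ms, length N+1, strictly increasing
    rr: np.ndarray          # ms, length N, all > 0
    included: np.ndarray    # bool, length N

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if len(self.rr) != len(self.beat_times) - 1:
            raise ValueError("len(rr) must equal len(beat_times) - 1")
        if len(self.included) != len(self.rr):
            raise ValueError("included mask must match rr length")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValueError("all RR intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_times, included=None) -> "RRSeries":
        beat_times = np.asarray(beat_times, dtype=float)
        rr = np.diff(beat_times)
        if included is None:
            included = np.ones(len(rr), dtype=bool)
        return cls(beat_times=beat_times, rr=rr, included=included)

    @classmethod
    def from_rr(cls, rr, t0: float = 0.0, included=None) -> "RRSeries":
        rr = np.asarray(rr, dtype=float)
        beat_times = t0 + np.concatenate([[0.0], np.cumsum(rr)])
        if included is None:
            included = np.ones(len(rr), dtype=bool)
        return cls(beat_times=beat_times, rr=rr, included=included)

    @property
    def n_included(self) -> int:
        return int(np.sum(self.included))

    def included_rr(self) -> np.ndarray:
        return self.rr[self.included]

    def successive_differences(self) -> np.ndarray:
        """Differences between adjacent intervals, both of which are included."""
        ok = self.included[:-1] & self.included[1:]
        return np.diff(self.rr)[ok]


@dataclass
class HrvTimeDomain:
    average_rr: float
    median_rr: float
    sdrr: float
    sdsd: float
    rmssd: float
    prr50: float  # percent


@dataclass
class HrvSpectrum:
    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray        # normalized Lomb periodogram values
    normalization: str = "variance"
    degenerate: bool = False


@dataclass
class HrvFreqDomain:
    vlf_pct: float
    lf_pct: float
    hf_pct: float
    lf_hf: float
    band_edges: tuple = BAND_EDGES


@dataclass
class PoincareResult:
    sd1: float
    sd2: float


def default_frequency_grid(step: float = 0.005, fmax: float = 5.0) -> np.ndarray:
    """Uniform frequency grid over (0, fmax] Hz (the murine band ceiling)."""
    n = int(round(fmax / step))
    return step * np.arange(1, n + 1)


def compute_time_domain(rr: RRSeries) -> HrvTimeDomain:
    """Time-domain HRV statistics over included intervals.

    SDRR and SDSD use the sample (n-1) convention; pRR50 counts successive
    absolute differences strictly greater than 50 ms.
    """
    x = rr.included_rr()
    if len(x) < 2:
        raise InsufficientDataError("time-domain HRV needs >= 2 included intervals")
    d = rr.successive_differences()
    if len(d) == 0:
        raise InsufficientDataError("no successive pairs of included intervals")
    return HrvTimeDomain(
        average_rr=float(np.mean(x)),
        median_rr=float(np.median(x)),
        sdrr=float(np.std(x, ddof=1)),
        sdsd=float(np.std(d, ddof=1)),
        rmssd=float(np.sqrt(np.mean(d ** 2))),
        prr50=float(100.0 * np.mean(np.abs(d) > PRR50_THRESHOLD_MS)),
    )


def lomb_periodogram(rr: RRSeries, freq_grid=None) -> HrvSpectrum:
    """Normalized Lomb periodogram of the tachogram (RR_i against beat time).

    The RR values are mean-subtracted and the classical Lomb estimate is
    divided by the population variance, i.e. the textbook
    P(f) = 1/(2 sigma^2) [ ... ] normalization.  A constant series has no
    variance to apportion and is returned flagged degenerate with zero power.
    """
    if freq_grid is None:
        freq_grid = default_frequency_grid()
    freq_grid = np.asarray(freq_grid, dtype=float)
    if len(freq_grid) < 2 or np.any(np.diff(freq_grid) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if rr.n_included < 30:
        raise InsufficientDataError("Lomb periodogram needs >= 30 included intervals")

    t = rr.beat_times[:-1][rr.included] / 1000.0  # interval start times, seconds
    x = rr.included_rr()
    var = float(np.var(x))  # population variance
    if var <= np.finfo(float).eps * np.mean(x) ** 2:
        return HrvSpectrum(frequencies=freq_grid,
                           power=np.zeros_like(freq_grid),
                           degenerate=True)
    power = lombscargle(t, x - np.mean(x), 2.0 * np.pi * freq_grid) / var
    return HrvSpectrum(frequencies=freq_grid, power=power)


def band_powers(spectrum: HrvSpectrum, band_edges=BAND_EDGES) -> HrvFreqDomain:
    """Integrate the periodogram over VLF/LF/HF and express each as a
    percentage of their sum (the three printed percentages add to 100)."""
    if spectrum.degenerate:
        raise DegenerateSpectrumError("band percentages undefined for a constant tachogram")
    f, p = spectrum.frequencies, spectrum.power
    lo_edges, hi_edges = band_edges[:-1], band_edges[1:]
    powers = []
    for i, (lo, hi) in enumerate(zip(lo_edges, hi_edges)):
        last = i == len(lo_edges) - 1
        mask = (f >= lo) & ((f <= hi) if last else (f < hi))
        if np.sum(mask) < 2:
            powers.append(0.0)
            continue
        powers.append(float(np.trapezoid(p[mask], f[mask])))
    total = sum(powers)
    if total <= 0:
        raise DegenerateSpectrumError("zero total band power")
    vlf, lf, hf = (100.0 * w / total for w in powers)
    return HrvFreqDomain(vlf_pct=vlf, lf_pct=lf, hf_pct=hf,
                         lf_hf=lf / hf if hf > 0 else np.inf,
                         band_edges=band_edges)


def poincare(rr: RRSeries, ddof: int = 0) -> PoincareResult:
    """Poincaré SD1/SD2 of the (RR_n, RR_n+1) scatter.

    SD1 is the dispersion perpendicular to the identity line, SD2 along it:
    SD1 = SD[(RR_n - RR_n+1)/sqrt(2)], SD2 = SD[(RR_n + RR_n+1)/sqrt(2)].
    The population convention (ddof=0) is the default so the algebraic
    identities SD1^2 = SDSD_pop^2/2 and SD1^2 + SD2^2 = 2 SDRR_pop^2 hold
    exactly; pass ddof=1 for the sample convention.
    """
    ok = rr.included[:-1] & rr.included[1:]
    a = rr.rr[:-1][ok]
    b = rr.rr[1:][ok]
    if len(a) < 2 or rr.n_included < 3:
        raise InsufficientDataError("Poincaré analysis needs >= 3 included intervals")
    sd1 = float(np.std((a - b) / np.sqrt(2.0), ddof=ddof))
    sd2 = float(np.std((a + b) / np.sqrt(2.0), ddof=ddof))
    return PoincareResult(sd1=sd1, sd2=sd2)


def analyze(rr: RRSeries, freq_grid=None) -> dict:
    """Convenience: all HRV quantities for one record as a flat dict."""
    td = compute_time_domain(rr)
    pc = poincare(rr)
    out = {
        "average_rr": td.average_rr, "median_rr": td.median_rr,
        "sdrr": td.sdrr, "sdsd": td.sdsd, "rmssd": td.rmssd, "prr50": td.prr50,
        "sd1": pc.sd1, "sd2": pc.sd2,
    }
    try:
        fd = band_powers(lomb_periodogram(rr, freq_grid))
        out.update({"vlf_pct": fd.vlf_pct, "lf_pct": fd.lf_pct,
                    "hf_pct": fd.hf_pct, "lf_hf": fd.lf_hf})
    except (InsufficientDataError, DegenerateSpectrumError):
        out.update({"vlf_pct": np.nan, "lf_pct": np.nan,
                    "hf_pct": np.nan, "lf_hf": np.nan})
    return out
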