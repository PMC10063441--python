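"""Synthetic murine ECG/RR generator and virtual-heart EP simulator.

Everything downstream (delineation, HRV, arrhythmia detection, EP analysis,
group statistics) is testable by recovery against the ground truth emitted
here.  Three parts:

1. An autonomic-tone RR generator: interval-domain sinusoidal modulation
   (LF, HF and a very-slow wander component) plus white noise, evaluated at
   cumulative beat times (point-process construction).  The bundled presets
   emulate three autonomic states of the mouse heart — awake, MMF narcosis
   (medetomidine-midazolam-fentanyl: deep bradycardia with dominant
   high-frequency vagal modulation) and IF narcosis (isoflurane-fentanyl:
   mild rate depression, near-awake variability).
2. An ECG synthesizer placing stylized P-QRS-T complexes (compact-support
   raised-cosine lobes) at ground-truth fiducials, plus injectors for
   conduction disorders: Wenckebach periodicity, intermittent third-degree
   AV block, ventricular runs and sinus arrhythmia.
3. A threshold-deterministic virtual heart driven by a programmed
   stimulation protocol (overdrive drives, decremental ramps, S1/S2(/S3)
   scans, burst pacing); only induction success and episode duration are
   stochastic, so refractory periods and conduction cycle lengths are
   recovered exactly up to protocol step size.

All times are ms from record start; identical seed + configuration gives
bit-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .delineation import EcgSignal
from .ep import StimEvent, StimLog
from .hrv import RRSeries

#: Fixed frequency (Hz) of the very-slow "wander" modulation; sits inside
#: the murine VLF band (0-0.15 Hz).
WANDER_FREQ_HZ = 0.05

#: Atrial induced episodes are floored at the qualifying duration (3 s) so a
#: "successful" induction always yields a countable episode.
ATRIAL_FLOOR_S = 3.0


@dataclass
class AutonomicPreset:
    """RR-generator parameters for one autonomic state.

    Amplitudes are fractions of the mean RR; lf_freq must sit in the murine
    LF band (0.15-1.5 Hz) and hf_freq in the HF band (1.5-5 Hz).
    """

    name: str
    mean_rr: float        # ms
    lf_amp: float
    lf_freq: float        # Hz
    hf_amp: float
    hf_freq: float        # Hz
    wander_amp: float
    noise_sd: float       # ms
    seed: int = 0

    def validate(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        for a in (self.lf_amp, self.hf_amp, self.wander_amp):
            if a < 0:
                raise ValueError("modulation amplitudes must be >= 0")
        if self.lf_amp + self.hf_amp + self.wander_amp >= 1.0:
            raise ValueError("summed modulation amplitudes must stay below 1 "
                             "(intervals would go non-positive)")
        if self.lf_amp > 0 and not (0.15 < self.lf_freq <= 1.5):
            raise ValueError("lf_freq must lie in (0.15, 1.5] Hz")
        if self.hf_amp > 0 and not (1.5 < self.hf_freq <= 5.0):
            raise ValueError("hf_freq must lie in (1.5, 5.0] Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# Calibration targets for the three autonomic states (group medians /
# variability structure of murine telemetry under each regimen):
# awake  median RR ~126 ms, modest mixed VLF/LF/HF power, LF/HF ~0.6;
# MMF    median RR ~227 ms, RMSSD ~130 ms, HF fraction > 80 %, LF/HF ~0.16;
# IF     median RR ~157 ms, awake-like variability.
PRESETS: dict[str, AutonomicPreset] = {
    "awake": AutonomicPreset(name="awake", mean_rr=126.1,
                             lf_amp=0.034, lf_freq=0.5,
                             hf_amp=0.044, hf_freq=2.5,
                             wander_amp=0.030, noise_sd=2.0),
    "mmf": AutonomicPreset(name="mmf", mean_rr=227.3,
                           lf_amp=0.08, lf_freq=0.5,
                           hf_amp=0.42, hf_freq=2.0,
                           wander_amp=0.01, noise_sd=3.0),
    "if": AutonomicPreset(name="if", mean_rr=157.5,
                          lf_amp=0.031, lf_freq=0.5,
                          hf_amp=0.046, hf_freq=2.5,
                          wander_amp=0.028, noise_sd=2.0),
}


def get_preset(name: str, seed: int | None = None, **overrides) -> AutonomicPreset:
    p = replace(PRESETS[name], **overrides)
    if seed is not None:
        p = replace(p, seed=seed)
    return p


def generate_rr_series(preset: AutonomicPreset, duration_s: float) -> RRSeries:
    """Generate a tachogram of at least `duration_s` seconds.

    RR_i = mean_rr * (1 + lf_amp sin(2 pi lf_freq t_i + phi_lf)
                        + hf_amp sin(2 pi hf_freq t_i + phi_hf)
                        + wander_amp sin(2 pi 0.05 t_i + phi_w))
           + N(0, noise_sd),
    with t_i the cumulative beat time at the start of interval i and the
    phases drawn once per record from the preset seed.
    """
    preset.validate()
    if duration_s < 10:
        raise ValueError("duration must be >= 10 s")
    rng = np.random.default_rng(preset.seed)
    phi = rng.uniform(0, 2 * np.pi, size=3)
    beat_times = [0.0]
    rr = []
    t = 0.0
    dur_ms = duration_s * 1000.0
    while t < dur_ms:
        ts = t / 1000.0
        mod = (preset.lf_amp * np.sin(2 * np.pi * preset.lf_freq * ts + phi[0])
               + preset.hf_amp * np.sin(2 * np.pi * preset.hf_freq * ts + phi[1])
               + preset.wander_amp * np.sin(2 * np.pi * WANDER_FREQ_HZ * ts + phi[2]))
        interval = preset.mean_rr * (1.0 + mod)
        if preset.noise_sd > 0:
            interval += rng.normal(0.0, preset.noise_sd)
        if interval <= 0:
            raise ValueError("non-positive RR interval generated; "
                             "preset amplitudes/noise violate the invariant")
        t += interval
        beat_times.append(t)
        rr.append(interval)
    return RRSeries(beat_times=np.array(beat_times), rr=np.array(rr),
                    included=np.ones(len(rr), dtype=bool))


# ---------------------------------------------------------------------------
# ECG ground truth and waveform synthesis
# ---------------------------------------------------------------------------

@dataclass
class TrueBeat:
    """Ground truth for one cardiac cycle.

    A conducted sinus beat has the full P-QRS-T fiducial set; a
    non-conducted atrial event (conducted=False) keeps only the P wave; a
    ventricular beat has no P.  All fields in ms.
    """

    beat_class: str               # sinus | ventricular | fusion
    p_onset: float | None = None
    p_offset: float | None = None
    qrs_onset: float | None = None
    r_peak: float | None = None
    qrs_offset: float | None = None
    t_end: float | None = None
    conducted: bool = True

    def anchor(self) -> float:
        return self.r_peak if self.r_peak is not None else self.p_onset

    def shift(self, delta: float) -> None:
        for f in ("p_onset", "p_offset", "qrs_onset", "r_peak",
                  "qrs_offset", "t_end"):
            v = getattr(self, f)
            if v is not None:
                setattr(self, f, v + delta)

    def validate(self) -> None:
        if self.p_onset is not None:
            if self.p_offset is None or self.p_offset <= self.p_onset:
                raise ValueError("p_offset must follow p_onset")
            if self.qrs_onset is not None and self.p_offset > self.qrs_onset:
                raise ValueError("p_offset must not exceed qrs_onset")
        if self.r_peak is not None:
            if not (self.qrs_onset <= self.r_peak <= self.qrs_offset):
                raise ValueError("r_peak must lie within the QRS")
            if not (self.qrs_onset < self.qrs_offset < self.t_end):
                raise ValueError("qrs_onset < qrs_offset < t_end required")
        if not self.conducted and self.r_peak is not None:
            raise ValueError("non-conducted atrial events carry no QRS")


@dataclass
class SynthTruth:
    """Ground-truth annotation set for one synthetic record."""

    beats: list[TrueBeat] = field(default_factory=list)
    morphology: dict = field(default_factory=dict)  # pr/p_dur/qrs_dur/qt used

    def validate(self) -> None:
        anchors = [b.anchor() for b in self.beats]
        if any(b <= a for a, b in zip(anchors, anchors[1:])):
            raise ValueError("beats must be strictly increasing in time")
        for b in self.beats:
            b.validate()

    @property
    def beat_times(self) -> np.ndarray:
        """R-peak times of beats that have a ventricular complex."""
        return np.array([b.r_peak for b in self.beats if b.r_peak is not None])

    def copy(self) -> "SynthTruth":
        return copy.deepcopy(self)


DEFAULT_MORPHOLOGY = {"pr": 38.0, "p_dur": 12.0, "qrs_dur": 10.0, "qt": 40.0}


def truth_from_rr(rr: RRSeries, morphology: dict | None = None,
                  t_start: float = 150.0) -> SynthTruth:
    """All-sinus ground truth with R peaks at the tachogram beat times.

    The record is shifted by `t_start` so the first P wave has room.
    Default morphology is a stylized murine complex: PR 38 ms, P 12 ms,
    QRS 10 ms, QT 40 ms.
    """
    m = dict(DEFAULT_MORPHOLOGY, **(morphology or {}))
    truth = SynthTruth(morphology=m)
    for t in rr.beat_times:
        r = t + t_start
        qon = r - 0.4 * m["qrs_dur"]
        truth.beats.append(TrueBeat(
            beat_class="sinus",
            p_onset=qon - m["pr"], p_offset=qon - m["pr"] + m["p_dur"],
            qrs_onset=qon, r_peak=r, qrs_offset=qon + m["qrs_dur"],
            t_end=qon + m["qt"], conducted=True))
    truth.validate()
    return truth


def _hann_lobe(t: np.ndarray, on: float, off: float, amp: float) -> np.ndarray:
    """Raised-cosine lobe with compact support on [on, off] (ms)."""
    y = np.zeros_like(t)
    m = (t >= on) & (t <= off)
    y[m] = amp * np.sin(np.pi * (t[m] - on) / (off - on)) ** 2
    return y


def _qrs_wave(t: np.ndarray, on: float, peak: float, off: float,
              amp: float) -> np.ndarray:
    """Asymmetric compact-support spike: raised-cosine rise on [on, peak],
    fall on [peak, off] (stylized murine QRS, no Q/S separation)."""
    y = np.zeros_like(t)
    m = (t >= on) & (t <= peak)
    y[m] = amp * np.sin(0.5 * np.pi * (t[m] - on) / (peak - on)) ** 2
    m = (t > peak) & (t <= off)
    y[m] = amp * np.sin(0.5 * np.pi * (off - t[m]) / (off - peak)) ** 2
    return y


def synthesize_ecg(truth: SynthTruth, sampling_rate: float = 2000.0,
                   noise_sd: float = 0.0, seed: int | None = None,
                   r_amp: float = 1.0, p_amp: float = 0.2,
                   t_amp: float = 0.3) -> tuple[EcgSignal, SynthTruth]:
    """Render the ground truth into a voltage trace (mV).

    One template complex per conducted beat, a lone P deflection for each
    non-conducted atrial event.  Waves are compact-support raised-cosine
    lobes, so delineation thresholds see true iso-electric baseline between
    waves.  Optional additive white noise (SNR relative to the 1 mV R peak).
    """
    truth.validate()
    if sampling_rate < 1000:
        raise ValueError("sampling_rate must be >= 1000 Hz to resolve a "
                         "~10 ms murine QRS")
    last = max(b.t_end if b.t_end is not None else b.p_offset
               for b in truth.beats)
    n = int(np.ceil((last + 100.0) * sampling_rate / 1000.0))
    t = np.arange(n) * (1000.0 / sampling_rate)
    x = np.zeros(n)
    dt = 1000.0 / sampling_rate

    def add(on, off, amp):
        i0 = max(0, int(np.floor(on / dt)))
        i1 = min(n, int(np.ceil(off / dt)) + 1)
        x[i0:i1] += _hann_lobe(t[i0:i1], on, off, amp)

    for b in truth.beats:
        if b.p_onset is not None:
            add(b.p_onset, b.p_offset, p_amp)
        if b.r_peak is not None:
            amp = r_amp * (0.6 if b.beat_class == "fusion" else 1.0)
            i0 = max(0, int(np.floor(b.qrs_onset / dt)))
            i1 = min(n, int(np.ceil(b.qrs_offset / dt)) + 1)
            x[i0:i1] += _qrs_wave(t[i0:i1], b.qrs_onset, b.r_peak,
                                  b.qrs_offset, amp)
            add(b.qrs_offset, b.t_end,
                t_amp * (0.6 if b.beat_class == "ventricular" else 1.0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)
    return EcgSignal(samples=x, sampling_rate=sampling_rate), truth


# ---------------------------------------------------------------------------
# Conduction-disorder injection
# ---------------------------------------------------------------------------

def _retime(truth: SynthTruth, new_rr: np.ndarray) -> None:
    """Shift beats so successive anchor gaps equal new_rr (cascading)."""
    anchors = np.array([b.anchor() for b in truth.beats])
    new_anchors = np.concatenate([[anchors[0]], anchors[0] + np.cumsum(new_rr)])
    for b, a_old, a_new in zip(truth.beats, anchors, new_anchors):
        b.shift(a_new - a_old)


def inject_wenckebach(truth: SynthTruth, start_index: int, n_cycles: int,
                      run_length: int = 3, pr_start: float = 35.0,
                      pr_step: float = 10.0) -> SynthTruth:
    """Wenckebach (second-degree type I) periodicity.

    From `start_index`, each cycle is `run_length` conducted beats with PR
    increasing by `pr_step`, then exactly one non-conducted P.  The atrial
    cadence (P timing) is preserved; ventricular fiducials move with the
    prolonging PR.
    """
    if run_length < 2:
        raise ValueError("a Wenckebach run needs >= 2 conducted beats")
    out = truth.copy()
    m = out.morphology
    i = start_index
    for _ in range(n_cycles):
        for j in range(run_length):
            if i >= len(out.beats):
                break
            b = out.beats[i]
            if b.p_onset is None:
                i += 1
                continue
            pr = pr_start + j * pr_step
            qon = b.p_onset + pr
            b.qrs_onset = qon
            b.r_peak = qon + 0.4 * m["qrs_dur"]
            b.qrs_offset = qon + m["qrs_dur"]
            b.t_end = qon + m["qt"]
            i += 1
        if i < len(out.beats):
            b = out.beats[i]
            b.conducted = False
            b.qrs_onset = b.r_peak = b.qrs_offset = b.t_end = None
            i += 1
    out.validate()
    return out


def inject_avb3(truth: SynthTruth, start_index: int, n_blocked: int,
                n_runs: int = 1, gap_beats: int = 10) -> SynthTruth:
    """Intermittent third-degree AV block: runs of >= 2 consecutive
    non-conducted P waves (ventricular pause; atrial rhythm continues)."""
    if n_blocked < 2:
        raise ValueError("intermittent complete block needs >= 2 consecutive "
                         "non-conducted P waves")
    out = truth.copy()
    i = start_index
    for _ in range(n_runs):
        for _ in range(n_blocked):
            if i >= len(out.beats):
                break
            b = out.beats[i]
            if b.p_onset is not None:
                b.conducted = False
                b.qrs_onset = b.r_peak = b.qrs_offset = b.t_end = None
            i += 1
        i += gap_beats
    out.validate()
    return out


def inject_ventricular_run(truth: SynthTruth, start_index: int,
                           length: int) -> SynthTruth:
    """Reclassify `length` consecutive beats as spontaneous ventricular
    activity (no preceding P).  Runs below 4 beats do not meet the
    definition of abnormal ventricular activity and are rejected."""
    if length < 4:
        raise ValueError("abnormal ventricular activity requires >= 4 "
                         "consecutive ventricular beats")
    out = truth.copy()
    for i in range(start_index, min(start_index + length, len(out.beats))):
        b = out.beats[i]
        b.beat_class = "ventricular"
        b.p_onset = b.p_offset = None
        b.conducted = True
    out.validate()
    return out


def inject_sinus_arrhythmia(truth: SynthTruth, start_index: int,
                            n_beats: int, cv: float = 0.35,
                            seed: int = 0) -> SynthTruth:
    """Perturb RR over a span so local RR variability clearly exceeds the
    sinus-arrhythmia detector's irregularity criterion (CV default 0.35
    against a detection threshold of 0.15)."""
    out = truth.copy()
    anchors = np.array([b.anchor() for b in out.beats])
    rr = np.diff(anchors)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    hi = min(start_index + n_beats, len(rr))
    factors = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                            size=hi - start_index)
    new_rr = rr.copy()
    new_rr[start_index:hi] = rr[start_index:hi] * factors
    _retime(out, new_rr)
    out.validate()
    return out


def inject_conduction_disorder(truth: SynthTruth, disorder: str,
                               **params) -> SynthTruth:
    """Dispatch by disorder name: wenckebach | intermittent_avb3 |
    ventricular_run | sinus_arrhythmia."""
    dispatch = {"wenckebach": inject_wenckebach,
                "intermittent_avb3": inject_avb3,
                "ventricular_run": inject_ventricular_run,
                "sinus_arrhythmia": inject_sinus_arrhythmia}
    if disorder not in dispatch:
        raise ValueError(f"unknown disorder {disorder!r}")
    return dispatch[disorder](truth, **params)


# ---------------------------------------------------------------------------
# Virtual heart and stimulation protocol
# ---------------------------------------------------------------------------

@dataclass
class VirtualHeartParams:
    """Ground-truth electrophysiology of one simulated animal.

    Conduction is threshold-deterministic: an extra stimulus captures iff
    its coupling exceeds the tissue ERP; atrial pacing conducts 1:1 iff
    CL > wb_cl_true, 2:1 iff CL <= two_to_one_cl_true (Wenckebach-type in
    between); ventricular pacing conducts retrogradely iff CL > va_cl_true.
    Only arrhythmia induction and episode durations are stochastic.
    """

    basic_cl: float = 150.0            # intrinsic sinus cycle length, ms
    snrt_true: float = 250.0           # uncorrected post-overdrive pause, ms
    aerp_true: float = 40.0
    averp_true: float = 60.0
    verp_true: float = 46.0
    wb_cl_true: float = 85.0
    two_to_one_cl_true: float = 65.0
    va_cl_true: float = 100.0
    atrial_induction_prob: float = 0.04
    ventricular_induction_prob: float = 0.01
    atrial_episode_s: tuple = (10.0, 4.0)      # mean, sd of episode duration
    ventricular_episode_s: tuple = (1.2, 0.4)
    seed: int = 0

    def validate(self) -> None:
        for f in ("basic_cl", "snrt_true", "aerp_true", "averp_true",
                  "verp_true", "wb_cl_true", "two_to_one_cl_true", "va_cl_true"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.two_to_one_cl_true >= self.wb_cl_true:
            raise ValueError("two_to_one_cl_true must be < wb_cl_true")
        for p in (self.atrial_induction_prob, self.ventricular_induction_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("induction probabilities must lie in [0, 1]")


@dataclass
class Maneuver:
    kind: str                 # snrt | ramp | erp_scan | induction_pes | induction_burst
    chamber: str              # atrium | ventricle
    drive_cl: float | None = None
    duration_s: float | None = None          # snrt / burst
    cycle_lengths: tuple = ()                # ramp
    couplings: tuple = ()                    # erp_scan / induction
    n_s1: int = 8
    stimuli_per_cl: int = 10
    burst_cl: float | None = None


@dataclass
class ProtocolSpec:
    maneuvers: list[Maneuver] = field(default_factory=list)


def standard_protocol(erp_step: float = 5.0) -> ProtocolSpec:
    """The standard murine PES protocol: SNRT drives of 30 s at 120 and
    100 ms; decremental atrial ramp (WB/2:1) and incremental ventricular
    ramp (VA); S1/S2 ERP scans at both drive CLs in atrium and ventricle;
    S1/S2/S3 double-extra-stimulus induction (couplings 40-20 ms, 5 ms
    decrements) at both drive CLs plus 3 s and 6 s bursts (40-10 ms CLs,
    5 ms decrements) in each chamber."""
    m: list[Maneuver] = []
    for cl in (120.0, 100.0):
        m.append(Maneuver(kind="snrt", chamber="atrium", drive_cl=cl,
                          duration_s=30.0))
    m.append(Maneuver(kind="ramp", chamber="atrium",
                      cycle_lengths=tuple(np.arange(120.0, 45.0, -5.0))))
    m.append(Maneuver(kind="ramp", chamber="ventricle",
                      cycle_lengths=tuple(np.arange(50.0, 155.0, 5.0))))
    erp_scan = tuple(np.arange(80.0, 15.0, -erp_step))
    for cl in (120.0, 100.0):
        m.append(Maneuver(kind="erp_scan", chamber="atrium", drive_cl=cl,
                          couplings=erp_scan))
        m.append(Maneuver(kind="erp_scan", chamber="ventricle", drive_cl=cl,
                          couplings=erp_scan))
    pes = tuple(np.arange(40.0, 15.0, -5.0))
    for chamber in ("atrium", "ventricle"):
        for cl in (120.0, 100.0):
            m.append(Maneuver(kind="induction_pes", chamber=chamber,
                              drive_cl=cl, couplings=pes))
        for dur in (3.0, 3.0, 6.0, 6.0):
            for burst_cl in np.arange(40.0, 5.0, -5.0):
                m.append(Maneuver(kind="induction_burst", chamber=chamber,
                                  duration_s=dur, burst_cl=float(burst_cl)))
    return ProtocolSpec(maneuvers=m)


def simulate_ep_responses(heart: VirtualHeartParams,
                          protocol: ProtocolSpec) -> StimLog:
    """Run the pacing protocol against the virtual heart; returns the
    stimulus/response event log an EP recording system would show."""
    heart.validate()
    rng = np.random.default_rng(heart.seed)
    events: list[StimEvent] = []
    t = 0.0
    # pre-protocol sinus rhythm for basic cycle length measurement
    for _ in range(8):
        events.append(StimEvent(time=t, kind="sense", chamber="atrium",
                                label="sinus", maneuver_id=-1))
        t += heart.basic_cl
    t += 500.0

    for mid, man in enumerate(protocol.maneuvers):
        if man.chamber not in ("atrium", "ventricle"):
            raise ValueError(f"catheter cannot stimulate chamber {man.chamber!r}")
        if man.kind == "snrt":
            n_stim = int(round(man.duration_s * 1000.0 / man.drive_cl))
            for _ in range(n_stim):
                events.append(StimEvent(t, "stimulus", "atrium", "S1", mid,
                                        drive_cl=man.drive_cl))
                t += man.drive_cl
            last = t - man.drive_cl
            ret = last + heart.snrt_true
            if heart.snrt_true <= 5000.0:
                events.append(StimEvent(ret, "sense", "atrium",
                                        "sinus_return", mid))
            t = max(t, ret) + 1000.0
        elif man.kind == "ramp":
            for cl in man.cycle_lengths:
                for k in range(man.stimuli_per_cl):
                    events.append(StimEvent(t, "stimulus", man.chamber, "S1",
                                            mid, drive_cl=cl))
                    if man.chamber == "atrium":
                        if cl > heart.wb_cl_true:
                            conducted = True
                        elif cl > heart.two_to_one_cl_true:
                            conducted = (k % 3) != 2   # 3:2 Wenckebach pattern
                        else:
                            conducted = (k % 2) == 0   # 2:1
                        events.append(StimEvent(
                            t + 30.0, "sense", "ventricle",
                            "conducted_response" if conducted else "no_response",
                            mid, drive_cl=cl))
                    else:  # ventricular pacing, retrograde conduction
                        conducted = cl > heart.va_cl_true
                        events.append(StimEvent(
                            t + 30.0, "sense", "atrium",
                            "conducted_response" if conducted else "no_response",
                            mid, drive_cl=cl))
                    t += cl
                t += 300.0
            t += 1000.0
        elif man.kind == "erp_scan":
            erp = heart.aerp_true if man.chamber == "atrium" else heart.verp_true
            for c in man.couplings:
                for _ in range(man.n_s1):
                    events.append(StimEvent(t, "stimulus", man.chamber, "S1",
                                            mid, drive_cl=man.drive_cl))
                    t += man.drive_cl
                s2_t = t - man.drive_cl + c
                events.append(StimEvent(s2_t, "stimulus", man.chamber, "S2",
                                        mid, drive_cl=man.drive_cl, coupling=c))
                if c > erp:
                    events.append(StimEvent(s2_t + 2.0, "sense", man.chamber,
                                            "capture", mid, coupling=c))
                    if man.chamber == "atrium" and c > heart.averp_true:
                        events.append(StimEvent(s2_t + 40.0, "sense",
                                                "ventricle",
                                                "conducted_response", mid,
                                                coupling=c))
                t = s2_t + 500.0
            t += 1000.0
        elif man.kind in ("induction_pes", "induction_burst"):
            if man.kind == "induction_pes":
                for _ in range(man.n_s1):
                    events.append(StimEvent(t, "stimulus", man.chamber, "S1",
                                            mid, drive_cl=man.drive_cl))
                    t += man.drive_cl
                c2 = man.couplings[0] if man.couplings else 40.0
                c3 = man.couplings[-1] if man.couplings else 20.0
                t_s2 = t - man.drive_cl + c2
                events.append(StimEvent(t_s2, "stimulus", man.chamber, "S2",
                                        mid, drive_cl=man.drive_cl, coupling=c2))
                events.append(StimEvent(t_s2 + c3, "stimulus", man.chamber,
                                        "S3", mid, drive_cl=man.drive_cl,
                                        coupling=c3))
                t = t_s2 + c3 + 100.0
            else:
                n_stim = int(round(man.duration_s * 1000.0 / man.burst_cl))
                for _ in range(n_stim):
                    events.append(StimEvent(t, "stimulus", man.chamber,
                                            "burst", mid,
                                            drive_cl=man.burst_cl))
                    t += man.burst_cl
                t += 50.0
            prob = (heart.atrial_induction_prob if man.chamber == "atrium"
                    else heart.ventricular_induction_prob)
            if rng.random() < prob:
                if man.chamber == "atrium":
                    dur = max(ATRIAL_FLOOR_S,
                              rng.normal(*heart.atrial_episode_s))
                    label, step = "atrial_ectopic", 25.0
                else:
                    dur = max(0.4, rng.normal(*heart.ventricular_episode_s))
                    label, step = "ventricular_ectopic", 100.0
                times = t + np.arange(0.0, dur * 1000.0 + step / 2, step)
                for tt in times:
                    events.append(StimEvent(float(tt), "sense", man.chamber,
                                            label, mid))
                t = float(times[-1]) + 500.0
            t += 1000.0
        else:
            raise ValueError(f"unknown maneuver kind {man.kind!r}")
    events.sort(key=lambda e: e.time)
    return StimLog(events=events)
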