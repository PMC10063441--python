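"""Invasive programmed-electrical-stimulation (EP study) parameter extraction.

Works on an abstract stimulus/response event log (StimLog): the catheter
signal chain is out of scope, each pacing stimulus and each sensed cardiac
response is one timestamped record.  From such a log the module extracts the
standard murine EP panel:

* corrected sinus node recovery time (SNRT) after 30 s overdrive drives,
  corrected by subtracting the basic (pre-pacing) atrial cycle length;
* AV conduction cycle lengths: Wenckebach (WB CL), 2:1 CL, and retrograde
  ventriculo-atrial (VA CL);
* effective refractory periods (AERP, AVERP, VERP) from S1/S2 scans;
* induced-arrhythmia episodes, inducibility percentage and burden.

Conventions (used consistently by the analyzer and by the virtual-heart
simulator, so round-trip recovery is exact):

* ERP = the longest S1-S2 coupling interval whose S2 fails (to capture for
  atrium/ventricle, to conduct for the AV node).
* WB CL = longest atrial pacing CL at which 1:1 conduction first fails;
  2:1 CL = longest CL showing 2:1 conduction; VA CL = longest ventricular
  pacing CL with retrograde block (larger VA CL = worse retrograde
  conduction).
* Parameters outside the tested range are censored, never extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

STIM_LABELS = ("S1", "S2", "S3", "burst")
SENSE_LABELS = ("sinus", "sinus_return", "capture", "conducted_response",
                "no_response", "atrial_ectopic", "ventricular_ectopic")

#: An atrial tachyarrhythmia must last at least this long (s) to count.
ATRIAL_EPISODE_MIN_S = 3.0
#: A ventricular arrhythmia needs at least this many consecutive beats.
VENTRICULAR_MIN_BEATS = 4
#: No sinus return within this window after overdrive = sinus arrest.
SINUS_RETURN_TIMEOUT_MS = 5000.0


@dataclass
class StimEvent:
    time: float               # ms
    kind: str                 # stimulus | sense
    chamber: str              # atrium | ventricle
    label: str
    maneuver_id: int
    drive_cl: float | None = None   # ms
    coupling: float | None = None   # ms, for S2/S3


@dataclass
class StimLog:
    events: list[StimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("StimLog events must be time-ordered")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"time_ms": e.time, "kind": e.kind, "chamber": e.chamber,
              "label": e.label, "maneuver_id": e.maneuver_id,
              "drive_cl_ms": e.drive_cl, "coupling_ms": e.coupling}
             for e in self.events],
            columns=["time_ms", "kind", "chamber", "label", "maneuver_id",
                     "drive_cl_ms", "coupling_ms"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimLog":
        events = [StimEvent(time=float(r.time_ms), kind=str(r.kind),
                            chamber=str(r.chamber), label=str(r.label),
                            maneuver_id=int(r.maneuver_id),
                            drive_cl=None if pd.isna(r.drive_cl_ms) else float(r.drive_cl_ms),
                            coupling=None if pd.isna(r.coupling_ms) else float(r.coupling_ms))
                  for r in df.itertuples()]
        return cls(events=events)

    def by_maneuver(self) -> dict[int, list[StimEvent]]:
        out: dict[int, list[StimEvent]] = {}
        for e in self.events:
            out.setdefault(e.maneuver_id, []).append(e)
        return out


@dataclass
class EpMeasurement:
    """A single EP parameter with explicit censoring state."""

    value: float | None
    censored: str | None = None   # below_range | above_range | arrest | None
    warning: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None and self.censored is None


@dataclass
class EpParameters:
    """Per-animal EP panel (all ms; keys of the dicts are drive CLs)."""

    snrt_corrected: dict[float, EpMeasurement] = field(default_factory=dict)
    wb_cl: EpMeasurement | None = None
    two_to_one_cl: EpMeasurement | None = None
    va_cl: EpMeasurement | None = None
    aerp: dict[float, EpMeasurement] = field(default_factory=dict)
    averp: dict[float, EpMeasurement] = field(default_factory=dict)
    verp: dict[float, EpMeasurement] = field(default_factory=dict)


@dataclass
class InducedEpisode:
    chamber: str
    maneuver_id: int
    onset: float      # ms
    offset: float     # ms
    n_beats: int

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / 1000.0


@dataclass
class InducibilityResult:
    chamber: str
    n_success: int
    n_maneuvers: int
    inducibility_pct: float
    episode_durations_s: list[float]
    mean_episode_duration_s: float
    burden_per_animal_s: float


def basic_cycle_length(log: StimLog) -> float:
    """Basic atrial cycle length from the pre-protocol sinus senses."""
    sinus = [e.time for e in log.events
             if e.kind == "sense" and e.label == "sinus"]
    if len(sinus) < 3:
        raise InsufficientDataError("need >= 3 pre-pacing sinus beats for basic CL")
    return float(np.median(np.diff(sinus)))


def compute_snrt(log: StimLog, drive_cl: float) -> EpMeasurement:
    """Corrected SNRT for one overdrive drive cycle length.

    SNRT_corrected = (first sinus return - last overdrive stimulus) - basic CL.
    Missing sinus return within 5 s is flagged as sinus arrest (censored).
    """
    bcl = basic_cycle_length(log)
    for mid, events in log.by_maneuver().items():
        stims = [e for e in events if e.kind == "stimulus" and e.label == "S1"
                 and e.chamber == "atrium" and e.drive_cl == drive_cl]
        # an SNRT drive is a long uninterrupted S1 train (>= 20 s of pacing)
        if len(stims) < 2 or (stims[-1].time - stims[0].time) < 20000.0:
            continue
        if any(e.kind == "stimulus" and e.label != "S1" for e in events):
            continue
        last = stims[-1].time
        returns = [e for e in events
                   if e.kind == "sense" and e.label == "sinus_return"
                   and e.time > last]
        if not returns:
            return EpMeasurement(value=None, censored="arrest",
                                 warning="no sinus return within timeout")
        ret = returns[0].time
        if ret - last > SINUS_RETURN_TIMEOUT_MS:
            return EpMeasurement(value=None, censored="arrest",
                                 warning="sinus return beyond 5 s timeout")
        return EpMeasurement(value=(ret - last) - bcl)
    raise InsufficientDataError(f"no SNRT overdrive maneuver at {drive_cl} ms")


def _ramp_outcomes(events: list[StimEvent]) -> dict[float, str]:
    """Per-cycle-length conduction outcome of a pacing ramp.

    Returns {cl: '1:1' | '2:1' | 'wenckebach' | 'block'} judged from the
    conducted-response ratio and its alternation pattern.
    """
    by_cl: dict[float, dict[str, list]] = {}
    for e in events:
        if e.drive_cl is None:
            continue
        slot = by_cl.setdefault(e.drive_cl, {"stim": [], "resp": []})
        if e.kind == "stimulus":
            slot["stim"].append(e)
        elif e.label in ("conducted_response", "no_response"):
            slot["resp"].append(e)
    outcomes: dict[float, str] = {}
    for cl, slot in by_cl.items():
        resp = slot["resp"]
        if not slot["stim"] or not resp:
            continue
        conducted = np.array([r.label == "conducted_response" for r in resp])
        ratio = conducted.mean()
        if ratio >= 0.95:
            outcomes[cl] = "1:1"
        elif ratio <= 0.05:
            outcomes[cl] = "block"
        elif abs(ratio - 0.5) <= 0.1 and np.all(conducted[:-1] != conducted[1:]):
            outcomes[cl] = "2:1"
        else:
            outcomes[cl] = "wenckebach"
    return outcomes


def find_conduction_cl(log: StimLog, endpoint: str) -> EpMeasurement:
    """Conduction cycle-length endpoints from pacing ramps.

    endpoint: 'wenckebach' -> longest atrial pacing CL at which 1:1
    conduction first fails; 'two_to_one' -> longest CL showing 2:1
    conduction; 'retrograde' -> longest ventricular pacing CL at which
    retrograde (VA) conduction fails.
    """
    if endpoint not in ("wenckebach", "two_to_one", "retrograde"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    chamber = "ventricle" if endpoint == "retrograde" else "atrium"
    outcomes: dict[float, str] = {}
    for mid, events in log.by_maneuver().items():
        stims = [e for e in events if e.kind == "stimulus"]
        if not stims or any(s.label != "S1" for s in stims):
            continue
        if stims[0].chamber != chamber:
            continue
        cls = {s.drive_cl for s in stims}
        if len(cls) < 2:    # a ramp spans several cycle lengths
            continue
        outcomes.update(_ramp_outcomes(events))
    if not outcomes:
        raise InsufficientDataError(f"no {chamber} pacing ramp in log")
    cls_sorted = sorted(outcomes)
    if endpoint == "wenckebach":
        failing = [cl for cl in cls_sorted if outcomes[cl] != "1:1"]
    elif endpoint == "two_to_one":
        failing = [cl for cl in cls_sorted if outcomes[cl] == "2:1"]
    else:  # retrograde: failure = VA block
        failing = [cl for cl in cls_sorted
                   if outcomes[cl] in ("block", "2:1", "wenckebach")]
    if not failing:
        return EpMeasurement(value=None, censored="below_range",
                             warning=f"{endpoint} endpoint not reached; "
                                     f"< {min(cls_sorted)} ms")
    value = max(failing)
    if value == max(cls_sorted):
        # even the slowest tested rate failed: endpoint above tested range
        return EpMeasurement(value=None, censored="above_range",
                             warning=f"{endpoint} endpoint > {max(cls_sorted)} ms")
    return EpMeasurement(value=float(value))


def compute_erp(log: StimLog, tissue: str, drive_cl: float) -> EpMeasurement:
    """Effective refractory period from an S1/S2 scan.

    ERP = longest coupling interval whose S2 fails — to capture the paced
    chamber (atrium/ventricle) or, for the AV node, to conduct to the
    ventricle despite atrial capture.  Non-monotonic scans resolve to the
    longest failing coupling with a warning.
    """
    if tissue not in ("atrium", "ventricle", "av_node"):
        raise ValueError(f"unknown tissue {tissue!r}")
    chamber = "ventricle" if tissue == "ventricle" else "atrium"
    results: dict[float, bool] = {}  # coupling -> S2 failed?
    for mid, events in log.by_maneuver().items():
        if any(e.kind == "stimulus" and e.label in ("S3", "burst")
               for e in events):
            continue  # induction maneuver, not a refractory scan
        s2s = [e for e in events if e.kind == "stimulus" and e.label == "S2"
               and e.chamber == chamber and e.drive_cl == drive_cl]
        for s2 in s2s:
            senses = [e for e in events if e.kind == "sense"
                      and s2.time <= e.time <= s2.time + 100.0]
            captured = any(e.label == "capture" and e.chamber == chamber
                           for e in senses)
            if tissue == "av_node":
                conducted = any(e.label == "conducted_response"
                                and e.chamber == "ventricle" for e in senses)
                if not captured:
                    continue  # S2 below AERP says nothing about the node
                failed = not conducted
            else:
                failed = not captured
            results[s2.coupling] = failed
    if not results:
        raise InsufficientDataError(
            f"no evaluable S1/S2 scan for {tissue} at drive {drive_cl} ms")
    couplings = sorted(results)
    failing = [c for c in couplings if results[c]]
    if not failing:
        return EpMeasurement(value=None, censored="below_range",
                             warning=f"ERP < {min(couplings)} ms (no failure seen)")
    erp = max(failing)
    warning = None
    if any(not results[c] for c in couplings if c < erp):
        warning = "non-monotonic capture scan; longest failing coupling used"
        warnings.warn(warning)
    if erp == max(couplings):
        return EpMeasurement(value=None, censored="above_range",
                             warning=f"ERP > {max(couplings)} ms (longest coupling failed)")
    return EpMeasurement(value=float(erp), warning=warning)


def detect_induced_episodes(log: StimLog, chamber: str) -> list[InducedEpisode]:
    """Post-stimulation arrhythmia episodes.

    Atrial: a run of atrial ectopic senses spanning >= 3 s.  Ventricular:
    >= 4 consecutive ventricular ectopic senses.  Each episode is linked to
    the maneuver whose senses produced it.
    """
    if chamber not in ("atrium", "ventricle"):
        raise ValueError(f"unknown chamber {chamber!r}")
    label = "atrial_ectopic" if chamber == "atrium" else "ventricular_ectopic"
    episodes: list[InducedEpisode] = []
    for mid, events in log.by_maneuver().items():
        stim_end = max((e.time for e in events if e.kind == "stimulus"),
                       default=None)
        if stim_end is None:
            continue
        ect = [e for e in events if e.kind == "sense" and e.label == label
               and e.time > stim_end]
        if not ect:
            continue
        # split into runs separated by > 500 ms gaps
        times = np.array([e.time for e in ect])
        breaks = np.where(np.diff(times) > 500.0)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(times) - 1]])
        for s, e_i in zip(starts, ends):
            onset, offset = times[s], times[e_i]
            n = int(e_i - s + 1)
            if chamber == "atrium":
                if (offset - onset) / 1000.0 >= ATRIAL_EPISODE_MIN_S:
                    episodes.append(InducedEpisode(chamber, mid, onset, offset, n))
            else:
                if n >= VENTRICULAR_MIN_BEATS:
                    episodes.append(InducedEpisode(chamber, mid, onset, offset, n))
    episodes.sort(key=lambda ep: ep.onset)
    return episodes


def induction_maneuver_ids(log: StimLog, chamber: str) -> list[int]:
    """Maneuvers that attempt arrhythmia induction in a chamber: extra
    stimuli (S2/S3) or burst pacing delivered there."""
    ids = []
    for mid, events in log.by_maneuver().items():
        if any(e.kind == "stimulus" and e.chamber == chamber
               and e.label in ("S2", "S3", "burst") for e in events):
            ids.append(mid)
    return sorted(ids)


def inducibility_and_burden(episodes: list[InducedEpisode],
                            maneuver_ids: list[int],
                            chamber: str) -> InducibilityResult:
    """Inducibility = successful maneuvers / all maneuvers; burden = summed
    episode duration of the animal (seconds)."""
    if not maneuver_ids:
        raise InsufficientDataError("empty maneuver roster")
    eps = [ep for ep in episodes if ep.chamber == chamber
           and ep.maneuver_id in maneuver_ids]
    success = {ep.maneuver_id for ep in eps}
    durations = [ep.duration_s for ep in eps]
    return InducibilityResult(
        chamber=chamber,
        n_success=len(success),
        n_maneuvers=len(maneuver_ids),
        inducibility_pct=100.0 * len(success) / len(maneuver_ids),
        episode_durations_s=durations,
        mean_episode_duration_s=float(np.mean(durations)) if durations else 0.0,
        burden_per_animal_s=float(np.sum(durations)),
    )


def extract_ep_parameters(log: StimLog,
                          drive_cls: tuple = (120.0, 100.0)) -> EpParameters:
    """Full per-animal EP panel from one study log."""
    params = EpParameters()
    for cl in drive_cls:
        try:
            params.snrt_corrected[cl] = compute_snrt(log, cl)
        except InsufficientDataError:
            pass
        for tissue, slot in (("atrium", params.aerp),
                             ("av_node", params.averp),
                             ("ventricle", params.verp)):
            try:
                slot[cl] = compute_erp(log, tissue, cl)
            except InsufficientDataError:
                pass
    for endpoint, attr in (("wenckebach", "wb_cl"),
                           ("two_to_one", "two_to_one_cl"),
                           ("retrograde", "va_cl")):
        try:
            setattr(params, attr, find_conduction_cl(log, endpoint))
        except InsufficientDataError:
            pass
    return params
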