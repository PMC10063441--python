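"""Rule-based detection of spontaneous rhythm disorders from beat annotations.

Four disorder classes of the murine surface ECG are covered:

* sinus arrhythmia — "visibly irregular sinus rhythm" operationalized as a
  10-beat sliding-window coefficient of variation of the sinus RR stream
  above a configurable threshold (default 0.15; this criterion is a choice
  of this package, the visual call it replaces has no formula);
* second-degree AV block type I (Wenckebach) — >= 2 conducted beats with
  strictly increasing PR followed by exactly one non-conducted P wave;
* (intermittent) third-degree AV block — >= 2 consecutive non-conducted
  P waves;
* abnormal spontaneous ventricular activity — >= 4 consecutive
  ventricular-class beats.

Wenckebach and third-degree episodes are disjoint by construction: a single
dropped P after PR prolongation is Wenckebach, two or more consecutive
dropped Ps are third-degree, and an isolated dropped P with no prolongation
is counted under neither subtype by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delineation import BeatFiducials
from .errors import InsufficientDataError, NotEvaluableError

#: Minimum consecutive ventricular beats for abnormal ventricular activity.
VENTRICULAR_RUN_MIN = 4
#: Sliding-window length (beats) and RR coefficient-of-variation threshold
#: for the sinus-arrhythmia criterion.
SA_WINDOW_BEATS = 10
SA_CV_THRESHOLD = 0.15

KINDS = ("sinus_arrhythmia", "avb2_wenckebach", "avb3", "ventricular_activity")


@dataclass
class RhythmEpisode:
    kind: str
    onset: float    # ms
    offset: float   # ms
    n_beats: int

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("episode offset must follow onset")
        if self.kind == "ventricular_activity" and self.n_beats < VENTRICULAR_RUN_MIN:
            raise ValueError("ventricular_activity episodes need >= 4 beats")


@dataclass
class RhythmFindings:
    subject_id: str = ""
    group: str = ""
    episodes: list[RhythmEpisode] = field(default_factory=list)

    @property
    def flags(self) -> dict[str, bool]:
        return {k: any(e.kind == k for e in self.episodes) for k in KINDS}


def _sinus_rr_stream(fiducials: BeatFiducials):
    """RR intervals between adjacent conducted sinus beats.

    An interval is dropped when any other event (ventricular beat or
    non-conducted P) falls inside it, so pauses caused by AV block are
    attributed to the block, not to sinus irregularity.
    """
    beats = fiducials.beats
    sinus_idx = [i for i, b in enumerate(beats) if b.beat_class == "sinus"]
    drops = np.array([e.p_onset for e in fiducials.atrial_events
                      if not e.conducted])
    rr, times = [], []
    for a, b in zip(sinus_idx[:-1], sinus_idx[1:]):
        if b != a + 1:
            continue  # another beat (ventricular/fusion) intervenes
        t0, t1 = beats[a].r_peak, beats[b].r_peak
        if len(drops) and np.any((drops > t0) & (drops < t1)):
            continue  # pause spans a blocked P
        rr.append(t1 - t0)
        times.append(t0)
    return np.array(rr), np.array(times)


def detect_sinus_arrhythmia(fiducials: BeatFiducials,
                            window: int = SA_WINDOW_BEATS,
                            cv_threshold: float = SA_CV_THRESHOLD
                            ) -> list[RhythmEpisode]:
    """Sliding-window irregularity detector on the conducted sinus RR stream."""
    rr, times = _sinus_rr_stream(fiducials)
    if len(rr) < max(window, 30 - 1):
        raise InsufficientDataError("sinus-arrhythmia screening needs >= 30 sinus beats")
    flagged = np.zeros(len(rr), dtype=bool)
    for i in range(len(rr) - window + 1):
        w = rr[i:i + window]
        if np.std(w) / np.mean(w) > cv_threshold:
            flagged[i:i + window] = True
    episodes: list[RhythmEpisode] = []
    i = 0
    while i < len(rr):
        if flagged[i]:
            j = i
            while j + 1 < len(rr) and flagged[j + 1]:
                j += 1
            episodes.append(RhythmEpisode(
                kind="sinus_arrhythmia", onset=float(times[i]),
                offset=float(times[j] + rr[j]), n_beats=j - i + 2))
            i = j + 1
        i += 1
    return episodes


def detect_av_block(fiducials: BeatFiducials,
                    count_unspecified: bool = False) -> list[RhythmEpisode]:
    """Wenckebach (type IIA) and intermittent third-degree AV block episodes.

    Raises NotEvaluableError when the record has no atrial annotations at
    all (absence of evidence, not evidence of absence).
    """
    events = fiducials.atrial_events
    if not events:
        raise NotEvaluableError("no atrial annotations; AV block not evaluable")
    episodes: list[RhythmEpisode] = []
    n = len(events)
    i = 0
    while i < n:
        if events[i].conducted:
            i += 1
            continue
        # run of consecutive non-conducted Ps starting at i
        j = i
        while j + 1 < n and not events[j + 1].conducted:
            j += 1
        run = j - i + 1
        if run >= 2:
            episodes.append(RhythmEpisode(
                kind="avb3", onset=events[i].p_onset,
                offset=(events[j + 1].p_onset if j + 1 < n
                        else events[j].p_onset + 100.0),
                n_beats=run))
        else:
            # single dropped P: Wenckebach if preceded by >= 2 conducted
            # beats with strictly increasing PR
            k = i - 1
            prs = []
            while k >= 0 and events[k].conducted and events[k].pr is not None:
                prs.append(events[k].pr)
                k -= 1
            prs = prs[::-1]
            inc = 0
            for a, b in zip(prs[:-1], prs[1:]):
                inc = inc + 1 if b > a else 0
            run_len = inc + 1 if prs else 0
            if run_len >= 2:
                onset_idx = i - run_len
                episodes.append(RhythmEpisode(
                    kind="avb2_wenckebach", onset=events[onset_idx].p_onset,
                    offset=(events[i + 1].p_onset if i + 1 < n
                            else events[i].p_onset + 100.0),
                    n_beats=run_len + 1))
            elif count_unspecified:
                episodes.append(RhythmEpisode(
                    kind="avb_unspecified", onset=events[i].p_onset,
                    offset=events[i].p_onset + 100.0, n_beats=1))
        i = j + 1
    return episodes


def detect_ventricular_activity(fiducials: BeatFiducials) -> list[RhythmEpisode]:
    """Maximal runs of >= 4 consecutive ventricular-class beats.

    Fusion beats neither extend nor terminate a run: they are transparent
    boundaries and are not counted in n_beats.
    """
    beats = fiducials.beats
    episodes: list[RhythmEpisode] = []
    run: list[int] = []

    def close() -> None:
        if len(run) >= VENTRICULAR_RUN_MIN:
            episodes.append(RhythmEpisode(
                kind="ventricular_activity",
                onset=beats[run[0]].r_peak - 5.0,
                offset=beats[run[-1]].r_peak + 5.0,
                n_beats=len(run)))
        run.clear()

    for i, b in enumerate(beats):
        if b.beat_class == "ventricular":
            run.append(i)
        elif b.beat_class == "fusion":
            continue
        else:
            close()
    close()
    return episodes


def analyze_rhythm(fiducials: BeatFiducials, subject_id: str = "",
                   group: str = "") -> RhythmFindings:
    """All detectors on one record; detectors that cannot run contribute
    no episodes."""
    episodes: list[RhythmEpisode] = []
    for det in (detect_sinus_arrhythmia, detect_av_block,
                detect_ventricular_activity):
        try:
            episodes.extend(det(fiducials))
        except (InsufficientDataError, NotEvaluableError):
            pass
    episodes.sort(key=lambda e: e.onset)
    return RhythmFindings(subject_id=subject_id, group=group, episodes=episodes)


def summarize_prevalence(findings: list[RhythmFindings]) -> pd.DataFrame:
    """Per-group fraction of animals flagged, per disorder kind.

    Returns a tidy frame (group, kind, n_flagged, n_animals, prevalence_pct).
    """
    if not findings:
        raise InsufficientDataError("no findings to summarize")
    rows = []
    by_group: dict[str, list[RhythmFindings]] = {}
    for f in findings:
        by_group.setdefault(f.group, []).append(f)
    for group, members in by_group.items():
        if not members:
            raise InsufficientDataError(f"empty group {group!r}")
        for kind in KINDS:
            n_flag = sum(f.flags[kind] for f in members)
            rows.append({"group": group, "kind": kind, "n_flagged": n_flag,
                         "n_animals": len(members),
                         "prevalence_pct": 100.0 * n_flag / len(members)})
    return pd.DataFrame(rows)
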