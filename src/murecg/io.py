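"""CSV readers and writers for the pipeline's artifact schemas.

All files are comma-separated UTF-8 with '.' decimals and documented
headers; times in ms, voltages in mV, episode durations in seconds.
Schemas:

* ECG trace:        time_ms,voltage_mV
* tachogram:        beat_time_ms,rr_ms,included
* truth/annotation: index,beat_class,conducted,p_onset_ms,p_offset_ms,
                    qrs_onset_ms,r_peak_ms,qrs_offset_ms,t_end_ms
* stimulation log:  time_ms,kind,chamber,label,maneuver_id,drive_cl_ms,
                    coupling_ms

Every reader validates its header and raises SchemaError naming the missing
column.  Round-trips are lossless to the printed precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .delineation import EcgSignal
from .ep import StimLog
from .errors import SchemaError
from .hrv import RRSeries
from .synthetic import SynthTruth, TrueBeat

FLOAT_FMT = "%.6f"


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def write_ecg(signal: EcgSignal, path) -> None:
    df = pd.DataFrame({"time_ms": signal.times_ms,
                       "voltage_mV": signal.samples})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_ecg(path, lead: str = "I", subject_id: str = "",
             group: str = "") -> EcgSignal:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as schema problem
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    _require_columns(df, ["time_ms", "voltage_mV"], path)
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: need >= 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-3 * np.median(dt) + 1e-9:
        raise SchemaError(f"{path}: time_ms must be uniformly increasing")
    fs = 1000.0 / float(np.median(dt))
    return EcgSignal(samples=df["voltage_mV"].to_numpy(dtype=float),
                     sampling_rate=fs, lead=lead, subject_id=subject_id,
                     group=group)


def write_tachogram(rr: RRSeries, path) -> None:
    df = pd.DataFrame({
        "beat_time_ms": rr.beat_times[1:],
        "rr_ms": rr.rr,
        "included": rr.included.astype(int),
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tachogram(path) -> RRSeries:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    _require_columns(df, ["beat_time_ms", "rr_ms"], path)
    end_times = df["beat_time_ms"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    if len(end_times) < 1:
        raise SchemaError(f"{path}: empty tachogram")
    beat_times = np.concatenate([[end_times[0] - rr[0]], end_times])
    included = (df["included"].to_numpy(dtype=bool)
                if "included" in df.columns
                else np.ones(len(rr), dtype=bool))
    return RRSeries(beat_times=beat_times, rr=rr, included=included)


_TRUTH_COLS = ["index", "beat_class", "conducted", "p_onset_ms", "p_offset_ms",
               "qrs_onset_ms", "r_peak_ms", "qrs_offset_ms", "t_end_ms"]


def write_truth(truth: SynthTruth, path) -> None:
    rows = []
    for i, b in enumerate(truth.beats):
        rows.append({"index": i, "beat_class": b.beat_class,
                     "conducted": int(b.conducted),
                     "p_onset_ms": b.p_onset, "p_offset_ms": b.p_offset,
                     "qrs_onset_ms": b.qrs_onset, "r_peak_ms": b.r_peak,
                     "qrs_offset_ms": b.qrs_offset, "t_end_ms": b.t_end})
    pd.DataFrame(rows, columns=_TRUTH_COLS).to_csv(path, index=False,
                                                   float_format=FLOAT_FMT)


def read_truth(path) -> SynthTruth:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    _require_columns(df, _TRUTH_COLS, path)

    def opt(v):
        return None if pd.isna(v) else float(v)

    truth = SynthTruth()
    for r in df.itertuples():
        truth.beats.append(TrueBeat(
            beat_class=str(r.beat_class), conducted=bool(r.conducted),
            p_onset=opt(r.p_onset_ms), p_offset=opt(r.p_offset_ms),
            qrs_onset=opt(r.qrs_onset_ms), r_peak=opt(r.r_peak_ms),
            qrs_offset=opt(r.qrs_offset_ms), t_end=opt(r.t_end_ms)))
    return truth


def write_stimlog(log: StimLog, path) -> None:
    log.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_stimlog(path) -> StimLog:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    _require_columns(df, ["time_ms", "kind", "chamber", "label",
                          "maneuver_id"], path)
    for col in ("drive_cl_ms", "coupling_ms"):
        if col not in df.columns:
            df[col] = np.nan
    return StimLog.from_frame(df)


def write_episodes(findings_or_episodes, path, subject_id: str = "") -> None:
    """Episode CSV: subject,kind,onset_ms,offset_ms,n_beats."""
    episodes = getattr(findings_or_episodes, "episodes", findings_or_episodes)
    subject = getattr(findings_or_episodes, "subject_id", subject_id)
    rows = [{"subject": subject, "kind": e.kind, "onset_ms": e.onset,
             "offset_ms": e.offset, "n_beats": e.n_beats} for e in episodes]
    pd.DataFrame(rows, columns=["subject", "kind", "onset_ms", "offset_ms",
                                "n_beats"]).to_csv(path, index=False,
                                                   float_format=FLOAT_FMT)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
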