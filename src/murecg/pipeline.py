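"""End-to-end study orchestration: simulate -> delineate -> HRV ->
arrhythmia detection -> EP analysis -> group statistics.

A study run is driven by a plain-dict configuration (YAML-friendly; see
``default_config``).  Every random choice derives from the single study
seed through ``numpy.random.SeedSequence``, so a re-run with the same
configuration is bit-identical.  Stage failures are recorded per stage and
do not abort the remaining stages; the bundle carries a nonzero exit code
when anything failed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import arrhythmia, delineation, ep, hrv, io, stats, synthetic
from .errors import MurecgError

__version__ = "0.1.0"

# Surface-ECG morphology ground truth per autonomic state (ms): PR and P
# duration lengthen under MMF (slowed AV/atrial conduction), QRS and QT are
# narcosis-insensitive.
GROUP_MORPHOLOGY = {
    "awake": {"pr": 38.05, "p_dur": 11.65, "qrs_dur": 10.0, "qt": 40.0},
    "mmf": {"pr": 54.01, "p_dur": 18.74, "qrs_dur": 10.0, "qt": 40.0},
    "if": {"pr": 44.43, "p_dur": 12.16, "qrs_dur": 10.0, "qt": 40.0},
}

# Virtual-heart population means per narcosis group (ms / probabilities):
# the MMF heart has sinus-node and AV-node depression (long SNRT, long 2:1
# and VA CLs, long AVERP) while atrial/ventricular refractoriness is shared.
GROUP_HEARTS = {
    "mmf": dict(basic_cl=227.3, snrt_true=315.2, wb_cl_true=88.7,
                two_to_one_cl_true=69.9, va_cl_true=117.6, averp_true=71.4,
                aerp_true=39.0, verp_true=46.4, atrial_induction_prob=0.032,
                ventricular_induction_prob=0.013,
                atrial_episode_s=(26.5, 10.0), ventricular_episode_s=(1.2, 0.4)),
    "if": dict(basic_cl=157.5, snrt_true=178.1, wb_cl_true=79.8,
               two_to_one_cl_true=55.3, va_cl_true=90.7, averp_true=53.9,
               aerp_true=41.1, verp_true=45.3, atrial_induction_prob=0.047,
               ventricular_induction_prob=0.0,
               atrial_episode_s=(9.5, 2.5), ventricular_episode_s=(1.2, 0.4)),
}


def default_config() -> dict:
    """Desk-scale three-group synthetic study configuration.

    Group sizes follow the telemetry/narcosis design (7 awake, 10 MMF,
    12 IF); the MMF disorder roster injects sinus arrhythmia in 9/10,
    AV block in 5/10 and ventricular runs in 3/10 animals.  Records are
    120 s at 1 kHz (a desk-scale stand-in for 5-min telemetry windows).
    """
    return {
        "seed": 1,
        "duration_s": 120.0,
        "sampling_rate_hz": 1000.0,
        "synthesize_ecg": True,
        "ep_enabled": True,
        "groups": [
            {"name": "awake", "preset": "awake", "n": 7},
            {"name": "mmf", "preset": "mmf", "n": 10,
             "disorders": {"sinus_arrhythmia": 9, "avb": 5,
                           "ventricular_run": 3}},
            {"name": "if", "preset": "if", "n": 12},
        ],
        "ep_groups": ["mmf", "if"],
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _animal_seed(ss: np.random.SeedSequence, *key: int) -> int:
    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(key))
    return int(child.generate_state(1)[0] % (2 ** 31))


def _simulate_animal(group_cfg: dict, idx: int, seed: int, config: dict):
    """One animal's tachogram, ground truth and (optionally) ECG trace."""
    preset = synthetic.get_preset(group_cfg["preset"], seed=seed)
    rr = synthetic.generate_rr_series(preset, config["duration_s"])
    morph = GROUP_MORPHOLOGY.get(group_cfg["preset"], None)
    truth = synthetic.truth_from_rr(rr, morphology=morph)

    disorders = group_cfg.get("disorders", {})
    n_beats = len(truth.beats)
    rng = np.random.default_rng(seed + 7)
    if idx < disorders.get("sinus_arrhythmia", 0):
        start = int(0.2 * n_beats)
        truth = synthetic.inject_sinus_arrhythmia(
            truth, start_index=start, n_beats=min(60, n_beats - start - 2),
            seed=seed + 11)
    if idx < disorders.get("avb", 0):
        mid = int(0.55 * n_beats)
        if idx % 2 == 0:
            truth = synthetic.inject_wenckebach(truth, start_index=mid,
                                                n_cycles=3)
        else:
            truth = synthetic.inject_avb3(truth, start_index=mid, n_blocked=3,
                                          n_runs=2)
    if idx < disorders.get("ventricular_run", 0):
        start = int(0.85 * n_beats)
        truth = synthetic.inject_ventricular_run(
            truth, start_index=start, length=4 + int(rng.integers(0, 3)))

    signal = None
    if config.get("synthesize_ecg", True):
        signal, truth = synthetic.synthesize_ecg(
            truth, sampling_rate=config["sampling_rate_hz"])
    return rr, truth, signal


def _make_heart(group: str, seed: int) -> synthetic.VirtualHeartParams:
    base = GROUP_HEARTS[group]
    rng = np.random.default_rng(seed)
    jitter = {k: float(max(1.0, base[k] + rng.normal(0, 0.05 * base[k])))
              for k in ("basic_cl", "snrt_true", "wb_cl_true",
                        "two_to_one_cl_true", "va_cl_true", "averp_true",
                        "aerp_true", "verp_true")}
    if jitter["two_to_one_cl_true"] >= jitter["wb_cl_true"]:
        jitter["two_to_one_cl_true"] = jitter["wb_cl_true"] - 5.0
    return synthetic.VirtualHeartParams(
        **jitter,
        atrial_induction_prob=base["atrial_induction_prob"],
        ventricular_induction_prob=base["ventricular_induction_prob"],
        atrial_episode_s=base["atrial_episode_s"],
        ventricular_episode_s=base["ventricular_episode_s"],
        seed=seed)


def run_study(config: dict | None = None, outdir=None) -> dict:
    """Run the full synthetic study; returns the results bundle.

    The bundle maps stage names to status ('ok'/'failed: ...'), carries the
    group tables as DataFrames, and ``exit_code`` (0 iff every stage ran).
    When ``outdir`` is given, per-animal artifacts, group tables, a JSON
    summary and a run manifest are written there.
    """
    config = config or default_config()
    ss = np.random.SeedSequence(int(config["seed"]))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        io.ensure_dir(out)
    bundle: dict = {"stages": {}, "tables": {}, "exit_code": 0}

    ecg_rows, hrv_rows, findings = [], [], []
    ep_rows, induc_rows = [], []

    for gi, gcfg in enumerate(config["groups"]):
        for ai in range(int(gcfg["n"])):
            subject = f"{gcfg['name']}-{ai + 1:02d}"
            seed = _animal_seed(ss, gi, ai)
            try:
                rr, truth, signal = _simulate_animal(gcfg, ai, seed, config)
            except MurecgError as exc:
                bundle["stages"][f"simulate:{subject}"] = f"failed: {exc}"
                bundle["exit_code"] = 1
                continue
            bundle["stages"].setdefault("simulate", "ok")
            if out is not None:
                adir = io.ensure_dir(out / "animals" / subject)
                io.write_tachogram(rr, adir / "tachogram.csv")
                io.write_truth(truth, adir / "truth.csv")
                if signal is not None:
                    io.write_ecg(signal, adir / "ecg.csv")

            # --- surface-ECG intervals ---
            try:
                if signal is not None:
                    r_peaks = delineation.detect_r_peaks(signal)
                    fid = delineation.delineate_beats(signal, r_peaks)
                else:
                    fid = delineation.fiducials_from_truth(truth)
                window = (0.0, config["duration_s"] * 1000.0 + 1000.0)
                iv = delineation.measure_intervals(fid, window)
                ecg_rows.append({"subject": subject, "group": gcfg["name"],
                                 "heart_rate_bpm": iv.heart_rate,
                                 "pr_ms": iv.pr, "p_duration_ms": iv.p_duration,
                                 "qrs_ms": iv.qrs, "qt_ms": iv.qt,
                                 "qtc_ms": iv.qtc, "n_beats": iv.n_beats})
                bundle["stages"].setdefault("ecg", "ok")
            except MurecgError as exc:
                bundle["stages"][f"ecg:{subject}"] = f"failed: {exc}"
                bundle["exit_code"] = 1
                fid = delineation.fiducials_from_truth(truth)

            # --- HRV on the tachogram ---
            try:
                row = hrv.analyze(rr)
                row.update({"subject": subject, "group": gcfg["name"]})
                hrv_rows.append(row)
                bundle["stages"].setdefault("hrv", "ok")
            except MurecgError as exc:
                bundle["stages"][f"hrv:{subject}"] = f"failed: {exc}"
                bundle["exit_code"] = 1

            # --- arrhythmia detection on truth-grade fiducials ---
            try:
                truth_fid = delineation.fiducials_from_truth(truth)
                f = arrhythmia.analyze_rhythm(truth_fid, subject_id=subject,
                                              group=gcfg["name"])
                findings.append(f)
                if out is not None:
                    io.write_episodes(f, out / "animals" / subject / "episodes.csv")
                bundle["stages"].setdefault("arrhythmia", "ok")
            except MurecgError as exc:
                bundle["stages"][f"arrhythmia:{subject}"] = f"failed: {exc}"
                bundle["exit_code"] = 1

            # --- EP study ---
            if config.get("ep_enabled", True) and \
                    gcfg["name"] in config.get("ep_groups", []):
                try:
                    heart = _make_heart(gcfg["name"], _animal_seed(ss, gi, ai, 1))
                    log = synthetic.simulate_ep_responses(
                        heart, synthetic.standard_protocol())
                    if out is not None:
                        io.write_stimlog(log, out / "animals" / subject / "stimlog.csv")
                    params = ep.extract_ep_parameters(log)
                    row = {"subject": subject, "group": gcfg["name"]}
                    for cl, m in params.snrt_corrected.items():
                        row[f"snrt_c_{int(cl)}_ms"] = m.value
                    for name, meas in (("wb_cl_ms", params.wb_cl),
                                       ("two_to_one_cl_ms", params.two_to_one_cl),
                                       ("va_cl_ms", params.va_cl)):
                        row[name] = meas.value if meas else None
                    for label, slot in (("aerp", params.aerp),
                                        ("averp", params.averp),
                                        ("verp", params.verp)):
                        for cl, m in slot.items():
                            row[f"{label}_{int(cl)}_ms"] = m.value
                    ep_rows.append(row)
                    for chamber in ("atrium", "ventricle"):
                        eps = ep.detect_induced_episodes(log, chamber)
                        roster = ep.induction_maneuver_ids(log, chamber)
                        res = ep.inducibility_and_burden(eps, roster, chamber)
                        induc_rows.append({
                            "subject": subject, "group": gcfg["name"],
                            "chamber": chamber, "n_success": res.n_success,
                            "n_maneuvers": res.n_maneuvers,
                            "inducibility_pct": res.inducibility_pct,
                            "mean_episode_duration_s": res.mean_episode_duration_s,
                            "burden_s": res.burden_per_animal_s})
                    bundle["stages"].setdefault("ep", "ok")
                except MurecgError as exc:
                    bundle["stages"][f"ep:{subject}"] = f"failed: {exc}"
                    bundle["exit_code"] = 1

    tables = bundle["tables"]
    tables["ecg_parameters"] = pd.DataFrame(ecg_rows)
    tables["hrv_parameters"] = pd.DataFrame(hrv_rows)
    if findings:
        tables["arrhythmia_prevalence"] = arrhythmia.summarize_prevalence(findings)
    if ep_rows:
        tables["ep_parameters"] = pd.DataFrame(ep_rows)
        tables["inducibility"] = pd.DataFrame(induc_rows)

    # --- group statistics ---
    try:
        tables["comparisons"] = _compare_groups(tables)
        bundle["stages"].setdefault("stats", "ok")
    except MurecgError as exc:
        bundle["stages"]["stats"] = f"failed: {exc}"
        bundle["exit_code"] = 1

    if out is not None:
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
        manifest = {"config": config, "config_sha256": _config_hash(config),
                    "seed": int(config["seed"]), "version": __version__,
                    "stages": bundle["stages"],
                    "n_animals": sum(int(g["n"]) for g in config["groups"])}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
        summary = {
            name: json.loads(df.to_json(orient="records"))
            for name, df in tables.items()}
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
    return bundle


def _compare_groups(tables: dict) -> pd.DataFrame:
    """Three-group ANOVA/Tukey on ECG and HRV parameters, two-group
    comparisons on EP parameters, chi-square on prevalence."""
    rows = []
    for tab, params in (("ecg_parameters",
                         ["heart_rate_bpm", "pr_ms", "p_duration_ms",
                          "qrs_ms", "qtc_ms"]),
                        ("hrv_parameters",
                         ["median_rr", "sdrr", "rmssd", "prr50", "vlf_pct",
                          "lf_pct", "hf_pct", "lf_hf", "sd1", "sd2"])):
        df = tables.get(tab)
        if df is None or df.empty:
            continue
        groups = sorted(df["group"].unique())
        if len(groups) != 3:
            continue
        for param in params:
            samples = [stats.GroupSample(group=g,
                                         values=df.loc[df.group == g, param]
                                         .dropna().to_numpy(),
                                         parameter=param)
                       for g in groups]
            try:
                res = stats.compare_three(samples)
            except MurecgError:
                continue
            rows.append({"parameter": param, "groups": "|".join(groups),
                         "test": res.test_used, "statistic": res.statistic,
                         "p_value": res.p_value,
                         "stars": stats.significance_stars(res.p_value)})
    df = tables.get("ep_parameters")
    if df is not None and not df.empty:
        groups = sorted(df["group"].unique())
        if len(groups) == 2:
            for param in [c for c in df.columns
                          if c not in ("subject", "group")]:
                a, b = (stats.GroupSample(group=g,
                                          values=df.loc[df.group == g, param]
                                          .dropna().to_numpy(),
                                          parameter=param)
                        for g in groups)
                try:
                    res = stats.compare_two(a, b)
                except MurecgError:
                    continue
                rows.append({"parameter": param, "groups": "|".join(groups),
                             "test": res.test_used, "statistic": res.statistic,
                             "p_value": res.p_value,
                             "stars": stats.significance_stars(res.p_value)})
    prev = tables.get("arrhythmia_prevalence")
    if prev is not None and not prev.empty:
        for kind in prev["kind"].unique():
            sub = prev[prev.kind == kind]
            if len(sub) < 2:
                continue
            try:
                res = stats.compare_proportions(sub.n_flagged.tolist(),
                                                sub.n_animals.tolist())
            except MurecgError:
                continue
            rows.append({"parameter": f"prevalence:{kind}",
                         "groups": "|".join(sub.group), "test": res.test_used,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "stars": stats.significance_stars(res.p_value)})
    return pd.DataFrame(rows, columns=["parameter", "groups", "test",
                                       "statistic", "p_value", "stars"])
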