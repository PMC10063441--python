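# murecg

Quantitative cardiac electrophysiology for the mouse: surface-ECG interval
measurement, heart-rate-variability (HRV) analysis, rule-based arrhythmia
detection, and invasive programmed-electrical-stimulation (EP study)
parameter extraction — together with a synthetic generator that produces
annotated ECG/RR data and a virtual heart with known ground truth, so every
analysis stage can be validated by recovery.

The package is aimed at small-animal electrophysiology labs comparing
cardiac phenotypes across conditions (here: awake telemetry versus two
anesthesia regimens, injectable medetomidine–midazolam–fentanyl "MMF" and
inhalational isoflurane–fentanyl "IF"), and at anyone who needs murine HRV
and EP analysis with explicit, testable definitions.

## What it computes

**Surface ECG** (from a single-lead trace): R-peak detection
(band-pass + derivative-energy threshold, 20 ms refractory lockout),
P/QRS/T delineation, and window-averaged heart rate, PR, P duration, QRS
and QT. QT is rate-corrected with the murine normalization

    QTc = QT / sqrt(RR / 100 ms)

**HRV** (from the RR tachogram `RR_n`, `n = 1…N`):

* time domain — average RR, median RR, SDRR, SDSD, RMSSD, and pRR50
  (percentage of successive differences strictly longer than 50 ms);
* frequency domain — the normalized Lomb periodogram computed directly from
  the unevenly sampled tachogram, integrated over the murine bands
  VLF 0–0.15 Hz, LF 0.15–1.5 Hz, HF 1.5–5 Hz, reported as percentages of
  the 0–5 Hz total plus the LF/HF ratio;
* nonlinear — Poincaré SD1/SD2 about the identity line RR(n) = RR(n+1):
  SD1 = SD[(RR_n − RR_n+1)/√2], SD2 = SD[(RR_n + RR_n+1)/√2].

**Arrhythmia detection** (from beat-level annotations): sinus arrhythmia
(sliding-window RR coefficient of variation), Wenckebach AV block
(progressively prolonging PR ending in a dropped P), intermittent
third-degree AV block (≥ 2 consecutive non-conducted P waves), and abnormal
spontaneous ventricular activity (≥ 4 consecutive ventricular beats), plus
per-group prevalence tables.

**EP study** (from a stimulus/response log): corrected sinus node recovery
time (SNRT − basic cycle length) after 30 s overdrive drives at 120 and
100 ms; Wenckebach, 2:1 and retrograde (VA) conduction cycle lengths from
pacing ramps; atrial, AV-nodal and ventricular effective refractory periods
from S1/S2 scans (ERP = longest failing coupling); induced-episode
detection (atrial ≥ 3 s, ventricular ≥ 4 beats), inducibility percentage
and arrhythmia burden.

**Group statistics**: mean ± s.e.m. summaries; D'Agostino–Pearson-gated
two-sided t-test / Mann–Whitney for two groups; one-way ANOVA with Tukey
HSD for three; chi-square (no continuity correction) for prevalence and
inducibility; α = 0.05.

## Worked example

Simulate five minutes of MMF-state RR intervals and analyze them:

```
$ murecg simulate --preset mmf --duration 300 --seed 11 --no-ecg --out demo
wrote 1255 intervals to demo
$ murecg analyze-hrv demo/tachogram.csv
{
  "average_rr": 239.2139830541833,
  "median_rr": 227.946675,
  "sdrr": 67.29682547612005,
  "sdsd": 126.88466038777305,
  "rmssd": 126.83407885600295,
  "prr50": 90.1116427432217,
  "sd1": 89.68522272898296,
  "sd2": 31.74783657815369,
  "vlf_pct": 0.7774307452925892,
  "lf_pct": 3.479362762966697,
  "hf_pct": 95.74320649174072,
  "lf_hf": 0.03634057068338153
}
```

The MMF preset emulates deep injectable narcosis: a long median RR
(~228 ms, i.e. severe bradycardia), very large beat-to-beat variability
(RMSSD ~127 ms, pRR50 ~90%), a spectrum dominated by the high-frequency
band (HF ~96%) and a collapsed LF/HF ratio — the signature of a strongly
vagal-dominant autonomic state. The `awake` preset (median RR ~126 ms,
mixed VLF/LF/HF) and `if` preset (~157 ms, awake-like variability) complete
the three study conditions.

A full synthetic study (three groups, 29 animals, ECG + HRV + arrhythmia +
EP + statistics, reproducible from one seed):

```
murecg run-study --seed 1 --out study_out
```

writes per-animal artifacts, group tables for every derived parameter, a
comparison table with significance stars, and a run manifest.

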