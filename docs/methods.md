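# Methods

This note documents the models, conventions and numerical choices behind
`murecg`, and what the synthetic generator does and does not emulate.

## Synthetic RR generation

RR series are produced by direct interval-domain modulation evaluated at
cumulative beat time (a point-process construction):

    RR_i = mean_rr * (1 + a_LF sin(2π f_LF t_i + φ_LF)
                        + a_HF sin(2π f_HF t_i + φ_HF)
                        + a_W  sin(2π 0.05 t_i + φ_W)) + ε_i

with `t_i` the time of the beat opening interval i, phases drawn once per
record from the preset seed, and ε white Gaussian noise (ms). The wander
term at a fixed 0.05 Hz supplies very-low-frequency power. Amplitudes are
fractions of the mean RR and must sum below 1 so intervals stay positive;
`f_LF` must lie in the murine LF band (0.15–1.5 Hz) and `f_HF` in the HF
band (1.5–5 Hz). An integral-pulse-frequency-modulation oscillator was
deliberately not used: interval-domain modulation is simpler, exactly
invertible for testing, and preserves spectral peak location at the
tolerances that matter here.

### Autonomic presets

The three presets are calibrated so that the *analysis pipeline itself*
(ECG synthesis → R detection → HRV) reproduces the target group statistics
of the three autonomic states:

| preset | mean RR | a_LF | f_LF | a_HF | f_HF | a_W | noise | targets |
|--------|--------:|-----:|-----:|-----:|-----:|----:|------:|---------|
| awake  | 126.1 ms | 0.034 | 0.5 Hz | 0.044 | 2.5 Hz | 0.030 | 2 ms | median RR ≈ 126 ms, VLF/LF/HF ≈ 20/28/52 %, LF/HF ≈ 0.55 |
| mmf    | 227.3 ms | 0.080 | 0.5 Hz | 0.420 | 2.0 Hz | 0.010 | 3 ms | median RR ≈ 227 ms, RMSSD ≈ 130 ms, pRR50 ≫ others, HF > 80 %, smallest LF/HF |
| if     | 157.5 ms | 0.031 | 0.5 Hz | 0.046 | 2.5 Hz | 0.028 | 2 ms | median RR ≈ 157 ms, awake-like variability |

The MMF preset's large HF amplitude at a slow beat rate produces the
vagal-dominant phenotype: successive-difference statistics (RMSSD, pRR50,
SD1) blow up while the spectrum concentrates in the HF band.

What the generator does **not** emulate: respiratory-cardiac coupling as a
physiological oscillator (tones are fixed-frequency sinusoids), circadian
drift, movement artifact, electrode noise spectra coloured like real
telemetry, or heart-rhythm fragmentation. Passing tests therefore
demonstrate correctness of the *analysis definitions* and recoverability
of known structure — not robustness to every pathology of real recordings.

### Aliasing caveat

A tachogram is sampled at the beats themselves, so a modulation at `f`
also appears at the beat-rate mirror `1/RR − f`, and uneven sampling
spreads a broadband pedestal that grows toward high frequency. At MMF-like
rates the mirror of an HF tone can fall back inside the HF band; at a
150 ms mean RR the mirror of a 3 Hz tone (3.67 Hz) does too, which biases
integrated LF/HF below the naive two-tone expectation even when the two
Lomb *peaks* are equal to within a percent. Tests therefore compare band
integrals against the independent direct-formula oracle rather than
against idealized ratios.

## ECG synthesis and delineation

Templates are compact-support raised-cosine (sin²) lobes — P and T as
symmetric lobes over [onset, offset], the QRS as an asymmetric spike (rise
to R, fall to offset), amplitudes 0.2 / 1.0 / 0.3 mV. No Q/S separation is
modeled; the fiducials are the authoritative ground truth and the
morphology is cosmetic. Compact support means true iso-electric baseline
between waves, which keeps threshold delineation well-posed. Default
sampling 2 kHz (≥ 1 kHz enforced: a ~10 ms murine QRS must be resolvable).

The R detector band-passes (10 Hz – min(300, 0.45·fs)), squares the
derivative, smooths 5 ms, thresholds at 25 % of the 99.5th percentile of
the energy envelope (QRS has a small duty cycle, so that percentile sits on
the QRS peaks) and enforces a 20 ms lockout (murine rates reach 800 bpm).

Delineation walks outward from each wave peak to a threshold crossing and
then debiases the crossing by tangent extrapolation to baseline. Noise is
estimated robustly from first differences and propagated through the
Savitzky–Golay smoothing actually applied (3 ms for QRS; 9 ms for P and
5 ms for T when the noise floor exceeds 0.02 mV). T-end uses the tangent
method at the steepest point of the descending limb; on rounded T waves
this lands slightly early, which is why tests allow 5 ms for QT against
2 ms for PR/P/QRS on noise-free records. Beat classification: a QRS with a
P onset 12–80 ms before QRS onset is sinus; a QRS with no such P is
ventricular; a P-like lobe with no QRS within 100 ms is a non-conducted
atrial event. Fusion beats are taken from synthetic truth only — automatic
fusion calling is out of scope. Interval reporting averages conducted
sinus beats over a half-open window `[start, end)` and requires ≥ 10 of
them; heart rate is 60000 / mean RR of the window.

QTc uses the murine normalization RR₀ = 100 ms (QTc = QT·√(100/RR)); the
constant is stated here because published murine work typically cites the
convention rather than the formula.

## HRV conventions

* SDRR/SDSD are reported with the sample (n−1) convention; the Poincaré
  SD1/SD2 default to the population convention so the identities
  SD1² = SDSD²_pop/2 and SD1² + SD2² = Var(RR_n) + Var(RR_n+1) hold
  exactly (a `ddof` argument exposes the alternative).
* pRR50 counts |ΔRR| **strictly** greater than 50 ms, in absolute ms
  (scale-equivariance of the SD-type statistics does not extend to the
  fixed 50 ms threshold — a documented asymmetry).
* The Lomb periodogram is the classical normalized form
  P(f) = [ … ]/(2σ²) with σ² the population variance of the mean-subtracted
  tachogram, evaluated with `scipy.signal.lombscargle` (verified against a
  direct evaluation of the formula to < 1e−8 relative). Default grid:
  0.005 Hz steps over (0, 5] Hz. A constant tachogram is flagged
  degenerate; band percentages then raise rather than return 0/0.
* Band percentages are normalized to the VLF+LF+HF (0–5 Hz) total, so the
  three printed percentages sum to 100; LF/HF is their ratio.
* Intervals adjacent to non-sinus beats are mask-excluded from time-domain
  and Poincaré statistics by default (toggle via the `included` mask).

## Arrhythmia detector rules

* **Sinus arrhythmia** — the underlying published definition is a visual
  call ("visibly irregular sinus rhythm"); this package operationalizes it
  as a 10-beat sliding-window coefficient of variation of the conducted
  sinus RR stream exceeding 0.15. Both window and threshold are exposed;
  the criterion is this package's choice, not a literature constant.
  Intervals spanning a blocked P or an ectopic beat are removed from the
  stream first, so AV-block pauses are attributed to block, not to sinus
  irregularity.
* **Wenckebach (II°A)** — ≥ 2 conducted beats with strictly increasing PR
  followed by exactly one non-conducted P; the ≥ 2 floor is the minimum
  observable periodicity.
* **Third-degree (intermittent)** — ≥ 2 consecutive non-conducted P waves.
  One consecutive run is one episode; a dropped P belongs to at most one
  episode, so the two block subtypes are disjoint by construction. An
  isolated dropped P with no PR prolongation is classed unspecified and
  counted under neither subtype by default (`count_unspecified` toggles).
* **Ventricular activity** — maximal runs of ≥ 4 consecutive
  ventricular-class beats; fusion beats neither extend nor terminate a run.

## Virtual heart and EP analysis

Conduction in the virtual heart is threshold-deterministic: an S2 captures
iff coupling > tissue ERP; atrial pacing conducts 1:1 iff CL > WB CL, 3:2
Wenckebach-type between WB CL and 2:1 CL, 2:1 at or below it; ventricular
pacing conducts retrogradely iff CL > VA CL; the first sinus return after
overdrive comes exactly SNRT ms after the last stimulus. Only induction
success (Bernoulli per maneuver) and episode duration (Gaussian, floored
at the qualifying duration) are stochastic. This makes every panel
parameter exactly recoverable up to protocol step size while preserving
realistic inducibility statistics.

Analyzer conventions (shared with the simulator so recovery is exact):

* ERP = the longest *failing* coupling (equivalently last-captured + one
  step). Non-monotonic scans resolve to the longest failing coupling with
  a logged warning.
* WB CL = longest pacing CL at which 1:1 conduction first fails; 2:1 CL =
  longest CL showing a strict alternating pattern (first occurrence, not
  stable persistence); VA CL = longest ventricular pacing CL with
  retrograde block, so a larger VA CL means worse retrograde conduction.
* Parameters outside the tested range are censored
  (`below_range`/`above_range`/`arrest`), never extrapolated. An AV-nodal
  ERP at or below the atrial ERP is unobservable by an atrial S1/S2 scan
  and is censored `below_range`.
* Corrected SNRT = (first sinus return − last stimulus) − basic cycle
  length, with the basic CL measured from pre-pacing sinus senses; no
  return within 5 s is flagged sinus arrest.
* Induced episodes: atrial runs qualify at ≥ 3 s span; ventricular runs at
  ≥ 4 consecutive ectopic senses. Inducibility = successful maneuvers /
  all maneuvers; burden = summed episode seconds per animal (cohort totals
  sum animals; per-animal means are reported over all animals of a group,
  with an inducible-only summary available, since the two denominators are
  genuinely different quantities).

## Statistics

Two-group comparisons apply a per-group D'Agostino–Pearson gate at
α = 0.05 with both-must-pass → two-sided t-test, otherwise two-sided
Mann–Whitney. The normality test requires n ≥ 8; smaller groups (common at
7–12 animals/group) fall back to Mann–Whitney, which is conservative.
Three groups use one-way ANOVA with Tukey HSD. Prevalence/inducibility
tables use Pearson chi-square without continuity correction (the common
Prism default; a Yates toggle exists). No multiplicity correction is
applied across parameters. Null simulations (n = 10/group, 2000 repeats)
put the empirical type-I error of both gated procedures within
[3.5 %, 6.5 %] at nominal 5 %.

## Study orchestration and problem sizes

`run_study` derives every per-animal seed from the single study seed via
`numpy.random.SeedSequence`, writes all artifacts with fixed float
formatting, and stamps a manifest (config hash, seeds, version, per-stage
status) with no timestamps — re-runs are bit-identical. The default
configuration uses 7/10/12 animals (awake/MMF/IF), 120 s records at 1 kHz,
and an MMF disorder roster of 9/10 sinus arrhythmia, 5/10 AV block, 3/10
ventricular runs; these desk-scale record lengths keep a full study run
under a minute while leaving every estimator comfortably inside its
asymptotic regime (the acceptance script uses 300 s records where medians
and band fractions are compared against calibration targets). Note that
the MMF preset's intrinsic variability itself exceeds the sinus-arrhythmia
criterion, so MMF prevalence reads 100 % in the default study even though
the injection roster says 9/10 — the detector is reporting the phenotype,
not the injection.

## Known limitations

* Single-lead analysis only; no inter-lead harmonization (lead I vs II).
* No adjudication model for ambiguous delineation (the published
  equivalent was a two-cardiologist visual read).
* Detector thresholds (sinus-arrhythmia CV, P-wave amplitude floors) are
  tuned on the synthetic morphology; real telemetry will need re-tuning.
* The virtual heart is a threshold automaton, not a tissue model: no rate
  adaptation of refractoriness, no decremental AV-nodal conduction curve,
  no spontaneous (non-paced) arrhythmia in the EP simulator.
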